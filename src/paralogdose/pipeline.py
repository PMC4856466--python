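"""End-to-end orchestration and machine-readable reporting.

``run_pipeline`` chains the stages — offset computation, fragment
collapsing (when a fragment map is supplied), low-expression filtering,
the three differential-expression contrasts, pooling, paralog preference,
specificity classification, ChIP-seq integration and abundance estimation
— and returns a JSON-serializable report containing every intermediate
summary, the configuration echo and the seed.  In simulation mode the
report additionally scores the classifier against the planted truth.

All randomness flows through the single simulation seed, so a fixed
configuration reproduces its report byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import abundance, chip, expression, preference, simulate, specificity
from .errors import ConfigurationError, DataError
from .simulate import SimulationConfig


@dataclass
class RunConfig:
    """Configuration for a full pipeline run.

    Thresholds default to the standard analysis values: 1.5-fold change at
    p < 0.05 for regulation, a 1.2-fold ceiling for the unaffected contrast
    in specificity calls, 3-fold enrichment at p < 5e-5 for peak calling
    and a +/- 10 kb TSS window for peak-to-gene assignment.
    """

    simulate: bool = True
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    seed: int | None = None  # overrides sim.seed when set

    # real-data inputs (used when simulate is False)
    matrix_path: str | None = None
    fragment_map_path: str | None = None
    mfi_path: str | None = None
    peak_paths: dict | None = None  # genotype -> BED path
    tss_path: str | None = None

    # thresholds
    fc: float = 1.5
    fc_ceiling: float = 1.2
    p: float = 0.05
    peak_fe: float = 3.0
    peak_p: float = 5e-5
    tss_window: int = 10_000
    peak_thresholds: tuple = (5.0, 12.0, 25.0, 55.0)

    # paralog expression inputs for the mRNA abundance estimate
    mrna_a: float = 15.0
    mrna_b: float = 30.0

    def __post_init__(self) -> None:
        for name in ("fc", "fc_ceiling", "p", "peak_fe", "peak_p", "tss_window"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"threshold {name} must be positive")
        if not self.simulate and self.matrix_path is None:
            raise ConfigurationError(
                "simulate=False requires an expression matrix path"
            )

    @property
    def effective_seed(self) -> int:
        return self.sim.seed if self.seed is None else self.seed

    def sim_config(self) -> SimulationConfig:
        if self.seed is None:
            return self.sim
        return dataclasses.replace(self.sim, seed=self.seed)


def _json_safe(obj):
    if isinstance(obj, dict):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        value = float(obj)
        return value if np.isfinite(value) else None
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return [_json_safe(v) for v in obj.tolist()]
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the report dictionary."""
    report: dict = {
        "config": _json_safe(dataclasses.asdict(config)),
        "seed": config.effective_seed,
    }

    truth = None
    if config.simulate:
        sim_cfg = config.sim_config()
        matrix, truth = simulate.generate_expression(sim_cfg)
        fragment_map = None
    else:
        matrix = expression.ExpressionMatrix.from_tsv(config.matrix_path)
        fragment_map = None
        if config.fragment_map_path:
            fm = pd.read_csv(config.fragment_map_path, sep="\t")
            fragment_map = dict(zip(fm["fragment_id"], fm["gene_id"]))

    report["n_input"] = matrix.n_genes

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        offset = expression.compute_offset(matrix)
    report["offset"] = offset
    report["offset_warnings"] = [str(w.message) for w in caught]

    if fragment_map is not None:
        matrix = expression.collapse_fragments(matrix, fragment_map)
    report["n_after_collapse"] = matrix.n_genes

    matrix = expression.filter_low_expression(matrix)
    report["n_after_filter"] = matrix.n_genes
    if matrix.n_genes == 0:
        raise DataError("no genes survive the low-expression filter")

    matrix = expression.apply_offset(matrix, offset)

    de_kwargs = dict(fc_threshold=config.fc, p_threshold=config.p)
    de_a = expression.compute_de(matrix, "A-KO", "WT", **de_kwargs)
    de_b = expression.compute_de(matrix, "B-KO", "WT", **de_kwargs)
    de_ab = expression.compute_de(matrix, "A-KO", "B-KO", **de_kwargs)
    report["n_regulated_a"] = int(de_a.table["regulated"].sum())
    report["n_regulated_b"] = int(de_b.table["regulated"].sum())

    pooled = expression.pool_regulated(de_a, de_b)
    report["n_pooled"] = len(pooled)

    if len(pooled):
        records = preference.build_preference_records(de_a, de_b, pooled)
        hist = preference.bin_preferences(records)
        report["preference"] = hist.to_dict()

        thresholds = specificity.SpecificityThresholds(
            fc=config.fc, fc_ceiling=config.fc_ceiling, p=config.p
        )
        calls = specificity.classify_specificity(
            de_a, de_b, de_ab, genes=pooled, thresholds=thresholds
        )
        report["specificity"] = _json_safe(specificity.summarize_specificity(calls))
        if truth is not None and truth.genes is not None:
            report["classifier_vs_truth"] = _json_safe(
                specificity.score_against_truth(calls, truth.genes)
            )
    else:
        report["preference"] = None
        report["specificity"] = None

    # ------------------------------------------------------------- ChIP-seq
    peak_sets = None
    tss = None
    if config.simulate:
        peak_sets, peak_truth = simulate.generate_peaks(
            config.sim_config(), thresholds=config.peak_thresholds
        )
        tss = peak_truth.tss
    elif config.peak_paths and config.tss_path:
        peak_sets = {
            genotype: chip.read_peaks_bed(path)
            for genotype, path in config.peak_paths.items()
        }
        tss = chip.read_tss_table(config.tss_path)

    if peak_sets is not None:
        filtered = {
            g: chip.filter_called_peaks(p, config.peak_fe, config.peak_p)
            for g, p in peak_sets.items()
        }
        report["peak_counts"] = {g: int(len(p)) for g, p in filtered.items()}
        per_peak, hist_df = chip.tss_localization(filtered["WT"], tss)
        report["pct_peaks_within_10kb"] = float(
            100.0 * (per_peak["distance"].abs() < config.tss_window).mean()
        )
        report["tss_localization"] = _json_safe(hist_df.to_dict(orient="list"))
        report["peak_overlap"] = _json_safe(
            chip.overlap_table(filtered).to_dict(orient="records")
        )
        groups, ko_only = chip.occupancy_hierarchy(
            filtered, tss, window=config.tss_window
        )
        wt_assign = chip.assign_peaks_to_genes(
            filtered["WT"], tss, window=config.tss_window
        )
        summary, n_dropped = chip.occupancy_vs_expression(groups, wt_assign, de_b)
        report["occupancy_groups"] = _json_safe(summary.to_dict(orient="records"))
        report["occupancy_genes_without_p"] = n_dropped
        report["ko_only_genes"] = len(ko_only)
    else:
        report["peak_counts"] = None

    # ------------------------------------------------------------ abundance
    report["abundance_mrna"] = _json_safe(
        abundance.mrna_paralog_percentages(config.mrna_a, config.mrna_b).to_dict()
    )
    if config.simulate:
        mfi = simulate.generate_mfi(config.sim_config())
    elif config.mfi_path:
        mfi = abundance.read_mfi_table(config.mfi_path)
    else:
        mfi = None
    if mfi is not None:
        report["abundance_protein"] = _json_safe(
            abundance.protein_paralog_percentages(mfi).to_dict()
        )

    _check_bookkeeping(report)
    return report


def _check_bookkeeping(report: dict) -> None:
    """Gene counts can only shrink along the pipeline."""
    chain = [
        report["n_input"],
        report["n_after_collapse"],
        report["n_after_filter"],
        report["n_pooled"],
    ]
    if any(a < b for a, b in zip(chain, chain[1:])):
        raise DataError(f"gene-count bookkeeping violated: {chain}")
    if report.get("specificity"):
        for count in report["specificity"]["counts"].values():
            if count > report["n_pooled"]:
                raise DataError("label count exceeds pooled gene count")


def report_to_json(report: dict, path=None) -> str:
    """Serialize a report deterministically (sorted keys, fixed format)."""
    text = json.dumps(_json_safe(report), indent=2, sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text
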