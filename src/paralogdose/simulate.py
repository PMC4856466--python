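"""Synthetic data with the statistical structure the analysis assumes.

The generator emulates a paralog-knockout RNA-seq design: 2-3 replicate
RPKM matrices for wild-type, Stat5a-deficient (A-KO) and Stat5b-deficient
(B-KO) T cells, plus height-thresholded ChIP-seq peak sets across the
genotype series and an MFI allele-series table.  Every planted parameter is
recorded in a truth object so downstream estimates can be checked against
ground truth.

Gene categories
---------------
``null``        no effect in either knockout.
``pan``         affected by both knockouts in the same direction, with the
                B-knockout effect larger by a fixed log2 increment: the
                planted asymmetry is |log2FC_B| = |log2FC_A| + log2(r)
                (shared sign), so the absolute fold changes satisfy
                absFC_B = r x absFC_A exactly and the preference statistic
                recovers log2(r) in closed form on noise-free data.
``a_specific``  affected only in the A-knockout (planted |log2FC| at or
                above a floor so specificity is unambiguous by
                construction); ``b_specific`` symmetrically.

Replicate values are baseline x 2^(planted log2FC + N(0, noise_sd)); the
baseline is lognormal, heavy-tailed like real RPKM distributions, so the
low-abundance offset and RPKM < 1 filter paths are exercised.

Peaks are placed around a deterministic synthetic TSS map and retained in a
genotype deterministically when their height reaches that genotype's
threshold; with thresholds ordered WT <= het <= A-KO <= B-KO this forces
the occupancy-hierarchy patterns (fewer peaks in the more deficient
genotypes; higher WT heights in more deeply shared groups) exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .abundance import MfiTable
from .errors import ConfigurationError
from .expression import ExpressionMatrix, matrix_from_arrays

CATEGORY_NULL = "null"
CATEGORY_PAN = "pan"
CATEGORY_A_SPECIFIC = "a_specific"
CATEGORY_B_SPECIFIC = "b_specific"
CATEGORIES = (CATEGORY_NULL, CATEGORY_PAN, CATEGORY_A_SPECIFIC, CATEGORY_B_SPECIFIC)

_CHROMS = ("chr1", "chr2", "chr3", "chr4", "chr5")
_GENE_SPACING = 200_000  # bp between synthetic TSSs on a chromosome


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic paralog-knockout experiment.

    Defaults describe a 1000-gene experiment in which roughly a third of
    genes respond to STAT5 loss, the Stat5b knockout hits pan genes twice
    as hard as the Stat5a knockout (``asymmetry_r = 2``), and 6% of genes
    are paralog-specific — about one in six of the STAT5-responsive pool,
    matching the share observed in primary T cells.  Pan effects centre on
    2-fold (log2 = 1.0, sd 0.3); specific effects are planted at or above
    1.5 on the log2 scale so they are specific by construction.  Baselines
    are lognormal with median 0.3 RPKM (most genes silent, as in real
    transcriptomes), and replicate noise is 0.4 on the log2 scale.
    """

    n_genes: int = 1000
    frac_null: float = 0.64
    frac_pan: float = 0.30
    frac_a_specific: float = 0.03
    frac_b_specific: float = 0.03
    asymmetry_r: float = 2.0
    effect_log2fc_mean: float = 1.0
    effect_log2fc_sd: float = 0.3
    specific_min_log2fc: float = 1.5
    frac_down: float = 0.8
    baseline_log_mean: float = math.log(0.3)
    baseline_log_sd: float = 2.2
    noise_sd: float = 0.4
    n_replicates: int = 3
    seed: int = 0
    # ChIP-seq peaks
    n_peaks: int = 240
    peak_height_log_mean: float = 3.0
    peak_height_log_sd: float = 0.8
    frac_distal: float = 0.1
    frac_weak: float = 0.1
    peak_min_width: int = 200
    peak_max_width: int = 800
    # MFI allele series
    mfi_baseline: float = 100.0
    mfi_unit_a: float = 1.0
    mfi_unit_b: float = 2.0

    def __post_init__(self) -> None:
        fracs = (
            self.frac_null,
            self.frac_pan,
            self.frac_a_specific,
            self.frac_b_specific,
        )
        if any(f < 0 or f > 1 for f in fracs):
            raise ConfigurationError("category proportions must lie in [0, 1]")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ConfigurationError(
                f"category proportions must sum to 1, got {sum(fracs)}"
            )
        if self.n_replicates < 2:
            raise ConfigurationError("need at least 2 replicates per genotype")
        if not self.asymmetry_r > 0:
            raise ConfigurationError("asymmetry_r must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be positive")
        if self.n_peaks > self.n_genes:
            raise ConfigurationError("n_peaks cannot exceed n_genes")
        if not 0 <= self.frac_distal <= 1 or not 0 <= self.frac_weak <= 1:
            raise ConfigurationError("frac_distal/frac_weak must lie in [0, 1]")
        if self.mfi_unit_a < 0 or self.mfi_unit_b < 0:
            raise ConfigurationError("per-allele unit contributions must be >= 0")
        if not self.mfi_baseline > 0:
            raise ConfigurationError("mfi_baseline must be positive")


@dataclass
class SyntheticTruth:
    """Planted ground truth for a simulated dataset.

    ``genes``: per-gene category, true log2 fold changes and baseline.
    ``peaks``: per-peak height, linked gene (NaN for distal peaks), filter
    status and per-genotype retention flags.  ``tss``: the synthetic TSS
    map the peaks were placed against.
    """

    genes: pd.DataFrame | None = None
    peaks: pd.DataFrame | None = None
    tss: pd.DataFrame | None = None

    def to_json(self, path) -> None:
        payload = {}
        for name in ("genes", "peaks", "tss"):
            df = getattr(self, name)
            if df is not None:
                payload[name] = df.reset_index().to_dict(orient="list")
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def _category_counts(config: SimulationConfig) -> dict[str, int]:
    """Deterministic largest-remainder apportionment of genes to categories."""
    fracs = {
        CATEGORY_NULL: config.frac_null,
        CATEGORY_PAN: config.frac_pan,
        CATEGORY_A_SPECIFIC: config.frac_a_specific,
        CATEGORY_B_SPECIFIC: config.frac_b_specific,
    }
    counts = {c: int(math.floor(f * config.n_genes)) for c, f in fracs.items()}
    remainder = config.n_genes - sum(counts.values())
    order = sorted(
        CATEGORIES,
        key=lambda c: (fracs[c] * config.n_genes) % 1.0,
        reverse=True,
    )
    for c in order[:remainder]:
        counts[c] += 1
    return counts


def gene_ids(config: SimulationConfig) -> list[str]:
    width = len(str(config.n_genes - 1))
    return [f"g{i:0{width}d}" for i in range(config.n_genes)]


def generate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate the replicate RPKM matrix and its planted truth.

    Identical configs (including the seed) yield byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    counts = _category_counts(config)
    categories = np.repeat(
        list(counts.keys()), list(counts.values())
    ).astype(object)

    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, n)
    magnitude = np.abs(
        rng.normal(config.effect_log2fc_mean, config.effect_log2fc_sd, n)
    )
    sign = np.where(rng.random(n) < config.frac_down, -1.0, 1.0)

    log2fc_a = np.zeros(n)
    log2fc_b = np.zeros(n)
    is_pan = categories == CATEGORY_PAN
    log2fc_a[is_pan] = sign[is_pan] * magnitude[is_pan]
    log2fc_b[is_pan] = sign[is_pan] * (
        magnitude[is_pan] + math.log2(config.asymmetry_r)
    )
    is_a = categories == CATEGORY_A_SPECIFIC
    log2fc_a[is_a] = sign[is_a] * np.maximum(
        magnitude[is_a], config.specific_min_log2fc
    )
    is_b = categories == CATEGORY_B_SPECIFIC
    log2fc_b[is_b] = sign[is_b] * np.maximum(
        magnitude[is_b], config.specific_min_log2fc
    )

    data = {}
    for genotype, fc in (("WT", np.zeros(n)), ("A-KO", log2fc_a), ("B-KO", log2fc_b)):
        for rep in range(1, config.n_replicates + 1):
            noise = rng.normal(0.0, config.noise_sd, n) if config.noise_sd > 0 else 0.0
            data[f"{genotype}_rep{rep}"] = baseline * np.exp2(fc + noise)

    matrix = matrix_from_arrays(gene_ids(config), data)
    truth_genes = pd.DataFrame(
        {
            "category": categories,
            "log2fc_a": log2fc_a,
            "log2fc_b": log2fc_b,
            "baseline": baseline,
        },
        index=pd.Index(gene_ids(config), name="gene_id"),
    )
    return matrix, SyntheticTruth(genes=truth_genes)


# ------------------------------------------------------------------- peaks


def make_tss_table(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic synthetic TSS map: genes laid out round-robin over five
    chromosomes, 200 kb apart, alternating strand."""
    ids = gene_ids(config)
    rows = [
        {
            "gene_id": gid,
            "chrom": _CHROMS[i % len(_CHROMS)],
            "strand": "+" if i % 2 == 0 else "-",
            "tss": _GENE_SPACING * (i // len(_CHROMS) + 1),
        }
        for i, gid in enumerate(ids)
    ]
    return pd.DataFrame(rows)


def retention_flags(heights, thresholds) -> dict[str, np.ndarray]:
    """Deterministic retention: a peak survives in a genotype iff its height
    reaches that genotype's threshold.  Thresholds are ordered
    WT <= het <= A-KO <= B-KO."""
    thresholds = tuple(float(t) for t in thresholds)
    if len(thresholds) != 4:
        raise ConfigurationError("need four thresholds (WT, het, A-KO, B-KO)")
    if any(a > b for a, b in zip(thresholds, thresholds[1:])):
        raise ConfigurationError(
            f"thresholds must be nondecreasing WT <= het <= A-KO <= B-KO, got {thresholds}"
        )
    heights = np.asarray(heights, dtype=float)
    return {
        genotype: heights >= t
        for genotype, t in zip(("WT", "het", "A-KO", "B-KO"), thresholds)
    }


def generate_peaks(
    config: SimulationConfig,
    thresholds: tuple[float, float, float, float] = (5.0, 12.0, 25.0, 55.0),
) -> tuple[dict[str, pd.DataFrame], SyntheticTruth]:
    """Simulate per-genotype peak sets with height-thresholded retention.

    Peak heights are lognormal; most peaks sit within +/- 9 kb of a
    (unique) gene's TSS so gene assignment recovers the planted link, while
    a ``frac_distal`` fraction is placed 15-80 kb away, beyond the
    assignment window.  A ``frac_weak`` fraction fails the fold-enrichment
    or p-value calling criteria to exercise peak filtering.

    Returns ({genotype: retained peak table}, truth); truth includes the
    full peak list, gene links and retention flags, plus the TSS table.
    """
    rng = np.random.default_rng([config.seed, 7])
    tss = make_tss_table(config)
    n = config.n_peaks

    gene_pos = rng.choice(config.n_genes, size=n, replace=False)
    gene_pos.sort()
    heights = rng.lognormal(config.peak_height_log_mean, config.peak_height_log_sd, n)
    distal = rng.random(n) < config.frac_distal
    offsets = np.where(
        distal,
        rng.integers(15_000, 80_000, n) * np.where(rng.random(n) < 0.5, -1, 1),
        rng.integers(-9_000, 9_001, n),
    )
    widths = rng.integers(config.peak_min_width, config.peak_max_width + 1, n)

    weak = rng.random(n) < config.frac_weak
    weak_mode = rng.random(n) < 0.5  # True: fails enrichment, False: fails p
    fold_enrichment = np.where(
        weak & weak_mode, rng.uniform(1.0, 2.9, n), 3.5 + heights / 10.0
    )
    pvalue = np.where(weak & ~weak_mode, rng.uniform(1e-4, 1e-2, n), 1e-9)

    tss_by_pos = tss.iloc[gene_pos]
    mids = tss_by_pos["tss"].values + offsets
    starts = mids - widths // 2
    ends = starts + widths
    flags = retention_flags(heights, thresholds)

    peaks = pd.DataFrame(
        {
            "chrom": tss_by_pos["chrom"].values,
            "start": starts.astype(int),
            "end": ends.astype(int),
            "name": [f"peak{i}" for i in range(n)],
            "score": np.zeros(n, dtype=int),
            "strand": ".",
            "height": heights,
            "fold_enrichment": fold_enrichment,
            "pvalue": pvalue,
        }
    )
    truth_peaks = peaks[["chrom", "start", "end", "height"]].copy()
    truth_peaks["gene_id"] = np.where(
        distal, None, tss_by_pos["gene_id"].values
    )
    truth_peaks["passes_called_filter"] = ~weak
    for genotype, flag in flags.items():
        truth_peaks[f"retained_{genotype}"] = flag

    peak_sets = {
        genotype: peaks.loc[flag].copy() for genotype, flag in flags.items()
    }
    return peak_sets, SyntheticTruth(peaks=truth_peaks, tss=tss)


# --------------------------------------------------------------------- MFI


def generate_mfi(
    config: SimulationConfig,
    unit_a: float | None = None,
    unit_b: float | None = None,
) -> MfiTable:
    """Noiseless MFI allele series: each genotype's MFI is
    baseline x (a_alleles x unit_a + b_alleles x unit_b)."""
    unit_a = config.mfi_unit_a if unit_a is None else unit_a
    unit_b = config.mfi_unit_b if unit_b is None else unit_b
    if unit_a < 0 or unit_b < 0:
        raise ConfigurationError("per-allele unit contributions must be >= 0")
    if not config.mfi_baseline > 0:
        raise ConfigurationError("mfi_baseline must be positive")
    from .abundance import ALLELE_SERIES

    values = {
        name: config.mfi_baseline * (a * unit_a + b * unit_b)
        for name, (a, b) in ALLELE_SERIES.items()
    }
    return MfiTable(**values)
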