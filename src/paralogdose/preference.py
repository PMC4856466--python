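"""Paralog preference: which STAT5 paralog a transcript depends on more.

For every STAT5-regulated transcript, each knockout-vs-WT contrast yields a
*paralog score*:

    score = |fold change| x max(RPKM_WT, RPKM_KO)

computed on offset-added genotype means.  Using the absolute fold change
removes the up/down distinction; multiplying by the larger of the two RPKMs
up-weights abundant transcripts.  The *preference score* is

    preference = log2(score_B / score_A)

so transcripts more impacted by loss of STAT5B are positive and transcripts
more impacted by loss of STAT5A are negative.  Preferences are summarized as
a 12-bin histogram (bin 1 below -5, unit-wide bins up to bin 12 at +5 and
above) together with the median of the raw values.
"""

from __future__ import annotations

from dataclasses import dataclass
import json

import numpy as np
import pandas as pd

from .errors import DataError
from .expression import DEResult, pool_regulated

#: 12 histogram bins: (-inf,-5), [-5,-4), ..., [4,5), [5,inf).
BIN_EDGES = np.concatenate(([-np.inf], np.arange(-5.0, 6.0), [np.inf]))

_FC_TOL = 1e-9


def paralog_score(abs_fc, rpkm_wt, rpkm_ko):
    """Absolute fold change times the higher of the WT and KO RPKM.

    Accepts scalars or aligned arrays.  ``abs_fc`` must be >= 1 (it is an
    absolute fold change) and RPKMs positive (offset-added).
    """
    abs_fc = np.asarray(abs_fc, dtype=float)
    rpkm_wt = np.asarray(rpkm_wt, dtype=float)
    rpkm_ko = np.asarray(rpkm_ko, dtype=float)
    if np.any(abs_fc < 1.0 - _FC_TOL):
        raise DataError("absolute fold change must be >= 1")
    if np.any(rpkm_wt <= 0) or np.any(rpkm_ko <= 0):
        raise DataError("RPKM values must be positive (offset-added)")
    out = abs_fc * np.maximum(rpkm_wt, rpkm_ko)
    return float(out) if out.ndim == 0 else out


def preference_score(score_b, score_a):
    """log2 ratio of the STAT5B-contrast score over the STAT5A-contrast score."""
    score_b = np.asarray(score_b, dtype=float)
    score_a = np.asarray(score_a, dtype=float)
    if np.any(score_b <= 0) or np.any(score_a <= 0):
        raise DataError("paralog scores must be positive")
    out = np.log2(score_b / score_a)
    return float(out) if out.ndim == 0 else out


def build_preference_records(
    de_a: DEResult, de_b: DEResult, genes=None
) -> pd.DataFrame:
    """Per-gene paralog scores and preference for a pooled gene list.

    ``de_a`` is the STAT5A-loss contrast (A-KO vs WT) and ``de_b`` the
    STAT5B-loss contrast.  Both contrasts' fold changes and RPKMs enter the
    score for every pooled gene, regardless of which contrast triggered its
    inclusion.  ``genes`` defaults to the pooled regulated list.

    Returns a DataFrame indexed by gene with columns ``score_a``,
    ``score_b`` and ``preference``.
    """
    if genes is None:
        genes = pool_regulated(de_a, de_b)
    genes = pd.Index(genes)
    for de, name in ((de_a, "A"), (de_b, "B")):
        missing = genes.difference(de.genes)
        if len(missing):
            raise DataError(
                f"genes absent from the {name} contrast: {sorted(missing)[:5]}"
            )
    ta = de_a.table.loc[genes]
    tb = de_b.table.loc[genes]
    score_a = paralog_score(ta["abs_fc"], ta["mean_g2"], ta["mean_g1"])
    score_b = paralog_score(tb["abs_fc"], tb["mean_g2"], tb["mean_g1"])
    return pd.DataFrame(
        {
            "score_a": np.asarray(score_a),
            "score_b": np.asarray(score_b),
            "preference": preference_score(np.asarray(score_b), np.asarray(score_a)),
        },
        index=genes,
    )


@dataclass
class PreferenceHistogram:
    """12-bin histogram of preference scores plus the raw-value median."""

    counts: np.ndarray
    edges: np.ndarray
    median: float
    n: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.sum() != self.n:
            raise DataError("histogram counts do not sum to n")

    def to_dict(self) -> dict:
        return {
            "edges": [float(e) for e in self.edges],
            "counts": [int(c) for c in self.counts],
            "median": float(self.median),
            "n": int(self.n),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def bin_preferences(preferences) -> PreferenceHistogram:
    """Histogram preference values into the 12 canonical bins.

    Accepts an array of preferences or the DataFrame produced by
    :func:`build_preference_records`.  The median is computed on the raw
    (unbinned) values with the usual mid-point convention for even n.
    """
    if isinstance(preferences, pd.DataFrame):
        preferences = preferences["preference"]
    values = np.asarray(preferences, dtype=float)
    if values.size == 0:
        raise DataError("cannot bin an empty set of preferences")
    if not np.all(np.isfinite(values)):
        raise DataError("preference values must be finite")
    counts, _ = np.histogram(values, bins=BIN_EDGES)
    return PreferenceHistogram(
        counts=counts,
        edges=BIN_EDGES.copy(),
        median=float(np.median(values)),
        n=int(values.size),
    )


def project_gene_set(
    records: pd.DataFrame, gene_list
) -> tuple[PreferenceHistogram, list[str]]:
    """Restrict the preference distribution to a gene set of interest
    (e.g. transcripts mobilized by ectopic STAT5A).

    Returns the histogram over the intersection plus the list of requested
    genes absent from ``records`` (reported, never silently dropped).
    """
    requested = pd.Index(gene_list)
    present = requested.intersection(records.index)
    missing = sorted(requested.difference(records.index))
    if len(present) == 0:
        raise DataError("gene set does not intersect the preference records")
    return bin_preferences(records.loc[present]), missing


def write_preference_tsv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index_label="gene_id")
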