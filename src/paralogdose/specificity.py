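"""Classify STAT5-regulated transcripts as pan-STAT5 or paralog-specific.

A transcript is a *paralog-specific* candidate when the two knockouts
differ directly from one another (> 1.5-fold, p < 0.05 in the KO-vs-KO
contrast).  A candidate is STAT5A-specific when it is regulated in the
A-KO-vs-WT contrast (> 1.5-fold, p < 0.05) while essentially unchanged in
the B-KO-vs-WT contrast (< 1.2-fold, no p condition), and symmetrically for
STAT5B-specific.  Transcripts significantly regulated in opposite
directions in the two knockouts are excluded outright; transcripts
regulated in both knockouts are *pan-STAT5*; everything else in the pooled
list is unclassified.

Exclusion takes precedence over the specific/pan labels, so the five labels
partition the pooled STAT5-regulated gene list.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .expression import DEResult, pool_regulated

LABEL_PAN = "pan"
LABEL_A_SPECIFIC = "a_specific"
LABEL_B_SPECIFIC = "b_specific"
LABEL_EXCLUDED = "excluded_opposite"
LABEL_UNCLASSIFIED = "unclassified"
LABELS = (
    LABEL_PAN,
    LABEL_A_SPECIFIC,
    LABEL_B_SPECIFIC,
    LABEL_EXCLUDED,
    LABEL_UNCLASSIFIED,
)


@dataclass(frozen=True)
class SpecificityThresholds:
    """Fold-change / p-value cutoffs for the classifier.

    ``fc``: a contrast counts as regulated above this absolute fold change
    (with ``p``); ``fc_ceiling``: the *other* contrast counts as unchanged
    below this absolute fold change (no p condition).
    """

    fc: float = 1.5
    fc_ceiling: float = 1.2
    p: float = 0.05

    def __post_init__(self) -> None:
        if not (self.fc > 1 and self.fc_ceiling > 1 and 0 < self.p < 1):
            raise DataError("invalid specificity thresholds")


def classify_specificity(
    de_a_wt: DEResult,
    de_b_wt: DEResult,
    de_a_b: DEResult,
    genes=None,
    thresholds: SpecificityThresholds = SpecificityThresholds(),
) -> pd.DataFrame:
    """Label every pooled gene with exactly one specificity call.

    Parameters
    ----------
    de_a_wt, de_b_wt
        The A-KO-vs-WT and B-KO-vs-WT contrasts.
    de_a_b
        The direct A-KO-vs-B-KO contrast.
    genes
        Gene list to classify; defaults to the pooled regulated list from
        the two vs-WT contrasts.

    Returns a DataFrame indexed by gene with a ``label`` column and the
    supporting fold changes / p-values of all three contrasts.
    """
    universe = set(de_a_wt.genes)
    if set(de_b_wt.genes) != universe or set(de_a_b.genes) != universe:
        raise DataError("the three DE tables cover different gene universes")
    if genes is None:
        genes = pool_regulated(de_a_wt, de_b_wt)
    genes = pd.Index(genes)
    if len(genes) == 0:
        raise DataError("no genes to classify")

    ta = de_a_wt.table.loc[genes]
    tb = de_b_wt.table.loc[genes]
    tab = de_a_b.table.loc[genes]
    th = thresholds

    reg_a = (ta["abs_fc"].values > th.fc) & (ta["pvalue"].values < th.p)
    reg_b = (tb["abs_fc"].values > th.fc) & (tb["pvalue"].values < th.p)
    opposite = reg_a & reg_b & (
        np.sign(ta["log2fc"].values) != np.sign(tb["log2fc"].values)
    )
    candidate = (tab["abs_fc"].values > th.fc) & (tab["pvalue"].values < th.p)
    a_specific = candidate & reg_a & (tb["abs_fc"].values < th.fc_ceiling)
    b_specific = candidate & reg_b & (ta["abs_fc"].values < th.fc_ceiling)

    label = np.where(
        opposite,
        LABEL_EXCLUDED,
        np.where(
            a_specific,
            LABEL_A_SPECIFIC,
            np.where(
                b_specific,
                LABEL_B_SPECIFIC,
                np.where(reg_a & reg_b, LABEL_PAN, LABEL_UNCLASSIFIED),
            ),
        ),
    )
    return pd.DataFrame(
        {
            "label": label,
            "absfc_a_wt": ta["abs_fc"].values,
            "p_a_wt": ta["pvalue"].values,
            "absfc_b_wt": tb["abs_fc"].values,
            "p_b_wt": tb["pvalue"].values,
            "absfc_a_b": tab["abs_fc"].values,
            "p_a_b": tab["pvalue"].values,
        },
        index=genes,
    )


def summarize_specificity(calls: pd.DataFrame) -> dict:
    """Counts and fractions per label plus the paralog-specific fraction."""
    if len(calls) == 0:
        raise DataError("no specificity calls to summarize")
    n = len(calls)
    counts = {label: int((calls["label"] == label).sum()) for label in LABELS}
    fractions = {label: counts[label] / n for label in LABELS}
    specific = counts[LABEL_A_SPECIFIC] + counts[LABEL_B_SPECIFIC]
    return {
        "n": n,
        "counts": counts,
        "fractions": fractions,
        "fraction_paralog_specific": specific / n,
    }


def score_against_truth(calls: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Precision/recall of paralog-specific detection against planted labels.

    ``truth`` is the per-gene table from the synthetic generator (indexed by
    gene with a ``category`` column).  Both metrics are computed over the
    genes present in ``calls`` — i.e. the genes that actually entered the
    analysis — and require the specific *direction* to match
    (``a_specific`` predicted as ``a_specific``, etc.).
    """
    genes = calls.index
    planted = truth.loc[genes, "category"]
    specific_labels = (LABEL_A_SPECIFIC, LABEL_B_SPECIFIC)
    pred = calls["label"].isin(specific_labels)
    true = planted.isin(specific_labels)
    correct = pred & true & (calls["label"] == planted)
    tp = int(correct.sum())
    n_pred = int(pred.sum())
    n_true = int(true.sum())
    return {
        "tp": tp,
        "n_predicted_specific": n_pred,
        "n_planted_specific": n_true,
        "precision": tp / n_pred if n_pred else float("nan"),
        "recall": tp / n_true if n_true else float("nan"),
    }


def write_calls_tsv(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, sep="\t", index_label="gene_id")
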