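"""ChIP-seq peak integration: filtering, overlap, TSS annotation, occupancy.

Peaks are BED-style 0-based half-open intervals carrying a height (tag
count), fold enrichment over background and a p-value, one set per
genotype.  Downstream of peak calling the analysis

* retains peaks with > 3-fold enrichment and p < 5e-5,
* counts overlapping peaks between genotype pairs (for a Circos-style
  sharing table),
* histograms peak-to-nearest-TSS distances in 10 kb bins,
* assigns peaks to genes whose TSS lies within +/- 10 kb of the peak
  midpoint (a peak may serve several genes), and
* groups WT-bound genes by how deep their binding persists across the
  genotype hierarchy WT -> het -> A-KO -> B-KO, relating each group's
  average WT peak height to the average expression dysregulation
  (-log10 p) of its genes.

Overlap counts are maximum one-to-one matchings (each peak counted once),
so the shared count is symmetric in its two arguments.
"""

from __future__ import annotations

import sys
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .expression import DEResult

PEAK_COLUMNS = ("chrom", "start", "end", "height", "fold_enrichment", "pvalue")

#: Peak-calling retention thresholds.
MIN_FOLD_ENRICHMENT = 3.0
MAX_PVALUE = 5e-5

#: Gene-assignment window around the TSS, in bp (closed at both ends).
TSS_WINDOW = 10_000

GENOTYPE_ORDER = ("WT", "het", "A-KO", "B-KO")

#: Occupancy groups, by the deepest genotype retaining binding.
GROUP_NAMES = {
    1: "WT-only",
    2: "WT+het",
    3: "WT+het+A-KO",
    4: "WT+het+A-KO+B-KO",
}


def validate_peaks(peaks: pd.DataFrame) -> pd.DataFrame:
    missing = set(PEAK_COLUMNS) - set(peaks.columns)
    if missing:
        raise DataError(f"peak table missing columns: {sorted(missing)}")
    if (peaks["start"] >= peaks["end"]).any():
        raise DataError("peak intervals must satisfy start < end")
    if (peaks["height"] <= 0).any():
        raise DataError("peak heights must be positive")
    return peaks


def read_peaks_bed(path) -> pd.DataFrame:
    """Read a 6-column BED with three extra numeric columns
    (height, fold_enrichment, pvalue)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand",
               "height", "fold_enrichment", "pvalue"],
    )
    return validate_peaks(df)


def write_peaks_bed(peaks: pd.DataFrame, path) -> None:
    out = validate_peaks(peaks).copy()
    if "name" not in out.columns:
        out["name"] = [f"peak{i}" for i in range(len(out))]
    if "score" not in out.columns:
        out["score"] = 0
    if "strand" not in out.columns:
        out["strand"] = "."
    cols = ["chrom", "start", "end", "name", "score", "strand",
            "height", "fold_enrichment", "pvalue"]
    out[cols].to_csv(path, sep="\t", header=False, index=False)


def read_tss_table(path) -> pd.DataFrame:
    """Read a TSS TSV with columns gene_id, chrom, strand, tss (0-based)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "strand", "tss"}
    if not required <= set(df.columns):
        raise DataError(f"TSS table needs columns {sorted(required)}")
    return df


# ---------------------------------------------------------------- filtering


def filter_called_peaks(
    peaks: pd.DataFrame,
    min_fold_enrichment: float = MIN_FOLD_ENRICHMENT,
    max_pvalue: float = MAX_PVALUE,
) -> pd.DataFrame:
    """Retain peaks with fold enrichment strictly above the cutoff and
    p-value strictly below it."""
    validate_peaks(peaks)
    keep = (peaks["fold_enrichment"] > min_fold_enrichment) & (
        peaks["pvalue"] < max_pvalue
    )
    return peaks.loc[keep]


# ------------------------------------------------------------------ overlap


def _overlap_adjacency(x: pd.DataFrame, y: pd.DataFrame) -> list[list[int]]:
    """For each row of ``x``, the positional indices of overlapping ``y``
    rows (same chrom, half-open intersection >= 1 bp)."""
    adj: list[list[int]] = [[] for _ in range(len(x))]
    for chrom, yc in y.groupby("chrom", sort=False):
        order = np.argsort(yc["start"].values, kind="stable")
        y_start = yc["start"].values[order]
        y_end = yc["end"].values[order]
        y_idx = np.flatnonzero((y["chrom"] == chrom).values)[order]
        xc_mask = (x["chrom"] == chrom).values
        for xi in np.flatnonzero(xc_mask):
            xs = x["start"].values[xi]
            xe = x["end"].values[xi]
            hi = np.searchsorted(y_start, xe, side="left")  # y.start < x.end
            cand = np.flatnonzero(y_end[:hi] > xs)  # y.end > x.start
            adj[xi] = [int(y_idx[c]) for c in cand]
    return adj


def _max_matching(adj: list[list[int]], n_right: int) -> list[tuple[int, int]]:
    """Maximum bipartite matching via augmenting paths (Kuhn's algorithm).

    Left nodes are processed in index order and neighbor lists are sorted,
    so the returned pairing is deterministic.
    """
    match_right = [-1] * n_right
    match_left = [-1] * len(adj)
    sys.setrecursionlimit(max(sys.getrecursionlimit(), 4 * (len(adj) + n_right) + 100))

    def try_augment(u: int, visited: set[int]) -> bool:
        for v in adj[u]:
            if v in visited:
                continue
            visited.add(v)
            if match_right[v] == -1 or try_augment(match_right[v], visited):
                match_right[v] = u
                match_left[u] = v
                return True
        return False

    for u in range(len(adj)):
        if adj[u]:
            try_augment(u, set())
    return [(u, v) for u, v in enumerate(match_left) if v != -1]


def overlap_peaks(x: pd.DataFrame, y: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Matched overlapping peak pairs between two peak sets.

    Two peaks overlap when they share a chromosome and their half-open
    intervals intersect in at least 1 bp.  Each peak participates in at
    most one pair (maximum matching), so the shared count is symmetric:
    ``overlap_peaks(x, y)[1] == overlap_peaks(y, x)[1]``.

    Returns (pairs, shared_count) where ``pairs`` has columns ``x_index``
    and ``y_index`` holding the original row labels.
    """
    validate_peaks(x)
    validate_peaks(y)
    adj = [sorted(nb) for nb in _overlap_adjacency(x, y)]
    pairs = _max_matching(adj, len(y))
    table = pd.DataFrame(
        {
            "x_index": [x.index[u] for u, _ in pairs],
            "y_index": [y.index[v] for _, v in pairs],
        }
    )
    return table, len(pairs)


def overlap_table(peak_sets: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Pairwise shared-peak counts between genotypes (Circos-ready)."""
    names = list(peak_sets)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            _, shared = overlap_peaks(peak_sets[a], peak_sets[b])
            rows.append({"group_x": a, "group_y": b, "shared": shared})
    return pd.DataFrame(rows)


# ------------------------------------------------------------- TSS distance


def _midpoints(peaks: pd.DataFrame) -> np.ndarray:
    # integer midpoint of the half-open interval
    return (peaks["start"].values + peaks["end"].values) // 2


def nearest_tss(peaks: pd.DataFrame, tss: pd.DataFrame) -> pd.DataFrame:
    """Nearest TSS per peak with a strand-aware signed distance.

    Distance is measured from the peak midpoint; the sign is negative when
    the peak lies upstream of the gene (relative to its strand) and
    positive downstream.  Ties on absolute distance break toward the
    lexicographically smaller gene id.
    """
    validate_peaks(peaks)
    if len(tss) == 0:
        raise DataError("empty TSS annotation")
    mids = _midpoints(peaks)
    gene_out = np.empty(len(peaks), dtype=object)
    dist_out = np.zeros(len(peaks), dtype=int)
    for chrom, tc in tss.groupby("chrom", sort=False):
        # sort by (position, gene_id) so equidistant ties resolve to the
        # smaller gene id deterministically
        tc = tc.sort_values(["tss", "gene_id"], kind="stable")
        pos = tc["tss"].values
        genes = tc["gene_id"].values
        strands = tc["strand"].values
        mask = (peaks["chrom"] == chrom).values
        for pi in np.flatnonzero(mask):
            mid = mids[pi]
            j = np.searchsorted(pos, mid)
            best = None  # (abs_dist, gene_id, signed_dist)
            for k in (j - 1, j, j + 1):
                if 0 <= k < len(pos):
                    signed = int(mid - pos[k]) if strands[k] == "+" else int(pos[k] - mid)
                    cand = (abs(signed), genes[k], signed)
                    if best is None or cand[:2] < best[:2]:
                        best = cand
            gene_out[pi] = best[1]
            dist_out[pi] = best[2]
    unassigned = [
        str(c) for c in peaks["chrom"].unique() if c not in set(tss["chrom"])
    ]
    if unassigned:
        raise DataError(f"no TSS on chromosome(s): {unassigned}")
    return pd.DataFrame(
        {"gene_id": gene_out, "distance": dist_out}, index=peaks.index
    )


def tss_localization(
    peaks: pd.DataFrame, tss: pd.DataFrame, bin_width: int = 10_000
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Percentage of peaks per 10 kb distance bin around the nearest TSS.

    Bins are signed and left-closed: ``[k*w, (k+1)*w)``; a peak sitting
    exactly on the TSS lands in the first downstream bin ``[0, w)``.

    Returns (per_peak, histogram) where ``histogram`` has columns
    ``bin_lo``, ``bin_hi``, ``count`` and ``pct`` (summing to 100).
    """
    if bin_width <= 0:
        raise ConfigurationError("bin_width must be positive")
    per_peak = nearest_tss(peaks, tss)
    if len(per_peak) == 0:
        raise DataError("no peaks to localize")
    bins = np.floor_divide(per_peak["distance"].values, bin_width)
    uniq, counts = np.unique(bins, return_counts=True)
    hist = pd.DataFrame(
        {
            "bin_lo": uniq * bin_width,
            "bin_hi": (uniq + 1) * bin_width,
            "count": counts,
            "pct": 100.0 * counts / counts.sum(),
        }
    ).sort_values("bin_lo", ignore_index=True)
    return per_peak, hist


# --------------------------------------------------------- gene assignment


def assign_peaks_to_genes(
    peaks: pd.DataFrame, tss: pd.DataFrame, window: int = TSS_WINDOW
) -> pd.DataFrame:
    """Assign each peak to every gene whose TSS lies within ``window`` bp of
    the peak midpoint (closed interval; multi-assignment allowed).

    Returns a DataFrame with columns ``gene_id``, ``peak_index`` and
    ``height``.
    """
    if not window > 0:
        raise ConfigurationError("window must be positive")
    validate_peaks(peaks)
    mids = _midpoints(peaks)
    rows = []
    for chrom, tc in tss.groupby("chrom", sort=False):
        tc = tc.sort_values(["tss", "gene_id"], kind="stable")
        pos = tc["tss"].values
        genes = tc["gene_id"].values
        mask = (peaks["chrom"] == chrom).values
        for pi in np.flatnonzero(mask):
            mid = mids[pi]
            lo = np.searchsorted(pos, mid - window, side="left")
            hi = np.searchsorted(pos, mid + window, side="right")
            for k in range(lo, hi):
                rows.append(
                    {
                        "gene_id": genes[k],
                        "peak_index": peaks.index[pi],
                        "height": float(peaks["height"].values[pi]),
                    }
                )
    return pd.DataFrame(rows, columns=["gene_id", "peak_index", "height"])


# ------------------------------------------------------ occupancy hierarchy


def occupancy_hierarchy(
    peak_sets: Mapping[str, pd.DataFrame],
    tss: pd.DataFrame,
    window: int = TSS_WINDOW,
) -> tuple[pd.Series, list[str]]:
    """Group WT-bound genes by how deep their binding persists.

    ``peak_sets`` maps the genotypes ``WT``, ``het``, ``A-KO`` and ``B-KO``
    to (already filtered) peak tables.  A WT-bound gene is placed in the
    deepest nested group whose genotypes *all* retain at least one assigned
    peak at that gene: group 1 = WT only, 2 = WT+het, 3 = WT+het+A-KO,
    4 = shared by all four genotypes.  Nesting is strict — a gene bound in
    WT and A-KO but not het stays in group 1.

    Returns (groups, ko_only_genes): a gene -> group-number Series for
    WT-bound genes, plus the sorted list of genes bound in some non-WT
    genotype but not in WT (reported, not grouped).
    """
    missing = [g for g in GENOTYPE_ORDER if g not in peak_sets]
    if missing:
        raise DataError(f"missing peak sets for genotypes: {missing}")
    bound = {
        g: set(assign_peaks_to_genes(peak_sets[g], tss, window)["gene_id"])
        for g in GENOTYPE_ORDER
    }
    groups = {}
    for gene in sorted(bound["WT"]):
        depth = 1
        for nxt in GENOTYPE_ORDER[1:]:
            if gene in bound[nxt]:
                depth += 1
            else:
                break
        groups[gene] = depth
    ko_only = sorted(
        set().union(*(bound[g] for g in GENOTYPE_ORDER[1:])) - bound["WT"]
    )
    return pd.Series(groups, dtype=int, name="group"), ko_only


def occupancy_vs_expression(
    groups: pd.Series,
    wt_assignments: pd.DataFrame,
    de: DEResult,
) -> tuple[pd.DataFrame, int]:
    """Per occupancy group: gene count, mean WT peak height, mean -log10 p.

    A gene's height is the mean of its assigned WT peak heights; the group
    height is the mean over genes.  Genes lacking a p-value in ``de`` (for
    example, filtered out of the expression analysis) are dropped and
    counted.  Empty groups report n = 0 with NaN means rather than silent
    zeros.
    """
    gene_height = wt_assignments.groupby("gene_id")["height"].mean()
    rows = []
    n_dropped = 0
    for group in (1, 2, 3, 4):
        genes = groups.index[groups.values == group]
        with_p = [g for g in genes if g in de.genes]
        n_dropped += len(genes) - len(with_p)
        if with_p:
            heights = gene_height.loc[with_p]
            neglogp = -np.log10(de.table.loc[with_p, "pvalue"].values)
            rows.append(
                {
                    "group": group,
                    "name": GROUP_NAMES[group],
                    "n_genes": len(with_p),
                    "mean_wt_height": float(heights.mean()),
                    "mean_neglog10_p": float(neglogp.mean()),
                }
            )
        else:
            rows.append(
                {
                    "group": group,
                    "name": GROUP_NAMES[group],
                    "n_genes": 0,
                    "mean_wt_height": float("nan"),
                    "mean_neglog10_p": float("nan"),
                }
            )
    return pd.DataFrame(rows), n_dropped
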