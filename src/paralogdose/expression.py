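"""Expression-matrix handling: normalization, collapsing, filtering, DE.

The workflow mirrors a standard low-replicate RPKM analysis of knockout
versus wild-type T cells:

1. A small pseudo-count offset — the second quartile (median) of the whole
   matrix, typically 0.2-0.3 for bulk RPKM data — is added to every value to
   damp fold-change artifacts from low-abundance transcripts.
2. When several fragments map to one gene, only the most abundant fragment
   (highest RPKM averaged across the genotype means) is kept.
3. Transcripts with RPKM < 1 in every genotype are excluded.  This filter is
   evaluated on raw (pre-offset) values so the threshold keeps its meaning
   independently of the dataset-specific offset.
4. Fold change and a p-value are computed per gene for a knockout-vs-WT (or
   knockout-vs-knockout) contrast.  A transcript is called regulated when it
   shows > 1.5-fold change with p < 0.05.

The differential-expression test is a pooled-variance two-sample t-test on
log2(offset-added RPKM) with a small variance floor added to the pooled
variance; it protects 2-3 replicate designs from zero-variance degeneracy.
Precomputed DE tables from external count-model tools can be loaded verbatim
through :func:`read_de_table` and flow through the rest of the pipeline
unchanged.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataError, OffsetRangeWarning

GENOTYPE_WT = "WT"
GENOTYPE_A_KO = "A-KO"
GENOTYPE_B_KO = "B-KO"
GENOTYPE_HET = "het"

#: Default regulation thresholds: > 1.5 linear fold change at p < 0.05.
FC_THRESHOLD = 1.5
P_THRESHOLD = 0.05

#: Variance floor added to the pooled variance of log2 values in the
#: stand-in DE test (guards n = 2-3 designs against zero sample variance).
VAR_FLOOR = 0.05

_SAMPLE_RE = re.compile(r"^(?P<genotype>.+)_rep(?P<rep>\d+)$")


@dataclass
class ExpressionMatrix:
    """A genes x samples RPKM matrix with genotype labels per sample.

    Parameters
    ----------
    values
        DataFrame indexed by gene (or fragment) id; one column per sample.
        Column names follow ``<genotype>_rep<k>`` (e.g. ``WT_rep1``).
    genotypes
        Series mapping each sample column to its genotype label.
    offset
        The pseudo-count added to all values, or ``None`` if not applied.
    """

    values: pd.DataFrame
    genotypes: pd.Series
    offset: float | None = None

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.genotypes.index):
            raise DataError("genotype labels do not match sample columns")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise DataError(f"duplicate gene ids: {list(dups[:5])}")
        if (self.values.values < 0).any():
            raise DataError("RPKM values must be nonnegative")

    @property
    def offset_applied(self) -> bool:
        return self.offset is not None

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def samples_for(self, genotype: str) -> list[str]:
        cols = [s for s, g in self.genotypes.items() if g == genotype]
        if not cols:
            raise DataError(f"genotype {genotype!r} has no samples")
        return cols

    def genotype_means(self) -> pd.DataFrame:
        """Arithmetic mean of replicate RPKMs, one column per genotype."""
        return self.values.T.groupby(self.genotypes).mean().T

    # ------------------------------------------------------------------ I/O

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        """Read a TSV whose header encodes genotype and replicate.

        Column names must look like ``WT_rep1``, ``A-KO_rep2`` etc.
        """
        values = pd.read_csv(path, sep="\t", index_col="gene_id")
        genotypes = _genotypes_from_columns(values.columns)
        return cls(values=values, genotypes=genotypes)


def _genotypes_from_columns(columns: Iterable[str]) -> pd.Series:
    labels = {}
    for col in columns:
        m = _SAMPLE_RE.match(col)
        if m is None:
            raise DataError(
                f"sample column {col!r} does not follow '<genotype>_rep<k>'"
            )
        labels[col] = m.group("genotype")
    return pd.Series(labels)


def matrix_from_arrays(
    gene_ids: Iterable[str],
    data: Mapping[str, np.ndarray],
) -> ExpressionMatrix:
    """Build an :class:`ExpressionMatrix` from per-sample arrays.

    ``data`` maps sample names (``WT_rep1`` style) to 1-D value arrays.
    """
    values = pd.DataFrame(dict(data), index=pd.Index(gene_ids, name="gene_id"))
    return ExpressionMatrix(values=values, genotypes=_genotypes_from_columns(values.columns))


# ---------------------------------------------------------------- offsets


def compute_offset(matrix: ExpressionMatrix) -> float:
    """Second quartile (median) of all matrix entries.

    For typical bulk RPKM matrices, where most annotated genes are silent,
    this lands around 0.2-0.3; a warning is recorded when it falls outside
    that range.
    """
    if matrix.offset_applied:
        raise DataError("offset already applied; compute it on the raw matrix")
    if matrix.values.size == 0:
        raise DataError("cannot compute an offset on an empty matrix")
    offset = float(np.median(matrix.values.values))
    if not (0.2 <= offset <= 0.3):
        warnings.warn(
            f"computed offset {offset:.4g} is outside the usual 0.2-0.3 range",
            OffsetRangeWarning,
            stacklevel=2,
        )
    return offset


def apply_offset(matrix: ExpressionMatrix, offset: float) -> ExpressionMatrix:
    """Add ``offset`` to every value; refuses to apply twice."""
    if matrix.offset_applied:
        raise DataError("offset already applied")
    if not offset > 0:
        raise ConfigurationError(f"offset must be positive, got {offset}")
    return ExpressionMatrix(
        values=matrix.values + offset,
        genotypes=matrix.genotypes,
        offset=float(offset),
    )


# --------------------------------------------------------------- collapse


def collapse_fragments(
    matrix: ExpressionMatrix, fragment_to_gene: Mapping[str, str]
) -> ExpressionMatrix:
    """Keep one fragment per gene: the one with the highest RPKM averaged
    over the genotype means.  Ties break on the lexicographically smaller
    fragment id.
    """
    fragments = matrix.values.index
    unmapped = [f for f in fragments if f not in fragment_to_gene]
    if unmapped:
        raise DataError(f"unmapped fragments: {sorted(unmapped)}")
    abundance = matrix.genotype_means().mean(axis=1)
    table = pd.DataFrame(
        {
            "gene": [fragment_to_gene[f] for f in fragments],
            "abundance": abundance.values,
        },
        index=fragments,
    ).sort_index()  # lexicographic order => idxmax keeps the smaller id on ties
    best = table.groupby("gene")["abundance"].idxmax()
    collapsed = matrix.values.loc[best.values].copy()
    collapsed.index = pd.Index(best.index, name="gene_id")
    collapsed = collapsed.sort_index()
    return ExpressionMatrix(
        values=collapsed, genotypes=matrix.genotypes, offset=matrix.offset
    )


# ----------------------------------------------------------------- filter


def filter_low_expression(
    matrix: ExpressionMatrix, min_rpkm: float = 1.0
) -> ExpressionMatrix:
    """Drop genes whose mean RPKM is below ``min_rpkm`` in every genotype.

    Operates on raw (pre-offset) values.
    """
    if matrix.offset_applied:
        raise DataError("low-expression filter must run before the offset")
    keep = matrix.genotype_means().max(axis=1) >= min_rpkm
    return ExpressionMatrix(
        values=matrix.values.loc[keep],
        genotypes=matrix.genotypes,
        offset=None,
    )


# --------------------------------------------------------------------- DE


@dataclass
class DEResult:
    """Per-gene fold change and p-value for one two-group contrast.

    ``table`` is indexed by gene id with columns ``mean_g1``, ``mean_g2``,
    ``log2fc`` (= log2(mean_g1 / mean_g2)), ``abs_fc`` (= 2^|log2fc|, >= 1),
    ``pvalue`` and ``regulated`` (bool).
    """

    table: pd.DataFrame
    group1: str
    group2: str

    def __post_init__(self) -> None:
        missing = {"mean_g1", "mean_g2", "log2fc", "abs_fc", "pvalue", "regulated"} - set(
            self.table.columns
        )
        if missing:
            raise DataError(f"DE table missing columns: {sorted(missing)}")

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    @property
    def regulated_genes(self) -> pd.Index:
        return self.table.index[self.table["regulated"].astype(bool)]

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["regulated"] = out["regulated"].astype(int)
        with open(path, "w") as fh:
            fh.write(f"# group1={self.group1}\tgroup2={self.group2}\n")
            out.to_csv(fh, sep="\t", index_label="gene_id")


def read_de_table(path, group1: str = "g1", group2: str = "g2") -> DEResult:
    """Load a precomputed DE table (e.g. exported from a count-model tool).

    A leading ``# group1=...\tgroup2=...`` comment line, if present,
    overrides the ``group1``/``group2`` arguments.
    """
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            fields = dict(
                part.split("=", 1) for part in first[1:].strip().split("\t") if "=" in part
            )
            group1 = fields.get("group1", group1)
            group2 = fields.get("group2", group2)
            table = pd.read_csv(fh, sep="\t", index_col="gene_id")
        else:
            fh.seek(0)
            table = pd.read_csv(fh, sep="\t", index_col="gene_id")
    table["regulated"] = table["regulated"].astype(bool)
    return DEResult(table=table, group1=group1, group2=group2)


def compute_de(
    matrix: ExpressionMatrix,
    group1: str,
    group2: str,
    fc_threshold: float = FC_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
    var_floor: float = VAR_FLOOR,
) -> DEResult:
    """Fold change and p-value for ``group1`` vs ``group2``.

    The fold change is computed on offset-added linear means; the p-value
    comes from a pooled-variance t-test on log2 values with ``var_floor``
    added to the pooled variance.
    """
    if not matrix.offset_applied:
        raise DataError("compute_de requires an offset-added matrix")
    x1 = matrix.values[matrix.samples_for(group1)].values
    x2 = matrix.values[matrix.samples_for(group2)].values
    n1, n2 = x1.shape[1], x2.shape[1]
    if n1 < 2 or n2 < 2:
        raise DataError(
            f"need >=2 replicates per group; got {group1}:{n1}, {group2}:{n2}"
        )
    mean1 = x1.mean(axis=1)
    mean2 = x2.mean(axis=1)
    log2fc = np.log2(mean1 / mean2)
    abs_fc = np.exp2(np.abs(log2fc))

    l1 = np.log2(x1)
    l2 = np.log2(x2)
    v1 = l1.var(axis=1, ddof=1)
    v2 = l2.var(axis=1, ddof=1)
    df = n1 + n2 - 2
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / df + var_floor
    se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    t = (l1.mean(axis=1) - l2.mean(axis=1)) / se
    pvalue = 2.0 * stats.t.sf(np.abs(t), df)
    pvalue = np.minimum(pvalue, 1.0)

    table = pd.DataFrame(
        {
            "mean_g1": mean1,
            "mean_g2": mean2,
            "log2fc": log2fc,
            "abs_fc": abs_fc,
            "pvalue": pvalue,
            "regulated": (abs_fc > fc_threshold) & (pvalue < p_threshold),
        },
        index=matrix.values.index,
    )
    return DEResult(table=table, group1=group1, group2=group2)


def pool_regulated(de_a: DEResult, de_b: DEResult) -> pd.Index:
    """Union of regulated genes across two contrasts, in the gene order of
    the first table (deterministic)."""
    if set(de_a.genes) != set(de_b.genes):
        raise DataError("DE tables cover different gene universes")
    reg_b = de_b.table["regulated"].reindex(de_a.genes).astype(bool)
    mask = de_a.table["regulated"].astype(bool) | reg_b
    return de_a.genes[mask]
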