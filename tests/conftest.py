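import numpy as np
import pandas as pd
import pytest

from paralogdose.expression import DEResult, ExpressionMatrix, matrix_from_arrays


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """4 genes x (3 genotypes x 2 replicates), hand-picked values."""
    genes = ["gA", "gB", "gC", "gD"]
    data = {
        "WT_rep1": np.array([10.0, 0.5, 2.0, 0.0]),
        "WT_rep2": np.array([10.0, 0.5, 2.0, 0.2]),
        "A-KO_rep1": np.array([5.0, 0.8, 2.0, 0.0]),
        "A-KO_rep2": np.array([5.0, 0.8, 2.0, 0.0]),
        "B-KO_rep1": np.array([2.5, 0.9, 2.0, 0.1]),
        "B-KO_rep2": np.array([2.5, 0.9, 2.0, 0.1]),
    }
    return matrix_from_arrays(genes, data)


def make_de(rows: dict, group1: str = "KO", group2: str = "WT") -> DEResult:
    """Build a DEResult from {gene: (mean_g1, mean_g2, log2fc, abs_fc, p)}.

    The regulated flag is derived with the standard 1.5-fold / 0.05 rule.
    """
    table = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["mean_g1", "mean_g2", "log2fc", "abs_fc", "pvalue"],
    )
    table.index.name = "gene_id"
    table["regulated"] = (table["abs_fc"] > 1.5) & (table["pvalue"] < 0.05)
    return DEResult(table=table, group1=group1, group2=group2)
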