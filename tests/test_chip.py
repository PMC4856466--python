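"""Peak filtering, interval overlap, TSS annotation and occupancy groups."""

import numpy as np
import pandas as pd
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

from paralogdose.chip import (
    assign_peaks_to_genes,
    filter_called_peaks,
    nearest_tss,
    occupancy_hierarchy,
    occupancy_vs_expression,
    overlap_peaks,
    read_peaks_bed,
    tss_localization,
    write_peaks_bed,
)
from paralogdose.errors import ConfigurationError, DataError

from conftest import make_de


def peaks(intervals, chrom="chr1", **extra):
    n = len(intervals)
    df = pd.DataFrame(
        {
            "chrom": [chrom] * n if isinstance(chrom, str) else chrom,
            "start": [i[0] for i in intervals],
            "end": [i[1] for i in intervals],
            "height": extra.get("height", [10.0] * n),
            "fold_enrichment": extra.get("fold_enrichment", [10.0] * n),
            "pvalue": extra.get("pvalue", [1e-9] * n),
        }
    )
    return df


def tss_table(entries):
    """entries: list of (gene_id, chrom, strand, tss)."""
    return pd.DataFrame(entries, columns=["gene_id", "chrom", "strand", "tss"])


class TestFilter:
    def test_boundary_enrichment_is_strict(self):
        p = peaks([(0, 100)], fold_enrichment=[3.0], pvalue=[1e-6])
        assert len(filter_called_peaks(p)) == 0

    def test_passing_peak_kept(self):
        p = peaks([(0, 100)], fold_enrichment=[10.0], pvalue=[4e-5])
        assert len(filter_called_peaks(p)) == 1

    def test_toy_set_counts(self):
        # 6 peaks: 2 fail enrichment, 2 fail p, 1 of those fails both -> 3 pass
        p = peaks(
            [(i * 200, i * 200 + 100) for i in range(6)],
            fold_enrichment=[2.0, 2.5, 10.0, 10.0, 10.0, 10.0],
            pvalue=[1e-9, 1e-3, 1e-3, 1e-9, 1e-9, 1e-9],
        )
        assert len(filter_called_peaks(p)) == 3

    def test_missing_columns_rejected(self):
        with pytest.raises(DataError):
            filter_called_peaks(pd.DataFrame({"chrom": ["chr1"]}))


class TestOverlap:
    def test_basic_overlap_and_half_open_boundary(self):
        x = peaks([(100, 200)])
        y = peaks([(150, 250)])
        _, shared = overlap_peaks(x, y)
        assert shared == 1
        y2 = peaks([(200, 300)])  # touching half-open intervals do not overlap
        _, shared2 = overlap_peaks(x, y2)
        assert shared2 == 0

    def test_different_chromosomes_never_overlap(self):
        x = peaks([(0, 100)], chrom="chr1")
        y = peaks([(0, 100)], chrom="chr2")
        assert overlap_peaks(x, y)[1] == 0

    def test_each_peak_counted_once(self):
        x = peaks([(0, 1000)])
        y = peaks([(10, 20), (30, 40), (50, 60)])
        _, shared = overlap_peaks(x, y)
        assert shared == 1

    def test_chained_overlaps_find_maximum_pairing(self):
        # naive first-available pairing would find only 1 pair here
        x = peaks([(0, 100), (40, 60)])
        y = peaks([(40, 60), (90, 150)])
        _, shared = overlap_peaks(x, y)
        assert shared == 2

    def test_malformed_intervals_rejected(self):
        with pytest.raises(DataError):
            overlap_peaks(peaks([(100, 100)]), peaks([(0, 10)]))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_quadratic_matching_oracle(self, seed):
        rng = np.random.default_rng(seed)
        def random_peaks(n):
            starts = rng.integers(0, 3000, n)
            widths = rng.integers(1, 300, n)
            chroms = rng.choice(["chr1", "chr2"], n)
            return peaks(
                list(zip(starts, starts + widths)), chrom=list(chroms)
            )

        x = random_peaks(int(rng.integers(5, 60)))
        y = random_peaks(int(rng.integers(5, 60)))
        _, shared = overlap_peaks(x, y)
        # independent oracle: all-pairs adjacency + scipy maximum matching
        adj = np.zeros((len(x), len(y)), dtype=int)
        for i in range(len(x)):
            for j in range(len(y)):
                if (
                    x["chrom"][i] == y["chrom"][j]
                    and x["start"][i] < y["end"][j]
                    and y["start"][j] < x["end"][i]
                ):
                    adj[i, j] = 1
        matching = maximum_bipartite_matching(csr_matrix(adj), perm_type="column")
        assert shared == int((matching != -1).sum())
        # symmetry
        assert overlap_peaks(y, x)[1] == shared


class TestTss:
    def test_peak_at_tss_lands_in_first_downstream_bin(self):
        p = peaks([(990, 1010)])  # midpoint 1000
        t = tss_table([("geneA", "chr1", "+", 1000)])
        per_peak, hist = tss_localization(p, t)
        assert per_peak["distance"].iloc[0] == 0
        assert hist.loc[0, "bin_lo"] == 0 and hist.loc[0, "bin_hi"] == 10_000
        assert hist["pct"].sum() == pytest.approx(100.0)

    def test_distance_bins_are_10kb(self):
        p = peaks([(25_990, 26_010)])  # midpoint 26000, TSS at 1000 -> 25 kb
        t = tss_table([("geneA", "chr1", "+", 1000)])
        _, hist = tss_localization(p, t)
        assert hist.loc[0, "bin_lo"] == 20_000 and hist.loc[0, "bin_hi"] == 30_000

    def test_strand_flips_distance_sign(self):
        p = peaks([(1990, 2010)])  # midpoint 2000
        plus = tss_table([("geneA", "chr1", "+", 1000)])
        minus = tss_table([("geneA", "chr1", "-", 1000)])
        assert nearest_tss(p, plus)["distance"].iloc[0] == 1000
        assert nearest_tss(p, minus)["distance"].iloc[0] == -1000

    def test_empty_annotation_rejected(self):
        with pytest.raises(DataError):
            tss_localization(peaks([(0, 10)]), tss_table([]))

    @pytest.mark.parametrize("seed", range(5))
    def test_nearest_matches_linear_scan_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        n_tss = int(rng.integers(3, 40))
        t = tss_table(
            [
                (f"g{i:02d}", "chr1", rng.choice(["+", "-"]), int(rng.integers(0, 10**6)))
                for i in range(n_tss)
            ]
        )
        starts = rng.integers(0, 10**6, 50)
        p = peaks(list(zip(starts, starts + 200)))
        got = nearest_tss(p, t)
        mids = (p["start"] + p["end"]) // 2
        for i in range(len(p)):
            best = min(
                (abs(mids[i] - row.tss), row.gene_id) for row in t.itertuples()
            )
            assert got["gene_id"].iloc[i] == best[1]
            assert abs(got["distance"].iloc[i]) == best[0]


class TestAssignment:
    def test_window_boundary_is_closed(self):
        p = peaks([(990, 1010)])  # midpoint 1000
        t = tss_table([("geneA", "chr1", "+", 11_000)])  # exactly 10 kb away
        assert len(assign_peaks_to_genes(p, t, window=10_000)) == 1
        t2 = tss_table([("geneA", "chr1", "+", 11_001)])
        assert len(assign_peaks_to_genes(p, t2, window=10_000)) == 0

    def test_multi_assignment_allowed(self):
        p = peaks([(990, 1010)])
        t = tss_table(
            [("geneA", "chr1", "+", 2000), ("geneB", "chr1", "-", 5000)]
        )
        assigned = assign_peaks_to_genes(p, t, window=10_000)
        assert sorted(assigned["gene_id"]) == ["geneA", "geneB"]

    def test_invalid_window_rejected(self):
        with pytest.raises(ConfigurationError):
            assign_peaks_to_genes(peaks([(0, 10)]), tss_table([]), window=0)


def _four_sets(spec):
    """spec: {genotype: list of (start, end, height)} on chr1."""
    return {
        g: peaks([(s, e) for s, e, _ in rows], height=[h for *_, h in rows])
        for g, rows in spec.items()
    }


class TestHierarchy:
    TSS = tss_table(
        [("geneA", "chr1", "+", 1000), ("geneB", "chr1", "+", 100_000)]
    )

    def test_gene_bound_everywhere_is_group_four(self):
        sets = _four_sets(
            {g: [(900, 1100, 50.0)] for g in ("WT", "het", "A-KO", "B-KO")}
        )
        groups, ko_only = occupancy_hierarchy(sets, self.TSS)
        assert groups["geneA"] == 4 and ko_only == []

    def test_wt_only_gene_is_group_one(self):
        sets = _four_sets(
            {
                "WT": [(900, 1100, 50.0)],
                "het": [(99_900, 100_100, 50.0)],
                "A-KO": [],
                "B-KO": [],
            }
        )
        groups, ko_only = occupancy_hierarchy(sets, self.TSS)
        assert groups["geneA"] == 1
        assert ko_only == ["geneB"]

    def test_nesting_is_strict(self):
        # bound in WT and A-KO but not het: the chain breaks at het
        sets = _four_sets(
            {
                "WT": [(900, 1100, 50.0)],
                "het": [],
                "A-KO": [(900, 1100, 20.0)],
                "B-KO": [],
            }
        )
        groups, _ = occupancy_hierarchy(sets, self.TSS)
        assert groups["geneA"] == 1


class TestOccupancyVsExpression:
    def test_single_gene_group_means(self):
        groups = pd.Series({"geneA": 1})
        assign = pd.DataFrame(
            {"gene_id": ["geneA"], "peak_index": [0], "height": [40.0]}
        )
        de = make_de({"geneA": (2.0, 1.0, 1.0, 2.0, 0.001)})
        summary, dropped = occupancy_vs_expression(groups, assign, de)
        row = summary[summary["group"] == 1].iloc[0]
        assert row["n_genes"] == 1
        assert row["mean_wt_height"] == 40.0
        assert row["mean_neglog10_p"] == pytest.approx(3.0)
        assert dropped == 0

    def test_two_gene_hand_arithmetic(self):
        groups = pd.Series({"geneA": 2, "geneB": 2})
        assign = pd.DataFrame(
            {
                "gene_id": ["geneA", "geneB"],
                "peak_index": [0, 1],
                "height": [10.0, 30.0],
            }
        )
        de = make_de(
            {"geneA": (2.0, 1.0, 1.0, 2.0, 0.1), "geneB": (2.0, 1.0, 1.0, 2.0, 0.001)}
        )
        summary, _ = occupancy_vs_expression(groups, assign, de)
        row = summary[summary["group"] == 2].iloc[0]
        assert row["mean_wt_height"] == pytest.approx(20.0)
        assert row["mean_neglog10_p"] == pytest.approx(2.0)

    def test_genes_without_pvalue_dropped_and_counted(self):
        groups = pd.Series({"geneA": 1, "geneB": 1})
        assign = pd.DataFrame(
            {"gene_id": ["geneA", "geneB"], "peak_index": [0, 1], "height": [10.0, 30.0]}
        )
        de = make_de({"geneA": (2.0, 1.0, 1.0, 2.0, 0.1)})
        summary, dropped = occupancy_vs_expression(groups, assign, de)
        assert dropped == 1
        assert summary[summary["group"] == 1].iloc[0]["n_genes"] == 1

    def test_empty_groups_flagged_not_zeroed(self):
        groups = pd.Series({"geneA": 4})
        assign = pd.DataFrame(
            {"gene_id": ["geneA"], "peak_index": [0], "height": [10.0]}
        )
        de = make_de({"geneA": (2.0, 1.0, 1.0, 2.0, 0.1)})
        summary, _ = occupancy_vs_expression(groups, assign, de)
        empty = summary[summary["group"] == 1].iloc[0]
        assert empty["n_genes"] == 0 and np.isnan(empty["mean_wt_height"])


class TestBedIO:
    def test_roundtrip(self, tmp_path):
        p = peaks([(0, 100), (500, 700)], height=[5.0, 9.0])
        path = tmp_path / "peaks.bed"
        write_peaks_bed(p, path)
        back = read_peaks_bed(path)
        np.testing.assert_array_equal(back["start"], p["start"])
        np.testing.assert_array_equal(back["height"], p["height"])
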