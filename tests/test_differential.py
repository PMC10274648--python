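"""Gene-level signal, bead normalization, grouped ratios, Mann-Whitney."""

import itertools

import numpy as np
import pandas as pd
import pytest

from spidr.differential import (
    gene_signal,
    group_test,
    mann_whitney,
    mann_whitney_exact,
    normalize_by_beads,
    read_count_ratio,
    top_grouped_ratios,
)

TX = pd.DataFrame(
    {
        "gene_id": ["G1", "G2", "G2"],
        "transcript_id": ["G1-T1", "G2-T1", "G2-T2"],
        "reference": ["chrS"] * 3,
        "start": [0, 500, 500],
        "end": [300, 900, 1200],
        "strand": ["+"] * 3,
    }
)


def _bedgraph(rows):
    return pd.DataFrame(rows, columns=["reference", "start", "end", "value"])


class TestGeneSignal:
    def test_absmax_over_gene(self):
        bg = _bedgraph(
            [("chrS", 0, 100, 2.0), ("chrS", 100, 200, 5.0), ("chrS", 200, 300, 3.0)]
        )
        out = gene_signal(bg, TX).set_index("gene_id")
        assert out.loc["G1", "raw_value"] == 5.0

    def test_isoform_with_highest_value_used(self):
        bg = _bedgraph([("chrS", 600, 700, 5.0), ("chrS", 1000, 1100, 8.0)])
        out = gene_signal(bg, TX).set_index("gene_id")
        assert out.loc["G2", "raw_value"] == 8.0
        assert out.loc["G2", "isoform"] == "G2-T2"

    def test_no_coverage_gives_zero(self):
        bg = _bedgraph([("chrS", 2000, 2100, 9.0)])
        out = gene_signal(bg, TX).set_index("gene_id")
        assert out.loc["G1", "raw_value"] == 0.0

    def test_absolute_magnitude(self):
        bg = _bedgraph([("chrS", 0, 100, -7.0), ("chrS", 100, 200, 3.0)])
        out = gene_signal(bg, TX).set_index("gene_id")
        assert out.loc["G1", "raw_value"] == 7.0

    def test_unsorted_bedgraph_raises(self):
        bg = _bedgraph([("chrS", 200, 300, 1.0), ("chrS", 0, 100, 1.0)])
        with pytest.raises(ValueError, match="sorted"):
            gene_signal(bg, TX)


class TestNormalizeByBeads:
    def _beads(self):
        return pd.DataFrame(
            {
                "protein": ["P", "P"],
                "sample_label": ["control", "torin"],
                "n_clusters": [100, 200],
            }
        )

    def test_ratio_arithmetic(self):
        sig_t = pd.DataFrame({"gene_id": ["G"], "isoform": ["t"], "raw_value": [40.0]})
        sig_c = pd.DataFrame({"gene_id": ["G"], "isoform": ["t"], "raw_value": [10.0]})
        nt = normalize_by_beads(sig_t, self._beads(), "P", "torin")
        nc = normalize_by_beads(sig_c, self._beads(), "P", "control")
        assert nt.corrected_value.iloc[0] == pytest.approx(0.2)
        assert nc.corrected_value.iloc[0] == pytest.approx(0.1)
        ratio = top_grouped_ratios(nt, nc, pd.DataFrame(columns=["gene_id", "score"]))
        assert ratio.log2_ratio.iloc[0] == pytest.approx(1.0)

    def test_equal_bead_counts_noop_on_ratios(self):
        beads = pd.DataFrame(
            {"protein": ["P", "P"], "sample_label": ["a", "b"], "n_clusters": [150, 150]}
        )
        sig = pd.DataFrame({"gene_id": ["G"], "isoform": ["t"], "raw_value": [6.0]})
        na = normalize_by_beads(sig, beads, "P", "a")
        nb = normalize_by_beads(sig.assign(raw_value=3.0), beads, "P", "b")
        ratios = top_grouped_ratios(na, nb, pd.DataFrame(columns=["gene_id", "score"]))
        assert ratios.log2_ratio.iloc[0] == pytest.approx(1.0)  # 6/3 unchanged

    def test_zero_bead_count_raises(self):
        sig = pd.DataFrame({"gene_id": ["G"], "isoform": ["t"], "raw_value": [1.0]})
        with pytest.raises(ValueError, match="cannot normalize"):
            normalize_by_beads(sig, self._beads(), "P", "missing")


class TestTopGroupedRatios:
    def _signals(self, values):
        return pd.DataFrame(
            {
                "gene_id": list(values),
                "isoform": ["t"] * len(values),
                "raw_value": list(values.values()),
                "corrected_value": list(values.values()),
            }
        )

    def test_identical_conditions_all_zero(self):
        sig = self._signals({"G1": 2.0, "G2": 5.0})
        out = top_grouped_ratios(sig, sig, pd.DataFrame(columns=["gene_id", "score"]))
        assert (out.log2_ratio == 0).all()

    def test_antisymmetric_under_condition_swap(self):
        a = self._signals({"G1": 4.0, "G2": 1.0})
        b = self._signals({"G1": 2.0, "G2": 8.0})
        scores = pd.DataFrame(columns=["gene_id", "score"])
        fwd = top_grouped_ratios(a, b, scores).set_index("gene_id").log2_ratio
        rev = top_grouped_ratios(b, a, scores).set_index("gene_id").log2_ratio
        assert np.allclose(fwd, -rev)

    def test_zero_coverage_genes_excluded(self):
        a = self._signals({"G1": 4.0, "G2": 0.0})
        b = self._signals({"G1": 2.0, "G2": 3.0})
        out = top_grouped_ratios(a, b, pd.DataFrame(columns=["gene_id", "score"]))
        assert list(out.gene_id) == ["G1"]

    def test_score_binning_and_unscored(self):
        a = self._signals({"G1": 4.0, "G2": 4.0, "G3": 4.0})
        b = self._signals({"G1": 2.0, "G2": 2.0, "G3": 2.0})
        scores = pd.DataFrame({"gene_id": ["G1", "G2"], "score": [0.5, 3.0]})
        out = top_grouped_ratios(a, b, scores, bin_edges=(1.0, 2.0)).set_index("gene_id")
        assert out.loc["G1", "top_group"] == "score<=1"
        assert out.loc["G2", "top_group"] == "score>2"
        assert out.loc["G3", "top_group"] == "unscored"

    def test_empty_intersection_raises(self):
        a = self._signals({"G1": 1.0})
        b = self._signals({"G2": 1.0})
        with pytest.raises(ValueError, match="shared"):
            top_grouped_ratios(a, b, pd.DataFrame(columns=["gene_id", "score"]))


def oracle_mann_whitney(a, b):
    """Full enumeration oracle computing U from the values directly."""
    pooled = list(a) + list(b)
    n = len(pooled)
    n_a = len(a)

    def u_of(subset):
        u = 0.0
        group_a = [pooled[i] for i in subset]
        group_b = [pooled[i] for i in range(n) if i not in subset]
        for x in group_a:
            for y in group_b:
                u += (x > y) + 0.5 * (x == y)
        return u

    obs = u_of(tuple(range(n_a)))
    us = [u_of(s) for s in itertools.combinations(range(n), n_a)]
    le = sum(u <= obs + 1e-9 for u in us)
    ge = sum(u >= obs - 1e-9 for u in us)
    return obs, min(1.0, 2.0 * min(le, ge) / len(us))


class TestMannWhitney:
    def test_identical_groups_p_one(self):
        r = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.p_value == pytest.approx(1.0)

    def test_separated_groups_exact(self):
        r = mann_whitney([1, 2, 3], [10, 11, 12])
        assert r.u_statistic == 0.0
        assert r.p_value == pytest.approx(0.1)  # 2/C(6,3)*... = 2/20
        assert r.method == "exact"

    @pytest.mark.parametrize(
        "a, b",
        [
            ([1, 2], [3, 4]),
            ([1, 5, 2], [2, 2, 9]),  # ties across and within groups
            ([0, 0, 0], [0, 0]),  # all tied
            ([3, 1, 4, 1], [5, 9, 2, 6]),
            ([1.5, 2.5], [1.5, 2.5, 3.5, 0.5]),
        ],
    )
    def test_exact_path_matches_full_enumeration(self, a, b):
        got = mann_whitney_exact(a, b)
        u_oracle, p_oracle = oracle_mann_whitney(a, b)
        assert got.u_statistic == pytest.approx(u_oracle)
        assert got.p_value == pytest.approx(p_oracle)

    def test_exact_and_asymptotic_agree_at_crossover(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 10)
        b = rng.normal(1, 1, 10)
        exact = mann_whitney_exact(a, b)
        from scipy.stats import mannwhitneyu

        u, p = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert exact.p_value == pytest.approx(p, rel=0.10)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney([], [1.0])

    def test_group_test_selects_groups(self):
        grouped = pd.DataFrame(
            {
                "log2_ratio": [0.1, 0.2, 0.3, 2.0, 2.1, 2.2],
                "top_group": ["low"] * 3 + ["high"] * 3,
            }
        )
        r = group_test(grouped, "high", "low")
        assert r.p_value < 0.2
        assert r.n_a == r.n_b == 3


class TestReadCountRatio:
    def _counts(self):
        return pd.DataFrame(
            {
                "protein": ["P1", "P1", "P2", "P2"],
                "condition": ["torin", "control"] * 2,
                "n_reads": [400, 100, 50, 50],
            }
        )

    def _beads(self):
        return pd.DataFrame(
            {
                "protein": ["P1", "P1", "P2", "P2"],
                "sample_label": ["torin", "control"] * 2,
                "n_clusters": [100, 100, 50, 50],
            }
        )

    def test_equal_normalized_reads_ratio_one(self):
        out = read_count_ratio(self._counts(), self._beads(), "torin", "control")
        assert out.set_index("protein").loc["P2", "ratio"] == pytest.approx(1.0)

    def test_sorted_by_ratio_descending(self):
        out = read_count_ratio(self._counts(), self._beads(), "torin", "control")
        assert list(out.protein) == ["P1", "P2"]
        assert out.ratio.iloc[0] == pytest.approx(4.0)

    def test_zero_denominator_flagged_infinite(self):
        counts = pd.DataFrame(
            {
                "protein": ["P1", "P1"],
                "condition": ["torin", "control"],
                "n_reads": [10, 0],
            }
        )
        beads = pd.DataFrame(
            {
                "protein": ["P1", "P1"],
                "sample_label": ["torin", "control"],
                "n_clusters": [5, 5],
            }
        )
        out = read_count_ratio(counts, beads, "torin", "control")
        assert bool(out.infinite.iloc[0])
        assert np.isinf(out.ratio.iloc[0])
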