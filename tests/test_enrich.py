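"""Window counting, permutation background, p-values, truncations."""

import numpy as np
import pandas as pd
import pytest

from spidr.clusters import RnaRecord
from spidr.enrich import (
    Genome,
    ReadSet,
    TruncationProfile,
    WindowGrid,
    call_peaks,
    count_windows,
    export_bedgraph,
    motif_centered_profile,
    permutation_background,
    read_bedgraph,
    run_enrichment,
    truncation_coordinate,
    truncation_enrichment,
    truncation_readset,
    window_enrichment,
)

GENOME = Genome({"chrS": 1000})


def _rs(records):
    return ReadSet.from_records(records, GENOME)


class TestCountWindows:
    def test_read_increments_every_overlapped_window(self):
        grid = WindowGrid(GENOME, 10)
        counts = count_windows(_rs([RnaRecord("chrS", 105, 125, "+")]), grid)
        assert counts["+"][10] == 1 and counts["+"][11] == 1 and counts["+"][12] == 1
        assert counts["+"].sum() == 3
        assert counts["-"].sum() == 0

    def test_half_open_boundary_single_window(self):
        grid = WindowGrid(GENOME, 10)
        counts = count_windows(_rs([RnaRecord("chrS", 100, 110, "+")]), grid)
        assert counts["+"][10] == 1
        assert counts["+"].sum() == 1

    def test_empty_input(self):
        grid = WindowGrid(GENOME, 10)
        counts = count_windows(_rs([]), grid)
        assert counts["+"].sum() == 0 and counts["-"].sum() == 0

    def test_read_off_reference_end_raises(self):
        grid = WindowGrid(GENOME, 10)
        rs = ReadSet(
            GENOME,
            np.array([0], dtype=np.int32),
            np.array([990]),
            np.array([1020]),
            np.array([False]),
        )
        with pytest.raises(ValueError, match="chrS:990-1020"):
            count_windows(rs, grid)

    def test_strand_separation(self):
        grid = WindowGrid(GENOME, 100)
        counts = count_windows(
            _rs([RnaRecord("chrS", 0, 50, "+"), RnaRecord("chrS", 0, 50, "-")]), grid
        )
        assert counts["+"][0] == 1 and counts["-"][0] == 1


class TestPermutationBackground:
    def _pool(self, n=400, seed=0):
        rng = np.random.default_rng(seed)
        starts = rng.integers(0, 950, size=n)
        return ReadSet(
            GENOME,
            np.zeros(n, dtype=np.int32),
            starts,
            starts + 50,
            rng.random(n) < 0.5,
        )

    def test_each_permutation_uses_exactly_target_n_reads(self):
        # one window spanning the whole contig: row sums count reads exactly
        grid = WindowGrid(Genome({"chrS": 1000}), 1000)
        pool = self._pool()
        perms = permutation_background(100, pool, grid, n_perms=20, seed=1)
        totals = perms["+"].sum(axis=1) + perms["-"].sum(axis=1)
        assert (totals == 100).all()

    def test_same_seed_identical_matrices(self):
        grid = WindowGrid(GENOME, 100)
        pool = self._pool()
        a = permutation_background(50, pool, grid, n_perms=10, seed=3)
        b = permutation_background(50, pool, grid, n_perms=10, seed=3)
        assert (a["+"] == b["+"]).all() and (a["-"] == b["-"]).all()

    def test_pool_too_small_raises(self):
        grid = WindowGrid(GENOME, 100)
        with pytest.raises(ValueError, match="replacement"):
            permutation_background(1000, self._pool(10), grid, n_perms=5, seed=0)

    def test_uniform_pool_mean_matches_expectation(self):
        """Sampling-without-replacement means track pool window masses."""
        grid = WindowGrid(GENOME, 100)
        pool = self._pool(n=2000, seed=5)
        target = 500
        perms = permutation_background(target, pool, grid, n_perms=200, seed=7)
        pool_counts = count_windows(pool, grid)
        for strand in "+-":
            expected = pool_counts[strand] * target / len(pool)
            got = perms[strand].mean(axis=0)
            assert np.allclose(got, expected, atol=1.5)


class TestWindowEnrichment:
    def _stats(self, observed, perm_rows):
        grid = WindowGrid(Genome({"chrS": 100}), 100)
        obs = {"+": np.array([observed]), "-": np.array([0])}
        perms = {
            "+": np.array(perm_rows, dtype=np.int32).reshape(-1, 1),
            "-": np.zeros((len(perm_rows), 1), dtype=np.int32),
        }
        return window_enrichment(obs, perms, grid)

    def test_enrichment_ratio(self):
        df = self._stats(20, [5] * 100)
        assert df.enrichment.iloc[0] == pytest.approx(4.0)

    def test_p_with_observed_included(self):
        df = self._stats(20, [5] * 100)  # no permutation reaches 20
        assert df.p_value.iloc[0] == pytest.approx(1 / 101)

    def test_p_is_one_when_all_permutations_reach_observed(self):
        df = self._stats(5, [5] * 100)
        assert df.p_value.iloc[0] == pytest.approx(1.0)

    def test_expected_floor_flagged(self):
        df = self._stats(3, [0] * 50)
        assert bool(df.expected_floored.iloc[0])
        assert df.enrichment.iloc[0] == pytest.approx(3 / (1 / 50))

    def test_p_monotone_in_observed(self):
        perm_rows = list(range(100))
        ps = [self._stats(obs, perm_rows).p_value.iloc[0] for obs in (5, 20, 50, 99)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestBruteForceOracle:
    def test_p_values_match_independent_recomputation(self):
        """Toy instance: <=50 reads, 5 windows; recompute permutations naively."""
        genome = Genome({"toy": 50})
        grid = WindowGrid(genome, 10)
        rng = np.random.default_rng(21)
        t_starts = np.concatenate([rng.integers(0, 40, 20), np.full(10, 12)])
        target = ReadSet(
            genome, np.zeros(30, dtype=np.int32), t_starts, t_starts + 8,
            np.zeros(30, dtype=bool),
        )
        p_starts = rng.integers(0, 40, 50)
        pool = ReadSet(
            genome, np.zeros(50, dtype=np.int32), p_starts, p_starts + 8,
            np.zeros(50, dtype=bool),
        )
        n_perms = 40
        observed = count_windows(target, grid)
        perms = permutation_background(30, pool, grid, n_perms=n_perms, seed=9)
        stats = window_enrichment(observed, perms, grid)

        # oracle: same sampled indices (same seeded draw), naive counting
        oracle_rng = np.random.default_rng(9)
        naive = np.zeros((n_perms, grid.total), dtype=int)
        for p in range(n_perms):
            idx = oracle_rng.choice(50, size=30, replace=False)
            for i in idx:
                for w in range(p_starts[i] // 10, (p_starts[i] + 8 - 1) // 10 + 1):
                    naive[p, w] += 1
        naive_obs = np.zeros(grid.total, dtype=int)
        for s in t_starts:
            for w in range(s // 10, (s + 8 - 1) // 10 + 1):
                naive_obs[w] += 1
        for row in stats.itertuples():
            col = row.start // 10
            assert row.observed == naive_obs[col]
            k = int((naive[:, col] >= naive_obs[col]).sum())
            assert row.p_value == pytest.approx((k + 1) / (n_perms + 1))
            expected = naive[:, col].mean()
            if expected > 0:
                assert row.enrichment == pytest.approx(naive_obs[col] / expected)


class TestCallPeaks:
    def _frame(self, observed, p):
        return pd.DataFrame(
            {
                "reference": ["chrS"], "start": [0], "end": [100], "strand": ["+"],
                "observed": [observed], "expected_mean": [1.0],
                "enrichment": [observed], "p_value": [p], "n_perms": [100],
                "expected_floored": [False],
            }
        )

    def test_min_reads_rejects(self):
        assert call_peaks(self._frame(9, 0.001)).empty

    def test_significant_window_kept(self):
        assert len(call_peaks(self._frame(15, 0.0099))) == 1

    def test_alpha_is_strict(self):
        assert call_peaks(self._frame(15, 0.05)).empty


class TestTruncations:
    def test_truncation_coordinate_plus_strand(self):
        assert truncation_coordinate(RnaRecord("chrS", 1000, 1150, "+")) == 1000

    def test_truncation_coordinate_minus_strand(self):
        assert truncation_coordinate(RnaRecord("chrS", 1000, 1150, "-")) == 1149

    def test_duplicates_share_coordinate(self):
        a = RnaRecord("chrS", 10, 60, "+")
        b = RnaRecord("chrS", 10, 60, "+")
        assert truncation_coordinate(a) == truncation_coordinate(b)

    def test_total_truncations_equals_reads(self):
        records = [RnaRecord("chrS", i * 10, i * 10 + 40, "+") for i in range(10)]
        records += [RnaRecord("chrS", i * 10, i * 10 + 40, "-") for i in range(5)]
        target = _rs(records)
        others = _rs(
            [RnaRecord("chrS", i * 7, i * 7 + 30, "+") for i in range(30)]
        )
        profile = truncation_enrichment(target, others, n_perms=10, seed=0)
        assert profile.total_truncations == len(records)

    def test_same_seed_identical_profile(self):
        target = _rs([RnaRecord("chrS", 100, 160, "+")] * 5)
        others = _rs([RnaRecord("chrS", i * 9, i * 9 + 30, "+") for i in range(40)])
        a = truncation_enrichment(target, others, n_perms=10, seed=4)
        b = truncation_enrichment(target, others, n_perms=10, seed=4)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_no_reads_empty_profile(self):
        profile = truncation_enrichment(_rs([]), _rs([]), n_perms=10, seed=0)
        assert profile.total_truncations == 0
        assert profile.table.empty


class TestMotifProfile:
    def _profile(self, positions, genome=GENOME):
        counts = {
            "+": np.zeros(genome.lengths["chrS"], dtype=np.int64),
            "-": np.zeros(genome.lengths["chrS"], dtype=np.int64),
        }
        for p in positions:
            counts["+"][p] += 1
        return TruncationProfile(genome=genome, counts=counts)

    def _peaks(self):
        return pd.DataFrame(
            {
                "reference": ["chrS"], "start": [0], "end": [1000], "strand": ["+"],
            }
        )

    def test_spike_two_nt_upstream(self):
        motifs = [("chrS", 100, 107, "+"), ("chrS", 300, 307, "+")]
        profile = self._profile([98, 298])
        table = motif_centered_profile(profile, self._peaks(), motifs, half_width=10)
        spike = table.loc[table["count"].idxmax()]
        assert spike.offset == -2
        assert spike.frequency == pytest.approx(1.0)

    def test_no_motifs_empty(self):
        table = motif_centered_profile(
            self._profile([98]), self._peaks(), [], half_width=10
        )
        assert table.empty

    def test_motif_outside_peaks_excluded(self):
        peaks = pd.DataFrame(
            {"reference": ["chrS"], "start": [0], "end": [50], "strand": ["+"]}
        )
        table = motif_centered_profile(
            self._profile([98]), peaks, [("chrS", 100, 107, "+")], half_width=10
        )
        assert table.empty

    def test_uniform_truncations_flat(self):
        rng = np.random.default_rng(8)
        positions = rng.integers(0, 1000, size=20_000)
        profile = self._profile(positions)
        motifs = [("chrS", int(m), int(m) + 7, "+") for m in rng.integers(50, 950, 30)]
        table = motif_centered_profile(profile, self._peaks(), motifs, half_width=20)
        # 41 offsets, ~uniform: all frequencies close to 1/41
        assert table.frequency.max() < 3 / 41


class TestBedgraph:
    def test_format_and_round_trip(self, tmp_path):
        stats = pd.DataFrame(
            {
                "reference": ["chrS", "chrS"], "start": [100, 200],
                "end": [110, 210], "strand": ["+", "+"],
                "observed": [12, 0], "expected_mean": [3.0, 1.0],
                "enrichment": [4.0, 0.0], "p_value": [0.01, 1.0],
                "n_perms": [100, 100], "expected_floored": [False, False],
            }
        )
        path = tmp_path / "x.bedgraph"
        n = export_bedgraph(stats, path, strand="+")
        assert n == 1  # zero-observed window omitted
        lines = path.read_text().splitlines()
        assert lines[1] == "chrS\t100\t110\t4.000000"
        back = read_bedgraph(path)
        assert back.value.iloc[0] == pytest.approx(4.0, abs=1e-6)

    def test_empty_stats_header_only(self, tmp_path):
        path = tmp_path / "empty.bedgraph"
        export_bedgraph(pd.DataFrame(columns=["reference", "start", "end", "strand",
                                              "observed", "enrichment"]), path)
        assert path.read_text().startswith("track")
        assert len(path.read_text().splitlines()) == 1


def test_peak_reads_fasta_exports_only_peak_reads(tmp_path):
    from spidr.enrich import peak_reads_fasta

    fasta = tmp_path / "g.fa"
    fasta.write_text(">chrS\n" + "ACGT" * 50 + "\n")
    peaks = pd.DataFrame(
        {"reference": ["chrS"], "start": [40], "end": [60], "strand": ["+"]}
    )
    reads = [
        RnaRecord("chrS", 45, 55, "+"),   # inside the peak
        RnaRecord("chrS", 100, 120, "+"),  # outside
        RnaRecord("chrS", 45, 55, "-"),   # wrong strand
    ]
    out = tmp_path / "reads.fa"
    n = peak_reads_fasta(reads, peaks, fasta, out)
    assert n == 1
    lines = out.read_text().splitlines()
    assert lines[0].startswith(">read0|chrS:45-55:+")
    assert lines[1] == ("ACGT" * 50)[45:55]


def test_run_enrichment_smoke():
    rng = np.random.default_rng(2)
    starts = rng.integers(0, 900, 300)
    pool = ReadSet(GENOME, np.zeros(300, dtype=np.int32), starts, starts + 50,
                   rng.random(300) < 0.5)
    t_starts = np.concatenate([rng.integers(0, 900, 40), np.full(20, 500)])
    target = ReadSet(GENOME, np.zeros(60, dtype=np.int32), t_starts, t_starts + 50,
                     np.zeros(60, dtype=bool))
    stats = run_enrichment(target, pool, window=100, n_perms=100, seed=5)
    peak_row = stats[(stats.start == 500) & (stats.strand == "+")]
    assert int(peak_row.observed.iloc[0]) >= 20
    assert float(peak_row.p_value.iloc[0]) < 0.05
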