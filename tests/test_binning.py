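"""Genome tiling, peak ingestion, decile normalization, blacklist filter."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import rankdata

from cobind.binning import (
    Blacklist,
    GenomeLayout,
    assign_peaks_to_bins,
    blacklist_windows,
    build_occupancy_matrix,
    decile_normalize,
    read_chrom_sizes,
    read_peaks,
    tile_genome,
)
from conftest import make_peakset


class TestTileGenome:
    def test_partial_last_bin(self):
        index = tile_genome(GenomeLayout({"c": 1000}), 300)
        frame = index.to_frame()
        assert list(frame["start"]) == [0, 300, 600, 900]
        assert list(frame["end"]) == [300, 600, 900, 1000]

    def test_exact_multiple_single_bin(self):
        index = tile_genome(GenomeLayout({"c": 300}), 300)
        assert index.n_bins == 1
        assert list(index.to_frame().iloc[0][["start", "end"]]) == [0, 300]

    def test_multi_chromosome_ids_in_declaration_order(self):
        index = tile_genome(GenomeLayout({"A": 700, "B": 500}), 300)
        frame = index.to_frame()
        assert index.n_bins == 5
        assert list(frame.index) == [0, 1, 2, 3, 4]
        assert list(frame["chrom"]) == ["A", "A", "A", "B", "B"]

    def test_rejects_bad_bin_size(self):
        with pytest.raises(ValueError):
            tile_genome(GenomeLayout({"c": 100}), 0)

    @settings(max_examples=25, deadline=None)
    @given(
        lengths=st.lists(st.integers(1, 5000), min_size=1, max_size=4),
        bin_size=st.integers(1, 700),
    )
    def test_bin_widths_conserve_genome_length(self, lengths, bin_size):
        layout = GenomeLayout({f"c{i}": n for i, n in enumerate(lengths)})
        frame = tile_genome(layout, bin_size).to_frame()
        assert (frame["end"] - frame["start"]).sum() == layout.total_length


class TestReadPeaks:
    def test_narrowpeak_signal_value(self, tmp_path):
        f = tmp_path / "a.narrowPeak"
        f.write_text("chr1\t100\t250\tp1\t0\t.\t8.1\t5.2\t3.3\t40\n")
        ps = read_peaks(f, format="narrowPeak", score_column="signalValue")
        row = ps.peaks.iloc[0]
        assert (row["chrom"], row["start"], row["end"], row["score"]) == (
            "chr1", 100, 250, 8.1,
        )

    def test_bed6_zero_score_retained(self, tmp_path):
        f = tmp_path / "a.bed"
        f.write_text("chr1\t5\t50\tx\t0\t+\n")
        ps = read_peaks(f, format="bed")
        assert ps.peaks.iloc[0]["score"] == 0.0

    def test_empty_file_gives_empty_peakset(self, tmp_path):
        f = tmp_path / "empty.bed"
        f.write_text("")
        assert len(read_peaks(f, format="bed")) == 0

    def test_malformed_coordinate_names_line(self, tmp_path):
        f = tmp_path / "bad.bed"
        f.write_text("chr1\t0\t10\tx\t1\t+\nchr1\toops\t20\ty\t2\t+\n")
        with pytest.raises(ValueError, match="line 2"):
            read_peaks(f, format="bed")

    def test_tsv_requires_score_column(self, tmp_path):
        f = tmp_path / "t.tsv"
        f.write_text("chrom\tstart\tend\tmyscore\nchr1\t0\t10\t3.5\n")
        ps = read_peaks(f, format="tsv", score_column="myscore")
        assert ps.peaks.iloc[0]["score"] == 3.5
        with pytest.raises(ValueError):
            read_peaks(f, format="tsv")
        with pytest.raises(ValueError):
            read_peaks(f, format="tsv", score_column="nope")

    def test_record_count_preserved(self, tmp_path):
        lines = "".join(f"chr1\t{i * 10}\t{i * 10 + 5}\tp{i}\t{i}\t.\n" for i in range(7))
        f = tmp_path / "a.bed"
        f.write_text(lines)
        assert len(read_peaks(f, format="bed")) == 7


class TestAssignPeaksToBins:
    def test_boundary_spanning_peak_hits_both_bins(self, toy_index):
        ps = make_peakset("t", [("chr1", 250, 320, 1.0)])
        assert set(assign_peaks_to_bins(ps, toy_index)) == {0, 1}

    def test_half_open_boundary(self, toy_index):
        ps = make_peakset("t", [("chr1", 300, 301, 1.0)])
        assert set(assign_peaks_to_bins(ps, toy_index)) == {1}

    def test_max_score_rule(self, toy_index):
        ps = make_peakset("t", [("chr1", 10, 50, 3.0), ("chr1", 60, 90, 7.0)])
        assert assign_peaks_to_bins(ps, toy_index)[0] == 7.0

    def test_unknown_chromosome_named_in_error(self, toy_index):
        ps = make_peakset("t", [("chrX", 0, 10, 1.0)])
        with pytest.raises(KeyError, match="chrX"):
            assign_peaks_to_bins(ps, toy_index)

    def test_matches_per_base_brute_force(self):
        rng = np.random.default_rng(0)
        layout = GenomeLayout({"c": 1000})
        index = tile_genome(layout, 37)
        starts = rng.integers(0, 990, size=100)
        ends = starts + rng.integers(1, 60, size=100)
        ends = np.minimum(ends, 1000)
        scores = rng.uniform(0, 10, size=100)
        ps = make_peakset("t", list(zip(["c"] * 100, starts, ends, scores)))
        got = assign_peaks_to_bins(ps, index)
        # brute force: mark every covered base, then collect per-bin maxima
        expect = {}
        for s, e, sc in zip(starts, ends, scores):
            for base in range(s, e):
                b = base // 37
                expect[b] = max(expect.get(b, -np.inf), sc)
        assert got == expect


class TestDecileNormalize:
    def test_distinct_scores_one_per_decile(self):
        scores = {i: float(i + 1) for i in range(10)}
        assert list(decile_normalize(scores).values()) == list(range(1, 11))

    def test_twenty_distinct_two_per_decile(self):
        deciles = decile_normalize({i: float(i) for i in range(20)})
        counts = pd.Series(list(deciles.values())).value_counts()
        assert (counts == 2).all() and len(counts) == 10

    def test_ties_share_average_rank_decile(self):
        # four tied scores: average rank 2.5 -> ceil(10*2.5/4) = 7
        deciles = decile_normalize({i: 5.0 for i in range(4)})
        assert set(deciles.values()) == {7}
        # cross-check against an independent midrank computation
        r = rankdata([5.0] * 4, method="average")
        assert all(d == math.ceil(10 * ri / 4) for d, ri in zip(deciles.values(), r))

    def test_empty_input(self):
        assert decile_normalize({}) == {}

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=200))
    def test_monotone_and_idempotent(self, values):
        scores = dict(enumerate(values))
        d1 = decile_normalize(scores)
        items = sorted(scores, key=scores.get)
        for a, b in zip(items, items[1:]):
            assert d1[a] <= d1[b]
        assert set(d1.values()) <= set(range(1, 11))
        # re-normalizing the deciles reproduces the same partition
        d2 = decile_normalize({k: float(v) for k, v in d1.items()})
        groups1 = {}
        for k, v in d1.items():
            groups1.setdefault(v, set()).add(k)
        groups2 = {}
        for k, v in d2.items():
            groups2.setdefault(v, set()).add(k)
        assert sorted(map(sorted, groups1.values())) == sorted(
            map(sorted, groups2.values())
        )


class TestBlacklist:
    def _coverage(self, counts):
        n = len(counts)
        return pd.DataFrame(
            {
                "chrom": ["c"] * n,
                "start": np.arange(n) * 200,
                "end": (np.arange(n) + 1) * 200,
                "count": counts,
            }
        )

    def test_extreme_window_flagged(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(50, size=1000).astype(float)
        counts[123] = 100_000
        bl = blacklist_windows(self._coverage(counts))
        # independent application of the stated rule
        x = np.log10(counts + 1)
        med = np.median(x)
        mad = max(1.4826 * np.median(np.abs(x - med)), 1e-8)
        expect = set(np.flatnonzero(np.abs(x - med) > 5 * mad))
        got = set(bl.windows["start"] // 200)
        assert got == expect
        assert 123 in got

    def test_uniform_counts_empty_blacklist(self):
        bl = blacklist_windows(self._coverage(np.full(100, 42.0)))
        assert len(bl) == 0

    def test_zero_count_flagged_as_undersampled(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(50, size=500).astype(float)
        counts[7] = 0.0
        bl = blacklist_windows(self._coverage(counts))
        assert 7 in set(bl.windows["start"] // 200)

    def test_all_zero_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="all-zero"):
            bl = blacklist_windows(self._coverage(np.zeros(10)))
        assert len(bl) == 0


class TestBuildOccupancyMatrix:
    def test_disjoint_tracks(self, toy_index):
        tracks = {"A": {0: 5, 1: 6}, "B": {2: 7}}
        mat = build_occupancy_matrix(tracks, toy_index)
        assert (mat.astype(bool).sum(axis=1) <= 1).all()
        assert mat.loc[0, "A"] == 5 and mat.loc[2, "B"] == 7

    def test_no_blacklist_keeps_all_bins(self, toy_index):
        mat = build_occupancy_matrix({"A": {0: 1}}, toy_index)
        assert len(mat) == toy_index.n_bins

    def test_blacklisted_bin_removed(self, toy_index):
        bl = Blacklist(pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]}))
        mat = build_occupancy_matrix({"A": {0: 1, 5: 2}}, toy_index, bl)
        assert 0 not in mat.index and 5 in mat.index
        assert len(mat) == toy_index.n_bins - 1


def test_read_chrom_sizes(tmp_path):
    f = tmp_path / "sizes.tsv"
    f.write_text("chr1\t1000\nchr2\t500\n")
    layout = read_chrom_sizes(f)
    assert layout.lengths == {"chr1": 1000, "chr2": 500}
    f.write_text("chr1\t1000\nchr1\t500\n")
    with pytest.raises(ValueError, match="duplicate"):
        read_chrom_sizes(f)
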