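"""Origin interval analytics: parsing, merging, IOD, overlap, cluster profiles."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from replikit.origins import (
    OriginSet,
    cluster_count_profile,
    inter_origin_distances,
    merge_origins,
    origin_overlap,
    read_peaks,
)
from replikit.simulate import generate_origin_bed


def _set(intervals, chrom="chr1"):
    return OriginSet.from_frame(
        pd.DataFrame([(chrom, s, e) for s, e in intervals], columns=["chrom", "start", "end"])
    )


def merge_oracle(intervals: list[tuple[int, int]], window: int) -> list[tuple[int, int]]:
    """O(n²) repeated pairwise merging until fixpoint."""
    ivs = sorted(intervals)
    changed = True
    while changed:
        changed = False
        for i in range(len(ivs)):
            for j in range(i + 1, len(ivs)):
                (s1, e1), (s2, e2) = ivs[i], ivs[j]
                gap = max(s1, s2) - min(e1, e2)
                if gap <= window:
                    ivs[i] = (min(s1, s2), max(e1, e2))
                    ivs.pop(j)
                    changed = True
                    break
            if changed:
                break
    return sorted(ivs)


class TestReadPeaks:
    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        assert len(read_peaks(p)) == 0

    def test_out_of_order_bed_sorted(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t500\t600\nchr1\t10\t40\nchr1\t100\t200\n")
        s = read_peaks(p)
        assert s.intervals["start"].tolist() == [10, 100, 500]

    def test_narrowpeak_extra_columns_tolerated(self, tmp_path):
        bed = tmp_path / "a.bed"
        npk = tmp_path / "a.narrowPeak"
        bed.write_text("chr1\t10\t200\nchr2\t50\t90\n")
        npk.write_text(
            "chr1\t10\t200\tpeak1\t500\t.\t8.1\t12.0\t9.3\t55\n"
            "chr2\t50\t90\tpeak2\t300\t.\t4.2\t8.0\t5.1\t20\n"
        )
        pd.testing.assert_frame_equal(read_peaks(bed).intervals, read_peaks(npk).intervals)

    def test_malformed_line_reports_number(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t10\t200\nchr1\tfoo\t300\n")
        with pytest.raises(ValueError, match=":2"):
            read_peaks(p)

    def test_inverted_interval_rejected(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t300\t200\n")
        with pytest.raises(ValueError, match=":1"):
            read_peaks(p)


class TestMerge:
    def test_window_zero_disjoint_unchanged(self):
        s = _set([(0, 100), (200, 300)])
        pd.testing.assert_frame_equal(merge_origins(s, 0).intervals, s.intervals)

    def test_spec_example(self):
        s = _set([(0, 100), (150, 200), (500, 600)])
        out = merge_origins(s, 100).intervals
        assert list(map(tuple, out[["start", "end"]].to_numpy())) == [(0, 200), (500, 600)]

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        starts = np.sort(rng.integers(0, 100_000, 50))
        s = _set([(int(a), int(a + rng.integers(50, 400))) for a in starts])
        once = merge_origins(s, 1000)
        twice = merge_origins(once, 1000)
        pd.testing.assert_frame_equal(once.intervals, twice.intervals)

    def test_negative_window_rejected(self):
        with pytest.raises(ValueError):
            merge_origins(_set([(0, 10)]), -1)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(0, 5000), st.integers(1, 300)),
            min_size=1,
            max_size=40,
        ),
        st.sampled_from([0, 50, 500]),
    )
    def test_matches_pairwise_oracle(self, raw, window):
        ivs = sorted(set((s, s + w) for s, w in raw))
        merged = merge_origins(_set(ivs), window).intervals
        got = list(map(tuple, merged[["start", "end"]].to_numpy()))
        assert got == merge_oracle(ivs, window)

    def test_matches_bedtools(self, tmp_path):
        """Distance-d merge semantics agree with the canonical interval tool."""
        rng = np.random.default_rng(5)
        starts = np.sort(rng.integers(0, 500_000, 120))
        s = _set([(int(a), int(a + rng.integers(100, 2000))) for a in starts])
        bed = tmp_path / "in.bed"
        s.to_bed(bed)
        for window in (0, 1000, 10_000):
            out = subprocess.run(
                ["bedtools", "merge", "-d", str(window), "-i", str(bed)],
                capture_output=True, text=True, check=True,
            )
            expected = [
                (int(f[1]), int(f[2]))
                for f in (line.split("\t") for line in out.stdout.strip().splitlines())
            ]
            got = list(map(tuple, merge_origins(s, window).intervals[["start", "end"]].to_numpy()))
            assert got == expected

    def test_span_never_shrinks(self):
        s = _set([(0, 100), (90, 250), (1000, 1100)])
        merged = merge_origins(s, 10)
        assert merged.intervals["end"].max() == 1100
        assert merged.intervals["start"].min() == 0


class TestIOD:
    def test_single_peak_per_chromosome(self):
        s = OriginSet.from_frame(
            pd.DataFrame({"chrom": ["chr1", "chr2"], "start": [0, 10], "end": [100, 200]})
        )
        assert inter_origin_distances(s).n == 0

    def test_mid_gap_arithmetic(self):
        s = _set([(50, 150), (350, 450), (950, 1050)])  # mids 100, 400, 1000
        stats = inter_origin_distances(s)
        assert stats.gaps["gap"].tolist() == [300, 600]
        assert stats.mean == pytest.approx(450.0)

    def test_gaps_do_not_cross_chromosomes(self):
        df = pd.DataFrame(
            {"chrom": ["chr1", "chr1", "chr2"], "start": [0, 1000, 5], "end": [10, 1010, 15]}
        )
        stats = inter_origin_distances(OriginSet.from_frame(df))
        assert stats.n == 1

    def test_merging_increases_mean_iod(self):
        s, _ = generate_origin_bed({"chr1": 200}, seed=3)
        raw = inter_origin_distances(s).mean
        merged = inter_origin_distances(merge_origins(s, 30_000)).mean
        assert merged >= raw

    def test_generator_truth_round_trip(self):
        s, truth = generate_origin_bed({"chr1": 40, "chr2": 25}, seed=9)
        stats = inter_origin_distances(s)
        assert stats.n == len(truth.gaps) == 39 + 24
        assert sorted(stats.gaps["gap"]) == sorted(truth.gaps["gap"])


class TestOverlap:
    def test_identical_sets(self):
        s = _set([(0, 10), (20, 30)])
        res = origin_overlap(s, s)
        assert res["pct_a_in_b"] == res["pct_b_in_a"] == 100.0

    def test_disjoint_sets(self):
        res = origin_overlap(_set([(0, 10)]), _set([(100, 110)]))
        assert res["shared_a_in_b"] == 0 and res["pct_of_union"] == 0.0

    def test_half_open_touching_does_not_overlap(self):
        res = origin_overlap(_set([(0, 10)]), _set([(10, 20)]))
        assert res["shared_a_in_b"] == 0

    def test_spec_example_direction_dependence(self):
        a = _set([(0, 10), (20, 30)])
        b = _set([(5, 8), (100, 110)])
        res = origin_overlap(a, b)
        assert res["shared_a_in_b"] == 1
        assert res["pct_a_in_b"] == pytest.approx(50.0)
        assert res["shared_b_in_a"] == 1
        assert res["pct_b_in_a"] == pytest.approx(50.0)

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(7)
        a = _set([(int(s), int(s + rng.integers(1, 200))) for s in np.sort(rng.integers(0, 20_000, 60))])
        b = _set([(int(s), int(s + rng.integers(1, 200))) for s in np.sort(rng.integers(0, 20_000, 60))])
        res = origin_overlap(a, b)
        brute = sum(
            any(sa < eb and ea > sb for sb, eb in b.intervals[["start", "end"]].to_numpy())
            for sa, ea in a.intervals[["start", "end"]].to_numpy()
        )
        assert res["shared_a_in_b"] == brute


class TestClusterProfile:
    def test_empty_set(self):
        empty = OriginSet.from_frame(pd.DataFrame(columns=["chrom", "start", "end"]))
        prof = cluster_count_profile(empty)
        assert (prof["n_origins"] == 0).all()

    def test_counts_from_generator_truth(self):
        gaps = [5_000, 15_000, 25_000, 40_000] * 10
        s, truth = generate_origin_bed({"chr1": 41}, gap_sampler=gaps, peak_width=300, seed=0)
        prof = cluster_count_profile(s).set_index("window")["n_origins"]
        # interval gap = mid gap - peak width; count = n - #(gaps <= window)
        interval_gaps = truth.gaps["gap"].to_numpy() - 300
        for w in (0, 10_000, 20_000, 30_000):
            assert prof[w] == 41 - (interval_gaps <= w).sum()

    def test_monotone_non_increasing(self):
        s, _ = generate_origin_bed({"chr1": 100, "chr2": 80}, seed=2)
        prof = cluster_count_profile(s, (10_000, 20_000, 30_000))
        assert (np.diff(prof["n_origins"]) <= 0).all()

    def test_unsorted_windows_rejected(self):
        s, _ = generate_origin_bed({"chr1": 5}, seed=1)
        with pytest.raises(ValueError):
            cluster_count_profile(s, (20_000, 10_000))
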