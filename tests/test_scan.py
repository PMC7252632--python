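"""Correlation thresholds, sliding-window scan, region merging/assignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import chromsig as cs
from chromsig.profiles import PROFILE_LEN, WINDOW_BP
from chromsig.scan import (
    SignificanceWindow,
    group_and_assign,
    lower_percentile,
    merge_windows,
    pearson,
    scan_genome,
    shorten_region,
)


def windows_from_starts(starts, cluster_id, r=0.9, chrom="chr1"):
    return [SignificanceWindow(chrom, s, s + WINDOW_BP - 1, cluster_id, r) for s in starts]


class TestPearson:
    def test_self_and_anti_correlation(self):
        x = np.arange(400.0)
        assert pearson(x, x) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        assert pearson([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_constant_vector_undefined(self):
        assert np.isnan(pearson(np.ones(4), [1, 2, 3, 4]))


class TestThresholds:
    def test_lower_percentile_convention(self):
        assert lower_percentile([0.1, 0.2, 0.3, 0.4, 0.5], 0.4) == pytest.approx(0.2)
        assert lower_percentile([0.3, 0.3, 0.3], 0.4) == pytest.approx(0.3)
        assert lower_percentile([0.1, 0.2, 0.5], 1.0) == pytest.approx(0.5)

    def test_identical_members_give_threshold_one(self):
        row = np.tile(np.arange(PROFILE_LEN, dtype=float), (4, 1))
        matrix = cs.ProfileMatrix(row)
        labels = np.ones(4, dtype=int)
        pats = cs.characteristic_patterns(matrix, labels)
        ts = cs.correlation_thresholds(matrix, pats, labels, alpha=0.4)
        assert ts.thresholds[1] == pytest.approx(1.0)

    def test_small_cluster_rejected(self):
        matrix = cs.ProfileMatrix(np.arange(2 * PROFILE_LEN, dtype=float).reshape(2, -1))
        labels = np.array([1, 2])
        pats = cs.characteristic_patterns(matrix, labels)
        with pytest.raises(ValueError, match="fewer than 2"):
            cs.correlation_thresholds(matrix, pats, labels)

    def test_thresholds_nondecreasing_in_alpha(self, sim400, trained400):
        matrix = trained400.matrix_raw
        labels = trained400.mixture.labels
        pats = [p for p in trained400.patterns if p.cluster_id in trained400.scan_clusters]
        prev = None
        for alpha in (0.3, 0.4, 0.5):
            ts = cs.correlation_thresholds(matrix, pats, labels, alpha=alpha)
            if prev is not None:
                assert all(ts.thresholds[k] >= prev.thresholds[k] for k in ts.thresholds)
            prev = ts


def _embedding_track(pattern_log, n_bins=600, at_bin=200):
    """Flat near-zero track with one exact raw-scale copy of a pattern."""
    counts = np.full((4, n_bins), 0.0)
    raw = np.expm1(pattern_log).reshape(4, 100)
    counts[:, at_bin : at_bin + 100] = raw
    return cs.GenomeTrack("chr1", list(counts), bin_size=100, offset=1)


class TestScanGenome:
    @pytest.fixture(scope="class")
    def setup(self):
        gen = cs.make_patterns()
        pats = [cs.CharacteristicPattern(k, np.expm1(gen[k - 1]), gen[k - 1], 10)
                for k in (1, 2, 3)]
        thresholds = cs.ThresholdSet(0.4, {1: 0.9, 2: 0.9, 3: 0.9})
        return pats, thresholds

    def test_embedded_pattern_found_with_r_near_one(self, setup):
        pats, thresholds = setup
        track = _embedding_track(pats[0].mean_log)
        hits = scan_genome(track, pats, thresholds)
        at = [w for w in hits if w.start == 1 + 200 * 100]
        assert at and at[0].cluster_id == 1 and at[0].r > 0.999

    def test_known_promoter_windows_excluded(self, setup):
        pats, thresholds = setup
        track = _embedding_track(pats[0].mean_log)
        site = ("chr1", 1 + 200 * 100, 200 * 100 + WINDOW_BP)
        hits = scan_genome(track, pats, thresholds, known_promoters=[site])
        assert all(not (w.start <= site[2] and w.end >= site[1]) for w in hits)

    def test_flat_track_yields_nothing(self, setup, flat_track):
        pats, thresholds = setup
        assert scan_genome(flat_track, pats, thresholds) == []

    def test_all_windows_are_10kb(self, setup):
        pats, thresholds = setup
        track = _embedding_track(pats[1].mean_log)
        for w in scan_genome(track, pats, thresholds):
            assert w.end - w.start + 1 == WINDOW_BP


class TestMergeWindows:
    def test_chained_run_merges_to_single_region(self):
        # 10 kb windows starting every 100 bp from 9701 through 22301
        starts = range(9701, 22302, 100)
        regions = merge_windows(windows_from_starts(starts, 1))
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end) == (9701, 32300)
        assert r.first_window.start == 9701 and r.last_window.start == 22301

    def test_second_region_of_worked_example(self):
        regions = merge_windows(windows_from_starts(range(66301, 67802, 100), 3))
        assert (regions[0].start, regions[0].end) == (66301, 77800)

    def test_disjoint_windows_stay_separate(self):
        regions = merge_windows(windows_from_starts([10_000, 40_000], 1))
        assert len(regions) == 2
        assert all(r.n_windows == 1 for r in regions)

    def test_mixed_clusters_rejected(self):
        ws = windows_from_starts([1000], 1) + windows_from_starts([1000], 2)
        with pytest.raises(ValueError, match="several clusters"):
            merge_windows(ws)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.integers(1, 500).map(lambda b: 1 + b * 100),
                    min_size=1, max_size=30, unique=True))
    def test_region_bounds_come_from_member_windows(self, starts):
        ws = windows_from_starts(starts, 1)
        regions = merge_windows(ws)
        w_starts = {w.start for w in ws}
        w_ends = {w.end for w in ws}
        assert sum(r.n_windows for r in regions) == len(ws)
        for a, b in zip(regions, regions[1:]):
            assert a.chrom != b.chrom or a.end < b.start  # pairwise disjoint
        for r in regions:
            assert r.start in w_starts and r.end in w_ends


def _region(start, end, cluster, max_r, chrom="chr1"):
    w1 = SignificanceWindow(chrom, start, start + WINDOW_BP - 1, cluster, max_r)
    w2 = SignificanceWindow(chrom, end - WINDOW_BP + 1, end, cluster, max_r)
    return cs.SignificanceRegion(chrom, start, end, cluster, max_r, w1, w2,
                                 n_windows=(end - start + 1 - WINDOW_BP) // 100 + 1)


class TestGroupAndAssign:
    def test_worked_example_union_and_winner(self):
        regions = [
            _region(9701, 32300, 1, 0.9),
            _region(22101, 36300, 2, 0.8),
            _region(25801, 40000, 3, 0.7),
        ]
        promoters = group_and_assign(regions)
        assert len(promoters) == 1
        p = promoters[0]
        assert (p.start, p.end, p.cluster_id) == (9701, 40000, 1)
        assert len(p.evidence) == 3

    def test_lone_region_promoted_verbatim(self):
        p, = group_and_assign([_region(66301, 77800, 3, 0.95)])
        assert (p.start, p.end, p.cluster_id) == (66301, 77800, 3)

    def test_tie_breaks_to_lowest_cluster(self):
        promoters = group_and_assign([
            _region(10_000, 25_000, 2, 0.8), _region(12_000, 27_000, 1, 0.8)])
        assert promoters[0].cluster_id == 1

    def test_promoters_pairwise_disjoint(self):
        regions = [_region(10_000, 25_000, 1, 0.9), _region(20_000, 35_000, 2, 0.7),
                   _region(60_000, 75_000, 2, 0.8)]
        ps = sorted(group_and_assign(regions), key=lambda p: p.start)
        assert len(ps) == 2 and ps[0].end < ps[1].start

    def test_min_windows_filters_spikes(self):
        spike = _region(10_000, 19_999, 1, 0.99)  # single-window region
        broad = _region(40_000, 55_000, 2, 0.7)
        assert len(group_and_assign([spike, broad], min_windows=2)) == 1


class TestShorten:
    def test_region_shortened_both_ends(self):
        region = merge_windows(windows_from_starts(range(9701, 22302, 100), 1))[0]
        out = shorten_region(region, mode="both")
        assert (out.start, out.end) == (14701, 27300)

    def test_promoter_shortened_first_then_last(self):
        regions = [
            _region(9701, 32300, 1, 0.9),
            _region(22101, 36300, 2, 0.8),
            _region(25801, 40000, 3, 0.7),
        ]
        p = group_and_assign(regions)[0]
        out = shorten_region(shorten_region(p, mode="first"), mode="last")
        assert (out.start, out.end) == (14701, 35000)
        both = shorten_region(p, mode="both")
        assert (both.start, both.end) == (14701, 35000)

    def test_single_window_region_unchanged(self):
        region = merge_windows(windows_from_starts([9701], 1))[0]
        out = shorten_region(region, mode="both")
        assert (out.start, out.end) == (region.start, region.end)

    def test_none_is_identity_and_bad_mode_rejected(self):
        region = merge_windows(windows_from_starts([9701], 1))[0]
        assert shorten_region(region, mode="none") is region
        with pytest.raises(ValueError):
            shorten_region(region, mode="half")
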