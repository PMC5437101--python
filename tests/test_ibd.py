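"""Genetic-map interpolation, IBD consensus, sharing and hotspot tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tempdiff.ibd import (GeneticMap, HotspotTrack, IBDSegment, annotate_cM,
                          classify_long, consensus_ibd, filter_short,
                          hotspot_occurrence, load_genetic_map,
                          load_ibd_segments, overlap_permutation_test,
                          pair_sharing, save_ibd_segments)
from tempdiff.sfs_data import RegionSet


@pytest.fixture
def simple_map():
    return GeneticMap({"1": (np.array([0.0, 1e6, 2e6]),
                             np.array([0.0, 1.0, 2.0])),
                       "2": (np.array([0.0, 1e6]),
                             np.array([0.0, 1.0]))})


def _seg(a="s1", b="s2", chrom="1", start=0, end=1_000_000, cm=None):
    if cm:
        return IBDSegment(a, b, chrom, start, end, cm[0], cm[1])
    return IBDSegment(a, b, chrom, start, end)


class TestGeneticMap:
    def test_midpoint_interpolation(self, simple_map):
        assert simple_map.interpolate("1", 5e5) == pytest.approx(0.5)

    def test_anchor_positions_exact(self, simple_map):
        assert simple_map.interpolate("1", 1e6) == pytest.approx(1.0)

    def test_out_of_range_extends_terminal_slope(self, simple_map):
        assert simple_map.interpolate("1", 3e6) == pytest.approx(3.0)
        assert simple_map.interpolate("1", -1e6) == pytest.approx(-1.0)

    def test_unknown_chromosome_rejected(self, simple_map):
        with pytest.raises(KeyError):
            simple_map.interpolate("7", 100.0)

    def test_inverse_roundtrip(self, simple_map):
        for cm in (0.0, 0.3, 1.7):
            bp = simple_map.inverse("1", cm)
            assert simple_map.interpolate("1", bp) == pytest.approx(cm)

    @given(st.lists(st.floats(0, 2e6), min_size=2, max_size=10))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_monotonicity(self, positions):
        gmap = GeneticMap({"1": (np.array([0.0, 1e6, 2e6]),
                                 np.array([0.0, 0.4, 2.0]))})
        positions = sorted(positions)
        cms = [gmap.interpolate("1", p) for p in positions]
        assert all(a <= b + 1e-12 for a, b in zip(cms, cms[1:]))

    def test_nonmonotone_anchors_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            GeneticMap({"1": (np.array([0.0, 2.0, 1.0]),
                              np.array([0.0, 1.0, 2.0]))})

    def test_tsv_roundtrip(self, tmp_path, simple_map):
        path = tmp_path / "map.tsv"
        with open(path, "w") as fh:
            for chrom, (bp, cm) in simple_map.anchors.items():
                for b, c in zip(bp, cm):
                    fh.write(f"{chrom}\t{int(b)}\t{c}\n")
        back = load_genetic_map(path)
        assert back.chroms() == ["1", "2"]
        assert back.interpolate("1", 5e5) == pytest.approx(0.5)


class TestConsensus:
    def test_identical_runs_return_segment_unchanged(self):
        run = [_seg(start=100, end=5000)]
        out = consensus_ibd([run] * 10)
        assert len(out) == 1
        assert (out[0].start_bp, out[0].end_bp) == (100, 5000)

    def test_segment_in_one_run_only_is_absent(self):
        runs = [[_seg()]] + [[] for _ in range(9)]
        assert consensus_ibd(runs) == []

    def test_half_overlapping_segments_yield_intersection(self):
        # 6 runs support [0, 100), 6 support [50, 150): only [50, 100)
        # reaches majority coverage (> 5 of 12... with 12 runs need 7);
        # build exactly the toy from interval arithmetic with 10 runs
        left = [_seg(start=0, end=100)]
        right = [_seg(start=50, end=150)]
        runs = [left] * 6 + [right] * 4
        out = consensus_ibd(runs)
        assert [(s.start_bp, s.end_bp) for s in out] == [(0, 100)]
        runs = [left] * 5 + [right] * 5
        out = consensus_ibd(runs)  # only the doubly-covered core survives
        assert [(s.start_bp, s.end_bp) for s in out] == [(50, 100)]

    def test_disjoint_sample_sets_rejected(self):
        runs = [[_seg(a="x", b="y")], [_seg(a="p", b="q")]]
        with pytest.raises(ValueError, match="disjoint"):
            consensus_ibd(runs)

    def test_consensus_coverage_bounds(self):
        # brute-force coverage counting: the unanimity consensus can never
        # cover more than the smallest run, and any consensus stays inside
        # the union of the runs
        rng = np.random.default_rng(0)
        runs = []
        for _ in range(10):
            segs = []
            for _ in range(rng.integers(1, 5)):
                start = int(rng.integers(0, 10_000))
                segs.append(_seg(start=start,
                                 end=start + int(rng.integers(100, 5000))))
            runs.append(segs)

        def coverage(segs):
            points = np.zeros(20_000, dtype=bool)
            for s in segs:
                points[s.start_bp:s.end_bp] = True
            return points

        unanimous = consensus_ibd(runs, min_runs=len(runs))
        assert coverage(unanimous).sum() <= min(coverage(r).sum() for r in runs)
        majority = coverage(consensus_ibd(runs))
        union = np.any([coverage(r) for r in runs], axis=0)
        assert not np.any(majority & ~union)


class TestLengthRules:
    def test_short_filter_boundary(self):
        short = _seg(cm=(0.0, 0.8))
        exact = _seg(cm=(0.0, 1.0))
        long = _seg(cm=(0.0, 1.5))
        assert filter_short([short, exact, long]) == [exact, long]
        assert filter_short([]) == []

    def test_short_filter_requires_cm(self):
        with pytest.raises(ValueError, match="cM"):
            filter_short([_seg()])

    def test_long_classification_boundary(self):
        labels = dict()
        for lo, hi in [(0.0, 7.5), (0.0, 6.9), (0.0, 7.0)]:
            (_, label), = classify_long([_seg(cm=(lo, hi))])
            labels[hi] = label
        assert labels == {7.5: "long", 6.9: "short", 7.0: "short"}


class TestPairSharing:
    def test_no_segments_all_zero(self):
        per_pair, per_pop = pair_sharing([], {"s1": "TS", "s2": "NSS"})
        assert per_pair.empty
        cross = per_pop[(per_pop.pop_a == "NSS") & (per_pop.pop_b == "TS")]
        assert cross["mean_cM_per_pair"].iloc[0] == 0.0

    def test_single_cross_population_segment(self):
        segs = [_seg(a="t1", b="n1", cm=(0.0, 7.0))]
        per_pair, per_pop = pair_sharing(segs, {"t1": "TS", "n1": "NSS"})
        assert per_pair["total_cM"].iloc[0] == pytest.approx(7.0)
        cross = per_pop[(per_pop.pop_a == "NSS") & (per_pop.pop_b == "TS")]
        assert cross["mean_cM_per_pair"].iloc[0] == pytest.approx(7.0)

    def test_doubling_segments_doubles_totals(self):
        segs = [_seg(a="t1", b="n1", cm=(0.0, 3.0)),
                _seg(a="t2", b="n1", cm=(1.0, 3.5))]
        pops = {"t1": "TS", "t2": "TS", "n1": "NSS"}
        _, once = pair_sharing(segs, pops)
        _, twice = pair_sharing(segs + segs, pops)
        np.testing.assert_allclose(twice["total_cM"], 2 * once["total_cM"])

    def test_zero_sharing_pairs_dilute_the_mean(self):
        # one 6.0 cM segment over 3 possible cross pairs -> mean 2.0
        segs = [_seg(a="t1", b="n1", cm=(0.0, 6.0))]
        pops = {"t1": "TS", "t2": "TS", "t3": "TS", "n1": "NSS"}
        _, per_pop = pair_sharing(segs, pops)
        cross = per_pop[(per_pop.pop_a == "NSS") & (per_pop.pop_b == "TS")]
        assert cross["mean_cM_per_pair"].iloc[0] == pytest.approx(2.0)


class TestHotspots:
    def test_single_window_occurrence(self, simple_map):
        segs = [_seg(cm=(0.2, 1.8))]
        track = hotspot_occurrence(segs, simple_map, window_cM=10.0, n_pairs=2)
        row = track.table[(track.table.chrom == "1")].iloc[0]
        assert row["occurrence"] == pytest.approx(0.5)
        other = track.table[(track.table.chrom == "2")]
        assert (other["occurrence"] == 0).all()

    def test_segment_spanning_two_windows_counts_in_each(self):
        gmap = GeneticMap({"1": (np.array([0.0, 30e6]),
                                 np.array([0.0, 30.0]))})
        segs = [_seg(start=8_000_000, end=12_000_000, cm=(8.0, 12.0))]
        track = hotspot_occurrence(segs, gmap, window_cM=10.0, n_pairs=1)
        occ = track.table["occurrence"].to_list()
        assert occ == [1.0, 1.0, 0.0]

    def test_no_segments_gives_zero_track(self, simple_map):
        track = hotspot_occurrence([], simple_map, n_pairs=3)
        assert (track.table["occurrence"] == 0).all()

    def test_order_invariance_and_additivity(self, simple_map):
        s1 = _seg(a="a", b="b", cm=(0.1, 1.2))
        s2 = _seg(a="c", b="d", cm=(0.5, 1.9))
        fwd = hotspot_occurrence([s1, s2], simple_map, n_pairs=4)
        rev = hotspot_occurrence([s2, s1], simple_map, n_pairs=4)
        assert fwd.table.equals(rev.table)
        only1 = hotspot_occurrence([s1], simple_map, n_pairs=4)
        only2 = hotspot_occurrence([s2], simple_map, n_pairs=4)
        np.testing.assert_allclose(
            fwd.table["n_segments"],
            only1.table["n_segments"] + only2.table["n_segments"])


def _uniform_track(n_windows, occurrences):
    import pandas as pd
    rows = [("1", 10.0 * i, 10.0 * (i + 1), 0, occ, False)
            for i, occ in enumerate(occurrences)]
    table = pd.DataFrame(rows, columns=["chrom", "start_cM", "end_cM",
                                        "n_segments", "occurrence", "partial"])
    return HotspotTrack(table, 10.0, 10)


def _window_map(n_windows):
    top = 10.0 * n_windows
    return GeneticMap({"1": (np.array([0.0, top * 1e6]),
                             np.array([0.0, top]))})


class TestOverlapPermutation:
    def test_regions_covering_everything_give_p_one(self):
        track = _uniform_track(40, np.linspace(1, 2, 40))
        gmap = _window_map(40)
        regions = RegionSet([("1", 0, int(400e6))])
        obs, p = overlap_permutation_test(track, regions, gmap, n_perm=99)
        assert obs == 1.0 and p == 1.0

    def test_regions_covering_nothing_give_p_one(self):
        track = _uniform_track(40, np.linspace(1, 2, 40))
        gmap = _window_map(40)
        obs, p = overlap_permutation_test(track, RegionSet([]), gmap, n_perm=99)
        assert obs == 0.0 and p == 1.0

    def test_planted_enrichment_detected(self):
        # the two busiest windows sit inside the selected regions
        occ = np.ones(40) * 0.1
        occ[[5, 17]] = 5.0
        track = _uniform_track(40, occ)
        gmap = _window_map(40)
        regions = RegionSet([("1", int(50e6), int(60e6)),
                             ("1", int(170e6), int(180e6))])
        obs, p = overlap_permutation_test(track, regions, gmap, n_perm=999,
                                          seed=1)
        assert obs == 1.0
        assert p <= 0.05

    def test_fewer_windows_than_quantile_rejected(self):
        track = _uniform_track(2, [1.0, 2.0])
        track.table = track.table.iloc[:0]
        with pytest.raises(ValueError, match="empty"):
            overlap_permutation_test(track, RegionSet([]), _window_map(2))


class TestSegmentIO:
    def test_tsv_roundtrip(self, tmp_path):
        segs = [_seg(start=10, end=500), _seg(a="p", b="q", chrom="2",
                                              start=5, end=99)]
        path = tmp_path / "ibd.tsv"
        save_ibd_segments(path, segs)
        back = load_ibd_segments(path)
        assert [(s.sample_a, s.chrom, s.start_bp, s.end_bp) for s in back] \
            == [(s.sample_a, s.chrom, s.start_bp, s.end_bp) for s in segs]

    def test_annotate_cm(self, simple_map):
        seg = _seg(start=500_000, end=1_500_000)
        (out,) = annotate_cM([seg], simple_map)
        assert out.start_cM == pytest.approx(0.5)
        assert out.end_cM == pytest.approx(1.5)
        assert out.length_cM == pytest.approx(1.0)

    def test_degenerate_segments_rejected(self):
        with pytest.raises(ValueError):
            IBDSegment("a", "a", "1", 0, 100)
        with pytest.raises(ValueError):
            IBDSegment("a", "b", "1", 100, 100)
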