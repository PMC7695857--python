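import itertools

import numpy as np
import pandas as pd
import pytest

from helixbreak.classification import (DamageCluster, classify_clusters,
                                       complexity_class, distant_dsb_filter,
                                       pair_dsbs, scavengeable_fraction,
                                       segment_clusters, source_class,
                                       summarize_yields, YieldSummary)


def breaks_frame(records):
    """records: (segment_id, bp_index, strand, source) tuples."""
    return pd.DataFrame(records, columns=["segment_id", "bp_index",
                                          "strand", "source"])


def brute_force_max_matching(bp, strand, d_dsb=10):
    """Exhaustive maximum matching over opposite-strand pairs."""
    s0 = [i for i in range(len(bp)) if strand[i] == 0]
    s1 = [i for i in range(len(bp)) if strand[i] == 1]
    edges = [(i, j) for i in s0 for j in s1 if abs(bp[i] - bp[j]) <= d_dsb]

    best = 0
    def extend(used, count, start):
        nonlocal best
        best = max(best, count)
        for idx in range(start, len(edges)):
            i, j = edges[idx]
            if i not in used and j not in used:
                extend(used | {i, j}, count + 1, idx + 1)
    extend(frozenset(), 0, 0)
    return best


class TestSegmentClusters:
    def test_gap_of_101_unbroken_bp_splits(self):
        clusters = segment_clusters(breaks_frame(
            [(0, 0, 0, "direct"), (0, 102, 0, "direct")]))
        assert len(clusters) == 2

    def test_gap_of_100_unbroken_bp_stays_together(self):
        clusters = segment_clusters(breaks_frame(
            [(0, 0, 0, "direct"), (0, 101, 0, "direct")]))
        assert len(clusters) == 1

    def test_empty_input(self):
        assert segment_clusters(breaks_frame([])) == []

    def test_never_spans_segments(self):
        clusters = segment_clusters(breaks_frame(
            [(0, 0, 0, "direct"), (1, 1, 0, "direct")]))
        assert len(clusters) == 2

    def test_partition_and_disjoint_spans(self, rng):
        records = [(int(s), int(bp), int(st), "direct")
                   for s, bp, st in zip(rng.integers(0, 3, 200),
                                        rng.integers(0, 5000, 200),
                                        rng.integers(0, 2, 200))]
        frame = breaks_frame(records).drop_duplicates(
            ["segment_id", "bp_index", "strand"])
        clusters = segment_clusters(frame)
        assert sum(c.n_breaks for c in clusters) == len(frame)
        by_seg = {}
        for c in clusters:
            by_seg.setdefault(c.segment_id, []).append(c.span_bp)
        for spans in by_seg.values():
            spans.sort()
            for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
                assert b1 < a2


class TestPairDsbs:
    def test_opposite_strands_within_10_bp_pair(self):
        assert len(pair_dsbs([100, 105], [0, 1])) == 1

    def test_separation_beyond_10_bp_does_not_pair(self):
        assert pair_dsbs([100, 115], [0, 1]) == []

    def test_same_strand_never_pairs(self):
        assert pair_dsbs([100, 101], [0, 0]) == []

    def test_greedy_by_distance_alone_would_be_suboptimal(self):
        # nearest-first pairing of (10,9) strands the ends; the optimal
        # matching pairs (0,9) and (10,19)
        pairs = pair_dsbs([0, 10, 9, 19], [0, 0, 1, 1])
        assert len(pairs) == 2

    def test_matches_exhaustive_maximum_matching(self, rng):
        for _ in range(500):
            k = int(rng.integers(1, 9))
            bp = rng.integers(0, 40, size=k)
            strand = rng.integers(0, 2, size=k)
            pairs = pair_dsbs(bp, strand)
            assert len(pairs) == brute_force_max_matching(bp, strand)
            for i, j in pairs:
                assert strand[i] != strand[j]
                assert abs(int(bp[i]) - int(bp[j])) <= 10

    def test_deterministic_realization(self, rng):
        bp = rng.integers(0, 30, size=8)
        strand = rng.integers(0, 2, size=8)
        assert pair_dsbs(bp, strand) == pair_dsbs(bp, strand)


def make_cluster(records, d_dsb=10):
    frame = breaks_frame([(0, bp, st, src) for bp, st, src in records])
    clusters = classify_clusters(frame, d_dsb=d_dsb)
    assert len(clusters) == 1
    return clusters[0]


class TestComplexityClass:
    def test_dsb_plus_extra_break_within_d_dsb_is_dsbp(self):
        cl = make_cluster([(100, 0, "direct"), (103, 1, "direct"),
                           (106, 1, "direct")])
        assert cl.complexity == "DSBp"

    def test_two_dsbs_make_dsbpp(self):
        cl = make_cluster([(100, 0, "direct"), (101, 1, "direct"),
                           (150, 0, "direct"), (151, 1, "direct")])
        assert cl.complexity == "DSBpp"

    def test_three_dsbs_still_one_dsbpp(self):
        cl = make_cluster([(0, 0, "direct"), (1, 1, "direct"),
                           (40, 0, "direct"), (41, 1, "direct"),
                           (80, 0, "direct"), (81, 1, "direct")])
        assert cl.complexity == "DSBpp"
        assert cl.n_dsb == 3

    def test_single_break_is_ssb_cluster(self):
        cl = make_cluster([(100, 0, "direct")])
        assert cl.complexity == "SSB_cluster"

    def test_lone_dsb_with_distant_extra_break_stays_dsb(self):
        cl = make_cluster([(100, 0, "direct"), (101, 1, "direct"),
                           (150, 0, "direct")])
        assert cl.complexity == "DSB"


class TestSourceClass:
    def test_all_direct_is_dsbdir(self):
        cl = make_cluster([(100, 0, "direct"), (102, 1, "direct")])
        assert cl.source_class == "DSBdir"

    def test_all_indirect_is_dsbind(self):
        cl = make_cluster([(100, 0, "indirect"), (102, 1, "indirect")])
        assert cl.source_class == "DSBind"

    def test_hybrid_pair_alone_is_dsbhyb(self):
        # removing the indirect break leaves no DSB
        cl = make_cluster([(100, 0, "direct"), (102, 1, "indirect")])
        assert cl.source_class == "DSBhyb"

    def test_direct_dsb_with_indirect_ssb_nearby_is_dsbmix(self):
        cl = make_cluster([(100, 0, "direct"), (102, 1, "direct"),
                           (105, 0, "indirect")])
        assert cl.source_class == "DSBmix"

    def test_on_cluster_without_dsb_rejected(self):
        cl = make_cluster([(100, 0, "direct")])
        with pytest.raises(ValueError):
            source_class(cl)

    def test_removal_oracle_on_enumerated_small_clusters(self):
        # every 3-break cluster on bp {0, 5, 9}: the label must follow the
        # delete-indirect-and-re-pair definition evaluated independently
        for strands in itertools.product([0, 1], repeat=3):
            for sources in itertools.product(["direct", "indirect"],
                                             repeat=3):
                bp = [0, 5, 9]
                frame = breaks_frame([(0, b, s, src) for b, s, src
                                      in zip(bp, strands, sources)])
                (cl,) = classify_clusters(frame)
                if cl.n_dsb == 0:
                    assert cl.source_class is None
                    continue
                srcs = set(cl.source)
                if srcs == {"direct"}:
                    assert cl.source_class == "DSBdir"
                elif srcs == {"indirect"}:
                    assert cl.source_class == "DSBind"
                else:
                    keep = [i for i in range(3) if sources[i] == "direct"]
                    survives = brute_force_max_matching(
                        [bp[i] for i in keep],
                        [strands[i] for i in keep]) > 0
                    expected = "DSBmix" if survives else "DSBhyb"
                    assert cl.source_class == expected

    def test_all_sources_direct_gives_dsbdir_everywhere(self, rng):
        records = [(0, int(b), int(s), "direct")
                   for b, s in zip(rng.integers(0, 2000, 120),
                                   rng.integers(0, 2, 120))]
        frame = breaks_frame(records).drop_duplicates(
            ["segment_id", "bp_index", "strand"])
        clusters = classify_clusters(frame)
        dsb_clusters = [c for c in clusters if c.n_dsb]
        assert dsb_clusters
        assert all(c.source_class == "DSBdir" for c in dsb_clusters)


class TestDistantDsbFilter:
    @pytest.mark.parametrize("mids,expected", [
        ([0, 20000], 2),
        ([0, 5000, 20000], 2),
        ([], 0),
        ([123], 1),
        ([0, 10000], 2),
        ([0, 9999], 1),
    ])
    def test_retention_scan(self, mids, expected):
        assert distant_dsb_filter(mids) == expected


class TestYieldSummary:
    def test_n_cdsb_formula(self):
        records = []
        # 3 DSBp clusters, 2 DSBpp clusters, on one long segment
        base = 0
        for _ in range(3):
            records += [(0, base, 0, "direct"), (0, base + 2, 1, "direct"),
                        (0, base + 5, 0, "direct")]
            base += 300
        for _ in range(2):
            records += [(0, base, 0, "direct"), (0, base + 1, 1, "direct"),
                        (0, base + 50, 0, "direct"),
                        (0, base + 51, 1, "direct")]
            base += 300
        clusters = classify_clusters(breaks_frame(records))
        summary = summarize_yields(clusters, dose_gy=1.0, genome_gbp=1.0)
        assert summary.n_dsbp == 3
        assert summary.n_dsbpp == 2
        assert summary.n_cdsb == 7

    def test_yield_normalization(self):
        records = [(0, 300 * i, 0, "direct") for i in range(100)]
        clusters = classify_clusters(breaks_frame(records))
        summary = summarize_yields(clusters, dose_gy=1.0, genome_gbp=0.01)
        assert summary.n_ssb == 100
        assert summary.ssb_yield == pytest.approx(1e4)

    def test_no_dsbs_ratio_is_missing(self):
        clusters = classify_clusters(breaks_frame([(0, 5, 0, "direct")]))
        summary = summarize_yields(clusters, dose_gy=1.0, genome_gbp=1.0)
        assert np.isnan(summary.ssb_dsb_ratio)
        assert np.isnan(summary.scavengeable_fraction)

    def test_zero_dose_rejected(self):
        with pytest.raises(ValueError):
            summarize_yields([], dose_gy=0.0, genome_gbp=1.0)

    def test_source_counts_partition_dsb_clusters(self, rng):
        records = [(0, int(b), int(s), src)
                   for b, s, src in zip(
                       rng.integers(0, 3000, 150),
                       rng.integers(0, 2, 150),
                       rng.choice(["direct", "indirect"], 150))]
        frame = breaks_frame(records).drop_duplicates(
            ["segment_id", "bp_index", "strand"])
        clusters = classify_clusters(frame)
        summary = summarize_yields(clusters, 1.0, 1.0)
        assert (summary.n_dsbdir + summary.n_dsbind + summary.n_dsbhyb
                + summary.n_dsbmix) == summary.n_dsb_clusters


class TestScavengeableFraction:
    def _summary(self, ndir, nmix, nind, nhyb):
        return YieldSummary(0, ndir + nmix + nind + nhyb,
                            ndir + nmix + nind + nhyb, 0, 0, 0, 0, 0,
                            ndir, nind, nhyb, nmix, 1.0, 1.0)

    def test_worked_example(self):
        assert scavengeable_fraction(
            self._summary(5, 1, 3, 1)) == pytest.approx(0.4)

    def test_all_direct_gives_zero(self):
        assert scavengeable_fraction(self._summary(4, 0, 0, 0)) == 0.0

    def test_all_indirect_gives_one(self):
        assert scavengeable_fraction(self._summary(0, 0, 7, 0)) == 1.0

    def test_zero_denominator_missing(self):
        assert np.isnan(scavengeable_fraction(self._summary(0, 0, 0, 0)))
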