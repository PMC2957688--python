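"""Multi-patient RHS intersection and the case-control sharing statistic."""

import numpy as np
import pytest

from qhmap.core import GenomeRegions, Segment, SegmentKind, SnpMarker
from qhmap.overlap import (
    SharingCounts,
    intersect_regions,
    rank_overlaps,
    sharing_counts,
    u_statistic,
)


def regions_from(intervals, sample_id="s", total=100.0):
    """intervals: list of (chrom, start_cm, end_cm); bp at 1 cM = 1 Mb."""
    segs = [
        Segment(c, a, b, int(a * 1e6), int(b * 1e6) + 1, kind=SegmentKind.RHS)
        for c, a, b in intervals
    ]
    return GenomeRegions(sample_id, segs, total_autosome_cm=total)


def random_region_set(rng, sample_id, n_max=6, span=10.0):
    n = int(rng.integers(0, n_max))
    edges = np.sort(rng.uniform(0, span, 2 * n))
    intervals = [
        (1, edges[2 * i], edges[2 * i + 1])
        for i in range(n)
        if edges[2 * i + 1] - edges[2 * i] > 1e-9
    ]
    return regions_from(intervals, sample_id)


def coverage_oracle(region_sets, grid):
    """Discretized oracle: a grid point is in the overlap iff every set covers it."""
    out = np.ones(len(grid), dtype=bool)
    for rs in region_sets:
        covered = np.zeros(len(grid), dtype=bool)
        for s in rs.segments:
            covered |= (grid >= s.start_cm) & (grid < s.end_cm)
        out &= covered
    return out


class TestIntersectRegions:
    def test_single_set_identity(self):
        rs = regions_from([(1, 1.0, 2.0), (2, 5.0, 9.0)])
        out = intersect_regions([rs])
        assert [(s.chrom, s.start_cm, s.end_cm) for s in out] == [
            (1, 1.0, 2.0), (2, 5.0, 9.0)
        ]

    def test_basic_interval_algebra(self):
        a = regions_from([(1, 10.0, 20.0)])
        b = regions_from([(1, 15.0, 30.0)])
        (seg,) = intersect_regions([a, b])
        assert (seg.start_cm, seg.end_cm) == (15.0, 20.0)
        assert seg.kind == SegmentKind.OVERLAP

    def test_disjoint_sets_empty(self):
        a = regions_from([(1, 0.0, 1.0)])
        b = regions_from([(1, 2.0, 3.0)])
        assert intersect_regions([a, b]) == []

    def test_matches_discretized_oracle(self, rng):
        grid = np.arange(0.005, 10.0, 0.01)
        for _ in range(50):
            sets = [random_region_set(rng, f"s{i}") for i in range(int(rng.integers(1, 5)))]
            out = intersect_regions(sets)
            mask = np.zeros(len(grid), dtype=bool)
            for s in out:
                mask |= (grid >= s.start_cm) & (grid < s.end_cm)
            np.testing.assert_array_equal(mask, coverage_oracle(sets, grid))

    def test_commutative_and_shrinking(self, rng):
        a = random_region_set(rng, "a")
        b = random_region_set(rng, "b")
        c = random_region_set(rng, "c")
        fwd = intersect_regions([a, b, c])
        rev = intersect_regions([c, b, a])
        assert [(s.start_cm, s.end_cm) for s in fwd] == pytest.approx(
            [(s.start_cm, s.end_cm) for s in rev]
        )
        two = sum(s.genetic_length_cm for s in intersect_regions([a, b]))
        three = sum(s.genetic_length_cm for s in fwd)
        assert three <= two + 1e-12


class TestSharingCounts:
    def test_full_case_coverage_no_controls(self):
        snp = SnpMarker("rs1", 1, int(5e6), 5.0)
        cases = [regions_from([(1, 4.0, 6.0)], f"p{i}") for i in range(3)]
        controls = [regions_from([(1, 8.0, 9.0)], f"c{i}") for i in range(4)]
        (c,) = sharing_counts([snp], cases, controls)
        assert (c.x1, c.n1, c.x2, c.n2) == (3, 3, 0, 4)

    def test_uncovered_snp(self):
        snp = SnpMarker("rs1", 2, 100, 0.5)
        cases = [regions_from([(1, 0.0, 10.0)])]
        (c,) = sharing_counts([snp], cases, cases)
        assert (c.x1, c.x2) == (0, 0)

    def test_half_open_boundary(self):
        start_snp = SnpMarker("rs1", 1, int(4e6), 4.0)
        end_snp = SnpMarker("rs2", 1, int(6e6), 6.0)
        cases = [regions_from([(1, 4.0, 6.0)])]
        counts = sharing_counts([start_snp, end_snp], cases, cases)
        assert counts[0].x1 == 1  # start included
        assert counts[1].x1 == 0  # end excluded

    def test_matches_bruteforce_membership(self, rng):
        sets = [random_region_set(rng, f"s{i}") for i in range(6)]
        snps = [
            SnpMarker(f"rs{j}", 1, j * 1000 + 1, float(rng.uniform(0, 10)))
            for j in range(40)
        ]
        counts = sharing_counts(snps, sets[:3], sets[3:])
        for c in counts:
            x1 = sum(
                any(s.start_cm <= c.snp.pos_cm < s.end_cm for s in rs.segments)
                for rs in sets[:3]
            )
            x2 = sum(
                any(s.start_cm <= c.snp.pos_cm < s.end_cm for s in rs.segments)
                for rs in sets[3:]
            )
            assert (c.x1, c.x2) == (x1, x2)


def snp(pos_cm=1.0, chrom=1):
    return SnpMarker("rs", chrom, max(1, int(pos_cm * 1e6)), pos_cm)


class TestUStatistic:
    def test_equal_proportions_give_null(self):
        u, p, nlp = u_statistic(SharingCounts(snp(), 3, 5, 3, 5))
        assert u == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(0.5)
        assert nlp == pytest.approx(np.log10(2), abs=1e-9)

    def test_published_style_example(self):
        u, p, nlp = u_statistic(SharingCounts(snp(), 5, 5, 4, 86))
        assert u == pytest.approx(6.179, abs=2e-3)
        assert nlp == pytest.approx(9.5, abs=0.05)

    def test_label_swap_antisymmetry(self, rng):
        for _ in range(25):
            n1, n2 = int(rng.integers(1, 50)), int(rng.integers(1, 200))
            x1, x2 = int(rng.integers(0, n1 + 1)), int(rng.integers(0, n2 + 1))
            u_fwd, *_ = u_statistic(SharingCounts(snp(), x1, n1, x2, n2))
            u_rev, *_ = u_statistic(SharingCounts(snp(), x2, n2, x1, n1))
            assert u_fwd == pytest.approx(-u_rev, abs=1e-12)

    def test_matches_high_precision_normal_tail(self):
        """P agrees with an mpmath erfc evaluation to 1e-10 over a count grid."""
        import mpmath

        mpmath.mp.dps = 40
        for n1, n2 in [(5, 86), (5, 20), (10, 10), (3, 100)]:
            for x1 in range(n1 + 1):
                for x2 in range(0, n2 + 1, max(1, n2 // 7)):
                    u, p, _ = u_statistic(SharingCounts(snp(), x1, n1, x2, n2))
                    p_ref = float(0.5 * mpmath.erfc(mpmath.mpf(u) / mpmath.sqrt(2)))
                    assert abs(p - p_ref) < 1e-10

    def test_neg_log10_p_monotone_in_x1(self):
        nlps = [u_statistic(SharingCounts(snp(), x1, 8, 2, 40))[2] for x1 in range(9)]
        assert np.all(np.diff(nlps) > 0)

    def test_legacy_variance_variant(self):
        c = SharingCounts(snp(), 5, 5, 4, 86)
        u_std, *_ = u_statistic(c)
        u_strict, *_ = u_statistic(c, legacy_variance=True)
        # 1/n1 + 1/n1 > 1/n1 + 1/n2 for n2 > n1, so the strict u is smaller
        assert u_strict < u_std


class TestRankOverlaps:
    def test_single_overlap_rank_one(self):
        seg = Segment(1, 0.0, 2.0, 0, 100, kind=SegmentKind.OVERLAP)
        (r,) = rank_overlaps([seg], [(snp(1.0), 5.0)])
        assert r.rank == 1 and r.max_neg_log10_p == 5.0

    def test_global_max_snp_wins(self):
        seg_a = Segment(1, 0.0, 2.0, 0, 100, kind=SegmentKind.OVERLAP)
        seg_b = Segment(1, 5.0, 6.0, 500, 600, kind=SegmentKind.OVERLAP)
        stats = [(snp(1.0), 3.0), (snp(5.5), 16.47), (snp(5.7), 2.0)]
        ranked = rank_overlaps([seg_a, seg_b], stats)
        assert ranked[0].segment is seg_b
        assert ranked[0].max_neg_log10_p == pytest.approx(16.47)
        assert ranked[0].best_snp.pos_cm == pytest.approx(5.5)

    def test_tie_broken_by_length(self):
        long_seg = Segment(1, 0.0, 3.0, 0, 300, kind=SegmentKind.OVERLAP)
        short_seg = Segment(2, 0.0, 1.0, 0, 100, kind=SegmentKind.OVERLAP)
        stats = [(snp(0.5, 1), 4.0), (snp(0.5, 2), 4.0)]
        ranked = rank_overlaps([short_seg, long_seg], stats)
        assert ranked[0].segment is long_seg
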