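"""RHS overlap across patients and case-control prioritization.

The overlap step intersects the RHS sets of all patients; under the model
the disease locus lies in the intersection with probability given by the
product rule in :mod:`qhmap.probability`.  Because SNP positioning,
haplotype blocks and population substructure make some regions prone to
runs of homozygosity in anyone, overlaps are then prioritized against a
control cohort: at each SNP the proportions of cases and controls whose RHS
covers it are compared with a continuity-corrected two-proportion z
statistic, and each overlap is ranked by its best ``-log10(P)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core import GenomeRegions, Segment, SegmentKind, SnpMarker


@dataclass
class SharingCounts:
    """Coverage counts at one SNP: x1 of n1 cases, x2 of n2 controls."""

    snp: SnpMarker
    x1: int
    n1: int
    x2: int
    n2: int

    def __post_init__(self) -> None:
        if not (0 <= self.x1 <= self.n1 and 0 <= self.x2 <= self.n2):
            raise ValueError("coverage counts out of range")
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("need at least one case and one control")


def _chrom_intervals(regions: GenomeRegions) -> dict[int, np.ndarray]:
    """Sorted (start_cm, end_cm, start_bp, end_bp) arrays per chromosome."""
    out: dict[int, np.ndarray] = {}
    for chrom in sorted({s.chrom for s in regions.segments}):
        segs = regions.by_chrom(chrom)
        out[chrom] = np.array(
            [[s.start_cm, s.end_cm, s.start_bp, s.end_bp] for s in segs], dtype=float
        )
    return out


def _intersect_two(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Intersect two sorted interval arrays (cM driving, bp carried along)."""
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i, 0], b[j, 0])
        hi = min(a[i, 1], b[j, 1])
        if hi > lo:
            out.append(
                [lo, hi, max(a[i, 2], b[j, 2]), min(a[i, 3], b[j, 3])]
            )
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return np.asarray(out, dtype=float).reshape(-1, 4)


def intersect_regions(region_sets: Sequence[GenomeRegions]) -> list[Segment]:
    """Maximal intervals covered by a segment in *every* input set."""
    if not region_sets:
        raise ValueError("need at least one region set")
    chroms = sorted({s.chrom for s in region_sets[0].segments})
    segments: list[Segment] = []
    per_set = [_chrom_intervals(r) for r in region_sets]
    for chrom in chroms:
        acc = per_set[0].get(chrom)
        for other in per_set[1:]:
            if acc is None or len(acc) == 0:
                acc = None
                break
            acc = _intersect_two(acc, other.get(chrom, np.empty((0, 4))))
        if acc is None:
            continue
        for lo, hi, sbp, ebp in acc:
            if ebp <= sbp:  # degenerate bp after intersection; keep 1 bp wide
                ebp = sbp + 1
            segments.append(
                Segment(
                    chrom=chrom,
                    start_cm=float(lo),
                    end_cm=float(hi),
                    start_bp=int(sbp),
                    end_bp=int(ebp),
                    kind=SegmentKind.OVERLAP,
                )
            )
    return segments


def _covers(intervals: dict[int, np.ndarray], snp: SnpMarker) -> bool:
    arr = intervals.get(snp.chrom)
    if arr is None or len(arr) == 0:
        return False
    i = int(np.searchsorted(arr[:, 0], snp.pos_cm, side="right")) - 1
    return i >= 0 and snp.pos_cm < arr[i, 1]


def sharing_counts(
    snps: Sequence[SnpMarker],
    patient_sets: Sequence[GenomeRegions],
    control_sets: Sequence[GenomeRegions],
) -> list[SharingCounts]:
    """Per-SNP counts of cases/controls whose RHS covers the SNP.

    Coverage is a point-in-interval test on the genetic coordinate with
    half-open intervals ``[start_cm, end_cm)``.
    """
    pat = [_chrom_intervals(r) for r in patient_sets]
    ctl = [_chrom_intervals(r) for r in control_sets]
    out = []
    for snp in snps:
        x1 = sum(_covers(iv, snp) for iv in pat)
        x2 = sum(_covers(iv, snp) for iv in ctl)
        out.append(SharingCounts(snp, x1, len(pat), x2, len(ctl)))
    return out


def u_statistic(
    c: SharingCounts, legacy_variance: bool = False
) -> tuple[float, float, float]:
    """Continuity-corrected two-proportion z statistic and one-sided P value.

    With ``p̂1* = (x1 + 0.5)/(n1 + 1)``, ``p̂2* = (x2 + 0.5)/(n2 + 1)`` and
    pooled ``p̂* = (x1 + x2 + 0.5)/(n1 + n2 + 1)``,

        u = (p̂1* - p̂2*) / sqrt(p̂* (1 - p̂*) (1/n1 + 1/n2)),

    and P is the upper-tail standard normal probability of ``u``.  Returns
    ``(u, P, -log10 P)``.  ``legacy_variance`` replaces ``1/n2`` by a
    second ``1/n1`` term in the variance (a published variant we read as a
    misprint of the standard two-sample form).
    """
    p1 = (c.x1 + 0.5) / (c.n1 + 1)
    p2 = (c.x2 + 0.5) / (c.n2 + 1)
    pp = (c.x1 + c.x2 + 0.5) / (c.n1 + c.n2 + 1)
    assert 0.0 < pp < 1.0, "pooled proportion degenerate despite continuity correction"
    inv = (1.0 / c.n1 + 1.0 / c.n1) if legacy_variance else (1.0 / c.n1 + 1.0 / c.n2)
    u = (p1 - p2) / np.sqrt(pp * (1.0 - pp) * inv)
    p_value = float(stats.norm.sf(u))
    with np.errstate(divide="ignore"):
        neg_log10_p = float(-np.log10(p_value)) if p_value > 0 else float("inf")
    return float(u), p_value, neg_log10_p


@dataclass
class RankedOverlap:
    segment: Segment
    max_neg_log10_p: float
    best_snp: SnpMarker | None
    rank: int = 0


def rank_overlaps(
    overlaps: Sequence[Segment],
    stats_at_snps: Sequence[tuple[SnpMarker, float]],
) -> list[RankedOverlap]:
    """Rank overlaps by the maximum ``-log10(P)`` over SNPs they contain.

    ``stats_at_snps`` pairs each evaluated SNP with its ``-log10(P)``.
    Ties break by genetic length (longer first), then by coordinate; an
    overlap containing no evaluated SNP ranks last with ``-inf``.
    """
    ranked = []
    for seg in overlaps:
        best, best_snp = float("-inf"), None
        for snp, nlp in stats_at_snps:
            if snp.chrom == seg.chrom and seg.start_cm <= snp.pos_cm < seg.end_cm:
                if nlp > best:
                    best, best_snp = nlp, snp
        ranked.append(RankedOverlap(seg, best, best_snp))
    ranked.sort(
        key=lambda r: (
            -r.max_neg_log10_p,
            -r.segment.genetic_length_cm,
            r.segment.chrom,
            r.segment.start_bp,
        )
    )
    for i, r in enumerate(ranked, start=1):
        r.rank = i
    return ranked
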