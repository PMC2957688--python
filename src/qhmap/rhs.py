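"""Detection of runs of homozygous SNPs (RHS) and per-sample summaries.

A candidate run is a maximal stretch of a chromosome containing no
heterozygous call.  Its genetic bounds are the cM positions of the flanking
heterozygous SNPs (or the chromosome map ends), its physical bounds come
from the outermost homozygous SNPs inside, and NO_CALL sites neither extend
nor break it.  A candidate qualifies as an RHS when its genetic length is
strictly greater than the cutoff and it contains at least ``min_snps``
homozygous SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Call, GenomeRegions, GenotypeTrack, Segment, SegmentKind
from .cutoff import DEFAULT_CUTOFF_CM


@dataclass
class RhsCallParams:
    cutoff_cm: float = DEFAULT_CUTOFF_CM
    min_snps: int = 1

    def __post_init__(self) -> None:
        if self.cutoff_cm < 0:
            raise ValueError("cutoff_cm must be >= 0")
        if self.min_snps < 1:
            raise ValueError("min_snps must be >= 1")


def detect_rhs(
    track: GenotypeTrack,
    params: RhsCallParams | None = None,
    chrom_start_cm: float | None = None,
    chrom_end_cm: float | None = None,
) -> list[Segment]:
    """Detect RHSs on one (already error-corrected) chromosome track.

    ``chrom_start_cm``/``chrom_end_cm`` bound runs at the chromosome ends;
    they default to the first/last marker's cM position.
    """
    params = params or RhsCallParams()
    if len(track) == 0:
        return []
    start_cm = float(track.pos_cm[0]) if chrom_start_cm is None else float(chrom_start_cm)
    end_cm = float(track.pos_cm[-1]) if chrom_end_cm is None else float(chrom_end_cm)

    het_idx = np.flatnonzero(track.calls == Call.HET)
    hom_mask = (track.calls == Call.HOM_A) | (track.calls == Call.HOM_B)
    # candidate intervals between consecutive HETs (and the chromosome ends)
    left_edges = np.concatenate(([-1], het_idx))
    right_edges = np.concatenate((het_idx, [len(track)]))
    segments: list[Segment] = []
    for li, ri in zip(left_edges, right_edges):
        lo_cm = start_cm if li < 0 else float(track.pos_cm[li])
        hi_cm = end_cm if ri >= len(track) else float(track.pos_cm[ri])
        if hi_cm - lo_cm <= params.cutoff_cm:
            continue
        inside = np.flatnonzero(hom_mask[li + 1 : ri]) + li + 1
        if inside.size < params.min_snps:
            continue
        first_bp = int(track.pos_bp[inside[0]])
        last_bp = int(track.pos_bp[inside[-1]])
        segments.append(
            Segment(
                chrom=track.chrom,
                start_cm=lo_cm,
                end_cm=hi_cm,
                start_bp=first_bp - 1,  # 1-based SNP -> 0-based half-open
                end_bp=last_bp,
                n_snps=int(inside.size),
                kind=SegmentKind.RHS,
            )
        )
    return segments


def detect_rhs_genome(
    tracks: list[GenotypeTrack],
    params: RhsCallParams | None = None,
    total_autosome_cm: float | None = None,
    chrom_bounds_cm: dict[int, tuple[float, float]] | None = None,
) -> GenomeRegions:
    """Run RHS detection over all tracks of one sample.

    ``total_autosome_cm`` defaults to the summed cM extent of the tracks
    (or of ``chrom_bounds_cm`` when supplied); it is carried into the
    resulting :class:`GenomeRegions` for the consanguinity estimate.
    """
    if not tracks:
        raise ValueError("no tracks given")
    bounds = chrom_bounds_cm or {}
    segments: list[Segment] = []
    extent = 0.0
    for t in sorted(tracks, key=lambda t: t.chrom):
        lo, hi = bounds.get(
            t.chrom,
            (float(t.pos_cm[0]), float(t.pos_cm[-1])) if len(t) else (0.0, 0.0),
        )
        extent += hi - lo
        segments.extend(detect_rhs(t, params, chrom_start_cm=lo, chrom_end_cm=hi))
    total = extent if total_autosome_cm is None else float(total_autosome_cm)
    return GenomeRegions(
        sample_id=tracks[0].sample_id, segments=segments, total_autosome_cm=total
    )


def longest_rhs_cm(regions: GenomeRegions) -> float:
    """Genetic length of the longest segment; 0 when there is none.

    The longest run indexes the most recent inbreeding event in the
    sample's ancestry and is what the family-history check compares against
    the simulated longest-AS distribution.
    """
    if not regions.segments:
        return 0.0
    return max(s.genetic_length_cm for s in regions.segments)


def estimate_f(regions: GenomeRegions) -> float:
    """Coefficient of consanguinity: total RHS length over L_autosome.

    Autozygosity tiles roughly a fraction F of the genome, so the summed
    genetic length of the detected runs divided by the total autosomal map
    length estimates F (1/16 for offspring of first cousins).
    """
    return regions.total_segment_cm / regions.total_autosome_cm
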