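"""Core domain types shared by every stage of the homozygosity-mapping pipeline.

Coordinate conventions
----------------------
* Physical positions (``pos_bp``) are 1-based on input; segment bp bounds are
  0-based half-open (BED convention).
* Genetic positions (``pos_cm``) are centimorgans from the telomere of the
  short arm (pter).
* Only autosomes 1-22 are handled; everything else is filtered at I/O time.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

AUTOSOMES = tuple(range(1, 23))


class Call(enum.IntEnum):
    """A genotype call at one biallelic SNP."""

    HOM_A = 0
    HET = 1
    HOM_B = 2
    NO_CALL = 3


#: text representations used by the native TSV format
CALL_TO_TEXT = {Call.HOM_A: "AA", Call.HET: "AB", Call.HOM_B: "BB", Call.NO_CALL: "NC"}
TEXT_TO_CALL = {v: k for k, v in CALL_TO_TEXT.items()}


@dataclass(frozen=True)
class SnpMarker:
    """One SNP's position on the physical and genetic map."""

    snp_id: str
    chrom: int
    pos_bp: int
    pos_cm: float

    def __post_init__(self) -> None:
        if self.chrom not in AUTOSOMES:
            raise ValueError(f"chrom must be an autosome 1-22, got {self.chrom!r}")
        if self.pos_bp < 1:
            raise ValueError(f"pos_bp must be >= 1, got {self.pos_bp}")
        if self.pos_cm < 0:
            raise ValueError(f"pos_cm must be >= 0, got {self.pos_cm}")


@dataclass
class GenotypeTrack:
    """Ordered genotype calls of one sample along one autosome.

    Markers are stored as parallel numpy arrays for efficiency; the
    :meth:`markers` accessor materialises :class:`SnpMarker` objects on demand.
    """

    sample_id: str
    chrom: int
    snp_ids: np.ndarray  # dtype=object or <U*, shape (n,)
    pos_bp: np.ndarray  # int64, strictly increasing
    pos_cm: np.ndarray  # float64, non-decreasing
    calls: np.ndarray  # int8, values in Call

    def __post_init__(self) -> None:
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.pos_cm = np.asarray(self.pos_cm, dtype=np.float64)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        n = len(self.pos_bp)
        if not (len(self.pos_cm) == len(self.calls) == len(self.snp_ids) == n):
            raise ValueError("parallel arrays of a GenotypeTrack differ in length")
        if self.chrom not in AUTOSOMES:
            raise ValueError(f"chrom must be an autosome 1-22, got {self.chrom!r}")
        if n > 1:
            if not np.all(np.diff(self.pos_bp) > 0):
                raise ValueError(
                    f"markers on chr{self.chrom} must be strictly sorted by pos_bp"
                )
            if not np.all(np.diff(self.pos_cm) >= 0):
                raise ValueError(
                    f"pos_cm must be non-decreasing along chr{self.chrom}"
                )

    def __len__(self) -> int:
        return len(self.pos_bp)

    def markers(self) -> Iterator[SnpMarker]:
        for i in range(len(self)):
            yield SnpMarker(
                str(self.snp_ids[i]), self.chrom, int(self.pos_bp[i]), float(self.pos_cm[i])
            )

    @property
    def n_called(self) -> int:
        """Number of SNPs successfully genotyped (non-NO_CALL)."""
        return int(np.count_nonzero(self.calls != Call.NO_CALL))

    @property
    def n_het(self) -> int:
        return int(np.count_nonzero(self.calls == Call.HET))

    @property
    def n_hom(self) -> int:
        return int(
            np.count_nonzero((self.calls == Call.HOM_A) | (self.calls == Call.HOM_B))
        )

    def copy(self) -> "GenotypeTrack":
        return GenotypeTrack(
            self.sample_id,
            self.chrom,
            self.snp_ids.copy(),
            self.pos_bp.copy(),
            self.pos_cm.copy(),
            self.calls.copy(),
        )


class SegmentKind(enum.Enum):
    AS = "AS"
    RHS = "RHS"
    OVERLAP = "OVERLAP"


@dataclass
class Segment:
    """A genomic interval with both physical and genetic bounds.

    Used for true autozygous segments (AS), detected runs of homozygous SNPs
    (RHS) and multi-sample overlaps.  ``start_bp``/``end_bp`` are 0-based
    half-open; cM bounds carry the genetic length used throughout the model.
    """

    chrom: int
    start_cm: float
    end_cm: float
    start_bp: int
    end_bp: int
    n_snps: int = 0
    kind: SegmentKind = SegmentKind.RHS

    def __post_init__(self) -> None:
        if self.chrom not in AUTOSOMES:
            raise ValueError(f"chrom must be an autosome 1-22, got {self.chrom!r}")
        if self.end_cm < self.start_cm:
            raise ValueError("end_cm < start_cm")
        if self.end_bp <= self.start_bp:
            raise ValueError("end_bp must exceed start_bp")
        if isinstance(self.kind, str):
            self.kind = SegmentKind(self.kind)

    @property
    def genetic_length_cm(self) -> float:
        return self.end_cm - self.start_cm


@dataclass
class GenomeRegions:
    """All segments of one kind for one sample, plus the autosomal map length."""

    sample_id: str
    segments: list[Segment] = field(default_factory=list)
    total_autosome_cm: float = 0.0

    def __post_init__(self) -> None:
        if self.total_autosome_cm <= 0:
            raise ValueError("total_autosome_cm must be positive")
        by_chrom: dict[int, list[Segment]] = {}
        for seg in self.segments:
            by_chrom.setdefault(seg.chrom, []).append(seg)
        for chrom, segs in by_chrom.items():
            segs = sorted(segs, key=lambda s: s.start_cm)
            for a, b in zip(segs, segs[1:]):
                if b.start_cm < a.end_cm and b.start_bp < a.end_bp:
                    raise ValueError(f"overlapping segments on chr{chrom}")
        self.segments = sorted(self.segments, key=lambda s: (s.chrom, s.start_bp))

    def by_chrom(self, chrom: int) -> list[Segment]:
        return [s for s in self.segments if s.chrom == chrom]

    @property
    def total_segment_cm(self) -> float:
        return float(sum(s.genetic_length_cm for s in self.segments))


def tracks_by_sample(tracks: Sequence[GenotypeTrack]) -> dict[str, list[GenotypeTrack]]:
    """Group tracks by sample id, each group sorted by chromosome."""
    out: dict[str, list[GenotypeTrack]] = {}
    for t in tracks:
        out.setdefault(t.sample_id, []).append(t)
    for sid in out:
        out[sid].sort(key=lambda t: t.chrom)
    return out
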