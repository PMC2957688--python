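"""Truth-annotated synthetic genotype data for end-to-end testing.

The generator emulates the input of an array-based homozygosity-mapping
study at desk scale: SNPs scattered uniformly in genetic distance over a few
chromosomes, founder haplotypes drawn at linkage equilibrium from per-SNP
allele frequencies, descent through a consanguinity loop simulated with
Haldane meioses (via :mod:`qhmap.simulate`), and genotyping errors injected
at a configurable rate.  Every inbred sample comes with its true autozygous
segments, so detection and correction can be scored against truth.

Real array data differ in ways deliberately not modelled here: linkage
disequilibrium / haplotype blocks (which inflate chance runs), population
substructure, and non-uniform SNP spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .core import Call, GenotypeTrack, Segment, SegmentKind, SnpMarker
from .simulate import PedigreeLoopConfig, _autozygous_intervals, _LoopSimulator

BP_PER_CM = 1_000_000  # toy physical scale: 1 cM = 1 Mb


@dataclass
class SynthConfig:
    """Scale, allele-frequency model and pedigree of a synthetic dataset."""

    n_snps_per_chrom: int = 5000
    chrom_lengths_cm: list[float] = field(default_factory=lambda: [150.0] * 4)
    major_freq_low: float = 0.5
    major_freq_high: float = 0.95
    pedigree: PedigreeLoopConfig | None = None  # None = outbred
    error_rate: float = 0.003
    no_call_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps_per_chrom < 2:
            raise ValueError("need at least 2 SNPs per chromosome")
        if not 0.0 <= self.error_rate <= 1.0 or not 0.0 <= self.no_call_rate <= 1.0:
            raise ValueError("rates must lie in [0, 1]")
        if not 0.5 <= self.major_freq_low <= self.major_freq_high <= 1.0:
            raise ValueError("major-allele frequency bounds must satisfy 0.5 <= low <= high <= 1")

    def loop(self) -> PedigreeLoopConfig:
        if self.pedigree is None:
            raise ValueError("config is outbred; no pedigree loop defined")
        return self.pedigree

    @classmethod
    def first_cousin(cls, **kwargs) -> "SynthConfig":
        """Convenience: offspring-of-first-cousins pedigree (m = n = 3)."""
        cfg = cls(**kwargs)
        cfg.pedigree = PedigreeLoopConfig(
            m=3, n=3, chrom_lengths_cm=list(cfg.chrom_lengths_cm), seed=cfg.seed
        )
        return cfg


@dataclass
class SyntheticMap:
    """Per-chromosome marker arrays plus per-SNP allele-A frequencies."""

    chrom_lengths_cm: list[float]
    pos_cm: list[np.ndarray]
    pos_bp: list[np.ndarray]
    snp_ids: list[np.ndarray]
    freq_a: list[np.ndarray]

    @property
    def n_chrom(self) -> int:
        return len(self.pos_cm)

    @property
    def total_cm(self) -> float:
        return float(sum(self.chrom_lengths_cm))

    def markers(self) -> Iterator[SnpMarker]:
        for ci in range(self.n_chrom):
            for j in range(len(self.pos_cm[ci])):
                yield SnpMarker(
                    str(self.snp_ids[ci][j]), ci + 1,
                    int(self.pos_bp[ci][j]), float(self.pos_cm[ci][j]),
                )

    def chrom_bounds_cm(self) -> dict[int, tuple[float, float]]:
        return {ci + 1: (0.0, float(L)) for ci, L in enumerate(self.chrom_lengths_cm)}


def generate_map(config: SynthConfig, rng: np.random.Generator | None = None) -> SyntheticMap:
    """Scatter SNPs uniformly in cM on each chromosome and draw allele frequencies.

    Physical positions follow the toy 1 cM = 1 Mb scale and are forced
    strictly increasing.  The major-allele frequency of each SNP is uniform
    on ``[major_freq_low, major_freq_high]``; which allele is the major one
    is a fair coin.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    pos_cm, pos_bp, ids, freq = [], [], [], []
    for ci, length in enumerate(config.chrom_lengths_cm):
        cm = np.sort(rng.random(config.n_snps_per_chrom) * length)
        bp = np.round(cm * BP_PER_CM).astype(np.int64) + 1
        bp = np.maximum(bp, np.arange(1, len(bp) + 1))  # strictly increasing floor
        while np.any(np.diff(bp) <= 0):
            up = np.flatnonzero(np.diff(bp) <= 0) + 1
            bp[up] = bp[up - 1] + 1
        maj = rng.uniform(config.major_freq_low, config.major_freq_high, len(cm))
        swap = rng.random(len(cm)) < 0.5
        fa = np.where(swap, 1.0 - maj, maj)
        pos_cm.append(cm)
        pos_bp.append(bp)
        ids.append(np.array([f"snp{ci + 1}_{j}" for j in range(len(cm))], dtype=object))
        freq.append(fa)
    return SyntheticMap(list(config.chrom_lengths_cm), pos_cm, pos_bp, ids, freq)


def _calls_from_alleles(hap_p: np.ndarray, hap_m: np.ndarray) -> np.ndarray:
    return (hap_p + hap_m).astype(np.int8)  # 0=HOM_A, 1=HET, 2=HOM_B


def _apply_no_calls(calls: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate > 0:
        calls = calls.copy()
        calls[rng.random(len(calls)) < rate] = Call.NO_CALL
    return calls


def _labelled_genotypes(
    smap: SyntheticMap,
    ci: int,
    bounds: list[float],
    labs_p: list[int],
    labs_m: list[int],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Haplotype alleles at the SNPs of one chromosome given origin labels.

    Founder haplotypes (A1, A2, B1, B2) are drawn once per chromosome; loci
    whose label is "outside the loop" receive independent population alleles
    (linkage equilibrium makes distinct outside sources exchangeable).
    """
    fa = smap.freq_a[ci]
    n = len(fa)
    founders = (rng.random((4, n)) < fa).astype(np.int8)
    outside = (rng.random((2, n)) < fa).astype(np.int8)
    b = np.asarray(bounds)
    idx = np.searchsorted(b, smap.pos_cm[ci], side="right") - 1
    lab_p = np.asarray(labs_p, dtype=np.int8)[idx]
    lab_m = np.asarray(labs_m, dtype=np.int8)[idx]
    hap_p = np.where(lab_p < 4, founders[np.minimum(lab_p, 3), np.arange(n)], outside[0])
    hap_m = np.where(lab_m < 4, founders[np.minimum(lab_m, 3), np.arange(n)], outside[1])
    return hap_p.astype(np.int8), hap_m.astype(np.int8)


def _truth_segment(ci: int, a: float, b: float) -> Segment:
    return Segment(
        chrom=ci + 1,
        start_cm=a,
        end_cm=b,
        start_bp=int(a * BP_PER_CM),
        end_bp=int(b * BP_PER_CM) + 1,
        kind=SegmentKind.AS,
    )


def generate_inbred_sample(
    config: SynthConfig,
    smap: SyntheticMap,
    rng: np.random.Generator,
    sample_id: str = "inbred",
) -> tuple[list[GenotypeTrack], list[Segment]]:
    """One offspring of the configured consanguinity loop, with true ASs.

    Before error injection, every SNP inside a true AS is homozygous by
    construction (both homologs copy the same founder haplotype).
    """
    loop = config.loop()
    sim = _LoopSimulator(loop.m, loop.n, config.chrom_lengths_cm)
    tracks, truth = [], []
    for ci, bounds, lp, lm in sim.sample_event(rng):
        hap_p, hap_m = _labelled_genotypes(smap, ci, bounds, lp, lm, rng)
        calls = _apply_no_calls(_calls_from_alleles(hap_p, hap_m), config.no_call_rate, rng)
        tracks.append(
            GenotypeTrack(sample_id, ci + 1, smap.snp_ids[ci],
                          smap.pos_bp[ci], smap.pos_cm[ci], calls)
        )
        for a, b in _autozygous_intervals(bounds, lp, lm, config.chrom_lengths_cm[ci]):
            truth.append(_truth_segment(ci, a, b))
    return tracks, truth


def generate_outbred_sample(
    config: SynthConfig,
    smap: SyntheticMap,
    rng: np.random.Generator,
    sample_id: str = "outbred",
) -> list[GenotypeTrack]:
    """An unrelated individual: two independent haplotypes per chromosome."""
    tracks = []
    for ci in range(smap.n_chrom):
        fa = smap.freq_a[ci]
        haps = (rng.random((2, len(fa))) < fa).astype(np.int8)
        calls = _apply_no_calls(_calls_from_alleles(haps[0], haps[1]), config.no_call_rate, rng)
        tracks.append(
            GenotypeTrack(sample_id, ci + 1, smap.snp_ids[ci],
                          smap.pos_bp[ci], smap.pos_cm[ci], calls)
        )
    return tracks


@dataclass
class BenchmarkBundle:
    """A planted-locus case-control dataset with truth annotations."""

    smap: SyntheticMap
    case_tracks: dict[str, list[GenotypeTrack]]
    control_tracks: dict[str, list[GenotypeTrack]]
    case_truth: dict[str, list[Segment]]
    planted_locus: tuple[int, float]
    n_errors_injected: int = 0


def make_benchmark(
    config: SynthConfig,
    n_cases: int,
    n_controls: int,
    planted_locus: tuple[int, float],
    rng: np.random.Generator | None = None,
    max_tries_per_case: int = 2000,
) -> BenchmarkBundle:
    """Cases autozygous at a planted locus, plus outbred controls.

    Cases are inbred samples rejection-sampled until their true-AS set
    covers ``planted_locus`` (chromosome, cM); the descent is re-simulated
    until acceptance, so accepted genomes follow the conditional law.
    Genotyping errors are injected into cases and controls at
    ``config.error_rate``.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    chrom, pos = planted_locus
    if not (1 <= chrom <= len(config.chrom_lengths_cm)) or not (
        0.0 <= pos <= config.chrom_lengths_cm[chrom - 1]
    ):
        raise ValueError("planted locus outside the synthetic map")
    loop = config.loop()
    sim = _LoopSimulator(loop.m, loop.n, config.chrom_lengths_cm)
    smap = generate_map(config, rng)

    from .correction import inject_errors  # late import to avoid a cycle

    case_tracks: dict[str, list[GenotypeTrack]] = {}
    case_truth: dict[str, list[Segment]] = {}
    n_err = 0
    for k in range(n_cases):
        sid = f"case{k + 1}"
        for attempt in range(max_tries_per_case):
            event = list(sim.sample_event(rng))
            ci0 = chrom - 1
            bounds, lp, lm = event[ci0][1], event[ci0][2], event[ci0][3]
            az = _autozygous_intervals(bounds, lp, lm, config.chrom_lengths_cm[ci0])
            if any(a <= pos < b for a, b in az):
                break
        else:
            raise RuntimeError(
                f"rejection sampling failed for {sid} after {max_tries_per_case} tries; "
                "increase max_tries_per_case"
            )
        tracks, truth = [], []
        for ci, bounds, lp, lm in event:
            hap_p, hap_m = _labelled_genotypes(smap, ci, bounds, lp, lm, rng)
            calls = _apply_no_calls(
                _calls_from_alleles(hap_p, hap_m), config.no_call_rate, rng
            )
            tracks.append(
                GenotypeTrack(sid, ci + 1, smap.snp_ids[ci],
                              smap.pos_bp[ci], smap.pos_cm[ci], calls)
            )
            for a, b in _autozygous_intervals(bounds, lp, lm, config.chrom_lengths_cm[ci]):
                truth.append(_truth_segment(ci, a, b))
        tracks, injected = inject_errors(tracks, config.error_rate, rng)
        n_err += injected
        case_tracks[sid] = tracks
        case_truth[sid] = truth

    control_tracks: dict[str, list[GenotypeTrack]] = {}
    for k in range(n_controls):
        sid = f"control{k + 1}"
        tracks = generate_outbred_sample(config, smap, rng, sample_id=sid)
        tracks, injected = inject_errors(tracks, config.error_rate, rng)
        n_err += injected
        control_tracks[sid] = tracks
    return BenchmarkBundle(smap, case_tracks, control_tracks, case_truth,
                           planted_locus, n_err)


def covered_fraction(
    truth: list[Segment],
    detected: list[Segment],
    min_truth_cm: float = 0.0,
) -> float:
    """Fraction of true-AS genetic length covered by detected segments.

    Only truth segments with genetic length strictly greater than
    ``min_truth_cm`` enter the tally; returns 1.0 when nothing qualifies.
    """
    by_chrom: dict[int, list[tuple[float, float]]] = {}
    for s in detected:
        by_chrom.setdefault(s.chrom, []).append((s.start_cm, s.end_cm))
    for chrom in by_chrom:
        by_chrom[chrom].sort()
    total = 0.0
    covered = 0.0
    for t in truth:
        if t.genetic_length_cm <= min_truth_cm:
            continue
        total += t.genetic_length_cm
        for a, b in by_chrom.get(t.chrom, ()):
            lo, hi = max(a, t.start_cm), min(b, t.end_cm)
            if hi > lo:
                covered += hi - lo
    return covered / total if total > 0 else 1.0
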