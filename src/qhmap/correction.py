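"""Genotyping-error correction: removal of isolated heterozygous calls.

A mistyped heterozygous SNP inside a long homozygous run sits much further
from its neighbouring heterozygous SNPs than chance allows.  With
heterozygote spacings ``~ Exp(lambda_het)``, the combined distance
``d = x + y`` from the previous to the next heterozygous SNP across a
genuine het is Erlang-2 distributed, so the probability of seeing a
separation at least as large by chance is ``(1 + lambda d) e^{-lambda d}``.
Heterozygous calls with this probability below a threshold (default 0.01)
are treated as mistyped and set to NO_CALL.

``lambda_het`` is estimated genome-wide for the sample *before* any removal
(``N_het / L_autosome``) and is not updated afterwards.  By default a single
simultaneous pass is made over the heterozygous calls, all distances being
measured in the original configuration; see the package methods notes for
why the pass is not iterated to a fixpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Call, GenotypeTrack

DEFAULT_REMOVAL_THRESHOLD = 0.01


def p_distance_by_chance(lambda_het: float, gap_cm) -> np.ndarray | float:
    """Chance probability of a het's flanking span ``d = x + y`` being >= observed.

    ``x`` and ``y`` are the genetic distances to the previous and next
    heterozygous SNP; under independent Exp(lambda) spacings their sum has
    the Erlang-2 survival function ``(1 + lambda d) e^{-lambda d}``.
    """
    if lambda_het <= 0:
        raise ValueError("lambda_het must be positive")
    d = np.asarray(gap_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("gap must be non-negative")
    ld = lambda_het * d
    out = (1.0 + ld) * np.exp(-ld)
    return float(out) if np.isscalar(gap_cm) else out


@dataclass
class CorrectionReport:
    """Removals made on one sample (possibly across several chromosomes)."""

    sample_id: str
    removed_snps: list[tuple[str, int, int, float]] = field(default_factory=list)
    lambda_het: float = float("nan")
    threshold: float = DEFAULT_REMOVAL_THRESHOLD

    @property
    def n_removed(self) -> int:
        return len(self.removed_snps)

    def merge(self, other: "CorrectionReport") -> None:
        self.removed_snps.extend(other.removed_snps)


def correct_track(
    track: GenotypeTrack,
    lambda_het: float,
    threshold: float = DEFAULT_REMOVAL_THRESHOLD,
    chrom_start_cm: float | None = None,
    chrom_end_cm: float | None = None,
    max_passes: int = 1,
) -> tuple[GenotypeTrack, CorrectionReport]:
    """Remove likely-mistyped heterozygous calls from one chromosome track.

    For every heterozygous call the span ``d`` from the previous heterozygous
    SNP (or the chromosome map start) to the next one (or the map end) is
    measured in cM; calls with ``p_distance_by_chance(lambda_het, d) <
    threshold`` are set to NO_CALL.  All spans of a pass are measured in the
    configuration at the start of that pass.  ``max_passes > 1`` repeats the
    pass on the reduced configuration (rarely useful; removals around real
    long runs then snowball outward, see methods notes).

    Returns a corrected copy of the track and a report of removals.
    """
    if lambda_het <= 0:
        raise ValueError("lambda_het must be positive")
    out = track.copy()
    report = CorrectionReport(track.sample_id, lambda_het=lambda_het, threshold=threshold)
    if len(out) == 0:
        return out, report
    start_cm = float(out.pos_cm[0]) if chrom_start_cm is None else float(chrom_start_cm)
    end_cm = float(out.pos_cm[-1]) if chrom_end_cm is None else float(chrom_end_cm)

    for _ in range(max_passes):
        het_idx = np.flatnonzero(out.calls == Call.HET)
        if het_idx.size == 0:
            break
        het_cm = out.pos_cm[het_idx]
        prev_cm = np.concatenate(([start_cm], het_cm[:-1]))
        next_cm = np.concatenate((het_cm[1:], [end_cm]))
        span = np.maximum(next_cm - prev_cm, 0.0)
        p = p_distance_by_chance(lambda_het, span)
        flagged = np.flatnonzero(p < threshold)
        if flagged.size == 0:
            break
        for j in flagged[np.argsort(p[flagged], kind="stable")]:  # most extreme first
            i = int(het_idx[j])
            report.removed_snps.append(
                (str(out.snp_ids[i]), out.chrom, int(out.pos_bp[i]), float(p[j]))
            )
            out.calls[i] = Call.NO_CALL
    return out, report


def correct_genome(
    tracks: list[GenotypeTrack],
    l_autosome_cm: float | None = None,
    threshold: float = DEFAULT_REMOVAL_THRESHOLD,
    chrom_bounds_cm: dict[int, tuple[float, float]] | None = None,
    max_passes: int = 1,
) -> tuple[list[GenotypeTrack], CorrectionReport]:
    """Correct all tracks of one sample with a genome-wide ``lambda_het``.

    ``lambda_het = N_het / L_autosome`` is computed over all tracks before
    any removal.  ``l_autosome_cm`` defaults to the summed cM extent of the
    tracks (or of ``chrom_bounds_cm`` when given).
    """
    if not tracks:
        raise ValueError("no tracks given")
    sample_id = tracks[0].sample_id
    bounds = chrom_bounds_cm or {}
    extents = []
    for t in tracks:
        lo, hi = bounds.get(
            t.chrom,
            (float(t.pos_cm[0]), float(t.pos_cm[-1])) if len(t) else (0.0, 0.0),
        )
        extents.append(hi - lo)
    total_cm = float(sum(extents)) if l_autosome_cm is None else float(l_autosome_cm)
    n_het = sum(t.n_het for t in tracks)
    if n_het == 0 or total_cm <= 0:
        return [t.copy() for t in tracks], CorrectionReport(
            sample_id, lambda_het=float("nan"), threshold=threshold
        )
    lam = n_het / total_cm
    out_tracks = []
    report = CorrectionReport(sample_id, lambda_het=lam, threshold=threshold)
    for t in tracks:
        lo, hi = bounds.get(t.chrom, (None, None))
        corrected, rep = correct_track(
            t, lam, threshold, chrom_start_cm=lo, chrom_end_cm=hi, max_passes=max_passes
        )
        out_tracks.append(corrected)
        report.merge(rep)
    return out_tracks, report


def inject_errors(
    tracks: list[GenotypeTrack],
    error_rate: float,
    seed: int | np.random.Generator,
) -> tuple[list[GenotypeTrack], int]:
    """Flip a seeded random subset of called genotypes to emulate array error.

    ``floor(N_called * error_rate)`` called SNPs are chosen uniformly without
    replacement across all tracks and each is flipped to one of the other two
    genotype calls with equal probability (symmetric confusion).  Returns the
    modified copies and the number of altered SNPs.
    """
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = [t.copy() for t in tracks]
    called = [(ti, i) for ti, t in enumerate(out) for i in np.flatnonzero(t.calls != Call.NO_CALL)]
    n_inject = int(len(called) * error_rate)
    if n_inject == 0:
        return out, 0
    chosen = rng.choice(len(called), size=n_inject, replace=False)
    genotypes = (Call.HOM_A, Call.HET, Call.HOM_B)
    for k in chosen:
        ti, i = called[int(k)]
        current = out[ti].calls[i]
        alternatives = [g for g in genotypes if g != current]
        out[ti].calls[i] = alternatives[int(rng.integers(len(alternatives)))]
    return out, n_inject
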