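"""Closed-form error model used to choose the RHS genetic-length cutoff.

The model treats two exponential length scales along the genome:

* Autozygous segments (AS) transmitted through a consanguinity loop with
  ``m + n`` meioses have lengths ``~ Exp(lambda_as)`` with
  ``lambda_as = (m + n) / 100`` per cM (Haldane crossovers, long-chromosome
  approximation).
* Spacings between heterozygous SNPs in non-autozygous sequence are
  ``~ Exp(lambda_het)`` with ``lambda_het = N_het / L_autosome``.

From these, the false-negative rate (AS length lost below the cutoff ``c``),
the type A false-positive rate (chance heterozygote spacings exceeding ``c``)
and the type B false-positive rate (end overhangs of true detections) follow
in closed form, and their trade-off motivates the default cutoff of 0.6 cM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: default RHS genetic-length cutoff (cM)
DEFAULT_CUTOFF_CM = 0.6


@dataclass
class CutoffModelParams:
    """Everything the cutoff error model needs about one dataset.

    ``mean_major_freq``/``mean_minor_freq`` are the array-wide average major
    and minor allele frequencies; ``n_pt`` is the number of SNPs successfully
    genotyped; ``error_rate`` is the per-call genotyping error probability.
    """

    m_plus_n: int
    cutoff_cm: float = DEFAULT_CUTOFF_CM
    n_het: int = 0
    n_hom: int = 0
    n_pt: int = 0
    l_autosome_cm: float = 1.0
    n_rhs: int = 0
    mean_major_freq: float = 0.75
    mean_minor_freq: float = 0.25
    error_rate: float = 0.003

    def __post_init__(self) -> None:
        if self.m_plus_n < 2:
            raise ValueError("m_plus_n must be >= 2")
        if self.cutoff_cm < 0:
            raise ValueError("cutoff_cm must be >= 0")
        if min(self.n_het, self.n_hom, self.n_rhs) < 0:
            raise ValueError("counts must be non-negative")
        if self.l_autosome_cm <= 0:
            raise ValueError("l_autosome_cm must be positive")
        if abs(self.mean_major_freq + self.mean_minor_freq - 1.0) > 1e-9:
            raise ValueError("major + minor mean frequencies must sum to 1")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")

    @property
    def lambda_as(self) -> float:
        """AS length rate, per cM."""
        return self.m_plus_n / 100.0

    @property
    def lambda_het(self) -> float:
        """Heterozygote spacing rate, per cM."""
        return self.n_het / self.l_autosome_cm


def as_length_pdf(m_plus_n: int, x_cm) -> np.ndarray | float:
    """Density of the AS length distribution, ``lambda * exp(-lambda x)``."""
    x = np.asarray(x_cm, dtype=float)
    if np.any(x < 0):
        raise ValueError("length must be non-negative")
    lam = m_plus_n / 100.0
    out = lam * np.exp(-lam * x)
    return float(out) if np.isscalar(x_cm) else out


def false_negative_rate(m_plus_n: int, cutoff_cm) -> np.ndarray | float:
    """Length fraction of ASs lost below the cutoff: ``1 - e^{-lc}(1 + lc)``.

    This is the length-weighted tail mass of the AS length distribution,
    i.e. the ratio of the expected AS length falling below ``c`` to the
    expected total AS length.
    """
    c = np.asarray(cutoff_cm, dtype=float)
    if np.any(c < 0):
        raise ValueError("cutoff must be non-negative")
    lc = (m_plus_n / 100.0) * c
    out = 1.0 - np.exp(-lc) * (1.0 + lc)
    return float(out) if np.isscalar(cutoff_cm) else out


def type_a_false_positive_rate(n_het: int, l_autosome_cm: float, cutoff_cm) -> np.ndarray | float:
    """Genome fraction in chance heterozygote gaps longer than the cutoff.

    With spacings ``~ Exp(lambda_het)``, the length-weighted mass of gaps
    exceeding ``c`` is ``(1 + lambda_het c) e^{-lambda_het c}``.
    """
    if n_het < 1:
        raise ValueError("n_het must be >= 1")
    if l_autosome_cm <= 0:
        raise ValueError("l_autosome_cm must be positive")
    c = np.asarray(cutoff_cm, dtype=float)
    lc = (n_het / l_autosome_cm) * c
    out = (1.0 + lc) * np.exp(-lc)
    return float(out) if np.isscalar(cutoff_cm) else out


def type_b_false_positive_rate(n_rhs: int, n_het: int) -> float:
    """Genome fraction in RHS end overhangs outside the contained AS.

    Each RHS is bounded by the flanking heterozygous SNPs, so a true
    detection overshoots the AS by on average half a heterozygote spacing,
    ``L_autosome / (2 N_het)``, at each end.  Counting both ends for every
    RHS (a deliberate overestimate: not every RHS contains an AS) gives
    ``n_rhs * (L/N_het) / L = n_rhs / n_het``.
    """
    if n_het < 1:
        raise ValueError("n_het must be >= 1")
    if n_rhs < 0:
        raise ValueError("n_rhs must be >= 0")
    return n_rhs / n_het


def false_positive_rate(params: CutoffModelParams) -> float:
    """Combined false-positive rate: type A plus type B."""
    return float(
        type_a_false_positive_rate(params.n_het, params.l_autosome_cm, params.cutoff_cm)
        + type_b_false_positive_rate(params.n_rhs, params.n_het)
    )


def expected_zygosity_counts(params: CutoffModelParams) -> tuple[float, float]:
    """Expected (N_homozygousSNP, N_heterozygousSNP) from mean allele frequencies.

    Under Hardy-Weinberg with array-average major/minor frequencies, of the
    ``N_pt`` successfully genotyped SNPs a fraction ``p^2 + q^2`` is expected
    homozygous and ``2pq`` heterozygous; the two add up to ``N_pt`` exactly.
    """
    p, q = params.mean_major_freq, params.mean_minor_freq
    n_hom = (p * p + q * q) * params.n_pt
    n_het = 2.0 * p * q * params.n_pt
    return n_hom, n_het


def cutoff_table(
    params: CutoffModelParams,
    cutoffs_cm: np.ndarray | None = None,
) -> pd.DataFrame:
    """Error rates on a grid of cutoff values (default 0-3 cM, step 0.01).

    Returns a DataFrame with columns ``cutoff_cm, r_false_negative,
    r_type_a_fp, r_type_b_fp, r_false_positive``; the type B component does
    not depend on the cutoff and is taken from ``params.n_rhs``.
    """
    if cutoffs_cm is None:
        cutoffs_cm = np.round(np.arange(0.0, 3.0 + 1e-9, 0.01), 10)
    c = np.asarray(cutoffs_cm, dtype=float)
    r_fn = false_negative_rate(params.m_plus_n, c)
    r_a = type_a_false_positive_rate(params.n_het, params.l_autosome_cm, c)
    r_b = type_b_false_positive_rate(params.n_rhs, params.n_het)
    return pd.DataFrame(
        {
            "cutoff_cm": c,
            "r_false_negative": r_fn,
            "r_type_a_fp": r_a,
            "r_type_b_fp": r_b,
            "r_false_positive": r_a + r_b,
        }
    )
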