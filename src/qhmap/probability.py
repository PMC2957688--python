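"""Gene-localization probabilities for homozygosity mapping.

For a patient with coefficient of consanguinity ``F`` and a recessive
disease allele of population frequency ``p``, the disease locus lies in an
autozygous segment with probability ``P_AS = F / ((1 - F) p + F)`` -- near 1
for strongly inbred patients and rare alleles.  Discounting by the RHS
false-negative rate gives the probability that the detected runs contain the
gene, and the product over patients gives the probability for the overlap of
their runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import prod
from typing import Sequence


@dataclass
class ConsanguinityParams:
    f: float  # coefficient of consanguinity
    p: float  # disease-allele population frequency
    r_fn: float = 0.0  # false-negative rate of RHS detection

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("f must be in [0, 1]")
        if not 0.0 < self.p <= 1.0:
            raise ValueError("p must be in (0, 1]")
        if not 0.0 <= self.r_fn < 1.0:
            raise ValueError("r_fn must be in [0, 1)")


def p_as(f: float, p: float) -> float:
    """Probability that the disease locus lies in an autozygous segment."""
    if not 0.0 <= f <= 1.0:
        raise ValueError("f must be in [0, 1]")
    if not 0.0 < p <= 1.0:
        raise ValueError("p must be in (0, 1] (f = p = 0 is undefined)")
    return f / ((1.0 - f) * p + f)


def p_gene_in_rhs(params: ConsanguinityParams) -> float:
    """Probability that the detected RHSs of one patient contain the gene."""
    return (1.0 - params.r_fn) * p_as(params.f, params.p)


def p_gene_in_overlap(per_patient: Sequence[float]) -> float:
    """Probability that the overlap of all patients' RHSs contains the gene."""
    if len(per_patient) == 0:
        raise ValueError("need at least one patient probability")
    if any(not 0.0 <= q <= 1.0 for q in per_patient):
        raise ValueError("probabilities must be in [0, 1]")
    return float(prod(per_patient))
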