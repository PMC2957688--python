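"""Monte Carlo simulation of autozygous segments through a consanguinity loop.

Model
-----
A consanguineous marriage closes a loop in the pedigree through a common
ancestor couple.  The affected subject is ``m`` meioses below the couple on
the paternal path and ``n`` meioses on the maternal path; the two paths run
through two different children of the couple.  Crossovers follow Haldane's
interference-free model: a Poisson process along genetic distance with rate
1/100 per cM per meiosis, with a fair-coin starting phase.

Along a chromosome, each meiosis in a path acts as an independent two-state
"telegraph" switch.  The founder-haplotype origin of the subject's paternal
homolog at a locus is read off the switch states: the ``m - 2`` lower
meioses decide whether loop material survived at all (versus material
married in from outside the loop), one meiosis chooses between the couple's
two members, and the top meiosis inside that ancestor chooses between that
ancestor's two haplotypes ``{A1, A2}`` or ``{B1, B2}``.  The maternal
homolog is labelled the same way with independent switches.  An autozygous
segment (AS) is a maximal interval where both homologs carry the same
founder haplotype; at each locus this happens with probability
``4 * (1/2)^m * (1/2)^n`` (1/16 for first cousins, m = n = 3).

The per-event longest AS summarises the most recent inbreeding: its
simulated distribution underpins the family-history consistency check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import AUTOSOMES, Segment, SegmentKind
from .genetic_map import default_autosome_lengths_cm

#: Haldane crossover rate per cM
CROSSOVER_RATE_PER_CM = 0.01

# label codes
_A1, _A2, _B1, _B2, _OUT_PAT, _OUT_MAT = 0, 1, 2, 3, 4, 5


@dataclass
class PedigreeLoopConfig:
    """Consanguinity-loop geometry and simulation size.

    ``m``/``n`` are the meiosis counts from the common-ancestor couple to the
    subject on the paternal and maternal path (first cousins: m = n = 3).
    ``n_events`` is the number of replicates with at least one AS collected
    by :func:`longest_as_distribution`.
    """

    m: int
    n: int
    chrom_lengths_cm: list[float] | None = None
    n_events: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1 or self.n < 1:
            raise ValueError("m and n must be >= 1")
        if self.chrom_lengths_cm is None:
            lengths = default_autosome_lengths_cm()
            self.chrom_lengths_cm = [lengths[c] for c in AUTOSOMES]
        if any(length <= 0 for length in self.chrom_lengths_cm):
            raise ValueError("chromosome lengths must be positive")
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")

    @property
    def m_plus_n(self) -> int:
        return self.m + self.n

    @property
    def total_length_cm(self) -> float:
        return float(sum(self.chrom_lengths_cm))


@dataclass
class AsSimulationSummary:
    """Summary of the AS process over events with at least one AS."""

    mean_count: float
    mean_length_cm: float
    max_length_samples: np.ndarray
    autozygous_fraction: float
    n_events: int = 0
    n_trials: int = 0

    def quantile(self, q) -> np.ndarray | float:
        """Quantile(s) of the per-event longest-AS length."""
        out = np.quantile(self.max_length_samples, q)
        return float(out) if np.isscalar(q) else out


def simulate_meiosis_mosaic(
    length_cm: float, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """One Haldane meiosis on a chromosome: crossover positions and start phase.

    Breakpoints are a Poisson process with rate 1/100 per cM; the starting
    phase (which parental homolog the gamete begins on) is a fair coin.
    """
    if length_cm <= 0:
        raise ValueError("length_cm must be positive")
    n = rng.poisson(length_cm * CROSSOVER_RATE_PER_CM)
    breakpoints = np.sort(rng.random(n) * length_cm)
    phase = int(rng.integers(2))
    return breakpoints, phase


def _n_switches(meioses: int) -> int:
    """Number of telegraph processes labelling one homolog."""
    return 1 if meioses == 1 else meioses + 1


def _label(states: list[int], off: int, meioses: int, maternal: bool) -> int:
    """Founder-origin label of one homolog from its switch states.

    Layout for ``meioses >= 2`` starting at ``off``: topA, topB, choice,
    then ``meioses - 2`` outside switches.  With a single meiosis the parent
    *is* one member of the couple (ancestor A on the paternal path, B on the
    maternal path) and the label is that ancestor's haplotype directly.
    """
    if meioses == 1:
        return (_B1 if maternal else _A1) + states[off]
    for i in range(off + 3, off + meioses + 1):
        if states[i]:
            return _OUT_MAT if maternal else _OUT_PAT
    if states[off + 2]:
        return _B1 + states[off + 1]
    return _A1 + states[off]


def _sweep_labels(
    m: int, n: int, length_cm: float,
    pos: np.ndarray, procs: np.ndarray, states: list[int],
) -> tuple[list[float], list[int], list[int]]:
    """Piecewise-constant (paternal, maternal) labels along one chromosome.

    ``pos``/``procs`` are the pooled switch events sorted by position;
    ``states`` the initial switch states (mutated in place).  Returns
    interval start positions (first 0.0) and the two label sequences.
    """
    kp = _n_switches(m)
    lab_p = _label(states, 0, m, maternal=False)
    lab_m = _label(states, kp, n, maternal=True)
    bounds = [0.0]
    labs_p = [lab_p]
    labs_m = [lab_m]
    for x, k in zip(pos.tolist(), procs.tolist()):
        states[k] ^= 1
        if k < kp:
            new_p = _label(states, 0, m, maternal=False)
            if new_p == lab_p:
                continue
            lab_p = new_p
        else:
            new_m = _label(states, kp, n, maternal=True)
            if new_m == lab_m:
                continue
            lab_m = new_m
        bounds.append(x)
        labs_p.append(lab_p)
        labs_m.append(lab_m)
    return bounds, labs_p, labs_m


def _autozygous_intervals(
    bounds: list[float], labs_p: list[int], labs_m: list[int], length_cm: float
) -> list[tuple[float, float]]:
    """Maximal intervals where both homolog labels name the same founder haplotype."""
    out: list[tuple[float, float]] = []
    start = None
    for i, b in enumerate(bounds):
        az = labs_p[i] == labs_m[i]
        if az and start is None:
            start = b
        elif not az and start is not None:
            out.append((start, b))
            start = None
    if start is not None:
        out.append((start, length_cm))
    return out


class _LoopSimulator:
    """Batched per-event sampler of homolog label tracks for one loop config."""

    def __init__(self, m: int, n: int, chrom_lengths_cm: list[float]):
        self.m, self.n = m, n
        self.lengths = np.asarray(chrom_lengths_cm, dtype=float)
        self.k_total = _n_switches(m) + _n_switches(n)
        self.lam = self.k_total * self.lengths * CROSSOVER_RATE_PER_CM

    def sample_event(self, rng: np.random.Generator):
        """Yield (chrom_index, bounds, labs_p, labs_m) for each chromosome."""
        counts = rng.poisson(self.lam)
        total = int(counts.sum())
        u = rng.random(total)
        procs_all = rng.integers(0, self.k_total, total)
        states_all = rng.integers(0, 2, (len(self.lengths), self.k_total))
        offset = 0
        for ci, (length, cnt) in enumerate(zip(self.lengths, counts)):
            cnt = int(cnt)
            pos = u[offset : offset + cnt] * length
            procs = procs_all[offset : offset + cnt]
            offset += cnt
            order = np.argsort(pos, kind="stable")
            yield ci, *_sweep_labels(
                self.m, self.n, length, pos[order], procs[order],
                states_all[ci].tolist(),
            )


def simulate_loop_event(
    config: PedigreeLoopConfig, rng: np.random.Generator | None = None
) -> list[Segment]:
    """Simulate one offspring genome and return its true AS segments.

    Physical bounds of the returned segments use the toy 1 cM = 1 Mb scale
    (the simulator works purely in genetic distance).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    sim = _LoopSimulator(config.m, config.n, config.chrom_lengths_cm)
    segments = []
    for ci, bounds, lp, lm in sim.sample_event(rng):
        for a, b in _autozygous_intervals(bounds, lp, lm, sim.lengths[ci]):
            segments.append(
                Segment(
                    chrom=ci + 1,
                    start_cm=a,
                    end_cm=b,
                    start_bp=int(a * 1e6),
                    end_bp=int(b * 1e6) + 1,
                    kind=SegmentKind.AS,
                )
            )
    return segments


def longest_as_distribution(config: PedigreeLoopConfig) -> AsSimulationSummary:
    """Distribution of the per-event longest AS over ``n_events`` qualifying events.

    Trials are repeated until ``config.n_events`` events with at least one
    AS in the autosomal region have been observed; events without any AS do
    not enter the summary.
    """
    rng = np.random.default_rng(config.seed)
    sim = _LoopSimulator(config.m, config.n, config.chrom_lengths_cm)
    total_l = config.total_length_cm
    maxima: list[float] = []
    counts_sum = 0
    length_sum = 0.0
    n_segments = 0
    n_trials = 0
    while len(maxima) < config.n_events:
        n_trials += 1
        ev_max = 0.0
        ev_count = 0
        for ci, bounds, lp, lm in sim.sample_event(rng):
            for a, b in _autozygous_intervals(bounds, lp, lm, sim.lengths[ci]):
                size = b - a
                ev_count += 1
                length_sum += size
                if size > ev_max:
                    ev_max = size
        if ev_count:
            maxima.append(ev_max)
            counts_sum += ev_count
            n_segments += ev_count
    return AsSimulationSummary(
        mean_count=counts_sum / len(maxima),
        mean_length_cm=length_sum / n_segments,
        max_length_samples=np.asarray(maxima),
        autozygous_fraction=length_sum / (len(maxima) * total_l),
        n_events=len(maxima),
        n_trials=n_trials,
    )


def history_consistency(
    longest_rhs_cm: float,
    summary: AsSimulationSummary,
    alpha: float = 0.025,
) -> tuple[str, float]:
    """Compare an observed longest RHS against the simulated longest-AS range.

    Returns a verdict -- ``"consistent"``, ``"shorter-than-expected"`` or
    ``"longer-than-expected"`` relative to the central ``1 - 2*alpha``
    interval -- and the observation's empirical percentile (0-100).
    """
    if not 0 < alpha < 0.5:
        raise ValueError("alpha must be in (0, 0.5)")
    lo = summary.quantile(alpha)
    hi = summary.quantile(1.0 - alpha)
    percentile = 100.0 * float(np.mean(summary.max_length_samples <= longest_rhs_cm))
    if longest_rhs_cm < lo:
        return "shorter-than-expected", percentile
    if longest_rhs_cm > hi:
        return "longer-than-expected", percentile
    return "consistent", percentile
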