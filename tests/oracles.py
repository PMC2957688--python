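"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's sweep logic: the RHS oracle
tests every index sub-interval with prefix-count bookkeeping (O(n^2)), and
the normal-tail oracle evaluates the Gaussian survival function with
high-precision arithmetic.
"""

import numpy as np

from qhmap.core import Call, GenotypeTrack
from qhmap.rhs import RhsCallParams


def rhs_oracle(track: GenotypeTrack, params: RhsCallParams,
               start_cm=None, end_cm=None):
    """Enumerate every maximal HET-free sub-interval and apply the RHS rules.

    Returns sorted tuples (start_cm, end_cm, start_bp, end_bp, n_snps).
    """
    n = len(track)
    if n == 0:
        return []
    start_cm = float(track.pos_cm[0]) if start_cm is None else start_cm
    end_cm = float(track.pos_cm[-1]) if end_cm is None else end_cm
    het = track.calls == Call.HET
    hom = (track.calls == Call.HOM_A) | (track.calls == Call.HOM_B)
    het_prefix = np.concatenate(([0], np.cumsum(het)))
    hom_prefix = np.concatenate(([0], np.cumsum(hom)))
    hom_idx = np.flatnonzero(hom)
    found = []
    for i in range(n):
        if i > 0 and not het[i - 1]:
            continue  # not maximal on the left
        for j in range(i, n):
            if het_prefix[j + 1] - het_prefix[i] > 0:
                break  # contains a HET; longer j only worse
            if j < n - 1 and not het[j + 1]:
                continue  # extendable right
            n_hom = int(hom_prefix[j + 1] - hom_prefix[i])
            if n_hom < params.min_snps:
                continue
            lo = start_cm if i == 0 else float(track.pos_cm[i - 1])
            hi = end_cm if j == n - 1 else float(track.pos_cm[j + 1])
            if hi - lo <= params.cutoff_cm:
                continue
            k = int(np.searchsorted(hom_idx, i))
            first = int(hom_idx[k])
            last = int(hom_idx[int(np.searchsorted(hom_idx, j, side="right")) - 1])
            found.append(
                (lo, hi, int(track.pos_bp[first]) - 1, int(track.pos_bp[last]), n_hom)
            )
    return sorted(set(found))


def normal_upper_tail(u: float) -> float:
    """One-sided upper-tail normal probability at 40 decimal digits."""
    import mpmath

    mpmath.mp.dps = 40
    return float(0.5 * mpmath.erfc(mpmath.mpf(u) / mpmath.sqrt(2)))
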