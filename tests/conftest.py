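import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from qhmap.core import Call, GenotypeTrack

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_track(
    calls,
    pos_cm,
    chrom: int = 1,
    sample_id: str = "s1",
    pos_bp=None,
) -> GenotypeTrack:
    """Build a track from call codes and cM positions (bp = 1 per index)."""
    calls = np.asarray(calls, dtype=np.int8)
    pos_cm = np.asarray(pos_cm, dtype=float)
    if pos_bp is None:
        pos_bp = np.round(pos_cm * 1e6).astype(np.int64) + np.arange(len(calls)) + 1
    ids = np.array([f"rs{i}" for i in range(len(calls))], dtype=object)
    return GenotypeTrack(sample_id, chrom, ids, np.asarray(pos_bp), pos_cm, calls)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_track():
    # AB AA BB AA AB AA at 0.0 0.2 0.5 0.9 1.0 1.3 cM
    return make_track(
        [Call.HET, Call.HOM_A, Call.HOM_B, Call.HOM_A, Call.HET, Call.HOM_A],
        [0.0, 0.2, 0.5, 0.9, 1.0, 1.3],
    )
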