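from pathlib import Path

import numpy as np
import pytest

from crosskymo import simkit
from crosskymo.datatypes import PhaseSegment

REPO_ROOT = Path(__file__).resolve().parents[1]


@pytest.fixture(scope="session")
def demo_config_path() -> Path:
    return REPO_ROOT / "configs" / "demo.toml"


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_segments(rng: np.random.Generator, n: int, kind: str = "growth") -> list[PhaseSegment]:
    """Random phase segments for oracle comparisons."""
    t = 0.0
    out = []
    sign = 1.0 if kind == "growth" else -1.0
    for _ in range(n):
        d = rng.uniform(1.0, 60.0)
        v = sign * rng.uniform(0.2, 40.0)
        out.append(PhaseSegment(kind, t, t + d, v))
        t += d
    return out


@pytest.fixture(scope="session")
def event_library():
    """40 constructed crosslink events, 10 per class, with companion tracks."""
    spec = [
        {"label": lab}
        for lab in ("bind_unbind", "sliding", "tip_tracking", "bundling")
        for _ in range(10)
    ]
    params = simkit.DynamicsParams(duration=400.0, rng_seed=31)
    mt, _, _ = simkit.simulate_dynamic_instability(params)
    tracks, records = simkit.simulate_crosslink_events(spec, mt, frame_interval=2.0, rng_seed=57)
    actin = {t.track_id.rsplit("_", 1)[0]: t for t in tracks if t.channel == "actin"}
    anillin = {t.track_id.rsplit("_", 1)[0]: t for t in tracks if t.channel == "anillin"}
    return mt, actin, anillin, records
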