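import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import wiresignal as ws

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def model():
    return ws.DetectorModel()


@pytest.fixture
def pen():
    return ws.DEFAULT_PENUMBRA


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noiseless_config():
    """Simulator conditions where truth equals the default prediction model:
    single shared exponent, no noise, no penumbral jitter."""
    return ws.SimulationConfig(
        seed=99,
        noise_sd=0.0,
        penumbra_jitter=0.0,
        lambda_range=(1.4034, 1.4034),
        true_penumbra=ws.DEFAULT_PENUMBRA.fractions,
    )


def brute_force_segment(segment, model):
    """Independent O(n^2) double-sum evaluation of the per-wire response."""
    n = model.n_wires
    out = np.zeros(n)
    for a in range(n):
        total = 0.0
        for w in range(n):
            d = abs(a - w) * model.wire_pitch
            if d <= model.scatter_cutoff:
                total += segment.separations[w] * np.exp(-model.lateral_exponent * d)
        out[a] = segment.mu * model.k * total
    return out
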