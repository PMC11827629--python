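import numpy as np
import pytest

from aptakinetics import TraceSimConfig, simulate_ensemble


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_ensemble():
    """A modest HD1-like ensemble shared across tests (seeded)."""
    cfg = TraceSimConfig(seed=101, n_frames=3000)
    traces, truth = simulate_ensemble(cfg, 40)
    return cfg, traces, truth


@pytest.fixture(scope="session")
def noiseless_ensemble():
    """Noise-free ensemble for exact oracle-equivalence checks."""
    cfg = TraceSimConfig(
        seed=77, n_frames=2000, noise_sd=0.0, background_mean=50.0,
        p_acceptor_dark=0.0,
    )
    traces, truth = simulate_ensemble(cfg, 25)
    return cfg, traces, truth
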