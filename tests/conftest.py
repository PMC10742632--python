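import numpy as np
import pytest

from ferriscope.relaxometry import EchoSeries, default_echo_times


@pytest.fixture(scope="session")
def te10() -> np.ndarray:
    """Default acquisition grid: 10 echoes spaced 2.26 ms."""
    return default_echo_times()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def decay_series(t2star: float, s0: float = 100.0, offset: float = 0.0,
                 te=None, noise_sd: float | None = None,
                 rician_sigma: float = 0.0, seed: int = 0) -> EchoSeries:
    """Noiseless or Rician-noised mono-exponential decay on the default grid."""
    te = default_echo_times() if te is None else np.asarray(te, dtype=float)
    clean = s0 * np.exp(-te / t2star) + offset
    if rician_sigma > 0:
        g = np.random.default_rng(seed)
        signal = np.hypot(clean + g.normal(0, rician_sigma, te.size),
                          g.normal(0, rician_sigma, te.size))
    else:
        signal = clean
    return EchoSeries(te, signal, noise_sd=noise_sd)
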