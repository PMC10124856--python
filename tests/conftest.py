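import numpy as np
import pytest

from stdpnet.model_core import NetworkConfig, STDPWindow


@pytest.fixture(scope="session")
def fig2_window() -> STDPWindow:
    """The workhorse depression-dominated window (A_p=0.08, A_d=-0.0533)."""
    return STDPWindow(A_p=0.08, A_d=-0.0533, tau_p=0.025, tau_d=0.05, mu=1.0)


@pytest.fixture(scope="session")
def fig5_window() -> STDPWindow:
    return STDPWindow(A_p=0.08, A_d=-0.044, tau_p=0.022, tau_d=0.055, mu=1.0)


@pytest.fixture
def small_config() -> NetworkConfig:
    return NetworkConfig(N=10, w_max=0.04, tau_s=0.01, lambda0=0.15, seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def substochastic_weights(rng: np.random.Generator, N: int, w_scale: float = 0.04) -> np.ndarray:
    """Random non-negative weights with spectral radius safely below 1."""
    W = rng.uniform(0.0, w_scale, size=(N, N))
    np.fill_diagonal(W, 0.0)
    sr = np.max(np.abs(np.linalg.eigvals(W)))
    if sr >= 0.8:
        W *= 0.8 / sr
    return W
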