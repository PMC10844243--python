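import numpy as np
import pytest

import sentinet as sn


def random_psd(rng: np.random.Generator, n: int) -> np.ndarray:
    """A random symmetric positive semidefinite matrix."""
    m = rng.standard_normal((n, n))
    return m @ m.T


def random_stable_drift(rng: np.random.Generator, n: int) -> np.ndarray:
    """A random (generally non-symmetric) matrix with stable spectrum."""
    m = rng.standard_normal((n, n))
    shift = np.abs(np.linalg.eigvals(m).real).max() + 0.5
    return m + shift * np.eye(n)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240205)


@pytest.fixture(scope="session")
def ba20() -> sn.Network:
    """Small scale-free network used for simulation tests."""
    return sn.generate_ba(20, 2, np.random.default_rng(1))


@pytest.fixture(scope="session")
def two_node_scenarios() -> dict[int, sn.TwoNodeParams]:
    """The three two-node parameter scenarios (w=0.5, sigma1=0.1, L=100)."""
    return {
        1: sn.TwoNodeParams(r=-0.3, delta_r=1.0, sigma2=0.1),
        2: sn.TwoNodeParams(r=-0.3, delta_r=0.5, sigma2=0.1),
        3: sn.TwoNodeParams(r=-0.3, delta_r=1.0, sigma2=0.2),
    }


@pytest.fixture(scope="session")
def chain_scenarios() -> dict[int, sn.ChainParams]:
    """The three chain parameter scenarios (w=0.05, sigma2=0.1, L=100)."""
    return {
        1: sn.ChainParams(r=-0.3, sigma1=0.1),
        2: sn.ChainParams(r=-0.3, sigma1=0.7),
        3: sn.ChainParams(r=-0.3, sigma1=0.015),
    }
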