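import numpy as np
import pytest

from hopfnet import (
    ConnectomeMatrix,
    HopfParams,
    generate_synthetic_connectome,
    normalize_connectome,
)


@pytest.fixture(scope="session")
def small_connectome() -> ConnectomeMatrix:
    """Deterministic 6-region connectome, alpha-normalized."""
    rng = np.random.default_rng(42)
    w = rng.uniform(0.0, 1.0, (6, 6))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    return normalize_connectome(ConnectomeMatrix(w))


@pytest.fixture(scope="session")
def sc90() -> ConnectomeMatrix:
    """Synthetic 90-region connectome at generator defaults."""
    return generate_synthetic_connectome(90, seed=7)


@pytest.fixture()
def fast_params() -> HopfParams:
    """Short, cheap simulation parameters for unit tests."""
    return HopfParams(f_f=12.0, G=0.5, duration=20.0, burn_in=2.0, seed=3)
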