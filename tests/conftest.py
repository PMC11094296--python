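import numpy as np
import pytest

from mirpls import DataMatrix, SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_xy(rng):
    """Well-conditioned 30x5 regression problem with a mild nonlinearity."""
    X = rng.standard_normal((30, 5))
    w = rng.standard_normal(5)
    w /= np.linalg.norm(w)
    y = np.tanh(X @ w) + 0.05 * rng.standard_normal(30)
    return DataMatrix(X), y


@pytest.fixture
def collinear_xy():
    """Single-latent monotone data on a rank-3 collinear X (noiseless y)."""
    rng = np.random.default_rng(9)
    L = rng.standard_normal((100, 3))
    V = rng.standard_normal((8, 3))
    X = DataMatrix(L @ V.T)
    w = rng.standard_normal(8)
    w /= np.linalg.norm(w)
    t = X.values @ w
    y = np.tanh(t)
    return X, y, {"t_true": t, "w_true": w, "u_true": y.copy()}
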