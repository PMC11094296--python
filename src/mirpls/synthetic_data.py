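"""Synthetic collinear predictors with monotone nonlinear latent responses.

The generator builds a rank-deficient predictor matrix X = L V^T (plus
optional isotropic noise), projects it onto a hidden unit weight vector to
get the true input scores, pushes the scores through a monotone link and
adds response noise. This reproduces the two regimes the estimator
targets — strong multicollinearity and a monotone nonlinear inner
relation — with full knowledge of the ground truth.

A single integer seed is expanded into independent sub-streams for the
latent structure, the X-noise and the y-noise, so changing one noise
level never reshuffles the underlying structure.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError
from .linear_pls import DataMatrix

__all__ = ["SyntheticSpec", "generate", "fixture_cm_like", "fixture_nir_like"]

INNER_FUNCTIONS = ("linear", "tanh", "exponential", "cubic", "logistic")


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dataset; generation is pure in the spec."""

    n_samples: int
    n_variables: int
    latent_rank: int
    inner_function: str = "tanh"
    noise_sd_x: float = 0.0
    noise_sd_y: float = 0.0
    seed: int = 0
    true_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.latent_rank > min(self.n_samples, self.n_variables):
            raise ParameterError(
                f"latent_rank={self.latent_rank} exceeds min(N, M)="
                f"{min(self.n_samples, self.n_variables)}"
            )
        if self.inner_function not in INNER_FUNCTIONS:
            raise ParameterError(
                f"inner_function must be one of {INNER_FUNCTIONS}"
            )
        if self.noise_sd_x < 0 or self.noise_sd_y < 0:
            raise ParameterError("noise standard deviations must be >= 0")
        if self.true_weights is not None:
            w = np.asarray(self.true_weights, dtype=float).ravel()
            if w.size != self.n_variables:
                raise ParameterError("true_weights length must equal n_variables")
            norm = np.linalg.norm(w)
            if norm <= 0:
                raise ParameterError("true_weights must be nonzero")
            self.true_weights = w / norm


def _monotone_link(name: str, t: np.ndarray) -> np.ndarray:
    """Monotone links rescaled so their curvature spans the realised t range."""
    mu, sd = t.mean(), t.std()
    z = (t - mu) / sd if sd > 0 else t - mu
    if name == "linear":
        return z
    if name == "tanh":
        return np.tanh(2.0 * z)
    if name == "exponential":
        return np.exp(z) - 1.0
    if name == "cubic":
        return z + 0.5 * z**3
    if name == "logistic":
        return 1.0 / (1.0 + np.exp(-3.0 * z))
    raise ParameterError(f"unknown inner function '{name}'")


def generate(spec: SyntheticSpec) -> tuple[DataMatrix, np.ndarray, dict]:
    """Generate (X, y, truth) from a :class:`SyntheticSpec`.

    ``truth`` holds the true scores ``t_true``, the noiseless response
    ``u_true`` and the unit weight vector ``w_true``.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_struct, rng_xnoise, rng_ynoise = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )
    n, m, r = spec.n_samples, spec.n_variables, spec.latent_rank
    L = rng_struct.standard_normal((n, r))
    V = rng_struct.standard_normal((m, r))
    X = L @ V.T
    if spec.noise_sd_x > 0:
        X = X + spec.noise_sd_x * rng_xnoise.standard_normal((n, m))
    if spec.true_weights is not None:
        w = spec.true_weights
    else:
        w = rng_struct.standard_normal(m)
        w /= np.linalg.norm(w)
    t_true = X @ w
    u_true = _monotone_link(spec.inner_function, t_true)
    y = u_true.copy()
    if spec.noise_sd_y > 0:
        y = y + spec.noise_sd_y * rng_ynoise.standard_normal(n)
    return (
        DataMatrix(X),
        y,
        {"t_true": t_true, "u_true": u_true, "w_true": w},
    )


def fixture_cm_like(seed: int, n_responses: int = 1) -> tuple[DataMatrix, DataMatrix]:
    """A tiny dose-effect-shaped fixture: M=8 predictors, N=12 or 13 rows.

    One response column gives N=12; two or three responses give N=13.
    Each response column uses a different monotone link.
    """
    if n_responses not in (1, 2, 3):
        raise ParameterError("n_responses must be 1, 2 or 3")
    n = 12 if n_responses == 1 else 13
    links = ["tanh", "exponential", "logistic"][:n_responses]
    spec = SyntheticSpec(
        n_samples=n, n_variables=8, latent_rank=3, noise_sd_x=0.05, seed=seed
    )
    X, _, _ = generate(spec)
    cols = []
    for j, link in enumerate(links):
        # independent response stream per column, same X structure
        rng = np.random.default_rng(np.random.SeedSequence([seed, j]))
        w = rng.standard_normal(8)
        w /= np.linalg.norm(w)
        t = X.values @ w
        u = _monotone_link(link, t)
        cols.append(u + 0.1 * rng.standard_normal(n))
    Y = DataMatrix(
        np.column_stack(cols), column_names=[f"y{j + 1}" for j in range(n_responses)]
    )
    return X, Y


def fixture_nir_like(seed: int, size: str = "small") -> tuple[DataMatrix, np.ndarray]:
    """A spectra-shaped fixture with smooth, highly correlated columns.

    ``small`` mimics an 80 x 576 layout, ``large`` a 415 x 100 layout.
    Columns are smooth functions of the wavelength index driven by a few
    latent factors, so adjacent columns are strongly correlated.
    """
    if size == "small":
        n, m = 80, 576
    elif size == "large":
        n, m = 415, 100
    else:
        raise ParameterError("size must be 'small' or 'large'")
    ss = np.random.SeedSequence([seed, 7])
    rng_struct, rng_y = (np.random.default_rng(s) for s in ss.spawn(2))
    r = 4
    wave = np.linspace(0.0, 1.0, m)
    # smooth spectral profiles: broad Gaussian bumps
    centers = np.linspace(0.15, 0.85, r)
    profiles = np.exp(-((wave[None, :] - centers[:, None]) ** 2) / (2 * 0.12**2))
    scores = rng_struct.standard_normal((n, r))
    X = scores @ profiles
    w = rng_struct.standard_normal(m)
    w /= np.linalg.norm(w)
    t = X @ w
    y = _monotone_link("tanh", t) + 0.05 * rng_y.standard_normal(n)
    return DataMatrix(X), y
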