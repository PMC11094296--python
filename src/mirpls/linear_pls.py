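"""Linear PLS regression via NIPALS.

Used three ways across the package: as the baseline comparator, as the
nested regression inside the weight-updating strategy of the monotone
nonlinear model, and as the linear limit for equivalence tests.

Conventions
-----------
* Rows are samples, columns are variables.
* Autoscaling uses the sample standard deviation (``ddof=1``); constant
  columns are centered, given divisor 1 and flagged.
* Component extraction stops early (with a recorded warning) when the
  score norm collapses on rank-deficient data.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateDataError, ParameterError, ShapeError, ValidationError

__all__ = [
    "DataMatrix",
    "Scaler",
    "PLSModel",
    "autoscale",
    "fit_pls",
    "predict_pls",
    "pls_coefficient_vector",
    "nipals",
    "pls_regression_coefficients",
]

#: score-norm collapse threshold, relative to the Frobenius norm of X
_T_COLLAPSE = 1e-12


@dataclass
class DataMatrix:
    """A numeric matrix with row and column identifiers.

    Parameters
    ----------
    values : ndarray of shape (N, M)
        Finite numeric entries.
    column_names : list of str, optional
        Defaults to ``x1 .. xM``.
    row_ids : list of str, optional
        Defaults to ``r1 .. rN``.
    """

    values: np.ndarray
    column_names: list[str] | None = None
    row_ids: list[str] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim == 1:
            v = v.reshape(-1, 1)
        if v.ndim != 2:
            raise ValidationError(f"expected a 2-D matrix, got ndim={v.ndim}")
        if v.shape[0] < 1 or v.shape[1] < 1:
            raise ValidationError(f"matrix must be at least 1x1, got {v.shape}")
        bad = ~np.isfinite(v)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-finite value at row {i}, column {j} (value={v[i, j]!r})"
            )
        self.values = v
        if self.column_names is None:
            self.column_names = [f"x{j + 1}" for j in range(v.shape[1])]
        if self.row_ids is None:
            self.row_ids = [f"r{i + 1}" for i in range(v.shape[0])]
        if len(self.column_names) != v.shape[1]:
            raise ValidationError(
                f"{len(self.column_names)} column names for {v.shape[1]} columns"
            )
        if len(self.row_ids) != v.shape[0]:
            raise ValidationError(f"{len(self.row_ids)} row ids for {v.shape[0]} rows")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]


@dataclass
class Scaler:
    """Column-wise affine scaler: ``z = (x - means) / stds``.

    Constant columns are flagged in ``zero_variance_mask`` and get divisor 1,
    so they map to exactly zero and invert losslessly.
    """

    means: np.ndarray
    stds: np.ndarray
    zero_variance_mask: np.ndarray

    @classmethod
    def fit(cls, values: np.ndarray, ddof: int = 1) -> "Scaler":
        values = np.asarray(values, dtype=float)
        means = values.mean(axis=0)
        n = values.shape[0]
        if n - ddof > 0:
            stds = values.std(axis=0, ddof=ddof)
        else:
            stds = np.zeros(values.shape[1])
        mask = stds <= 0.0
        stds = np.where(mask, 1.0, stds)
        return cls(means=means, stds=stds, zero_variance_mask=mask)

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.means) / self.stds

    def inverse_transform(self, values: np.ndarray) -> np.ndarray:
        return np.asarray(values, dtype=float) * self.stds + self.means

    def to_dict(self) -> dict:
        return {
            "means": self.means.tolist(),
            "stds": self.stds.tolist(),
            "zero_variance_mask": self.zero_variance_mask.astype(bool).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Scaler":
        return cls(
            means=np.asarray(d["means"], dtype=float),
            stds=np.asarray(d["stds"], dtype=float),
            zero_variance_mask=np.asarray(d["zero_variance_mask"], dtype=bool),
        )


def autoscale(X: DataMatrix, ddof: int = 1) -> tuple[DataMatrix, Scaler]:
    """Scale each column to zero mean and (sample) unit variance.

    Returns the scaled matrix and the fitted :class:`Scaler`.
    """
    scaler = Scaler.fit(X.values, ddof=ddof)
    scaled = DataMatrix(
        scaler.transform(X.values),
        column_names=list(X.column_names),
        row_ids=list(X.row_ids),
    )
    return scaled, scaler


@dataclass
class PLSModel:
    """A fitted NIPALS PLS model on autoscaled data."""

    n_components: int
    weights: np.ndarray  # M x A
    x_loadings: np.ndarray  # M x A
    y_loadings: np.ndarray  # K x A
    inner_slopes: np.ndarray  # length A
    x_scaler: Scaler
    y_scaler: Scaler
    x_scores: np.ndarray  # N x A (training scores)
    y_scores: np.ndarray  # N x A
    column_names: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_x_vars(self) -> int:
        return self.weights.shape[0]

    @property
    def n_y_vars(self) -> int:
        return self.y_loadings.shape[0]


def nipals(
    X: np.ndarray,
    Y: np.ndarray,
    n_components: int,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> dict:
    """Raw NIPALS on already-prepared matrices (no scaling, no checks).

    For a single y column the inner u/t alternation is non-iterative.
    Returns a dict with W, P, Q, b, T, U and the list of warnings; the
    extraction truncates (recorded) when the score norm collapses.
    """
    X = np.array(X, dtype=float)
    Y = np.array(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y.reshape(-1, 1)
    n, m = X.shape
    k = Y.shape[1]
    W = np.zeros((m, n_components))
    P = np.zeros((m, n_components))
    Q = np.zeros((k, n_components))
    b = np.zeros(n_components)
    T = np.zeros((n, n_components))
    U = np.zeros((n, n_components))
    warnings: list[str] = []
    actual = 0
    for h in range(n_components):
        x_norm = np.linalg.norm(X)
        y_norm = np.linalg.norm(Y)
        if x_norm <= 0 or y_norm <= 0:
            warnings.append(f"component {h + 1}: residual matrix exhausted, truncating")
            break
        # start u at the y column with largest variance
        u = Y[:, np.argmax(np.sum(Y**2, axis=0))].copy()
        w = np.zeros(m)
        t = np.zeros(n)
        for _ in range(max_iter if k > 1 else 1):
            w = X.T @ u / (u @ u)
            wn = np.linalg.norm(w)
            if wn <= 0:
                break
            w /= wn
            t_new = X @ w
            q = Y.T @ t_new / (t_new @ t_new)
            qn = np.linalg.norm(q)
            if qn > 0:
                q /= qn
            u = Y @ q
            if np.linalg.norm(t_new - t) <= tol * max(np.linalg.norm(t_new), 1.0):
                t = t_new
                break
            t = t_new
        t_norm = np.linalg.norm(t)
        if t_norm < _T_COLLAPSE * max(x_norm, 1.0):
            warnings.append(f"component {h + 1}: score norm collapsed, truncating")
            break
        q = Y.T @ t / (t @ t)
        qn = np.linalg.norm(q)
        if qn > 0:
            q = q / qn
        u = Y @ q
        p = X.T @ t / (t @ t)
        bh = (t @ u) / (t @ t)
        W[:, h], P[:, h], Q[:, h], b[h] = w, p, q, bh
        T[:, h], U[:, h] = t, u
        X = X - np.outer(t, p)
        Y = Y - bh * np.outer(t, q)
        actual = h + 1
    return {
        "W": W[:, :actual],
        "P": P[:, :actual],
        "Q": Q[:, :actual],
        "b": b[:actual],
        "T": T[:, :actual],
        "U": U[:, :actual],
        "n_components": actual,
        "warnings": warnings,
    }


def fit_pls(X: DataMatrix, Y: DataMatrix, n_components: int) -> PLSModel:
    """Fit a linear PLS model with autoscaling of X and Y.

    ``n_components`` must lie in ``[1, min(N - 1, M)]``.
    """
    if X.n_rows < 2:
        raise ValidationError("need at least 2 samples to fit")
    if Y.n_rows != X.n_rows:
        raise ShapeError(f"X has {X.n_rows} rows but Y has {Y.n_rows}")
    a_max = min(X.n_rows - 1, X.n_cols)
    if not 1 <= n_components <= a_max:
        raise ParameterError(
            f"n_components={n_components} outside [1, {a_max}] for shape {X.values.shape}"
        )
    Xs, x_scaler = autoscale(X)
    Ys, y_scaler = autoscale(Y)
    if y_scaler.zero_variance_mask.all():
        raise DegenerateDataError("all response columns are constant")
    res = nipals(Xs.values, Ys.values, n_components)
    return PLSModel(
        n_components=res["n_components"],
        weights=res["W"],
        x_loadings=res["P"],
        y_loadings=res["Q"],
        inner_slopes=res["b"],
        x_scaler=x_scaler,
        y_scaler=y_scaler,
        x_scores=res["T"],
        y_scores=res["U"],
        column_names=list(X.column_names),
        warnings=res["warnings"],
    )


def predict_pls(model: PLSModel, Xnew: DataMatrix) -> DataMatrix:
    """Predict responses for new samples with a fitted model."""
    if Xnew.n_cols != model.n_x_vars:
        raise ShapeError(
            f"model was trained on {model.n_x_vars} variables, got {Xnew.n_cols}"
        )
    Xs = model.x_scaler.transform(Xnew.values)
    n = Xs.shape[0]
    yhat = np.zeros((n, model.n_y_vars))
    for h in range(model.n_components):
        t = Xs @ model.weights[:, h]
        yhat += model.inner_slopes[h] * np.outer(t, model.y_loadings[:, h])
        Xs = Xs - np.outer(t, model.x_loadings[:, h])
    return DataMatrix(
        model.y_scaler.inverse_transform(yhat),
        column_names=[f"y{j + 1}" for j in range(model.n_y_vars)],
        row_ids=list(Xnew.row_ids),
    )


def pls_coefficient_vector(model: PLSModel) -> np.ndarray:
    """Regression coefficients beta (scaled X -> scaled y), single response.

    ``y_scaled_hat = X_scaled @ beta``; unscale with the model's y scaler.
    """
    if model.n_y_vars != 1:
        raise ShapeError("coefficient vector is defined for a single response only")
    W, P = model.weights, model.x_loadings
    # R maps X_scaled directly to scores: T = X_scaled @ R
    R = W @ np.linalg.inv(P.T @ W)
    return R @ (model.inner_slopes * model.y_loadings[0, :])


def pls_regression_coefficients(
    X: np.ndarray, y: np.ndarray, n_components: int
) -> np.ndarray:
    """Coefficient vector of a raw (uncentered, unscaled) PLS1 regression.

    This is the nested regression used by the weight-updating strategy:
    the returned ``beta`` satisfies ``y ~= X @ beta`` with the requested
    number of latent variables (fewer if extraction truncates). Returns
    zeros when no component can be extracted (degenerate response).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).reshape(-1, 1)
    res = nipals(X, y, n_components)
    if res["n_components"] == 0:
        return np.zeros(X.shape[1])
    W, P = res["W"], res["P"]
    R = W @ np.linalg.inv(P.T @ W)
    return R @ (res["b"] * res["Q"][0, :])
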