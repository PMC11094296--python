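"""The MIR-PLS estimator.

Each latent component relates input scores t = X w to output scores u
through a monotone cubic spline instead of a straight line. Because the
inner model is monotone it is invertible, and that invertibility drives
the weight update: the discrepancy e = phi^{-1}(u) - t is regressed on the
current X residual with a nested two-component linear PLS, and the
resulting coefficient vector corrects w. The outer loop extracts
components with standard bilinear deflation.

The fit is fully deterministic: identical inputs give bit-identical models.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    DegenerateDataError,
    ParameterError,
    ShapeError,
    ValidationError,
)
from .linear_pls import DataMatrix, Scaler, autoscale, pls_regression_coefficients
from .monotone_spline import (
    MonotoneSpline,
    eval_spline,
    fit_monotone_spline,
    invert_spline,
)

__all__ = [
    "LatentComponent",
    "FitTrace",
    "MIRPLSModel",
    "update_weights",
    "fit_mirpls",
    "predict_mirpls",
    "fit_mirpls_multiresponse",
]

logger = logging.getLogger(__name__)

DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 30
NESTED_PLS_COMPONENTS = 2


@dataclass
class LatentComponent:
    """One extracted factor: weights, loadings, inner spline and scores."""

    w: np.ndarray  # input weight, unit norm, length M
    p: np.ndarray  # input loading, length M
    q: float  # output loading (+-1 for a single response)
    inner_model: MonotoneSpline
    t_train: np.ndarray
    u_train: np.ndarray


@dataclass
class IterationRecord:
    component: int
    iteration: int
    weight_correction_norm: float
    score_change: float
    error_norm: float


@dataclass
class ComponentRecord:
    component: int
    iterations_used: int
    converged: bool
    final_score_change: float
    n_knots_used: int
    notes: list[str] = field(default_factory=list)


@dataclass
class FitTrace:
    """Per-iteration and per-component convergence bookkeeping."""

    iterations: list[IterationRecord] = field(default_factory=list)
    components: list[ComponentRecord] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "components": [
                {
                    "component": c.component,
                    "iterations_used": c.iterations_used,
                    "converged": c.converged,
                    "final_score_change": c.final_score_change,
                    "n_knots_used": c.n_knots_used,
                    "notes": list(c.notes),
                }
                for c in self.components
            ]
        }


@dataclass
class MIRPLSModel:
    """Ordered latent components plus the training scalers and fit trace."""

    components: list[LatentComponent]
    x_scaler: Scaler
    y_scaler: Scaler
    n_knots: int
    tol: float
    max_iter: int
    trace: FitTrace
    column_names: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def n_x_vars(self) -> int:
        return int(self.components[0].w.size)


def update_weights(
    X_h: np.ndarray, w: np.ndarray, t: np.ndarray, t_hat: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Weight correction from the invertibility discrepancy e = t_hat - t.

    e is regressed on X_h with a nested linear PLS using at most
    ``NESTED_PLS_COMPONENTS`` latent variables; the coefficient vector is
    the correction, and ``w_new = (w + delta_w)`` renormalised. A
    degenerate (essentially zero) e short-circuits to ``delta_w = 0``.
    """
    X_h = np.asarray(X_h, dtype=float)
    w = np.asarray(w, dtype=float)
    e = np.asarray(t_hat, dtype=float) - np.asarray(t, dtype=float)
    scale = max(1.0, float(np.linalg.norm(t)))
    if np.linalg.norm(e) <= 1e-14 * scale:
        return w.copy(), np.zeros_like(w)
    delta_w = pls_regression_coefficients(X_h, e, NESTED_PLS_COMPONENTS)
    w_new = w + delta_w
    norm = np.linalg.norm(w_new)
    if norm <= 0:
        logger.warning("weight update collapsed to zero; keeping previous weights")
        return w.copy(), np.zeros_like(w)
    return w_new / norm, delta_w


def _as_column(y: DataMatrix | np.ndarray) -> np.ndarray:
    v = y.values if isinstance(y, DataMatrix) else np.asarray(y, dtype=float)
    if v.ndim == 1:
        v = v.reshape(-1, 1)
    if v.shape[1] != 1:
        raise ShapeError(f"expected a single response column, got {v.shape[1]}")
    return v


def fit_mirpls(
    X: DataMatrix,
    y: DataMatrix | np.ndarray,
    n_components: int,
    n_knots: int,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    derivative_floor: float = 0.0,
) -> MIRPLSModel:
    """Fit MIR-PLS for a single response.

    Per component: initialise u from the y residual, w from u, t = X w;
    then iterate { fit monotone spline u ~ phi(t); update q and u; invert
    to get t_hat; correct w by nested PLS on t_hat - t; recompute t } until
    the relative score change drops below ``tol`` or ``max_iter`` passes;
    finally refit the spline on the converged scores, compute the input
    loading and deflate both residual streams.
    """
    if not isinstance(X, DataMatrix):
        X = DataMatrix(np.asarray(X, dtype=float))
    yv = _as_column(y)
    if yv.shape[0] != X.n_rows:
        raise ShapeError(f"X has {X.n_rows} rows but y has {yv.shape[0]}")
    if X.n_rows < 4:
        raise ValidationError("need at least 4 samples to fit the cubic inner model")
    a_max = min(X.n_rows - 1, X.n_cols)
    if not 1 <= n_components <= a_max:
        raise ParameterError(
            f"n_components={n_components} outside [1, {a_max}] for shape {X.values.shape}"
        )
    if n_knots < 0:
        raise ParameterError("n_knots must be >= 0")
    if yv.std(ddof=1) <= 0:
        raise DegenerateDataError("response is constant")

    Xs, x_scaler = autoscale(X)
    y_scaler = Scaler.fit(yv)
    Xh = Xs.values.copy()
    yh = y_scaler.transform(yv)[:, 0]

    trace = FitTrace()
    components: list[LatentComponent] = []
    for h in range(n_components):
        notes: list[str] = []
        x_norm = np.linalg.norm(Xh)
        if np.linalg.norm(yh) <= 1e-12 or x_norm <= 1e-12:
            notes.append("residual exhausted; stopped early")
            logger.info("component %d: residual exhausted, stopping", h + 1)
            break
        u = yh.copy()
        w = Xh.T @ u / (u @ u)
        wn = np.linalg.norm(w)
        if wn <= 1e-12 * max(1.0, x_norm):
            logger.info("component %d: weight vector collapsed, stopping", h + 1)
            break
        w = w / wn
        t = Xh @ w
        if np.linalg.norm(t) < 1e-12 * max(1.0, x_norm):
            logger.info("component %d: score norm collapsed, stopping", h + 1)
            break

        spline: MonotoneSpline | None = None
        q = 1.0
        converged = False
        score_change = np.inf
        iters = 0
        for i in range(max_iter):
            iters = i + 1
            spline = fit_monotone_spline(
                t, u, n_knots, derivative_floor=derivative_floor
            )
            u_hat = spline.fitted_values
            qn = float(u_hat @ yh)
            q = 1.0 if qn >= 0 else -1.0
            u = yh * q
            t_hat = invert_spline(spline, u)
            w_new, delta_w = update_weights(Xh, w, t, t_hat)
            t_new = Xh @ w_new
            t_norm = np.linalg.norm(t)
            score_change = (
                float(np.linalg.norm(t_new - t) / t_norm) if t_norm > 0 else 0.0
            )
            trace.iterations.append(
                IterationRecord(
                    component=h + 1,
                    iteration=iters,
                    weight_correction_norm=float(np.linalg.norm(delta_w)),
                    score_change=score_change,
                    error_norm=float(np.linalg.norm(t_hat - t)),
                )
            )
            w, t = w_new, t_new
            if score_change < tol:
                converged = True
                break

        # refit the inner model on the converged scores
        spline = fit_monotone_spline(t, u, n_knots, derivative_floor=derivative_floor)
        if spline.knots.n_interior < n_knots:
            notes.append(
                f"knots reduced to {spline.knots.n_interior} (requested {n_knots})"
            )
        u_hat_new = spline.fitted_values
        p = Xh.T @ t / (t @ t)

        components.append(
            LatentComponent(
                w=w.copy(),
                p=p,
                q=float(q),
                inner_model=spline,
                t_train=t.copy(),
                u_train=u.copy(),
            )
        )
        trace.components.append(
            ComponentRecord(
                component=h + 1,
                iterations_used=iters,
                converged=converged,
                final_score_change=score_change,
                n_knots_used=spline.knots.n_interior,
                notes=notes,
            )
        )
        Xh = Xh - np.outer(t, p)
        yh = yh - u_hat_new * q

    if not components:
        raise DegenerateDataError("no latent component could be extracted")
    return MIRPLSModel(
        components=components,
        x_scaler=x_scaler,
        y_scaler=y_scaler,
        n_knots=n_knots,
        tol=tol,
        max_iter=max_iter,
        trace=trace,
        column_names=list(X.column_names),
    )


def predict_mirpls(
    model: MIRPLSModel,
    Xnew: DataMatrix | np.ndarray,
    n_components: int | None = None,
) -> np.ndarray:
    """Predict a new sample set by mirroring the training-side deflation.

    Scale with the training x scaler; for each component project onto w,
    pass the scores through the component's spline, accumulate the scaled
    prediction through q, and deflate with the training loading p; finally
    unscale with the training y scaler. ``n_components`` truncates the
    model to its first components (they are extracted sequentially, so the
    truncation equals a model fitted with a smaller component count).
    """
    if not isinstance(Xnew, DataMatrix):
        Xnew = DataMatrix(np.asarray(Xnew, dtype=float))
    if Xnew.n_cols != model.n_x_vars:
        raise ShapeError(
            f"model was trained on {model.n_x_vars} variables, got {Xnew.n_cols}"
        )
    if n_components is None:
        n_components = model.n_components
    Xs = model.x_scaler.transform(Xnew.values)
    yhat = np.zeros(Xs.shape[0])
    for comp in model.components[:n_components]:
        t = Xs @ comp.w
        u_hat = eval_spline(comp.inner_model, t)
        yhat += u_hat * comp.q
        Xs = Xs - np.outer(t, comp.p)
    return model.y_scaler.inverse_transform(yhat.reshape(-1, 1))[:, 0]


def fit_mirpls_multiresponse(
    X: DataMatrix,
    Y: DataMatrix,
    n_components: int | list[int],
    n_knots: int | list[int],
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> list[MIRPLSModel]:
    """One independent single-response model per column of Y.

    ``n_components`` / ``n_knots`` may be scalars (shared) or per-column
    lists. Errors from individual fits are re-raised labelled by column.
    """
    if Y.n_cols < 2:
        raise ShapeError("multiresponse fitting expects at least 2 response columns")
    k = Y.n_cols
    a_list = n_components if isinstance(n_components, (list, tuple)) else [n_components] * k
    j_list = n_knots if isinstance(n_knots, (list, tuple)) else [n_knots] * k
    if len(a_list) != k or len(j_list) != k:
        raise ParameterError("per-column hyperparameter lists must match Y columns")
    models = []
    for j in range(k):
        ycol = DataMatrix(
            Y.values[:, [j]], column_names=[Y.column_names[j]], row_ids=list(Y.row_ids)
        )
        try:
            models.append(
                fit_mirpls(X, ycol, a_list[j], j_list[j], tol=tol, max_iter=max_iter)
            )
        except Exception as exc:
            raise type(exc)(f"response column '{Y.column_names[j]}': {exc}") from exc
    return models
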