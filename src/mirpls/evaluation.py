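"""Metrics, cross-validated grid search and paired model comparison.

RMSE, MAPE and R^2 follow the printed definitions: MAPE is in percent,
R^2 compares against the mean predictor and is deliberately never clamped
(negative values are meaningful and reported as-is). Grid search selects
the (components, knots) pair with minimal RMSECV, breaking ties toward
the more parsimonious model (smaller component count, then fewer knots).
The Wilcoxon signed-rank comparison is exact (full sign enumeration via a
rank-sum distribution recursion) up to n = 25 pairs and switches to the
tie-corrected normal approximation above.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ParameterError, ShapeError, ValidationError
from .linear_pls import DataMatrix

__all__ = [
    "MetricsReport",
    "CVResult",
    "ComparisonResult",
    "compute_metrics",
    "k_improvement",
    "cross_validate",
    "wilcoxon_signed_rank",
    "make_folds",
    "mirpls_fit_predict",
    "mirpls_fit_predict_multi",
    "pls_fit_predict",
]

logger = logging.getLogger(__name__)

EXACT_WILCOXON_MAX_N = 25


@dataclass
class MetricsReport:
    """RMSE / MAPE / R^2 for one prediction vector."""

    rmse: float
    mape: float | None
    r2: float | None
    n: int
    mape_defined: bool = True
    r2_defined: bool = True


def compute_metrics(y: np.ndarray, yhat: np.ndarray) -> MetricsReport:
    """Root-mean-square error, mean absolute percentage error and R^2.

    MAPE is undefined (flagged) when any observation is zero; R^2 is
    undefined (flagged) when the observations are constant.
    """
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size:
        raise ShapeError(f"length mismatch: {y.size} vs {yhat.size}")
    if y.size < 2:
        raise ValidationError("need at least 2 observations")
    if not (np.isfinite(y).all() and np.isfinite(yhat).all()):
        raise ValidationError("non-finite values in metric inputs")
    resid = y - yhat
    rmse = float(np.sqrt(resid @ resid / y.size))
    if np.any(y == 0):
        mape, mape_defined = None, False
    else:
        mape = float(np.mean(np.abs(resid / y)) * 100.0)
        mape_defined = True
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        r2, r2_defined = None, False
    else:
        r2 = float(1.0 - np.sum(resid**2) / ss_tot)
        r2_defined = True
    return MetricsReport(
        rmse=rmse, mape=mape, r2=r2, n=y.size,
        mape_defined=mape_defined, r2_defined=r2_defined,
    )


def k_improvement(rmse_mirpls: float, rmse_other: float) -> float:
    """Relative RMSE improvement in percent: (1 - a/b) * 100."""
    if rmse_other <= 0:
        raise ParameterError("reference RMSE must be positive")
    return (1.0 - rmse_mirpls / rmse_other) * 100.0


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class GridPoint:
    n_components: int
    n_knots: int
    rmsecv: float | None
    mapecv: float | None
    feasible: bool = True


@dataclass
class CVResult:
    grid: list[GridPoint]
    best_n_components: int
    best_n_knots: int
    scheme: str
    fold_assignments: np.ndarray
    seed: int | None

    @property
    def best_rmsecv(self) -> float:
        for g in self.grid:
            if (
                g.feasible
                and g.n_components == self.best_n_components
                and g.n_knots == self.best_n_knots
            ):
                return g.rmsecv
        raise ValueError("selected grid point missing")


def make_folds(
    n: int,
    scheme: str = "loo",
    k: int = 5,
    seed: int | None = None,
    fold_indices: np.ndarray | None = None,
) -> np.ndarray:
    """Fold assignment vector of length n (values 0..n_folds-1)."""
    if fold_indices is not None:
        fa = np.asarray(fold_indices, dtype=int)
        if fa.size != n:
            raise ShapeError(f"fold index vector length {fa.size} != {n}")
        return fa
    if scheme == "loo":
        return np.arange(n)
    if scheme == "kfold":
        if not 2 <= k <= n:
            raise ParameterError(f"k={k} must be in [2, {n}]")
        rng = np.random.default_rng(seed)
        fa = np.arange(n) % k  # balanced: sizes differ by at most one
        rng.shuffle(fa)
        return fa
    raise ParameterError(f"unknown CV scheme '{scheme}'")


def cross_validate(
    X: DataMatrix,
    y: np.ndarray,
    fit_predict_fn,
    component_grid,
    knot_grid,
    scheme: str = "loo",
    k: int = 5,
    seed: int | None = None,
    fold_indices: np.ndarray | None = None,
    fit_predict_multi_fn=None,
) -> CVResult:
    """Grid search over (components, knots) by pooled out-of-fold RMSE.

    ``fit_predict_fn(X_train, y_train, X_test, n_components, n_knots)``
    must return predictions for the held-out rows; any per-fold scaling
    happens inside the fit function, so no information leaks across folds.
    Grid points whose component count exceeds the feasible bound of some
    training fold are marked infeasible and skipped. The winner attains
    the minimum RMSECV; exact ties resolve to smaller component count,
    then fewer knots.

    Sequentially extracted latent-variable models let one fit at the
    largest component count serve every smaller count; pass
    ``fit_predict_multi_fn(X_train, y_train, X_test, component_list,
    n_knots)`` returning ``{a: predictions}`` to exploit that (one fit per
    fold and knot count instead of one per grid point).
    """
    if not isinstance(X, DataMatrix):
        X = DataMatrix(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if y.size != X.n_rows:
        raise ShapeError(f"X has {X.n_rows} rows but y has {y.size}")
    component_grid = sorted(set(int(a) for a in component_grid))
    knot_grid = sorted(set(int(j) for j in knot_grid))
    if not component_grid or not knot_grid:
        raise ParameterError("grids must be non-empty")
    n = X.n_rows
    fa = make_folds(n, scheme=scheme, k=k, seed=seed, fold_indices=fold_indices)
    folds = [np.where(fa == f)[0] for f in np.unique(fa)]
    min_train = min(n - f.size for f in folds)
    a_bound = min(min_train - 1, X.n_cols)
    a_feasible = [a for a in component_grid if a <= a_bound]

    def fold_views(test_idx):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        Xtr = DataMatrix(
            X.values[train_idx],
            column_names=list(X.column_names),
            row_ids=[X.row_ids[i] for i in train_idx],
        )
        return Xtr, y[train_idx], X.values[test_idx]

    # out-of-fold predictions per feasible (a, j); None marks a failed fit
    yhat_by_aj: dict[tuple[int, int], np.ndarray | None] = {}
    if fit_predict_multi_fn is not None and a_feasible:
        for j in knot_grid:
            preds = {a: np.empty(n) for a in a_feasible}
            for test_idx in folds:
                Xtr, ytr, Xte = fold_views(test_idx)
                try:
                    out = fit_predict_multi_fn(Xtr, ytr, Xte, a_feasible, j)
                except Exception as exc:
                    logger.info("knot count J=%d failed: %s", j, exc)
                    preds = None
                    break
                for a in a_feasible:
                    preds[a][test_idx] = out[a]
            for a in a_feasible:
                yhat_by_aj[(a, j)] = None if preds is None else preds[a]
    else:
        for a in a_feasible:
            for j in knot_grid:
                yhat = np.empty(n)
                for test_idx in folds:
                    Xtr, ytr, Xte = fold_views(test_idx)
                    try:
                        yhat[test_idx] = fit_predict_fn(Xtr, ytr, Xte, a, j)
                    except Exception as exc:  # infeasible fold (rank collapse..)
                        logger.info("grid point (A=%d, J=%d) failed: %s", a, j, exc)
                        yhat = None
                        break
                yhat_by_aj[(a, j)] = yhat

    grid: list[GridPoint] = []
    best = None
    for a in component_grid:
        for j in knot_grid:
            yhat = yhat_by_aj.get((a, j))
            if a > a_bound or yhat is None:
                if a > a_bound:
                    logger.info("grid point (A=%d, J=%d) infeasible, skipped", a, j)
                grid.append(GridPoint(a, j, None, None, feasible=False))
                continue
            m = compute_metrics(y, yhat)
            gp = GridPoint(a, j, m.rmse, m.mape if m.mape_defined else None)
            grid.append(gp)
            key = (gp.rmsecv, a, j)
            if best is None or key < best[0]:
                best = (key, gp)
    if best is None:
        raise ParameterError("no feasible grid point")
    gp = best[1]
    return CVResult(
        grid=grid,
        best_n_components=gp.n_components,
        best_n_knots=gp.n_knots,
        scheme=scheme if fold_indices is None else "custom",
        fold_assignments=fa,
        seed=seed,
    )


def mirpls_fit_predict(Xtr, ytr, Xte, n_components, n_knots):
    """Adapter for :func:`cross_validate` fitting a MIR-PLS model."""
    from .mirpls_core import fit_mirpls, predict_mirpls

    model = fit_mirpls(Xtr, ytr, n_components, n_knots)
    return predict_mirpls(model, Xte)


def mirpls_fit_predict_multi(Xtr, ytr, Xte, component_list, n_knots):
    """Multi-count adapter: one fit at max(component_list), truncated
    predictions for every requested count (components are sequential)."""
    from .mirpls_core import fit_mirpls, predict_mirpls

    model = fit_mirpls(Xtr, ytr, max(component_list), n_knots)
    return {
        a: predict_mirpls(model, Xte, n_components=min(a, model.n_components))
        for a in component_list
    }


def pls_fit_predict(Xtr, ytr, Xte, n_components, n_knots=None):
    """Adapter for :func:`cross_validate` fitting linear PLS (knots ignored)."""
    from .linear_pls import fit_pls, predict_pls

    ytr = np.asarray(ytr, dtype=float).reshape(-1, 1)
    model = fit_pls(Xtr, DataMatrix(ytr), n_components)
    if not isinstance(Xte, DataMatrix):
        Xte = DataMatrix(np.asarray(Xte, dtype=float))
    return predict_pls(model, Xte).values[:, 0]


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank comparison


@dataclass
class ComparisonResult:
    """Paired comparison of two models' prediction errors."""

    k_improvement: float
    wilcoxon_statistic: float
    p_value: float
    n_pairs: int
    method: str = "exact"
    degenerate: bool = False
    insufficient_pairs: bool = False
    notes: list[str] = field(default_factory=list)


def _signed_rank_distribution(double_ranks: np.ndarray) -> np.ndarray:
    """Counts over 2^n sign assignments of the positive-rank sum.

    Ranks arrive doubled so midranks from ties are integers. Entry s of
    the returned vector counts assignments with doubled rank-sum s.
    """
    total = int(double_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in double_ranks.astype(int):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(
    errors_a: np.ndarray, errors_b: np.ndarray
) -> ComparisonResult:
    """Two-sided Wilcoxon signed-rank test on paired absolute errors.

    Differences of |errors_a| and |errors_b| are ranked by magnitude with
    midranks for ties; zero differences are dropped (classical Wilcoxon
    treatment). The statistic is the positive-rank sum W+. Up to 25
    effective pairs the p-value comes from the exact null distribution
    over all sign assignments; beyond that a tie-corrected normal
    approximation is used. The k-improvement of the result compares the
    two error vectors' RMS magnitudes.
    """
    a = np.abs(np.asarray(errors_a, dtype=float).ravel())
    b = np.abs(np.asarray(errors_b, dtype=float).ravel())
    if a.size != b.size:
        raise ShapeError(f"length mismatch: {a.size} vs {b.size}")
    rms_a = float(np.sqrt(np.mean(a**2)))
    rms_b = float(np.sqrt(np.mean(b**2)))
    k_imp = k_improvement(rms_a, rms_b) if rms_b > 0 else 0.0

    d = a - b
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return ComparisonResult(
            k_improvement=k_imp, wilcoxon_statistic=0.0, p_value=1.0,
            n_pairs=0, method="degenerate", degenerate=True,
            notes=["all paired differences are zero"],
        )
    # midranks of |d|
    order = np.argsort(np.abs(d), kind="stable")
    ad = np.abs(d)[order]
    ranks = np.empty(n)
    i = 0
    pos = 1
    while i < n:
        j = i
        while j + 1 < n and ad[j + 1] == ad[i]:
            j += 1
        ranks[i : j + 1] = 0.5 * (pos + (pos + (j - i)))
        pos += j - i + 1
        i = j + 1
    full_ranks = np.empty(n)
    full_ranks[order] = ranks
    w_plus = float(full_ranks[d > 0].sum())

    if n < 5:
        return ComparisonResult(
            k_improvement=k_imp, wilcoxon_statistic=w_plus, p_value=1.0,
            n_pairs=n, method="insufficient", insufficient_pairs=True,
            notes=[f"only {n} nonzero pairs; test not run"],
        )

    if n <= EXACT_WILCOXON_MAX_N:
        dr = np.rint(2.0 * full_ranks).astype(int)
        counts = _signed_rank_distribution(dr)
        total = counts.sum()
        wd = int(round(2.0 * w_plus))
        p_low = counts[: wd + 1].sum() / total
        p_high = counts[wd:].sum() / total
        p = min(1.0, 2.0 * min(p_low, p_high))
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ad, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        from scipy.stats import norm

        z = (w_plus - mean) / np.sqrt(var)
        p = float(2.0 * norm.sf(abs(z)))
        p = min(1.0, p)
        method = "normal-approx"
    return ComparisonResult(
        k_improvement=k_imp, wilcoxon_statistic=w_plus, p_value=p,
        n_pairs=n, method=method,
    )
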