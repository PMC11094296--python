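"""Monotone piecewise-cubic inner model: fit, evaluate, invert.

The inner relation between input scores t and output scores u is modelled
by a C^2 piecewise-cubic spline constrained to be monotone, with interior
knots placed at empirical quantiles so every polynomial piece covers an
(almost) equal share of the sorted data.

Fitting solves the inequality-constrained least-squares problem

    min ||u - g(t)||^2   s.t.   g'(x) >= derivative_floor on a dense grid

over the cubic spline space on the chosen knots, parameterised by B-spline
coefficients. The solver is the deterministic Lawson-Hanson LSI -> LDP ->
NNLS transformation, so the result is the exact constrained optimum (up to
NNLS termination), not a heuristic. Decreasing relations are handled by
mirroring the abscissa: a non-decreasing spline g is fitted to
(direction * t, u) with direction = sign of the sample correlation.

Monotone + continuous means invertible: inversion uses bracketed bisection
on the evaluator, returning the midpoint of the preimage interval on flat
stretches, and inverting the linear extrapolation outside the fitted range.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.optimize import nnls

from .exceptions import DegenerateDataError, KnotPlacementError, ValidationError

__all__ = [
    "KnotVector",
    "MonotoneSpline",
    "place_knots",
    "fit_monotone_spline",
    "eval_spline",
    "invert_spline",
]

logger = logging.getLogger(__name__)

#: grid size for the derivative monotonicity certificate
N_CONSTRAINT_GRID = 512

#: constraint grid used for fitting: dense enough that the value-level
#: monotonicity error between adjacent grid points (which scales with the
#: squared spacing) sits below the 1e-9 evaluation and inversion contracts
N_FIT_CONSTRAINT_GRID = 4096

#: between grid points the quadratic derivative may dip below the floor;
#: cutting planes remove any dip whose *value*-level monotonicity cost
#: exceeds this, so evaluation stays monotone at the 1e-9 level while the
#: fit remains the dense-grid constrained optimum
_VALUE_CUT_TOL = 2.5e-10

#: bisection iterations for inversion (interval shrinks below double ulp)
_BISECT_ITERS = 52


@dataclass
class KnotVector:
    """Interior knots plus the boundary of the fitted abscissa range."""

    interior_knots: np.ndarray
    boundary: tuple[float, float]

    def __post_init__(self) -> None:
        k = np.asarray(self.interior_knots, dtype=float)
        lo, hi = self.boundary
        if not lo < hi:
            raise ValidationError(f"degenerate boundary ({lo}, {hi})")
        if k.size and (np.any(np.diff(k) < 0) or k[0] <= lo or k[-1] >= hi):
            raise ValidationError("interior knots must lie strictly inside the boundary")
        self.interior_knots = k

    @property
    def n_interior(self) -> int:
        return int(self.interior_knots.size)


def place_knots(t: np.ndarray, n_knots: int) -> KnotVector:
    """Place ``n_knots`` interior knots at the empirical quantiles i/(J+1).

    Sorting the data and cutting it into J+1 equal-count segments puts
    knot i at the linear-interpolation quantile i/(J+1), so segment sizes
    differ by at most one data point. Duplicate or boundary-coincident
    quantiles raise :class:`KnotPlacementError` so the caller can retry
    with a smaller J.
    """
    t = np.asarray(t, dtype=float).ravel()
    if n_knots < 0:
        raise ValidationError("number of knots must be >= 0")
    distinct = np.unique(t)
    if distinct.size < n_knots + 2:
        raise KnotPlacementError(
            f"{distinct.size} distinct values cannot support {n_knots} interior knots"
        )
    lo, hi = float(t.min()), float(t.max())
    if n_knots == 0:
        return KnotVector(np.empty(0), (lo, hi))
    q = np.arange(1, n_knots + 1) / (n_knots + 1)
    knots = np.quantile(t, q)  # linear interpolation convention
    knots = np.unique(knots)
    knots = knots[(knots > lo) & (knots < hi)]
    if knots.size < n_knots:
        raise KnotPlacementError(
            f"quantile placement collapsed {n_knots} knots to {knots.size}"
        )
    return KnotVector(knots, (lo, hi))


def _full_knots(knots: KnotVector) -> np.ndarray:
    lo, hi = knots.boundary
    return np.concatenate([[lo] * 4, knots.interior_knots, [hi] * 4])


def _derivative_operator(t4: np.ndarray) -> np.ndarray:
    """Matrix L with ``BSpline(t4, c, 3).derivative() == BSpline(t3, L @ c, 2)``."""
    p = t4.size - 4
    L = np.zeros((p - 1, p))
    for i in range(p - 1):
        dt = t4[i + 4] - t4[i + 1]
        L[i, i + 1] = 3.0 / dt
        L[i, i] = -3.0 / dt
    return L


def _design(x: np.ndarray, t4: np.ndarray, degree: int) -> np.ndarray:
    x = np.clip(x, t4[0], t4[-1])
    return BSpline.design_matrix(x, t4, degree, extrapolate=False).toarray()


def _derivative_violations(
    t4: np.ndarray, dcoef: np.ndarray, floor: float, value_tol: float
) -> tuple[np.ndarray, np.ndarray]:
    """Interior minima of the quadratic derivative spline lying below floor.

    The derivative of the cubic fit is piecewise quadratic; each piece's
    minimum is at an endpoint or at its interior vertex. Endpoints are
    covered by the constraint grid, so only vertices matter. Each piece's
    quadratic is recovered from three evaluations (vectorised over pieces).

    A dip of depth d and curvature c2 spans width 2*sqrt(d/c2) and costs
    the *value* of the spline at most ~d^1.5 / sqrt(c2) of monotonicity;
    only dips whose value cost exceeds ``value_tol`` are reported, which
    keeps the fit at the dense-grid optimum while bounding non-monotone
    wiggles between grid points at the value level the evaluation and
    inversion contracts need. Returns (locations, dip values).
    """
    breaks = np.unique(t4)
    a = breaks[:-1]
    b = breaks[1:]
    hlen = b - a
    mid = 0.5 * (a + b)
    d = BSpline(t4[1:-1], dcoef, 2, extrapolate=False)
    vals = d(np.concatenate([a, mid, np.minimum(b, t4[-1])]))
    P = a.size
    fa, fm, fb = vals[:P], vals[P : 2 * P], vals[2 * P :]
    c2 = (2 * fa - 4 * fm + 2 * fb) / hlen**2
    c1 = (-3 * fa + 4 * fm - fb) / hlen
    with np.errstate(divide="ignore", invalid="ignore"):
        sv = -c1 / (2 * c2)
        fv = fa - c1**2 / (4 * c2)
    with np.errstate(divide="ignore", invalid="ignore"):
        dip = np.maximum(floor - fv, 0.0)
        value_cost = dip**1.5 / np.sqrt(np.abs(c2))
    # trigger on value-level cost (evaluation monotonicity) or on the raw
    # derivative dip (the 1e-9 derivative certificate), whichever bites
    ok = (
        (c2 > 0)
        & (sv > 0)
        & (sv < hlen)
        & ((value_cost > value_tol) | (dip > 5e-10))
    )
    if not ok.any():
        return np.empty(0), np.empty(0)
    # Cut at the vertex plus a bracket at the predicted tangency distance
    # d = sqrt(dip / curvature): plain vertex cuts only halve the distance
    # to the limiting tangency point each round (a slow geometric tail),
    # while bracketing the limit point directly converges in a few rounds.
    xv = a[ok] + sv[ok]
    d = np.sqrt((floor - fv[ok]) / c2[ok])
    offsets = np.array([-2.0, -1.0, -0.5, -0.25, 0.0, 0.25, 0.5, 1.0, 2.0])
    k = offsets.size
    pts = (xv[:, None] + d[:, None] * offsets[None, :]).ravel()
    pts = np.clip(pts, np.repeat(a[ok], k), np.repeat(b[ok], k))
    return pts, fv[ok]


def _lsi(
    A: np.ndarray,
    b: np.ndarray,
    G: np.ndarray,
    h: np.ndarray,
    svd: tuple | None = None,
) -> np.ndarray:
    """Least squares with linear inequalities: min ||Az - b|| s.t. Gz >= h.

    Lawson-Hanson: reduce to least distance programming via the SVD of A,
    then solve LDP through a single NNLS call. Rank-deficient A is handled
    by restricting to its row space (minimum-norm convention). A
    precomputed reduced SVD of A may be passed to amortise repeated calls.
    """
    if svd is None:
        svd = np.linalg.svd(A, full_matrices=False)
    U, s, Vt = svd
    keep = s > s[0] * 1e-12 if s.size else np.zeros(0, dtype=bool)
    U, s, Vt = U[:, keep], s[keep], Vt[keep]
    r = s.size
    if r == 0:
        return np.zeros(A.shape[1])
    ub = U.T @ b
    Gp = (G @ Vt.T) / s  # constraints in the whitened coordinates
    hp = h - Gp @ ub
    # LDP: min ||y|| s.t. Gp y >= hp
    E = np.vstack([Gp.T, hp])
    f = np.zeros(r + 1)
    f[-1] = 1.0
    w, _ = nnls(E, f)
    resid = E @ w - f
    if abs(resid[-1]) < 1e-13:
        raise DegenerateDataError("monotone fit infeasible under the derivative floor")
    y = -resid[:-1] / resid[-1]
    return Vt.T @ ((y + ub) / s)


@dataclass
class MonotoneSpline:
    """An invertible monotone C^2 piecewise-cubic inner model.

    The spline is stored as a clamped cubic B-spline ``g`` on the mirrored
    abscissa ``x = direction * t``; ``phi(t) = g(direction * t)`` so that
    ``direction * phi`` is non-decreasing. Outside the fitted domain the
    evaluation continues linearly with the boundary slope, which keeps the
    extension monotone and globally invertible.
    """

    knots: KnotVector  # in original t coordinates
    basis_coefficients: np.ndarray  # cubic B-spline coefficients of g
    direction: int = 1
    derivative_floor: float = 0.0
    fitted_domain: tuple[float, float] = (0.0, 1.0)
    n_knots_requested: int = 0
    fitted_values: np.ndarray | None = field(default=None, repr=False)
    sse: float = float("nan")

    def __post_init__(self) -> None:
        self.basis_coefficients = np.asarray(self.basis_coefficients, dtype=float)
        if self.direction not in (-1, 1):
            raise ValidationError("direction must be +1 or -1")
        self._rebuild()

    def _rebuild(self) -> None:
        tlo, thi = self.fitted_domain
        if self.direction == 1:
            xknots = KnotVector(self.knots.interior_knots.copy(), (tlo, thi))
        else:
            xknots = KnotVector(np.sort(-self.knots.interior_knots), (-thi, -tlo))
        t4 = _full_knots(xknots)
        self._t4 = t4
        self._g = BSpline(t4, self.basis_coefficients, 3, extrapolate=False)
        self._dg = self._g.derivative()
        self._xlo, self._xhi = float(t4[0]), float(t4[-1])
        self._glo = float(self._g(self._xlo))
        self._ghi = float(self._g(self._xhi))
        self._slope_lo = float(self._dg(self._xlo))
        self._slope_hi = float(self._dg(self._xhi))

    # -- plumbing ----------------------------------------------------------
    @property
    def intercept(self) -> float:
        """Value of the non-decreasing branch at its left boundary."""
        return self._glo

    def _eval_g(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.empty_like(x)
        left = x < self._xlo
        right = x > self._xhi
        mid = ~(left | right)
        if mid.any():
            out[mid] = self._g(x[mid])
        if left.any():
            out[left] = self._glo + self._slope_lo * (x[left] - self._xlo)
        if right.any():
            out[right] = self._ghi + self._slope_hi * (x[right] - self._xhi)
        return out

    def derivative_certificate(self, n_grid: int = N_CONSTRAINT_GRID) -> float:
        """Minimum of d(direction*phi)/dt over an ``n_grid``-point grid."""
        grid = np.linspace(self._xlo, self._xhi, n_grid)
        return float(np.min(self._dg(grid)))

    def piecewise_polynomial(self):
        """The non-decreasing branch g as a scipy PPoly (one cubic per piece).

        Pieces join at the interior knots of the mirrored abscissa
        ``x = direction * t``; useful for continuity checks and for
        recovering per-piece polynomial coefficients.
        """
        from scipy.interpolate import PPoly

        return PPoly.from_spline(self._g)

    def to_dict(self) -> dict:
        return {
            "interior_knots": self.knots.interior_knots.tolist(),
            "boundary": [self.knots.boundary[0], self.knots.boundary[1]],
            "basis_coefficients": self.basis_coefficients.tolist(),
            "direction": int(self.direction),
            "derivative_floor": float(self.derivative_floor),
            "fitted_domain": [self.fitted_domain[0], self.fitted_domain[1]],
            "n_knots_requested": int(self.n_knots_requested),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MonotoneSpline":
        return cls(
            knots=KnotVector(
                np.asarray(d["interior_knots"], dtype=float), tuple(d["boundary"])
            ),
            basis_coefficients=np.asarray(d["basis_coefficients"], dtype=float),
            direction=int(d["direction"]),
            derivative_floor=float(d["derivative_floor"]),
            fitted_domain=tuple(d["fitted_domain"]),
            n_knots_requested=int(d["n_knots_requested"]),
        )


def fit_monotone_spline(
    t: np.ndarray,
    u: np.ndarray,
    n_knots: int,
    derivative_floor: float = 0.0,
) -> MonotoneSpline:
    """Constrained least-squares fit of a monotone cubic spline u = phi(t).

    The monotonicity direction is the sign of the sample correlation of
    (t, u) (+1 on ties). If quantile knot placement collapses duplicated
    knots, the knot count is reduced automatically (logged).
    """
    t = np.asarray(t, dtype=float).ravel()
    u = np.asarray(u, dtype=float).ravel()
    if t.size != u.size:
        raise ValidationError(f"t and u lengths differ: {t.size} vs {u.size}")
    if t.size < 4:
        raise ValidationError("need at least 4 points to fit a cubic inner model")
    if not (np.isfinite(t).all() and np.isfinite(u).all()):
        raise ValidationError("non-finite values in spline inputs")
    distinct = np.unique(t)
    if distinct.size < 2:
        raise DegenerateDataError("all abscissa values identical; inner model undefined")

    st, su = t.std(), u.std()
    if st > 0 and su > 0:
        corr = float(np.mean((t - t.mean()) * (u - u.mean())) / (st * su))
    else:
        corr = 0.0
    direction = -1 if corr < 0 else 1
    x = direction * t

    j = min(n_knots, distinct.size - 2)
    if j < n_knots:
        logger.info("knot count reduced from %d to %d (too few distinct t)", n_knots, j)
    while True:
        try:
            xknots = place_knots(x, j)
            break
        except KnotPlacementError:
            j -= 1
            logger.info("quantile knots collapsed; retrying with %d knots", j)

    t4 = _full_knots(xknots)
    A = _design(x, t4, 3)
    L = _derivative_operator(t4)
    grid = np.linspace(t4[0], t4[-1], N_FIT_CONSTRAINT_GRID)
    scale = max(1.0, float(np.abs(u).max()))
    grid_tol = 1e-11 * scale

    def grid_violations(c):
        dv = BSpline(t4[1:-1], L @ c, 2, extrapolate=False)(grid)
        return grid[np.nan_to_num(dv) < derivative_floor - grid_tol]

    def vertex_violations(c):
        """Inter-grid dips whose value-level cost breaks the 1e-9 contracts."""
        vv, _ = _derivative_violations(
            t4, L @ c, derivative_floor, _VALUE_CUT_TOL * scale
        )
        return vv

    def deriv_at(c, pts):
        return np.nan_to_num(BSpline(t4[1:-1], L @ c, 2, extrapolate=False)(pts))

    def subsample(pts, limit=64):
        if pts.size <= limit:
            return pts
        return pts[np.linspace(0, pts.size - 1, limit).round().astype(int)]

    # fast path: unconstrained optimum already monotone
    c, *_ = np.linalg.lstsq(A, u, rcond=None)
    if grid_violations(c).size or vertex_violations(c).size:
        # Working-set outer loop. Round by round the constraint set is
        # rebuilt from a coarse base grid, the constraints active at the
        # current iterate, and a bounded subsample of the currently
        # violated certificate-grid points (phase 2 adds the analytic
        # per-piece derivative minima between grid points). Keeping the
        # working set small keeps the inner LDP/NNLS solve fast and
        # well-conditioned; at termination the iterate is feasible for the
        # full dense-grid problem and optimal over a subset of its
        # constraints, i.e. it is the dense-grid optimum.
        svd = np.linalg.svd(A, full_matrices=False)
        base = np.append(grid[::64], grid[-1])
        pool = base
        G = _design(pool, t4[1:-1], 2) @ L
        h = np.full(pool.size, derivative_floor)
        c = _lsi(A, u, G, h, svd=svd)
        pool_cap = 384
        for phase2 in (False, True):
            for _ in range(60):
                viol = grid_violations(c)
                if phase2:
                    viol = np.concatenate([viol, vertex_violations(c)])
                if viol.size == 0:
                    break
                worst = viol[np.argmin(deriv_at(c, viol))]
                pool = np.unique(np.concatenate([pool, subsample(viol), [worst]]))
                if pool.size > pool_cap:
                    # evict only clearly inactive points; keep the base grid,
                    # everything near-binding and the fresh violations
                    near = pool[
                        deriv_at(c, pool) <= derivative_floor + 1e-5 * scale
                    ]
                    pool = np.unique(
                        np.concatenate([base, near, subsample(viol), [worst]])
                    )
                G = _design(pool, t4[1:-1], 2) @ L
                h = np.full(pool.size, derivative_floor)
                c = _lsi(A, u, G, h, svd=svd)
            else:
                logger.info("monotone fit working-set loop hit round limit")
        # rare pathological cycling (heavily over-parameterised corners):
        # repair with a general-purpose QP solve over the full dense grid,
        # keeping a candidate only when it improves worst-case feasibility
        remaining = np.concatenate([grid_violations(c), vertex_violations(c)])
        if remaining.size:
            from scipy.optimize import minimize

            G = _design(grid, t4[1:-1], 2) @ L
            h = np.full(grid.size, derivative_floor)
            candidates = [c]
            for start in (c, np.full(c.size, float(np.mean(u)))):
                res = minimize(
                    lambda z: float(np.sum((A @ z - u) ** 2)),
                    start,
                    jac=lambda z: 2.0 * A.T @ (A @ z - u),
                    constraints=[{"type": "ineq", "fun": lambda z: G @ z - h,
                                  "jac": lambda z: G}],
                    method="SLSQP",
                    options={"maxiter": 300, "ftol": 1e-14},
                )
                candidates.append(res.x)
            feas = [deriv_at(z, grid).min() for z in candidates]
            c = candidates[int(np.argmax(feas))]

    if direction == 1:
        knots_t = KnotVector(xknots.interior_knots.copy(), xknots.boundary)
        domain = xknots.boundary
    else:
        knots_t = KnotVector(
            np.sort(-xknots.interior_knots), (-xknots.boundary[1], -xknots.boundary[0])
        )
        domain = knots_t.boundary

    spline = MonotoneSpline(
        knots=knots_t,
        basis_coefficients=c,
        direction=direction,
        derivative_floor=derivative_floor,
        fitted_domain=domain,
        n_knots_requested=n_knots,
    )
    fitted = eval_spline(spline, t)
    spline.fitted_values = fitted
    spline.sse = float(np.sum((u - fitted) ** 2))
    return spline


def eval_spline(s: MonotoneSpline, t: np.ndarray) -> np.ndarray:
    """Evaluate phi(t); linear extrapolation with boundary slope outside."""
    t = np.asarray(t, dtype=float)
    if not np.isfinite(t).all():
        raise ValidationError("non-finite query points")
    return s._eval_g(s.direction * t)


def invert_spline(s: MonotoneSpline, u: np.ndarray) -> np.ndarray:
    """Invert phi: return t with phi(t) = u.

    In-range values are bracketed by bisection; on flat stretches the
    midpoint of the preimage interval is returned; out-of-range values
    invert the linear extrapolation (or return the boundary when the
    boundary slope vanishes). A globally flat spline maps every query to
    the domain midpoint.
    """
    u = np.asarray(u, dtype=float)
    scalar = u.ndim == 0
    u = np.atleast_1d(u).astype(float)
    if not np.isfinite(u).all():
        raise ValidationError("non-finite query values")
    xlo, xhi, glo, ghi = s._xlo, s._xhi, s._glo, s._ghi
    height = ghi - glo
    if height <= 1e-14 * max(1.0, abs(glo), abs(ghi)):
        x = np.full(u.shape, 0.5 * (xlo + xhi))
    else:
        x = np.empty_like(u)
        below = u < glo
        above = u > ghi
        inside = ~(below | above)
        if below.any():
            x[below] = (
                xlo + (u[below] - glo) / s._slope_lo if s._slope_lo > 0 else xlo
            )
        if above.any():
            x[above] = (
                xhi + (u[above] - ghi) / s._slope_hi if s._slope_hi > 0 else xhi
            )
        if inside.any():
            ui = u[inside]
            # leftmost point with g >= u
            alo = np.full(ui.shape, xlo)
            ahi = np.full(ui.shape, xhi)
            blo = alo.copy()
            bhi = ahi.copy()
            for _ in range(_BISECT_ITERS):
                amid = 0.5 * (alo + ahi)
                bmid = 0.5 * (blo + bhi)
                gm = s._g(np.concatenate([amid, bmid]))
                ga, gb = gm[: amid.size], gm[amid.size :]
                take = ga < ui
                alo = np.where(take, amid, alo)
                ahi = np.where(take, ahi, amid)
                takeb = gb <= ui
                blo = np.where(takeb, bmid, blo)
                bhi = np.where(takeb, bhi, bmid)
            xl = 0.5 * (alo + ahi)
            xr = 0.5 * (blo + bhi)
            xm = 0.5 * (xl + xr)
            # On flat stretches xl/xr bracket the preimage interval and the
            # midpoint is exact. Sub-1e-9 non-monotone wiggles between
            # certificate grid points can put several crossings inside the
            # bracket; fall back to whichever point reproduces u best.
            cand = np.stack([xm, xl, xr])
            err = np.abs(s._g(cand) - ui[None, :])
            pick = np.where(
                err[0] <= 1e-9 * (1.0 + np.abs(ui)), 0, np.argmin(err, axis=0)
            )
            x[inside] = cand[pick, np.arange(ui.size)]
    t = s.direction * x
    return float(t[0]) if scalar else t
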