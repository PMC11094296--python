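import numpy as np
import pytest
from scipy.interpolate import BSpline
from scipy.optimize import minimize

from mirpls import (
    MonotoneSpline,
    eval_spline,
    fit_monotone_spline,
    invert_spline,
    place_knots,
)
from mirpls.exceptions import DegenerateDataError, KnotPlacementError, ValidationError
from mirpls.monotone_spline import N_FIT_CONSTRAINT_GRID


def constrained_ls_oracle(t, u, spline):
    """Independent oracle: SLSQP over the cubic B-spline space on the same
    knots, derivative >= 0 enforced on the same 512-point grid. Returns SSE."""
    direction = spline.direction
    x = np.sort(direction * t)
    lo, hi = x.min(), x.max()
    if direction == 1:
        interior = spline.knots.interior_knots
    else:
        interior = np.sort(-spline.knots.interior_knots)
    t4 = np.r_[[lo] * 4, interior, [hi] * 4]
    xs = direction * t
    A = BSpline.design_matrix(np.clip(xs, lo, hi), t4, 3).toarray()
    grid = np.linspace(lo, hi, N_FIT_CONSTRAINT_GRID)

    def deriv_rows(pts):
        p = t4.size - 4
        rows = np.zeros((pts.size, p))
        for i in range(p):
            c = np.zeros(p)
            c[i] = 1.0
            rows[:, i] = BSpline(t4, c, 3).derivative()(pts)
        return rows

    G = deriv_rows(grid)

    def obj(c):
        r = A @ c - u
        return r @ r

    def jac(c):
        return 2 * A.T @ (A @ c - u)

    cons = [{"type": "ineq", "fun": lambda c: G @ c, "jac": lambda c: G}]
    x0 = np.full(t4.size - 4, u.mean())
    best = None
    for start in (x0, np.linalg.lstsq(A, u, rcond=None)[0]):
        res = minimize(obj, start, jac=jac, constraints=cons, method="SLSQP",
                       options={"maxiter": 1000, "ftol": 1e-14})
        if best is None or res.fun < best:
            best = res.fun
    return best


class TestPlaceKnots:
    def test_hundred_points_three_knots(self, rng):
        t = np.sort(rng.standard_normal(100))
        kv = place_knots(t, 3)
        assert kv.n_interior == 3
        # each of the four segments holds exactly 25 of the sorted points
        edges = np.r_[-np.inf, kv.interior_knots, np.inf]
        counts = np.histogram(t, bins=edges)[0]
        assert counts.max() - counts.min() <= 1
        np.testing.assert_array_equal(counts, [25, 25, 25, 25])
        # knot i sits between the (25i)th and (25i+1)th sorted points
        for i, k in enumerate(kv.interior_knots, start=1):
            assert t[25 * i - 1] <= k <= t[25 * i]

    def test_zero_knots(self):
        kv = place_knots(np.arange(10.0), 0)
        assert kv.n_interior == 0
        assert kv.boundary == (0.0, 9.0)

    def test_median_knot(self):
        kv = place_knots(np.arange(1.0, 11.0), 1)
        np.testing.assert_allclose(kv.interior_knots, [5.5])

    def test_too_few_distinct_values(self):
        with pytest.raises(KnotPlacementError):
            place_knots(np.array([1.0, 1.0, 2.0, 2.0]), 3)

    def test_segment_balance_random(self, rng):
        for n, j in [(37, 2), (50, 4), (12, 1)]:
            t = rng.standard_normal(n)
            kv = place_knots(t, j)
            edges = np.r_[-np.inf, kv.interior_knots, np.inf]
            counts = np.histogram(t, bins=edges)[0]
            assert counts.max() - counts.min() <= 1


class TestFitMonotoneSpline:
    def test_identity_data(self, rng):
        t = np.sort(rng.uniform(-2, 2, 30))
        s = fit_monotone_spline(t, t, 2)
        assert s.direction == 1
        np.testing.assert_allclose(s.fitted_values, t, atol=1e-8)
        assert s.derivative_certificate() >= -1e-9

    def test_mirrored_data(self, rng):
        t = np.sort(rng.uniform(-2, 2, 30))
        s = fit_monotone_spline(t, -t, 2)
        assert s.direction == -1
        np.testing.assert_allclose(s.fitted_values, -t, atol=1e-8)

    def test_oracle_equivalence_single_instance(self, rng):
        t = np.sort(rng.standard_normal(50) * 2)
        u = np.tanh(t) + rng.normal(scale=0.05, size=50)
        s = fit_monotone_spline(t, u, 2)
        sse_oracle = constrained_ls_oracle(t, u, s)
        assert s.sse <= sse_oracle + 1e-5 * max(sse_oracle, 1e-12)
        assert abs(s.sse - sse_oracle) <= 1e-5 * max(sse_oracle, 1.0)

    def test_beats_or_matches_monotone_linear_fit(self, rng):
        t = np.sort(rng.standard_normal(40))
        u = np.exp(t) + rng.normal(scale=0.1, size=40)
        s = fit_monotone_spline(t, u, 1)
        # best monotone linear fit (slope sign matching the data direction)
        A = np.column_stack([np.ones(40), t])
        coef, *_ = np.linalg.lstsq(A, u, rcond=None)
        if coef[1] * s.direction < 0:
            coef = np.array([u.mean(), 0.0])
        sse_lin = np.sum((u - A @ coef) ** 2)
        assert s.sse <= sse_lin + 1e-9

    def test_nesting_zero_vs_more_knots(self, rng):
        # the J=0 family is a subspace of every J>=1 family on nested knots
        t = np.sort(rng.standard_normal(60))
        u = np.tanh(2 * t) + rng.normal(scale=0.1, size=60)
        sse0 = fit_monotone_spline(t, u, 0).sse
        for j in (1, 2, 3):
            assert fit_monotone_spline(t, u, j).sse <= sse0 + 1e-9

    def test_c2_continuity_at_knots(self, rng):
        # value, first and second derivative of adjacent cubic pieces agree
        # at every interior knot
        t = np.sort(rng.standard_normal(80) * 2)
        u = np.tanh(t) + rng.normal(scale=0.05, size=80)
        s = fit_monotone_spline(t, u, 3)
        pp = s.piecewise_polynomial()
        breaks = np.unique(pp.x)[1:-1]
        assert breaks.size >= 3
        for order in range(3):
            d = pp.derivative(order) if order else pp
            for k in breaks:
                i_left = np.searchsorted(pp.x, k, side="left") - 1
                i_right = np.searchsorted(pp.x, k, side="right") - 1
                left = np.polyval(d.c[:, i_left], k - d.x[i_left])
                right = np.polyval(d.c[:, i_right], k - d.x[i_right])
                assert abs(left - right) <= 1e-8 * max(1.0, abs(left), abs(right))

    def test_knot_reduction_on_few_distinct_values(self):
        t = np.repeat([0.0, 1.0, 2.0], 5)
        u = t + 0.1
        s = fit_monotone_spline(t, u, 4)
        assert s.knots.n_interior <= 1
        assert s.n_knots_requested == 4

    def test_degenerate_abscissa(self):
        with pytest.raises(DegenerateDataError):
            fit_monotone_spline(np.ones(10), np.arange(10.0), 1)

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            fit_monotone_spline(np.arange(5.0), np.arange(4.0), 0)

    def test_derivative_floor(self, rng):
        t = np.sort(rng.standard_normal(40))
        u = np.tanh(3 * t)
        s = fit_monotone_spline(t, u, 1, derivative_floor=0.05)
        assert s.derivative_certificate() >= 0.05 - 1e-9

    def test_monotonicity_certificate_random_instances(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 60))
            j = int(rng.integers(0, 4))
            t = rng.standard_normal(n)
            u = rng.standard_normal(n)  # even unordered noise must fit monotone
            s = fit_monotone_spline(t, u, j)
            assert s.derivative_certificate() >= -1e-9


class TestEvalSpline:
    @pytest.fixture
    def fitted(self, rng):
        t = np.sort(rng.standard_normal(50) * 2)
        u = np.tanh(t) + rng.normal(scale=0.05, size=50)
        return t, u, fit_monotone_spline(t, u, 2)

    def test_training_values_bit_identical(self, fitted):
        t, _, s = fitted
        np.testing.assert_array_equal(eval_spline(s, t), s.fitted_values)

    def test_linear_extrapolation(self, fitted):
        t, _, s = fitted
        hi = s.fitted_domain[1]
        delta = 0.37
        f_hi = eval_spline(s, np.array([hi]))[0]
        eps = 1e-7
        slope = (f_hi - eval_spline(s, np.array([hi - eps]))[0]) / eps
        expected = f_hi + slope * delta
        got = eval_spline(s, np.array([hi + delta]))[0]
        np.testing.assert_allclose(got, expected, atol=1e-5)
        # extrapolation is exactly linear: second differences vanish
        pts = hi + np.array([0.5, 1.0, 1.5])
        v = eval_spline(s, pts)
        np.testing.assert_allclose(v[2] - v[1], v[1] - v[0], atol=1e-10)

    def test_sorted_outputs_monotone(self, fitted):
        _, _, s = fitted
        q = np.linspace(s.fitted_domain[0] - 1, s.fitted_domain[1] + 1, 700)
        out = s.direction * eval_spline(s, q)
        assert np.all(np.diff(out) >= -1e-9)

    def test_rejects_non_finite(self, fitted):
        _, _, s = fitted
        with pytest.raises(ValidationError):
            eval_spline(s, np.array([np.nan]))


class TestInvertSpline:
    def test_identity_spline(self, rng):
        t = np.linspace(-1, 1, 20)
        s = fit_monotone_spline(t, t, 0)
        u = rng.uniform(-1, 1, 50)
        np.testing.assert_allclose(invert_spline(s, u), u, atol=1e-10)

    def test_round_trip(self, rng):
        t = np.sort(rng.standard_normal(60) * 2)
        u = np.tanh(t) + rng.normal(scale=0.05, size=60)
        s = fit_monotone_spline(t, u, 2)
        lo, hi = s.fitted_domain
        rng_vals = eval_spline(s, np.array([lo, hi]))
        q = np.linspace(min(rng_vals), max(rng_vals), 100)
        back = eval_spline(s, invert_spline(s, q))
        assert np.max(np.abs(back - q)) < 1e-8 * (1 + np.max(np.abs(q)))

    def test_decreasing_round_trip(self, rng):
        t = np.sort(rng.standard_normal(50))
        u = -np.tanh(2 * t) + rng.normal(scale=0.03, size=50)
        s = fit_monotone_spline(t, u, 1)
        assert s.direction == -1
        lo, hi = s.fitted_domain
        rng_vals = eval_spline(s, np.array([lo, hi]))
        q = np.linspace(min(rng_vals), max(rng_vals), 60)
        back = eval_spline(s, invert_spline(s, q))
        assert np.max(np.abs(back - q)) < 1e-8 * (1 + np.max(np.abs(q)))

    def test_out_of_range_inverts_extrapolation(self, rng):
        t = np.sort(rng.standard_normal(40))
        u = t + 0.1 * rng.standard_normal(40)
        s = fit_monotone_spline(t, u, 1)
        hi = s.fitted_domain[1]
        u_hi = eval_spline(s, np.array([hi]))[0]
        q = u_hi + 0.5
        t_inv = invert_spline(s, np.array([q]))[0]
        assert t_inv > hi
        np.testing.assert_allclose(
            eval_spline(s, np.array([t_inv]))[0], q, atol=1e-8
        )

    def test_flat_spline_returns_domain_midpoint(self):
        t = np.linspace(0.0, 4.0, 12)
        s = fit_monotone_spline(t, np.full(12, 3.0), 1)
        q = np.array([2.0, 3.0, 5.0])
        np.testing.assert_allclose(invert_spline(s, q), np.full(3, 2.0), atol=1e-9)

    def test_scalar_query(self, rng):
        t = np.linspace(-1, 1, 15)
        s = fit_monotone_spline(t, t, 0)
        assert isinstance(invert_spline(s, 0.25), float)


class TestSerialization:
    def test_round_trip(self, rng):
        t = np.sort(rng.standard_normal(45))
        u = -np.exp(-t) + rng.normal(scale=0.05, size=45)
        s = fit_monotone_spline(t, u, 2)
        s2 = MonotoneSpline.from_dict(s.to_dict())
        q = np.linspace(t.min() - 1, t.max() + 1, 200)
        np.testing.assert_array_equal(eval_spline(s, q), eval_spline(s2, q))


class TestOracleEquivalenceBatch:
    def test_twenty_random_instances(self):
        # mirrors the acceptance contract at module level with fewer instances
        rng = np.random.default_rng(123)
        for _ in range(5):
            n = int(rng.integers(20, 61))
            j = int(rng.integers(0, 4))
            t = np.sort(rng.standard_normal(n) * 2)
            u = np.tanh(t) + rng.normal(scale=0.1, size=n)
            s = fit_monotone_spline(t, u, j)
            sse_oracle = constrained_ls_oracle(t, u, s)
            assert abs(s.sse - sse_oracle) <= 1e-5 * max(sse_oracle, 1.0)
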