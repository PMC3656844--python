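"""Firing-rate reduction, mode analysis, nullclines, flow labels."""

import numpy as np
import pytest

from thetaflow.presets import two_node_preset
from thetaflow.rate import (
    FlowClass,
    RateSystem,
    classify_flow,
    find_fixed_points,
    fit_polynomial_nullclines,
    integrate_rate,
    mode_eigenvalue,
    mode_eigenvalues,
    mode_fixed_point,
    nullclines,
    numerical_jacobian,
    polynomial_intersections,
    rate_rhs,
    reduction_error,
    surrogate_omega_trace,
)

EXPECTED_FLOW = {
    "fixed-point": FlowClass.FIXED_POINT,
    "limit-cycle": FlowClass.LIMIT_CYCLE,
    "bistable": FlowClass.BISTABLE,
    "monostable": FlowClass.MONOSTABLE,
}


class TestRateRhs:
    def test_origin_is_fixed_without_input(self):
        system = RateSystem(n=3, coupling=np.zeros((3, 3)), input=np.zeros(3))
        assert np.allclose(rate_rhs(np.zeros(3), system), 0.0)

    def test_derivative_vanishes_at_mode_fixed_point(self):
        w = mode_fixed_point(0.4, n=4, input=0.1)
        system = RateSystem(n=4, coupling=np.full((4, 4), 0.4), input=np.full(4, 0.1))
        assert np.linalg.norm(rate_rhs(np.full(4, w), system)) < 1e-10

    def test_dimension_mismatch(self):
        system = RateSystem(n=2, coupling=np.zeros((2, 2)), input=np.zeros(2))
        with pytest.raises(ValueError):
            rate_rhs(np.zeros(3), system)

    def test_simplified_drops_square_root(self):
        full = RateSystem(n=1, coupling=np.zeros((1, 1)), input=np.array([0.25]))
        simp = RateSystem(
            n=1, coupling=np.zeros((1, 1)), input=np.array([0.25]), simplified=True
        )
        w = np.array([0.0])
        # sqrt(0.25) = 0.5 vs 0.25: the simplified drive term is halved
        assert rate_rhs(w, simp)[0] == pytest.approx(rate_rhs(w, full)[0] / 2.0)


class TestModeAnalysis:
    def test_quiescent_without_input_or_coupling(self):
        assert mode_fixed_point(0.0, n=5, input=0.0) == 0.0

    def test_grows_with_coupling(self):
        values = [mode_fixed_point(c, n=5, input=0.05) for c in np.linspace(0, 1, 11)]
        assert np.all(np.diff(values) > -1e-12)

    def test_eigenvalue_matches_numerical_jacobian(self):
        # finite-difference Jacobian of the full rate system as the oracle
        for c in np.linspace(-0.5, 0.5, 21):
            n = 5
            lam_u, lam_deg = mode_eigenvalues(c, n=n, input=0.1)
            w = mode_fixed_point(c, n=n, input=0.1)
            system = RateSystem(
                n=n, coupling=np.full((n, n), c), input=np.full(n, 0.1)
            )
            eig = np.sort(
                np.linalg.eigvals(numerical_jacobian(system, np.full(n, w))).real
            )
            closed = np.sort(np.r_[[lam_u], np.full(n - 1, lam_deg)])
            assert np.abs(eig - closed).max() < 1e-6

    def test_strong_coupling_stabilizes_the_mode(self):
        weak = mode_eigenvalue(0.0, n=5, input=0.1)
        strong_pos = mode_eigenvalue(3.0, n=5, input=0.1)
        strong_neg = mode_eigenvalue(-3.0, n=5, input=0.1)
        assert strong_pos < weak
        assert strong_neg < weak

    def test_dispersion_shrinks_under_strong_coupling(self, rng):
        # dispersed constant inputs; steady-state spread of the drives
        n = 8
        inputs = 0.15 + 0.05 * rng.standard_normal(n)

        def spread(c):
            system = RateSystem(n=n, coupling=np.full((n, n), c), input=inputs)
            _, y = integrate_rate(system, np.full(n, 0.2), 2500.0, dt_out=50.0)
            return float(y[:, -1].std())

        weak = spread(0.0)
        assert spread(3.0) < weak
        assert spread(-3.0) < weak


class TestNullclines:
    def test_intersections_coincide_with_fixed_points(self):
        system, _ = two_node_preset("fixed-point")
        fps = find_fixed_points(system, seeds_per_axis=10)
        c1, c2 = nullclines(system, box=(0.0, 0.6, 0.0, 0.6), resolution=300)
        pts1 = np.vstack(c1)
        pts2 = np.vstack(c2)
        for fp in fps:
            assert np.linalg.norm(pts1 - fp.omega, axis=1).min() < 5e-3
            assert np.linalg.norm(pts2 - fp.omega, axis=1).min() < 5e-3

    def test_symmetric_system_mirror_nullclines(self):
        system, _ = two_node_preset("bistable")  # exchange-symmetric
        c1, c2 = nullclines(system, box=(0.0, 0.5, 0.0, 0.5), resolution=200)
        flipped = np.vstack(c2)[:, ::-1]
        pts1 = np.vstack(c1)
        # every flipped point of curve 2 lies on curve 1
        dists = [
            np.linalg.norm(pts1 - p, axis=1).min() for p in flipped[::10]
        ]
        assert max(dists) < 5e-3

    def test_empty_box_rejected(self):
        system, _ = two_node_preset("fixed-point")
        with pytest.raises(ValueError):
            nullclines(system, box=(0.5, 0.5, 0.0, 1.0))


class TestPolynomialFits:
    def test_constant_curve_exact_at_degree_zero(self):
        curve = np.column_stack([np.linspace(0, 1, 50), np.full(50, 0.3)])
        (fit,) = fit_polynomial_nullclines([curve], degree=0)
        assert np.allclose(fit(curve[:, 0]), 0.3)

    def test_residual_decreases_with_degree(self):
        x = np.linspace(0, 1, 80)
        curve = np.column_stack([x, np.sin(3 * x)])
        residuals = []
        for deg in (1, 3, 5, 7):
            (fit,) = fit_polynomial_nullclines([curve], degree=deg)
            residuals.append(float(np.sum((fit(x) - curve[:, 1]) ** 2)))
        assert all(a >= b for a, b in zip(residuals, residuals[1:]))

    @pytest.mark.parametrize("degree", [7])
    def test_fits_preserve_intersection_count(self, two_node_name, degree):
        """Polynomial approximations of the nullclines keep the same number
        of crossings, hence a qualitatively identical flow skeleton."""
        system, _ = two_node_preset(two_node_name)
        box = (0.005, 0.6, 0.005, 0.6)
        c1, c2 = nullclines(system, box=box, resolution=400)
        # fit the longest polyline of each family
        long1 = max(c1, key=len)
        long2 = max(c2, key=len)
        window = (
            max(long1[:, 0].min(), long2[:, 0].min()),
            min(long1[:, 0].max(), long2[:, 0].max()),
        )
        (f1,) = fit_polynomial_nullclines([long1], degree)
        (f2,) = fit_polynomial_nullclines([long2], degree)
        fitted = polynomial_intersections(f1, f2, window)
        # source intersections = root-found fixed points lying on both
        # fitted branches inside the window
        src = []
        for fp in find_fixed_points(system, seeds_per_axis=10):
            x = fp.omega[0]
            if not window[0] <= x <= window[1]:
                continue
            on1 = np.linalg.norm(long1 - fp.omega, axis=1).min() < 0.02
            on2 = np.linalg.norm(long2 - fp.omega, axis=1).min() < 0.02
            if on1 and on2:
                src.append(x)
        src_count = len(_dedupe(src, tol=0.02))
        fit_count = len(_dedupe(fitted, tol=0.02))
        assert fit_count == src_count

    def test_too_few_samples_rejected(self):
        curve = np.column_stack([[0.0, 1.0], [0.0, 1.0]])
        with pytest.raises(ValueError):
            fit_polynomial_nullclines([curve], degree=3)


def _dedupe(xs, tol):
    out = []
    for x in sorted(xs):
        if not out or x - out[-1] > tol:
            out.append(x)
    return out


class TestReductionError:
    def test_identical_traces_report_floor(self):
        x = np.linspace(0, 1, 100)
        assert reduction_error(x, x) == -12.0

    def test_high_rate_beats_low_rate(self):
        # the mean-rate approximation is better when many spikes average out
        def err(rate, seed):
            t, mean = surrogate_omega_trace(rate, 2000.0, 1.0, "mean-rate")
            _, isi = surrogate_omega_trace(rate, 2000.0, 1.0, "equal-isi")
            return reduction_error(mean, isi)

        assert err(0.25, 0) < err(0.02, 0)

    def test_surrogates_computable_from_same_rate(self):
        for kind in ("equal-isi", "poisson"):
            t, w = surrogate_omega_trace(0.1, 500.0, 1.0, kind, seed=3)
            assert w.shape == t.shape
            assert np.all(np.isfinite(w))
        with pytest.raises(ValueError):
            surrogate_omega_trace(0.1, 100.0, 1.0, "bogus")

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            reduction_error(np.zeros(5), np.zeros(6))


class TestClassifyFlow:
    def test_canonical_two_node_flows(self, two_node_name):
        system, _ = two_node_preset(two_node_name)
        report = classify_flow(system, seed=0)
        assert report.classification is EXPECTED_FLOW[two_node_name]

    def test_uncoupled_relaxation_is_fixed_point(self):
        system = RateSystem(n=2, coupling=np.zeros((2, 2)), input=np.full(2, 0.2))
        report = classify_flow(system, seed=0)
        assert report.classification is FlowClass.FIXED_POINT
        assert len(report.stable_fixed_points) == 1

    def test_report_serializes(self):
        system, _ = two_node_preset("fixed-point")
        text = classify_flow(system, seed=0).to_text()
        assert "classification: FIXED_POINT" in text
        assert "fixed_point [stable]" in text
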