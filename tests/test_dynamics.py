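"""The spiking core: phase equation, period map, event handling."""

import numpy as np
import pytest
from scipy.integrate import quad

from thetaflow.dynamics import (
    DimensionError,
    InputSchedule,
    NetworkParams,
    SpikeTrain,
    closed_form_period,
    firing_rate,
    omega_rhs,
    simulate_network,
    spike_increment,
    theta_rhs,
)


def single(k=0.0, coupling=0.0):
    return NetworkParams(n=1, coupling=np.array([[coupling]]), k=k)


class TestThetaRhs:
    def test_suprathreshold_drive_positive_everywhere(self):
        params = single()
        grid = np.linspace(0, 2 * np.pi, 1000, endpoint=False)
        dtheta = [
            theta_rhs(np.array([th]), np.array([0.0]), params, np.array([0.3]))[0]
            for th in grid
        ]
        assert min(dtheta) > 0.0

    def test_subthreshold_drive_has_rest_state(self):
        params = single()
        grid = np.linspace(0, 2 * np.pi, 2000, endpoint=False)
        dtheta = np.array(
            [
                theta_rhs(np.array([th]), np.array([0.0]), params, np.array([-0.2]))[0]
                for th in grid
            ]
        )
        assert dtheta.min() < 0.0 < dtheta.max()  # a zero crossing exists

    def test_coupling_enters_linearly(self):
        c = np.array([[0.0, 0.7], [0.2, 0.0]])
        p1 = NetworkParams(n=2, coupling=c)
        p2 = NetworkParams(n=2, coupling=2 * c)
        theta = np.array([1.0, 2.0])
        omega = np.array([0.3, 0.1])
        zero = np.zeros(2)
        base = theta_rhs(theta, zero, p1, zero)
        d1 = theta_rhs(theta, omega, p1, zero) - base
        d2 = theta_rhs(theta, omega, p2, zero) - base
        assert np.allclose(d2, 2 * d1)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(DimensionError):
            theta_rhs(np.zeros(3), np.zeros(3), single(), np.zeros(3))


class TestPeriodMap:
    def test_matches_numeric_quadrature(self):
        # independent oracle: integrate dtheta / thetadot over one cycle
        for rho in (0.04, 0.25, 1.0):
            oracle, _ = quad(
                lambda th: 1.0 / ((1 - np.cos(th)) + (1 + np.cos(th)) * rho),
                -np.pi, np.pi,
            )
            assert closed_form_period(rho) == pytest.approx(oracle, rel=1e-9)

    def test_negative_radicand_is_quiescent(self):
        assert np.isinf(closed_form_period(-0.1))
        assert firing_rate(-0.1) == 0.0
        assert firing_rate(0.0) == 0.0

    def test_quadrupled_drive_halves_period(self):
        assert closed_form_period(0.4) == pytest.approx(
            closed_form_period(0.1) / 2.0
        )

    def test_rate_is_reciprocal_and_monotone(self):
        rhos = np.linspace(0.01, 2.0, 50)
        rates = firing_rate(rhos)
        assert np.allclose(rates * closed_form_period(rhos), 1.0)
        assert np.all(np.diff(rates) > 0)


class TestOmegaDynamics:
    def test_exponential_decay_with_tau_s(self):
        params = single()
        omega = np.array([0.5])
        assert omega_rhs(omega, params)[0] == pytest.approx(-0.5 / 20.0)

    def test_spike_increment_saturates(self):
        params = single(k=0.1)
        assert spike_increment(0.0, params) == pytest.approx(0.1)
        assert spike_increment(1.0, params) == pytest.approx(0.0)

    def test_zero_k_ignores_spikes(self):
        params = single(k=0.0)
        sched = InputSchedule.constant(0.3, 1)
        res = simulate_network(
            params, sched, init=(np.array([0.0]), np.array([0.4])),
            duration=100.0, dt=0.05,
        )
        assert len(res.spikes) > 0
        # omega decays purely exponentially despite the spikes
        expected = 0.4 * np.exp(-res.t / 20.0)
        assert np.allclose(res.omega[0], expected, atol=1e-6)


class TestSimulate:
    def test_isi_matches_closed_form(self):
        params = single()
        rho = 0.09
        sched = InputSchedule.constant(rho, 1)
        res = simulate_network(
            params, sched, init=(np.array([0.0]), np.array([0.0])),
            duration=400.0, dt=0.01,
        )
        isis = res.spikes.isis(0)
        assert isis.size >= 10
        assert np.abs(isis - closed_form_period(rho)).max() < 1e-3 * closed_form_period(rho)

    def test_subthreshold_emits_no_spikes(self):
        params = single()
        sched = InputSchedule.constant(-0.05, 1)
        res = simulate_network(
            params, sched, init=(np.array([0.0]), np.array([0.0])),
            duration=300.0, dt=0.05,
        )
        assert len(res.spikes) == 0

    def test_deterministic_given_seed(self):
        params = NetworkParams(n=3, coupling=0.1 * np.ones((3, 3)))
        sched = InputSchedule.constant(0.2, 3)
        a = simulate_network(params, sched, duration=200.0, dt=0.05, seed=7)
        b = simulate_network(params, sched, duration=200.0, dt=0.05, seed=7)
        assert np.array_equal(a.theta, b.theta)
        assert np.array_equal(a.omega, b.omega)
        assert np.array_equal(a.spikes.times, b.spikes.times)

    def test_uncoupled_identical_drives_equal_isis(self):
        params = NetworkParams(n=4, coupling=np.zeros((4, 4)))
        sched = InputSchedule.constant(0.16, 4)
        theta0 = np.array([0.0, 1.0, 2.0, 5.0])
        res = simulate_network(
            params, sched, init=(theta0, np.zeros(4)), duration=300.0, dt=0.02
        )
        means = [res.spikes.isis(i).mean() for i in range(4)]
        assert np.ptp(means) < 1e-6

    def test_isi_error_shrinks_with_dt(self):
        params = single()
        sched = InputSchedule.constant(0.09, 1)
        errors = []
        for dt in (0.2, 0.1, 0.05):
            res = simulate_network(
                params, sched, init=(np.array([0.0]), np.array([0.0])),
                duration=200.0, dt=dt,
            )
            errors.append(
                abs(res.spikes.isis(0).mean() - closed_form_period(0.09))
            )
        assert errors[0] > errors[2]  # at least first order in dt

    def test_bad_arguments(self):
        params = single()
        sched = InputSchedule.constant(0.1, 1)
        with pytest.raises(ValueError):
            simulate_network(params, sched, duration=10.0, dt=-0.1)
        with pytest.raises(ValueError):
            simulate_network(params, sched, duration=0.0, dt=0.1)


class TestContainers:
    def test_input_schedule_segments(self):
        sched = InputSchedule(
            np.array([0.0, 10.0]), np.array([[0.1, 0.2], [0.3, 0.4]])
        )
        assert np.allclose(sched(5.0), [0.1, 0.2])
        assert np.allclose(sched(10.0), [0.3, 0.4])
        with pytest.raises(ValueError):
            InputSchedule(np.array([0.0, 0.0]), np.zeros((2, 1)))

    def test_spike_train_validation(self):
        with pytest.raises(ValueError):
            SpikeTrain(np.array([2.0, 1.0]), np.array([0, 0]))
        train = SpikeTrain(np.array([1.0, 2.0, 3.0]), np.array([0, 1, 0]))
        assert np.allclose(train.of_neuron(0), [1.0, 3.0])

    def test_params_validation(self):
        with pytest.raises(ValueError):
            NetworkParams(n=0, coupling=np.zeros((0, 0)))
        with pytest.raises(ValueError):
            NetworkParams(n=1, coupling=np.zeros((1, 1)), tau_s=-1.0)
        with pytest.raises(DimensionError):
            NetworkParams(n=2, coupling=np.zeros((3, 3)))
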