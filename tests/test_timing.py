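"""Phase response curves, synchronization, and two-neuron locking."""

import numpy as np
import pytest

from thetaflow.presets import TIMING_PRESETS, timing_preset
from thetaflow.timing import (
    LockedState,
    PhaseNetwork,
    analytic_prc,
    analytic_prc_slope,
    lock_section_map,
    numerical_prc,
    order_parameter,
    order_parameter_series,
    phase_locked_states,
    relative_phase_series,
    simulate_phase_network,
    sync_mode_eigenvalue,
    sync_perturbation_matrix,
    sync_return_map_jacobian,
)

ETA = 0.04


class TestAnalyticPrc:
    def test_zero_coupling_gives_zero_shift(self):
        phi = np.linspace(0.01, 2 * np.pi - 0.01, 50)
        assert np.allclose(analytic_prc(phi, 0.0, ETA), 0.0, atol=1e-12)

    def test_periodic_in_phase(self):
        for phi in (0.3, 2.0, 5.5):
            assert analytic_prc(phi, 0.2, ETA) == pytest.approx(
                analytic_prc(phi + 2 * np.pi, 0.2, ETA)
            )

    def test_excitatory_advances_inhibitory_delays(self):
        phi = np.linspace(0.2, 2 * np.pi - 0.2, 40)
        assert np.all(analytic_prc(phi, 0.2, ETA) > 0)
        assert np.all(analytic_prc(phi, -0.2, ETA) < 0)

    def test_slope_matches_finite_differences(self):
        phi = np.linspace(0.3, 2 * np.pi - 0.4, 30)
        h = 1e-6
        fd = (analytic_prc(phi + h, 0.25, ETA) - analytic_prc(phi - h, 0.25, ETA)) / (
            2 * h
        )
        assert np.abs(analytic_prc_slope(phi, 0.25, ETA) - fd).max() < 1e-6

    def test_requires_oscillating_neuron(self):
        with pytest.raises(ValueError):
            analytic_prc(1.0, 0.1, -0.2)


class TestNumericalPrc:
    @pytest.mark.parametrize("kappa", [0.3, -0.3])
    def test_matches_closed_form(self, kappa):
        phi = np.linspace(1e-3, 2 * np.pi - 1e-3, 64)
        err = np.abs(numerical_prc(phi, kappa, ETA) - analytic_prc(phi, kappa, ETA))
        assert err.max() < 1e-2

    def test_zero_strength_pulse_is_silent(self):
        phi = np.array([0.5, 3.0, 5.5])
        assert np.allclose(numerical_prc(phi, 0.0, ETA), 0.0, atol=1e-9)


class TestOrderParameter:
    def test_coherent_phases(self):
        assert order_parameter(np.full(10, 1.3)).magnitude == pytest.approx(1.0)

    def test_antiphase_pair_cancels(self):
        assert order_parameter(np.array([0.0, np.pi])).magnitude == pytest.approx(
            0.0, abs=1e-12
        )

    def test_uniform_splay_cancels(self):
        phases = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        assert order_parameter(phases).magnitude == pytest.approx(0.0, abs=1e-12)

    def test_series_shape(self):
        traj = np.zeros((5, 7))
        assert order_parameter_series(traj).shape == (7,)


class TestSynchronization:
    def test_excitatory_coupling_synchronizes(self):
        net = PhaseNetwork.homogeneous(50, ETA, 1.0)
        _, traj, _ = simulate_phase_network(net, 5000.0, seed=3)
        r = order_parameter_series(traj)
        assert r[-300:].mean() > 0.99

    def test_inhibitory_coupling_disperses(self):
        net = PhaseNetwork.homogeneous(50, ETA, -0.5)
        _, traj, _ = simulate_phase_network(net, 8000.0, seed=3)
        r = order_parameter_series(traj)
        assert r[-300:].mean() < 0.2

    def test_uncoupled_phases_keep_their_spread(self):
        net = PhaseNetwork.homogeneous(20, ETA, 0.0)
        init = np.linspace(0, 2 * np.pi, 20, endpoint=False)
        _, traj, _ = simulate_phase_network(net, 1000.0, init=init)
        r = order_parameter_series(traj)
        assert np.all(r < 0.05)

    def test_simulation_deterministic(self):
        net = PhaseNetwork.homogeneous(10, ETA, 0.4)
        a = simulate_phase_network(net, 500.0, seed=5)
        b = simulate_phase_network(net, 500.0, seed=5)
        assert np.array_equal(a[1], b[1])
        assert np.array_equal(a[2].times, b[2].times)


class TestSyncEigenvalue:
    @pytest.mark.parametrize("n", [3, 5, 10])
    @pytest.mark.parametrize("coupling", [0.1, -0.1, -0.05])
    def test_closed_form_matches_dense_eigensolve(self, n, coupling):
        lam, _ = sync_mode_eigenvalue(n, coupling, ETA)
        spectrum = np.linalg.eigvals(sync_perturbation_matrix(n, coupling, ETA))
        spectrum = np.sort(spectrum.real)
        # one neutral eigenvalue, n - 1 copies of the unique one
        assert np.isclose(spectrum, 1.0, atol=1e-9).sum() >= 1
        others = spectrum[~np.isclose(spectrum, 1.0, atol=1e-9)]
        if others.size:
            assert np.abs(others - lam).max() < 1e-9
        else:  # lambda itself equals 1 only at zero coupling
            assert lam == pytest.approx(1.0)

    def test_verdicts_cross_zero_coupling(self):
        lam_pos, verdict_pos = sync_mode_eigenvalue(10, 1.0, ETA)
        lam_zero, verdict_zero = sync_mode_eigenvalue(10, 0.0, ETA)
        lam_neg, verdict_neg = sync_mode_eigenvalue(10, -1.0, ETA)
        assert verdict_pos == "stable" and lam_pos == 0.0  # absorbed volley
        assert verdict_zero == "neutral"
        assert lam_neg != 0.0

    @pytest.mark.parametrize("coupling", [0.1, -0.05])
    def test_agrees_with_event_driven_return_map(self, coupling):
        """The straggler eigenvalue of the exact event-driven volley map
        (weak-coupling smooth regime) tracks the closed form."""
        for n in (3, 5):
            lam, _ = sync_mode_eigenvalue(n, coupling, ETA, offset=0.3)
            jac = sync_return_map_jacobian(n, coupling, ETA, offset=0.3)
            eigs = np.linalg.eigvals(jac).real
            closest = eigs[np.argmin(np.abs(eigs - lam))]
            assert abs(closest - lam) < 0.06


class TestLocking:
    def test_zero_coupling_is_degenerate(self):
        net = PhaseNetwork(2, np.array([ETA, ETA]), np.zeros((2, 2)))
        states = phase_locked_states(net)
        assert len(states) == 1 and states[0].degenerate

    def test_synchrony_preset_locks_at_zero_offset(self):
        net = timing_preset("synchrony")
        stable = [s for s in phase_locked_states(net) if s.stable]
        assert len(stable) == 1
        assert stable[0].offset_fraction == pytest.approx(0.0, abs=0.02)

    def test_drift_preset_has_no_stable_lock(self):
        net = timing_preset("phase-drift")
        assert not any(s.stable for s in phase_locked_states(net))

    def test_monostable_preset_lock_with_separatrix(self):
        net = timing_preset("timing-monostable")
        states = phase_locked_states(net)
        stable = [s for s in states if s.stable]
        unstable = [s for s in states if not s.stable and not s.degenerate]
        assert len(stable) == 1 and len(unstable) >= 1

    def test_monostable_large_kick_transient_rotation(self):
        """A strong perturbation of the locked pair triggers one slow
        rotation of the relative phase -- passing through synchrony --
        before relocking."""
        net = timing_preset("timing-monostable")
        stable = [s for s in phase_locked_states(net) if s.stable][0]
        z = np.array(stable.state)
        # small kick: relocks without a rotation
        small = _iterate_offsets(net, z + np.array([0.0, -0.5]), 60)
        assert not _wrapped(small)
        assert abs(small[-1] - stable.offset_phase) < 0.05
        # large kick: full rotation, then relock
        large = _iterate_offsets(net, z + np.array([0.0, -2.5]), 60)
        assert _wrapped(large)
        assert abs(large[-1] - stable.offset_phase) < 0.05

    def test_locked_offset_matches_simulation(self):
        net = timing_preset("timing-monostable")
        stable = [s for s in phase_locked_states(net) if s.stable][0]
        _, _, spikes = simulate_phase_network(net, 5000.0, seed=4)
        _, off = relative_phase_series(spikes.of_neuron(0), spikes.of_neuron(1))
        late = 2 * np.pi * off[-60:]
        z = np.exp(1j * late).mean()
        assert np.abs(z) > 0.99  # converged
        measured = np.angle(z) % (2 * np.pi) / (2 * np.pi)
        assert measured == pytest.approx(stable.offset_fraction, abs=0.02)


def _iterate_offsets(net, z, rounds):
    out = []
    for _ in range(rounds):
        z = np.asarray(lock_section_map(net, (z[0], np.mod(z[1], 2 * np.pi))))
        out.append(z[1])
    return np.array(out)


def _wrapped(seq):
    return bool(np.any(np.abs(np.diff(seq)) > 3.0))


class TestRelativePhase:
    def test_synchronous_trains_have_zero_offsets(self):
        t = np.arange(10.0)
        _, off = relative_phase_series(t, t)
        assert np.allclose(np.minimum(off, 1 - off), 0.0, atol=1e-9)

    def test_antiphase_trains_half_period(self):
        t = np.arange(10.0)
        _, off = relative_phase_series(t, t + 0.5)
        assert np.allclose(off, 0.5)

    def test_too_few_spikes_empty(self):
        _, off = relative_phase_series(np.array([1.0]), np.array([1.0, 2.0]))
        assert off.size == 0
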