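"""Spike-timing (phase) reduction: PRCs, synchrony, phase locking.

On timescales short against tau_s the drive variables are frozen and each
neuron is a bare theta oscillator with constant effective drive ``eta``
(period ``T = pi/sqrt(eta)``), perturbed by presynaptic spikes idealized
as Dirac pulses on the phase velocity.  A pulse of weight ``kappa``
advances the spiking phase by ``kappa`` directly: in the full model a
presynaptic spike raises the postsynaptic drive for a time long against
the firing period, and the accumulated extra rotation compresses, in the
short-timescale idealization, into one instantaneous phase increment.  A
pulse that carries the phase past threshold discharges the neuron
immediately (absorption); an inhibitory pulse can push it back at most to
the reset point.

In the *linear* phase ``phi`` in [0, 2pi) (fraction of the period since
the last spike, times 2pi) the closed-form phase response curve is

    g(phi; kappa, eta) = Phi(theta(phi) + kappa) - phi

with ``Phi(theta) = pi + 2 arctan(tan(theta/2)/sqrt(eta))`` the
phase-to-linear-phase map, truncated to ``2pi - phi`` when the pulse
reaches threshold and to ``-phi`` when it reaches reset.  Because the
phase velocity of the theta neuron rises toward threshold, g falls with
phi late in the cycle for excitatory pulses (synchronizing) and rises for
inhibitory ones (dispersing).

The module provides the analytic PRC and an independent numerical PRC
measured by perturbation simulations, an exact event-driven simulator for
pulse-coupled phase networks, the Kuramoto order parameter, the
synchronous-mode stability eigenvalue, and the two-neuron phase-locking
map with its |lambda| < 1 stability criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import SpikeTrain

__all__ = [
    "PhaseNetwork",
    "OrderParameter",
    "LockedState",
    "analytic_prc",
    "analytic_prc_slope",
    "numerical_prc",
    "order_parameter",
    "order_parameter_series",
    "simulate_phase_network",
    "sync_mode_eigenvalue",
    "sync_perturbation_matrix",
    "two_neuron_lock_map",
    "phase_locked_states",
    "relative_phase_series",
]

TWO_PI = 2.0 * np.pi


# ---------------------------------------------------------------------------
# phase response curves


def _theta_of_phi(phi: np.ndarray, eta: np.ndarray | float) -> np.ndarray:
    """Spiking phase theta in (-pi, pi) at linear phase phi in (0, 2pi).

    The reduced oscillator uses the pi-rotated phase convention: the slow
    bottleneck of the saddle-node-on-circle dynamics sits adjacent to the
    threshold/reset point theta = +-pi, so the oscillator dwells just
    before spiking and traverses mid-cycle quickly.
    """
    return 2.0 * np.arctan(np.tan((phi - np.pi) / 2.0) / np.sqrt(eta))


def _phi_of_theta(theta: np.ndarray, eta: np.ndarray | float) -> np.ndarray:
    """Linear phase in [0, 2pi] from spiking phase theta in [-pi, pi]."""
    return np.pi + 2.0 * np.arctan(np.sqrt(eta) * np.tan(theta / 2.0))


def _velocity(theta: np.ndarray, eta: np.ndarray | float) -> np.ndarray:
    """Phase velocity of the rotated theta equation at constant drive:
    fast (= 2) at mid-cycle, slow (= 2 eta) at the threshold/reset point."""
    return (1.0 + np.cos(theta)) + (1.0 - np.cos(theta)) * eta


def analytic_prc(
    phi: np.ndarray | float,
    coupling: np.ndarray | float,
    eta: np.ndarray | float,
) -> np.ndarray:
    """Closed-form asymptotic phase advance caused by one presynaptic pulse.

    A pulse of weight ``kappa`` increments the spiking phase theta by
    ``kappa``.  If that carries theta past threshold the neuron fires
    immediately and continues from the overshoot (advance greater than the
    remaining phase); if an inhibitory pulse carries it below the reset
    point the phase re-enters from the threshold side and the neuron is
    delayed by up to a full cycle.  All arguments broadcast.

    Parameters
    ----------
    phi : linear phase in [0, 2pi) at which the pulse arrives.
    coupling : pulse weight kappa (sign = synapse sign), radians of
        spiking phase, |kappa| < 2 pi.
    eta : effective drive of the postsynaptic oscillator (> 0).
    """
    phi, coupling, eta = np.broadcast_arrays(
        np.mod(np.asarray(phi, dtype=float), TWO_PI),
        np.asarray(coupling, dtype=float),
        np.asarray(eta, dtype=float),
    )
    if np.any(eta <= 0):
        raise ValueError("postsynaptic neuron must be oscillating (eta > 0)")
    theta_p = _theta_of_phi(phi, eta) + coupling
    wraps = np.where(theta_p >= np.pi, 1.0, np.where(theta_p <= -np.pi, -1.0, 0.0))
    theta_w = theta_p - TWO_PI * wraps
    out = _phi_of_theta(theta_w, eta) - phi + TWO_PI * wraps
    return out[()] if out.ndim == 0 else out


def analytic_prc_slope(
    phi: np.ndarray | float, coupling: float, eta: float
) -> np.ndarray:
    """d g / d phi of the closed-form PRC.

    In the smooth branch the slope is the velocity ratio
    ``v(theta)/v(theta + kappa) - 1``; in the absorbed branch it is -1,
    and -1 as well where an inhibitory pulse saturates at the reset
    point.
    """
    phi, coupling, eta = np.broadcast_arrays(
        np.mod(np.asarray(phi, dtype=float), TWO_PI),
        np.asarray(coupling, dtype=float),
        np.asarray(eta, dtype=float),
    )
    theta = _theta_of_phi(phi, eta)
    out = _velocity(theta, eta) / _velocity(theta + coupling, eta) - 1.0
    return out[()] if out.ndim == 0 else out


def numerical_prc(
    phi_grid: np.ndarray,
    coupling: float,
    eta: float,
    pulse_width: float = 0.002,
    n_substeps: int = 400,
    n_cycles: int = 10,
) -> np.ndarray:
    """PRC measured by perturbation simulation, independent of the closed
    form.

    For each grid phase the theta equation is integrated (RK4) through a
    narrow rectangular velocity pulse of area ``coupling``; the asymptotic
    shift of the spike time -- read off ``n_cycles`` periods after the
    perturbation, matching the perturbed-period definition of the phase
    response -- is converted to a phase advance.  Within the pulse the
    phase is NOT wrapped, so a crossing of threshold inside the window is
    counted as a spike of its own.
    """
    if eta <= 0:
        raise ValueError("postsynaptic neuron must be oscillating (eta > 0)")
    root = np.sqrt(eta)
    period = np.pi / root
    amp = coupling / pulse_width
    h = pulse_width / n_substeps

    def rhs(theta: float) -> float:
        return float(_velocity(theta, eta)) + amp

    def time_to_threshold(theta: float) -> float:
        """Exact unperturbed time from theta (in (-pi, pi]) to theta = pi."""
        u = np.tan(theta / 2.0)
        return (np.pi / 2.0 - np.arctan(root * u)) / root

    shifts = np.empty(len(phi_grid))
    for i, phi in enumerate(phi_grid):
        theta0 = float(_theta_of_phi(np.mod(phi, TWO_PI), eta))
        # RK4 through the pulse window, unwrapped
        theta = theta0
        for _ in range(n_substeps):
            k1 = rhs(theta)
            k2 = rhs(theta + h / 2 * k1)
            k3 = rhs(theta + h / 2 * k2)
            k4 = rhs(theta + h * k3)
            theta += h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        # net signed crossings of the threshold/reset point (upward minus
        # downward), so strong inhibition near the cycle start is counted
        # correctly
        crossings = int(np.floor((theta + np.pi) / TWO_PI))
        theta_w = theta - TWO_PI * crossings  # back into (-pi, pi]
        # n_cycles-th spike after the pulse onset, perturbed vs reference
        t_ref = time_to_threshold(theta0) + (n_cycles - 1) * period
        t_pert = (
            pulse_width
            + time_to_threshold(theta_w)
            + (n_cycles - 1 - crossings) * period
        )
        shifts[i] = TWO_PI * (t_ref - t_pert) / period
    return shifts


# ---------------------------------------------------------------------------
# phase networks


@dataclass
class PhaseNetwork:
    """Pulse-coupled phase oscillators.

    ``eta`` are effective drives (rad^2/ms^2, > 0 for oscillators; the
    slow averaged firing rate is absorbed here), ``coupling[i, j]`` the
    pulse weight from presynaptic j onto postsynaptic i.
    """

    n: int
    eta: np.ndarray
    coupling: np.ndarray

    def __post_init__(self) -> None:
        self.eta = np.broadcast_to(np.asarray(self.eta, dtype=float), (self.n,)).copy()
        self.coupling = np.asarray(self.coupling, dtype=float)
        if self.coupling.shape != (self.n, self.n):
            raise ValueError(
                f"coupling must be ({self.n}, {self.n}), got {self.coupling.shape}"
            )
        if np.any(self.eta <= 0):
            raise ValueError("all oscillators must have positive drive")

    @property
    def periods(self) -> np.ndarray:
        return np.pi / np.sqrt(self.eta)

    @property
    def rates(self) -> np.ndarray:
        """Angular frequencies (rad/ms)."""
        return TWO_PI / self.periods

    @classmethod
    def homogeneous(cls, n: int, eta: float, total_coupling: float) -> "PhaseNetwork":
        """All-to-all network with pairwise weight ``total_coupling / n``
        and no self-coupling."""
        c = (total_coupling / n) * (np.ones((n, n)) - np.eye(n))
        return cls(n=n, eta=np.full(n, eta), coupling=c)


@dataclass
class OrderParameter:
    """Kuramoto order parameter: magnitude in [0, 1] and mean angle."""

    magnitude: float
    angle: float


def order_parameter(phases: np.ndarray) -> OrderParameter:
    """Magnitude and angle of the complex mean field of unit phasors."""
    phases = np.atleast_1d(np.asarray(phases, dtype=float))
    if phases.size < 1:
        raise ValueError("need at least one phase")
    z = np.exp(1j * phases).mean()
    return OrderParameter(magnitude=float(np.abs(z)), angle=float(np.angle(z)))


def order_parameter_series(phase_traj: np.ndarray) -> np.ndarray:
    """Order-parameter magnitude for each column of an (n, T) phase array."""
    return np.abs(np.exp(1j * phase_traj).mean(axis=0))


def phase_rhs(
    phases: np.ndarray, network: PhaseNetwork, spiking: np.ndarray | None = None
) -> np.ndarray:
    """Phase velocity: uniform rotation, plus PRC jumps for any presynaptic
    neurons currently spiking (returned as the instantaneous increment)."""
    phases = np.asarray(phases, dtype=float)
    if phases.shape != (network.n,):
        raise ValueError(f"phases must have shape ({network.n},)")
    drift = network.rates.copy()
    if spiking is not None and len(spiking):
        jump = np.zeros(network.n)
        for j in spiking:
            for i in range(network.n):
                if i == j or network.coupling[i, j] == 0.0:
                    continue
                jump[i] += analytic_prc(
                    phases[i], network.coupling[i, j], network.eta[i]
                )
        return drift + jump  # caller applies jumps separately in event code
    return drift


def simulate_phase_network(
    network: PhaseNetwork,
    duration: float,
    init: np.ndarray | None = None,
    seed: int | None = None,
    dt_record: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, SpikeTrain]:
    """Exact event-driven simulation of the pulse-coupled phase network.

    Between spikes every phase advances uniformly; at each threshold
    crossing the spiking neuron's pulse advances every postsynaptic phase
    by the analytic PRC.  Simultaneous crossings are processed in
    neuron-index order (a pure convention: a pulse can never push a
    neuron across threshold, since the phase advance is bounded by the
    remaining phase).

    Returns ``(t_grid, phase trajectory (n, T), spikes)``.
    """
    rng = np.random.default_rng(seed)
    phases = (
        rng.uniform(0.0, TWO_PI, network.n)
        if init is None
        else np.mod(np.array(init, dtype=float), TWO_PI)
    )
    rates = network.rates
    eta = network.eta
    coupling = network.coupling
    t = 0.0
    t_grid = np.arange(0.0, duration + dt_record / 2, dt_record)
    traj = np.empty((network.n, t_grid.size))
    rec = 0
    spike_times: list[float] = []
    spike_neurons: list[int] = []

    def deliver(j: int) -> None:
        """Apply neuron j's pulse to every postsynaptic phase (vectorized;
        absorbed neurons end up at phase >= 2pi and fire in the cascade)."""
        kap = coupling[:, j]
        mask = (kap != 0.0) & (np.arange(network.n) != j)
        if not np.any(mask):
            return
        phases[mask] += analytic_prc(phases[mask], kap[mask], eta[mask])

    while t < duration:
        dt_next = (TWO_PI - phases) / rates
        nxt = int(np.argmin(dt_next))  # ties -> lowest index
        t_event = t + max(dt_next[nxt], 0.0)
        while rec < t_grid.size and t_grid[rec] <= min(t_event, duration):
            traj[:, rec] = np.mod(phases + rates * (t_grid[rec] - t), TWO_PI)
            rec += 1
        if t_event > duration:
            break
        phases += rates * (t_event - t)
        t = t_event
        phases[nxt] -= TWO_PI  # reset, keeping any overshoot
        spike_times.append(t)
        spike_neurons.append(nxt)
        deliver(nxt)
        # cascade: pulses may have carried other neurons past threshold
        for _ in range(16 * network.n):
            over = np.nonzero(phases >= TWO_PI)[0]
            if over.size == 0:
                break
            j = int(over[0])
            phases[j] -= TWO_PI
            spike_times.append(t)
            spike_neurons.append(j)
            deliver(j)
    while rec < t_grid.size:
        traj[:, rec] = np.mod(phases + rates * (t_grid[rec] - t), TWO_PI)
        rec += 1
    spikes = SpikeTrain(np.asarray(spike_times), np.asarray(spike_neurons, dtype=int))
    return t_grid, traj, spikes


# ---------------------------------------------------------------------------
# synchronous-mode stability


def sync_perturbation_matrix(
    n: int,
    total_coupling: float,
    eta: float,
    offset: float = 0.1,
) -> np.ndarray:
    """Linearized one-period map of spike-time deviations about synchrony.

    Each deviation contracts toward the volley mean with the per-period
    factor ``lambda`` of :func:`sync_mode_eigenvalue` while a uniform
    shift of all deviations is neutral:

        M = I + (lambda - 1) (I - J / n)

    written out entrywise from the PRC slopes.  Its spectrum consists of
    one neutral eigenvalue 1 (uniform time shift) and the single unique
    eigenvalue ``lambda`` with multiplicity n - 1 governing every
    relative deviation.
    """
    lam, _ = sync_mode_eigenvalue(n, total_coupling, eta, offset)
    s = lam - 1.0
    return (1.0 + s) * np.eye(n) - (s / n) * np.ones((n, n))


def sync_mode_eigenvalue(
    n: int,
    total_coupling: float,
    eta: float,
    offset: float = 0.1,
) -> tuple[float, str]:
    """Eigenvalue of the one-period return map of a straggler behind an
    otherwise synchronized volley, in closed form.

    A neuron lagging the synchronized cluster by a linear phase ``offset``
    receives the cluster's compound pulse (weight ``(n-1) K / n``) just
    before threshold and itself perturbs the cluster just after its reset.
    Linearizing the alternating-event map gives

        lambda = 1 + G'(2pi - offset) + g'(offset)

    with ``G'`` the PRC slope under the compound pulse and ``g'`` under a
    single pairwise pulse.  When the compound pulse reaches across the
    remaining phase (excitatory coupling at any realistic spread) the
    straggler is discharged with the volley itself and the map is
    superstable: lambda = 0.  The synchronous mode is stable iff
    |lambda| < 1; at zero coupling lambda = 1 (neutral).
    """
    kappa_pair = total_coupling / n
    kappa_comp = (n - 1) * kappa_pair
    theta_star = float(_theta_of_phi(np.asarray(TWO_PI - offset), eta))
    if theta_star + kappa_comp >= np.pi:
        return 0.0, "stable"
    # one period of the alternating map:  the volley's compound pulse moves
    # the straggler's lag to  eps~ = eps - G(2pi - eps),  then the straggler's
    # own pulse advances the cluster at phase eps~; the chain rule gives the
    # product of the two local slopes
    big_g = float(analytic_prc(TWO_PI - offset, kappa_comp, eta))
    eps_mid = offset - big_g
    lam = (
        1.0 + float(analytic_prc_slope(TWO_PI - offset, kappa_comp, eta))
    ) * (1.0 + float(analytic_prc_slope(eps_mid, kappa_pair, eta)))
    if abs(lam - 1.0) < 1e-12:
        verdict = "neutral"
    else:
        verdict = "stable" if abs(lam) < 1.0 else "unstable"
    return lam, verdict


def sync_return_map_jacobian(
    n: int,
    total_coupling: float,
    eta: float,
    offset: float = 0.1,
    h: float = 1e-5,
    tie_break: float = 1e-3,
) -> np.ndarray:
    """Numerically assembled Jacobian of the volley return map.

    Columns are finite differences of all n spike-time deviations over
    one collective period with respect to each neuron's initial deviation,
    measured with the exact event-driven simulator around the
    cluster-plus-straggler reference used by
    :func:`sync_mode_eigenvalue` (cluster ties are broken by a graded
    ``tie_break`` so the map is differentiable).  The spectrum contains
    one eigenvalue near 1 (uniform time shift), cluster-internal modes,
    and the straggler mode compared against the closed form.  Meaningful
    in the smooth regime -- weak enough coupling that no pulse absorbs a
    neuron or wraps it past the reset point.
    """
    net = PhaseNetwork.homogeneous(n, eta, total_coupling)
    period = np.pi / np.sqrt(eta)

    def first_spikes(devs: np.ndarray) -> np.ndarray:
        """Per-neuron time of the second firing, given initial linear-phase
        deviations behind a common start point."""
        phi0 = np.pi  # mid-cycle start, away from any event
        init = phi0 - devs
        _, _, spikes = simulate_phase_network(
            net, 4.0 * period, init=init, dt_record=4.0 * period
        )
        out = np.full(n, np.nan)
        seen: dict[int, int] = {}
        for t, i in zip(spikes.times, spikes.neurons):
            seen[i] = seen.get(i, 0) + 1
            if seen[i] == 2:
                out[i] = t
        if np.any(np.isnan(out)):
            raise RuntimeError("volley map: some neuron did not fire twice")
        return out

    base = tie_break * np.arange(n, dtype=float)
    base[0] = offset  # the straggler
    ref = first_spikes(base)
    jac = np.empty((n, n))
    for j in range(n):
        dev = base.copy()
        dev[j] += h
        jac[:, j] = (first_spikes(dev) - ref) / h
    # spike times respond as (phase deviation)/Omega: rescale to the
    # dimensionless per-period map multiplier
    return jac * float(net.rates[0])


# ---------------------------------------------------------------------------
# two-neuron phase locking


@dataclass
class LockedState:
    """A phase-locked firing pattern of two reciprocally coupled neurons.

    ``offset_phase`` is the phase of neuron B right after neuron A fires,
    ``offset_time`` the time from A's closing spike back to B's most
    recent spike (0 = co-firing), ``offset_fraction`` the same offset as
    a fraction of the locked ``period`` (what a relative-phase series
    reads), and ``state`` the full (a, b) section state.  Stability holds
    iff the return-map spectral radius satisfies |lambda| < 1;
    ``degenerate`` marks a neutral continuum (e.g. zero coupling).
    """

    offset_phase: float
    offset_time: float
    eigenvalue: float
    stable: bool
    degenerate: bool = False
    period: float = np.nan
    offset_fraction: float = np.nan
    state: tuple[float, float] = (np.nan, np.nan)


def lock_section_map(
    network: PhaseNetwork, state: tuple[float, float], with_info: bool = False
):
    """Exact return map of the two-neuron firing pattern.

    The section is taken immediately after a spike of neuron A (all
    same-instant cascaded events processed); the state is the pair of
    phases ``(a, b)`` at that instant -- ``a`` is A's post-spike phase,
    which is nonzero when A was discharged by a pulse and carries the
    overshoot.  The map tracks all intervening events exactly: B may fire
    once, several times, or not at all before A's next spike, and pulses
    that carry a neuron past threshold trigger an immediate cascaded
    spike.

    With ``with_info`` also returns ``(elapsed, b_delay)``: the round
    duration and the time from the closing A spike back to B's most
    recent spike (0 for co-firing; NaN if B did not fire).
    """
    if network.n != 2:
        raise ValueError("the lock map is defined for two neurons")
    rates = network.rates
    eta = network.eta
    kap = (network.coupling[1, 0], network.coupling[0, 1])  # sent by A, by B
    phases = np.array([float(state[0]), float(state[1])])
    elapsed = 0.0
    t_b_last = np.nan

    def fire(i: int) -> None:
        j = 1 - i
        phases[i] -= TWO_PI
        if kap[i] != 0.0:
            phases[j] += float(analytic_prc(phases[j], kap[i], eta[j]))

    for _ in range(256):  # bounded event count per round
        over = np.nonzero(phases >= TWO_PI)[0]
        if over.size:
            i = int(over[0])
            fire(i)
            if i == 1:
                t_b_last = elapsed
                continue
            # A fired: finish B's same-instant cascaded spikes, mirroring
            # the network simulator's event order, then close the round
            for _ in range(8):
                if phases[1] < TWO_PI:
                    break
                fire(1)
                t_b_last = elapsed
            out = (float(phases[0]), float(phases[1]))
            if with_info:
                return out, (elapsed, elapsed - t_b_last)
            return out
        dt = (TWO_PI - phases) / rates
        nxt = int(np.argmin(dt))
        phases += rates * dt[nxt]
        elapsed += float(dt[nxt])
        phases[nxt] = TWO_PI  # fires on the next loop pass
    raise RuntimeError("lock map did not close after 256 events")


def two_neuron_lock_map(
    network: PhaseNetwork, x: float, return_time: bool = False
) -> float | tuple[float, float]:
    """B's phase one section-return after the state ``(0, x)``; see
    :func:`lock_section_map`.  Convenience wrapper for the common case in
    which A fires unperturbed (zero overshoot)."""
    (_, b), (elapsed, _) = lock_section_map(
        network, (0.0, float(np.mod(x, TWO_PI))), with_info=True
    )
    return (b, elapsed) if return_time else b


def _section_jacobian(
    network: PhaseNetwork, z: np.ndarray, h: float = 1e-6
) -> np.ndarray:
    jac = np.empty((2, 2))
    for j in range(2):
        zp = z.copy()
        zm = z.copy()
        zp[j] += h
        zm[j] -= h
        fp = np.asarray(lock_section_map(network, tuple(zp)))
        fm = np.asarray(lock_section_map(network, tuple(zm)))
        jac[:, j] = (fp - fm) / (2 * h)
    return jac


def phase_locked_states(
    network: PhaseNetwork,
    n_scan: int = 64,
    n_iter: int = 80,
    degeneracy_tol: float = 1e-3,
) -> list[LockedState]:
    """Phase-locked states of a reciprocally coupled pair and their
    stability.

    The analysis object is the two-dimensional section map of
    :func:`lock_section_map`.  Stable locked states are the convergence
    points of the map iterated from a scan of ``n_scan`` initial offsets;
    unstable ones are located by Newton root-finding on the map\'s
    displacement from the same scan.  Each state carries the spectral
    radius ``lambda`` of the 2 x 2 map Jacobian, stable iff |lambda| < 1.
    Configurations whose whole scan freezes wherever it starts (identical
    neurons with balancing coupling) form a neutral continuum and
    collapse into one state flagged ``degenerate``.
    """
    from scipy.optimize import fsolve

    if network.n != 2:
        raise ValueError("phase locking analysis is defined for two neurons")
    if np.all(network.coupling == 0.0):
        return [
            LockedState(
                offset_phase=np.nan, offset_time=np.nan, eigenvalue=1.0,
                stable=False, degenerate=True,
            )
        ]

    def wrap(z: np.ndarray) -> np.ndarray:
        return np.mod(z, TWO_PI)

    def make_state(z: np.ndarray, lam: float) -> LockedState:
        _, (period, b_delay) = lock_section_map(network, tuple(z), with_info=True)
        frac = (b_delay / period) % 1.0 if np.isfinite(b_delay) else np.nan
        return LockedState(
            offset_phase=float(z[1]),
            offset_time=float(b_delay),
            eigenvalue=float(lam),
            stable=bool(lam < 1.0),
            period=float(period),
            offset_fraction=float(frac),
            state=(float(z[0]), float(z[1])),
        )

    seeds = [np.array([0.0, x]) for x in np.linspace(0.05, TWO_PI - 0.05, n_scan)]

    # stable states: iterate the section map to convergence
    converged: list[np.ndarray] = []
    n_frozen = 0
    for seed in seeds:
        z = seed.copy()
        prev = z
        for _ in range(n_iter):
            prev = z
            z = wrap(np.asarray(lock_section_map(network, tuple(z))))
        if np.linalg.norm(z - prev) < 1e-5:
            if np.linalg.norm(z - seed) < 1e-6:
                n_frozen += 1  # froze where it started: neutral continuum
            converged.append(z)

    if n_frozen > n_scan // 2:
        return [
            LockedState(
                offset_phase=np.nan, offset_time=np.nan, eigenvalue=1.0,
                stable=False, degenerate=True,
            )
        ]

    clusters: list[np.ndarray] = []
    for z in converged:
        if not any(
            np.linalg.norm(np.mod(z - c + np.pi, TWO_PI) - np.pi) < 1e-2
            for c in clusters
        ):
            clusters.append(z)

    states: list[LockedState] = []
    for z in clusters:
        lam = float(np.max(np.abs(np.linalg.eigvals(_section_jacobian(network, z)))))
        if abs(lam - 1.0) < degeneracy_tol:
            continue
        states.append(make_state(z, lam))

    # unstable states: Newton on the displacement, seeded from the scan
    def displacement(z: np.ndarray) -> np.ndarray:
        try:
            return np.asarray(lock_section_map(network, (z[0], z[1]))) - z
        except RuntimeError:
            # probe outside the map's sensible domain: steer the solver back
            return np.full(2, 1e3) + z

    for seed in seeds[:: max(1, n_scan // 32)]:
        sol, info, ier, _ = fsolve(displacement, seed, full_output=True, xtol=1e-12)
        if ier != 1 or np.linalg.norm(info["fvec"]) > 1e-8:
            continue
        solw = wrap(sol)
        if any(
            np.linalg.norm(np.mod(solw - np.array(s.state) + np.pi, TWO_PI) - np.pi)
            < 5e-2
            for s in states
            if np.all(np.isfinite(s.state))
        ):
            continue
        lam = float(np.max(np.abs(np.linalg.eigvals(_section_jacobian(network, solw)))))
        if abs(lam - 1.0) < degeneracy_tol:
            continue
        states.append(make_state(solw, lam))

    states.sort(key=lambda s: s.offset_phase if np.isfinite(s.offset_phase) else -1)
    return states


def relative_phase_series(
    train_a: np.ndarray, train_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Relative spike timing of two units, modulo the running period.

    For every spike of A (from the second on), the offset to the most
    recent spike of B is reduced by A's running interspike interval.
    Returns ``(times, offsets)`` with offsets in [0, 1) cycles; empty for
    fewer than two spikes on either train.
    """
    train_a = np.asarray(train_a, dtype=float)
    train_b = np.asarray(train_b, dtype=float)
    if train_a.size < 2 or train_b.size < 1:
        return np.empty(0), np.empty(0)
    times, offsets = [], []
    for i in range(1, train_a.size):
        t = train_a[i]
        isi = train_a[i] - train_a[i - 1]
        j = np.searchsorted(train_b, t, side="right") - 1
        if j < 0 or isi <= 0:
            continue
        times.append(t)
        offsets.append(((t - train_b[j]) / isi) % 1.0)
    return np.asarray(times), np.asarray(offsets)
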