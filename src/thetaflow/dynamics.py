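"""The full spiking network model.

Each neuron carries two state variables: a phase ``theta`` on the circle
[0, 2pi) describing the spike generator, and a synaptic-drive variable
``omega`` (units rad^2 ms^-2) that is kicked up by the neuron's own spikes
and relaxes with timescale ``tau_s``.  ``omega`` acts as a running proxy for
the neuron's firing rate; the directed coupling ``c_ij`` (from presynaptic j
to postsynaptic i) feeds the presynaptic drives into the postsynaptic
phase velocity.

The phase equation is the theta-neuron (SNIC) normal form

    tau_theta * dtheta_i/dt = (1 - cos theta_i) + (1 + cos theta_i) * rho_i
    rho_i = I_i + sum_j c_ij * omega_j

A spike is the upward crossing of ``theta = pi``; the phase simply continues
around the circle (threshold pi, reset -pi = pi on the circle).  At each of
its own spikes, neuron i's drive jumps by ``k * (b - omega_i)`` -- the area
of an idealized Dirac synaptic pulse with saturation level ``b`` -- and
between spikes decays as

    d omega_i/dt = -omega_i / tau_s.

For suprathreshold constant drive ``rho > 0`` the phase equation integrates
in closed form to the period ``T = pi * tau_theta / sqrt(rho)``; a negative
radicand means an infinite period (quiescent neuron), adopting the
convention that the square root of a negative radicand is zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "THETA_SPIKE",
    "NetworkParams",
    "InputSchedule",
    "SpikeTrain",
    "SimulationResult",
    "theta_rhs",
    "omega_rhs",
    "spike_increment",
    "closed_form_period",
    "firing_rate",
    "simulate_network",
    "random_initial_state",
]

#: Phase at which a spike is emitted (threshold; the reset value -pi is the
#: same point of the circle, so the phase continues smoothly).
THETA_SPIKE = np.pi


class DimensionError(ValueError):
    """Raised when state / parameter dimensions do not match."""


@dataclass
class NetworkParams:
    """Parameters of a spiking theta-neuron network.

    Parameters
    ----------
    n : int
        Number of neurons.
    coupling : (n, n) ndarray
        Directed weights ``c_ij``: row = postsynaptic i, column =
        presynaptic j.
    tau_s : float, default 20.0
        Synaptic-drive relaxation timescale, ms.
    k : float, default 0.1
        Strength of the effect of one spike on the neuron's own drive
        (dimensionless fraction of the remaining headroom ``b - omega``).
    b : float, default 1.0
        Saturation level of the synaptic drive, rad^2 ms^-2.
    tau_theta : float, default 1.0
        Fast timescale of the phase equation, ms.
    """

    n: int
    coupling: np.ndarray
    tau_s: float = 20.0
    k: float = 0.1
    b: float = 1.0
    tau_theta: float = 1.0

    def __post_init__(self) -> None:
        self.coupling = np.asarray(self.coupling, dtype=float)
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if self.tau_s <= 0:
            raise ValueError(f"tau_s must be > 0, got {self.tau_s}")
        if self.tau_theta <= 0:
            raise ValueError(f"tau_theta must be > 0, got {self.tau_theta}")
        if self.coupling.shape != (self.n, self.n):
            raise DimensionError(
                f"coupling must be ({self.n}, {self.n}), got {self.coupling.shape}"
            )
        if not np.all(np.isfinite(self.coupling)):
            raise ValueError("coupling contains non-finite entries")


@dataclass
class InputSchedule:
    """Piecewise-constant per-neuron drive ``I_i(t)``.

    ``breakpoints`` are strictly increasing times (ms) delimiting segments;
    ``values`` has one row per segment and one column per neuron.  Segment
    ``s`` applies on ``[breakpoints[s], breakpoints[s+1])``; the final
    segment extends to the end of the simulation.
    """

    breakpoints: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.breakpoints = np.atleast_1d(np.asarray(self.breakpoints, dtype=float))
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if np.any(np.diff(self.breakpoints) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if self.values.shape[0] != self.breakpoints.size:
            raise ValueError(
                "values must have one row per breakpoint: "
                f"{self.values.shape[0]} rows vs {self.breakpoints.size} breakpoints"
            )

    @classmethod
    def constant(cls, drive: np.ndarray | float, n: int) -> "InputSchedule":
        """A time-independent drive (scalar broadcast over neurons)."""
        vec = np.broadcast_to(np.asarray(drive, dtype=float), (n,))
        return cls(np.array([0.0]), vec[None, :].copy())

    def __call__(self, t: float) -> np.ndarray:
        idx = int(np.searchsorted(self.breakpoints, t, side="right") - 1)
        idx = max(idx, 0)
        return self.values[idx]


@dataclass
class SpikeTrain:
    """Ordered (time, neuron) spike events."""

    times: np.ndarray
    neurons: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.neurons = np.asarray(self.neurons, dtype=int)
        if self.times.shape != self.neurons.shape:
            raise ValueError("times and neurons must have equal length")
        if self.times.size and np.any(np.diff(self.times) < 0):
            raise ValueError("spike times must be nondecreasing")

    def __len__(self) -> int:
        return self.times.size

    def of_neuron(self, i: int) -> np.ndarray:
        """Spike times of neuron ``i``."""
        return self.times[self.neurons == i]

    def isis(self, i: int) -> np.ndarray:
        """Interspike intervals of neuron ``i``."""
        return np.diff(self.of_neuron(i))


@dataclass
class SimulationResult:
    """Trajectories and spikes from :func:`simulate_network`."""

    t: np.ndarray
    theta: np.ndarray  # (n, T)
    omega: np.ndarray  # (n, T)
    spikes: SpikeTrain
    dt: float
    seed: int | None = None
    params: NetworkParams | None = None
    mode_means: np.ndarray | None = field(default=None, repr=False)


def _effective_drive(
    omega: np.ndarray, params: NetworkParams, external: np.ndarray
) -> np.ndarray:
    return external + params.coupling @ omega


def theta_rhs(
    theta: np.ndarray,
    omega: np.ndarray,
    params: NetworkParams,
    external: np.ndarray,
) -> np.ndarray:
    """Phase velocity ``dtheta/dt`` of every neuron.

    The coupling enters as the weighted sum over presynaptic drives,
    ``rho_i = I_i + sum_j c_ij omega_j``, multiplying the ``1 + cos theta``
    term of the theta-neuron equation.
    """
    theta = np.asarray(theta, dtype=float)
    omega = np.asarray(omega, dtype=float)
    if theta.shape != (params.n,) or omega.shape != (params.n,):
        raise DimensionError(
            f"state must have shape ({params.n},); got theta {theta.shape}, "
            f"omega {omega.shape}"
        )
    rho = _effective_drive(omega, params, np.asarray(external, dtype=float))
    return ((1.0 - np.cos(theta)) + (1.0 + np.cos(theta)) * rho) / params.tau_theta


def omega_rhs(omega: np.ndarray, params: NetworkParams) -> np.ndarray:
    """Smooth part of the drive dynamics: relaxation with timescale tau_s.

    Spike-triggered jumps are applied separately (see
    :func:`spike_increment`); between spikes the drive decays exponentially.
    """
    omega = np.asarray(omega, dtype=float)
    if omega.shape != (params.n,):
        raise DimensionError(f"omega must have shape ({params.n},), got {omega.shape}")
    return -omega / params.tau_s


def spike_increment(omega: float | np.ndarray, params: NetworkParams) -> np.ndarray:
    """Jump of the drive variable at one of the neuron's own spikes.

    The Dirac synaptic pulse is applied as the instantaneous increment
    ``k * (b - omega)``: a fixed fraction of the remaining headroom below
    the saturation level, so repeated spikes drive omega toward ``b``
    without overshooting.
    """
    return params.k * (params.b - np.asarray(omega, dtype=float))


def closed_form_period(rho: float | np.ndarray, tau_theta: float = 1.0) -> np.ndarray:
    """Oscillation period (ms) at constant effective drive ``rho``.

    Integrating ``tau_theta dtheta / [(1-cos theta) + (1+cos theta) rho]``
    over one cycle gives ``T = pi tau_theta / sqrt(rho)``.  For a negative
    radicand the square root is taken to be zero: the period is infinite
    and the neuron is quiescent.
    """
    rho = np.asarray(rho, dtype=float)
    with np.errstate(divide="ignore"):
        out = np.where(rho > 0.0, np.pi * tau_theta / np.sqrt(np.maximum(rho, 0.0)), np.inf)
    return out[()] if out.ndim == 0 else out


def firing_rate(rho: float | np.ndarray, tau_theta: float = 1.0) -> np.ndarray:
    """Firing rate (spikes/ms): reciprocal period, zero below threshold."""
    rho = np.asarray(rho, dtype=float)
    out = np.where(rho > 0.0, np.sqrt(np.maximum(rho, 0.0)) / (np.pi * tau_theta), 0.0)
    return out[()] if out.ndim == 0 else out


def random_initial_state(
    params: NetworkParams, seed: int | None, omega_scale: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded random initial condition: uniform phases, small positive drives."""
    rng = np.random.default_rng(seed)
    theta0 = rng.uniform(0.0, 2.0 * np.pi, size=params.n)
    omega0 = omega_scale * rng.uniform(0.0, 1.0, size=params.n)
    return theta0, omega0


def simulate_network(
    params: NetworkParams,
    schedule: InputSchedule,
    init: tuple[np.ndarray, np.ndarray] | None = None,
    duration: float = 1000.0,
    dt: float = 0.05,
    seed: int | None = None,
    record_stride: int = 1,
) -> SimulationResult:
    """Integrate the spiking network with fixed-step RK4 + event handling.

    The smooth part of the flow is advanced with classical RK4; within each
    step, upward crossings of ``theta = pi`` are located by linear
    interpolation (the phase velocity at pi equals ``2 / tau_theta``
    regardless of drive, so crossings are always transversal and upward).
    The crossing neuron's drive then receives the saturating pulse
    increment.  Deterministic given ``init`` (or ``seed``), the schedule
    and the step.

    Parameters
    ----------
    init : (theta0, omega0) or None
        Initial state; if None, drawn from :func:`random_initial_state`
        with ``seed``.
    record_stride : int
        Store every ``record_stride``-th step in the trajectory arrays
        (spike times are always exact to within the step).
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if duration < dt:
        raise ValueError("duration must be at least one step")
    if init is None:
        theta, omega = random_initial_state(params, seed)
    else:
        theta = np.array(init[0], dtype=float)
        omega = np.array(init[1], dtype=float)
    if theta.shape != (params.n,) or omega.shape != (params.n,):
        raise DimensionError("initial state has wrong shape")
    theta = np.mod(theta, 2.0 * np.pi)

    n_steps = int(round(duration / dt))
    rec_idx = range(0, n_steps + 1, record_stride)
    n_rec = len(rec_idx)
    t_rec = np.empty(n_rec)
    theta_rec = np.empty((params.n, n_rec))
    omega_rec = np.empty((params.n, n_rec))
    spike_times: list[float] = []
    spike_neurons: list[int] = []

    def rhs(t: float, th: np.ndarray, om: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ext = schedule(t)
        return theta_rhs(th, om, params, ext), omega_rhs(om, params)

    r = 0
    if 0 in rec_idx:
        t_rec[r], theta_rec[:, r], omega_rec[:, r] = 0.0, theta, omega
        r += 1

    two_pi = 2.0 * np.pi
    for step in range(n_steps):
        t = step * dt
        k1t, k1o = rhs(t, theta, omega)
        k2t, k2o = rhs(t + dt / 2, theta + dt / 2 * k1t, omega + dt / 2 * k1o)
        k3t, k3o = rhs(t + dt / 2, theta + dt / 2 * k2t, omega + dt / 2 * k2o)
        k4t, k4o = rhs(t + dt, theta + dt * k3t, omega + dt * k3o)
        theta_new = theta + dt / 6 * (k1t + 2 * k2t + 2 * k3t + k4t)
        omega_new = omega + dt / 6 * (k1o + 2 * k2o + 2 * k3o + k4o)

        if not (np.all(np.isfinite(theta_new)) and np.all(np.isfinite(omega_new))):
            raise FloatingPointError(
                f"non-finite state at t = {t + dt:.3f} ms; reduce dt or check inputs"
            )

        # spike = upward crossing of pi within the step (phases advance by
        # far less than one turn per step at sane dt, so a single test on
        # the unwrapped increment suffices)
        crossed = (theta < THETA_SPIKE) & (theta_new >= THETA_SPIKE)
        if np.any(crossed):
            idx = np.nonzero(crossed)[0]
            frac = (THETA_SPIKE - theta[idx]) / (theta_new[idx] - theta[idx])
            for neuron, f in sorted(zip(idx, frac), key=lambda p: p[1]):
                spike_times.append(t + float(f) * dt)
                spike_neurons.append(int(neuron))
            omega_new[idx] += spike_increment(omega_new[idx], params)

        theta = np.mod(theta_new, two_pi)
        omega = omega_new
        if (step + 1) in rec_idx:
            t_rec[r], theta_rec[:, r], omega_rec[:, r] = (step + 1) * dt, theta, omega
            r += 1

    order = np.argsort(spike_times, kind="stable")
    spikes = SpikeTrain(
        np.asarray(spike_times)[order] if spike_times else np.empty(0),
        np.asarray(spike_neurons)[order] if spike_neurons else np.empty(0, dtype=int),
    )
    return SimulationResult(
        t=t_rec, theta=theta_rec, omega=omega_rec, spikes=spikes, dt=dt, seed=seed,
        params=params,
    )
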