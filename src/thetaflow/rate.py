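"""Firing-rate reduction, mode analysis, nullclines, and flow labels.

Replacing each neuron's own spike train by its mean firing rate
``f(rho) = sqrt(rho)_+ / (pi tau_theta)`` turns the spiking network into
the closed rate system

    d omega_i / dt = -omega_i / tau_s + k (b - omega_i) f(I_i + sum_j c_ij omega_j)

whose slow flow in the (omega_1, ..., omega_n) space carries the network's
emergent dynamics.  The optional *simplified* variant drops the square root
(``f = rho_+ / (pi tau_theta)``), which preserves the qualitative flow in
the operating regime and makes the 3-node phase reduction tractable.

This module provides the right-hand side, the homogeneous-mode fixed point
and its stability eigenvalues, two-node nullclines with polynomial fits,
the spiking-vs-rate reduction error, and a protocol-based classifier that
labels a system's flow as FIXED_POINT, LIMIT_CYCLE, BISTABLE, MONOSTABLE
or MULTISTABLE.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, fsolve

from .dynamics import InputSchedule, NetworkParams, SpikeTrain, simulate_network

__all__ = [
    "RateSystem",
    "FlowClass",
    "FixedPoint",
    "FlowReport",
    "rate_rhs",
    "integrate_rate",
    "mode_fixed_point",
    "mode_eigenvalues",
    "mode_eigenvalue",
    "find_fixed_points",
    "numerical_jacobian",
    "nullclines",
    "fit_polynomial_nullclines",
    "polynomial_intersections",
    "surrogate_omega_trace",
    "reduction_error",
    "classify_flow",
]


@dataclass
class RateSystem:
    """A firing-rate network: same dimensions and parameters as the
    spiking network it reduces, plus a constant input vector and the
    ``simplified`` (square-root-dropped) flag."""

    n: int
    coupling: np.ndarray
    input: np.ndarray
    tau_s: float = 20.0
    k: float = 0.1
    b: float = 1.0
    tau_theta: float = 1.0
    simplified: bool = False

    def __post_init__(self) -> None:
        self.coupling = np.asarray(self.coupling, dtype=float)
        self.input = np.broadcast_to(
            np.asarray(self.input, dtype=float), (self.n,)
        ).copy()
        if self.coupling.shape != (self.n, self.n):
            raise ValueError(
                f"coupling must be ({self.n}, {self.n}), got {self.coupling.shape}"
            )

    @classmethod
    def from_network(
        cls, params: NetworkParams, input: np.ndarray | float, simplified: bool = False
    ) -> "RateSystem":
        return cls(
            n=params.n,
            coupling=params.coupling,
            input=np.broadcast_to(np.asarray(input, dtype=float), (params.n,)).copy(),
            tau_s=params.tau_s,
            k=params.k,
            b=params.b,
            tau_theta=params.tau_theta,
            simplified=simplified,
        )

    def to_network(self) -> NetworkParams:
        return NetworkParams(
            n=self.n, coupling=self.coupling, tau_s=self.tau_s, k=self.k,
            b=self.b, tau_theta=self.tau_theta,
        )

    def rate(self, rho: np.ndarray) -> np.ndarray:
        """Mean firing rate as a function of effective drive (clipped at
        zero below threshold)."""
        rho = np.asarray(rho, dtype=float)
        pos = np.maximum(rho, 0.0)
        if self.simplified:
            return pos / (np.pi * self.tau_theta)
        return np.sqrt(pos) / (np.pi * self.tau_theta)

    def rate_derivative(self, rho: np.ndarray) -> np.ndarray:
        """d rate / d drive, zero below threshold."""
        rho = np.asarray(rho, dtype=float)
        if self.simplified:
            return np.where(rho > 0.0, 1.0 / (np.pi * self.tau_theta), 0.0)
        with np.errstate(divide="ignore"):
            d = 1.0 / (2.0 * np.pi * self.tau_theta * np.sqrt(np.maximum(rho, 1e-300)))
        return np.where(rho > 0.0, d, 0.0)


def rate_rhs(omega: np.ndarray, system: RateSystem) -> np.ndarray:
    """Time derivative of the drive vector under the rate reduction."""
    omega = np.asarray(omega, dtype=float)
    if omega.shape != (system.n,):
        raise ValueError(f"omega must have shape ({system.n},), got {omega.shape}")
    rho = system.input + system.coupling @ omega
    return -omega / system.tau_s + system.k * (system.b - omega) * system.rate(rho)


def numerical_jacobian(
    system: RateSystem, omega: np.ndarray, eps: float = 1e-7
) -> np.ndarray:
    """Central finite-difference Jacobian of :func:`rate_rhs`."""
    omega = np.asarray(omega, dtype=float)
    jac = np.empty((system.n, system.n))
    for j in range(system.n):
        dv = np.zeros(system.n)
        dv[j] = eps
        jac[:, j] = (rate_rhs(omega + dv, system) - rate_rhs(omega - dv, system)) / (
            2 * eps
        )
    return jac


def integrate_rate(
    system: RateSystem,
    omega0: np.ndarray,
    duration: float,
    dt_out: float = 1.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the rate equations; returns ``(t, omega)`` with omega of
    shape (n, len(t))."""
    t_eval = np.arange(0.0, duration + dt_out / 2, dt_out)
    sol = solve_ivp(
        lambda _t, w: rate_rhs(w, system),
        (0.0, float(t_eval[-1])),
        np.asarray(omega0, dtype=float),
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
        method="RK45",
    )
    if not sol.success:  # pragma: no cover - solver failure is exceptional
        raise RuntimeError(f"rate integration failed: {sol.message}")
    return sol.t, sol.y


# ---------------------------------------------------------------------------
# homogeneous-mode analysis


def _homogeneous_system(
    global_coupling: float, n: int, input: float, k: float, tau_s: float,
    b: float, tau_theta: float,
) -> RateSystem:
    return RateSystem(
        n=n, coupling=np.full((n, n), global_coupling), input=np.full(n, input),
        tau_s=tau_s, k=k, b=b, tau_theta=tau_theta,
    )


def mode_fixed_point(
    global_coupling: float,
    n: int,
    input: float = 0.0,
    k: float = 0.1,
    tau_s: float = 20.0,
    b: float = 1.0,
    tau_theta: float = 1.0,
) -> float:
    """Homogeneous steady state omega* of a globally coupled network.

    With identical coupling ``c`` everywhere and identical input, all nodes
    share the nullcline equation

        omega / tau_s = k (b - omega) f(I + n c omega)

    and must all be equal; the largest nonnegative solution (the active
    mode when one exists, the quiescent state otherwise) is returned by
    bracketed root finding on [0, b].
    """
    sys1 = _homogeneous_system(global_coupling, n, input, k, tau_s, b, tau_theta)

    def g(w: float) -> float:
        return float(rate_rhs(np.full(n, w), sys1)[0])

    grid = np.linspace(0.0, b, 201)
    vals = np.array([g(w) for w in grid])
    roots = [0.0] if abs(vals[0]) < 1e-14 else []
    for lo, hi, vlo, vhi in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if vlo == 0.0 and lo not in roots:
            roots.append(lo)
        elif vlo * vhi < 0.0:
            roots.append(brentq(g, lo, hi, xtol=1e-14))
    if abs(vals[-1]) < 1e-14:
        roots.append(b)
    if not roots:
        # g(0) > 0 and g(b) < 0 always bracket a root, so this is unreachable
        # unless parameters are pathological
        raise ValueError("no mode fixed point found on [0, b]")
    return float(max(roots))


def mode_eigenvalues(
    global_coupling: float,
    n: int,
    input: float = 0.0,
    k: float = 0.1,
    tau_s: float = 20.0,
    b: float = 1.0,
    tau_theta: float = 1.0,
) -> tuple[float, float]:
    """Closed-form spectrum of the homogeneous-mode Jacobian.

    At the homogeneous fixed point the Jacobian is
    ``mu I + k (b - omega*) f'(rho*) c J`` with ``J`` the all-ones matrix
    and ``mu = -1/tau_s - k f(rho*)``, so there are n - 1 degenerate
    eigenvalues equal to ``mu`` (transverse, mode-forming directions) and a
    single unique eigenvalue

        lambda_u = mu + n c k (b - omega*) f'(rho*)

    along the uniform direction, which determines the stability of the
    collective mode.  Returns ``(lambda_unique, lambda_degenerate)``.
    """
    omega_star = mode_fixed_point(global_coupling, n, input, k, tau_s, b, tau_theta)
    sys1 = _homogeneous_system(global_coupling, n, input, k, tau_s, b, tau_theta)
    rho = input + n * global_coupling * omega_star
    mu = -1.0 / tau_s - k * float(sys1.rate(np.array(rho)))
    lam_u = mu + n * global_coupling * k * (b - omega_star) * float(
        sys1.rate_derivative(np.array(rho))
    )
    return lam_u, mu


def mode_eigenvalue(
    global_coupling: float,
    n: int,
    input: float = 0.0,
    k: float = 0.1,
    tau_s: float = 20.0,
    b: float = 1.0,
    tau_theta: float = 1.0,
) -> float:
    """The unique (uniform-direction) eigenvalue; see
    :func:`mode_eigenvalues`."""
    return mode_eigenvalues(global_coupling, n, input, k, tau_s, b, tau_theta)[0]


# ---------------------------------------------------------------------------
# fixed points, nullclines, classification


@dataclass
class FixedPoint:
    omega: np.ndarray
    eigenvalues: np.ndarray
    stable: bool


class FlowClass(str, enum.Enum):
    FIXED_POINT = "FIXED_POINT"
    LIMIT_CYCLE = "LIMIT_CYCLE"
    BISTABLE = "BISTABLE"
    MONOSTABLE = "MONOSTABLE"
    MULTISTABLE = "MULTISTABLE"
    UNCLASSIFIED = "UNCLASSIFIED"


@dataclass
class FlowReport:
    classification: FlowClass
    fixed_points: list[FixedPoint]
    log: list[str] = field(default_factory=list)
    evidence: dict = field(default_factory=dict)

    @property
    def stable_fixed_points(self) -> list[FixedPoint]:
        return [fp for fp in self.fixed_points if fp.stable]

    def to_text(self) -> str:
        lines = [f"classification: {self.classification.value}"]
        for fp in self.fixed_points:
            kind = "stable" if fp.stable else "unstable"
            w = " ".join(f"{x: .6f}" for x in fp.omega)
            ev = " ".join(f"{x.real: .5f}{x.imag:+.5f}j" for x in fp.eigenvalues)
            lines.append(f"fixed_point [{kind}] omega=({w}) eig=({ev})")
        lines += [f"log: {entry}" for entry in self.log]
        return "\n".join(lines) + "\n"


def find_fixed_points(
    system: RateSystem,
    box: tuple[float, float] | None = None,
    seeds_per_axis: int = 20,
    dedup_tol: float = 1e-6,
    residual_tol: float = 1e-9,
) -> list[FixedPoint]:
    """Global fixed-point search: dense grid of Newton seeds, deduplicated.

    The grid spans ``box`` (default [0, b]) along every axis; converged
    roots with residual below ``residual_tol`` are kept, deduplicated with
    tolerance ``dedup_tol``, and equipped with Jacobian eigenvalues.
    """
    lo, hi = box if box is not None else (0.0, system.b)
    axes = np.linspace(lo, hi, seeds_per_axis)
    grids = np.meshgrid(*([axes] * system.n), indexing="ij")
    seeds = np.stack([g.ravel() for g in grids], axis=1)
    found: list[np.ndarray] = []
    for w0 in seeds:
        sol, info, ier, _ = fsolve(
            lambda w: rate_rhs(w, system), w0, full_output=True, xtol=1e-12
        )
        if ier != 1 or np.linalg.norm(info["fvec"]) > residual_tol:
            continue
        if any(np.linalg.norm(sol - f) < dedup_tol for f in found):
            continue
        if np.any(sol < lo - 0.2 * (hi - lo)) or np.any(sol > hi + 0.2 * (hi - lo)):
            continue
        found.append(sol)
    out = []
    for sol in sorted(found, key=lambda s: tuple(np.round(s, 8))):
        eig = np.linalg.eigvals(numerical_jacobian(system, sol))
        out.append(FixedPoint(sol, eig, bool(np.all(eig.real < -1e-9))))
    return out


def nullclines(
    system: RateSystem,
    box: tuple[float, float, float, float] = (0.0, 1.0, 0.0, 1.0),
    resolution: int = 400,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Zero-level sets of the two components of the rate flow (n = 2).

    Returns ``(curves_1, curves_2)``: for each component, a list of ordered
    (m, 2) polylines in (omega_1, omega_2) coordinates extracted by
    marching squares on a ``resolution x resolution`` grid over
    ``box = (x_min, x_max, y_min, y_max)``.
    """
    if system.n != 2:
        raise ValueError("nullclines are defined for two-node systems")
    from skimage import measure

    x_min, x_max, y_min, y_max = box
    if not (x_max > x_min and y_max > y_min):
        raise ValueError("empty bounding box")
    x = np.linspace(x_min, x_max, resolution)
    y = np.linspace(y_min, y_max, resolution)
    xx, yy = np.meshgrid(x, y, indexing="ij")
    pts = np.stack([xx.ravel(), yy.ravel()], axis=1)
    rho = system.input[None, :] + pts @ system.coupling.T
    f = system.rate(rho)
    dw = -pts / system.tau_s + system.k * (system.b - pts) * f
    comps = dw.reshape(resolution, resolution, 2)

    out: list[list[np.ndarray]] = []
    dx = (x_max - x_min) / (resolution - 1)
    dy = (y_max - y_min) / (resolution - 1)
    for c in range(2):
        curves = []
        for contour in measure.find_contours(comps[:, :, c], 0.0):
            curve = np.empty_like(contour)
            curve[:, 0] = x_min + contour[:, 0] * dx
            curve[:, 1] = y_min + contour[:, 1] * dy
            curves.append(curve)
        out.append(curves)
    return out[0], out[1]


def fit_polynomial_nullclines(
    curves: list[np.ndarray],
    degree: int,
    window: tuple[float, float] | None = None,
) -> list[np.polynomial.Polynomial]:
    """Least-squares polynomial fit omega_2(omega_1) to sampled nullclines.

    Each polyline is fitted independently over its own omega_1 range
    (optionally restricted to ``window``); returns one Polynomial per
    curve.  Degree-0 fits a constant exactly for constant curves.
    """
    fits = []
    for curve in curves:
        pts = curve
        if window is not None:
            mask = (curve[:, 0] >= window[0]) & (curve[:, 0] <= window[1])
            pts = curve[mask]
        if pts.shape[0] < degree + 1:
            raise ValueError(
                f"need at least degree+1 = {degree + 1} samples, got {pts.shape[0]}"
            )
        fits.append(np.polynomial.Polynomial.fit(pts[:, 0], pts[:, 1], degree))
    return fits


def polynomial_intersections(
    p1: np.polynomial.Polynomial,
    p2: np.polynomial.Polynomial,
    window: tuple[float, float],
) -> np.ndarray:
    """Real intersection abscissae of two fitted curves inside a window."""
    # fitted polynomials carry their own scaled domains; compare in the
    # common power basis
    diff = p1.convert() - p2.convert()
    roots = diff.roots()
    real = roots[np.abs(roots.imag) < 1e-8].real
    return np.sort(real[(real >= window[0]) & (real <= window[1])])


# ---------------------------------------------------------------------------
# reduction error (rate approximation vs explicit spike trains)


def surrogate_omega_trace(
    rate: float,
    duration: float,
    dt: float,
    kind: str,
    k: float = 0.1,
    b: float = 1.0,
    tau_s: float = 20.0,
    omega0: float = 0.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Drive trace of one neuron receiving a surrogate spike train.

    ``kind`` is one of ``"mean-rate"`` (continuous mean-field term),
    ``"equal-isi"`` (deterministic train at the given rate) or
    ``"poisson"`` (seeded Poisson train at the given rate).  Exact
    exponential decay between events.
    """
    t = np.arange(0.0, duration + dt / 2, dt)
    if kind == "mean-rate":
        omega = np.empty_like(t)
        omega[0] = omega0
        w = omega0
        for i in range(1, t.size):
            # exact sub-step for the linear ODE  w' = -w/tau_s + k (b - w) r
            a = 1.0 / tau_s + k * rate
            w = (w - k * b * rate / a) * np.exp(-a * dt) + k * b * rate / a
            omega[i] = w
        return t, omega
    if kind == "equal-isi":
        if rate <= 0:
            times = np.empty(0)
        else:
            isi = 1.0 / rate
            times = np.arange(isi, duration, isi)
    elif kind == "poisson":
        rng = np.random.default_rng(seed)
        if rate <= 0:
            times = np.empty(0)
        else:
            n_exp = int(rate * duration * 3 + 50)
            gaps = rng.exponential(1.0 / rate, size=n_exp)
            times = np.cumsum(gaps)
            times = times[times < duration]
    else:
        raise ValueError(f"unknown surrogate kind: {kind!r}")
    omega = np.empty_like(t)
    w = omega0
    prev = 0.0
    j = 0
    for i, ti in enumerate(t):
        while j < times.size and times[j] <= ti:
            w *= np.exp(-(times[j] - prev) / tau_s)
            w += k * (b - w)
            prev = times[j]
            j += 1
        omega[i] = w * np.exp(-(ti - prev) / tau_s)
    return t, omega


def reduction_error(
    omega_a: np.ndarray, omega_b: np.ndarray, floor: float = -12.0
) -> float:
    """log10 of the summed squared difference between two drive traces.

    Identical traces report the ``floor`` value (standing in for -inf).
    """
    omega_a = np.asarray(omega_a, dtype=float)
    omega_b = np.asarray(omega_b, dtype=float)
    if omega_a.shape != omega_b.shape:
        raise ValueError(
            f"trace shapes differ: {omega_a.shape} vs {omega_b.shape}"
        )
    sse = float(np.sum((omega_a - omega_b) ** 2))
    if sse <= 10.0 ** floor:
        return floor
    return float(np.log10(sse))


# ---------------------------------------------------------------------------
# flow classification


def _oscillation_metrics(
    t: np.ndarray, traj: np.ndarray, transient: float
) -> tuple[float, float | None]:
    """Peak-to-peak amplitude and autocorrelation period of the late part
    of a trajectory (first component with the largest swing)."""
    mask = t >= transient
    late = traj[:, mask]
    swing = late.max(axis=1) - late.min(axis=1)
    comp = late[int(np.argmax(swing))]
    amp = float(comp.max() - comp.min())
    x = comp - comp.mean()
    if x.size < 8 or np.allclose(x, 0.0):
        return amp, None
    ac = np.correlate(x, x, mode="full")[x.size - 1 :]
    ac /= ac[0] if ac[0] > 0 else 1.0
    # first local max after the first zero crossing marks a repeating period
    below = np.nonzero(ac < 0)[0]
    if below.size == 0:
        return amp, None
    start = below[0]
    rest = ac[start:]
    peak = int(np.argmax(rest)) + start
    if ac[peak] < 0.2:
        return amp, None
    dt_grid = float(t[1] - t[0])
    return amp, peak * dt_grid


def _kick_directions(n: int, rng: np.random.Generator, count: int = 8) -> np.ndarray:
    """Perturbation directions: the uniform circle for planar systems,
    seeded random unit vectors otherwise."""
    if n == 2:
        ang = np.linspace(0.0, 2.0 * np.pi, count, endpoint=False)
        return np.stack([np.cos(ang), np.sin(ang)], axis=1)
    dirs = rng.normal(size=(count, n))
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


def kick_return_time(
    system: RateSystem,
    fp: np.ndarray,
    kick: float,
    directions: np.ndarray,
    duration: float,
    radius: float,
) -> float:
    """Longest time to settle back into a ball around the fixed point.

    A flow with a separatrix near the fixed point answers a suprathreshold
    kick with a large transient -- a loop through distant phase space or a
    slow dwell near a fixed-point ghost -- so the time to re-enter (and
    stay inside) a ball of ``radius`` greatly exceeds the direct
    relaxation time, which is bounded by a few tau_s in this model family.
    """
    best = 0.0
    for direction in directions:
        w0 = np.clip(fp + kick * direction, 0.0, None)
        if np.linalg.norm(w0 - fp) < 1e-9:
            continue
        t, y = integrate_rate(system, w0, duration, dt_out=1.0)
        dist = np.linalg.norm(y - fp[:, None], axis=0)
        outside = np.nonzero(dist >= radius)[0]
        if outside.size and outside[-1] == dist.size - 1:
            best = max(best, float(duration))  # never settled
        elif outside.size:
            best = max(best, float(t[outside[-1] + 1]))
    return best


def classify_flow(
    system: RateSystem,
    seed: int = 0,
    box: tuple[float, float] | None = None,
    seeds_per_axis: int = 12,
    transient_factor: float = 10.0,
    osc_amplitude_tol: float = 1e-3,
    small_kick: float = 0.01,
    large_kicks: tuple[float, ...] = (0.25, 0.5),
    return_radius: float = 0.1,
    return_time_factor: float = 3.0,
    sim_duration: float | None = None,
) -> FlowReport:
    """Label the flow of a rate system by a root-finding + perturbation
    protocol.

    1. Global fixed-point search with linear stability.
    2. No stable fixed point + sustained late-time oscillation (peak-to-peak
       above ``osc_amplitude_tol`` with a repeating autocorrelation period
       after a transient of ``transient_factor * tau_s``) -> LIMIT_CYCLE.
    3. Two / more stable fixed points -> BISTABLE / MULTISTABLE.
    4. One stable fixed point: kick it by 1% (return check) and by large
       fractions of the saturation level ``b`` (the attractor scale).  If
       some suprathreshold kick produces a transient that takes longer than
       ``return_time_factor * tau_s`` to settle back into a ball of radius
       ``return_radius * b`` (see :func:`kick_return_time`, the separatrix
       signature), the flow is MONOSTABLE; otherwise FIXED_POINT.
    """
    rng = np.random.default_rng(seed)
    log: list[str] = []
    fps = find_fixed_points(system, box=box, seeds_per_axis=seeds_per_axis)
    stable = [fp for fp in fps if fp.stable]
    log.append(f"fixed points: {len(fps)} total, {len(stable)} stable")
    transient = transient_factor * system.tau_s
    duration = sim_duration if sim_duration is not None else 4.0 * transient
    evidence: dict = {}

    if len(stable) == 0:
        amps = []
        for _ in range(3):
            w0 = rng.uniform(0.0, system.b, size=system.n)
            t, y = integrate_rate(system, w0, duration, dt_out=1.0)
            amp, period = _oscillation_metrics(t, y, transient)
            amps.append((amp, period))
        log.append(f"oscillation metrics: {amps}")
        evidence["oscillation"] = amps
        if any(a > osc_amplitude_tol and p is not None for a, p in amps):
            return FlowReport(FlowClass.LIMIT_CYCLE, fps, log, evidence)
        return FlowReport(FlowClass.UNCLASSIFIED, fps, log, evidence)

    if len(stable) == 2:
        return FlowReport(FlowClass.BISTABLE, fps, log, evidence)
    if len(stable) > 2:
        return FlowReport(FlowClass.MULTISTABLE, fps, log, evidence)

    fp = stable[0]
    directions = _kick_directions(system.n, rng)
    radius = return_radius * system.b
    small = kick_return_time(
        system, fp.omega, small_kick * system.b, directions, duration, radius
    )
    times = {
        kick: kick_return_time(
            system, fp.omega, kick * system.b, directions, duration, radius
        )
        for kick in large_kicks
    }
    log.append(f"return times (ms) small={small:.0f} large={times}")
    evidence["kicks"] = {"small": small, "large": times}
    if max(times.values()) >= return_time_factor * system.tau_s:
        return FlowReport(FlowClass.MONOSTABLE, fps, log, evidence)
    return FlowReport(FlowClass.FIXED_POINT, fps, log, evidence)


# ---------------------------------------------------------------------------
# flow classification from spiking trajectories


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    ker = np.ones(width) / width
    return np.apply_along_axis(lambda r: np.convolve(r, ker, mode="same"), 1, x)


def classify_spiking_flow(
    params: NetworkParams,
    input: np.ndarray | float,
    seed: int = 0,
    duration: float = 1500.0,
    dt: float = 0.05,
    n_initial: int = 3,
    smooth_ms: float = 25.0,
    transient: float = 400.0,
    osc_amplitude_tol: float = 0.1,
    cluster_tol: float = 0.05,
    kicks: tuple[float, ...] = (0.25, 0.5),
    kick_directions: int = 4,
    return_radius: float = 0.1,
    return_time_factor: float = 3.0,
) -> FlowReport:
    """Label the flow of a *spiking* network from its omega trajectories.

    Mirrors the :func:`classify_flow` protocol but judges the smoothed
    synaptic-drive traces of full spiking simulations, so the per-spike
    sawtooth is averaged out before any decision:

    1. Seeded runs from ``n_initial`` random initial conditions; sustained
       smoothed oscillation (peak-to-peak above ``osc_amplitude_tol * b``
       with a repeating autocorrelation period) -> LIMIT_CYCLE.
    2. Distinct settled end states across runs (separated by more than
       ``cluster_tol * b``) -> BISTABLE / MULTISTABLE.
    3. One end state: kicked runs started at the settled drive plus a
       graded kick.  The separatrix signature is a transient that takes
       longer than ``return_time_factor * tau_s`` to settle back into a
       ball of radius ``return_radius * b`` around the settled state
       (judged on the smoothed traces).
    """
    rng = np.random.default_rng(seed)
    ext = np.broadcast_to(np.asarray(input, dtype=float), (params.n,)).copy()
    schedule = InputSchedule.constant(ext, params.n)
    stride = max(int(round(1.0 / dt)), 1)  # record at 1 ms
    width = max(int(round(smooth_ms)), 1)
    log: list[str] = []

    def run(theta0, omega0):
        res = simulate_network(
            params, schedule, init=(theta0, omega0), duration=duration, dt=dt,
            record_stride=stride,
        )
        return res.t, _moving_average(res.omega, width)

    window = duration - transient - 2 * smooth_ms
    ends, metrics = [], []
    for _ in range(n_initial):
        theta0 = rng.uniform(0.0, 2 * np.pi, params.n)
        omega0 = rng.uniform(0.0, 0.6 * params.b, params.n)
        t, om = run(theta0, omega0)
        mask = (t >= transient) & (t <= transient + window)
        late = om[:, mask]
        amp, period = _oscillation_metrics(t[mask], late, t[mask][0])
        metrics.append((amp, period))
        ends.append(late[:, -int(min(100, late.shape[1])) :].mean(axis=1))
    log.append(f"oscillation metrics: {metrics}")
    if any(
        a > osc_amplitude_tol * params.b and p is not None for a, p in metrics
    ):
        return FlowReport(FlowClass.LIMIT_CYCLE, [], log, {"oscillation": metrics})

    clusters: list[np.ndarray] = []
    for e in ends:
        if not any(np.linalg.norm(e - c) < cluster_tol * params.b for c in clusters):
            clusters.append(e)
    log.append(f"settled states: {[c.round(3).tolist() for c in clusters]}")
    if len(clusters) == 2:
        return FlowReport(FlowClass.BISTABLE, [], log, {"clusters": clusters})
    if len(clusters) > 2:
        return FlowReport(FlowClass.MULTISTABLE, [], log, {"clusters": clusters})

    settled = clusters[0]
    directions = _kick_directions(params.n, rng, count=kick_directions)
    radius = return_radius * params.b
    best = 0.0
    for kick in kicks:
        for direction in directions:
            omega0 = np.clip(settled + kick * params.b * direction, 0.0, None)
            if np.linalg.norm(omega0 - settled) < 1e-9:
                continue
            theta0 = rng.uniform(0.0, 2 * np.pi, params.n)
            t, om = run(theta0, omega0)
            mask = t <= duration - 2 * smooth_ms
            dist = np.linalg.norm(om[:, mask] - settled[:, None], axis=0)
            outside = np.nonzero(dist >= radius)[0]
            if outside.size and outside[-1] == dist.size - 1:
                # never came back: a second stationary state (not a slow
                # transient) means the kick crossed into another basin
                tail = om[:, mask][:, -300:]
                stationary = float((tail.max(axis=1) - tail.min(axis=1)).max())
                if stationary < cluster_tol * params.b:
                    log.append(
                        f"kick revealed second attractor at {tail.mean(axis=1).round(3)}"
                    )
                    return FlowReport(
                        FlowClass.BISTABLE, [], log,
                        {"clusters": [settled, tail.mean(axis=1)]},
                    )
                best = max(best, float(duration))
            elif outside.size:
                best = max(best, float(t[mask][outside[-1] + 1]))
    log.append(f"kick return time: {best:.0f} ms")
    if best >= return_time_factor * params.tau_s:
        return FlowReport(FlowClass.MONOSTABLE, [], log, {"return_time": best})
    return FlowReport(FlowClass.FIXED_POINT, [], log, {"return_time": best})
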