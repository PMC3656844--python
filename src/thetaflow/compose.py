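"""The multifunctional 4-mode circuit and the subspace-transition statistic.

Four neural modes share one 25-neuron spiking network.  Mode-level
competition is wired so that different subsets of modes, selected by
inhibiting the others, realize different slow flows: modes (1, 2) are a
winner-take-all pair (bistable), modes (1, 2, 3) an excitable circuit
(monostable), and modes (1, 3, 4) a heteroclinic triple (limit cycle).
Control inputs on a timescale long against tau_s therefore reshape the
effective phase space of one and the same network.

Transitions between flows are detected blindly from the synaptic-drive
traces by a sliding-window principal component analysis: each window
yields the leading eigenvectors of the trace covariance, and the
dissimilarity of consecutive eigenvector sets (sum of squared entries of
``E_a^T E_b - I``) spikes when the active subspace of the network's state
space is reorganized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import ModeSkeleton, expand_skeleton
from .dynamics import InputSchedule, NetworkParams, SimulationResult, simulate_network
from .rate import FlowClass, FlowReport, _kick_directions, _moving_average, \
    _oscillation_metrics

__all__ = [
    "COMPOSED_SKELETON",
    "COMPOSED_ACTIVE_SETS",
    "COMPOSED_ACTIVE_LEVEL",
    "COMPOSED_INHIBITION",
    "composed_skeleton",
    "build_multifunctional",
    "GatingSchedule",
    "fig_schedule",
    "run_schedule",
    "classify_gated",
    "SubspaceSeries",
    "subspace_similarity",
    "sliding_pca",
    "first_component_trace",
]

#: Canonical 4-mode coupling skeleton.  Modes 1/2 inhibit each other at
#: the winner-take-all strength; modes 1/3/4 carry the cyclic asymmetric
#: inhibition of the heteroclinic triple; the free entries close the
#: excitable (monostable) circuit over modes 1/2/3.
COMPOSED_SKELETON = np.array(
    [
        [0.0, -2.5, -4.3, -0.7],
        [-2.5, 0.0, -1.0, -1.0],
        [-0.7, -2.0, 0.0, -4.3],
        [-4.3, -1.0, -0.7, 0.0],
    ]
)

#: Mode subsets realizing each flow when the remaining modes are inhibited.
COMPOSED_ACTIVE_SETS = {
    "bistable": (0, 1),
    "monostable": (0, 1, 2),
    "limit-cycle": (0, 2, 3),
}

#: Drive applied to active modes / inhibition applied to inactive ones.
COMPOSED_ACTIVE_LEVEL = 0.35
COMPOSED_INHIBITION = -0.8


def composed_skeleton(n_neurons: int = 25) -> ModeSkeleton:
    """The canonical skeleton distributed over ``n_neurons`` spiking
    neurons (as even a split as possible)."""
    return ModeSkeleton.even_split(COMPOSED_SKELETON, n_neurons)


def build_multifunctional(
    skeleton: ModeSkeleton | None = None, **params
) -> tuple[NetworkParams, ModeSkeleton]:
    """Expand the mode skeleton into a spiking network.

    Returns ``(network params, skeleton)``; extra keyword arguments are
    passed to :class:`NetworkParams` (tau_s, k, b, ...).
    """
    skeleton = skeleton if skeleton is not None else composed_skeleton()
    if skeleton.n_modes != 4:
        raise ValueError("the multifunctional circuit uses a 4-mode skeleton")
    coupling = expand_skeleton(skeleton)
    return NetworkParams(n=skeleton.n_neurons, coupling=coupling, **params), skeleton


@dataclass
class GatingSchedule:
    """Piecewise-constant per-mode input pattern plus perturbation pulses.

    ``segments`` is a list of ``(t_start, t_end, levels)`` with one level
    per mode (ms; segments must tile the simulated interval);
    ``pulses`` a list of ``(t_start, duration, amplitudes)`` added on top
    of the running segment.
    """

    segments: list[tuple[float, float, np.ndarray]]
    pulses: list[tuple[float, float, np.ndarray]] = field(default_factory=list)

    @property
    def duration(self) -> float:
        return max(t1 for _, t1, _ in self.segments)

    def mode_level(self, t: float) -> np.ndarray:
        for t0, t1, levels in self.segments:
            if t0 <= t < t1:
                out = np.asarray(levels, dtype=float).copy()
                break
        else:
            raise ValueError(f"schedule does not cover t = {t}")
        for t0, dur, amps in self.pulses:
            if t0 <= t < t0 + dur:
                out = out + np.asarray(amps, dtype=float)
        return out

    def to_input_schedule(self, skeleton: ModeSkeleton) -> InputSchedule:
        """Expand the mode-level pattern to a per-neuron input schedule."""
        edges = {t0 for t0, _, _ in self.segments}
        edges |= {t1 for _, t1, _ in self.segments}
        for t0, dur, _ in self.pulses:
            edges |= {t0, t0 + dur}
        breaks = np.array(sorted(e for e in edges if e < self.duration))
        values = []
        for t0 in breaks:
            mode_vals = self.mode_level(float(t0))
            row = np.concatenate(
                [
                    np.full(int(c), mode_vals[m])
                    for m, c in enumerate(skeleton.counts)
                ]
            )
            values.append(row)
        return InputSchedule(breaks, np.array(values))


def fig_schedule(
    active_level: float = COMPOSED_ACTIVE_LEVEL,
    inhibition: float = COMPOSED_INHIBITION,
    pulse_amp: float = 0.8,
    pulse_ms: float = 30.0,
) -> GatingSchedule:
    """The canonical composed-run schedule.

    Limit-cycle flow from 0 ms; the inhibition pattern switches to the
    bistable pair at 500 ms; perturbation pulses at 700 and 1000 ms flip
    the dominant mode; at 1100 ms the monostable circuit is selected and
    a pulse at 1350 ms (on the excitable mode-1 direction) triggers its
    large transient.  Runs to 1600 ms.
    """

    def levels(active: tuple[int, ...]) -> np.ndarray:
        out = np.full(4, inhibition)
        out[list(active)] = active_level
        return out

    return GatingSchedule(
        segments=[
            (0.0, 500.0, levels(COMPOSED_ACTIVE_SETS["limit-cycle"])),
            # mode 2 is released 30 ms late so the bistable pair always
            # enters with mode 1 dominant, making the pulse-driven winner
            # flips deterministic
            (500.0, 530.0, levels((0,))),
            (530.0, 1100.0, levels(COMPOSED_ACTIVE_SETS["bistable"])),
            (1100.0, 1600.0, levels(COMPOSED_ACTIVE_SETS["monostable"])),
        ],
        pulses=[
            (700.0, pulse_ms, pulse_amp * np.array([0.0, 1.0, 0.0, 0.0])),
            (1000.0, pulse_ms, pulse_amp * np.array([1.0, 0.0, 0.0, 0.0])),
            (1350.0, pulse_ms, pulse_amp * np.array([1.0, 0.0, 0.0, 0.0])),
        ],
    )


def mode_mean_fields(
    result: SimulationResult, skeleton: ModeSkeleton
) -> np.ndarray:
    """Per-mode mean synaptic drive, shape (n_modes, T)."""
    return np.stack(
        [result.omega[sl].mean(axis=0) for sl in skeleton.mode_slices()]
    )


def run_schedule(
    params: NetworkParams,
    skeleton: ModeSkeleton,
    schedule: GatingSchedule,
    seed: int | None = 0,
    dt: float = 0.05,
    record_ms: float = 1.0,
    settle_ms: float = 400.0,
) -> SimulationResult:
    """Full spiking simulation under the gated inputs; the per-mode mean
    fields are attached to the result as ``mode_means``.

    A settling run of ``settle_ms`` under the schedule's first segment
    precedes the recorded interval, so the network starts on the first
    flow's attractor rather than at the seeded random state.
    """
    inputs = schedule.to_input_schedule(skeleton)
    stride = max(int(round(record_ms / dt)), 1)
    init = None
    if settle_ms > 0:
        t0, _, levels = schedule.segments[0]
        pre_sched = GatingSchedule(
            segments=[(0.0, settle_ms, levels)]
        ).to_input_schedule(skeleton)
        pre = simulate_network(
            params, pre_sched, duration=settle_ms, dt=dt, seed=seed,
            record_stride=max(int(round(settle_ms / dt)) - 1, 1),
        )
        init = (pre.theta[:, -1], pre.omega[:, -1])
    result = simulate_network(
        params, inputs, init=init, duration=schedule.duration, dt=dt, seed=seed,
        record_stride=stride,
    )
    result.mode_means = mode_mean_fields(result, skeleton)
    return result


def classify_gated(
    active: tuple[int, ...],
    skeleton: ModeSkeleton | None = None,
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
    """Label the flow realized by an active mode subset of the composed
    spiking network (inactive modes inhibited).

    The protocol mirrors the spiking flow classifier, applied to the
    *active-mode mean fields* of the 25-neuron network: seeded runs for
    oscillation and end-state clustering, then graded kicks of the active
    modes' drives with the return-time separatrix criterion.
    """
    skeleton = skeleton if skeleton is not None else composed_skeleton()
    params, skeleton = build_multifunctional(skeleton)
    rng = np.random.default_rng(seed)
    m = len(active)
    levels = np.full(skeleton.n_modes, COMPOSED_INHIBITION)
    levels[list(active)] = COMPOSED_ACTIVE_LEVEL
    schedule = GatingSchedule(segments=[(0.0, duration, levels)])
    inputs = schedule.to_input_schedule(skeleton)
    stride = max(int(round(1.0 / dt)), 1)
    width = max(int(round(smooth_ms)), 1)
    slices = skeleton.mode_slices()
    b = params.b
    log: list[str] = []

    def run(theta0: np.ndarray, mode_omega0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        omega0 = np.zeros(params.n)
        for mode, val in zip(active, mode_omega0):
            omega0[slices[mode]] = val
        res = simulate_network(
            params, inputs, init=(theta0, omega0), duration=duration, dt=dt,
            record_stride=stride,
        )
        means = np.stack([res.omega[slices[mode]].mean(axis=0) for mode in active])
        return res.t, _moving_average(means, width)

    window = duration - transient - 2 * smooth_ms
    ends, metrics = [], []
    for _ in range(n_initial):
        theta0 = rng.uniform(0.0, 2 * np.pi, params.n)
        t, om = run(theta0, rng.uniform(0.0, 0.6 * b, m))
        mask = (t >= transient) & (t <= transient + window)
        late = om[:, mask]
        amp, period = _oscillation_metrics(t[mask], late, t[mask][0])
        metrics.append((amp, period))
        ends.append(late[:, -100:].mean(axis=1))
    log.append(f"oscillation metrics: {metrics}")
    if any(a > osc_amplitude_tol * b and p is not None for a, p in metrics):
        return FlowReport(FlowClass.LIMIT_CYCLE, [], log, {"oscillation": metrics})

    clusters: list[np.ndarray] = []
    for e in ends:
        if not any(np.linalg.norm(e - c) < cluster_tol * b for c in clusters):
            clusters.append(e)
    log.append(f"settled states: {[c.round(3).tolist() for c in clusters]}")
    if len(clusters) == 2:
        return FlowReport(FlowClass.BISTABLE, [], log, {"clusters": clusters})
    if len(clusters) > 2:
        return FlowReport(FlowClass.MULTISTABLE, [], log, {"clusters": clusters})

    settled = clusters[0]
    directions = _kick_directions(m, rng, count=kick_directions)
    radius = return_radius * b
    best = 0.0
    for kick in kicks:
        for direction in directions:
            omega0 = np.clip(settled + kick * b * direction, 0.0, None)
            if np.linalg.norm(omega0 - settled) < 1e-9:
                continue
            t, om = run(rng.uniform(0.0, 2 * np.pi, params.n), omega0)
            mask = t <= duration - 2 * smooth_ms
            dist = np.linalg.norm(om[:, mask] - settled[:, None], axis=0)
            outside = np.nonzero(dist >= radius)[0]
            if outside.size and outside[-1] == dist.size - 1:
                tail = om[:, mask][:, -300:]
                stationary = float((tail.max(axis=1) - tail.min(axis=1)).max())
                if stationary < cluster_tol * b:
                    log.append("kick revealed second attractor")
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


# ---------------------------------------------------------------------------
# sliding-window principal component analysis


@dataclass
class SubspaceSeries:
    """Leading principal subspaces of sliding windows and the
    dissimilarity of consecutive pairs."""

    centers: np.ndarray  # window centers, ms
    bases: list[np.ndarray] = field(repr=False)  # (n, k) orthonormal each
    similarity: np.ndarray = field(default=None)  # len = len(bases) - 1

    def peak_times(self, n_peaks: int = 2, min_separation: float = 120.0):
        """Times of the largest local maxima of the similarity series,
        greedily separated by at least ``min_separation`` ms."""
        centers = 0.5 * (self.centers[1:] + self.centers[:-1])
        s = self.similarity
        order = np.argsort(s)[::-1]
        picked: list[float] = []
        for idx in order:
            t = centers[idx]
            if all(abs(t - p) >= min_separation for p in picked):
                picked.append(float(t))
            if len(picked) == n_peaks:
                break
        return picked


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    """Resolve eigenvector sign ambiguity: largest-|loading| entry positive."""
    out = vecs.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def subspace_similarity(e_a: np.ndarray, e_b: np.ndarray, n_components: int | None = None) -> float:
    """Sum of squared entries of ``E_a^T E_b - I`` over the leading
    components: 0 for identical bases, growing as the subspaces (or the
    order of their axes) reorganize."""
    if n_components is not None:
        e_a = e_a[:, :n_components]
        e_b = e_b[:, :n_components]
    if e_a.shape != e_b.shape:
        raise ValueError(f"basis shapes differ: {e_a.shape} vs {e_b.shape}")
    for e in (e_a, e_b):
        if not np.allclose(e.T @ e, np.eye(e.shape[1]), atol=1e-8):
            raise ValueError("basis columns must be orthonormal")
    d = e_a.T @ e_b - np.eye(e_a.shape[1])
    return float(np.sum(d * d))


def sliding_pca(
    traces: np.ndarray,
    dt_ms: float = 1.0,
    window: float = 160.0,
    overlap: float = 100.0,
    n_components: int = 10,
    smooth_ms: float = 10.0,
) -> SubspaceSeries:
    """Sliding-window PCA of drive traces with consecutive-pair
    dissimilarity.

    ``traces`` is (n, T) sampled every ``dt_ms``; each window of length
    ``window`` ms (advanced by ``window - overlap``) contributes the
    ``n_components`` leading eigenvectors of its covariance, signs fixed
    by the largest-loading convention.  A short moving average
    (``smooth_ms``) suppresses the per-spike sawtooth before the
    covariance is formed, so the windows compare mode-level structure
    rather than spike noise; set it to 0 to disable.
    """
    if overlap >= window:
        raise ValueError("overlap must be smaller than the window")
    if smooth_ms > 0:
        traces = _moving_average(traces, max(int(round(smooth_ms / dt_ms)), 1))
    n, T = traces.shape
    k = min(n_components, n)
    w = int(round(window / dt_ms))
    step = int(round((window - overlap) / dt_ms))
    if w > T:
        raise ValueError("window longer than the record")
    centers, bases = [], []
    for start in range(0, T - w + 1, step):
        seg = traces[:, start : start + w]
        seg = seg - seg.mean(axis=1, keepdims=True)
        cov = seg @ seg.T / (w - 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1][:k]
        bases.append(_fix_signs(evecs[:, order]))
        centers.append((start + w / 2) * dt_ms)
    sims = np.array(
        [subspace_similarity(a, b) for a, b in zip(bases[:-1], bases[1:])]
    )
    return SubspaceSeries(np.asarray(centers), bases, sims)


def first_component_trace(traces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Projection of the traces onto the global first principal
    eigenvector (sign fixed by the largest-loading convention).

    Returns ``(loading vector, score time series)``.
    """
    centered = traces - traces.mean(axis=1, keepdims=True)
    cov = centered @ centered.T / (traces.shape[1] - 1)
    evals, evecs = np.linalg.eigh(cov)
    lead = _fix_signs(evecs[:, [int(np.argmax(evals))]])[:, 0]
    return lead, lead @ centered
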