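"""Canonical parameter sets used across the documentation and tests.

The two-node matrices realizing the four flow classes, the three-node
heteroclinic family, and the composition skeleton are package canonical
examples: each was located once by a parameter exploration of the rate
system and frozen here.  All share the default neuron parameters
(tau_s = 20 ms, k = 0.1, b = 1, tau_theta = 1).
"""

from __future__ import annotations

import numpy as np

from .connectivity import (
    TwoNodeDecomposition,
    further_asymmetry_matrix,
    heteroclinic_matrix,
    two_node_matrix,
)
from .dynamics import NetworkParams
from .rate import RateSystem

__all__ = [
    "TWO_NODE_PRESETS",
    "two_node_preset",
    "HETEROCLINIC_STRENGTH",
    "HETEROCLINIC_INPUT",
    "ALPHA_CYCLE_REDUCED",
    "MONO_REDUCED",
    "ALPHA_CYCLE_FULL",
    "MONO_FULL",
    "three_node_matrix",
    "three_node_system",
]

#: (decomposition, per-node input) for the four two-node flows.  The
#: decomposition parameters are (inter-neuron strength s, self-coupling c,
#: inter-neuron difference a, self-coupling difference d).
TWO_NODE_PRESETS: dict[str, tuple[TwoNodeDecomposition, tuple[float, float]]] = {
    # weak symmetric mutual excitation: single stable rate state
    "fixed-point": (TwoNodeDecomposition(s=0.3, c=0.2, a=0.0, d=0.0), (0.15, 0.15)),
    # activator-inhibitor: node 1 self-excites and drives node 2, which
    # suppresses node 1 -> large-amplitude relaxation oscillation
    "limit-cycle": (TwoNodeDecomposition(s=0.0, c=1.5, a=-2.0, d=1.5), (0.10, 0.00)),
    # symmetric mutual inhibition: winner-take-all pair of states
    "bistable": (TwoNodeDecomposition(s=-2.5, c=0.0, a=0.0, d=0.0), (0.25, 0.25)),
    # activator-inhibitor tuned just below the oscillation onset: one
    # stable state with a separatrix nearby (excitable)
    "monostable": (TwoNodeDecomposition(s=0.9, c=1.1, a=-2.7, d=1.5), (0.29, 0.11)),
}


def two_node_preset(
    name: str, as_network: bool = False
) -> tuple[NetworkParams | RateSystem, np.ndarray]:
    """Canonical two-node system by flow name.

    Returns ``(system, input)`` where ``system`` is a :class:`RateSystem`
    (default) or :class:`NetworkParams` (``as_network=True``).
    """
    if name not in TWO_NODE_PRESETS:
        raise KeyError(
            f"unknown preset {name!r}; choose from {sorted(TWO_NODE_PRESETS)}"
        )
    decomp, inputs = TWO_NODE_PRESETS[name]
    coupling = two_node_matrix(decomp)
    ext = np.asarray(inputs, dtype=float)
    if as_network:
        return NetworkParams(n=2, coupling=coupling), ext
    return RateSystem(n=2, coupling=coupling, input=ext), ext


# --- three-node heteroclinic family ---------------------------------------

#: Mutual-inhibition strength of the canonical 3-node family.
HETEROCLINIC_STRENGTH = -2.5
#: Per-node constant input of the canonical 3-node family.
HETEROCLINIC_INPUT = 0.35

#: Cyclic asymmetry at which the *reduced* (simplified-rate) phase flow is
#: a limit cycle; the symmetric case alpha = 0 has three stable states.
ALPHA_CYCLE_REDUCED = 1.0
#: (alpha, gamma) giving a monostable reduced phase flow.
MONO_REDUCED = (0.2, 1.5)

#: Cyclic asymmetry at which the *full* (square-root) rate system and the
#: spiking network cycle; the full system bifurcates later than the
#: simplified one.
ALPHA_CYCLE_FULL = 1.8
#: (alpha, gamma) giving a monostable full rate system / spiking network.
MONO_FULL = (1.3, 0.5)


def three_node_matrix(alpha: float, gamma: float = 0.0) -> np.ndarray:
    """Canonical 3-node matrix at cyclic asymmetry ``alpha`` and pairwise
    further asymmetry ``gamma`` (strength fixed at the canonical value)."""
    if gamma == 0.0:
        return heteroclinic_matrix(HETEROCLINIC_STRENGTH, alpha)
    return further_asymmetry_matrix(HETEROCLINIC_STRENGTH, alpha, gamma)


# --- spike-timing (two-oscillator) regimes ---------------------------------

#: (eta_A, eta_B, kappa_A<-B, kappa_B<-A) for the three canonical
#: relative-phase regimes of a reciprocally pulse-coupled pair.
TIMING_PRESETS: dict[str, tuple[float, float, float, float]] = {
    # mutual excitation, slight detuning: synchronous firing, absorbed lock
    "synchrony": (0.04, 0.0408, 0.30, 0.30),
    # mixed coupling too weak to hold the detuned pair: the relative phase
    # drifts, oscillating on a timescale slow against the firing period
    "phase-drift": (0.04, 0.0488, -0.05, 0.27),
    # one stable lock with a nearby unstable offset (separatrix): small
    # kicks relock, large kicks produce one slow transient rotation that
    # passes through synchrony before relocking
    "timing-monostable": (0.04, 0.0496, 0.23, -0.30),
}


def timing_preset(name: str):
    """Canonical two-oscillator phase network by regime name."""
    from .timing import PhaseNetwork

    if name not in TIMING_PRESETS:
        raise KeyError(
            f"unknown preset {name!r}; choose from {sorted(TIMING_PRESETS)}"
        )
    ea, eb, kab, kba = TIMING_PRESETS[name]
    return PhaseNetwork(
        2, np.array([ea, eb]), np.array([[0.0, kab], [kba, 0.0]])
    )


#: Total coupling strengths of the 50-oscillator synchronization demo
#: (excitatory -> full synchrony, zero -> free rotation, inhibitory ->
#: dispersal), with common drive ETA_SYNC.
ETA_SYNC = 0.04
SYNC_COUPLINGS = {"positive": 1.0, "zero": 0.0, "negative": -0.5}


def three_node_system(
    alpha: float, gamma: float = 0.0, simplified: bool = True
) -> RateSystem:
    """Canonical 3-node rate system (simplified by default, as used by the
    phase reduction)."""
    return RateSystem(
        n=3,
        coupling=three_node_matrix(alpha, gamma),
        input=np.full(3, HETEROCLINIC_INPUT),
        simplified=simplified,
    )
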