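"""Coupling-matrix constructors and symmetry decomposition.

The coupling matrix is the locus of symmetry breaking: its symmetric part
drives the fast collapse onto a low-dimensional mode, while the
antisymmetric part generates the slow structured flow on that mode.
Orientation is fixed throughout the package as row = postsynaptic,
column = presynaptic (``c_ij`` couples neuron j into neuron i).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "decompose_symmetry",
    "TwoNodeDecomposition",
    "two_node_matrix",
    "decompose_two_node",
    "heteroclinic_matrix",
    "further_asymmetry_matrix",
    "ModeSkeleton",
    "expand_skeleton",
    "read_matrix",
    "write_matrix",
]


def decompose_symmetry(c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a square matrix into symmetric and antisymmetric parts.

    Returns ``(S, A)`` with ``S = (C + C^T)/2``, ``A = (C - C^T)/2``;
    ``S + A`` reproduces the input exactly.
    """
    c = np.asarray(c, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError(f"matrix must be square, got shape {c.shape}")
    s = (c + c.T) / 2.0
    a = (c - c.T) / 2.0
    return s, a


@dataclass
class TwoNodeDecomposition:
    """Four-parameter description of a 2 x 2 coupling matrix.

    ``s``  inter-neuron strength        (symmetric, off-diagonal)
    ``c``  self-coupling strength       (symmetric, diagonal)
    ``a``  inter-neuron difference      (antisymmetric, off-diagonal)
    ``d``  self-coupling difference     (symmetric, diagonal +/-)
    """

    s: float
    c: float
    a: float
    d: float


def two_node_matrix(decomp: TwoNodeDecomposition) -> np.ndarray:
    """Compose the 2 x 2 coupling matrix

        C = c*I + s*[[0,1],[1,0]] + a*[[0,1],[-1,0]] + d*[[1,0],[0,-1]]
          = [[c + d, s + a], [s - a, c - d]]

    ``a = d = 0`` gives a symmetric matrix; the composition is the exact
    inverse of :func:`decompose_two_node`.
    """
    s, c, a, d = decomp.s, decomp.c, decomp.a, decomp.d
    return np.array([[c + d, s + a], [s - a, c - d]], dtype=float)


def decompose_two_node(mat: np.ndarray) -> TwoNodeDecomposition:
    """Recover (s, c, a, d) from a 2 x 2 matrix (exact round-trip)."""
    mat = np.asarray(mat, dtype=float)
    if mat.shape != (2, 2):
        raise ValueError(f"expected a 2x2 matrix, got {mat.shape}")
    return TwoNodeDecomposition(
        s=(mat[0, 1] + mat[1, 0]) / 2.0,
        c=(mat[0, 0] + mat[1, 1]) / 2.0,
        a=(mat[0, 1] - mat[1, 0]) / 2.0,
        d=(mat[0, 0] - mat[1, 1]) / 2.0,
    )


#: Cyclic antisymmetric pattern: 1 -> 2 -> 3 -> 1 favoured for alpha > 0.
_CYCLIC = np.array(
    [[0.0, -1.0, 1.0], [1.0, 0.0, -1.0], [-1.0, 1.0, 0.0]]
)


def heteroclinic_matrix(s: float, alpha: float) -> np.ndarray:
    """Fully coupled 3-node matrix with cyclic asymmetry.

        C = s * (J - I) + alpha * [[0,-1,1],[1,0,-1],[-1,1,0]]

    With inhibitory strength (``s < 0``) the symmetric part supports
    winner-take-all multistability among the three nodes; the circulant
    antisymmetric part of degree ``alpha`` tilts the competition into a
    cyclic (heteroclinic) rotation 1 -> 2 -> 3 -> 1.  ``alpha = 0`` gives
    an exactly symmetric matrix.
    """
    j = np.ones((3, 3)) - np.eye(3)
    return s * j + alpha * _CYCLIC


def further_asymmetry_matrix(s: float, alpha: float, gamma: float) -> np.ndarray:
    """3-node matrix with an extra pairwise asymmetry on top of the cycle.

    Adds ``gamma`` antisymmetrically to the (1, 2) pair only, breaking the
    three-fold rotation symmetry of :func:`heteroclinic_matrix`;
    ``gamma = 0`` reduces to it exactly.  At suitable (s, alpha, gamma)
    the reduced phase flow is monostable: one stable fixed point with a
    separatrix (a near-degenerate zero-crossing pair) nearby.
    """
    extra = np.zeros((3, 3))
    extra[0, 1] += gamma
    extra[1, 0] -= gamma
    return heteroclinic_matrix(s, alpha) + extra


@dataclass
class ModeSkeleton:
    """Mode-level coupling matrix plus per-mode neuron counts."""

    coupling: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.coupling = np.asarray(self.coupling, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        m = self.coupling.shape[0]
        if self.coupling.shape != (m, m):
            raise ValueError("skeleton coupling must be square")
        if self.counts.shape != (m,):
            raise ValueError(
                f"need one neuron count per mode: {self.counts.shape} vs {m} modes"
            )
        if np.any(self.counts <= 0):
            raise ValueError("per-mode neuron counts must be positive")

    @property
    def n_modes(self) -> int:
        return self.coupling.shape[0]

    @property
    def n_neurons(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def even_split(cls, coupling: np.ndarray, n_neurons: int) -> "ModeSkeleton":
        """Distribute ``n_neurons`` as evenly as possible over the modes,
        giving the remainder to the first modes."""
        coupling = np.asarray(coupling, dtype=float)
        m = coupling.shape[0]
        base, extra = divmod(n_neurons, m)
        counts = np.full(m, base, dtype=int)
        counts[:extra] += 1
        return cls(coupling, counts)

    def mode_slices(self) -> list[slice]:
        edges = np.concatenate([[0], np.cumsum(self.counts)])
        return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


def expand_skeleton(skeleton: ModeSkeleton) -> np.ndarray:
    """Expand a mode-level skeleton into a full neuron-level matrix.

    Every neuron of mode p receives from every neuron of mode q the weight
    ``skeleton[p, q] / counts[q]``: dividing by the presynaptic block size
    makes the mode mean fields of the expanded network obey the skeleton's
    own rate equations, so the skeleton IS the mean-field model of its
    expansion.
    """
    blocks = skeleton.mode_slices()
    n = skeleton.n_neurons
    full = np.empty((n, n))
    for p, sp in enumerate(blocks):
        for q, sq in enumerate(blocks):
            full[sp, sq] = skeleton.coupling[p, q] / skeleton.counts[q]
    return full


def write_matrix(path: str | Path, mat: np.ndarray) -> None:
    """Write a coupling matrix as whitespace-delimited text."""
    mat = np.atleast_2d(np.asarray(mat, dtype=float))
    header = "rows=post cols=pre"
    np.savetxt(path, mat, header=header)


def read_matrix(path: str | Path) -> np.ndarray:
    """Read a whitespace-delimited coupling matrix written by
    :func:`write_matrix` (or any plain text matrix)."""
    mat = np.atleast_2d(np.loadtxt(path))
    if mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{path}: coupling matrix must be square, got {mat.shape}")
    return mat
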