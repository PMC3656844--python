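"""Reduction of the 3-node rate network to a scalar phase flow.

A fully coupled three-node network with cyclic asymmetric coupling is the
smallest network carrying a heteroclinic cycle.  Its slow flow lives on a
plane: the right singular vectors of the antisymmetric coupling component
split state space into a normal direction (the uniform mode, for a cyclic
asymmetry) and the two in-plane directions.  Transforming the in-plane
dynamics to polar coordinates and replacing the radius and the normal
coordinate by their phase averages leaves a single 2pi-periodic equation
``dphi/dt = F(phi)`` whose zeros are the winner-take-all states.  As the
cyclic asymmetry grows the zeros annihilate pairwise and the flow
bifurcates from multistability to a limit cycle; a further pairwise
asymmetry instead leaves one stable zero with a separatrix remnant nearby
(monostable / excitable flow).

The module also provides the two-dimensional excitable reference system
(position / velocity with a cubic restoring nullcline) whose bistable,
limit-cycle and monostable regimes the network flows emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, fsolve

from .rate import RateSystem, rate_rhs

__all__ = [
    "ProjectionBasis",
    "svd_projection",
    "ReducedPhaseModel",
    "reduce_to_phase",
    "phase_fixed_points",
    "bifurcation_scan",
    "ExcitatorParams",
    "excitator_rhs",
    "excitator_fixed_points",
    "integrate_excitator",
    "EXCITATOR_REGIMES",
]


@dataclass
class ProjectionBasis:
    """Orthonormal triple splitting state space at a 3-node reduction.

    ``normal`` spans the direction annihilated by the antisymmetric
    coupling (the uniform mode for a cyclic asymmetry); ``e1``/``e2`` span
    the plane carrying the slow flow.
    """

    normal: np.ndarray
    e1: np.ndarray
    e2: np.ndarray

    def matrix(self) -> np.ndarray:
        """Rows (e1, e2, normal): maps state vectors to (x, y, n)."""
        return np.stack([self.e1, self.e2, self.normal])

    def to_plane(self, omega: np.ndarray) -> np.ndarray:
        return self.matrix() @ omega

    def from_plane(self, xyn: np.ndarray) -> np.ndarray:
        return self.matrix().T @ xyn


def _fix_sign(v: np.ndarray) -> np.ndarray:
    nz = np.nonzero(np.abs(v) > 1e-12)[0]
    if nz.size and v[nz[0]] < 0:
        return -v
    return v


def svd_projection(asym: np.ndarray, tol: float = 1e-12) -> ProjectionBasis:
    """Projection basis from the right singular vectors of the
    antisymmetric coupling component.

    A 3x3 antisymmetric matrix acts as a cross product with a fixed axis;
    its singular values are (|a|, |a|, 0) and the null right singular
    vector is the axis itself -- the direction along which the asymmetry
    exerts no rotation, taken as the normal.  The two leading right
    singular vectors span the plane of the slow flow.  Signs are fixed by
    making each vector's first nonzero component positive, and the pair
    (e1, e2) is re-orthogonalized into a frame with e1 x e2 = +-normal.
    """
    asym = np.asarray(asym, dtype=float)
    if asym.shape != (3, 3):
        raise ValueError(f"expected a 3x3 matrix, got {asym.shape}")
    if not np.allclose(asym, -asym.T, atol=1e-10):
        raise ValueError("matrix must be antisymmetric")
    if np.linalg.norm(asym) < tol:
        raise ValueError("zero asymmetry: no preferred plane")
    _, _s, vt = np.linalg.svd(asym)
    e1, e2, normal = (_fix_sign(v) for v in vt)
    e2 = e2 - (e2 @ e1) * e1
    e2 /= np.linalg.norm(e2)
    normal = _fix_sign(np.cross(e1, e2))
    return ProjectionBasis(normal=normal, e1=e1, e2=e2)


@dataclass
class ReducedPhaseModel:
    """Scalar phase flow of a 3-node system after radius / normal averaging."""

    system: RateSystem
    basis: ProjectionBasis
    radius: float
    normal: float
    phi_grid: np.ndarray = field(repr=False)
    dphi: np.ndarray = field(repr=False)

    def __call__(self, phi: np.ndarray | float) -> np.ndarray:
        """dphi/dt at phase phi (periodic linear interpolation)."""
        phi = np.mod(np.asarray(phi, dtype=float), 2.0 * np.pi)
        grid = np.concatenate([self.phi_grid, [2.0 * np.pi]])
        vals = np.concatenate([self.dphi, [self.dphi[0]]])
        out = np.interp(phi, grid, vals)
        return out[()] if out.ndim == 0 else out

    def state(self, phi: float) -> np.ndarray:
        """Full-space point corresponding to phase ``phi`` on the manifold."""
        xyn = np.array(
            [self.radius * np.cos(phi), self.radius * np.sin(phi), self.normal]
        )
        return self.basis.from_plane(xyn)


def _plane_flow(
    system: RateSystem, basis: ProjectionBasis, r: float, n: float, phi: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(dr, dn, dphi) sampled on a phase grid at fixed radius / normal."""
    x = r * np.cos(phi)
    y = r * np.sin(phi)
    m = basis.matrix()
    states = m.T @ np.stack([x, y, np.full_like(phi, n)])
    derivs = np.stack(
        [rate_rhs(states[:, i], system) for i in range(phi.size)], axis=1
    )
    dx, dy, dn = m @ derivs
    dr = np.cos(phi) * dx + np.sin(phi) * dy
    dphi = (np.cos(phi) * dy - np.sin(phi) * dx) / max(r, 1e-12)
    return dr, dn, dphi


def reduce_to_phase(
    system: RateSystem,
    basis: ProjectionBasis | None = None,
    n_phi: int = 512,
    r_bounds: tuple[float, float] = (1e-3, 1.5),
) -> ReducedPhaseModel:
    """Average the radius and normal dynamics over phase and return the
    scalar phase flow.

    The averaged radius ``r_bar`` and normal ``n_bar`` solve
    ``<dr/dt>_phi = 0`` and ``<dn/dt>_phi = 0`` (trapezoid average over
    ``n_phi`` grid points); substituting them into the in-plane dynamics
    leaves ``dphi/dt`` as a function of phase alone.  Valid while the full
    trajectory stays near the manifold of the averaged radius and normal.
    """
    if system.n != 3:
        raise ValueError("phase reduction is defined for 3-node systems")
    if basis is None:
        from .connectivity import decompose_symmetry

        _, asym = decompose_symmetry(system.coupling)
        basis = svd_projection(asym)
    phi = np.linspace(0.0, 2.0 * np.pi, n_phi, endpoint=False)

    def averages(rn: np.ndarray) -> np.ndarray:
        r, n = rn
        dr, dn, _ = _plane_flow(system, basis, float(r), float(n), phi)
        return np.array([dr.mean(), dn.mean()])

    # coarse scan for starting points, then Newton polish; the symmetric
    # point r = 0 always solves the averaged equations, so starts are kept
    # away from it and degenerate solutions are retried from other seeds
    r_lo = max(r_bounds[0], 0.02 * system.b)
    starts = []
    for r0 in np.linspace(r_lo, r_bounds[1], 12):
        for n0 in np.linspace(0.0, np.sqrt(3.0) * system.b, 12):
            res = float(np.linalg.norm(averages(np.array([r0, n0]))))
            starts.append((res, r0, n0))
    starts.sort()
    r_bar = n_bar = None
    last_msg = "no starting points"
    for _res, r0, n0 in starts[:10]:
        sol, info, ier, last_msg = fsolve(
            averages, np.array([r0, n0]), full_output=True, xtol=1e-12
        )
        if ier == 1 and np.linalg.norm(info["fvec"]) < 1e-9 and sol[0] > 0.01 * system.b:
            r_bar, n_bar = float(sol[0]), float(sol[1])
            break
    if r_bar is None:
        raise RuntimeError(
            "radius/normal averaging did not converge to a nontrivial "
            f"radius: {last_msg}"
        )
    _, _, dphi = _plane_flow(system, basis, r_bar, n_bar, phi)
    return ReducedPhaseModel(
        system=system, basis=basis, radius=r_bar, normal=n_bar,
        phi_grid=phi, dphi=dphi,
    )


def phase_fixed_points(
    model: ReducedPhaseModel | Callable[[float], float],
    n_scan: int = 4096,
) -> tuple[np.ndarray, np.ndarray]:
    """All zeros of the phase flow on [0, 2pi): (stable, unstable) arrays.

    Zeros are bracketed by sign changes on a dense grid and polished by
    bisection; stability follows the sign of the slope through the zero.
    """
    f = model
    phi = np.linspace(0.0, 2.0 * np.pi, n_scan, endpoint=False)
    vals = np.array([float(f(p)) for p in phi])
    stable, unstable = [], []
    for i in range(n_scan):
        a = phi[i]
        b = phi[i + 1] if i + 1 < n_scan else 2.0 * np.pi
        va = vals[i]
        vb = vals[(i + 1) % n_scan]
        if va == 0.0:
            vprev = vals[i - 1]
            if vprev > 0 and vb < 0:
                stable.append(a)
            elif vprev < 0 and vb > 0:
                unstable.append(a)
            continue
        if va * vb < 0:
            root = brentq(lambda p: float(f(p)), a, b, xtol=1e-12)
            (stable if va > 0 else unstable).append(root)
    return np.asarray(stable), np.asarray(unstable)


def bifurcation_scan(
    family: Callable[[float], ReducedPhaseModel | Callable[[float], float]],
    alpha_range: tuple[float, float],
    tol: float = 1e-4,
) -> float | None:
    """Smallest asymmetry at which the phase flow loses all fixed points.

    ``family`` maps an asymmetry degree to a reduced phase model.  The
    transition is located by bisection on the fixed-point count between
    the range endpoints; returns None if the count never drops to zero in
    the scanned range.
    """
    lo, hi = alpha_range
    if hi <= lo:
        raise ValueError("alpha range must be increasing")

    def has_fp(alpha: float) -> bool:
        s, u = phase_fixed_points(family(alpha))
        return (s.size + u.size) > 0

    if not has_fp(lo):
        return lo
    if has_fp(hi):
        return None
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if has_fp(mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# the two-dimensional excitable reference system


@dataclass
class ExcitatorParams:
    """Position/velocity excitable system with a cubic restoring nullcline.

        dx/dt = tau * (x - x^3 / 3 - y + drive)
        dy/dt = (x + a - b * y) / tau

    ``x`` is the end-effector position and ``y`` its velocity-like
    recovery variable; depending on (a, b, drive) the flow is bistable, a
    limit cycle, or monostable with a separatrix near the fixed point.
    """

    a: float = 0.7
    b: float = 0.8
    drive: float = 0.0
    tau: float = 3.0


#: Canonical parameter sets for the three regimes.
EXCITATOR_REGIMES = {
    "monostable": ExcitatorParams(a=0.7, b=0.8, drive=0.0),
    "limit-cycle": ExcitatorParams(a=0.7, b=0.8, drive=0.5),
    "bistable": ExcitatorParams(a=0.0, b=2.5, drive=0.0),
}


def excitator_rhs(state: np.ndarray, params: ExcitatorParams) -> np.ndarray:
    x, y = state
    return np.array(
        [
            params.tau * (x - x**3 / 3.0 - y + params.drive),
            (x + params.a - params.b * y) / params.tau,
        ]
    )


def excitator_fixed_points(
    params: ExcitatorParams, box: float = 3.0, seeds_per_axis: int = 12
) -> list[tuple[np.ndarray, bool]]:
    """Fixed points with stability flags (grid-seeded Newton + analytic
    Jacobian eigenvalues, mirroring the rate-flow classification
    protocol)."""
    found: list[np.ndarray] = []
    for x0 in np.linspace(-box, box, seeds_per_axis):
        for y0 in np.linspace(-box, box, seeds_per_axis):
            sol, info, ier, _ = fsolve(
                lambda s: excitator_rhs(s, params), np.array([x0, y0]),
                full_output=True, xtol=1e-13,
            )
            if ier != 1 or np.linalg.norm(info["fvec"]) > 1e-10:
                continue
            if np.max(np.abs(sol)) > box + 1:
                continue
            if any(np.linalg.norm(sol - f) < 1e-6 for f in found):
                continue
            found.append(sol)
    out = []
    for sol in sorted(found, key=lambda s: tuple(np.round(s, 8))):
        x = sol[0]
        jac = np.array(
            [
                [params.tau * (1.0 - x**2), -params.tau],
                [1.0 / params.tau, -params.b / params.tau],
            ]
        )
        eig = np.linalg.eigvals(jac)
        out.append((sol, bool(np.all(eig.real < -1e-9))))
    return out


def integrate_excitator(
    params: ExcitatorParams,
    state0: np.ndarray,
    duration: float,
    dt_out: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    t_eval = np.arange(0.0, duration + dt_out / 2, dt_out)
    sol = solve_ivp(
        lambda _t, s: excitator_rhs(s, params),
        (0.0, float(t_eval[-1])),
        np.asarray(state0, dtype=float),
        t_eval=t_eval,
        rtol=1e-9,
        atol=1e-11,
    )
    return sol.t, sol.y
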