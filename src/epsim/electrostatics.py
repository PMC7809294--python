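"""Electrostatic potential, field and temperature-dependent conductivity.

The quasi-static potential obeys charge conservation, div(sigma grad Phi)=0,
with Dirichlet values on electrode nodes and zero normal current through
tissue-air surfaces.  The tissue conductivity rises linearly with
temperature, sigma = sigma_b (1 + alpha (T - T0)), and is refreshed from the
current temperature before every solve (one-way Picard coupling per time
step).  E = -grad Phi by second-order finite differences.

Discretization: 7-point stencil with harmonic-mean face conductivities,
which is flux-continuous across material interfaces and reproduces the
series-slab closed form exactly; solved by red-black SOR with warm starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import relax
from .errors import ConfigurationError, StateError
from .mesh import Grid, NodeLabels


@dataclass
class SolverSettings:
    """Relaxation controls for the Laplace solve."""

    tol: float = 1e-6        # relative L2 residual
    max_iter: int = 50000
    omega: float = 1.8       # SOR relaxation factor

    def __post_init__(self):
        if self.tol <= 0:
            raise ConfigurationError("solver tolerance must be positive")
        if self.max_iter < 1:
            raise ConfigurationError("solver max_iter must be >= 1")
        if not 0.0 < self.omega < 2.0:
            raise ConfigurationError("solver omega must lie in (0, 2)")


@dataclass
class FieldState:
    """All per-node fields plus the simulation clock."""

    phi: np.ndarray          # V
    T: np.ndarray            # degC
    sigma: np.ndarray        # S/m
    E: np.ndarray            # V/m, shape (3, nx, ny, nz)
    J: np.ndarray            # A/m^2, shape (3, nx, ny, nz)
    t: float = 0.0           # s

    @classmethod
    def initial(cls, grid: Grid, t_init: float, sigma: np.ndarray
                ) -> "FieldState":
        shape = grid.shape
        return cls(phi=np.zeros(shape), T=np.full(shape, float(t_init)),
                   sigma=sigma, E=np.zeros((3,) + shape),
                   J=np.zeros((3,) + shape), t=0.0)


def conductivity_from_temperature(T: np.ndarray, sigma_b: float, alpha: float,
                                  t_ref: float) -> np.ndarray:
    """sigma = sigma_b (1 + alpha (T - T0)); errors on non-physical sigma."""
    sigma = sigma_b * (1.0 + alpha * (T - t_ref))
    if np.any(sigma <= 0.0):
        bad = np.asarray(T)[sigma <= 0.0].flat[0]
        raise StateError(
            f"conductivity dropped to <= 0 S/m at temperature {bad:.3f} degC "
            f"(sigma_b={sigma_b}, alpha={alpha}, T0={t_ref})")
    return sigma


def _edge_factors(n: int) -> np.ndarray:
    # half-cell control volumes at the domain boundary
    w = np.ones(n)
    w[0] = w[-1] = 0.5
    return w


def face_conductivities(sigma: np.ndarray, spacing: float):
    """Finite-volume stencil weights: harmonic-mean face conductivity times
    the transverse face area, per h^2.

    Boundary control volumes are half cells, so faces in a boundary row
    carry half (quarter at edges) of the interior face area.  This makes the
    discrete surface integral of J around an electrode reproduce geometric
    cross-sections exactly in the 1D limit while conserving current to
    solver tolerance.
    """
    h2 = spacing ** 2
    nx, ny, nz = sigma.shape
    ax, ay, az = (_edge_factors(n) for n in (nx, ny, nz))

    def harm(a, b):
        return 2.0 * a * b / (a + b) / h2

    wx = harm(sigma[:-1, :, :], sigma[1:, :, :]) \
        * ay[None, :, None] * az[None, None, :]
    wy = harm(sigma[:, :-1, :], sigma[:, 1:, :]) \
        * ax[:, None, None] * az[None, None, :]
    wz = harm(sigma[:, :, :-1], sigma[:, :, 1:]) \
        * ax[:, None, None] * ay[None, :, None]
    return wx, wy, wz


def solve_potential(grid: Grid, labels: NodeLabels, sigma: np.ndarray,
                    v_anode: float, v_cathode: float,
                    settings: SolverSettings | None = None,
                    phi0: np.ndarray | None = None):
    """Solve div(sigma grad Phi) = 0; returns (phi, iterations).

    Dirichlet on electrode nodes, zero-flux on the domain boundary.  A
    previous potential may seed the iteration (warm start).
    """
    settings = settings or SolverSettings()
    if not labels.anode_mask.any() or not labels.cathode_mask.any():
        raise ConfigurationError("potential solve needs both an anode and a "
                                 "cathode")
    phi = (np.zeros(grid.shape) if phi0 is None
           else np.array(phi0, dtype=float, copy=True))
    phi[labels.anode_mask] = v_anode
    phi[labels.cathode_mask] = v_cathode
    wx, wy, wz = face_conductivities(sigma, grid.spacing)
    phi, iters, _ = relax.solve(phi, labels.tissue_mask, wx, wy, wz,
                                extra_diag=0.0, rhs=0.0,
                                omega=settings.omega, tol=settings.tol,
                                max_iter=settings.max_iter)
    return phi, iters


def solve_potential_direct(grid: Grid, labels: NodeLabels, sigma: np.ndarray,
                           v_anode: float, v_cathode: float) -> np.ndarray:
    """Sparse direct solve of the identical stencil (reference path)."""
    phi = np.zeros(grid.shape)
    phi[labels.anode_mask] = v_anode
    phi[labels.cathode_mask] = v_cathode
    wx, wy, wz = face_conductivities(sigma, grid.spacing)
    return relax.direct_solve(phi, labels.tissue_mask, wx, wy, wz,
                              extra_diag=0.0, rhs=0.0)


def electric_field(phi: np.ndarray, grid: Grid) -> np.ndarray:
    """E = -grad Phi: central differences, second-order one-sided at edges."""
    grads = np.gradient(phi, grid.spacing, edge_order=2)
    return -np.stack(grads)


def off_stage_field(state: FieldState, voltage: float = 0.0) -> FieldState:
    """Zero Phi, E, J without a solve (OFF stage / zero-voltage segment)."""
    if voltage != 0.0:
        raise StateError(
            f"Laplace bypass requested while the applied voltage is "
            f"{voltage} V")
    state.phi.fill(0.0)
    state.E.fill(0.0)
    state.J.fill(0.0)
    return state
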