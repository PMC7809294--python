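"""Pennes bioheat equation with Joule heating.

    rho Cp dT/dt = div(kappa grad T) - rho_b w_b C_b (T - T_b)
                   + sigma |grad Phi|^2 + q_m

Perfusion and metabolic terms act in tissue nodes only; electrode nodes
conduct heat with the electrode metal's kappa/rho/Cp and generate no Joule
heat (they are treated as perfect electric conductors).  Boundary
conditions: zero flux on tissue-air faces, convective (Robin) cooling
-kappa dT/dn = h (T - T_r) on exposed electrode faces.

Time stepping is backward Euler: the paper-style OFF stage covers ~0.95 s in
a single step, far beyond any explicit diffusion stability bound, so an
implicit scheme is required.  The linear system per step is solved by the
same red-black relaxation kernel as the potential, in increment form
(unknown dT = T_new - T_old): the right-hand side is then the per-step
forcing, so a steady state converges immediately and uniform-source limits
are resolved to near machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import relax
from .errors import ConfigurationError
from .mesh import BOUNDARY_FACES, Grid, NodeLabels, _boundary_slice


@dataclass(frozen=True)
class PhysicalParameters:
    """Tissue, blood and environment constants (SI, temperatures in degC)."""

    # tissue
    sigma_b: float = 0.2       # S/m, baseline electrical conductivity
    alpha: float = 0.02        # 1/degC, conductivity rise per degree
    t_ref: float = 37.0        # degC, reference temperature of the sigma law
    rho: float = 1050.0        # kg/m^3
    cp: float = 3600.0         # J/(kg K)
    kappa: float = 0.5         # W/(m K)
    q_m: float = 420.0         # W/m^3, metabolic heat
    # blood
    rho_b: float = 1060.0      # kg/m^3
    omega_b: float = 1e-3      # 1/s, perfusion rate
    c_b: float = 3600.0        # J/(kg K)
    t_b: float = 37.0          # degC, arterial temperature
    # environment
    h_conv: float = 10.0       # W/(m^2 K), heat-transfer coefficient
    t_room: float = 25.0       # degC
    t_init: float = 37.0       # degC, initial tissue temperature T_p

    def __post_init__(self):
        positives = {"rho": self.rho, "cp": self.cp, "kappa": self.kappa,
                     "rho_b": self.rho_b, "c_b": self.c_b,
                     "sigma_b": self.sigma_b}
        for name, val in positives.items():
            if val <= 0:
                raise ConfigurationError(f"parameter {name} must be positive, "
                                         f"got {val}")
        for name, val in {"omega_b": self.omega_b, "q_m": self.q_m,
                          "h_conv": self.h_conv}.items():
            if val < 0:
                raise ConfigurationError(f"parameter {name} must be >= 0, "
                                         f"got {val}")


def initialize_temperature(grid: Grid, params: PhysicalParameters
                           ) -> np.ndarray:
    """Uniform initial temperature T_p over tissue and electrodes."""
    return np.full(grid.shape, float(params.t_init))


class BioheatStepper:
    """Backward-Euler integrator for the bioheat equation on a fixed mesh.

    Precomputes the conduction weights, heat capacities, perfusion sinks and
    Robin boundary coefficients once; ``step`` then advances T by dt.
    """

    def __init__(self, grid: Grid, labels: NodeLabels, electrodes,
                 params: PhysicalParameters, tol: float = 1e-12,
                 max_iter: int = 50000, omega: float = 1.5,
                 fixed_mask: np.ndarray | None = None,
                 fixed_values: np.ndarray | None = None):
        self.grid = grid
        self.params = params
        self.tol = tol
        self.max_iter = max_iter
        self.omega = omega
        shape = grid.shape
        h = grid.spacing

        kappa = np.full(shape, params.kappa)
        rho_cp = np.full(shape, params.rho * params.cp)
        for idx, el in enumerate(electrodes):
            m = labels.electrode_id == idx
            kappa[m] = el.material.kappa
            rho_cp[m] = el.material.rho * el.material.cp
        self.rho_cp = rho_cp
        self.tissue = labels.tissue_mask

        h2 = h ** 2
        self.wx = 2 * kappa[:-1] * kappa[1:] / (kappa[:-1] + kappa[1:]) / h2
        self.wy = (2 * kappa[:, :-1] * kappa[:, 1:]
                   / (kappa[:, :-1] + kappa[:, 1:]) / h2)
        self.wz = (2 * kappa[:, :, :-1] * kappa[:, :, 1:]
                   / (kappa[:, :, :-1] + kappa[:, :, 1:]) / h2)
        self.wdeg = relax.weight_degree(self.wx, self.wy, self.wz, shape)

        # perfusion sink coefficient, tissue only
        self.perf = np.where(self.tissue,
                             params.rho_b * params.omega_b * params.c_b, 0.0)
        self.q_m = np.where(self.tissue, params.q_m, 0.0)

        # Robin coefficient h/h_grid per exposed boundary face of a node
        robin = np.zeros(shape)
        if labels.electrode_air:
            for face in BOUNDARY_FACES:
                tag = labels.electrode_air.get(face)
                if tag is not None and tag.any():
                    sl = _boundary_slice(face, shape)
                    robin[sl][tag] += params.h_conv / h
        self.robin = robin

        if fixed_mask is None:
            self.free = np.ones(shape, dtype=bool)
            self.fixed_values = None
        else:
            self.free = ~fixed_mask
            self.fixed_values = fixed_values

    def laplacian(self, T: np.ndarray) -> np.ndarray:
        """Discrete div(kappa grad T) per unit volume (W/m^3)."""
        return relax.neighbor_sum(T, self.wx, self.wy, self.wz) - self.wdeg * T

    def step(self, T: np.ndarray, dt: float,
             joule: np.ndarray | float = 0.0):
        """One backward-Euler step; returns (T_new, iterations).

        ``joule`` is the volumetric source sigma |grad Phi|^2 (W/m^3),
        evaluated at the step start and applied in tissue nodes only; pass 0
        during OFF stages.
        """
        if dt <= 0:
            raise ConfigurationError(f"time step must be positive, got {dt}")
        p = self.params
        source = np.where(self.tissue, joule, 0.0) + self.q_m
        rhs = (self.laplacian(T)
               - self.perf * (T - p.t_b)
               - self.robin * (T - p.t_room)
               + source)
        extra = self.rho_cp / dt + self.perf + self.robin
        delta0 = np.zeros_like(T)
        if self.fixed_values is not None:
            delta0[~self.free] = (self.fixed_values - T)[~self.free]
        delta, iters, _ = relax.solve(delta0, self.free, self.wx, self.wy,
                                      self.wz, extra_diag=extra, rhs=rhs,
                                      omega=self.omega, tol=self.tol,
                                      max_iter=self.max_iter)
        return T + delta, iters


def step_temperature(T: np.ndarray, grid: Grid, labels: NodeLabels,
                     electrodes, params: PhysicalParameters, dt: float,
                     joule: np.ndarray | float = 0.0, tol: float = 1e-12):
    """One-shot convenience wrapper around :class:`BioheatStepper`."""
    stepper = BioheatStepper(grid, labels, electrodes, params, tol=tol)
    return stepper.step(T, dt, joule=joule)
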