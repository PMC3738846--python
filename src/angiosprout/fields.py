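"""Scalar fields: steady-state VEGF, ECM degradation, MMP reaction-diffusion.

VEGF is static: the tumor is a planar source beyond the top edge and the
gradient is the 1D steady state of a diffusion-decay balance,
``c_V(d) = c_V(0) exp(-d/lambda)`` with ``lambda = sqrt(D_V/epsilon_V)``
and ``d`` the distance from the tumor edge (the top row).

ECM and MMP evolve with forward Euler on the CPM lattice, five-point
Laplacian for MMP diffusion, zero-value (Dirichlet) conditions on the
lattice edge, and operator splitting against the CPM: the sigma grid is
held fixed while ``n_substeps`` Euler steps run between MCSs.

    dc_E/dt = -delta(sigma,0) * epsilon_EM * c_M * c_E
    dc_M/dt = alpha_MV * c_V * [sigma>=1] * H(c_M_max - c_M)
              - delta(sigma,0) * epsilon_M * c_M + D_M lap(c_M)

ECM is degraded only on medium sites (the value under a cell is frozen
until the cell retracts); MMPs are secreted only on cell-covered sites
while below the cap ``c_M_max`` (H(0) = 0: secretion stops exactly at
the cap) and decay only on medium sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import MEDIUM, ConfigurationError, SimConfig
from .cpm import LatticeState


@dataclass
class ScalarField:
    """One real-valued grid with its role in the model."""

    values: np.ndarray  # shape (Y, X), indexed [x2, x1]
    role: str           # "VEGF" | "ECM" | "MMP"

    def copy(self) -> "ScalarField":
        return ScalarField(self.values.copy(), self.role)


@dataclass
class FieldSet:
    c_V: ScalarField
    c_E: ScalarField
    c_M: ScalarField

    def copy(self) -> "FieldSet":
        return FieldSet(self.c_V.copy(), self.c_E.copy(), self.c_M.copy())


def vegf_steady_state(cfg: SimConfig,
                      dims: tuple[int, int] | None = None) -> ScalarField:
    """Analytic steady-state VEGF gradient, planar from the top edge."""
    if cfg.D_V <= 0 or cfg.epsilon_V <= 0:
        raise ConfigurationError("D_V and epsilon_V must be > 0")
    X, Y = dims if dims is not None else (cfg.X, cfg.Y)
    lam = cfg.vegf_decay_length()
    x2 = np.arange(Y, dtype=np.float64)
    profile = cfg.c_V0 * np.exp(-((Y - 1) - x2) / lam)
    return ScalarField(np.repeat(profile[:, None], X, axis=1), "VEGF")


def init_ecm_field(cfg: SimConfig,
                   state: LatticeState | None = None) -> ScalarField:
    """Initial ECM: dense outside the vessel, intermediate inside,
    and a semicircular linear ramp in front of the gap.

    The half-disc has radius ``X_gap``, is centered on the gap midpoint
    at the wall's top edge, and ramps from the vessel concentration at
    the opening to the outside concentration at the rim.
    """
    X, Y = (cfg.X, cfg.Y) if state is None else state.dims
    vals = np.full((Y, X), cfg.c_E_init, dtype=np.float64)
    vals[: cfg.Y_gap, :] = cfg.c_E_vessel
    wlo, whi = cfg.wall_rows()
    glo, ghi = cfg.gap_columns()
    vals[wlo:whi + 1, glo:ghi + 1] = cfg.c_E_vessel  # the opening itself
    cx = 0.5 * (glo + ghi)
    cy = float(whi)
    x1g, x2g = np.meshgrid(np.arange(X), np.arange(Y))
    r = np.hypot(x1g - cx, x2g - cy)
    above = x2g > whi
    disc = above & (r <= cfg.X_gap)
    ramp = cfg.c_E_vessel + (cfg.c_E_init - cfg.c_E_vessel) * r / cfg.X_gap
    vals[disc] = ramp[disc]
    return ScalarField(vals, "ECM")


def initialize_fields(cfg: SimConfig, state: LatticeState) -> FieldSet:
    X, Y = state.dims
    return FieldSet(
        c_V=vegf_steady_state(cfg, (X, Y)),
        c_E=init_ecm_field(cfg, state),
        c_M=ScalarField(np.zeros((Y, X), dtype=np.float64), "MMP"),
    )


def _laplacian_dirichlet(f: np.ndarray) -> np.ndarray:
    """Five-point Laplacian with zero values outside the lattice."""
    p = np.pad(f, 1)
    return (p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:]
            - 4.0 * f)


def pde_substep(state: LatticeState, c_E: np.ndarray, c_M: np.ndarray,
                c_V: np.ndarray, cfg: SimConfig,
                cell_mask: np.ndarray | None = None,
                medium_mask: np.ndarray | None = None,
                ) -> tuple[np.ndarray, np.ndarray]:
    """One forward-Euler step of length dt; returns (c_E', c_M')."""
    if cell_mask is None:
        cell_mask = state.sigma > 0
    if medium_mask is None:
        medium_mask = state.sigma == MEDIUM
    dt = cfg.dt
    c_E_new = c_E - dt * cfg.epsilon_EM * c_M * c_E * medium_mask
    secretion = cfg.alpha_MV * c_V * (cell_mask & (c_M < cfg.c_M_max))
    c_M_new = (c_M + dt * (secretion - cfg.epsilon_M * c_M * medium_mask
                           + cfg.lattice_D_M() * _laplacian_dirichlet(c_M)))
    # zero-value boundary condition on the lattice edge
    c_M_new[0, :] = 0.0
    c_M_new[-1, :] = 0.0
    c_M_new[:, 0] = 0.0
    c_M_new[:, -1] = 0.0
    return c_E_new, c_M_new


def couple_fields_per_mcs(state: LatticeState, fields: FieldSet,
                          cfg: SimConfig, use_kernel: bool = True) -> FieldSet:
    """Operator splitting: n_substeps Euler steps at fixed sigma grid.

    The compiled fused loop and the per-step reference implementation
    (:func:`pde_substep`) produce the same fields.
    """
    c_E = fields.c_E.values
    c_M = fields.c_M.values
    c_V = fields.c_V.values
    if use_kernel:
        from ._kernel import pde_substeps
        c_M = pde_substeps(state.sigma, c_E, c_M, c_V, cfg.n_substeps,
                           cfg.dt, cfg.epsilon_EM, cfg.alpha_MV,
                           cfg.epsilon_M, cfg.lattice_D_M(), cfg.c_M_max)
    else:
        cell_mask = state.sigma > 0
        medium_mask = state.sigma == MEDIUM
        for _ in range(cfg.n_substeps):
            c_E, c_M = pde_substep(state, c_E, c_M, c_V, cfg,
                                   cell_mask, medium_mask)
    fields.c_E.values = c_E
    fields.c_M.values = c_M
    return fields
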