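"""Simulation configuration: reference parameter set, presets, validation.

All model parameters live in a single flat :class:`SimConfig`. The field
names mirror the conventional symbols of the model: ``chi`` (chemotaxis
strength), ``Gamma``/``s`` (haptotaxis strength and saturation), ``eta``
(haptokinesis strength), ``epsilon_EM`` (MMP-dependent ECM degradation
constant), ``alpha_MV``/``epsilon_M``/``D_M`` (MMP secretion, decay,
diffusion), ``D_V``/``epsilon_V`` (VEGF diffusion and decay), ``rho_min``
(proliferation threshold), ``lambda_A``/``lambda_L`` (area and length
constraint strengths), ``c_E_init``/``c_V0`` (initial ECM density and
tumor-edge VEGF concentration), lattice geometry ``X``/``Y``/``Y_gap``/
``X_gap`` and the run length ``MCS_tot``.

Two unit schemes are supported for the field rates. Under the default
``units="physical"`` scheme the diffusion coefficients are read as m^2/s
and converted to lattice units with a lattice spacing ``dx_physical``
(default 2 um per site, i.e. a 500 um dish across 250 sites) and one
second per Euler substep. Under ``units="lattice"`` the raw values are
used as site^2/step directly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml

FROZEN = -1  # sentinel index for wall / border sites
MEDIUM = 0


class ConfigurationError(ValueError):
    """Raised when a configuration is internally inconsistent."""


@dataclass
class SimConfig:
    # --- guidance strengths ---
    chi: float = 5000.0            # chemotaxis strength
    Gamma: float = 300.0           # haptotaxis strength
    s: float = 7.0                 # haptotaxis saturation
    eta: float = 200.0             # haptokinesis strength
    mu: float = 0.5                # optimal ECM density for haptokinesis
    rho: float = 0.2               # haptokinesis Gaussian width

    # --- field rates (physical units by default, see `units`) ---
    epsilon_EM: float = 3e-3       # ECM degradation constant [1/(conc s)]
    alpha_MV: float = 8e-5         # MMP secretion rate [1/s]
    epsilon_M: float = 1e-3        # MMP decay rate [1/s]
    D_M: float = 1e-14             # MMP diffusion coefficient [m^2/s]
    D_V: float = 6e-11             # VEGF diffusion coefficient [m^2/s]
    epsilon_V: float = 1e-3        # VEGF decay rate [1/s]
    c_M_max: float = 1.0           # MMP secretion cap
    c_E_init: float = 0.9          # initial ECM density outside the vessel
    c_E_vessel: float = 0.5        # initial ECM density inside the vessel
    c_V0: float = 0.87             # VEGF concentration at the tumor edge

    # --- CPM energies ---
    J_CC: float = 40.0             # cell-cell adhesion energy
    J_CM: float = 25.0             # cell-matrix adhesion energy
    J_border: float = 25.0         # cell-frozen (wall/border) bond energy
    lambda_A: float = 25.0         # area constraint strength
    lambda_L: float = 25.0         # length constraint strength
    M: float = 100.0               # intrinsic membrane motility
    A_T: float = 50.0              # nominal target area [sites]
    L_T: float = 15.0              # nominal target length [sites]
    adhesion_order: int = 2        # neighbor order for adhesion bonds and
                                   # perimeter pairs (2 = with diagonals);
                                   # copy sources always use order 4 (20)

    # --- proliferation ---
    rho_min: float = 0.73          # ECM-contact threshold ratio
    proliferation_period: int = 5  # MCS between proliferation sweeps
    growth_dA_T: float = 2.0       # target-area regrowth per sweep [sites]
    growth_dL_T: float = 0.6       # target-length regrowth per sweep [sites]
    eligibility_offset: float = 15.0  # min height above the wall [sites]
    eligibility_reference: str = "tip"  # "tip": the cell's topmost site
                                   # must clear the offset; "centroid":
                                   # its center of mass must

    # --- geometry ---
    X: int = 250                   # dish width [sites]
    Y: int = 350                   # dish height [sites]
    Y_gap: int = 30                # wall distance from bottom [sites]
    X_gap: int = 25                # gap width in the wall [sites]
    wall_thickness: int = 2        # wall band thickness [sites]
    n_cells: int = 125             # initial cell count

    # --- numerics ---
    units: str = "physical"        # "physical" (m^2/s + dx) or "lattice"
    dx_physical: float = 2e-6      # lattice spacing [m/site]
    dt: float = 1.0                # Euler substep [s]
    n_substeps: int = 15           # PDE substeps per MCS

    # --- model variants ---
    haptokinesis_reference: str = "source"  # site whose ECM level gates motility
    chemotactic_retraction: bool = False

    # --- run block ---
    MCS_tot: int = 40000
    metric_period: int = 100
    snapshot_period: int = 1000
    seed: int = 0
    replicates: int = 10

    # ------------------------------------------------------------------
    def lattice_D_M(self) -> float:
        """MMP diffusion coefficient in site^2 per substep."""
        if self.units == "physical":
            return self.D_M / self.dx_physical**2
        return self.D_M

    def lattice_D_V(self) -> float:
        """VEGF diffusion coefficient in site^2 per substep."""
        if self.units == "physical":
            return self.D_V / self.dx_physical**2
        return self.D_V

    def vegf_decay_length(self) -> float:
        """Decay length lambda = sqrt(D_V / epsilon_V) in lattice sites."""
        return float(np.sqrt(self.lattice_D_V() / self.epsilon_V))

    # geometry helpers -------------------------------------------------
    def wall_rows(self) -> tuple[int, int]:
        """Inclusive row range (bottom, top) occupied by the wall band."""
        return self.Y_gap, self.Y_gap + self.wall_thickness - 1

    def gap_columns(self) -> tuple[int, int]:
        """Inclusive column range of the gap, centered in the wall."""
        lo = (self.X - self.X_gap) // 2
        return lo, lo + self.X_gap - 1

    def first_row_above_wall(self) -> int:
        return self.Y_gap + self.wall_thickness

    # ------------------------------------------------------------------
    def validate(self) -> "SimConfig":
        if self.M <= 0:
            raise ConfigurationError("intrinsic motility M must be > 0")
        if self.rho <= 0:
            raise ConfigurationError("haptokinesis width rho must be > 0")
        for name in ("chi", "Gamma", "s", "eta", "lambda_A", "lambda_L"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0.0 <= self.rho_min <= 1.0:
            raise ConfigurationError("rho_min must lie in [0, 1]")
        if self.adhesion_order not in (1, 2, 3, 4):
            raise ConfigurationError("adhesion_order must be in 1..4")
        if self.units not in ("physical", "lattice"):
            raise ConfigurationError("units must be 'physical' or 'lattice'")
        if self.haptokinesis_reference not in ("source", "target"):
            raise ConfigurationError(
                "haptokinesis_reference must be 'source' or 'target'")
        if self.eligibility_reference not in ("tip", "centroid"):
            raise ConfigurationError(
                "eligibility_reference must be 'tip' or 'centroid'")
        # explicit-scheme stability and positivity guards
        dm = self.lattice_D_M()
        if dm * self.dt > 0.25:
            raise ConfigurationError(
                f"forward-Euler stability violated: D_M*dt = {dm * self.dt}"
                " > 1/4 in lattice units")
        if self.epsilon_M * self.dt >= 1:
            raise ConfigurationError("epsilon_M*dt must be < 1")
        if self.epsilon_EM * self.c_M_max * self.dt >= 1:
            raise ConfigurationError("epsilon_EM*c_M_max*dt must be < 1")
        # geometry
        if self.X_gap > self.X:
            raise ConfigurationError("gap wider than the dish")
        if self.Y_gap + self.wall_thickness >= self.Y - 1:
            raise ConfigurationError("wall does not fit below the top border")
        from .cpm import plan_initial_tiling  # local import, avoids cycle
        plan_initial_tiling(self)  # raises ConfigurationError if unfittable
        return self

    # serialization ----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def replace(self, **over: Any) -> "SimConfig":
        return dataclasses.replace(self, **over)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


# ----------------------------------------------------------------------
# Named presets: columns A-F of the incremental model-component table.
# Every preset overrides the reference set above; "fig3F" is an alias of
# column F (the fully assembled model with haptotaxis raised to 1000).
PRESETS: dict[str, dict[str, float]] = {
    "A": dict(chi=0.0, eta=0.0, c_E_init=0.0, epsilon_EM=0.0, rho_min=1.0,
              Gamma=0.0),
    "B": dict(chi=6000.0, eta=0.0, c_E_init=0.0, epsilon_EM=0.0, rho_min=1.0,
              Gamma=0.0),
    "C": dict(chi=6000.0, eta=200.0, c_E_init=0.9, epsilon_EM=0.0,
              rho_min=1.0, Gamma=0.0),
    "D": dict(chi=6000.0, eta=200.0, c_E_init=0.9, epsilon_EM=2e-3,
              rho_min=1.0, Gamma=0.0),
    "E": dict(chi=6000.0, eta=200.0, c_E_init=0.9, epsilon_EM=2e-3,
              rho_min=0.73, Gamma=0.0),
    "F": dict(chi=6000.0, eta=200.0, c_E_init=0.9, epsilon_EM=2e-3,
              rho_min=0.73, Gamma=1000.0),
}
PRESETS["fig3F"] = dict(PRESETS["F"])


def preset_config(name: str, base: SimConfig | None = None) -> SimConfig:
    if name not in PRESETS:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    base = base if base is not None else SimConfig()
    return base.replace(**PRESETS[name])


def scaled_config(**over: Any) -> SimConfig:
    """A reduced-size study condition for qualitative runs.

    100x140 dish, 45 cells, 5000 MCS: the same vessel/wall/gap geometry
    and reference parameters, with the dish width scaled by 2/5 so that
    full bands of 50-site cells tile the vessel exactly, and a run length
    long enough for the early sprout morphology to develop.
    """
    cfg = SimConfig(X=100, Y=140, X_gap=25, Y_gap=30, n_cells=45,
                    MCS_tot=5000)
    return cfg.replace(**over)
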