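"""Guidance energy terms: chemotaxis, haptotaxis, haptokinesis.

All three act only on membrane *extensions* into the medium (the target
site of the copy is ECM): filopodia sense the environment, retracting
membrane does not. Each term is a reduction (negative energy change)
when the move is favored:

* chemotaxis: ``-chi * (c_V(x) - c_V(x'))`` up the VEGF gradient;
* haptotaxis: ``-Gamma * (f(c_E(x)) - f(c_E(x')))`` with the saturating
  response ``f(c) = c / (1 + s c)``;
* haptokinesis: a reverse Gaussian of the local ECM density,
  ``-eta * (-1 + exp(-(c_E - mu)^2 / (2 rho^2)) / (rho sqrt(2 pi)))``,
  maximally favorable at the intermediate density ``mu`` and a penalty
  (+eta) far from it — membrane activity peaks on intermediate matrix.

The haptokinesis Gaussian is evaluated at the *source* site's ECM level
by default (the formula's printed reference); a config switch
(``haptokinesis_reference="target"``) evaluates it at the target site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import MEDIUM, SimConfig
from .cpm import EnergyParams, LatticeState, delta_H_core


@dataclass
class GuidanceParams:
    chi: float = 5000.0
    Gamma: float = 300.0
    s: float = 7.0
    eta: float = 200.0
    mu: float = 0.5
    rho: float = 0.2
    haptokinesis_reference: str = "source"
    chemotactic_retraction: bool = False

    def __post_init__(self):
        if self.rho <= 0:
            raise ValueError("rho must be > 0")
        if min(self.chi, self.Gamma, self.s, self.eta) < 0:
            raise ValueError("guidance strengths must be >= 0")

    @classmethod
    def from_config(cls, cfg: SimConfig) -> "GuidanceParams":
        return cls(chi=cfg.chi, Gamma=cfg.Gamma, s=cfg.s, eta=cfg.eta,
                   mu=cfg.mu, rho=cfg.rho,
                   haptokinesis_reference=cfg.haptokinesis_reference,
                   chemotactic_retraction=cfg.chemotactic_retraction)


def dH_chemotaxis(c_V: np.ndarray, x_target, x_source, sigma_target: int,
                  chi: float) -> float:
    """Energy change from chemotaxis; zero unless extending into medium."""
    if sigma_target != MEDIUM:
        return 0.0
    t1, t2 = x_target
    s1, s2 = x_source
    return -chi * (c_V[t2, t1] - c_V[s2, s1])


def dH_haptotaxis(c_E: np.ndarray, x_target, x_source, sigma_target: int,
                  Gamma: float, s: float) -> float:
    """Energy change from haptotaxis with saturating ECM response."""
    if sigma_target != MEDIUM:
        return 0.0
    t1, t2 = x_target
    s1, s2 = x_source
    ce_t = c_E[t2, t1]
    ce_s = c_E[s2, s1]
    return -Gamma * (ce_t / (1.0 + s * ce_t) - ce_s / (1.0 + s * ce_s))


def dH_haptokinesis(c_E: np.ndarray, x_target, x_source, sigma_target: int,
                    eta: float, mu: float = 0.5, rho: float = 0.2,
                    reference: str = "source") -> float:
    """Energy change from haptokinesis (reverse-Gaussian ECM response)."""
    if sigma_target != MEDIUM:
        return 0.0
    if reference == "source":
        r1, r2 = x_source
    else:
        r1, r2 = x_target
    ce = c_E[r2, r1]
    gauss_norm = 1.0 / (rho * math.sqrt(2.0 * math.pi))
    g = gauss_norm * math.exp(-(ce - mu) ** 2 / (2.0 * rho * rho))
    return -eta * (-1.0 + g)


def dH_total(state: LatticeState, fields, cfg: SimConfig,
             x_target, x_source) -> float:
    """Total energy change of a copy: core Hamiltonian difference plus
    the three guidance terms (extensions into the medium only)."""
    params = EnergyParams.from_config(cfg)
    sig_t = int(state.sigma[x_target[1], x_target[0]])
    sig_s = int(state.sigma[x_source[1], x_source[0]])
    dE = delta_H_core(state, x_target, x_source, params)
    if sig_t == MEDIUM:
        dE += -cfg.chi * (fields.c_V.values[x_target[1], x_target[0]]
                          - fields.c_V.values[x_source[1], x_source[0]])
        ce_t = fields.c_E.values[x_target[1], x_target[0]]
        ce_s = fields.c_E.values[x_source[1], x_source[0]]
        dE += -cfg.Gamma * (ce_t / (1.0 + cfg.s * ce_t)
                            - ce_s / (1.0 + cfg.s * ce_s))
        if cfg.haptokinesis_reference == "source":
            ce_ref = ce_s
        else:
            ce_ref = ce_t
        gauss_norm = 1.0 / (cfg.rho * math.sqrt(2.0 * math.pi))
        g = gauss_norm * math.exp(-(ce_ref - cfg.mu) ** 2
                                  / (2.0 * cfg.rho * cfg.rho))
        dE += -cfg.eta * (-1.0 + g)
    elif cfg.chemotactic_retraction and sig_s == MEDIUM:
        dE += -cfg.chi * (fields.c_V.values[x_target[1], x_target[0]]
                          - fields.c_V.values[x_source[1], x_source[0]])
    return dE
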