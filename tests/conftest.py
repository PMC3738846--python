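"""Shared fixtures: small lattices, uniform fields, evolved random states."""

import numpy as np
import pytest

from angiosprout import LatticeState, SimConfig, monte_carlo_step
from angiosprout.config import FROZEN
from angiosprout.fields import FieldSet, ScalarField, initialize_fields


def make_uniform_fields(X, Y, c_E=0.5, c_V=0.0):
    """Flat fields on an X x Y lattice (no gradients, no MMPs)."""
    return FieldSet(
        c_V=ScalarField(np.full((Y, X), float(c_V)), "VEGF"),
        c_E=ScalarField(np.full((Y, X), float(c_E)), "ECM"),
        c_M=ScalarField(np.zeros((Y, X)), "MMP"),
    )


def make_open_state(X, Y, rects, capacity=16):
    """Frozen frame plus one rectangular cell per (x1, x2, w, h) entry."""
    st = LatticeState(X, Y, capacity=capacity)
    st.sigma[0, :] = FROZEN
    st.sigma[-1, :] = FROZEN
    st.sigma[:, 0] = FROZEN
    st.sigma[:, -1] = FROZEN
    for x1, x2, w, h in rects:
        i = st.add_cell(50.0, 15.0)
        st.paint_rect(i, x1, x2, w, h)
    return st


@pytest.fixture
def small_cfg():
    return SimConfig(X=40, Y=60, n_cells=6, MCS_tot=20,
                     metric_period=10, snapshot_period=10).validate()


@pytest.fixture
def neutral_cfg():
    """No guidance, no field dynamics: pure adhesion + constraints."""
    return SimConfig(X=40, Y=60, n_cells=6, chi=0.0, Gamma=0.0, eta=0.0,
                     rho_min=1.0, epsilon_EM=0.0, alpha_MV=0.0,
                     c_E_init=0.5, c_E_vessel=0.5).validate()


@pytest.fixture
def evolved_state(neutral_cfg):
    """A 40x60 multi-cell state churned for 30 MCS (irregular shapes)."""
    from angiosprout import build_initial_state

    st = build_initial_state(neutral_cfg)
    fields = initialize_fields(neutral_cfg, st)
    rng = np.random.default_rng(7)
    for _ in range(30):
        monte_carlo_step(st, fields, neutral_cfg, rng)
    return st, fields
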