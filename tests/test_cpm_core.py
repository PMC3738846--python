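"""Core CPM: neighborhoods, energies, copy dynamics, bookkeeping."""

import math

import numpy as np
import pytest
from scipy import ndimage

import angiosprout as ap
from angiosprout.config import FROZEN, ConfigurationError
from angiosprout.cpm import (EnergyParams, N_OFFSETS_BY_ORDER, OFF20,
                             apply_copy, is_gain_attached, length_from_sums,
                             plan_initial_tiling)
from conftest import make_open_state, make_uniform_fields


# ---------------------------------------------------------------- neighborhood
@pytest.mark.parametrize("order,count", [(1, 4), (2, 8), (3, 12), (4, 20)])
def test_neighborhood_interior_counts(order, count):
    sites = ap.neighborhood_sites((10, 10), order, dims=(30, 30))
    assert len(sites) == count
    assert len(set(sites)) == count


@pytest.mark.parametrize("corner", [(0, 0), (0, 29), (29, 0), (29, 29)])
def test_neighborhood_clipping_matches_enumeration(corner):
    got = ap.neighborhood_sites(corner, 4, dims=(30, 30))
    expect = sorted((corner[0] + dx1, corner[1] + dx2)
                    for dx1, dx2 in OFF20
                    if 0 <= corner[0] + dx1 < 30 and 0 <= corner[1] + dx2 < 30)
    assert got == expect
    assert len(got) < 20


def test_neighborhood_rejects_bad_order():
    with pytest.raises(ValueError):
        ap.neighborhood_sites((5, 5), 5)


# ------------------------------------------------------------- initial state
def test_build_initial_state_default():
    cfg = ap.SimConfig().validate()
    st = ap.build_initial_state(cfg)
    assert st.n_cells == 125
    areas = st.area[1:st.n_cells + 1]
    assert (areas == 50).all()
    st.check_invariants()
    # wall band: frozen outside the gap, open inside it
    wlo, whi = cfg.wall_rows()
    glo, ghi = cfg.gap_columns()
    wall = st.sigma[wlo:whi + 1]
    assert (wall[:, glo:ghi + 1] == 0).all()
    assert (wall[:, 1:glo] == FROZEN).all()
    assert (wall[:, ghi + 1:-1] == FROZEN).all()
    # the monolayer abuts the wall from below
    assert (st.sigma[cfg.Y_gap - 1, 1:-1] > 0).any()


def test_initial_tiling_rejects_impossible_geometry():
    cfg = ap.SimConfig(X=60, Y=60, n_cells=125)
    with pytest.raises(ConfigurationError):
        plan_initial_tiling(cfg)


def test_surface_tension_of_defaults():
    p = EnergyParams.from_config(ap.SimConfig())
    assert p.gamma_CM == pytest.approx(5.0)


def test_contact_lowers_adhesion_energy():
    """Positive surface tension: merging two cell interfaces into one
    cell-cell contact lowers the summed adhesion energy."""
    params = EnergyParams.from_config(ap.SimConfig())
    apart = make_open_state(40, 40, [(5, 5, 5, 10), (20, 5, 5, 10)])
    touching = make_open_state(40, 40, [(5, 5, 5, 10), (10, 5, 5, 10)])
    e_apart = ap.total_hamiltonian(apart, params)
    e_touch = ap.total_hamiltonian(touching, params)
    assert e_touch < e_apart


# ------------------------------------------------------------------ energies
def test_area_term_of_single_site_loss():
    """A 50-site cell at its target area losing one site pays
    lambda_A * ((49-50)^2 - 0) = 25 through the area constraint."""
    cfg = ap.SimConfig(lambda_L=0.0, J_CC=0.0, J_CM=0.0, J_border=0.0)
    st = make_open_state(40, 40, [(10, 10, 10, 5)])
    params = EnergyParams.from_config(cfg)
    # retraction: medium source copies onto a corner cell site
    d = ap.delta_H_core(st, (10, 10), (9, 10), params)
    assert d == pytest.approx(cfg.lambda_A * 1.0)


def test_delta_H_against_full_hamiltonian(evolved_state, neutral_cfg):
    """Incremental energy change equals the full-grid recomputation for
    1000 random heterotypic proposals on an evolved state."""
    st, _ = evolved_state
    params = EnergyParams.from_config(neutral_cfg)
    rng = np.random.default_rng(3)
    X, Y = st.dims
    checked = 0
    while checked < 1000:
        t1 = int(rng.integers(0, X))
        t2 = int(rng.integers(0, Y))
        off = OFF20[rng.integers(0, 20)]
        s1, s2 = t1 + int(off[0]), t2 + int(off[1])
        if not (0 <= s1 < X and 0 <= s2 < Y):
            continue
        stv, ssv = int(st.sigma[t2, t1]), int(st.sigma[s2, s1])
        if stv == FROZEN or ssv == FROZEN or stv == ssv:
            continue
        h0 = ap.total_hamiltonian(st, params)
        d = ap.delta_H_core(st, (t1, t2), (s1, s2), params)
        trial = st.copy()
        apply_copy(trial, (t1, t2), ssv)
        h1 = ap.total_hamiltonian(trial, params)
        assert d == pytest.approx(h1 - h0, abs=1e-6)
        checked += 1
        if checked % 5 == 0 and ap.is_copy_connectivity_safe(st, (t1, t2)) \
                and is_gain_attached(st, (t1, t2), ssv):
            st = trial  # evolve occasionally for shape variety


# ---------------------------------------------------------------- acceptance
def test_boltzmann_closed_forms():
    assert ap.acceptance_probability(-1.0, 100.0) == 1.0
    assert ap.acceptance_probability(0.0, 100.0) == 1.0
    assert ap.acceptance_probability(100.0, 100.0) == pytest.approx(
        math.exp(-1.0))
    with pytest.raises(ValueError):
        ap.acceptance_probability(1.0, 0.0)


def test_boltzmann_accept_empirical_at_M():
    rng = np.random.default_rng(12)
    n = 100_000
    hits = sum(ap.boltzmann_accept(100.0, 100.0, rng) for _ in range(n))
    p = math.exp(-1.0)
    sd = math.sqrt(n * p * (1 - p))
    assert abs(hits - n * p) < 3 * sd


# -------------------------------------------------------------- connectivity
def test_center_of_solid_block_is_unsafe():
    st = make_open_state(20, 20, [(5, 5, 3, 3)])
    assert not ap.is_copy_connectivity_safe(st, (6, 6))


def test_bar_endpoint_safe_and_flood_fill_agreement():
    """The ring test never removes a site whose loss would split the
    cell (flood-fill oracle); endpoint removal of a bar is allowed."""
    st = make_open_state(20, 20, [(5, 5, 3, 1)])
    assert ap.is_copy_connectivity_safe(st, (5, 5))
    # oracle comparison on every site of an irregular blob
    st2 = make_open_state(24, 24, [(5, 5, 6, 3)])
    st2.sigma[8:10, 7] = 1
    st2.sigma[10, 7] = 1
    st2.set_cell_sites_stats(1, st2.cell_sites(1))
    for x1, x2 in st2.cell_sites(1):
        if ap.is_copy_connectivity_safe(st2, (int(x1), int(x2))):
            mask = st2.sigma == 1
            mask[x2, x1] = False
            _, n = ndimage.label(mask, structure=np.ones((3, 3)))
            assert n == 1, f"ring test allowed a split at {(x1, x2)}"


def test_medium_is_exempt():
    st = make_open_state(20, 20, [(5, 5, 3, 3)])
    assert ap.is_copy_connectivity_safe(st, (15, 15))


def test_last_site_cannot_be_lost():
    st = make_open_state(20, 20, [(5, 5, 1, 1)])
    assert not ap.is_copy_connectivity_safe(st, (5, 5))


def test_gain_attachment_blocks_detached_satellites():
    st = make_open_state(20, 20, [(5, 5, 3, 3)])
    assert not is_gain_attached(st, (10, 10), 1)   # two sites clear
    assert is_gain_attached(st, (8, 5), 1)         # touches the block
    assert is_gain_attached(st, (10, 10), 0)       # medium exempt


# --------------------------------------------------------------- cell length
def test_length_of_bar_and_square():
    st = make_open_state(20, 20, [(5, 5, 5, 1)])
    # 1x5 bar: lambda_max = 10, A = 5 -> sqrt(24)
    assert ap.cell_length(st.cell(1)) == pytest.approx(math.sqrt(24))
    sq = make_open_state(20, 20, [(5, 5, 3, 3)])
    wide = make_open_state(20, 20, [(5, 5, 3, 3)])
    assert ap.cell_length(sq.cell(1)) == pytest.approx(
        ap.cell_length(wide.cell(1)))  # symmetric eigenvalues
    assert ap.cell_length(sq.cell(1)) == pytest.approx(math.sqrt(8))


def test_single_site_length_is_one():
    assert length_from_sums(1, 3, 4, 9, 16, 12) == 1.0


def test_incremental_bookkeeping_matches_recount(neutral_cfg):
    """Areas, centroid and inertia sums survive ~2.4e4 copy attempts."""
    st = ap.build_initial_state(neutral_cfg)
    fields = make_uniform_fields(*st.dims)
    rng = np.random.default_rng(5)
    for _ in range(10):  # 10 MCS x 2400 sites = 2.4e4 attempts
        ap.monte_carlo_step(st, fields, neutral_cfg, rng)
    st.check_invariants()


# ------------------------------------------------------------- copy dynamics
def test_all_medium_lattice_never_changes(small_cfg):
    st = ap.LatticeState(20, 20)
    fields = make_uniform_fields(20, 20)
    rng = np.random.default_rng(0)
    before = st.sigma.copy()
    for _ in range(5):
        accepted = ap.monte_carlo_step(st, fields, small_cfg, rng)
        assert accepted == 0
    assert np.array_equal(st.sigma, before)
    assert st.mcs_counter == 5


def test_same_seed_same_trajectory(neutral_cfg):
    outs = []
    for _ in range(2):
        st = ap.build_initial_state(neutral_cfg)
        fields = make_uniform_fields(*st.dims)
        rng = np.random.default_rng(99)
        for _ in range(20):
            ap.monte_carlo_step(st, fields, neutral_cfg, rng)
        outs.append(st.sigma.copy())
    assert np.array_equal(outs[0], outs[1])


def test_kernel_and_python_paths_agree(neutral_cfg):
    """The compiled kernel and the per-attempt reference implementation
    walk the identical trajectory from the same random stream."""
    states = []
    for use_kernel in (True, False):
        st = ap.build_initial_state(neutral_cfg)
        fields = make_uniform_fields(*st.dims)
        rng = np.random.default_rng(42)
        for _ in range(5):
            ap.monte_carlo_step(st, fields, neutral_cfg, rng,
                                use_kernel=use_kernel)
        states.append(st)
    assert np.array_equal(states[0].sigma, states[1].sigma)
    assert np.array_equal(states[0].area, states[1].area)
    assert np.array_equal(states[0].sx12, states[1].sx12)


def test_frozen_target_rejected(neutral_cfg):
    st = ap.build_initial_state(neutral_cfg)
    fields = make_uniform_fields(*st.dims)
    # proposal aimed at the frozen corner site (flat index 0)
    changed = ap.attempt_copy(st, fields, neutral_cfg,
                              proposal=np.array([0.0, 0.0, 0.0]))
    assert not changed
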