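"""Division probability, axis, splitting, regrowth, sweep rules."""

import numpy as np
import pytest

import angiosprout as ap
from angiosprout.proliferation import (contact_counts, divide_cell,
                                       division_axis, division_probability,
                                       ecm_contact_ratio, growth_update,
                                       proliferation_sweep)
from conftest import make_open_state


# --------------------------------------------------------------- ECM contact
def test_isolated_cell_touches_only_medium():
    st = make_open_state(30, 30, [(10, 10, 5, 5)])
    assert ecm_contact_ratio(st, 1) == 1.0


def test_enclosed_cell_touches_no_medium():
    st = make_open_state(30, 30, [(10, 10, 9, 9)])
    j = st.add_cell(9.0, 3.0)
    st.paint_rect(j, 13, 13, 3, 3)     # carve cell 2 inside cell 1
    st.set_cell_sites_stats(1, st.cell_sites(1))
    assert ecm_contact_ratio(st, 2) == 0.0


def test_single_site_cell_half_medium_half_cells():
    """Explicit pair enumeration over the order-4 neighborhood: exactly
    half of a lone site's 20 neighbors medium, half other-cell."""
    st = make_open_state(30, 30, [])
    i = st.add_cell(1.0, 1.0)
    st.sigma[15, 15] = i
    st.set_cell_sites_stats(i, st.cell_sites(i))
    j = st.add_cell(10.0, 3.0)
    neigh = ap.neighborhood_sites((15, 15), 4)
    for x1, x2 in neigh[:10]:
        st.sigma[x2, x1] = j
    st.set_cell_sites_stats(j, st.cell_sites(j))
    assert ecm_contact_ratio(st, i, order=4) == pytest.approx(0.5)


def test_batch_counts_match_per_cell(evolved_state):
    st, _ = evolved_state
    for order in (2, 4):
        numer, denom = contact_counts(st, order)
        for i in st.live_cells():
            if i == 0:
                continue
            assert numer[i] / denom[i] == pytest.approx(
                ecm_contact_ratio(st, int(i), order=order))


# ---------------------------------------------------------------- probability
@pytest.mark.parametrize("rho_i,rho_min,expect", [
    (0.5, 0.73, 0.0),
    (0.73, 0.73, 0.0),
    (1.0, 0.73, pytest.approx(0.27)),
    (0.9, 0.5, pytest.approx(0.4)),
])
def test_division_probability_piecewise(rho_i, rho_min, expect):
    assert division_probability(rho_i, rho_min) == expect


# ----------------------------------------------------------------- axis
def test_division_axis_of_bars():
    rng = np.random.default_rng(0)
    horiz = make_open_state(20, 20, [(5, 10, 3, 1)])
    d = division_axis(horiz, 1, rng)
    assert d == pytest.approx([0.0, 1.0])
    vert = make_open_state(20, 20, [(10, 5, 1, 3)])
    d = division_axis(vert, 1, rng)
    assert abs(d[0]) == pytest.approx(1.0)
    assert d[1] == pytest.approx(0.0)


def test_degenerate_tensor_gives_random_unit_direction():
    square = make_open_state(20, 20, [(5, 5, 2, 2)])
    d1 = division_axis(square, 1, np.random.default_rng(1))
    d2 = division_axis(square, 1, np.random.default_rng(2))
    assert np.hypot(*d1) == pytest.approx(1.0)
    assert np.hypot(*d2) == pytest.approx(1.0)
    assert not np.allclose(d1, d2)


def test_axis_requires_area_two():
    st = make_open_state(20, 20, [(5, 5, 1, 1)])
    with pytest.raises(ValueError):
        division_axis(st, 1, np.random.default_rng(0))


# ----------------------------------------------------------------- splitting
def test_divide_bar_halves_targets_and_sites():
    st = make_open_state(20, 20, [(5, 10, 4, 1)])
    st.target_area[1] = 50.0
    st.target_length[1] = 15.0
    before = int(st.area[1])
    j = divide_cell(st, 1, np.random.default_rng(0))
    assert j == 2
    assert st.target_area[1] == 25.0 and st.target_area[2] == 25.0
    assert st.target_length[1] == 7.5 and st.target_length[2] == 7.5
    assert int(st.area[1] + st.area[2]) == before
    assert st.area[1] == 2 and st.area[2] == 2
    st.check_invariants()


def test_daughters_separate_along_major_axis():
    """For 100 random elongated cells the daughter centroids separate
    mainly along the parent's long axis."""
    rng = np.random.default_rng(4)
    for _ in range(100):
        w = int(rng.integers(2, 5))
        h = int(rng.integers(3 * w, 6 * w))
        if rng.random() < 0.5:
            w, h = h, w
        st = make_open_state(40, 40, [(3, 3, w, h)])
        rec = st.cell(1)
        I = rec.inertia_tensor
        evals, evecs = np.linalg.eigh(I)
        # the tensor is tr*Id - covariance, so its eigenvectors are the
        # covariance eigenvectors with the eigenvalue order swapped
        major = evecs[:, np.argmin(evals)]
        minor = evecs[:, np.argmax(evals)]
        j = divide_cell(st, 1, rng)
        assert j is not None
        c1 = np.array(st.cell(1).centroid)
        c2 = np.array(st.cell(j).centroid)
        dc = c2 - c1
        assert abs(dc @ major) > abs(dc @ minor)
        st.check_invariants()


def test_divide_conserves_connectivity():
    st = make_open_state(30, 30, [(5, 5, 3, 12)])
    j = divide_cell(st, 1, np.random.default_rng(9))
    from scipy import ndimage
    for i in (1, j):
        _, n = ndimage.label(st.sigma == i, structure=np.ones((3, 3)))
        assert n == 1


# ------------------------------------------------------------------- sweep
def test_rho_min_one_forbids_all_divisions():
    cfg = ap.SimConfig(X=40, Y=60, n_cells=6, rho_min=1.0).validate()
    st = make_open_state(40, 60, [(10, 50, 10, 5)])  # well above the wall
    rng = np.random.default_rng(0)
    for _ in range(20):
        new = proliferation_sweep(st, cfg, rng)
        assert new == []
    assert st.n_cells == 1


def test_vessel_cells_never_divide():
    cfg = ap.SimConfig(X=40, Y=60, n_cells=6, rho_min=0.0).validate()
    st = make_open_state(40, 60, [(10, 5, 10, 5)])   # inside the vessel
    rng = np.random.default_rng(0)
    for _ in range(20):
        assert proliferation_sweep(st, cfg, rng) == []


def test_exposed_cell_above_wall_divides_at_zero_threshold():
    cfg = ap.SimConfig(X=40, Y=60, n_cells=6, rho_min=0.0).validate()
    st = make_open_state(40, 60, [(10, 50, 10, 5)])
    new = proliferation_sweep(st, cfg, np.random.default_rng(0))
    assert new == [2]  # isolated: rho=1, P=1


def test_eligibility_reference_centroid_is_stricter():
    cfg = ap.SimConfig(X=40, Y=60, n_cells=6, rho_min=0.0,
                       eligibility_reference="centroid").validate()
    # tip reaches the threshold but the centroid does not
    thr = cfg.Y_gap + cfg.wall_thickness - 1 + cfg.eligibility_offset  # 46
    st = make_open_state(40, 60, [(10, 36, 3, 11)])  # rows 36..46
    assert proliferation_sweep(st, cfg, np.random.default_rng(0)) == []
    cfg_tip = cfg.replace(eligibility_reference="tip")
    st2 = make_open_state(40, 60, [(10, 36, 3, 11)])
    assert proliferation_sweep(st2, cfg_tip, np.random.default_rng(0)) == [2]


# ------------------------------------------------------------------- growth
def test_growth_schedule_regrows_daughter_in_13_sweeps():
    cfg = ap.SimConfig()
    st = make_open_state(20, 20, [(5, 5, 5, 10)])
    st.target_area[1] = 25.0
    st.target_length[1] = 7.5
    sweeps = 0
    while st.target_area[1] < cfg.A_T:
        growth_update(st, cfg)
        sweeps += 1
    assert sweeps == 13
    assert st.target_area[1] == 50.0            # capped, not 51
    assert st.target_length[1] == pytest.approx(15.0)  # capped


def test_growth_never_exceeds_nominal():
    cfg = ap.SimConfig()
    st = make_open_state(20, 20, [(5, 5, 5, 10)])
    for _ in range(5):
        growth_update(st, cfg)
    assert st.target_area[1] == cfg.A_T
    assert st.target_length[1] == cfg.L_T
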