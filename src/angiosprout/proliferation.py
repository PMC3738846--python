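"""Contact-inhibition-released cell division and gradual regrowth.

A cell divides with probability ``max(0, rho_i - rho_min)`` where
``rho_i`` is the fraction of its heterotypic boundary pairs (over the
same 20-site neighborhood as adhesion) that touch the medium: cells
largely surrounded by ECM have escaped contact inhibition. Division is
perpendicular to the cell's long axis, read off the inertia tensor; the
daughters each inherit half the parent's target area and target length
and regrow them by 2 sites and 0.6 sites per sweep up to the nominal
values. Only cells whose centroid lies at least one cell length above
the vessel wall may divide (quiescent vessel endothelium).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .config import MEDIUM, SimConfig
from .cpm import N_OFFSETS_BY_ORDER, OFF20, LatticeState

_STRUCT8 = np.ones((3, 3), dtype=bool)


def contact_counts(state: LatticeState,
                   order: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Arrays (numer, denom): per-cell medium-contact and perimeter pair
    counts over the same adjacency as the adhesion bonds."""
    from ._kernel import contact_counts as _cc
    return _cc(state.sigma, state.n_cells, N_OFFSETS_BY_ORDER[order])


def ecm_contact_ratio(state: LatticeState, i: int, order: int = 2) -> float:
    """Fraction of cell i's heterotypic boundary pairs touching medium."""
    sites = state.cell_sites(i)
    if len(sites) == 0:
        raise ValueError(f"cell {i} has no sites")
    X, Y = state.dims
    numer = 0
    denom = 0
    for x1, x2 in sites:
        for dx1, dx2 in OFF20[: N_OFFSETS_BY_ORDER[order]]:
            p1, p2 = x1 + dx1, x2 + dx2
            if not (0 <= p1 < X and 0 <= p2 < Y):
                continue
            sn = int(state.sigma[p2, p1])
            if sn != i:
                denom += 1
                if sn == MEDIUM:
                    numer += 1
    if denom == 0:
        raise ValueError(f"cell {i} has zero perimeter")
    return numer / denom


def division_probability(rho_i: float, rho_min: float) -> float:
    """Piecewise-linear release of contact inhibition."""
    if rho_i < rho_min:
        return 0.0
    return rho_i - rho_min


def division_axis(state: LatticeState, i: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Unit direction of the division plane (the cell's minor axis).

    ``d = (I_12, lambda_b - I_11)`` with ``lambda_b`` the larger
    eigenvalue of the inertia tensor. That eigenvector form vanishes
    when the long axis lies along x2 (lambda_b = I_11, I_12 = 0); the
    complementary form ``(lambda_b - I_22, I_12)`` covers that case. A
    rotationally symmetric tensor gives a uniformly random direction.
    """
    if state.area[i] < 2:
        raise ValueError(f"cell {i} has area < 2 and cannot divide")
    I = state.cell(i).inertia_tensor
    lam_b = 0.5 * (I[0, 0] + I[1, 1]
                   + np.sqrt((I[0, 0] - I[1, 1]) ** 2 + 4 * I[0, 1] ** 2))
    scale = max(abs(lam_b), 1.0)
    d = np.array([I[0, 1], lam_b - I[0, 0]], dtype=float)
    if np.hypot(*d) < 1e-9 * scale:
        d = np.array([lam_b - I[1, 1], I[0, 1]], dtype=float)
    n = np.hypot(*d)
    if n < 1e-9 * scale:
        theta = rng.uniform(0.0, 2.0 * np.pi)
        return np.array([np.cos(theta), np.sin(theta)])
    return d / n


def _components(sites: np.ndarray) -> list[np.ndarray]:
    """8-connected components of an (n, 2) site set, largest first."""
    if len(sites) == 0:
        return []
    x1min, x2min = sites.min(axis=0)
    local = sites - [x1min, x2min]
    mask = np.zeros(local.max(axis=0)[::-1] + 1, dtype=bool)
    mask[local[:, 1], local[:, 0]] = True
    lab, n = ndimage.label(mask, structure=_STRUCT8)
    comps = []
    for k in range(1, n + 1):
        rc = np.argwhere(lab == k)
        comps.append(rc[:, ::-1] + [x1min, x2min])
    comps.sort(key=len, reverse=True)
    return comps


def divide_cell(state: LatticeState, i: int, rng: np.random.Generator,
                direction: np.ndarray | None = None) -> int | None:
    """Split cell i across the plane through its centroid.

    Sites strictly on the positive side of the plane go to a new index;
    sites on the plane stay with the parent. Orphan fragments left
    disconnected on either side are reassigned to the other daughter.
    Returns the new index, or None if the split would leave a daughter
    empty or disconnected (the state is then unchanged).
    """
    sites = state.cell_sites(i)
    if len(sites) < 2:
        return None
    if direction is None:
        direction = division_axis(state, i, rng)
    c1 = state.sx1[i] / state.area[i]
    c2 = state.sx2[i] / state.area[i]
    side = ((sites[:, 0] - c1) * direction[1]
            - (sites[:, 1] - c2) * direction[0])
    new_mask = side > 1e-12
    set_new = sites[new_mask]
    set_old = sites[~new_mask]
    if len(set_new) == 0 or len(set_old) == 0:
        return None
    # reattach orphan fragments to the opposite daughter
    comps = _components(set_new)
    if len(comps) > 1:
        set_new = comps[0]
        set_old = np.concatenate([set_old] + comps[1:])
    comps = _components(set_old)
    if len(comps) > 1:
        set_old = comps[0]
        set_new = np.concatenate([set_new] + comps[1:])
        if len(_components(set_new)) > 1:
            return None  # irreducibly fragmented; abort the division
    if len(set_new) == 0 or len(set_old) == 0:
        return None
    j = state.add_cell(state.target_area[i] / 2.0,
                       state.target_length[i] / 2.0)
    state.target_area[i] /= 2.0
    state.target_length[i] /= 2.0
    state.sigma[set_new[:, 1], set_new[:, 0]] = j
    state.set_cell_sites_stats(i, set_old)
    state.set_cell_sites_stats(j, set_new)
    return j


def growth_update(state: LatticeState, cfg: SimConfig) -> None:
    """Regrow target area/length toward the nominal cell size."""
    live = state.live_cells()
    live = live[live > 0]
    state.target_area[live] = np.minimum(
        state.target_area[live] + cfg.growth_dA_T, cfg.A_T)
    state.target_length[live] = np.minimum(
        state.target_length[live] + cfg.growth_dL_T, cfg.L_T)


def proliferation_sweep(state: LatticeState, cfg: SimConfig,
                        rng: np.random.Generator) -> list[int]:
    """One proliferation step: stochastic divisions, then regrowth.

    Eligibility (centroid at least ``eligibility_offset`` above the
    wall's top edge) and the ECM-contact ratios are evaluated on a
    snapshot of the state at the start of the sweep; divisions are then
    applied in ascending cell-index order.
    """
    numer, denom = contact_counts(state, cfg.adhesion_order)
    wall_top = cfg.Y_gap + cfg.wall_thickness - 1
    threshold = wall_top + cfg.eligibility_offset
    new_cells: list[int] = []
    live = [int(i) for i in state.live_cells() if i > 0]
    if cfg.eligibility_reference == "tip":
        # topmost site per cell, one grid pass
        occ = np.argwhere(state.sigma > 0)
        tip = np.zeros(state.n_cells + 1, dtype=np.int64)
        np.maximum.at(tip, state.sigma[occ[:, 0], occ[:, 1]], occ[:, 0])
    eligible = []
    for i in live:
        if state.area[i] < 2 or denom[i] == 0:
            continue
        if cfg.eligibility_reference == "tip":
            height = float(tip[i])
        else:
            height = state.sx2[i] / state.area[i]
        if height < threshold:
            continue
        eligible.append((i, numer[i] / denom[i]))
    for i, rho_i in eligible:
        p = division_probability(rho_i, cfg.rho_min)
        if p > 0.0 and rng.random() < p:
            j = divide_cell(state, i, rng)
            if j is not None:
                new_cells.append(j)
    growth_update(state, cfg)
    return new_cells
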