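"""Cellular Potts core: lattice state, Hamiltonian, copy dynamics.

Cells are connected patches of lattice sites sharing a positive integer
index ``sigma``; index 0 is the medium (which carries the ECM field) and
the sentinel ``FROZEN`` (-1) marks immobile wall/border sites. The grid
is stored as an array of shape (Y, X) indexed ``sigma[x2, x1]`` with
``x1`` the column and ``x2`` the row counted from the vessel side
(bottom) toward the tumor (top). Public functions take sites as
``(x1, x2)`` tuples.

The effective energy is

    H = sum_bonds J(tau, tau') (1 - delta(sigma, sigma'))
        + sum_cells lambda_A (A - A_T)^2 + lambda_L (L - L_T)^2

with adhesion bonds running over the 20-site (order <= 4) neighborhood,
and copy attempts accepted with Boltzmann probability
P = exp(-dH/M) for dH >= 0 and 1 for dH < 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import FROZEN, MEDIUM, ConfigurationError, SimConfig

# ----------------------------------------------------------------------
# Neighborhood offsets (dx1, dx2), grouped by order on the square lattice
NEIGHBOR_OFFSETS_BY_ORDER: dict[int, list[tuple[int, int]]] = {
    1: [(1, 0), (-1, 0), (0, 1), (0, -1)],
    2: [(1, 1), (1, -1), (-1, 1), (-1, -1)],
    3: [(2, 0), (-2, 0), (0, 2), (0, -2)],
    4: [(1, 2), (1, -2), (-1, 2), (-1, -2),
        (2, 1), (2, -1), (-2, 1), (-2, -1)],
}

OFF20 = np.array(
    [o for k in (1, 2, 3, 4) for o in NEIGHBOR_OFFSETS_BY_ORDER[k]],
    dtype=np.int64,
)

# number of offsets within order <= k (OFF20 is sorted by order)
N_OFFSETS_BY_ORDER = {1: 4, 2: 8, 3: 12, 4: 20}


def _half_offsets(order: int) -> np.ndarray:
    """One offset per unordered bond direction within the given order."""
    offs = OFF20[: N_OFFSETS_BY_ORDER[order]]
    return np.array([o for o in offs
                     if (o[1] > 0) or (o[1] == 0 and o[0] > 0)],
                    dtype=np.int64)


# half of OFF20, one offset per unordered bond direction
HALF20 = _half_offsets(4)

# 8-neighborhood in cyclic order, for the local connectivity ring test
RING8 = np.array([(1, 0), (1, 1), (0, 1), (-1, 1),
                  (-1, 0), (-1, -1), (0, -1), (1, -1)], dtype=np.int64)


def neighborhood_sites(site: tuple[int, int], max_order: int = 4,
                       dims: tuple[int, int] | None = None
                       ) -> list[tuple[int, int]]:
    """Sites within the first- to ``max_order``-th order neighborhood.

    With ``dims = (X, Y)`` given, out-of-bounds sites are clipped away.
    Returns sites in lexicographic order.
    """
    if not 1 <= max_order <= 4:
        raise ValueError("max_order must be in 1..4")
    x1, x2 = site
    out = []
    for k in range(1, max_order + 1):
        for dx1, dx2 in NEIGHBOR_OFFSETS_BY_ORDER[k]:
            p = (x1 + dx1, x2 + dx2)
            if dims is not None:
                if not (0 <= p[0] < dims[0] and 0 <= p[1] < dims[1]):
                    continue
            out.append(p)
    return sorted(out)


# ----------------------------------------------------------------------
@dataclass
class EnergyParams:
    """Adhesion energies and shape-constraint strengths."""

    J_CC: float = 40.0
    J_CM: float = 25.0
    J_border: float = 25.0
    lambda_A: float = 25.0
    lambda_L: float = 25.0
    M: float = 100.0
    A_T_nominal: float = 50.0
    L_T_nominal: float = 15.0
    adhesion_order: int = 2  # bond adjacency: 2 = 8-neighborhood

    @property
    def gamma_CM(self) -> float:
        """Cell-medium surface tension J_CM - J_CC/2 (positive: cells adhere)."""
        return self.J_CM - self.J_CC / 2.0

    @classmethod
    def from_config(cls, cfg: SimConfig) -> "EnergyParams":
        if cfg.M <= 0:
            raise ConfigurationError("intrinsic motility M must be > 0")
        return cls(J_CC=cfg.J_CC, J_CM=cfg.J_CM, J_border=cfg.J_border,
                   lambda_A=cfg.lambda_A, lambda_L=cfg.lambda_L, M=cfg.M,
                   A_T_nominal=cfg.A_T, L_T_nominal=cfg.L_T,
                   adhesion_order=cfg.adhesion_order)


def bond_energy(sa: int, sb: int, params: EnergyParams) -> float:
    """Adhesion energy of the bond between sites with indices sa, sb."""
    if sa == sb:
        return 0.0
    a_cell, b_cell = sa > 0, sb > 0
    if a_cell and b_cell:
        return params.J_CC
    if a_cell or b_cell:
        other = sb if a_cell else sa
        return params.J_border if other == FROZEN else params.J_CM
    return 0.0  # medium-frozen interface carries no energy


# ----------------------------------------------------------------------
def length_from_sums(area: float, sx1: float, sx2: float,
                     sx11: float, sx22: float, sx12: float) -> float:
    """Rod-equivalent cell length sqrt(12 lambda_max / A).

    ``lambda_max`` is the larger eigenvalue of the inertia tensor
    I = [[S(x2-C2)^2, -S(x1-C1)(x2-C2)], [sym., S(x1-C1)^2]].
    A single-site cell has length 1 by convention.
    """
    if area <= 0:
        return 0.0
    if area == 1:
        return 1.0
    i11 = sx22 - sx2 * sx2 / area
    i22 = sx11 - sx1 * sx1 / area
    i12 = -(sx12 - sx1 * sx2 / area)
    lam_max = 0.5 * ((i11 + i22)
                     + math.sqrt((i11 - i22) ** 2 + 4.0 * i12 * i12))
    return math.sqrt(12.0 * lam_max / area)


@dataclass
class CellRecord:
    """Bookkeeping of one cell: area, targets, centroid/inertia sums."""

    index: int
    area: int
    target_area: float
    target_length: float
    sx1: int
    sx2: int
    sx11: int
    sx22: int
    sx12: int

    @property
    def centroid(self) -> tuple[float, float]:
        return self.sx1 / self.area, self.sx2 / self.area

    @property
    def inertia_tensor(self) -> np.ndarray:
        a = self.area
        i11 = self.sx22 - self.sx2 ** 2 / a
        i22 = self.sx11 - self.sx1 ** 2 / a
        i12 = -(self.sx12 - self.sx1 * self.sx2 / a)
        return np.array([[i11, i12], [i12, i22]], dtype=float)

    @property
    def length(self) -> float:
        return length_from_sums(self.area, self.sx1, self.sx2,
                                self.sx11, self.sx22, self.sx12)


def cell_length(cell: CellRecord) -> float:
    """Length estimate of a cell (see :func:`length_from_sums`)."""
    return cell.length


# ----------------------------------------------------------------------
class LatticeState:
    """The sigma grid plus per-cell bookkeeping arrays."""

    def __init__(self, X: int, Y: int, capacity: int = 16):
        self.sigma = np.zeros((Y, X), dtype=np.int32)
        self.dims = (X, Y)
        self.mcs_counter = 0
        self.n_cells = 0
        cap = capacity + 1
        self.area = np.zeros(cap, dtype=np.int64)
        self.target_area = np.zeros(cap, dtype=np.float64)
        self.target_length = np.zeros(cap, dtype=np.float64)
        self.sx1 = np.zeros(cap, dtype=np.int64)
        self.sx2 = np.zeros(cap, dtype=np.int64)
        self.sx11 = np.zeros(cap, dtype=np.int64)
        self.sx22 = np.zeros(cap, dtype=np.int64)
        self.sx12 = np.zeros(cap, dtype=np.int64)

    # -- cell management ----------------------------------------------
    def _grow(self, need: int) -> None:
        cap = len(self.area)
        if need < cap:
            return
        new = max(need + 1, 2 * cap)
        for name in ("area", "sx1", "sx2", "sx11", "sx22", "sx12",
                     "target_area", "target_length"):
            arr = getattr(self, name)
            ext = np.zeros(new, dtype=arr.dtype)
            ext[:cap] = arr
            setattr(self, name, ext)

    @classmethod
    def from_sigma(cls, sigma: np.ndarray,
                   target_area: float = 50.0,
                   target_length: float = 15.0) -> "LatticeState":
        """Reconstruct a state (with fresh bookkeeping) from a sigma grid."""
        Y, X = sigma.shape
        n = int(sigma.max(initial=0))
        st = cls(X, Y, capacity=max(16, n))
        st.sigma = sigma.astype(np.int32)
        st.n_cells = n
        st.target_area[1:n + 1] = target_area
        st.target_length[1:n + 1] = target_length
        st.recompute_bookkeeping()
        return st

    def add_cell(self, target_area: float, target_length: float) -> int:
        self.n_cells += 1
        idx = self.n_cells
        self._grow(idx)
        self.target_area[idx] = target_area
        self.target_length[idx] = target_length
        return idx

    def cell(self, i: int) -> CellRecord:
        if not (1 <= i <= self.n_cells):
            raise KeyError(f"no cell with index {i}")
        return CellRecord(i, int(self.area[i]), float(self.target_area[i]),
                          float(self.target_length[i]), int(self.sx1[i]),
                          int(self.sx2[i]), int(self.sx11[i]),
                          int(self.sx22[i]), int(self.sx12[i]))

    @property
    def cells(self) -> dict[int, CellRecord]:
        return {i: self.cell(i) for i in self.live_cells()}

    def live_cells(self) -> np.ndarray:
        return np.flatnonzero(self.area[: self.n_cells + 1] > 0)

    def cell_sites(self, i: int) -> np.ndarray:
        """(n, 2) array of (x1, x2) sites of cell i."""
        rc = np.argwhere(self.sigma == i)
        return rc[:, ::-1]

    # -- bookkeeping ---------------------------------------------------
    def set_cell_sites_stats(self, i: int, sites: np.ndarray) -> None:
        """Recompute bookkeeping of cell i from an (n, 2) site array."""
        x1 = sites[:, 0].astype(np.int64)
        x2 = sites[:, 1].astype(np.int64)
        self.area[i] = len(sites)
        self.sx1[i] = x1.sum()
        self.sx2[i] = x2.sum()
        self.sx11[i] = (x1 * x1).sum()
        self.sx22[i] = (x2 * x2).sum()
        self.sx12[i] = (x1 * x2).sum()

    def recompute_bookkeeping(self) -> None:
        for i in range(1, self.n_cells + 1):
            self.set_cell_sites_stats(i, self.cell_sites(i))

    def paint_rect(self, i: int, x1: int, x2: int, w: int, h: int) -> None:
        self.sigma[x2:x2 + h, x1:x1 + w] = i
        self.set_cell_sites_stats(i, self.cell_sites(i))

    def copy(self) -> "LatticeState":
        st = LatticeState.__new__(LatticeState)
        st.sigma = self.sigma.copy()
        st.dims = self.dims
        st.mcs_counter = self.mcs_counter
        st.n_cells = self.n_cells
        for name in ("area", "sx1", "sx2", "sx11", "sx22", "sx12",
                     "target_area", "target_length"):
            setattr(st, name, getattr(self, name).copy())
        return st

    def check_invariants(self) -> None:
        """Assert bookkeeping against a from-scratch recount."""
        total = (self.area[1:self.n_cells + 1].sum()
                 + (self.sigma == MEDIUM).sum()
                 + (self.sigma == FROZEN).sum())
        assert total == self.sigma.size, "site accounting broken"
        for i in range(1, self.n_cells + 1):
            sites = self.cell_sites(i)
            assert len(sites) == self.area[i], f"area mismatch for cell {i}"
            if len(sites) == 0:
                continue
            x1 = sites[:, 0].astype(np.int64)
            x2 = sites[:, 1].astype(np.int64)
            assert self.sx1[i] == x1.sum() and self.sx2[i] == x2.sum()
            assert self.sx11[i] == (x1 * x1).sum()
            assert self.sx22[i] == (x2 * x2).sum()
            assert self.sx12[i] == (x1 * x2).sum()


# ----------------------------------------------------------------------
def plan_initial_tiling(cfg: SimConfig) -> list[tuple[int, int, int, int]]:
    """Rectangles (x1, x2, w, h) tiling ``n_cells`` 50-site cells in the vessel.

    The monolayer abuts the wall: full bands of 10x5-site cells are
    packed downward from the wall's underside; a remainder that no
    longer fits a 5-row band is laid out as 25x2-site cells below them.
    Raises :class:`ConfigurationError` when the vessel region cannot
    hold them.
    """
    inner = cfg.X - 2  # one-site frozen frame on either side
    rects: list[tuple[int, int, int, int]] = []
    remaining = cfg.n_cells
    top = cfg.Y_gap - 1
    per10 = inner // 10
    while remaining > 0 and per10 > 0 and top - 4 >= 1:
        k = min(per10, remaining)
        start = 1 + (inner - 10 * k) // 2
        rects.extend((start + 10 * j, top - 4, 10, 5) for j in range(k))
        remaining -= k
        top -= 5
    per25 = inner // 25
    while remaining > 0 and per25 > 0 and top - 1 >= 1:
        k = min(per25, remaining)
        start = 1 + (inner - 25 * k) // 2
        rects.extend((start + 25 * j, top - 1, 25, 2) for j in range(k))
        remaining -= k
        top -= 2
    if remaining > 0:
        raise ConfigurationError(
            f"cannot fit {cfg.n_cells} cells of 50 sites below the wall "
            f"(X={cfg.X}, Y_gap={cfg.Y_gap})")
    return rects


def build_initial_state(cfg: SimConfig) -> LatticeState:
    """Initial configuration: monolayer behind a frozen wall with a gap."""
    rects = plan_initial_tiling(cfg)
    state = LatticeState(cfg.X, cfg.Y, capacity=max(16, 4 * cfg.n_cells))
    sig = state.sigma
    # frozen one-site frame around the dish
    sig[0, :] = FROZEN
    sig[-1, :] = FROZEN
    sig[:, 0] = FROZEN
    sig[:, -1] = FROZEN
    # frozen wall band with a centered gap
    wlo, whi = cfg.wall_rows()
    glo, ghi = cfg.gap_columns()
    sig[wlo:whi + 1, :] = FROZEN
    sig[wlo:whi + 1, glo:ghi + 1] = MEDIUM
    for x1, x2, w, h in rects:
        i = state.add_cell(cfg.A_T, cfg.L_T)
        state.paint_rect(i, x1, x2, w, h)
    return state


# ----------------------------------------------------------------------
def acceptance_probability(dH: float, M: float) -> float:
    """Boltzmann acceptance: exp(-dH/M) for dH >= 0, else 1."""
    if M <= 0:
        raise ValueError("motility M must be > 0")
    if dH < 0:
        return 1.0
    return math.exp(-dH / M)


def boltzmann_accept(dH: float, M: float, rng: np.random.Generator) -> bool:
    p = acceptance_probability(dH, M)
    return bool(p >= 1.0 or rng.random() < p)


def is_gain_attached(state: LatticeState, x_target: tuple[int, int],
                     gaining_index: int) -> bool:
    """True when the gained site touches the gaining cell (8-adjacency).

    Copy sources come from the 20-site neighborhood, so an order-3/4
    source would otherwise paint a detached satellite site two sites
    away from the cell body. Medium gains are exempt.
    """
    if gaining_index <= 0:
        return True
    x1, x2 = x_target
    X, Y = state.dims
    sig = state.sigma
    for dx1, dx2 in RING8:
        p1, p2 = x1 + dx1, x2 + dx2
        if 0 <= p1 < X and 0 <= p2 < Y and sig[p2, p1] == gaining_index:
            return True
    return False


def is_copy_connectivity_safe(state: LatticeState,
                              x_target: tuple[int, int]) -> bool:
    """Local ring test: may the target site leave its current cell?

    Counts membership transitions of the losing cell around the cyclic
    8-neighborhood of the target. Exactly two transitions means the
    cell's local sites form a single arc, so removal neither splits the
    cell nor punches a hole. Medium (and frozen) sites are exempt; a
    cell may not lose its last site.
    """
    x1, x2 = x_target
    s = int(state.sigma[x2, x1])
    if s <= 0:
        return True
    if state.area[s] == 1:
        return False
    X, Y = state.dims
    sig = state.sigma
    prev = None
    first = None
    transitions = 0
    for dx1, dx2 in RING8:
        p1, p2 = x1 + dx1, x2 + dx2
        member = (0 <= p1 < X and 0 <= p2 < Y and sig[p2, p1] == s)
        if prev is None:
            first = member
        elif member != prev:
            transitions += 1
        prev = member
    if prev != first:
        transitions += 1
    return transitions == 2


# ----------------------------------------------------------------------
def delta_H_core(state: LatticeState, x_target: tuple[int, int],
                 x_source: tuple[int, int], params: EnergyParams) -> float:
    """Energy change of copying sigma(x_source) onto x_target.

    Only terms that change are evaluated: adhesion bonds around the
    target (within ``params.adhesion_order``), and the area and length
    constraints of the losing and gaining cells.
    """
    X, Y = state.dims
    sig = state.sigma
    t1, t2 = x_target
    st = int(sig[t2, t1])
    ss = int(sig[x_source[1], x_source[0]])
    dE = 0.0
    # adhesion
    for dx1, dx2 in OFF20[: N_OFFSETS_BY_ORDER[params.adhesion_order]]:
        p1, p2 = t1 + dx1, t2 + dx2
        if not (0 <= p1 < X and 0 <= p2 < Y):
            continue
        sn = int(sig[p2, p1])
        dE += bond_energy(ss, sn, params) - bond_energy(st, sn, params)
    # area constraint
    if st > 0:
        a = float(state.area[st])
        at = state.target_area[st]
        dE += params.lambda_A * ((a - 1.0 - at) ** 2 - (a - at) ** 2)
    if ss > 0:
        a = float(state.area[ss])
        at = state.target_area[ss]
        dE += params.lambda_A * ((a + 1.0 - at) ** 2 - (a - at) ** 2)
    # length constraint (from updated inertia accumulators)
    if st > 0:
        lb = length_from_sums(state.area[st], state.sx1[st], state.sx2[st],
                              state.sx11[st], state.sx22[st], state.sx12[st])
        la = length_from_sums(state.area[st] - 1, state.sx1[st] - t1,
                              state.sx2[st] - t2, state.sx11[st] - t1 * t1,
                              state.sx22[st] - t2 * t2,
                              state.sx12[st] - t1 * t2)
        lt = state.target_length[st]
        dE += params.lambda_L * ((la - lt) ** 2 - (lb - lt) ** 2)
    if ss > 0:
        lb = length_from_sums(state.area[ss], state.sx1[ss], state.sx2[ss],
                              state.sx11[ss], state.sx22[ss], state.sx12[ss])
        la = length_from_sums(state.area[ss] + 1, state.sx1[ss] + t1,
                              state.sx2[ss] + t2, state.sx11[ss] + t1 * t1,
                              state.sx22[ss] + t2 * t2,
                              state.sx12[ss] + t1 * t2)
        lt = state.target_length[ss]
        dE += params.lambda_L * ((la - lt) ** 2 - (lb - lt) ** 2)
    return dE


def total_hamiltonian(state: LatticeState, params: EnergyParams) -> float:
    """Full-grid effective energy (reference implementation).

    Sums every unordered adhesion bond in the configured adjacency plus
    the area and length constraints of all live cells. Quadratic in
    lattice size; intended for validation on small lattices.
    """
    sig = state.sigma
    Y, X = sig.shape
    E = 0.0
    for dx1, dx2 in _half_offsets(params.adhesion_order):
        # slice pairs a = sigma[x], b = sigma[x + offset]
        a = sig[max(0, -dx2):Y - max(0, dx2), max(0, -dx1):X - max(0, dx1)]
        b = sig[max(0, dx2):Y + min(0, dx2), max(0, dx1):X + min(0, dx1)]
        diff = a != b
        a_cell = a > 0
        b_cell = b > 0
        cc = diff & a_cell & b_cell
        cm = (a_cell & (b == MEDIUM)) | (b_cell & (a == MEDIUM))
        cf = (a_cell & (b == FROZEN)) | (b_cell & (a == FROZEN))
        E += (params.J_CC * cc.sum() + params.J_CM * cm.sum()
              + params.J_border * cf.sum())
    for i in state.live_cells():
        if i == 0:
            continue
        a = float(state.area[i])
        L = length_from_sums(state.area[i], state.sx1[i], state.sx2[i],
                             state.sx11[i], state.sx22[i], state.sx12[i])
        E += params.lambda_A * (a - state.target_area[i]) ** 2
        E += params.lambda_L * (L - state.target_length[i]) ** 2
    return E


# ----------------------------------------------------------------------
def apply_copy(state: LatticeState, x_target: tuple[int, int],
               new_index: int) -> None:
    """Overwrite the target site's index and update bookkeeping."""
    t1, t2 = x_target
    old = int(state.sigma[t2, t1])
    state.sigma[t2, t1] = new_index
    if old > 0:
        state.area[old] -= 1
        state.sx1[old] -= t1
        state.sx2[old] -= t2
        state.sx11[old] -= t1 * t1
        state.sx22[old] -= t2 * t2
        state.sx12[old] -= t1 * t2
    if new_index > 0:
        state.area[new_index] += 1
        state.sx1[new_index] += t1
        state.sx2[new_index] += t2
        state.sx11[new_index] += t1 * t1
        state.sx22[new_index] += t2 * t2
        state.sx12[new_index] += t1 * t2


def attempt_copy(state: LatticeState, fields, cfg: SimConfig,
                 rng: np.random.Generator | None = None,
                 proposal: np.ndarray | None = None) -> bool:
    """One copy attempt (pure-Python reference path).

    Draws a uniform target site and a uniform source among its 20
    neighbors; silently rejects same-index, frozen or connectivity-
    unsafe proposals (they still count as attempts); otherwise accepts
    with Boltzmann probability on the total energy change.

    ``proposal`` may supply the three uniform deviates (site, neighbor,
    acceptance) explicitly, which lets callers replay a stream.
    """
    from .motility import dH_total  # deferred import (module cycle)

    if proposal is None:
        proposal = rng.random(3)
    X, Y = state.dims
    flat = int(proposal[0] * (X * Y))
    t2, t1 = divmod(flat, X)
    st = int(state.sigma[t2, t1])
    if st == FROZEN:
        return False
    ni = int(proposal[1] * 20)
    s1 = t1 + int(OFF20[ni, 0])
    s2 = t2 + int(OFF20[ni, 1])
    if not (0 <= s1 < X and 0 <= s2 < Y):
        return False
    ss = int(state.sigma[s2, s1])
    if ss == FROZEN or ss == st:
        return False
    if not is_copy_connectivity_safe(state, (t1, t2)):
        return False
    if not is_gain_attached(state, (t1, t2), ss):
        return False
    dH = dH_total(state, fields, cfg, (t1, t2), (s1, s2))
    if dH < 0:
        accepted = True
    else:
        accepted = proposal[2] < math.exp(-dH / cfg.M)
    if accepted:
        apply_copy(state, (t1, t2), ss)
    return accepted


def monte_carlo_step(state: LatticeState, fields, cfg: SimConfig,
                     rng: np.random.Generator, use_kernel: bool = True) -> int:
    """One MCS: N = X*Y copy attempts; returns the number accepted.

    The default path runs a compiled kernel; ``use_kernel=False`` runs
    the per-attempt Python reference over the identical random stream,
    producing the same trajectory.
    """
    X, Y = state.dims
    rand = rng.random((X * Y, 3))
    if use_kernel:
        from ._kernel import run_attempts
        accepted = run_attempts(
            state.sigma, state.area, state.target_area, state.target_length,
            state.sx1, state.sx2, state.sx11, state.sx22, state.sx12,
            fields.c_V.values, fields.c_E.values, rand,
            cfg.J_CC, cfg.J_CM, cfg.J_border, cfg.lambda_A, cfg.lambda_L,
            cfg.M, cfg.chi, cfg.Gamma, cfg.s, cfg.eta, cfg.mu, cfg.rho,
            cfg.haptokinesis_reference == "source", cfg.chemotactic_retraction,
            N_OFFSETS_BY_ORDER[cfg.adhesion_order])
    else:
        accepted = 0
        for k in range(rand.shape[0]):
            accepted += attempt_copy(state, fields, cfg, proposal=rand[k])
    state.mcs_counter += 1
    return int(accepted)
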