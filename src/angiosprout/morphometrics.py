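"""Sprout morphometrics: compactness, height, size.

All three measures are pure functions of the sigma grid. They are
computed on the largest connected component of cells, where two cells
are connected when any pair of their sites touches under 8-connectivity
(diagonal contact counts, consistent with the wide copy neighborhood).

* *compactness* C = A_object / A_hull, with A_object the number of
  component sites lying strictly above the vessel wall and A_hull the
  number of lattice sites in the rasterized convex hull of those sites.
  C = 1 for a convex (unbranched) object and approaches 0 for a highly
  branched one.
* *height*: the largest distance from the dish bottom reached by the
  component (dislodged cells are ignored).
* *size*: the number of cells in the component, including those still
  inside the parent vessel.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull

from .config import SimConfig
from .cpm import LatticeState

_STRUCT8 = np.ones((3, 3), dtype=bool)


def largest_connected_component(state: LatticeState) -> np.ndarray:
    """Sorted indices of the cells in the largest connected component.

    Ties on cell count are broken toward the component containing the
    smallest cell index. Returns an empty array when there are no cells.
    """
    mask = state.sigma > 0
    if not mask.any():
        return np.array([], dtype=np.int64)
    lab, n = ndimage.label(mask, structure=_STRUCT8)
    sig = state.sigma.ravel()
    labf = lab.ravel()
    occ = sig > 0
    pairs = np.unique(np.stack([sig[occ], labf[occ]], axis=1), axis=0)
    # each cell is one connected patch, so it maps to exactly one label
    best: tuple[int, int] | None = None  # (count, min_index) of best label
    best_label = 0
    for k in range(1, n + 1):
        members = pairs[pairs[:, 1] == k, 0]
        key = (len(members), -int(members.min()))
        if best is None or key > best:
            best = key
            best_label = k
    return np.sort(pairs[pairs[:, 1] == best_label, 0])


def _component_site_mask(state: LatticeState) -> np.ndarray:
    comp = largest_connected_component(state)
    if len(comp) == 0:
        return np.zeros_like(state.sigma, dtype=bool)
    return np.isin(state.sigma, comp)


def rasterized_hull_area(points: np.ndarray) -> int:
    """Lattice sites inside or on the convex hull of a site set.

    The hull is taken over the four corners of each site's unit pixel;
    a site counts when its center lies inside the hull or on its
    boundary. A convex lattice object therefore scores exactly its own
    site count.
    """
    points = np.asarray(points, dtype=float)
    if len(points) == 0:
        raise ValueError("empty point set has no hull")
    if len(points) == 1:
        return 1
    offs = np.array([(0.5, 0.5), (0.5, -0.5), (-0.5, 0.5), (-0.5, -0.5)])
    corners = (points[:, None, :] + offs[None, :, :]).reshape(-1, 2)
    hull = ConvexHull(corners)
    eqs = hull.equations  # rows: [a, b, c] with a*x + b*y + c <= 0 inside
    lo = points.min(axis=0).astype(int)
    hi = points.max(axis=0).astype(int)
    xs = np.arange(lo[0], hi[0] + 1)
    ys = np.arange(lo[1], hi[1] + 1)
    gx, gy = np.meshgrid(xs, ys)
    centers = np.stack([gx.ravel(), gy.ravel()], axis=1).astype(float)
    inside = np.all(centers @ eqs[:, :2].T + eqs[:, 2] <= 1e-9, axis=1)
    return int(inside.sum())


def compactness(state: LatticeState, cfg: SimConfig) -> float:
    """Area of the sprout over the area of its rasterized convex hull.

    The sprout is the part of the largest connected component lying
    strictly above the vessel wall; NaN when no such sites exist.
    """
    mask = _component_site_mask(state)
    first_above = cfg.first_row_above_wall()
    mask[:first_above, :] = False
    sites = np.argwhere(mask)[:, ::-1]  # (x1, x2)
    if len(sites) == 0:
        return float("nan")
    return len(sites) / rasterized_hull_area(sites)


def sprout_height(state: LatticeState) -> float:
    """Highest row (distance from the dish bottom) reached by the
    largest connected component; NaN when there are no cells."""
    mask = _component_site_mask(state)
    rows = np.flatnonzero(mask.any(axis=1))
    if len(rows) == 0:
        return float("nan")
    return float(rows.max())


def sprout_size(state: LatticeState) -> int:
    """Number of cells in the largest connected component."""
    return int(len(largest_connected_component(state)))


def metrics_row(state: LatticeState, cfg: SimConfig) -> dict:
    """All morphometrics of the current state as one record."""
    return {
        "mcs": state.mcs_counter,
        "compactness": compactness(state, cfg),
        "height": sprout_height(state),
        "size": sprout_size(state),
        "n_cells": int(len(state.live_cells())),
    }
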