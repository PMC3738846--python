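"""Snapshot export: labeled rasters and lossless array dumps."""

from __future__ import annotations

import colorsys

import numpy as np
import imageio.v3 as iio

from .config import FROZEN, MEDIUM


def index_colormap(max_index: int) -> np.ndarray:
    """Deterministic index -> RGB map (golden-angle hue walk).

    Row 0 is the medium (white), row 1 the frozen sentinel (black),
    rows 2.. the cell indices 1..max_index.
    """
    table = np.zeros((max_index + 2, 3), dtype=np.uint8)
    table[0] = (255, 255, 255)
    table[1] = (0, 0, 0)
    for i in range(1, max_index + 1):
        h = (i * 0.6180339887498949) % 1.0
        r, g, b = colorsys.hsv_to_rgb(h, 0.65, 0.95)
        table[i + 1] = (int(255 * r), int(255 * g), int(255 * b))
    return table


def sigma_to_rgb(sigma: np.ndarray) -> np.ndarray:
    table = index_colormap(int(sigma.max(initial=0)))
    idx = np.where(sigma == MEDIUM, 0,
                   np.where(sigma == FROZEN, 1, sigma + 1))
    # flip so the vessel side (row 0) sits at the image bottom
    return table[idx][::-1]


def render_state(sigma: np.ndarray, path) -> None:
    """Write the sigma grid as a PNG with a deterministic color map."""
    iio.imwrite(path, sigma_to_rgb(sigma))


def render_field(values: np.ndarray, path, vmax: float | None = None) -> None:
    """Write a scalar field as an 8-bit grayscale PNG."""
    vmax = float(values.max()) if vmax is None else vmax
    scaled = np.zeros_like(values) if vmax == 0 else values / vmax
    img = (np.clip(scaled, 0.0, 1.0) * 255).astype(np.uint8)
    iio.imwrite(path, img[::-1])


def dump_arrays(path, **arrays: np.ndarray) -> None:
    """Lossless dump of grids (npz)."""
    np.savez_compressed(path, **arrays)


def load_arrays(path) -> dict[str, np.ndarray]:
    with np.load(path) as data:
        return {k: data[k] for k in data.files}
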