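"""Phosphene-grid quantization and rendering.

The processed scene is reduced to an n x n electrode grid (default 32 x 32,
around the threshold of scene recognition), each cell quantized to one of 8
gray levels — implanted patients reliably distinguish roughly 4-12 levels —
and rendered as a field of round, tangent phosphenes on black. Dropped
electrode sites render entirely black.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dropout import DropoutMap
from .imaging import as_gray

__all__ = [
    "QuantizerParams",
    "PhospheneFrame",
    "quantize",
    "quantize_image",
    "downsample_to_grid",
    "render",
]

#: the 8-level gray codebook: level i maps to 36*i
DEFAULT_MAPPED_VALUES: tuple[int, ...] = (0, 36, 72, 108, 144, 180, 216, 252)


@dataclass(frozen=True)
class QuantizerParams:
    """Gray-level codebook: bin ``floor(v * n_levels / 256)`` -> mapped value."""

    n_levels: int = 8
    mapped_values: tuple[int, ...] = DEFAULT_MAPPED_VALUES

    def __post_init__(self) -> None:
        if len(self.mapped_values) != self.n_levels:
            raise ValueError("mapped_values length must equal n_levels")
        vals = list(self.mapped_values)
        if vals != sorted(set(vals)):
            raise ValueError("mapped_values must be strictly increasing")
        if vals[0] < 0 or vals[-1] > 255:
            raise ValueError("mapped_values must lie within [0, 255]")


@dataclass(frozen=True)
class PhospheneFrame:
    """Quantized intensity grid plus its rendered round-phosphene raster."""

    grid_intensities: np.ndarray
    dropout: DropoutMap
    cell_px: int
    raster: np.ndarray

    @property
    def grid_side(self) -> int:
        return self.grid_intensities.shape[0]


def quantize(value: float, params: QuantizerParams | None = None) -> int:
    """Map an 8-bit intensity to its quantized gray level."""
    if params is None:
        params = QuantizerParams()
    if not (0 <= value <= 255):
        raise ValueError(f"intensity must be in [0, 255], got {value}")
    bin_idx = int(value) * params.n_levels // 256
    return params.mapped_values[bin_idx]


def quantize_image(
    img: np.ndarray, params: QuantizerParams | None = None
) -> np.ndarray:
    """Vectorized :func:`quantize` over a whole array."""
    if params is None:
        params = QuantizerParams()
    arr = np.asarray(img)
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("intensities must be in [0, 255]")
    bins = arr.astype(np.int64) * params.n_levels // 256
    return np.asarray(params.mapped_values, dtype=np.uint8)[bins]


def downsample_to_grid(img: np.ndarray, n: int) -> np.ndarray:
    """Reduce an image to an n x n grid of block means (rounded half-up).

    The image is partitioned into n x n near-equal rectangular blocks; each
    grid cell carries the mean intensity of its block — the cell's total
    light content, the quantity an electrode would encode.
    """
    gray = as_gray(img)
    h, w = gray.shape
    if n < 1:
        raise ValueError("grid side must be at least 1")
    if h < n or w < n:
        raise ValueError(f"image {gray.shape} smaller than {n}x{n} grid")
    r_edges = (np.arange(n + 1) * h) // n
    c_edges = (np.arange(n + 1) * w) // n
    out = np.empty((n, n), dtype=np.uint8)
    for i in range(n):
        for j in range(n):
            block = gray[r_edges[i] : r_edges[i + 1], c_edges[j] : c_edges[j + 1]]
            out[i, j] = int(np.floor(block.mean() + 0.5))
    return out


def _disc_mask(cell_px: int) -> np.ndarray:
    """Filled disc of diameter cell_px; a pixel is in when its center is."""
    c = cell_px / 2.0
    coords = np.arange(cell_px) + 0.5
    dy = coords[:, None] - c
    dx = coords[None, :] - c
    return dy**2 + dx**2 <= c**2


def render(
    grid: np.ndarray,
    dmap: DropoutMap,
    cell_px: int = 16,
    quantizer: QuantizerParams | None = None,
) -> PhospheneFrame:
    """Render an intensity grid as a raster of round phosphenes.

    Each working cell contains a filled disc of diameter ``cell_px`` (discs
    tangent — the inter-phosphene gap is zero) at the quantized intensity on
    a black background; dropped cells are entirely black.
    """
    grid = np.asarray(grid)
    if grid.ndim != 2:
        raise ValueError("grid must be 2-D")
    if grid.shape != dmap.shape:
        raise ValueError(
            f"grid shape {grid.shape} does not match dropout map {dmap.shape}"
        )
    if cell_px < 1:
        raise ValueError("cell_px must be at least 1")
    if quantizer is None:
        quantizer = QuantizerParams()
    q = quantize_image(grid, quantizer)
    q = np.where(dmap.grid, 0, q).astype(np.uint8)

    disc = _disc_mask(cell_px)
    rows, cols = grid.shape
    raster = np.zeros((rows * cell_px, cols * cell_px), dtype=np.uint8)
    for i in range(rows):
        for j in range(cols):
            if q[i, j]:
                cell = raster[
                    i * cell_px : (i + 1) * cell_px, j * cell_px : (j + 1) * cell_px
                ]
                cell[disc] = q[i, j]
    return PhospheneFrame(
        grid_intensities=q, dropout=dmap, cell_px=cell_px, raster=raster
    )
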