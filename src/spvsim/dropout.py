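"""Electrode dropout simulation and dropout-handling object placement.

Electrodes malfunction over time; their phosphene sites render permanently
black ("dropouts"). The dropout-handling technique translates the object of
interest to the spot in the visual field overlapping the fewest dropped
sites. The optimal spot is found by valid-region cross-correlation of the
*availability* matrix (1 - dropout indicator) with the object's binary
support: the correlation value at a placement equals the number of working
sites under the object, so its argmax is the minimum-dropout location.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import correlate2d

from .imaging import BoundingBox, as_gray

__all__ = [
    "DropoutMap",
    "Placement",
    "generate_dropout_map",
    "best_placement",
    "apply_translation",
    "save_dropout_map",
    "load_dropout_map",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DropoutMap:
    """Boolean grid of malfunctioning phosphene sites, fixed per seed."""

    grid: np.ndarray
    rate: float
    seed: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def n_dropped(self) -> int:
        return int(self.grid.sum())


@dataclass(frozen=True)
class Placement:
    """Chosen object position on the phosphene grid.

    ``translation`` is the (row, col) shift, in grid cells, that moves the
    object from its original position to the chosen one; ``score`` is the
    number of working sites under the object's support there.
    """

    center_row: int
    center_col: int
    translation: tuple[int, int]
    score: int
    grid_shape: tuple[int, int]


def generate_dropout_map(
    rows: int, cols: int, rate: float = 0.10, seed: int = 0
) -> DropoutMap:
    """Mark exactly ``round(rate * rows * cols)`` sites as dropped.

    Sites are chosen uniformly without replacement by a seeded generator,
    so the same (rows, cols, rate, seed) always reproduces the same map —
    mirroring fixed electrode malfunction within one session.
    """
    if not (0 <= rate < 1):
        raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
    if rows < 1 or cols < 1:
        raise ValueError("grid must be at least 1x1")
    n_cells = rows * cols
    n_drop = int(np.floor(rate * n_cells + 0.5))
    grid = np.zeros(n_cells, dtype=bool)
    if n_drop:
        rng = np.random.default_rng(seed)
        grid[rng.choice(n_cells, size=n_drop, replace=False)] = True
    return DropoutMap(grid=grid.reshape(rows, cols), rate=rate, seed=seed)


def _support_array(support: np.ndarray) -> np.ndarray:
    sup = np.asarray(support)
    if sup.ndim != 2:
        raise ValueError("support must be a 2-D binary mask")
    return (sup != 0).astype(np.int32)


def best_placement(
    dmap: DropoutMap,
    support: np.ndarray,
    orig_topleft: tuple[int, int] | None = None,
    exclude=None,
) -> Placement:
    """Placement of ``support`` with the fewest dropped sites underneath.

    Cross-correlates the availability matrix (1 - dropout) with the binary
    support over all fully-inside positions and returns the argmax. Ties are
    broken by smallest Euclidean distance of the placement center to the
    object's original center, then row-major order, so results are
    deterministic and stay close to the object's true location.

    ``orig_topleft`` is the object's current grid position (defaults to the
    grid-centered position). ``exclude``, if given, is a predicate on the
    candidate top-left (row, col) marking placements that are not allowed
    (e.g. already occupied by another object).
    """
    sup = _support_array(support)
    rows, cols = dmap.shape
    sh, sw = sup.shape
    if sh > rows or sw > cols:
        raise ValueError(
            f"support {sup.shape} does not fit inside grid {dmap.shape}"
        )
    if orig_topleft is None:
        orig_topleft = ((rows - sh) // 2, (cols - sw) // 2)
    availability = (~dmap.grid).astype(np.int32)
    scores = correlate2d(availability, sup, mode="valid")

    orig_center = (orig_topleft[0] + (sh - 1) / 2, orig_topleft[1] + (sw - 1) / 2)
    best = None  # (-score, distance2, r0, c0)
    for r0 in range(scores.shape[0]):
        for c0 in range(scores.shape[1]):
            if exclude is not None and exclude((r0, c0)):
                continue
            center = (r0 + (sh - 1) / 2, c0 + (sw - 1) / 2)
            d2 = (center[0] - orig_center[0]) ** 2 + (center[1] - orig_center[1]) ** 2
            key = (-int(scores[r0, c0]), d2, r0, c0)
            if best is None or key < best:
                best = key
    if best is None:
        raise ValueError("no admissible placement (everything excluded)")
    score, _, r0, c0 = -best[0], best[1], best[2], best[3]
    return Placement(
        center_row=r0 + (sh - 1) // 2,
        center_col=c0 + (sw - 1) // 2,
        translation=(r0 - orig_topleft[0], c0 - orig_topleft[1]),
        score=int(score),
        grid_shape=(rows, cols),
    )


def apply_translation(
    img: np.ndarray,
    bbox: BoundingBox,
    placement: Placement,
    fill: int = 0,
) -> tuple[np.ndarray, BoundingBox]:
    """Move the bbox contents by the placement's grid translation.

    The grid-cell shift is scaled to pixels by the image/grid size ratio.
    The vacated source region is filled with ``fill``. A shift that would
    push the box off-image is clamped to the nearest fully-inside position
    (with a warning), so the object never leaves the frame.
    """
    gray = as_gray(img)
    h, w = gray.shape
    if not bbox.within(gray.shape):
        raise ValueError("bbox lies outside the image")
    g_rows, g_cols = placement.grid_shape
    dr_px = int(np.floor(placement.translation[0] * h / g_rows + 0.5))
    dc_px = int(np.floor(placement.translation[1] * w / g_cols + 0.5))

    new_r0 = bbox.row0 + dr_px
    new_c0 = bbox.col0 + dc_px
    clamped_r0 = min(max(new_r0, 0), h - bbox.height)
    clamped_c0 = min(max(new_c0, 0), w - bbox.width)
    if (clamped_r0, clamped_c0) != (new_r0, new_c0):
        logger.warning(
            "translation (%d, %d) px pushes bbox off-image; clamped to (%d, %d)",
            dr_px, dc_px, clamped_r0, clamped_c0,
        )
    patch = gray[bbox.slices()].copy()
    out = gray.copy()
    out[bbox.slices()] = fill
    new_bbox = BoundingBox(clamped_r0, clamped_c0, bbox.height, bbox.width)
    out[new_bbox.slices()] = patch
    return out, new_bbox


def save_dropout_map(dmap: DropoutMap, path: str | Path) -> None:
    """Store a dropout map as a small CSV grid of 0/1."""
    np.savetxt(path, dmap.grid.astype(int), fmt="%d", delimiter=",")


def load_dropout_map(path: str | Path, rate: float = 0.10, seed: int = 0) -> DropoutMap:
    grid = np.loadtxt(path, delimiter=",", dtype=int) != 0
    if grid.ndim == 1:
        grid = grid[None, :]
    return DropoutMap(grid=grid, rate=rate, seed=seed)
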