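"""Grayscale conversion and the circular field-of-view mask.

A visual-prosthesis user perceives a roughly 20-degree circular window of
the scene. The simulation restricts every frame to the inscribed disc of
the image: pixels whose centers fall outside the disc are zeroed before
the frame is reduced to the electrode grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging import as_gray, as_rgb

__all__ = ["FovParams", "to_grayscale", "make_fov_mask", "apply_fov_mask"]

# ITU-R BT.601 luma weights, the dominant RGB->gray convention.
BT601_WEIGHTS = (0.299, 0.587, 0.114)


def round_half_up(x: np.ndarray | float) -> np.ndarray | float:
    """Round with ties away from zero-half upward (0.5 -> 1)."""
    return np.floor(np.asarray(x, dtype=float) + 0.5)


@dataclass(frozen=True)
class FovParams:
    """Simulated visual field.

    ``field_of_view`` is carried as metadata (degrees of visual angle); the
    mask itself is the inscribed circle of the frame, since pixel-per-degree
    calibration depends on the capture optics.
    """

    field_of_view: float = 20.0

    def __post_init__(self) -> None:
        if self.field_of_view <= 0:
            raise ValueError("field_of_view must be positive")


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Convert an RGB image to grayscale with BT.601 luma weights.

    Already-gray input is passed through unchanged.
    """
    arr = np.asarray(img)
    if arr.ndim == 2:
        return as_gray(arr)
    rgb = as_rgb(img).astype(float)
    wr, wg, wb = BT601_WEIGHTS
    luma = wr * rgb[..., 0] + wg * rgb[..., 1] + wb * rgb[..., 2]
    return np.clip(round_half_up(luma), 0, 255).astype(np.uint8)


def make_fov_mask(
    height: int, width: int, params: FovParams | None = None
) -> np.ndarray:
    """Binary disc mask: 1 inside the inscribed circle of the frame, else 0.

    The disc has diameter ``min(height, width)`` and is centered on the
    geometric center of the frame. A pixel belongs to the disc when its
    center lies at distance <= radius from the frame center.
    """
    if height < 1 or width < 1:
        raise ValueError("mask dimensions must be at least 1x1")
    if params is None:
        params = FovParams()
    radius = min(height, width) / 2.0
    rows = np.arange(height)[:, None] + 0.5 - height / 2.0
    cols = np.arange(width)[None, :] + 0.5 - width / 2.0
    inside = rows**2 + cols**2 <= radius**2
    return inside.astype(np.uint8)


def apply_fov_mask(img: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Element-wise product of image and binary mask (outside-field -> 0)."""
    gray = as_gray(img)
    mask = np.asarray(mask)
    if mask.shape != gray.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match image shape {gray.shape}"
        )
    return (gray * (mask != 0)).astype(np.uint8)
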