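"""Shared raster types, geometry and lossless image file I/O.

Images are plain ``numpy.uint8`` arrays throughout the package:

* a *grayscale image* is a 2-D array of shape ``(height, width)``;
* an *RGB image* is a 3-D array of shape ``(height, width, 3)``.

The raster convention is row-major with the origin at the top-left corner;
bounding boxes are 0-based and half-open. Only lossless file formats (PNG,
PGM/PPM, BMP) are supported so that pipeline intermediates round-trip
bit-exactly; JPEG is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "BoundingBox",
    "ImageFormatError",
    "as_gray",
    "as_rgb",
    "is_gray",
    "is_rgb",
    "read_image",
    "write_image",
]

#: file suffixes accepted for reading and writing
LOSSLESS_SUFFIXES = {".png", ".pgm", ".ppm", ".bmp"}


class ImageFormatError(ValueError):
    """Raised for unsupported or lossy image file formats."""


def as_gray(img: np.ndarray) -> np.ndarray:
    """Validate and return ``img`` as a uint8 grayscale image."""
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise ValueError(f"grayscale image must be 2-D, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError("image must be at least 1x1")
    if arr.dtype != np.uint8:
        if np.issubdtype(arr.dtype, np.integer) or np.issubdtype(arr.dtype, np.bool_):
            if arr.min() < 0 or arr.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            arr = arr.astype(np.uint8)
        else:
            raise ValueError(f"expected integer intensities, got dtype {arr.dtype}")
    return arr


def as_rgb(img: np.ndarray) -> np.ndarray:
    """Validate and return ``img`` as a uint8 RGB image."""
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"RGB image must have shape (h, w, 3), got {arr.shape}")
    if arr.dtype != np.uint8:
        if np.issubdtype(arr.dtype, np.integer):
            if arr.min() < 0 or arr.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            arr = arr.astype(np.uint8)
        else:
            raise ValueError(f"expected integer channels, got dtype {arr.dtype}")
    return arr


def is_gray(img: np.ndarray) -> bool:
    return np.asarray(img).ndim == 2


def is_rgb(img: np.ndarray) -> bool:
    arr = np.asarray(img)
    return arr.ndim == 3 and arr.shape[2] == 3


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned pixel region, 0-based and half-open.

    Covered rows are ``[row0, row0 + height)`` and covered columns
    ``[col0, col0 + width)``.
    """

    row0: int
    col0: int
    height: int
    width: int

    def __post_init__(self) -> None:
        for name in ("row0", "col0", "height", "width"):
            object.__setattr__(self, name, int(getattr(self, name)))
        if self.height < 1 or self.width < 1:
            raise ValueError("bounding box must be at least 1x1")
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError("bounding box origin must be non-negative")

    @property
    def row1(self) -> int:
        return self.row0 + self.height

    @property
    def col1(self) -> int:
        return self.col0 + self.width

    @property
    def area(self) -> int:
        return self.height * self.width

    @property
    def center(self) -> tuple[float, float]:
        """Geometric midpoint ``(row, col)`` of the covered region."""
        return (self.row0 + (self.height - 1) / 2, self.col0 + (self.width - 1) / 2)

    def slices(self) -> tuple[slice, slice]:
        return slice(self.row0, self.row1), slice(self.col0, self.col1)

    def within(self, shape: tuple[int, ...]) -> bool:
        """True when the box lies fully inside an image of the given shape."""
        return self.row1 <= shape[0] and self.col1 <= shape[1]

    def intersects(self, other: "BoundingBox") -> bool:
        return not (
            self.row1 <= other.row0
            or other.row1 <= self.row0
            or self.col1 <= other.col0
            or other.col1 <= self.col0
        )


def _check_suffix(path: Path) -> None:
    suffix = path.suffix.lower()
    if suffix in {".jpg", ".jpeg"}:
        raise ImageFormatError(
            f"{path}: JPEG is lossy and not supported; use PNG, PGM or BMP"
        )
    if suffix not in LOSSLESS_SUFFIXES:
        raise ImageFormatError(
            f"{path}: unsupported format {suffix!r}; use PNG, PGM or BMP"
        )


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG, PGM/PPM or BMP file.

    Single-channel files yield a grayscale array, 3-channel files an RGB
    array. Alpha channels are dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    _check_suffix(path)
    with Image.open(path) as im:
        if im.mode in ("LA",):
            im = im.convert("L")
        elif im.mode in ("RGBA", "P"):
            im = im.convert("RGB")
        arr = np.asarray(im)
    if arr.ndim == 2:
        return as_gray(arr)
    return as_rgb(arr)


def write_image(img: np.ndarray, path: str | Path) -> None:
    """Write a grayscale or RGB image losslessly (round-trips bit-exactly)."""
    path = Path(path)
    _check_suffix(path)
    if is_gray(img):
        arr = as_gray(img)
    else:
        arr = as_rgb(img)
    if path.suffix.lower() == ".pgm" and arr.ndim == 3:
        raise ImageFormatError("PGM stores a single channel; use PPM or PNG for RGB")
    Image.fromarray(arr).save(path)
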