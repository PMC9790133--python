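"""Image-domain enhancement techniques for prosthetic vision.

Three techniques act on the scene before it is reduced to the phosphene
grid:

* **edge sharpening** — Canny edges of the object painted full white on top
  of the grayscale image, so object outlines survive the 8-level quantizer;
* **corner emphasis** — FAST (Features from Accelerated Segment Test)
  corners, each dilated to a 3x3 white dot (a single pixel would vanish at
  32x32 phosphene resolution);
* **clip-art substitution** — the detected object is replaced by a
  simplified high-contrast silhouette of its class, resized to the object's
  bounding box.

Object detection is pluggable: any callable mapping a grayscale image to a
list of :class:`Detection` works. :func:`stub_detector` echoes ground-truth
detections registered by the synthetic-scene generator, standing in for a
trained detector in tests.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage import feature

from .imaging import BoundingBox, as_gray, read_image

__all__ = [
    "CannyParams",
    "FastParams",
    "CornerSet",
    "ClipArtRegistry",
    "Detection",
    "DetectorError",
    "detect_edges",
    "sharpen_edges",
    "detect_corners",
    "emphasize_corners",
    "substitute_clipart",
    "resize_nearest",
    "stub_detector",
    "register_ground_truth",
]


@dataclass(frozen=True)
class CannyParams:
    """Canny edge-detector settings.

    Thresholds are fractions of the full gradient scale; the hysteresis
    keeps weak edges (above ``low_threshold``) only when connected to strong
    ones (above ``high_threshold``). ``gaussian_sigma`` is the smoothing
    width of the derivative-of-Gaussian gradient, in pixels.
    """

    low_threshold: float = 0.1
    high_threshold: float = 0.15
    gaussian_sigma: float = 1.4

    def __post_init__(self) -> None:
        if not (0 < self.low_threshold < self.high_threshold <= 1):
            raise ValueError(
                "thresholds must satisfy 0 < low < high <= 1, got "
                f"low={self.low_threshold}, high={self.high_threshold}"
            )
        if self.gaussian_sigma <= 0:
            raise ValueError("gaussian_sigma must be positive")


@dataclass(frozen=True)
class FastParams:
    """FAST segment-test settings.

    ``t`` is the intensity threshold as a fraction of the 0-255 scale; a
    circle pixel counts as brighter/darker only when it differs from the
    center by more than ``t * 255``. ``n_contiguous`` is the arc length
    required on the 16-pixel Bresenham circle of radius 3. ``min_quality``
    discards corners scoring below that fraction of the strongest corner.
    """

    t: float = 0.2
    n_contiguous: int = 12
    min_quality: float = 0.1

    def __post_init__(self) -> None:
        if not (0 < self.t < 1):
            raise ValueError("t must be in (0, 1)")
        if not (9 <= self.n_contiguous <= 16):
            raise ValueError("n_contiguous must be in [9, 16]")
        if not (0 <= self.min_quality <= 1):
            raise ValueError("min_quality must be in [0, 1]")


#: 16-pixel Bresenham circle of radius 3, clockwise from 12 o'clock,
#: as (row, col) offsets.
FAST_CIRCLE: tuple[tuple[int, int], ...] = (
    (-3, 0), (-3, 1), (-2, 2), (-1, 3),
    (0, 3), (1, 3), (2, 2), (3, 1),
    (3, 0), (3, -1), (2, -2), (1, -3),
    (0, -3), (-1, -3), (-2, -2), (-3, -1),
)


@dataclass(frozen=True)
class CornerSet:
    """Detected corners: (row, col) coordinates with segment-test scores."""

    points: tuple[tuple[int, int], ...]
    scores: tuple[float, ...] = ()

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class Detection:
    """One detected object: class label, bounding box and confidence."""

    label: str
    bbox: BoundingBox
    score: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.score <= 1):
            raise ValueError("detection score must be in [0, 1]")


class DetectorError(RuntimeError):
    """Raised when the stub detector has no ground truth for an image."""


def detect_edges(img: np.ndarray, params: CannyParams | None = None) -> np.ndarray:
    """Binary Canny edge map of a grayscale image.

    Runs the full Canny chain: derivative-of-Gaussian gradient,
    non-maximum suppression, and double-threshold hysteresis.
    """
    gray = as_gray(img)
    if gray.shape[0] < 3 or gray.shape[1] < 3:
        raise ValueError("edge detection requires an image of at least 3x3")
    if params is None:
        params = CannyParams()
    edges = feature.canny(
        gray.astype(float) / 255.0,
        sigma=params.gaussian_sigma,
        low_threshold=params.low_threshold,
        high_threshold=params.high_threshold,
    )
    return edges.astype(np.uint8)


def sharpen_edges(img: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Saturating overlay of the edge map: edge pixels become white.

    Equivalent to ``clip(img + 255 * edges, 0, 255)``; non-edge pixels are
    untouched, so the operation never darkens any pixel.
    """
    gray = as_gray(img)
    edges = np.asarray(edges)
    if edges.shape != gray.shape:
        raise ValueError(
            f"edge map shape {edges.shape} does not match image {gray.shape}"
        )
    return np.where(edges != 0, np.uint8(255), gray)


def _segment_scores(img: np.ndarray, n_contiguous: int) -> np.ndarray:
    """Per-pixel FAST segment-test score.

    The score of pixel p is the largest margin m such that some arc of
    ``n_contiguous`` contiguous circle pixels is entirely brighter than
    I(p) by at least m, or entirely darker by at least m. A pixel is a
    corner at threshold t when its score exceeds t*255. Border pixels
    (within 3 of the edge) score 0.
    """
    h, w = img.shape
    scores = np.zeros((h, w), dtype=np.int32)
    if h < 7 or w < 7:
        return scores
    center = img[3 : h - 3, 3 : w - 3].astype(np.int32)
    ring = np.stack(
        [img[3 + dr : h - 3 + dr, 3 + dc : w - 3 + dc] for dr, dc in FAST_CIRCLE]
    ).astype(np.int32)
    inner = np.full(center.shape, -(10**9), dtype=np.int32)
    for margins in (ring - center[None], center[None] - ring):
        # wrap the circle so arcs crossing index 0 are covered
        tiled = np.concatenate([margins, margins[: n_contiguous - 1]], axis=0)
        for k in range(16):
            arc_min = np.minimum.reduce(tiled[k : k + n_contiguous])
            np.maximum(inner, arc_min, out=inner)
    scores[3 : h - 3, 3 : w - 3] = np.maximum(inner, 0)
    return scores


def _nms_keep(scores: np.ndarray, candidates: np.ndarray) -> np.ndarray:
    """3x3 non-maximum suppression with row-major tie-break.

    A candidate survives when every 3x3 neighbor has a strictly lower
    score, or an equal score but a later row-major position.
    """
    h, w = scores.shape
    keep = candidates.copy()
    rows, cols = np.nonzero(candidates)
    for r, c in zip(rows, cols):
        s = scores[r, c]
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if not (0 <= rr < h and 0 <= cc < w):
                    continue
                sn = scores[rr, cc]
                if sn > s or (sn == s and (rr, cc) < (r, c)):
                    keep[r, c] = False
                    break
            if not keep[r, c]:
                break
    return keep


def detect_corners(img: np.ndarray, params: FastParams | None = None) -> CornerSet:
    """FAST corner detection on the 16-pixel Bresenham circle of radius 3.

    A pixel is a corner when at least ``n_contiguous`` contiguous circle
    pixels are all brighter than the center by more than ``t*255`` or all
    darker by more than ``t*255``. Each corner is scored by the largest
    threshold that preserves its cornerness; 3x3 non-maximum suppression is
    applied, then corners below ``min_quality`` of the maximum score are
    dropped.
    """
    gray = as_gray(img)
    if gray.shape[0] < 7 or gray.shape[1] < 7:
        raise ValueError("FAST requires an image of at least 7x7")
    if params is None:
        params = FastParams()
    scores = _segment_scores(gray, params.n_contiguous)
    candidates = scores > params.t * 255.0
    if not candidates.any():
        return CornerSet(points=())
    keep = _nms_keep(scores, candidates)
    rows, cols = np.nonzero(keep)
    kept_scores = scores[rows, cols].astype(float)
    cutoff = params.min_quality * kept_scores.max()
    sel = kept_scores >= cutoff
    pts = tuple((int(r), int(c)) for r, c in zip(rows[sel], cols[sel]))
    return CornerSet(points=pts, scores=tuple(kept_scores[sel]))


def emphasize_corners(img: np.ndarray, corners: CornerSet) -> np.ndarray:
    """Paint each corner pixel and its 3x3 neighborhood white."""
    gray = as_gray(img).copy()
    h, w = gray.shape
    for r, c in corners.points:
        r0, r1 = max(r - 1, 0), min(r + 2, h)
        c0, c1 = max(c - 1, 0), min(c + 2, w)
        gray[r0:r1, c0:c1] = 255
    return gray


@dataclass
class ClipArtRegistry:
    """Mapping from object class label to a grayscale clip-art raster."""

    arts: dict[str, np.ndarray] = field(default_factory=dict)

    def add(self, label: str, art: np.ndarray) -> None:
        if label in self.arts:
            raise ValueError(f"duplicate clip-art label {label!r}")
        self.arts[label] = as_gray(art)

    def get(self, label: str) -> np.ndarray:
        try:
            return self.arts[label]
        except KeyError:
            raise KeyError(f"no clip art registered for label {label!r}") from None

    def __contains__(self, label: str) -> bool:
        return label in self.arts

    @classmethod
    def from_directory(cls, path: str | Path) -> "ClipArtRegistry":
        """Load every ``<label>.png`` (or .pgm/.bmp) in a directory."""
        path = Path(path)
        reg = cls()
        for f in sorted(path.iterdir()):
            if f.suffix.lower() in {".png", ".pgm", ".bmp"}:
                img = read_image(f)
                if img.ndim == 3:
                    from .preprocess import to_grayscale

                    img = to_grayscale(img)
                reg.add(f.stem, img)
        return reg


def resize_nearest(img: np.ndarray, height: int, width: int) -> np.ndarray:
    """Nearest-neighbor resize, preserving hard silhouette boundaries."""
    gray = as_gray(img)
    src_h, src_w = gray.shape
    rows = (np.arange(height) * src_h) // height
    cols = (np.arange(width) * src_w) // width
    return gray[np.ix_(rows, cols)]


def substitute_clipart(
    img: np.ndarray, det: Detection, registry: ClipArtRegistry
) -> np.ndarray:
    """Replace the detected object's bounding box with its class clip art.

    The clip art is resized (nearest-neighbor) to exactly the bbox size;
    pixels outside the bbox are untouched.
    """
    gray = as_gray(img)
    if not det.bbox.within(gray.shape):
        raise ValueError("detection bbox lies outside the image")
    art = registry.get(det.label)
    out = gray.copy()
    out[det.bbox.slices()] = resize_nearest(art, det.bbox.height, det.bbox.width)
    return out


# Ground-truth sidecar store for the stub detector, keyed by image content.
_GROUND_TRUTH: dict[str, tuple[Detection, ...]] = {}


def _image_key(img: np.ndarray) -> str:
    gray = as_gray(img)
    digest = hashlib.sha256(gray.tobytes()).hexdigest()
    return f"{gray.shape[0]}x{gray.shape[1]}:{digest}"


def register_ground_truth(img: np.ndarray, detections: list[Detection]) -> None:
    """Attach ground-truth detections to an image (by content hash)."""
    _GROUND_TRUTH[_image_key(img)] = tuple(detections)


def stub_detector(img: np.ndarray) -> list[Detection]:
    """Deterministic detector echoing registered ground truth.

    Stands in for a trained object detector: synthetic scenes register
    their true detections at generation time; this returns them in
    left-to-right order. A real detector backend can be slotted in through
    the same image -> list-of-Detection contract.
    """
    key = _image_key(img)
    if key not in _GROUND_TRUTH:
        raise DetectorError(
            "no ground-truth detections registered for this image; "
            "use a synthetic scene or provide detections explicitly"
        )
    dets = sorted(_GROUND_TRUTH[key], key=lambda d: (d.bbox.col0, d.bbox.row0))
    return list(dets)
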