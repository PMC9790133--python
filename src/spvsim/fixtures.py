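"""Synthetic scenes and clip arts for fully offline, deterministic testing.

Scenes emulate the experimental tabletop: high-contrast object silhouettes
(bottle, cup, banana, car toy, laptop, plus backpack and chair for
navigation scenes) rendered dark on a light background. Shapes are
parametric — rectangles, ellipse arcs and crescents in box-local
coordinates — so position and scale are exact and ground-truth bounding
boxes are computed from the rendered mask itself (hence always tight).

Each generated scene registers its ground-truth detections with the stub
detector, standing in for a trained object detector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .enhance import ClipArtRegistry, Detection, register_ground_truth
from .imaging import BoundingBox, write_image

__all__ = [
    "SceneObject",
    "SceneSpec",
    "SceneError",
    "OBJECT_LABELS",
    "make_scene",
    "make_clipart",
    "default_registry",
    "standard_scene_specs",
    "export_scenes",
]


class SceneError(ValueError):
    """Invalid scene specification (overlap, out of frame, unknown label)."""


@dataclass(frozen=True)
class SceneObject:
    """One object to place: template label and its nominal box."""

    label: str
    row0: int
    col0: int
    height: int
    width: int


@dataclass(frozen=True)
class SceneSpec:
    """A synthetic tabletop scene.

    Background defaults to light gray 230 — bright enough for the
    white-table contrast of the experiments while leaving headroom so
    edge sharpening to 255 stays visible after 8-level quantization.
    """

    objects: tuple[SceneObject, ...] = ()
    size: tuple[int, int] = (256, 256)
    background: int = 230
    foreground: int = 40
    seed: int = 0


def _grid(h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Normalized box-local coordinates in [0, 1): y rows, x cols."""
    y = (np.arange(h)[:, None] + 0.5) / h
    x = (np.arange(w)[None, :] + 0.5) / w
    return y, x


def _ellipse(y, x, cy, cx, ry, rx) -> np.ndarray:
    return ((y - cy) / ry) ** 2 + ((x - cx) / rx) ** 2 <= 1.0


def _bottle(h: int, w: int) -> np.ndarray:
    y, x = _grid(h, w)
    neck = (y < 0.30) & (np.abs(x - 0.5) <= 0.20)
    body = y >= 0.30
    return neck | body


def _cup(h: int, w: int) -> np.ndarray:
    y, x = _grid(h, w)
    body = x < 0.72
    handle = _ellipse(y, x, 0.5, 0.70, 0.32, 0.30) & ~_ellipse(
        y, x, 0.5, 0.70, 0.16, 0.15
    ) & (x >= 0.70)
    return body | handle


def _banana(h: int, w: int) -> np.ndarray:
    y, x = _grid(h, w)
    outer = _ellipse(y, x, 0.20, 0.5, 0.80, 0.50)
    inner = _ellipse(y, x, -0.20, 0.5, 0.80, 0.50)
    return outer & ~inner


def _car(h: int, w: int) -> np.ndarray:
    y, x = _grid(h, w)
    cabin = (y < 0.25) & (np.abs(x - 0.5) <= 0.25)
    body = (y >= 0.25) & (y < 0.70)
    wheels = _ellipse(y, x, 0.82, 0.25, 0.18, 0.13) | _ellipse(
        y, x, 0.82, 0.75, 0.18, 0.13
    )
    return cabin | body | wheels


def _laptop(h: int, w: int) -> np.ndarray:
    y, x = _grid(h, w)
    screen = (y < 0.55) & (np.abs(x - 0.5) <= 0.35)
    base = y >= 0.55
    return screen | base


def _backpack(h: int, w: int) -> np.ndarray:
    y, x = _grid(h, w)
    body = (y >= 0.15) & (np.abs(x - 0.5) <= 0.40)
    flap = (y < 0.15) & (np.abs(x - 0.5) <= 0.20)
    pockets = (y >= 0.40) & (y < 0.80) & (np.abs(x - 0.5) > 0.40)
    return body | flap | pockets


def _chair(h: int, w: int) -> np.ndarray:
    y, x = _grid(h, w)
    backrest = (x < 0.18) & (y < 0.60)
    seat = (y >= 0.45) & (y < 0.60)
    legs = (y >= 0.60) & ((x < 0.15) | (x >= 0.85))
    return backrest | seat | legs


_TEMPLATES = {
    "bottle": _bottle,
    "cup": _cup,
    "banana": _banana,
    "car": _car,
    "laptop": _laptop,
    "backpack": _backpack,
    "chair": _chair,
}

OBJECT_LABELS: tuple[str, ...] = tuple(_TEMPLATES)


def _tight_bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return rows[0], cols[0], rows[-1] - rows[0] + 1, cols[-1] - cols[0] + 1


def make_scene(spec: SceneSpec) -> tuple[np.ndarray, list[Detection]]:
    """Render a scene and return it with its ground-truth detections.

    Deterministic: the same spec always yields bit-identical images. The
    returned bounding boxes tightly contain every non-background pixel of
    their object; detections are also registered with the stub detector.
    """
    h, w = spec.size
    img = np.full((h, w), spec.background, dtype=np.uint8)
    detections: list[Detection] = []
    for obj in spec.objects:
        if obj.label not in _TEMPLATES:
            raise SceneError(
                f"unknown object label {obj.label!r}; known: {sorted(_TEMPLATES)}"
            )
        if obj.row0 < 0 or obj.col0 < 0 or obj.row0 + obj.height > h or obj.col0 + obj.width > w:
            raise SceneError(f"object {obj.label!r} does not fit inside the frame")
        mask = _TEMPLATES[obj.label](obj.height, obj.width)
        r, c, bh, bw = _tight_bbox(mask)
        bbox = BoundingBox(obj.row0 + r, obj.col0 + c, bh, bw)
        for prev in detections:
            if bbox.intersects(prev.bbox):
                raise SceneError(
                    f"objects {obj.label!r} and {prev.label!r} overlap"
                )
        region = img[obj.row0 : obj.row0 + obj.height, obj.col0 : obj.col0 + obj.width]
        region[mask] = spec.foreground
        detections.append(Detection(label=obj.label, bbox=bbox, score=1.0))
    register_ground_truth(img, detections)
    return img, detections


def make_clipart(label: str, size: int = 64) -> np.ndarray:
    """High-contrast binary silhouette of a template, black on white."""
    if label not in _TEMPLATES:
        raise KeyError(f"no clip-art template for label {label!r}")
    mask = _TEMPLATES[label](size, size)
    art = np.full((size, size), 255, dtype=np.uint8)
    art[mask] = 0
    return art


def default_registry(size: int = 64) -> ClipArtRegistry:
    """Registry holding the synthetic clip art of every template."""
    reg = ClipArtRegistry()
    for label in _TEMPLATES:
        reg.add(label, make_clipart(label, size))
    return reg


def standard_scene_specs(size: tuple[int, int] = (256, 256)) -> dict[str, SceneSpec]:
    """The standard scene set mirroring the experimental conditions.

    Five single objects (cup, bottle, banana, car toy, laptop), three pairs
    (bottle+cup, bottle+banana, banana+cup) and three navigation objects of
    small/medium/large size (bottle, backpack, chair).
    """
    h, w = size

    def centered(label, oh, ow):
        return SceneSpec(
            objects=(SceneObject(label, (h - oh) // 2, (w - ow) // 2, oh, ow),),
            size=size,
        )

    def pair(label_a, label_b):
        oh, ow = h // 2, w // 4
        top = (h - oh) // 2
        return SceneSpec(
            objects=(
                SceneObject(label_a, top, w // 8, oh, ow),
                SceneObject(label_b, top, w - w // 8 - ow, oh, ow),
            ),
            size=size,
        )

    specs = {
        "single-cup": centered("cup", h // 3, w // 3),
        "single-bottle": centered("bottle", h // 2, w // 5),
        "single-banana": centered("banana", h // 3, w // 2),
        "single-car": centered("car", h // 4, w // 2),
        "single-laptop": centered("laptop", h // 3, w // 2),
        "pair-bottle-cup": pair("bottle", "cup"),
        "pair-bottle-banana": pair("bottle", "banana"),
        "pair-banana-cup": pair("banana", "cup"),
        "nav-bottle": centered("bottle", h // 3, w // 8),
        "nav-backpack": centered("backpack", h // 2, w // 3),
        "nav-chair": centered("chair", 3 * h // 4, w // 2),
    }
    return specs


def export_scenes(out_dir: str | Path, size: tuple[int, int] = (256, 256)) -> list[Path]:
    """Write the standard scene set as PNG + JSON detection sidecars."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, spec in standard_scene_specs(size).items():
        img, dets = make_scene(spec)
        png = out_dir / f"{name}.png"
        write_image(img, png)
        sidecar = out_dir / f"{name}.json"
        sidecar.write_text(
            json.dumps(
                [
                    {
                        "label": d.label,
                        "bbox": [d.bbox.row0, d.bbox.col0, d.bbox.height, d.bbox.width],
                        "score": d.score,
                    }
                    for d in dets
                ],
                indent=2,
            )
        )
        written.extend([png, sidecar])
    return written
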