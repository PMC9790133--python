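"""Full simulation pipeline with per-technique toggles.

One frame flows through: grayscale conversion -> per-object enhancements
(clip-art substitution, Canny edge sharpening, FAST corner emphasis,
dropout-handling translation, each independently toggleable) -> circular
field-of-view mask -> block-mean reduction to the electrode grid ->
8-level quantization -> round-phosphene rendering with the seeded dropout
map. The field-of-view mask is applied after object translation so dropout
handling can never move an object outside the visible disc.

The eight named condition presets mirror the single-object experimental
conditions: a control with no enhancement, six pairwise combinations, and
all four techniques together.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import dropout as dropout_mod
from .dropout import generate_dropout_map
from .enhance import (
    CannyParams,
    ClipArtRegistry,
    Detection,
    FastParams,
    detect_corners,
    detect_edges,
    emphasize_corners,
    sharpen_edges,
    stub_detector,
    substitute_clipart,
)
from .imaging import BoundingBox, as_gray
from .phosphene import PhospheneFrame, QuantizerParams, downsample_to_grid, render
from .preprocess import FovParams, apply_fov_mask, make_fov_mask, to_grayscale

__all__ = [
    "PipelineConfig",
    "CONDITIONS",
    "condition_config",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to turn one captured frame into a phosphene view."""

    grid_side: int = 32
    field_of_view: float = 20.0
    dropout_rate: float = 0.10
    seed: int = 0
    cell_px: int = 16
    use_clipart: bool = False
    use_edges: bool = False
    use_corners: bool = False
    use_dropout_handling: bool = False
    canny: CannyParams = field(default_factory=CannyParams)
    fast: FastParams = field(default_factory=FastParams)
    quantizer: QuantizerParams = field(default_factory=QuantizerParams)

    @property
    def needs_detections(self) -> bool:
        return (
            self.use_clipart
            or self.use_edges
            or self.use_corners
            or self.use_dropout_handling
        )


#: the 8 experimental condition presets:
#: (use_clipart, use_edges, use_corners, use_dropout_handling)
CONDITIONS: dict[str, tuple[bool, bool, bool, bool]] = {
    "control": (False, False, False, False),
    "dropout-clipart": (True, False, False, True),
    "dropout-edges": (False, True, False, True),
    "dropout-fast": (False, False, True, True),
    "edges-fast": (False, True, True, False),
    "clipart-edges": (True, True, False, False),
    "clipart-fast": (True, False, True, False),
    "all": (True, True, True, True),
}


def condition_config(name: str, **overrides) -> PipelineConfig:
    """Pipeline config for a named condition preset."""
    if name not in CONDITIONS:
        raise KeyError(
            f"unknown condition {name!r}; choose from {', '.join(CONDITIONS)}"
        )
    clip, edges, corners, dh = CONDITIONS[name]
    return PipelineConfig(
        use_clipart=clip,
        use_edges=edges,
        use_corners=corners,
        use_dropout_handling=dh,
        **overrides,
    )


def _grid_support(
    obj_mask: np.ndarray, grid_side: int
) -> tuple[np.ndarray, tuple[int, int]] | None:
    """Object silhouette at grid resolution: (support, grid top-left).

    A grid cell belongs to the support when any object pixel falls in it.
    Returns None for an empty mask.
    """
    h, w = obj_mask.shape
    r_edges = (np.arange(grid_side + 1) * h) // grid_side
    c_edges = (np.arange(grid_side + 1) * w) // grid_side
    occupancy = np.zeros((grid_side, grid_side), dtype=bool)
    for i in range(grid_side):
        for j in range(grid_side):
            block = obj_mask[r_edges[i] : r_edges[i + 1], c_edges[j] : c_edges[j + 1]]
            occupancy[i, j] = bool(block.any())
    if not occupancy.any():
        return None
    rows = np.flatnonzero(occupancy.any(axis=1))
    cols = np.flatnonzero(occupancy.any(axis=0))
    support = occupancy[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    return support, (int(rows[0]), int(cols[0]))


def _object_mask(region: np.ndarray, background: float) -> np.ndarray:
    """Pixels of a bbox region that belong to the object (darker side)."""
    return region.astype(float) < (background + region.astype(float).min()) / 2


def run_pipeline(
    img: np.ndarray,
    cfg: PipelineConfig | None = None,
    detections: list[Detection] | None = None,
    registry: ClipArtRegistry | None = None,
    trace: dict | None = None,
) -> PhospheneFrame:
    """Run the full pipeline on one frame; deterministic given (img, cfg).

    ``detections`` may be supplied explicitly (e.g. from a sidecar file or a
    real detector); otherwise the stub detector is consulted when any
    object-level enhancement is enabled. ``registry`` defaults to the
    synthetic clip-art registry. When a ``trace`` dict is passed, the chosen
    placements and the pre-mask working image are recorded in it for
    inspection.
    """
    if cfg is None:
        cfg = PipelineConfig()
    gray = to_grayscale(img) if np.asarray(img).ndim == 3 else as_gray(img)
    work = gray.copy()
    h, w = work.shape
    logger.info("pipeline start: %dx%d frame, seed %d", h, w, cfg.seed)

    dmap = generate_dropout_map(
        cfg.grid_side, cfg.grid_side, cfg.dropout_rate, cfg.seed
    )

    dets: list[Detection] = []
    if cfg.needs_detections:
        if detections is None:
            dets = stub_detector(gray)
        else:
            dets = sorted(detections, key=lambda d: (d.bbox.col0, d.bbox.row0))
    if cfg.use_clipart and dets and registry is None:
        from .fixtures import default_registry

        registry = default_registry()

    # scene background estimate: vacated regions are refilled with it
    background = float(np.median(gray))
    placed_boxes: list[BoundingBox] = []
    for det in dets:
        bbox = det.bbox
        logger.info("object %s at %s", det.label, bbox)
        if cfg.use_clipart:
            work = substitute_clipart(work, Detection(det.label, bbox), registry)

        support_info = None
        if cfg.use_dropout_handling:
            # object silhouette on the full canvas, before edge/corner
            # whitening, reduced to its footprint on the electrode grid
            full_mask = np.zeros((h, w), dtype=bool)
            full_mask[bbox.slices()] = _object_mask(work[bbox.slices()], background)
            support_info = _grid_support(full_mask, cfg.grid_side)

        if cfg.use_edges:
            region = work[bbox.slices()]
            if region.shape[0] >= 3 and region.shape[1] >= 3:
                edges = detect_edges(region, cfg.canny)
                work[bbox.slices()] = sharpen_edges(region, edges)
        if cfg.use_corners:
            region = work[bbox.slices()]
            if region.shape[0] >= 7 and region.shape[1] >= 7:
                corners = detect_corners(region, cfg.fast)
                work[bbox.slices()] = emphasize_corners(region, corners)

        if cfg.use_dropout_handling:
            if support_info is None:
                # featureless region: fall back to an all-ones bbox support
                support = np.ones(
                    (
                        max((bbox.height * cfg.grid_side) // h, 1),
                        max((bbox.width * cfg.grid_side) // w, 1),
                    ),
                    dtype=bool,
                )
                orig_topleft = (
                    (bbox.row0 * cfg.grid_side) // h,
                    (bbox.col0 * cfg.grid_side) // w,
                )
            else:
                support, orig_topleft = support_info

            def _excluded(topleft, _bbox=bbox, _orig=orig_topleft):
                # a placement is admissible only when the implied pixel bbox
                # stays fully inside the frame and collides with no
                # previously placed object
                dr = topleft[0] - _orig[0]
                dc = topleft[1] - _orig[1]
                dr_px = int(np.floor(dr * h / cfg.grid_side + 0.5))
                dc_px = int(np.floor(dc * w / cfg.grid_side + 0.5))
                r0 = _bbox.row0 + dr_px
                c0 = _bbox.col0 + dc_px
                if r0 < 0 or c0 < 0 or r0 + _bbox.height > h or c0 + _bbox.width > w:
                    return True
                cand = BoundingBox(r0, c0, _bbox.height, _bbox.width)
                return any(cand.intersects(p) for p in placed_boxes)

            placement = dropout_mod.best_placement(
                dmap,
                support,
                orig_topleft=orig_topleft,
                exclude=_excluded,
            )
            logger.info(
                "placement for %s: center (%d, %d), translation %s, score %d",
                det.label,
                placement.center_row,
                placement.center_col,
                placement.translation,
                placement.score,
            )
            work, new_bbox = dropout_mod.apply_translation(
                work, bbox, placement, fill=int(round(background))
            )
            placed_boxes.append(new_bbox)
            if trace is not None:
                trace.setdefault("placements", []).append(
                    (det.label, support, orig_topleft, placement, new_bbox)
                )
        else:
            placed_boxes.append(bbox)

    if trace is not None:
        trace["pre_mask"] = work.copy()
        trace["dropout_map"] = dmap
    mask = make_fov_mask(h, w, FovParams(field_of_view=cfg.field_of_view))
    masked = apply_fov_mask(work, mask)
    grid = downsample_to_grid(masked, cfg.grid_side)
    frame = render(grid, dmap, cfg.cell_px, cfg.quantizer)
    logger.info("pipeline done: raster %s", frame.raster.shape)
    return frame
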