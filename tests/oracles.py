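"""Independent brute-force oracles used to check the fast implementations.

Everything here is written as plainly as possible — explicit Python loops
over pixel coordinates — and shares no code with the package internals.
"""

from __future__ import annotations

import numpy as np

# 16-pixel Bresenham circle of radius 3, clockwise from 12 o'clock.
CIRCLE = [
    (-3, 0), (-3, 1), (-2, 2), (-1, 3),
    (0, 3), (1, 3), (2, 2), (3, 1),
    (3, 0), (3, -1), (2, -2), (1, -3),
    (0, -3), (-1, -3), (-2, -2), (-3, -1),
]


def fast_score(img: np.ndarray, r: int, c: int, n: int) -> int:
    """Segment-test score of one pixel by explicit enumeration.

    The score is the largest margin m for which some arc of n contiguous
    circle pixels is entirely brighter than the center by >= m, or entirely
    darker by >= m (0 when no arc qualifies even at margin 1).
    """
    center = int(img[r, c])
    ring = [int(img[r + dr, c + dc]) for dr, dc in CIRCLE]
    best = 0
    for start in range(16):
        arc = [ring[(start + k) % 16] for k in range(n)]
        bright = min(v - center for v in arc)
        dark = min(center - v for v in arc)
        best = max(best, bright, dark)
    return best


def fast_corners(img: np.ndarray, t: float, n: int, min_quality: float):
    """Full FAST detection by brute force: scores, 3x3 NMS, quality filter.

    NMS keeps a candidate when every 3x3 neighbor scores strictly lower, or
    equal but later in row-major order.
    """
    h, w = img.shape
    thresh = t * 255.0
    scores = {}
    for r in range(3, h - 3):
        for c in range(3, w - 3):
            s = fast_score(img, r, c, n)
            if s > thresh:
                scores[(r, c)] = s
    kept = []
    for (r, c), s in scores.items():
        suppressed = False
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if (dr, dc) == (0, 0):
                    continue
                q = (r + dr, c + dc)
                if q in scores:
                    sq = scores[q]
                    if sq > s or (sq == s and q < (r, c)):
                        suppressed = True
        if not suppressed:
            kept.append(((r, c), s))
    if not kept:
        return []
    smax = max(s for _, s in kept)
    return sorted(p for p, s in kept if s >= min_quality * smax)


def placement_by_enumeration(drop_grid: np.ndarray, support: np.ndarray,
                             orig_topleft: tuple[int, int]):
    """Best object placement by trying every position.

    Returns (topleft, score) where score is the number of working sites
    under the support; ties broken by distance of the placement center to
    the original center, then row-major.
    """
    rows, cols = drop_grid.shape
    sh, sw = support.shape
    oc = (orig_topleft[0] + (sh - 1) / 2, orig_topleft[1] + (sw - 1) / 2)
    best = None
    for r0 in range(rows - sh + 1):
        for c0 in range(cols - sw + 1):
            score = 0
            for i in range(sh):
                for j in range(sw):
                    if support[i, j] and not drop_grid[r0 + i, c0 + j]:
                        score += 1
            center = (r0 + (sh - 1) / 2, c0 + (sw - 1) / 2)
            d2 = (center[0] - oc[0]) ** 2 + (center[1] - oc[1]) ** 2
            key = (-score, d2, r0, c0)
            if best is None or key < best[0]:
                best = (key, (r0, c0), score)
    return best[1], best[2]
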