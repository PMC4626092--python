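"""Automated marker-positive cell detection and double-positive matching.

Manual click-counting is replaced by multi-scale Laplacian-of-Gaussian blob
detection with greedy non-maximum suppression; double positives are counted
as a one-to-one greedy matching between two detection sets within a pairing
radius.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = ["DetectionSet", "detect_cells", "double_positive", "density"]

POINT_COLUMNS = ["row", "col", "scale", "score"]


@dataclass
class DetectionSet:
    """Detected points for one channel of one image field."""

    points: pd.DataFrame  # columns: row, col, scale, score
    channel: str = ""
    image_shape: tuple[int, int] = (0, 0)
    pixel_size: float = 1.0

    @property
    def count(self) -> int:
        return len(self.points)

    @property
    def image_area_mm2(self) -> float:
        h, w = self.image_shape
        return h * w * self.pixel_size**2 / 1.0e6

    def coordinates(self) -> np.ndarray:
        return self.points[["row", "col"]].to_numpy(dtype=float)


def _greedy_nms(cands: np.ndarray, min_distance: float) -> np.ndarray:
    """Keep candidates in priority order, dropping any within min_distance
    of an already-kept point.  ``cands`` rows: (row, col, scale, score),
    pre-sorted by descending score with (row, col) tie-break."""
    kept: list[np.ndarray] = []
    if len(cands) == 0:
        return cands
    kept_xy: list[tuple[float, float]] = []
    for c in cands:
        ok = True
        if kept_xy:
            # rebuild rarely; linear scan is fine at field-scale counts
            for r, q in kept_xy:
                if (c[0] - r) ** 2 + (c[1] - q) ** 2 < min_distance**2:
                    ok = False
                    break
        if ok:
            kept.append(c)
            kept_xy.append((c[0], c[1]))
    return np.array(kept) if kept else np.empty((0, 4))


def detect_cells(
    img,
    min_scale: float = 3.0,
    max_scale: float = 8.0,
    score_threshold: float = 8.0,
    min_distance: float = 5.0,
    n_scales: int = 6,
    channel: str = "",
    pixel_size: float = 1.0,
) -> DetectionSet:
    """Multi-scale LoG blob detection with greedy NMS.

    ``min_scale``/``max_scale`` are blob radii in px.  The response is the
    scale-normalized negative Laplacian of Gaussian (bright blobs score
    positive); local maxima across space and scale above
    ``score_threshold`` survive, then greedy suppression enforces
    ``min_distance`` between centers keeping higher scores first.
    """
    a = np.asarray(img, dtype=float)
    if a.ndim != 2:
        raise ValueError("expected a 2-D single-channel image")
    if not 0 < min_scale <= max_scale:
        raise ValueError("require 0 < min_scale <= max_scale")
    if min_distance < 0:
        raise ValueError("min_distance must be >= 0")

    radii = np.geomspace(min_scale, max_scale, n_scales)
    sigmas = radii / np.sqrt(2.0)
    stack = np.stack(
        [
            -(s**2) * ndimage.gaussian_laplace(a, s, mode="nearest")
            for s in sigmas
        ]
    )
    # local maxima over 3x3x3 (scale, row, col) neighborhoods
    peaks = (
        stack == ndimage.maximum_filter(stack, size=(3, 3, 3), mode="nearest")
    ) & (stack > score_threshold)
    k, r, c = np.nonzero(peaks)
    cands = np.column_stack(
        [r.astype(float), c.astype(float), radii[k], stack[k, r, c]]
    )
    # deterministic priority: score desc, then row, col asc
    order = np.lexsort((cands[:, 1], cands[:, 0], -cands[:, 3]))
    kept = _greedy_nms(cands[order], min_distance)
    points = pd.DataFrame(kept, columns=POINT_COLUMNS)
    return DetectionSet(
        points=points,
        channel=channel,
        image_shape=a.shape,
        pixel_size=pixel_size,
    )


def double_positive(
    a: DetectionSet, b: DetectionSet, pairing_radius: float = 5.0
) -> dict:
    """Count double-positive objects by one-to-one greedy matching.

    Pairs (a_i, b_j) with center distance <= pairing_radius are matched
    greedily by ascending distance with a deterministic (distance, row,
    col) tie-break; each point matches at most once, so
    ``count_ab <= min(count_a, count_b)``.
    """
    if a.image_shape != b.image_shape:
        raise ValueError("detection sets come from different image frames")
    if pairing_radius < 0:
        raise ValueError("pairing_radius must be >= 0")
    pa = a.coordinates()
    pb = b.coordinates()
    count_ab = 0
    pairs: list[tuple[int, int]] = []
    if len(pa) and len(pb):
        tree = cKDTree(pb)
        cand: list[tuple[float, float, float, int, int]] = []
        for i, p in enumerate(pa):
            for j in tree.query_ball_point(p, pairing_radius):
                d = float(np.hypot(*(p - pb[j])))
                cand.append((d, p[0], p[1], i, j))
        cand.sort()
        used_a: set[int] = set()
        used_b: set[int] = set()
        for d, _, _, i, j in cand:
            if i in used_a or j in used_b:
                continue
            used_a.add(i)
            used_b.add(j)
            pairs.append((i, j))
        count_ab = len(pairs)
    return {
        "count_a": a.count,
        "count_b": b.count,
        "count_ab": count_ab,
        "pairs": pairs,
    }


def density(d: DetectionSet) -> float:
    """Detections per mm^2 of imaged field."""
    area = d.image_area_mm2
    if area <= 0:
        raise ValueError("image area must be positive")
    return d.count / area
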