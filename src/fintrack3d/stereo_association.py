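"""Stereo correspondence logic.

Covers the three association mechanisms used by the stereo pipelines:

* mask/box IOU cost matrices with minimum-cost (Hungarian) assignment,
* confidence + inside-box filtering of sparse feature matches, with the
  offset-vector estimator of the right-image key point,
* mask centroids.

Cross-view IOU is computed in the shared rectified pixel frame with no
disparity compensation; an optional pre-shift of the right-side items by a
caller-supplied disparity exists for wide-baseline use (off by default).

Mask pixel coordinates may be sub-pixel (oracle segmenters emit exact
silhouettes); IOU rasterises them to the integer grid by rounding, while
centroids use the raw coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .geometry import PixelPoint
from .tracking import Box, Detection, iou as box_iou

__all__ = [
    "MaskRegion",
    "FeatureMatch",
    "StereoPair",
    "mask_centroid",
    "mask_iou",
    "iou_cost_matrix",
    "assign",
    "filter_matches",
    "estimate_right_point",
    "DEFAULT_MIN_IOU",
    "DEFAULT_MATCH_CONF_MIN",
    "EPIPOLAR_WARN_PX",
]

logger = logging.getLogger(__name__)

#: IOU below which an assigned stereo pair is discarded as spurious.
DEFAULT_MIN_IOU = 0.1
#: Feature matches at or below this confidence are discarded.
DEFAULT_MATCH_CONF_MIN = 0.1
#: Vertical residual (px) above which an estimated right point is flagged.
EPIPOLAR_WARN_PX = 5.0

_PAD_COST = 1e6


@dataclass(frozen=True)
class MaskRegion:
    """A segmentation mask: member pixel coordinates plus its parent box.

    ``pixels`` is an (N, 2) float array of (u, v) coordinates.  Raster masks
    carry integers; oracle masks may carry sub-pixel coordinates.
    """

    frame: int
    side: str
    pixels: np.ndarray
    parent_box: Box | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[1] != 2 or px.shape[0] == 0:
            raise ValueError("mask pixels must be a non-empty (N, 2) array")
        object.__setattr__(self, "pixels", px)

    def __len__(self) -> int:
        return self.pixels.shape[0]


@dataclass(frozen=True)
class FeatureMatch:
    """A sparse stereo feature correspondence with a confidence score."""

    frame: int
    left_pt: PixelPoint
    right_pt: PixelPoint
    conf: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.conf <= 1.0):
            raise ValueError(f"confidence {self.conf} outside [0, 1]")


@dataclass(frozen=True)
class StereoPair:
    """An accepted left/right correspondence (indices into the input lists)."""

    left_index: int
    right_index: int
    iou_score: float


def mask_centroid(mask: MaskRegion) -> PixelPoint:
    """Centroid of a mask: arithmetic mean of its member pixel coordinates."""
    mean = mask.pixels.mean(axis=0)
    return PixelPoint(float(mean[0]), float(mean[1]))


def _encode(pixels: np.ndarray) -> np.ndarray:
    """Round sub-pixel coordinates to the grid and encode (u, v) as int64 keys."""
    grid = np.rint(pixels).astype(np.int64)
    return np.unique(grid[:, 0] * 2**22 + grid[:, 1])


def mask_iou(a: MaskRegion, b: MaskRegion) -> float:
    """IOU of two masks on the integer pixel grid."""
    ka, kb = _encode(a.pixels), _encode(b.pixels)
    inter = np.intersect1d(ka, kb, assume_unique=True).size
    if inter == 0:
        return 0.0
    union = ka.size + kb.size - inter
    return inter / union


def iou_cost_matrix(
    left_items: Sequence[MaskRegion] | Sequence[Detection],
    right_items: Sequence[MaskRegion] | Sequence[Detection],
    mode: Literal["mask", "bbox"],
    *,
    disparity_shift: float = 0.0,
) -> np.ndarray:
    """Cost matrix with entries ``1 - IOU(left_i, right_j)``.

    ``mode='mask'`` computes IOU on pixel sets (items are
    :class:`MaskRegion`); ``mode='bbox'`` on (x, y, w, h) boxes (items are
    :class:`Detection`).  All items must come from one frame.
    ``disparity_shift`` > 0 shifts right items toward +u before comparing
    (wide-baseline aid; default off).
    """
    frames = {it.frame for it in left_items} | {it.frame for it in right_items}
    if len(frames) > 1:
        raise ValueError(f"items span multiple frames: {sorted(frames)}")
    n_l, n_r = len(left_items), len(right_items)
    cost = np.ones((n_l, n_r))
    if mode == "mask":
        for j, rm in enumerate(right_items):
            if disparity_shift:
                rm = MaskRegion(
                    rm.frame, rm.side, rm.pixels + np.array([disparity_shift, 0.0])
                )
            for i, lm in enumerate(left_items):
                cost[i, j] = 1.0 - mask_iou(lm, rm)
    elif mode == "bbox":
        for j, rd in enumerate(right_items):
            rbox = rd.box
            if disparity_shift:
                rbox = (rbox[0] + disparity_shift, rbox[1], rbox[2], rbox[3])
            for i, ld in enumerate(left_items):
                cost[i, j] = 1.0 - box_iou(ld.box, rbox)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return cost


def assign(cost: np.ndarray, min_iou: float = DEFAULT_MIN_IOU) -> list[StereoPair]:
    """Minimum-total-cost one-to-one assignment, then gate by IOU.

    The matrix is padded square with a large constant so unbalanced inputs
    are handled; padded assignments are discarded, as are pairs whose IOU
    ``1 - cost`` falls below ``min_iou``.
    """
    cost = np.asarray(cost, dtype=float)
    if cost.size == 0:
        return []
    if not np.isfinite(cost).all():
        raise ValueError("cost matrix must be finite")
    n_l, n_r = cost.shape
    n = max(n_l, n_r)
    padded = np.full((n, n), _PAD_COST)
    padded[:n_l, :n_r] = cost
    rows, cols = linear_sum_assignment(padded)
    pairs: list[StereoPair] = []
    for i, j in zip(rows, cols):
        if i >= n_l or j >= n_r:
            continue
        score = 1.0 - cost[i, j]
        if score < min_iou:
            continue
        pairs.append(StereoPair(int(i), int(j), float(score)))
    return sorted(pairs, key=lambda p: (p.left_index, p.right_index))


def _point_in_box(pt: PixelPoint, box: Box) -> bool:
    # box edges count as inside
    x, y, w, h = box
    return x <= pt.u <= x + w and y <= pt.v <= y + h


def filter_matches(
    matches: Sequence[FeatureMatch],
    boxes: Sequence[Detection],
    conf_min: float = DEFAULT_MATCH_CONF_MIN,
) -> dict[int, list[FeatureMatch]]:
    """Filter feature matches and group the survivors by containing box.

    A match survives if its confidence is strictly above ``conf_min`` and
    its left point lies inside at least one of the left-side boxes (box
    edges count as inside).  Each survivor is associated to exactly one box;
    when several boxes contain the point, the box whose centre is nearest
    wins (ties to the lower box index).  Returns ``{box_index: matches}``
    with only non-empty groups.
    """
    frames = {m.frame for m in matches} | {b.frame for b in boxes}
    if len(frames) > 1:
        raise ValueError(f"matches and boxes span multiple frames: {sorted(frames)}")
    grouped: dict[int, list[FeatureMatch]] = {}
    for m in matches:
        if m.conf <= conf_min:
            continue
        best: int | None = None
        best_d2 = np.inf
        for bi, det in enumerate(boxes):
            if not _point_in_box(m.left_pt, det.box):
                continue
            cx, cy = det.center
            d2 = (m.left_pt.u - cx) ** 2 + (m.left_pt.v - cy) ** 2
            if d2 < best_d2:
                best, best_d2 = bi, d2
        if best is not None:
            grouped.setdefault(best, []).append(m)
    return grouped


def estimate_right_point(
    box_center_left: PixelPoint, group: Sequence[FeatureMatch]
) -> PixelPoint:
    """Estimate where the left box centre falls in the right image.

    The offset of the box centre from the mean matched left point is added
    to the mean matched right point.  The left triangulation key remains the
    box centre itself; only the horizontal component of the result feeds the
    disparity, while the vertical residual serves as an epipolar diagnostic.
    """
    if not group:
        raise ValueError("no matches for box")
    lefts = np.array([[m.left_pt.u, m.left_pt.v] for m in group])
    rights = np.array([[m.right_pt.u, m.right_pt.v] for m in group])
    offset = np.array([box_center_left.u, box_center_left.v]) - lefts.mean(axis=0)
    est = rights.mean(axis=0) + offset
    v_residual = abs(float(est[1]) - box_center_left.v)
    if v_residual > EPIPOLAR_WARN_PX:
        logger.warning(
            "epipolar residual %.2f px exceeds %.1f px for box centre (%.1f, %.1f)",
            v_residual,
            EPIPOLAR_WARN_PX,
            box_center_left.u,
            box_center_left.v,
        )
    return PixelPoint(float(est[0]), float(est[1]))
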