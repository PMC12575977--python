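"""The four fish–camera distance pipelines over pluggable perception backends.

Every pipeline starts from per-frame bounding-box detections, tracks the
left stream to obtain persistent identities, then derives one 3D point per
tracked box per frame:

* ``superglue``      — sparse feature matches filtered to boxes; the right
  key point is estimated by the offset-vector rule; stereo triangulation.
* ``segmentdepth``   — per-box segmentation masks on both sides, associated
  by mask IOU (or box IOU in the ``match_on='bbox'`` variant); triangulation
  of mask centroids.
* ``bboxdepth``      — boxes associated directly by IOU; triangulation of
  box centres.
* ``mono``           — a metric depth raster is read at the box-centre pixel
  and the centre is back-projected.

Backends (segmenter, matcher, depth source) are structural protocols; both
file-replay (:mod:`fintrack3d.io`) and simulator-oracle
(:mod:`fintrack3d.simulator`) implementations ship with the package.

Stereo pipelines attach track ids from the left tracker only; right-side
detections stay anonymous.  Frames with identical indices are assumed to be
hardware-synchronized pairs.  Every dropped record is accounted for with a
reason code in the run summary.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal, Protocol, Sequence

import numpy as np

from .geometry import (
    CameraPoint3D,
    PixelPoint,
    RejectionError,
    StereoCalibration,
    backproject,
    triangulate,
)
from .stereo_association import (
    DEFAULT_MATCH_CONF_MIN,
    DEFAULT_MIN_IOU,
    FeatureMatch,
    MaskRegion,
    assign,
    estimate_right_point,
    filter_matches,
    iou_cost_matrix,
    mask_centroid,
)
from .tracking import Box, Detection, TrackerParams, track_sequence

__all__ = [
    "Segmenter",
    "Matcher",
    "DepthMapSource",
    "PipelineConfig",
    "TrajectoryRecord",
    "RunSummary",
    "run_superglue",
    "run_segmentdepth",
    "run_bboxdepth",
    "run_mono",
    "run_pipeline",
    "PIPELINES",
]

logger = logging.getLogger(__name__)

PIPELINES = ("segmentdepth", "bboxdepth", "superglue", "mono")


class Segmenter(Protocol):
    """Per-box promptable segmentation backend."""

    def segment(
        self, frame: int, side: str, boxes: Sequence[Box]
    ) -> list[MaskRegion | None]:
        """Return one mask per box (``None`` where segmentation failed)."""
        ...


class Matcher(Protocol):
    """Sparse stereo feature-matching backend."""

    def match(self, frame: int) -> list[FeatureMatch]:
        ...


class DepthMapSource(Protocol):
    """Per-frame metric depth raster backend (metres per pixel)."""

    def depth_map(self, frame: int) -> np.ndarray:
        ...


@dataclass(frozen=True)
class PipelineConfig:
    d_min: float = 0.5
    z_max: float = 10.0
    min_iou: float = DEFAULT_MIN_IOU
    match_conf_min: float = DEFAULT_MATCH_CONF_MIN
    match_on: Literal["mask", "bbox"] = "mask"
    mono_patch_median: bool = False  # 3x3 median instead of a single-pixel read


@dataclass(frozen=True)
class TrajectoryRecord:
    """One 3D observation of one tracked identity in one frame."""

    frame: int
    track_id: int
    point: CameraPoint3D
    distance_m: float
    pipeline: str


@dataclass
class RunSummary:
    pipeline: str
    n_frames: int = 0
    n_tracked_boxes: int = 0
    n_records: int = 0
    rejections: Counter = field(default_factory=Counter)

    def as_dict(self) -> dict:
        return {
            "pipeline": self.pipeline,
            "n_frames": self.n_frames,
            "n_tracked_boxes": self.n_tracked_boxes,
            "n_records": self.n_records,
            "rejections": dict(self.rejections),
        }


def _tracked_boxes_by_frame(
    detections: Iterable[Detection], params: TrackerParams | None
) -> dict[int, list[tuple[int, Box]]]:
    """Track the stream and pivot to {frame: [(track_id, box), ...]}."""
    out: dict[int, list[tuple[int, Box]]] = {}
    for trk in track_sequence(detections, params):
        for frame, box, _conf in trk.history:
            out.setdefault(frame, []).append((trk.track_id, box))
    for frame in out:
        out[frame].sort(key=lambda tb: tb[0])
    return out


def _dets_by_frame(detections: Iterable[Detection]) -> dict[int, list[Detection]]:
    out: dict[int, list[Detection]] = {}
    for det in detections:
        out.setdefault(det.frame, []).append(det)
    return out


def _center(box: Box) -> PixelPoint:
    x, y, w, h = box
    return PixelPoint(x + w / 2.0, y + h / 2.0)


def _record(
    frame: int, track_id: int, point: CameraPoint3D, pipeline: str
) -> TrajectoryRecord:
    return TrajectoryRecord(frame, track_id, point, point.distance_m, pipeline)


def run_superglue(
    detections_left: Iterable[Detection],
    matcher: Matcher,
    calib: StereoCalibration,
    cfg: PipelineConfig | None = None,
    tracker_params: TrackerParams | None = None,
) -> tuple[list[TrajectoryRecord], RunSummary]:
    """Feature-match pipeline: left tracking + filtered matches + offset vector."""
    cfg = cfg or PipelineConfig()
    summary = RunSummary("superglue")
    records: list[TrajectoryRecord] = []
    tracked = _tracked_boxes_by_frame(detections_left, tracker_params)
    summary.n_frames = len(tracked)
    for frame in sorted(tracked):
        boxes = tracked[frame]
        summary.n_tracked_boxes += len(boxes)
        matches = matcher.match(frame)
        proxies = [Detection(frame, box, 1.0) for _tid, box in boxes]
        groups = filter_matches(matches, proxies, cfg.match_conf_min)
        for bi, (tid, box) in enumerate(boxes):
            group = groups.get(bi)
            if not group:
                summary.rejections["no-match"] += 1
                continue
            center = _center(box)
            right = estimate_right_point(center, group)
            try:
                point = triangulate(
                    calib, center, right.u, d_min=cfg.d_min, z_max=cfg.z_max
                )
            except RejectionError as err:
                summary.rejections[err.reason] += 1
                continue
            records.append(_record(frame, tid, point, "superglue"))
    summary.n_records = len(records)
    return records, summary


def _associate_and_triangulate(
    frame: int,
    left_boxes: list[tuple[int, Box]],
    right_dets: list[Detection],
    segmenter: Segmenter | None,
    calib: StereoCalibration,
    cfg: PipelineConfig,
    pipeline: str,
    summary: RunSummary,
    records: list[TrajectoryRecord],
) -> None:
    """Shared stereo-association core of segmentdepth and bboxdepth.

    With a segmenter, keys are mask centroids and (in ``match_on='mask'``
    mode) association runs on mask IOU; without one, keys are box centres
    and association runs on box IOU.
    """
    if not left_boxes or not right_dets:
        summary.rejections["no-match"] += len(left_boxes)
        return
    left_proxies = [Detection(frame, box, 1.0) for _tid, box in left_boxes]

    left_masks: list[MaskRegion | None] | None = None
    right_masks: list[MaskRegion | None] | None = None
    if segmenter is not None:
        left_masks = segmenter.segment(frame, "left", [b for _t, b in left_boxes])
        right_masks = segmenter.segment(frame, "right", [d.box for d in right_dets])

    # keep only items with usable keys, remembering original indices
    if segmenter is not None:
        li = [i for i, m in enumerate(left_masks) if m is not None]
        ri = [j for j, m in enumerate(right_masks) if m is not None]
        summary.rejections["empty-mask"] += (len(left_boxes) - len(li))
    else:
        li = list(range(len(left_boxes)))
        ri = list(range(len(right_dets)))
    if not li or not ri:
        summary.rejections["no-match"] += len(li)
        return

    if segmenter is not None and cfg.match_on == "mask":
        cost = iou_cost_matrix(
            [left_masks[i] for i in li], [right_masks[j] for j in ri], mode="mask"
        )
    else:
        cost = iou_cost_matrix(
            [left_proxies[i] for i in li], [right_dets[j] for j in ri], mode="bbox"
        )
    pairs = assign(cost, min_iou=cfg.min_iou)
    paired_left = set()
    for pair in pairs:
        i, j = li[pair.left_index], ri[pair.right_index]
        paired_left.add(i)
        tid = left_boxes[i][0]
        if segmenter is not None:
            left_key = mask_centroid(left_masks[i])
            right_key = mask_centroid(right_masks[j])
        else:
            left_key = _center(left_boxes[i][1])
            right_key = _center(right_dets[j].box)
        try:
            point = triangulate(
                calib, left_key, right_key.u, d_min=cfg.d_min, z_max=cfg.z_max
            )
        except RejectionError as err:
            summary.rejections[err.reason] += 1
            continue
        records.append(_record(frame, tid, point, pipeline))
    summary.rejections["no-match"] += len([i for i in li if i not in paired_left])


def run_segmentdepth(
    detections_left: Iterable[Detection],
    detections_right: Iterable[Detection],
    segmenter: Segmenter,
    calib: StereoCalibration,
    cfg: PipelineConfig | None = None,
    tracker_params: TrackerParams | None = None,
) -> tuple[list[TrajectoryRecord], RunSummary]:
    """Segmentation pipeline: masks on both sides, centroid triangulation.

    ``cfg.match_on`` selects mask-IOU association (default) or the faster
    box-IOU variant in which masks are still segmented and their centroids
    still supply the triangulation keys.
    """
    cfg = cfg or PipelineConfig()
    summary = RunSummary("segmentdepth")
    records: list[TrajectoryRecord] = []
    tracked = _tracked_boxes_by_frame(detections_left, tracker_params)
    right_by_frame = _dets_by_frame(detections_right)
    summary.n_frames = len(tracked)
    for frame in sorted(tracked):
        boxes = tracked[frame]
        summary.n_tracked_boxes += len(boxes)
        _associate_and_triangulate(
            frame,
            boxes,
            right_by_frame.get(frame, []),
            segmenter,
            calib,
            cfg,
            "segmentdepth",
            summary,
            records,
        )
    summary.n_records = len(records)
    return records, summary


def run_bboxdepth(
    detections_left: Iterable[Detection],
    detections_right: Iterable[Detection],
    calib: StereoCalibration,
    cfg: PipelineConfig | None = None,
    tracker_params: TrackerParams | None = None,
) -> tuple[list[TrajectoryRecord], RunSummary]:
    """Box pipeline: IOU + Hungarian on boxes, box-centre triangulation."""
    cfg = cfg or PipelineConfig()
    summary = RunSummary("bboxdepth")
    records: list[TrajectoryRecord] = []
    tracked = _tracked_boxes_by_frame(detections_left, tracker_params)
    right_by_frame = _dets_by_frame(detections_right)
    summary.n_frames = len(tracked)
    for frame in sorted(tracked):
        boxes = tracked[frame]
        summary.n_tracked_boxes += len(boxes)
        _associate_and_triangulate(
            frame,
            boxes,
            right_by_frame.get(frame, []),
            None,
            calib,
            cfg,
            "bboxdepth",
            summary,
            records,
        )
    summary.n_records = len(records)
    return records, summary


def run_mono(
    detections_left: Iterable[Detection],
    depth_source: DepthMapSource,
    calib: StereoCalibration,
    cfg: PipelineConfig | None = None,
    tracker_params: TrackerParams | None = None,
) -> tuple[list[TrajectoryRecord], RunSummary]:
    """Monocular pipeline: depth-raster lookup at the box-centre pixel.

    The lookup is a single read at the floored centre coordinates (a 3x3
    patch median behind ``cfg.mono_patch_median``); the value is trusted as
    is — there is no stereo consistency check.
    """
    cfg = cfg or PipelineConfig()
    summary = RunSummary("mono")
    records: list[TrajectoryRecord] = []
    tracked = _tracked_boxes_by_frame(detections_left, tracker_params)
    summary.n_frames = len(tracked)
    for frame in sorted(tracked):
        boxes = tracked[frame]
        summary.n_tracked_boxes += len(boxes)
        raster = np.asarray(depth_source.depth_map(frame))
        h, w = raster.shape
        for tid, box in boxes:
            center = _center(box)
            col, row = int(math.floor(center.u)), int(math.floor(center.v))
            if not (0 <= row < h and 0 <= col < w):
                summary.rejections["bounds"] += 1
                continue
            if cfg.mono_patch_median:
                patch = raster[
                    max(0, row - 1) : row + 2, max(0, col - 1) : col + 2
                ]
                vals = patch[np.isfinite(patch)]
                z = float(np.median(vals)) if vals.size else float("nan")
            else:
                z = float(raster[row, col])
            if not (math.isfinite(z) and z > 0):
                summary.rejections["invalid-depth"] += 1
                continue
            try:
                point = backproject(calib, center, z)
            except RejectionError as err:
                summary.rejections[err.reason] += 1
                continue
            records.append(_record(frame, tid, point, "mono"))
    summary.n_records = len(records)
    return records, summary


def run_pipeline(
    name: str,
    *,
    detections_left: Iterable[Detection],
    calib: StereoCalibration,
    detections_right: Iterable[Detection] | None = None,
    segmenter: Segmenter | None = None,
    matcher: Matcher | None = None,
    depth_source: DepthMapSource | None = None,
    cfg: PipelineConfig | None = None,
    tracker_params: TrackerParams | None = None,
) -> tuple[list[TrajectoryRecord], RunSummary]:
    """Dispatch a pipeline by name, validating that its inputs are present."""
    if name == "superglue":
        if matcher is None:
            raise ValueError("superglue requires a matcher backend")
        return run_superglue(detections_left, matcher, calib, cfg, tracker_params)
    if name == "segmentdepth":
        if detections_right is None or segmenter is None:
            raise ValueError("segmentdepth requires right detections and a segmenter")
        return run_segmentdepth(
            detections_left, detections_right, segmenter, calib, cfg, tracker_params
        )
    if name == "bboxdepth":
        if detections_right is None:
            raise ValueError("bboxdepth requires right detections")
        return run_bboxdepth(
            detections_left, detections_right, calib, cfg, tracker_params
        )
    if name == "mono":
        if depth_source is None:
            raise ValueError("mono requires a depth-map backend")
        return run_mono(detections_left, depth_source, calib, cfg, tracker_params)
    raise ValueError(f"unknown pipeline {name!r}; expected one of {PIPELINES}")
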