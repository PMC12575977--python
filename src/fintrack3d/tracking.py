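"""Multi-object tracking of fin detections via two-stage IOU association.

The tracker associates per-frame bounding-box detections to persistent
identities in two passes per frame, in the style of byte-level association
trackers: high-confidence detections are matched first against all live
(active + lost) tracks, then the remaining *active* tracks get a second
chance against low-confidence detections.  Matching is a minimum-cost
bipartite assignment on ``1 - IOU``; association is on the track's last
observed box (no motion model by default).

Determinism: within a frame, detections are put into a canonical order
(descending confidence, then box coordinates) before association, and tied
assignment costs are broken toward lower track id / lower detection index by
an infinitesimal lexicographic perturbation.  The output is therefore
invariant to the input order of detections within a frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = ["Detection", "Track", "TrackerParams", "iou", "track_sequence"]

Box = tuple[float, float, float, float]  # x, y, w, h — top-left corner + size

_BIG_COST = 1e6
_TIE_EPS = 1e-9


@dataclass(frozen=True)
class Detection:
    """One bounding-box observation: ``box`` is (x, y, w, h) in pixels."""

    frame: int
    box: Box
    conf: float
    side: str = "left"
    class_label: str = "fin"

    def __post_init__(self) -> None:
        x, y, w, h = self.box
        if w <= 0 or h <= 0:
            raise ValueError(f"degenerate box {self.box}")
        if not (0.0 <= self.conf <= 1.0):
            raise ValueError(f"confidence {self.conf} outside [0, 1]")

    @property
    def center(self) -> tuple[float, float]:
        x, y, w, h = self.box
        return (x + w / 2.0, y + h / 2.0)


@dataclass
class Track:
    """A temporal identity: ordered (frame, box, conf) history plus state."""

    track_id: int
    history: list[tuple[int, Box, float]] = field(default_factory=list)
    state: str = "active"  # active | lost | removed
    frames_lost: int = 0

    @property
    def last_box(self) -> Box:
        return self.history[-1][1]

    @property
    def frames(self) -> list[int]:
        return [f for f, _, _ in self.history]

    def add(self, frame: int, box: Box, conf: float) -> None:
        if self.history and frame <= self.history[-1][0]:
            raise ValueError("history frames must be strictly increasing")
        self.history.append((frame, box, conf))
        self.state = "active"
        self.frames_lost = 0


@dataclass(frozen=True)
class TrackerParams:
    """Association thresholds.

    The field study's exact values are not public; these defaults are
    documented, configurable stand-ins.
    """

    conf_high: float = 0.5
    conf_low: float = 0.1
    iou_gate_high: float = 0.2
    iou_gate_low: float = 0.5
    track_buffer: int = 30

    def __post_init__(self) -> None:
        if not (0.0 <= self.conf_low <= self.conf_high <= 1.0):
            raise ValueError("require 0 <= conf_low <= conf_high <= 1")
        if not (0.0 <= self.iou_gate_high <= 1.0 and 0.0 <= self.iou_gate_low <= 1.0):
            raise ValueError("IOU gates must lie in [0, 1]")
        if self.track_buffer < 0:
            raise ValueError("track_buffer must be >= 0")


def iou(box_a: Box, box_b: Box) -> float:
    """Intersection-over-union of two (x, y, w, h) boxes."""
    ax, ay, aw, ah = box_a
    bx, by, bw, bh = box_b
    if aw <= 0 or ah <= 0 or bw <= 0 or bh <= 0:
        raise ValueError("degenerate box")
    ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    if inter == 0.0:
        return 0.0
    union = aw * ah + bw * bh - inter
    return inter / union


def _match(
    tracks: Sequence[Track],
    detections: Sequence[Detection],
    iou_gate: float,
) -> tuple[list[tuple[int, int]], set[int], set[int]]:
    """Gated Hungarian matching of tracks to detections on cost ``1 - IOU``.

    Returns (matched (track_idx, det_idx) pairs, unmatched track indices,
    unmatched detection indices).
    """
    if not tracks or not detections:
        return [], set(range(len(tracks))), set(range(len(detections)))
    n_t, n_d = len(tracks), len(detections)
    cost = np.full((n_t, n_d), _BIG_COST)
    for i, trk in enumerate(tracks):
        for j, det in enumerate(detections):
            score = iou(trk.last_box, det.box)
            if score >= iou_gate:
                # perturbation prefers lower track id then detection index on ties
                cost[i, j] = (1.0 - score) + _TIE_EPS * (i * (n_d + 1) + j)
    rows, cols = linear_sum_assignment(cost)
    matched: list[tuple[int, int]] = []
    used_t: set[int] = set()
    used_d: set[int] = set()
    for i, j in zip(rows, cols):
        if cost[i, j] >= _BIG_COST:
            continue
        matched.append((i, j))
        used_t.add(i)
        used_d.add(j)
    return (
        matched,
        set(range(n_t)) - used_t,
        set(range(n_d)) - used_d,
    )


def _canonical_order(dets: Iterable[Detection]) -> list[Detection]:
    return sorted(dets, key=lambda d: (-d.conf, d.box))


def track_sequence(
    detections: Iterable[Detection],
    params: TrackerParams | None = None,
) -> list[Track]:
    """Track a detection stream across frames.

    Per frame: stage 1 assigns high-confidence detections
    (``conf >= conf_high``) to all live tracks (active and lost), gated at
    ``iou_gate_high``; stage 2 assigns the leftover *active* tracks to
    low-confidence detections (``conf_low <= conf < conf_high``), gated at
    ``iou_gate_low``.  Unmatched high-confidence detections spawn new
    tracks; detections below ``conf_low`` are dropped.  Tracks unmatched for
    more than ``track_buffer`` consecutive frames are removed and never
    re-associated.

    Returns every track ever spawned (including removed ones), ordered by id.
    """
    params = params or TrackerParams()
    by_frame: dict[int, list[Detection]] = {}
    for det in detections:
        by_frame.setdefault(det.frame, []).append(det)
    if not by_frame:
        return []

    tracks: list[Track] = []
    next_id = 1
    for frame in range(min(by_frame), max(by_frame) + 1):
        dets = _canonical_order(by_frame.get(frame, []))
        high = [d for d in dets if d.conf >= params.conf_high]
        low = [d for d in dets if params.conf_low <= d.conf < params.conf_high]

        live = sorted(
            (t for t in tracks if t.state in ("active", "lost")),
            key=lambda t: t.track_id,
        )
        matched1, un_t1, un_d1 = _match(live, high, params.iou_gate_high)
        matched_tracks: set[int] = set()
        for ti, dj in matched1:
            live[ti].add(frame, high[dj].box, high[dj].conf)
            matched_tracks.add(live[ti].track_id)

        # stage 2: only still-active tracks get the low-confidence pass
        remaining_active = [t for (ti, t) in enumerate(live) if ti in un_t1 and t.state == "active"]
        matched2, _, _ = _match(remaining_active, low, params.iou_gate_low)
        for ti, dj in matched2:
            remaining_active[ti].add(frame, low[dj].box, low[dj].conf)
            matched_tracks.add(remaining_active[ti].track_id)

        for trk in live:
            if trk.track_id in matched_tracks:
                continue
            trk.frames_lost += 1
            trk.state = "removed" if trk.frames_lost > params.track_buffer else "lost"

        for dj in sorted(un_d1):
            trk = Track(track_id=next_id)
            next_id += 1
            trk.add(frame, high[dj].box, high[dj].conf)
            tracks.append(trk)

    return sorted(tracks, key=lambda t: t.track_id)
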