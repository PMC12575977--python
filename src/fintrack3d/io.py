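"""Readers, writers and file-replay backends for the pipeline streams.

Formats
-------
* Detections: MOT-style CSV ``frame,id,x,y,w,h,conf,class`` (``id = -1`` on
  input), UTF-8, header row required.
* Feature matches: CSV ``frame,xl,yl,xr,yr,conf``.
* Trajectories: CSV ``frame,track_id,X,Y,Z,distance_m``.
* Masks: either per-mask cropped PNG rasters (nonzero = member) plus a JSON
  index, or a single JSON file of column-major run-length encodings over the
  mask's integer bounding window.
* Depth maps: one single-channel 32-bit float TIFF per frame
  (``{frame:06d}.tif``), metres per pixel.

The replay backends defined here satisfy the backend protocols of
:mod:`fintrack3d.pipelines` by reading those files back.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .geometry import PixelPoint, save_calibration
from .pipelines import TrajectoryRecord
from .simulator import FixtureBundle, SceneTruth
from .stereo_association import FeatureMatch, MaskRegion
from .tracking import Box, Detection, iou as box_iou

__all__ = [
    "read_detections_csv",
    "write_detections_csv",
    "read_matches_csv",
    "write_matches_csv",
    "read_trajectories_csv",
    "write_trajectories_csv",
    "write_truth_csv",
    "read_truth_csv",
    "encode_rle",
    "decode_rle",
    "write_masks",
    "read_masks",
    "ReplaySegmenter",
    "ReplayMatcher",
    "ReplayDepthSource",
    "write_depth_map",
    "write_bundle",
]

PathLike = Union[str, Path]

DETECTION_COLUMNS = ["frame", "id", "x", "y", "w", "h", "conf", "class"]
MATCH_COLUMNS = ["frame", "xl", "yl", "xr", "yr", "conf"]
TRAJECTORY_COLUMNS = ["frame", "track_id", "X", "Y", "Z", "distance_m"]


# ---------------------------------------------------------------- CSV streams


def write_detections_csv(
    detections: Iterable[Detection], path: PathLike, side: str = "left"
) -> None:
    rows = [
        {
            "frame": d.frame,
            "id": -1,
            "x": d.box[0],
            "y": d.box[1],
            "w": d.box[2],
            "h": d.box[3],
            "conf": d.conf,
            "class": d.class_label,
        }
        for d in detections
    ]
    pd.DataFrame(rows, columns=DETECTION_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def read_detections_csv(path: PathLike, side: str = "left") -> list[Detection]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(DETECTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"detection CSV {path} missing columns: {sorted(missing)}")
    return [
        Detection(
            frame=int(r["frame"]),
            box=(float(r["x"]), float(r["y"]), float(r["w"]), float(r["h"])),
            conf=float(r["conf"]),
            side=side,
            class_label=str(r["class"]),  # itertuples would mangle this name
        )
        for r in df.to_dict("records")
    ]


def write_matches_csv(
    matches: Iterable[FeatureMatch] | dict[int, list[FeatureMatch]], path: PathLike
) -> None:
    if isinstance(matches, dict):
        flat = [m for frame in sorted(matches) for m in matches[frame]]
    else:
        flat = list(matches)
    rows = [
        {
            "frame": m.frame,
            "xl": m.left_pt.u,
            "yl": m.left_pt.v,
            "xr": m.right_pt.u,
            "yr": m.right_pt.v,
            "conf": m.conf,
        }
        for m in flat
    ]
    pd.DataFrame(rows, columns=MATCH_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def read_matches_csv(path: PathLike) -> dict[int, list[FeatureMatch]]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(MATCH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"match CSV {path} missing columns: {sorted(missing)}")
    out: dict[int, list[FeatureMatch]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(int(r.frame), []).append(
            FeatureMatch(
                frame=int(r.frame),
                left_pt=PixelPoint(float(r.xl), float(r.yl)),
                right_pt=PixelPoint(float(r.xr), float(r.yr)),
                conf=float(r.conf),
            )
        )
    return out


def write_trajectories_csv(records: Iterable[TrajectoryRecord], path: PathLike) -> None:
    rows = [
        {
            "frame": r.frame,
            "track_id": r.track_id,
            "X": r.point.X,
            "Y": r.point.Y,
            "Z": r.point.Z,
            "distance_m": r.distance_m,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def read_trajectories_csv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV {path} missing columns: {sorted(missing)}")
    return df


def write_truth_csv(truth: SceneTruth, path: PathLike) -> None:
    rows = []
    for t in range(truth.n_frames):
        for f in range(truth.n_fish):
            X, Y, Z = truth.positions[t, f]
            rows.append(
                {
                    "frame": t,
                    "fish_id": f,
                    "X": X,
                    "Y": Y,
                    "Z": Z,
                    "vis_left": int(truth.vis_left[t, f]),
                    "vis_right": int(truth.vis_right[t, f]),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_truth_csv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


# --------------------------------------------------------------------- masks


def encode_rle(mask_bool: np.ndarray) -> list[int]:
    """Column-major run-length counts, starting with the zeros run."""
    flat = np.asarray(mask_bool, dtype=bool).flatten(order="F")
    counts: list[int] = []
    value = False
    run = 0
    for bit in flat:
        if bit == value:
            run += 1
        else:
            counts.append(run)
            value = bool(bit)
            run = 1
    counts.append(run)
    return counts


def decode_rle(counts: Sequence[int], shape: tuple[int, int]) -> np.ndarray:
    total = int(np.sum(counts))
    if total != shape[0] * shape[1]:
        raise ValueError(f"RLE length {total} does not match shape {shape}")
    flat = np.zeros(total, dtype=bool)
    pos = 0
    value = False
    for run in counts:
        if value:
            flat[pos : pos + run] = True
        pos += run
        value = not value
    return flat.reshape(shape, order="F")


def _rasterize(mask: MaskRegion) -> tuple[np.ndarray, tuple[int, int]]:
    """Quantize a mask to a boolean window; returns (window, (x0, y0))."""
    grid = np.unique(np.rint(mask.pixels).astype(int), axis=0)
    x0, y0 = grid.min(axis=0)
    w = grid[:, 0].max() - x0 + 1
    h = grid[:, 1].max() - y0 + 1
    window = np.zeros((h, w), dtype=bool)
    window[grid[:, 1] - y0, grid[:, 0] - x0] = True
    return window, (int(x0), int(y0))


def write_masks(
    masks: Iterable[MaskRegion], path: PathLike, fmt: str = "rle"
) -> None:
    """Write masks as RLE JSON (``fmt='rle'``) or cropped PNGs + JSON index.

    Each record keeps the mask's parent box so replay can re-associate masks
    with detection boxes regardless of ordering.
    """
    path = Path(path)
    records = []
    for i, mask in enumerate(masks):
        window, (x0, y0) = _rasterize(mask)
        rec = {
            "frame": mask.frame,
            "side": mask.side,
            "origin": [x0, y0],
            "size": [int(window.shape[0]), int(window.shape[1])],
            "box": list(mask.parent_box) if mask.parent_box else None,
        }
        if fmt == "rle":
            rec["counts"] = encode_rle(window)
        elif fmt == "png":
            path.mkdir(parents=True, exist_ok=True)
            name = f"{mask.side}_{mask.frame:06d}_{i:04d}.png"
            Image.fromarray(window.astype(np.uint8) * 255).save(path / name)
            rec["file"] = name
        else:
            raise ValueError(f"unknown mask format {fmt!r}")
        records.append(rec)
    if fmt == "rle":
        path.write_text(json.dumps({"format": "rle", "masks": records}), encoding="utf-8")
    else:
        (path / "index.json").write_text(
            json.dumps({"format": "png", "masks": records}), encoding="utf-8"
        )


def read_masks(path: PathLike) -> list[MaskRegion]:
    """Read masks written by :func:`write_masks` (either format)."""
    path = Path(path)
    if path.is_dir():
        payload = json.loads((path / "index.json").read_text(encoding="utf-8"))
    else:
        payload = json.loads(path.read_text(encoding="utf-8"))
    out: list[MaskRegion] = []
    for rec in payload["masks"]:
        h, w = rec["size"]
        if payload["format"] == "rle":
            window = decode_rle(rec["counts"], (h, w))
        else:
            window = np.asarray(Image.open(path / rec["file"])) > 0
        rows, cols = np.nonzero(window)
        x0, y0 = rec["origin"]
        pixels = np.stack([cols + x0, rows + y0], axis=1).astype(float)
        box = tuple(rec["box"]) if rec.get("box") else None
        out.append(MaskRegion(int(rec["frame"]), rec["side"], pixels, parent_box=box))
    return out


# ----------------------------------------------------------- replay backends


class ReplaySegmenter:
    """Serve stored masks, re-associated to requested boxes by box IOU."""

    def __init__(self, masks: Iterable[MaskRegion]) -> None:
        self._by_key: dict[tuple[str, int], list[MaskRegion]] = {}
        for m in masks:
            self._by_key.setdefault((m.side, m.frame), []).append(m)

    def segment(
        self, frame: int, side: str, boxes: Sequence[Box]
    ) -> list[MaskRegion | None]:
        stored = self._by_key.get((side, frame), [])
        out: list[MaskRegion | None] = []
        for box in boxes:
            best = None
            best_iou = 0.0
            for m in stored:
                if m.parent_box is None:
                    continue
                score = box_iou(box, m.parent_box)
                if score > best_iou:
                    best, best_iou = m, score
            out.append(best)
        return out


class ReplayMatcher:
    """Serve feature matches loaded from a match CSV."""

    def __init__(self, matches_by_frame: dict[int, list[FeatureMatch]]) -> None:
        self._matches = matches_by_frame

    @classmethod
    def from_csv(cls, path: PathLike) -> "ReplayMatcher":
        return cls(read_matches_csv(path))

    def match(self, frame: int) -> list[FeatureMatch]:
        return list(self._matches.get(frame, []))


class ReplayDepthSource:
    """Serve per-frame float32 TIFF depth rasters from a directory."""

    def __init__(self, directory: PathLike) -> None:
        self._dir = Path(directory)

    def depth_map(self, frame: int) -> np.ndarray:
        return tifffile.imread(self._dir / f"{frame:06d}.tif")


def write_depth_map(raster: np.ndarray, directory: PathLike, frame: int) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = directory / f"{frame:06d}.tif"
    tifffile.imwrite(out, np.asarray(raster, dtype=np.float32))
    return out


# ------------------------------------------------------------ bundle writing


def _config_to_jsonable(cfg) -> dict:
    raw = dataclasses.asdict(cfg)
    raw["calib"] = dataclasses.asdict(cfg.calib)
    raw["volume"] = [list(axis) for axis in cfg.volume]
    raw["conf_beta"] = list(cfg.conf_beta)
    return raw


def write_bundle(
    bundle: FixtureBundle,
    outdir: PathLike,
    *,
    mask_format: str = "rle",
    write_depth: bool = False,
) -> Path:
    """Write a rendered scene as the on-disk fixture layout the CLI consumes.

    Emits per-side detection CSVs, the match CSV, rasterized masks, the
    ground-truth CSV, calibration JSON and a manifest recording the full
    scene config (seed included).  Depth TIFFs are opt-in (they are large:
    one full frame per video frame).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = bundle.config

    write_detections_csv(bundle.detections["left"], outdir / "detections_left.csv")
    write_detections_csv(bundle.detections["right"], outdir / "detections_right.csv")
    write_matches_csv(bundle.matches, outdir / "matches.csv")
    write_truth_csv(bundle.truth, outdir / "truth.csv")
    save_calibration(cfg.calib, outdir / "calib.json")

    segmenter = bundle.oracle_segmenter()
    masks: list[MaskRegion] = []
    frames = sorted({frame for (_side, frame) in bundle.fins})
    for frame in frames:
        for side in ("left", "right"):
            boxes = [fin.box for fin in bundle.fins.get((side, frame), [])]
            if not boxes:
                continue
            for mask in segmenter.segment(frame, side, boxes):
                if mask is not None:
                    masks.append(mask)
    mask_path = outdir / ("masks" if mask_format == "png" else "masks.json")
    write_masks(masks, mask_path, fmt=mask_format)

    if write_depth:
        source = bundle.oracle_depth_source()
        for frame in range(bundle.truth.n_frames):
            write_depth_map(source.depth_map(frame), outdir / "depth", frame)

    manifest = {
        "seed": cfg.seed,
        "config": _config_to_jsonable(cfg),
        "mask_format": mask_format,
        "depth_maps": bool(write_depth),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2), encoding="utf-8"
    )
    return outdir
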