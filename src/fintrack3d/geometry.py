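"""Rectified pinhole stereo camera model.

Triangulation, back-projection and forward projection for a horizontally
rectified stereo pair: the right camera is displaced by the baseline along
the camera x-axis, so corresponding points share a vertical coordinate and
disparity is purely horizontal (``xl - xr >= 0`` for points in front of the
rig).

Conventions
-----------
* Pixel coordinates are continuous, 0-based, origin at the top-left corner,
  y pointing down.
* The 3D frame is the left camera's: x right, y down, z forward along the
  optical axis.  Baselines are configured in millimetres (matching typical
  rig datasheets); all 3D outputs are in metres.  The mm->m conversion
  happens in exactly one place (:func:`triangulate`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import yaml

__all__ = [
    "StereoCalibration",
    "PixelPoint",
    "CameraPoint3D",
    "RejectionError",
    "DegenerateDisparityError",
    "DepthOutOfRangeError",
    "InvalidDepthError",
    "triangulate",
    "backproject",
    "project_stereo",
    "load_calibration",
    "DEFAULT_D_MIN_PX",
    "DEFAULT_Z_MAX_M",
]

#: Minimum accepted disparity (px); smaller values are treated as degenerate.
DEFAULT_D_MIN_PX = 0.5
#: Maximum accepted range (m); triangulated points beyond it are rejected.
DEFAULT_Z_MAX_M = 10.0


class RejectionError(ValueError):
    """A geometric observation was rejected; ``reason`` is a short code."""

    reason = "rejected"


class DegenerateDisparityError(RejectionError):
    """Disparity at or below the degeneracy gate (non-positive/degenerate)."""

    reason = "disparity"


class DepthOutOfRangeError(RejectionError):
    """Triangulated depth beyond the configured range cap."""

    reason = "range"


class InvalidDepthError(RejectionError):
    """A non-positive or non-finite depth value."""

    reason = "invalid-depth"


@dataclass(frozen=True)
class PixelPoint:
    """A continuous 2D pixel location (may fall outside the frame)."""

    u: float
    v: float

    def __iter__(self):
        yield self.u
        yield self.v


@dataclass(frozen=True)
class CameraPoint3D:
    """A 3D point in the left-camera frame (metres)."""

    X: float
    Y: float
    Z: float

    @property
    def distance_m(self) -> float:
        """Euclidean distance from the camera origin."""
        return math.sqrt(self.X * self.X + self.Y * self.Y + self.Z * self.Z)

    def __iter__(self):
        yield self.X
        yield self.Y
        yield self.Z


@dataclass(frozen=True)
class StereoCalibration:
    """Intrinsics and baseline of a rectified stereo pair.

    Parameters
    ----------
    fx, fy : float
        Focal length in pixels along x and y.
    cx, cy : float
        Principal point in pixels.
    baseline_mm : float
        Physical separation of the two camera centres, millimetres.
    width, height : int
        Image size in pixels.
    """

    fx: float
    fy: float
    cx: float
    cy: float
    baseline_mm: float
    width: int
    height: int

    def __post_init__(self) -> None:
        if not (self.fx > 0 and self.fy > 0):
            raise ValueError(f"focal lengths must be positive, got fx={self.fx}, fy={self.fy}")
        if self.baseline_mm <= 0:
            raise ValueError(f"baseline_mm must be positive, got {self.baseline_mm}")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("image size must be positive")
        if not (0 <= self.cx < self.width):
            raise ValueError(f"cx={self.cx} outside [0, {self.width})")
        if not (0 <= self.cy < self.height):
            raise ValueError(f"cy={self.cy} outside [0, {self.height})")

    @property
    def baseline_m(self) -> float:
        return self.baseline_mm / 1000.0

    def contains(self, pt: PixelPoint) -> bool:
        return 0 <= pt.u < self.width and 0 <= pt.v < self.height


def triangulate(
    calib: StereoCalibration,
    left: PixelPoint,
    xr: float,
    *,
    d_min: float = DEFAULT_D_MIN_PX,
    z_max: float = DEFAULT_Z_MAX_M,
) -> CameraPoint3D:
    """Triangulate a rectified stereo correspondence into a 3D point.

    ``Z = b * fx / (xl - xr)`` with the baseline ``b`` converted mm -> m,
    then ``X = Z (u - cx) / fx`` and ``Y = Z (v - cy) / fy`` with ``(u, v)``
    taken from the left-image point.  Disparity is horizontal, so the focal
    length entering the depth formula is ``fx``.

    Raises
    ------
    DegenerateDisparityError
        If ``left.u - xr <= d_min``.
    DepthOutOfRangeError
        If the triangulated depth exceeds ``z_max``.
    """
    d = left.u - xr
    if not math.isfinite(d) or d <= d_min:
        raise DegenerateDisparityError(
            f"non-positive/degenerate disparity {d!r} (gate {d_min} px)"
        )
    Z = (calib.baseline_mm * calib.fx / d) / 1000.0
    if Z > z_max:
        raise DepthOutOfRangeError(f"depth {Z:.3f} m out of range (cap {z_max} m)")
    X = Z * (left.u - calib.cx) / calib.fx
    Y = Z * (left.v - calib.cy) / calib.fy
    return CameraPoint3D(X, Y, Z)


def backproject(calib: StereoCalibration, pixel: PixelPoint, Z: float) -> CameraPoint3D:
    """Lift a pixel to 3D given a known metric depth ``Z`` (m)."""
    if not (math.isfinite(Z) and Z > 0):
        raise InvalidDepthError(f"invalid depth {Z!r}")
    X = Z * (pixel.u - calib.cx) / calib.fx
    Y = Z * (pixel.v - calib.cy) / calib.fy
    return CameraPoint3D(X, Y, Z)


def project_stereo(
    calib: StereoCalibration, point: CameraPoint3D
) -> tuple[PixelPoint, PixelPoint]:
    """Project a 3D point into both rectified views.

    Returns ``(left, right)`` pixel points; both share the vertical
    coordinate and their horizontal offset is ``baseline_mm * fx / (1000 Z)``.
    """
    if not (math.isfinite(point.Z) and point.Z > 0):
        raise InvalidDepthError(f"cannot project point with Z={point.Z!r}")
    u_l = calib.fx * point.X / point.Z + calib.cx
    v = calib.fy * point.Y / point.Z + calib.cy
    u_r = calib.fx * (point.X - calib.baseline_m) / point.Z + calib.cx
    return PixelPoint(u_l, v), PixelPoint(u_r, v)


def disparity_for_depth(calib: StereoCalibration, Z: float) -> float:
    """Disparity (px) of a point at depth ``Z`` metres."""
    if Z <= 0:
        raise InvalidDepthError(f"invalid depth {Z!r}")
    return calib.baseline_mm * calib.fx / (1000.0 * Z)


_CALIB_KEYS = {"fx", "fy", "cx", "cy", "baseline_mm", "width", "height"}


def calibration_from_dict(raw: dict) -> StereoCalibration:
    """Build a :class:`StereoCalibration` from a config mapping, strictly."""
    if not isinstance(raw, dict):
        raise ValueError("calibration config must be a mapping")
    missing = _CALIB_KEYS - raw.keys()
    if missing:
        raise ValueError(f"calibration config missing keys: {sorted(missing)}")
    extra = raw.keys() - _CALIB_KEYS
    if extra:
        raise ValueError(f"calibration config has unknown keys: {sorted(extra)}")
    return StereoCalibration(
        fx=float(raw["fx"]),
        fy=float(raw["fy"]),
        cx=float(raw["cx"]),
        cy=float(raw["cy"]),
        baseline_mm=float(raw["baseline_mm"]),
        width=int(raw["width"]),
        height=int(raw["height"]),
    )


def load_calibration(path: Union[str, Path]) -> StereoCalibration:
    """Load calibration from a JSON (``.json``) or YAML (``.yml``/``.yaml``) file."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    elif path.suffix.lower() in {".yml", ".yaml"}:
        raw = yaml.safe_load(text)
    else:
        raise ValueError(f"unsupported calibration format: {path.suffix!r}")
    return calibration_from_dict(raw)


def save_calibration(calib: StereoCalibration, path: Union[str, Path]) -> None:
    path = Path(path)
    payload = {
        "fx": calib.fx,
        "fy": calib.fy,
        "cx": calib.cx,
        "cy": calib.cy,
        "baseline_mm": calib.baseline_mm,
        "width": calib.width,
        "height": calib.height,
    }
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
    elif path.suffix.lower() in {".yml", ".yaml"}:
        path.write_text(yaml.safe_dump(payload), encoding="utf-8")
    else:
        raise ValueError(f"unsupported calibration format: {path.suffix!r}")
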