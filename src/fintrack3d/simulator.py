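"""Synthetic stereo fish-scene generator with ground truth.

Emulates the field acquisition geometry (42 mm baseline, 1920x1200 px
frames, 25 fps, fish at roughly 1–4 m) so that every pipeline and statistic
can be exercised without field data.  Fish caudal fins are modelled as
planar ellipses facing the camera; the pipelines only consume boxes, masks,
sparse point matches and depth rasters, so silhouette realism suffices.

One master seed drives independent per-component generators (motion, box
noise, dropout, confidence, matches, mask jitter) so each noise source can
be varied in isolation.

Oracle backends note: the oracle segmenter emits silhouettes as a symmetric
integer offset pattern around the *exact* (sub-pixel) projected fin centre,
so mask centroids reproduce the projection to machine precision; IOU-based
association rasterises them to the pixel grid internally.  Raster masks
written to disk are quantized to integer pixels by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geometry import (
    CameraPoint3D,
    PixelPoint,
    StereoCalibration,
    project_stereo,
)
from .stereo_association import FeatureMatch, MaskRegion
from .tracking import Box, Detection, iou as box_iou

__all__ = [
    "SceneConfig",
    "SceneTruth",
    "RenderedFin",
    "FixtureBundle",
    "default_calibration",
    "simulate_trajectories",
    "render_observations",
    "simulate_scene",
    "OracleSegmenter",
    "OracleMatcher",
    "OracleDepthSource",
]

Volume = tuple[tuple[float, float], tuple[float, float], tuple[float, float]]


def default_calibration() -> StereoCalibration:
    """Simulator stand-in for the field rig (intrinsics were never published)."""
    return StereoCalibration(
        fx=1400.0,
        fy=1400.0,
        cx=960.0,
        cy=600.0,
        baseline_mm=42.0,
        width=1920,
        height=1200,
    )


@dataclass(frozen=True)
class SceneConfig:
    """Everything needed to generate one reproducible scene."""

    n_fish: int = 3
    n_frames: int = 100
    fps: float = 25.0
    calib: StereoCalibration = field(default_factory=default_calibration)
    volume: Volume = ((-0.8, 0.8), (-0.45, 0.45), (1.5, 3.5))
    speed_mean: float = 0.25  # m/s
    speed_sd: float = 0.08
    turn_sd: float = 0.25  # rad/frame
    fin_halfwidth_m: float = 0.09
    fin_aspect: float = 0.6  # vertical/horizontal silhouette semiaxis ratio
    pixel_noise_sd: float = 0.0  # box corner + mask localization noise, px
    dropout_p: float = 0.0  # per-side per-frame detection miss probability
    dropout_p_left: float | None = None  # per-side overrides of dropout_p
    dropout_p_right: float | None = None
    conf_beta: tuple[float, float] = (8.0, 2.0)
    n_matches_per_fin: int = 6
    match_jitter_sd: float = 0.0  # px
    background_depth_m: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fish < 0 or self.n_frames < 0 or self.n_matches_per_fin < 0:
            raise ValueError("counts must be >= 0")
        for p in (self.dropout_p, self.dropout_p_left, self.dropout_p_right):
            if p is not None and not (0.0 <= p <= 1.0):
                raise ValueError(f"dropout probability {p} outside [0, 1]")
        (x0, x1), (y0, y1), (z0, z1) = self.volume
        if not (x0 < x1 and y0 < y1 and z0 < z1):
            raise ValueError("empty volume")
        if z0 <= 0:
            raise ValueError("volume must lie strictly in front of the camera")
        if self.fps <= 0 or self.fin_halfwidth_m <= 0 or self.fin_aspect <= 0:
            raise ValueError("fps, fin size and aspect must be positive")

    @property
    def dropout_left(self) -> float:
        return self.dropout_p if self.dropout_p_left is None else self.dropout_p_left

    @property
    def dropout_right(self) -> float:
        return self.dropout_p if self.dropout_p_right is None else self.dropout_p_right


@dataclass
class SceneTruth:
    """Ground truth: per-frame per-fish fin centre, heading and visibility."""

    positions: np.ndarray  # (n_frames, n_fish, 3), metres, camera frame
    headings: np.ndarray  # (n_frames, n_fish), azimuth rad (orientation wobble)
    vis_left: np.ndarray  # (n_frames, n_fish) bool, geometric visibility
    vis_right: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_fish(self) -> int:
        return self.positions.shape[1]


@dataclass(frozen=True)
class RenderedFin:
    """Internal per-side per-frame rendering of one fish's fin."""

    fish_id: int
    center: PixelPoint  # exact projection (sub-pixel)
    mask_center: PixelPoint  # projection + localization jitter
    a_px: float  # horizontal silhouette semiaxis
    b_px: float
    depth_m: float
    box: Box  # noisy detection box
    clean_box: Box  # noiseless silhouette extent
    conf: float


@dataclass
class FixtureBundle:
    """All observation streams for one rendered scene, plus ground truth."""

    config: SceneConfig
    truth: SceneTruth
    detections: dict[str, list[Detection]]  # side -> flat detection list
    fins: dict[tuple[str, int], list[RenderedFin]]  # (side, frame) -> fins
    matches: dict[int, list[FeatureMatch]]

    def oracle_segmenter(self) -> "OracleSegmenter":
        return OracleSegmenter(self)

    def oracle_matcher(self) -> "OracleMatcher":
        return OracleMatcher(self)

    def oracle_depth_source(self) -> "OracleDepthSource":
        return OracleDepthSource(self)


def _fin_axes_px(calib: StereoCalibration, cfg: SceneConfig, Z: float) -> tuple[float, float]:
    a = cfg.fin_halfwidth_m * calib.fx / Z
    return a, a * cfg.fin_aspect


def _silhouette_visible(
    calib: StereoCalibration, center: PixelPoint, a: float, b: float
) -> bool:
    return (
        center.u - a >= 0
        and center.u + a < calib.width
        and center.v - b >= 0
        and center.v + b < calib.height
    )


def simulate_trajectories(cfg: SceneConfig) -> SceneTruth:
    """Correlated-random-walk fin paths inside the configured volume.

    Heading evolves by Gaussian turns, speed is drawn from a truncated
    Gaussian (capped at ``3 * speed_mean`` so per-frame displacement never
    exceeds ``3 * speed_mean / fps``), and paths reflect at the volume
    boundaries.  Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(6)[0])
    (x0, x1), (y0, y1), (z0, z1) = cfg.volume
    lo = np.array([x0, y0, z0])
    hi = np.array([x1, y1, z1])
    n_f, n_t = cfg.n_fish, cfg.n_frames

    positions = np.zeros((n_t, n_f, 3))
    headings = np.zeros((n_t, n_f))
    pos = rng.uniform(lo, hi, size=(n_f, 3))
    theta = rng.uniform(0.0, 2 * math.pi, size=n_f)
    pitch = rng.normal(0.0, 0.15, size=n_f)
    for t in range(n_t):
        positions[t] = pos
        headings[t] = theta
        if t == n_t - 1:
            break
        theta = theta + rng.normal(0.0, cfg.turn_sd, size=n_f)
        pitch = np.clip(pitch + rng.normal(0.0, cfg.turn_sd / 2.0, size=n_f), -0.5, 0.5)
        speed = rng.normal(cfg.speed_mean, cfg.speed_sd, size=n_f)
        speed = np.clip(speed, 0.0, 3.0 * cfg.speed_mean)
        step = speed / cfg.fps
        direction = np.stack(
            [
                np.cos(pitch) * np.cos(theta),
                np.sin(pitch),
                np.cos(pitch) * np.sin(theta),
            ],
            axis=1,
        )
        pos = pos + direction * step[:, None]
        # reflect at the walls, flipping the corresponding heading component
        for axis in range(3):
            under = pos[:, axis] < lo[axis]
            over = pos[:, axis] > hi[axis]
            pos[under, axis] = 2 * lo[axis] - pos[under, axis]
            pos[over, axis] = 2 * hi[axis] - pos[over, axis]
            if axis != 1 and (under.any() or over.any()):
                flip = under | over
                theta[flip] = (math.pi - theta[flip]) if axis == 0 else -theta[flip]
            if axis == 1:
                pitch[under | over] *= -1
        pos = np.clip(pos, lo, hi)

    vis_left = np.zeros((n_t, n_f), dtype=bool)
    vis_right = np.zeros((n_t, n_f), dtype=bool)
    calib = cfg.calib
    for t in range(n_t):
        for f in range(n_f):
            p = CameraPoint3D(*positions[t, f])
            left, right = project_stereo(calib, p)
            a, b = _fin_axes_px(calib, cfg, p.Z)
            vis_left[t, f] = _silhouette_visible(calib, left, a, b)
            vis_right[t, f] = _silhouette_visible(calib, right, a, b)
    return SceneTruth(positions, headings, vis_left, vis_right)


def _noisy_box(
    clean: Box, sigma: float, rng: np.random.Generator
) -> Box:
    if sigma <= 0:
        return clean
    x, y, w, h = clean
    c1 = np.array([x, y]) + rng.normal(0.0, sigma, size=2)
    c2 = np.array([x + w, y + h]) + rng.normal(0.0, sigma, size=2)
    nx, ny = np.minimum(c1, c2)
    nw, nh = np.abs(c2 - c1)
    return (float(nx), float(ny), float(max(nw, 1e-3)), float(max(nh, 1e-3)))


def render_observations(truth: SceneTruth, cfg: SceneConfig) -> FixtureBundle:
    """Render detection, match and (lazily) mask/depth streams from truth.

    Detections are emitted per side per frame with probability
    ``1 - dropout``, Beta-distributed confidences, and Gaussian corner noise
    on the silhouette extent.  Feature matches are sampled on the fin for
    fish visible in both views (matching is independent of detection).
    Masks and depth rasters are produced on demand by the oracle backends.
    """
    seqs = np.random.SeedSequence(cfg.seed).spawn(6)
    rng_box = np.random.default_rng(seqs[1])
    rng_drop = np.random.default_rng(seqs[2])
    rng_conf = np.random.default_rng(seqs[3])
    rng_match = np.random.default_rng(seqs[4])
    rng_mask = np.random.default_rng(seqs[5])

    calib = cfg.calib
    detections: dict[str, list[Detection]] = {"left": [], "right": []}
    fins: dict[tuple[str, int], list[RenderedFin]] = {}
    matches: dict[int, list[FeatureMatch]] = {}

    for t in range(truth.n_frames):
        frame_matches: list[FeatureMatch] = []
        for f in range(truth.n_fish):
            p = CameraPoint3D(*truth.positions[t, f])
            left, right = project_stereo(calib, p)
            a, b = _fin_axes_px(calib, cfg, p.Z)
            for side, center, visible, drop_p in (
                ("left", left, truth.vis_left[t, f], cfg.dropout_left),
                ("right", right, truth.vis_right[t, f], cfg.dropout_right),
            ):
                dropped = rng_drop.uniform() < drop_p  # always drawn: keeps streams aligned
                conf = float(np.clip(rng_conf.beta(*cfg.conf_beta), 1e-6, 1.0))
                jitter = rng_mask.normal(0.0, cfg.pixel_noise_sd, size=2) if cfg.pixel_noise_sd > 0 else (0.0, 0.0)
                if not visible or dropped:
                    continue
                clean_box = (center.u - a, center.v - b, 2 * a, 2 * b)
                box = _noisy_box(clean_box, cfg.pixel_noise_sd, rng_box)
                fin = RenderedFin(
                    fish_id=f,
                    center=center,
                    mask_center=PixelPoint(center.u + jitter[0], center.v + jitter[1]),
                    a_px=a,
                    b_px=b,
                    depth_m=p.Z,
                    box=box,
                    clean_box=clean_box,
                    conf=conf,
                )
                fins.setdefault((side, t), []).append(fin)
                detections[side].append(Detection(t, box, conf, side=side))
            if truth.vis_left[t, f] and truth.vis_right[t, f]:
                disparity = left.u - right.u
                for _ in range(cfg.n_matches_per_fin):
                    r = math.sqrt(rng_match.uniform()) * 0.9
                    phi = rng_match.uniform(0.0, 2 * math.pi)
                    du = r * math.cos(phi) * a
                    dv = r * math.sin(phi) * b
                    jl = rng_match.normal(0.0, cfg.match_jitter_sd, size=2) if cfg.match_jitter_sd > 0 else (0.0, 0.0)
                    jr = rng_match.normal(0.0, cfg.match_jitter_sd, size=2) if cfg.match_jitter_sd > 0 else (0.0, 0.0)
                    conf_m = float(np.clip(rng_match.beta(*cfg.conf_beta), 1e-6, 1.0))
                    frame_matches.append(
                        FeatureMatch(
                            frame=t,
                            left_pt=PixelPoint(left.u + du + jl[0], left.v + dv + jl[1]),
                            right_pt=PixelPoint(
                                left.u + du - disparity + jr[0], left.v + dv + jr[1]
                            ),
                            conf=conf_m,
                        )
                    )
        matches[t] = frame_matches
    return FixtureBundle(cfg, truth, detections, fins, matches)


def simulate_scene(cfg: SceneConfig) -> FixtureBundle:
    """Convenience: trajectories + rendering in one call."""
    return render_observations(simulate_trajectories(cfg), cfg)


def _ellipse_offsets(a: float, b: float) -> np.ndarray:
    """Symmetric integer (du, dv) offsets inside an ellipse with semiaxes a, b."""
    ia, ib = int(math.floor(a)), int(math.floor(b))
    du = np.arange(-ia, ia + 1)
    dv = np.arange(-ib, ib + 1)
    uu, vv = np.meshgrid(du, dv, indexing="ij")
    inside = (uu / a) ** 2 + (vv / b) ** 2 <= 1.0
    return np.stack([uu[inside], vv[inside]], axis=1).astype(float)


class OracleSegmenter:
    """Ground-truth segmenter: exact elliptical fin silhouettes.

    The silhouette is a symmetric integer offset pattern translated to the
    fin's (jittered) sub-pixel centre, so the mask centroid equals that
    centre to machine precision.  A requested box is resolved to the fish
    whose clean silhouette box overlaps it the most.
    """

    def __init__(self, bundle: FixtureBundle) -> None:
        self._bundle = bundle

    def segment(
        self, frame: int, side: str, boxes: Sequence[Box]
    ) -> list[MaskRegion | None]:
        fins = self._bundle.fins.get((side, frame), [])
        out: list[MaskRegion | None] = []
        for box in boxes:
            best: RenderedFin | None = None
            best_iou = 0.0
            for fin in fins:
                score = box_iou(box, fin.clean_box)
                if score > best_iou:
                    best, best_iou = fin, score
            if best is None:
                out.append(None)
                continue
            offsets = _ellipse_offsets(best.a_px, best.b_px)
            pixels = offsets + np.array([best.mask_center.u, best.mask_center.v])
            out.append(MaskRegion(frame, side, pixels, parent_box=box))
        return out


class OracleMatcher:
    """Replay of the matches sampled at render time."""

    def __init__(self, bundle: FixtureBundle) -> None:
        self._bundle = bundle

    def match(self, frame: int) -> list[FeatureMatch]:
        return list(self._bundle.matches.get(frame, []))


class OracleDepthSource:
    """Z-buffer depth raster: fin ellipses over a constant background."""

    def __init__(self, bundle: FixtureBundle, side: str = "left") -> None:
        self._bundle = bundle
        self._side = side

    def depth_map(self, frame: int) -> np.ndarray:
        cfg = self._bundle.config
        calib = cfg.calib
        raster = np.full(
            (calib.height, calib.width), cfg.background_depth_m, dtype=np.float32
        )
        fins = sorted(
            self._bundle.fins.get((self._side, frame), []),
            key=lambda fin: -fin.depth_m,
        )
        for fin in fins:  # painter's order: nearer fins overwrite farther ones
            offsets = _ellipse_offsets(fin.a_px, fin.b_px)
            cols = np.rint(offsets[:, 0] + fin.center.u).astype(int)
            rows = np.rint(offsets[:, 1] + fin.center.v).astype(int)
            ok = (rows >= 0) & (rows < calib.height) & (cols >= 0) & (cols < calib.width)
            raster[rows[ok], cols[ok]] = fin.depth_m
        return raster
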