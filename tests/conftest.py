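import numpy as np
import pytest

from fintrack3d.geometry import StereoCalibration
from fintrack3d.simulator import (
    SceneConfig,
    SceneTruth,
    default_calibration,
    render_observations,
    simulate_scene,
)


@pytest.fixture(scope="session")
def calib() -> StereoCalibration:
    return default_calibration()


@pytest.fixture(scope="session")
def simple_calib() -> StereoCalibration:
    """Round numbers for hand-checked examples."""
    return StereoCalibration(
        fx=1000.0, fy=1000.0, cx=960.0, cy=600.0, baseline_mm=42.0,
        width=1920, height=1200,
    )


@pytest.fixture(scope="session")
def noiseless_scene():
    """A 3-fish 40-frame scene with zero noise and zero dropout."""
    cfg = SceneConfig(n_fish=3, n_frames=40, seed=7)
    return simulate_scene(cfg)


def make_static_truth(positions_m, cfg: SceneConfig) -> SceneTruth:
    """Ground truth with fish pinned at fixed 3D positions every frame."""
    pos = np.tile(np.asarray(positions_m, dtype=float), (cfg.n_frames, 1, 1))
    truth = SceneTruth(
        positions=pos,
        headings=np.zeros(pos.shape[:2]),
        vis_left=np.ones(pos.shape[:2], dtype=bool),
        vis_right=np.ones(pos.shape[:2], dtype=bool),
    )
    # recompute geometric visibility the same way the simulator does
    from fintrack3d.geometry import CameraPoint3D, project_stereo
    from fintrack3d.simulator import _fin_axes_px, _silhouette_visible

    for t in range(cfg.n_frames):
        for f in range(pos.shape[1]):
            p = CameraPoint3D(*pos[t, f])
            left, right = project_stereo(cfg.calib, p)
            a, b = _fin_axes_px(cfg.calib, cfg, p.Z)
            truth.vis_left[t, f] = _silhouette_visible(cfg.calib, left, a, b)
            truth.vis_right[t, f] = _silhouette_visible(cfg.calib, right, a, b)
    return truth


@pytest.fixture(scope="session")
def static_scene():
    """Three well-separated, non-overlapping static fish (no noise/dropout)."""
    cfg = SceneConfig(n_fish=3, n_frames=25, speed_mean=0.0, speed_sd=0.0, seed=3)
    truth = make_static_truth(
        [[-0.5, -0.2, 2.0], [0.5, 0.2, 2.5], [0.0, 0.3, 3.0]], cfg
    )
    return render_observations(truth, cfg)
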