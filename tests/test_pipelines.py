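import numpy as np
import pytest

from fintrack3d.pipelines import (
    PipelineConfig,
    run_bboxdepth,
    run_mono,
    run_pipeline,
    run_segmentdepth,
    run_superglue,
)
from fintrack3d.simulator import SceneConfig, simulate_scene
from fintrack3d.stereo_association import FeatureMatch
from fintrack3d.tracking import Detection


def nearest_truth_error(bundle, record):
    """Distance from a record's 3D point to the nearest ground-truth fin."""
    truth = bundle.truth.positions[record.frame]
    p = np.array(list(record.point))
    return min(np.linalg.norm(truth[f] - p) for f in range(truth.shape[0]))


@pytest.fixture(scope="module")
def stereo_runs(noiseless_scene):
    bundle = noiseless_scene
    calib = bundle.config.calib
    seg, _ = run_segmentdepth(
        bundle.detections["left"], bundle.detections["right"],
        bundle.oracle_segmenter(), calib,
    )
    bbox, _ = run_bboxdepth(
        bundle.detections["left"], bundle.detections["right"], calib
    )
    sup, _ = run_superglue(bundle.detections["left"], bundle.oracle_matcher(), calib)
    return {"segmentdepth": seg, "bboxdepth": bbox, "superglue": sup}


class TestNoiselessRecovery:
    def test_stereo_pipelines_recover_truth(self, noiseless_scene, stereo_runs):
        for name, records in stereo_runs.items():
            assert records, name
            worst = max(nearest_truth_error(noiseless_scene, r) for r in records)
            assert worst < 1e-6, name

    def test_stereo_pipelines_agree(self, stereo_runs):
        keyed = {
            name: {(r.frame, r.track_id): np.array(list(r.point)) for r in records}
            for name, records in stereo_runs.items()
        }
        shared = set.intersection(*(set(k) for k in keyed.values()))
        assert shared
        for key in shared:
            for name in ("bboxdepth", "superglue"):
                assert np.linalg.norm(keyed["segmentdepth"][key] - keyed[name][key]) < 1e-6

    def test_mono_exact_at_fin_pixels(self, noiseless_scene):
        bundle = noiseless_scene
        records, _ = run_mono(
            bundle.detections["left"], bundle.oracle_depth_source(), bundle.config.calib
        )
        assert records
        for r in records:
            truth_z = bundle.truth.positions[r.frame, :, 2]
            # raster stores float32; the lookup must reproduce it bit-exactly
            assert any(np.float32(z) == np.float32(r.point.Z) for z in truth_z)


class TestSuperglue:
    def test_all_low_confidence_yields_no_records(self, noiseless_scene):
        bundle = noiseless_scene

        class LowConfMatcher:
            def match(self, frame):
                return [
                    FeatureMatch(m.frame, m.left_pt, m.right_pt, 0.05)
                    for m in bundle.matches.get(frame, [])
                ]

        records, summary = run_superglue(
            bundle.detections["left"], LowConfMatcher(), bundle.config.calib
        )
        assert records == []
        assert summary.rejections["no-match"] == summary.n_tracked_boxes

    def test_degenerate_disparity_counted(self, noiseless_scene):
        bundle = noiseless_scene

        class ZeroDisparityMatcher:
            def match(self, frame):
                return [
                    FeatureMatch(m.frame, m.left_pt, m.left_pt, m.conf)
                    for m in bundle.matches.get(frame, [])
                ]

        records, summary = run_superglue(
            bundle.detections["left"], ZeroDisparityMatcher(), bundle.config.calib
        )
        assert records == []
        assert summary.rejections["disparity"] == summary.n_tracked_boxes


class TestBBoxDepth:
    def test_right_box_inflation_invariance(self, noiseless_scene):
        bundle = noiseless_scene
        calib = bundle.config.calib
        base, _ = run_bboxdepth(
            bundle.detections["left"], bundle.detections["right"], calib
        )
        inflated = [
            Detection(
                d.frame,
                (
                    d.box[0] - 0.1 * d.box[2],
                    d.box[1] - 0.1 * d.box[3],
                    1.2 * d.box[2],
                    1.2 * d.box[3],
                ),
                d.conf,
                side="right",
            )
            for d in bundle.detections["right"]
        ]
        other, _ = run_bboxdepth(bundle.detections["left"], inflated, calib)
        assert len(base) == len(other)
        for a, b in zip(base, other):
            assert (a.frame, a.track_id) == (b.frame, b.track_id)
            assert np.allclose(list(a.point), list(b.point), atol=1e-9)


class TestSegmentDepth:
    def test_match_on_variants_agree_noiselessly(self, noiseless_scene):
        bundle = noiseless_scene
        calib = bundle.config.calib
        args = (
            bundle.detections["left"],
            bundle.detections["right"],
            bundle.oracle_segmenter(),
            calib,
        )
        mask_recs, _ = run_segmentdepth(*args, PipelineConfig(match_on="mask"))
        bbox_recs, _ = run_segmentdepth(*args, PipelineConfig(match_on="bbox"))
        assert len(mask_recs) == len(bbox_recs)
        for a, b in zip(mask_recs, bbox_recs):
            assert (a.frame, a.track_id) == (b.frame, b.track_id)
            assert np.allclose(list(a.point), list(b.point), atol=1e-9)

    def test_missing_right_side_yields_no_records(self, noiseless_scene):
        bundle = noiseless_scene
        records, summary = run_segmentdepth(
            bundle.detections["left"], [], bundle.oracle_segmenter(),
            bundle.config.calib,
        )
        assert records == []
        assert summary.rejections["no-match"] == summary.n_tracked_boxes


class TestMono:
    def test_constant_raster(self, noiseless_scene):
        bundle = noiseless_scene
        calib = bundle.config.calib

        class ConstantDepth:
            def depth_map(self, frame):
                return np.full((calib.height, calib.width), 2.5, dtype=np.float32)

        records, _ = run_mono(bundle.detections["left"], ConstantDepth(), calib)
        assert records
        assert all(r.point.Z == 2.5 for r in records)

    def test_background_center_reads_background_depth(self, noiseless_scene):
        # zero out fin pixels: every centre falls on "background"
        bundle = noiseless_scene
        calib = bundle.config.calib
        bg = bundle.config.background_depth_m

        class BackgroundOnly:
            def depth_map(self, frame):
                return np.full((calib.height, calib.width), bg, dtype=np.float32)

        records, _ = run_mono(bundle.detections["left"], BackgroundOnly(), calib)
        assert all(r.point.Z == np.float32(bg) for r in records)

    def test_nonfinite_raster_dropped(self, noiseless_scene):
        bundle = noiseless_scene
        calib = bundle.config.calib

        class NanDepth:
            def depth_map(self, frame):
                return np.full((calib.height, calib.width), np.nan, dtype=np.float32)

        records, summary = run_mono(bundle.detections["left"], NanDepth(), calib)
        assert records == []
        assert summary.rejections["invalid-depth"] == summary.n_tracked_boxes

    def test_patch_median_option(self, noiseless_scene):
        bundle = noiseless_scene
        calib = bundle.config.calib

        class ConstantDepth:
            def depth_map(self, frame):
                return np.full((calib.height, calib.width), 1.5, dtype=np.float32)

        records, _ = run_mono(
            bundle.detections["left"], ConstantDepth(), calib,
            PipelineConfig(mono_patch_median=True),
        )
        assert all(r.point.Z == 1.5 for r in records)


class TestCrossPipelineInvariants:
    def test_record_schema(self, noiseless_scene, stereo_runs):
        bundle = noiseless_scene
        mono, _ = run_mono(
            bundle.detections["left"], bundle.oracle_depth_source(), bundle.config.calib
        )
        for name, records in {**stereo_runs, "mono": mono}.items():
            for r in records:
                assert r.pipeline == name
                assert r.distance_m == pytest.approx(r.point.distance_m)
                assert r.distance_m > 0

    def test_record_count_bounds(self):
        cfg = SceneConfig(n_fish=3, n_frames=40, dropout_p=0.25, seed=17)
        bundle = simulate_scene(cfg)
        calib = cfg.calib
        mono, ms = run_mono(bundle.detections["left"], bundle.oracle_depth_source(), calib)
        seg, ss = run_segmentdepth(
            bundle.detections["left"], bundle.detections["right"],
            bundle.oracle_segmenter(), calib,
        )
        bbox, bs = run_bboxdepth(bundle.detections["left"], bundle.detections["right"], calib)
        sup, ps = run_superglue(bundle.detections["left"], bundle.oracle_matcher(), calib)
        for records, summary in ((mono, ms), (seg, ss), (bbox, bs), (sup, ps)):
            assert len(records) == summary.n_records <= summary.n_tracked_boxes
        for stereo in (seg, bbox, sup):
            assert len(mono) >= len(stereo)

    def test_full_right_dropout_stereo_empty_mono_unaffected(self):
        cfg = SceneConfig(n_fish=2, n_frames=25, dropout_p_right=1.0, seed=19)
        bundle = simulate_scene(cfg)
        calib = cfg.calib
        seg, _ = run_segmentdepth(
            bundle.detections["left"], bundle.detections["right"],
            bundle.oracle_segmenter(), calib,
        )
        bbox, _ = run_bboxdepth(bundle.detections["left"], bundle.detections["right"], calib)
        mono, _ = run_mono(bundle.detections["left"], bundle.oracle_depth_source(), calib)
        assert seg == [] and bbox == []
        assert mono


def _median_depth_error(bundle, records):
    errs = []
    for r in records:
        truth = bundle.truth.positions[r.frame]
        p = np.array(list(r.point))
        f = int(np.argmin(np.linalg.norm(truth - p, axis=1)))
        errs.append(abs(truth[f, 2] - r.point.Z))
    return float(np.median(errs)) if errs else np.nan


def test_noise_monotonicity_smoke():
    """Median depth error grows from sigma=0 to sigma=2 (small smoke version)."""
    sigmas = (0.0, 2.0)
    meds = {name: [] for name in ("segmentdepth", "bboxdepth", "superglue")}
    for sigma in sigmas:
        pooled = {name: [] for name in meds}
        for seed in range(3):
            cfg = SceneConfig(
                n_fish=2, n_frames=30, pixel_noise_sd=sigma,
                match_jitter_sd=sigma, seed=100 + seed,
            )
            bundle = simulate_scene(cfg)
            calib = cfg.calib
            seg, _ = run_segmentdepth(
                bundle.detections["left"], bundle.detections["right"],
                bundle.oracle_segmenter(), calib,
            )
            bbox, _ = run_bboxdepth(
                bundle.detections["left"], bundle.detections["right"], calib
            )
            sup, _ = run_superglue(
                bundle.detections["left"], bundle.oracle_matcher(), calib
            )
            for name, records in (
                ("segmentdepth", seg), ("bboxdepth", bbox), ("superglue", sup)
            ):
                pooled[name].append(_median_depth_error(bundle, records))
        for name in meds:
            meds[name].append(float(np.nanmedian(pooled[name])))
    for name, series in meds.items():
        assert series[0] <= series[1], (name, series)


class TestDispatch:
    def test_unknown_pipeline(self, noiseless_scene):
        with pytest.raises(ValueError, match="unknown pipeline"):
            run_pipeline(
                "nope",
                detections_left=noiseless_scene.detections["left"],
                calib=noiseless_scene.config.calib,
            )

    @pytest.mark.parametrize(
        "name,msg",
        [
            ("superglue", "matcher"),
            ("segmentdepth", "segmenter"),
            ("bboxdepth", "right detections"),
            ("mono", "depth-map"),
        ],
    )
    def test_missing_backend(self, noiseless_scene, name, msg):
        with pytest.raises(ValueError, match=msg):
            run_pipeline(
                name,
                detections_left=noiseless_scene.detections["left"],
                calib=noiseless_scene.config.calib,
            )
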