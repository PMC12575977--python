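# fintrack3d

Camera-based estimation of 3D fish–object distances from per-frame fin
detections. Four pipelines share one trajectory schema:

| pipeline       | inputs                              | 3D key                                   |
|----------------|-------------------------------------|------------------------------------------|
| `segmentdepth` | stereo detections + per-box masks   | triangulated mask centroids              |
| `bboxdepth`    | stereo detections                   | triangulated box centres                 |
| `superglue`    | left detections + feature matches   | box centre + offset-vector right point   |
| `mono`         | left detections + metric depth maps | depth-raster lookup at the box centre    |

Supporting machinery:

- **geometry** — rectified pinhole stereo model: triangulation,
  back-projection, forward projection, calibration config IO (JSON/YAML).
- **tracking** — two-stage IOU association tracker (high-confidence pass
  against all live tracks, low-confidence pass against the remainder) with a
  configurable lost-track buffer.
- **stereo_association** — mask/box IOU cost matrices, Hungarian assignment
  with an IOU acceptance gate, feature-match filtering (confidence > 0.1 and
  inside-box), offset-vector right-point estimation, mask centroids.
- **simulator** — synthetic stereo fish scenes (42 mm baseline, 1920×1200 px,
  25 fps by default) with correlated-random-walk trajectories, elliptical fin
  silhouettes, configurable pixel noise / dropout / match jitter, and oracle
  backends exposing exact ground truth for end-to-end tests.
- **evaluation** — per-frame closest-fish distance, per-case aggregation
  across replicates, MAE with Student-t 95% CI against a reference,
  depth-based ranking of individuals, Savitzky–Golay trajectory smoothing.

Perception models (detector, segmenter, matcher, depth network) are *not*
included: the pipelines consume their outputs through pluggable backend
protocols, with file-replay and simulator-oracle implementations shipped.

## CLI

Generate a synthetic scene fixture bundle (detections, matches, masks,
ground truth, calibration; depth TIFFs opt-in):

```sh
fintrack3d simulate --config scene.yaml --out scene/ --seed 7 --write-depth
```

`scene.yaml` may set any scene field (`n_fish`, `n_frames`, `pixel_noise_sd`,
`dropout_p`, `volume`, inline `calib`, ...); omitted fields keep defaults.

Run a pipeline over file streams:

```sh
fintrack3d run --pipeline segmentdepth --calib scene/calib.json \
    --detections-left scene/detections_left.csv \
    --detections-right scene/detections_right.csv \
    --masks scene/masks.json --out run/ --seed 7
```

(`--matches` for `superglue`, `--depthmaps` for `mono`,
`--match-on bbox` for the box-matched segmentdepth variant.)
Outputs `trajectories.csv` (`frame,track_id,X,Y,Z,distance_m`) and a
`summary.json` with per-stage counts and per-reason rejection tallies.

Score per-case closest-distance summaries against a reference
(`<case>_<replicate>.csv` files in a directory; the published sonar
reference ships as the `builtin` default):

```sh
fintrack3d eval --trajectories cases/ --reference builtin --out report.json
```

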