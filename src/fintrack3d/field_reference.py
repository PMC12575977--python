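"""Published field-validation summary values, bundled as canned inputs.

The originating field campaign exposed caged fish to six object
configurations (big/small cylinder or cube, yellow or white: BY, BW, CY,
CW, SY, SW) and reported, per pipeline, the mean minimum fish-object
distance for each case, alongside an independent sonar-derived reference.
A single annotated frame additionally yielded per-individual depth
estimates from all four pipelines.

These numbers are *inputs* to the error statistics in
:mod:`fintrack3d.evaluation` (the underlying video data are not publicly
available); nothing in this module is computed.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "CASES",
    "CASE_MEANS_M",
    "CASE_SDS_M",
    "SONAR_REFERENCE_MEANS_M",
    "SONAR_REFERENCE_SDS_M",
    "SINGLE_FRAME_DEPTHS_M",
    "reference_frame",
]

#: Case order used throughout (shape/size/colour combinations).
CASES = ("BY", "BW", "CY", "CW", "SY", "SW")

#: Mean minimum fish-object distance per case and pipeline (m).
CASE_MEANS_M: dict[str, dict[str, float]] = {
    "mono": {"BY": 1.80, "BW": 1.51, "CY": 1.59, "CW": 1.58, "SY": 1.65, "SW": 1.44},
    "superglue": {"BY": 1.55, "BW": 1.15, "CY": 1.34, "CW": 1.05, "SY": 1.38, "SW": 0.91},
    "segmentdepth": {"BY": 1.72, "BW": 1.19, "CY": 1.46, "CW": 1.06, "SY": 1.64, "SW": 1.00},
    "bboxdepth": {"BY": 1.73, "BW": 1.19, "CY": 1.47, "CW": 1.06, "SY": 1.64, "SW": 0.95},
}

#: Standard deviations accompanying :data:`CASE_MEANS_M` (m).
CASE_SDS_M: dict[str, dict[str, float]] = {
    "mono": {"BY": 0.25, "BW": 0.21, "CY": 0.20, "CW": 0.30, "SY": 0.30, "SW": 0.27},
    "superglue": {"BY": 0.44, "BW": 0.33, "CY": 0.48, "CW": 0.26, "SY": 0.54, "SW": 0.41},
    "segmentdepth": {"BY": 0.53, "BW": 0.36, "CY": 0.59, "CW": 0.28, "SY": 0.79, "SW": 0.54},
    "bboxdepth": {"BY": 0.54, "BW": 0.37, "CY": 0.59, "CW": 0.28, "SY": 0.79, "SW": 0.53},
}

#: Sonar-derived reference distances per case (m).
SONAR_REFERENCE_MEANS_M: dict[str, float] = {
    "BY": 1.72, "BW": 0.93, "CY": 1.72, "CW": 0.99, "SY": 1.23, "SW": 0.77,
}
SONAR_REFERENCE_SDS_M: dict[str, float] = {
    "BY": 0.21, "BW": 0.06, "CY": 0.26, "CW": 0.04, "SY": 0.25, "SW": 0.05,
}

#: Per-individual depth estimates (m) from one annotated frame, keyed by
#: pipeline then track id.
SINGLE_FRAME_DEPTHS_M: dict[str, dict[int, float]] = {
    "superglue": {
        628: 2.174, 652: 1.582, 670: 2.017, 683: 1.350, 685: 0.670,
        695: 2.244, 696: 1.062, 697: 1.514, 699: 1.933,
    },
    "segmentdepth": {
        628: 3.748, 652: 1.898, 670: 2.015, 683: 1.378, 685: 0.678,
        695: 2.221, 696: 0.739, 697: 1.471, 699: 1.955,
    },
    "bboxdepth": {
        628: 2.734, 652: 1.960, 670: 1.659, 683: 1.414, 685: 0.717,
        695: 2.262, 696: 1.011, 697: 1.630, 699: 2.227,
    },
    "mono": {
        628: 2.302, 652: 2.844, 670: 1.896, 683: 2.114, 685: 1.381,
        695: 2.397, 696: 1.300, 697: 2.848, 699: 3.400,
    },
}


def reference_frame() -> pd.DataFrame:
    """The sonar reference as a ``case,mean_m,sd_m`` DataFrame."""
    return pd.DataFrame(
        {
            "case": list(CASES),
            "mean_m": [SONAR_REFERENCE_MEANS_M[c] for c in CASES],
            "sd_m": [SONAR_REFERENCE_SDS_M[c] for c in CASES],
        }
    )
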