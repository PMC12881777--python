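import math

import numpy as np
import pytest

from rootplan.root_measure import (
    RootGeometry,
    RootMeasurements,
    cusp_angles,
    cusp_coaptation_height,
    disproportionate_ratio,
    radial_offset_e,
)
from rootplan.synthetic_roots import circle_params, make_root

# CT-cohort group means used throughout as a realistic worked example
CT_MEAN = {
    "vbr": 28.0,
    "cca": 1330.7,
    "icd": {"a": 32.0, "b": 36.5, "c": 34.8},
    "ch": {"NL": 22.6, "LR": 23.0, "RN": 24.9},
    "gh": {"L": 18.6, "R": 18.0, "N": 20.7},
    "eh": {"L": 12.9, "R": 13.4, "N": 13.3},
    "sov": {"L": 45.5, "R": 46.7, "N": 46.2},
}


@pytest.fixture
def circle_root():
    """Noise-free circular root with exact ground truth."""
    return make_root(circle_params())


@pytest.fixture
def ct_mean_measurements() -> RootMeasurements:
    """RootMeasurements assembled directly from the CT-cohort mean values
    (not via a geometry), for planner worked examples."""
    c = CT_MEAN
    a, b, ic = c["icd"]["a"], c["icd"]["b"], c["icd"]["c"]
    alpha, beta, gamma = cusp_angles(a, b, ic)
    e = radial_offset_e(c["cca"], c["vbr"])
    return RootMeasurements(
        vbr_area=615.3,
        vbr_perimeter=88.4,
        estimated_vbr_diameter=c["vbr"],
        major_diameter=30.0,
        minor_diameter=26.0,
        ellipticity_index=30.0 / 26.0,
        cca=c["cca"],
        cca_radius=math.sqrt(c["cca"] / math.pi),
        icd=dict(c["icd"]),
        ch=dict(c["ch"]),
        horizontal_offset_e=e,
        predicted_ch={k: math.hypot(v, e) for k, v in c["ch"].items()},
        cusp_angle={"L": alpha, "R": beta, "N": gamma},
        cch={k: cusp_coaptation_height(c["gh"][k], c["vbr"]) for k in "LRN"},
        disproportionate_ratio_icd=disproportionate_ratio((a, b, ic)),
        disproportionate_ratio_ch=disproportionate_ratio(tuple(c["ch"].values())),
        disproportionate_ratio_sov=disproportionate_ratio(tuple(c["sov"].values())),
        geometric_height=dict(c["gh"]),
        effective_height=dict(c["eh"]),
        sov_diameter=dict(c["sov"]),
        ar_grade="none_trivial",
    )


@pytest.fixture
def simple_geometry() -> RootGeometry:
    """Minimal valid hand-built root: circular annulus radius 14 at z=0,
    commissures on a radius-20 circle at height 22."""
    t = np.linspace(0, 2 * np.pi, 36, endpoint=False)
    contour = np.column_stack([14 * np.cos(t), 14 * np.sin(t), np.zeros_like(t)])
    ang = {"NL": 0.0, "LR": 120.0, "RN": 240.0}
    com = {
        k: [20 * np.cos(np.radians(v)), 20 * np.sin(np.radians(v)), 22.0]
        for k, v in ang.items()
    }
    nad = {
        k: [14 * np.cos(np.radians(v)), 14 * np.sin(np.radians(v)), 0.0]
        for k, v in {"L": 60.0, "R": 180.0, "N": 300.0}.items()
    }
    return RootGeometry(
        annulus_contour=contour,
        nadirs=nad,
        commissures=com,
        geometric_height={"L": 18.0, "R": 18.0, "N": 20.0},
        effective_height={"L": 13.0, "R": 13.0, "N": 13.0},
        ar_grade="none_trivial",
    )
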