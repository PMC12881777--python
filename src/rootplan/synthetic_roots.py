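"""Parametric aortic-root generator with analytic ground truth.

Builds :class:`~rootplan.root_measure.RootGeometry` objects from explicit
geometric parameters — an elliptical basal ring in the z = 0 plane, three
commissure apices on a cylinder of given radius at given heights and
angular positions, cusp heights attached as attributes — together with the
exact measurements those parameters imply.  Optional isotropic Gaussian
landmark noise and a rigid transform emulate CT annotation error and the
arbitrary scanner frame; the ground truth always refers to the noise-free,
untransformed root.

Cohort presets draw each parameter from normal distributions whose means
and SDs emulate published preoperative CT cohorts of annuloaortic-ectasia
patients undergoing valve-sparing root replacement (and their controls);
they are statistical emulations, not patient data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation
from scipy.special import ellipe

from .root_measure import (
    COMMISSURE_KEYS,
    CUSP_KEYS,
    RootGeometry,
    RootMeasurements,
    cusp_angles,
    cusp_coaptation_height,
    disproportionate_ratio,
    estimated_vbr_diameter,
)

__all__ = [
    "RigidTransform",
    "SyntheticRootParams",
    "ct_group_distributions",
    "control_group_distributions",
    "circle_params",
    "ct_group_params",
    "make_root",
    "make_cohort",
    "truth_table",
    "make_rater_tables",
]


@dataclass(frozen=True)
class RigidTransform:
    """Rotation followed by translation, applied to all landmarks."""

    rotation: np.ndarray          # (3, 3) proper rotation matrix
    translation: np.ndarray       # (3,) mm

    def __post_init__(self):
        r = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-9) or np.linalg.det(r) < 0:
            raise ValueError("rotation must be a proper orthogonal matrix")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(
            self, "translation", np.asarray(self.translation, dtype=float).reshape(3)
        )

    @classmethod
    def from_euler(cls, angles_deg, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Build from intrinsic x-y-z Euler angles in degrees."""
        rot = Rotation.from_euler("xyz", angles_deg, degrees=True)
        return cls(rotation=rot.as_matrix(), translation=translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(rotation=np.eye(3), translation=np.zeros(3))

    def apply(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.rotation.T + self.translation


def _ellipse_perimeter(a: float, b: float) -> float:
    # complete elliptic integral of the second kind; exact to machine precision
    return float(4.0 * a * ellipe(1.0 - (b / a) ** 2))


@dataclass
class SyntheticRootParams:
    """Ground-truth parameters of one synthetic root (mm / degrees).

    ``commissure_angles`` position the apices around the root axis;
    ``nadir_angles`` pick the nadirs on the annulus contour (parametric
    ellipse angle).  Defaults reproduce a circular root at the CT-cohort
    mean dimensions.
    """

    vbr_semi_axes: tuple = (14.0, 14.0)              # (a, b), a >= b
    commissure_radius: float = 20.58
    commissure_heights: dict = field(
        default_factory=lambda: {"NL": 22.6, "LR": 23.0, "RN": 24.9}
    )
    commissure_angles: dict = field(
        default_factory=lambda: {"NL": 0.0, "LR": 111.5, "RN": 238.7}
    )
    nadir_angles: dict = field(
        default_factory=lambda: {"L": 55.75, "R": 175.1, "N": 299.35}
    )
    gh: dict = field(default_factory=lambda: {"L": 18.6, "R": 18.0, "N": 20.7})
    eh: dict = field(default_factory=lambda: {"L": 12.9, "R": 13.4, "N": 13.3})
    sov: Optional[dict] = field(
        default_factory=lambda: {"L": 45.5, "R": 46.7, "N": 46.2}
    )
    ar_grade: str = "none_trivial"
    contour_points: int = 360
    noise_sd: float = 0.0
    rigid_transform: Optional[RigidTransform] = None
    seed: int = 0

    def __post_init__(self):
        a, b = (float(v) for v in self.vbr_semi_axes)
        if not (a >= b > 0):
            raise ValueError("vbr_semi_axes must satisfy a >= b > 0")
        self.vbr_semi_axes = (a, b)
        if not self.commissure_radius > 0:
            raise ValueError("commissure_radius must be positive")
        if any(self.commissure_heights[k] <= 0 for k in COMMISSURE_KEYS):
            raise ValueError("commissure heights must be positive")
        angles = [self.commissure_angles[k] % 360.0 for k in COMMISSURE_KEYS]
        if len({round(v, 9) for v in angles}) != 3:
            raise ValueError("commissure angles must be distinct")
        if self.contour_points < 3:
            raise ValueError("contour needs at least 3 points")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _ground_truth(p: SyntheticRootParams) -> RootMeasurements:
    a, b = p.vbr_semi_axes
    area = math.pi * a * b
    perimeter = _ellipse_perimeter(a, b)
    est_d = estimated_vbr_diameter(area, perimeter)

    com = {
        k: np.array(
            [
                p.commissure_radius * math.cos(math.radians(p.commissure_angles[k])),
                p.commissure_radius * math.sin(math.radians(p.commissure_angles[k])),
                p.commissure_heights[k],
            ]
        )
        for k in COMMISSURE_KEYS
    }
    icd_a = float(np.linalg.norm(com["NL"] - com["LR"]))
    icd_b = float(np.linalg.norm(com["LR"] - com["RN"]))
    icd_c = float(np.linalg.norm(com["RN"] - com["NL"]))
    # circumradius from chord lengths: R = abc / (4K), K by Heron's formula
    s = 0.5 * (icd_a + icd_b + icd_c)
    k_area = math.sqrt(s * (s - icd_a) * (s - icd_b) * (s - icd_c))
    cca_radius = icd_a * icd_b * icd_c / (4.0 * k_area)
    cca = math.pi * cca_radius**2

    alpha, beta, gamma = cusp_angles(icd_a, icd_b, icd_c)
    e = max(0.0, cca_radius - est_d / 2.0)
    ch = dict(p.commissure_heights)
    return RootMeasurements(
        vbr_area=area,
        vbr_perimeter=perimeter,
        estimated_vbr_diameter=est_d,
        major_diameter=2 * a,
        minor_diameter=2 * b,
        ellipticity_index=a / b,
        cca=cca,
        cca_radius=cca_radius,
        icd={"a": icd_a, "b": icd_b, "c": icd_c},
        ch=ch,
        horizontal_offset_e=e,
        predicted_ch={k: math.hypot(ch[k], e) for k in COMMISSURE_KEYS},
        cusp_angle={"L": alpha, "R": beta, "N": gamma},
        cch={k: cusp_coaptation_height(p.gh[k], est_d) for k in CUSP_KEYS},
        disproportionate_ratio_icd=disproportionate_ratio((icd_a, icd_b, icd_c)),
        disproportionate_ratio_ch=disproportionate_ratio(
            tuple(ch[k] for k in COMMISSURE_KEYS)
        ),
        disproportionate_ratio_sov=(
            disproportionate_ratio(tuple(p.sov[k] for k in CUSP_KEYS)) if p.sov else None
        ),
        geometric_height=dict(p.gh),
        effective_height=dict(p.eh),
        sov_diameter=dict(p.sov) if p.sov else None,
        ar_grade=p.ar_grade,
    )


def make_root(params: SyntheticRootParams) -> tuple[RootGeometry, RootMeasurements]:
    """Generate one root and its exact (noise-free, untransformed)
    measurements.  Reproducible for a fixed seed."""
    p = params
    a, b = p.vbr_semi_axes
    t = np.linspace(0.0, 2.0 * math.pi, p.contour_points, endpoint=False)
    contour = np.column_stack([a * np.cos(t), b * np.sin(t), np.zeros_like(t)])

    nadirs = {}
    for k in CUSP_KEYS:
        ang = math.radians(p.nadir_angles[k])
        nadirs[k] = np.array([a * math.cos(ang), b * math.sin(ang), 0.0])
    commissures = {
        k: np.array(
            [
                p.commissure_radius * math.cos(math.radians(p.commissure_angles[k])),
                p.commissure_radius * math.sin(math.radians(p.commissure_angles[k])),
                p.commissure_heights[k],
            ]
        )
        for k in COMMISSURE_KEYS
    }

    truth = _ground_truth(p)

    rng = np.random.default_rng(p.seed)
    if p.noise_sd > 0:
        # Contour annotation error is spatially correlated (workstation
        # contours are smooth splines), so perturb the contour with smooth
        # periodic fields — random low-order Fourier harmonics with
        # pointwise SD = noise_sd — radially and vertically, rather than
        # with white per-point noise, which would corrupt the perimeter.
        def smooth_field(angles):
            field_ = np.zeros_like(angles)
            for k in (1, 2, 3):
                ak, bk = rng.normal(0.0, p.noise_sd / math.sqrt(3), 2)
                field_ += ak * np.cos(k * angles) + bk * np.sin(k * angles)
            return field_

        radial, vertical = smooth_field(t), smooth_field(t)
        radial_unit = contour[:, :2] / np.linalg.norm(contour[:, :2], axis=1, keepdims=True)
        contour = contour + np.column_stack(
            [radial * radial_unit[:, 0], radial * radial_unit[:, 1], vertical]
        )
        # nadirs are re-annotated points, not contour samples: iid noise
        nadirs = {k: v + rng.normal(0.0, p.noise_sd, 3) for k, v in nadirs.items()}
        commissures = {
            k: v + rng.normal(0.0, p.noise_sd, 3) for k, v in commissures.items()
        }
    if p.rigid_transform is not None:
        tr = p.rigid_transform
        contour = tr.apply(contour)
        nadirs = {k: tr.apply(v)[0] for k, v in nadirs.items()}
        commissures = {k: tr.apply(v)[0] for k, v in commissures.items()}

    geometry = RootGeometry(
        annulus_contour=contour,
        nadirs=nadirs,
        commissures=commissures,
        geometric_height=dict(p.gh),
        effective_height=dict(p.eh),
        sov_diameter=dict(p.sov) if p.sov else None,
        ar_grade=p.ar_grade,
    )
    return geometry, truth


# ---------------------------------------------------------------------------
# cohort presets
# ---------------------------------------------------------------------------

def ct_group_distributions() -> dict:
    """Parameter means/SDs emulating the CT-planned surgical cohort."""
    return {
        "vbr_diameter": (28.0, 3.2),
        "ellipticity": (1.25, 0.15),
        "cca": (1330.7, 403.3),
        "ch_NL": (22.6, 3.7),
        "ch_LR": (23.0, 3.7),
        "ch_RN": (24.9, 4.9),
        "angle_LCC": (111.5, 8.2),
        "angle_RCC": (127.2, 6.2),
        "gh_L": (18.6, 2.8),
        "gh_R": (18.0, 2.0),
        "gh_N": (20.7, 2.8),
        "eh_L": (12.9, 2.5),
        "eh_R": (13.4, 2.6),
        "eh_N": (13.3, 2.4),
        "sov_L": (45.5, 5.3),
        "sov_R": (46.7, 6.3),
        "sov_N": (46.2, 5.9),
        "ar_probs": (0.55, 0.25, 0.15, 0.05),
    }


def control_group_distributions() -> dict:
    """Parameter means/SDs emulating the control surgical cohort."""
    return {
        "vbr_diameter": (28.6, 3.0),
        "ellipticity": (1.18, 0.12),
        "cca": (1189.2, 286.3),
        "ch_NL": (19.9, 3.0),
        "ch_LR": (21.8, 3.8),
        "ch_RN": (21.8, 4.1),
        "angle_LCC": (115.9, 5.1),
        "angle_RCC": (124.2, 4.7),
        "gh_L": (19.2, 2.1),
        "gh_R": (16.9, 2.6),
        "gh_N": (20.0, 2.9),
        "eh_L": (11.6, 1.9),
        "eh_R": (11.5, 2.6),
        "eh_N": (11.5, 2.2),
        "sov_L": (43.9, 4.8),
        "sov_R": (43.5, 5.1),
        "sov_N": (43.5, 4.6),
        "ar_probs": (0.65, 0.05, 0.15, 0.15),
    }


PRESETS = {
    "ct_group": ct_group_distributions,
    "control_group": control_group_distributions,
}


def circle_params(**overrides) -> SyntheticRootParams:
    """A perfectly circular root (all defaults); handy as an exact oracle."""
    return SyntheticRootParams(**overrides)


def ct_group_params(**overrides) -> SyntheticRootParams:
    """The CT-cohort *mean* root (default parameter values)."""
    return SyntheticRootParams(**overrides)


def _draw_positive(rng, mean, sd, low=1e-3):
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v > low:
            return float(v)
    raise RuntimeError("truncated draw failed; check distribution parameters")


def sample_params(
    dists: dict, rng: np.random.Generator, noise_sd: float = 0.0, seed: int = 0
) -> SyntheticRootParams:
    """Draw one root's parameters from a preset distribution dict."""
    d = _draw_positive(rng, *dists["vbr_diameter"])
    q = max(1.0, rng.normal(*dists["ellipticity"]))
    m = d / 2.0
    a, b = m * math.sqrt(q), m / math.sqrt(q)
    cca = _draw_positive(rng, *dists["cca"], low=100.0)
    alpha = _draw_positive(rng, *dists["angle_LCC"], low=30.0)
    beta = _draw_positive(rng, *dists["angle_RCC"], low=30.0)
    # renormalize so the three cusp angles tile the circumference
    gamma_mean = 360.0 - dists["angle_LCC"][0] - dists["angle_RCC"][0]
    gamma = _draw_positive(rng, gamma_mean, 5.0, low=30.0)
    total = alpha + beta + gamma
    alpha, beta, gamma = (360.0 * v / total for v in (alpha, beta, gamma))
    ar = str(rng.choice(
        ["none_trivial", "mild", "moderate", "severe"], p=dists["ar_probs"]
    ))
    return SyntheticRootParams(
        vbr_semi_axes=(a, b),
        commissure_radius=math.sqrt(cca / math.pi),
        commissure_heights={
            "NL": _draw_positive(rng, *dists["ch_NL"], low=5.0),
            "LR": _draw_positive(rng, *dists["ch_LR"], low=5.0),
            "RN": _draw_positive(rng, *dists["ch_RN"], low=5.0),
        },
        commissure_angles={"NL": 0.0, "LR": alpha, "RN": alpha + beta},
        nadir_angles={
            "L": alpha / 2.0,
            "R": alpha + beta / 2.0,
            "N": alpha + beta + gamma / 2.0,
        },
        gh={k: _draw_positive(rng, *dists[f"gh_{k}"], low=5.0) for k in CUSP_KEYS},
        eh={k: _draw_positive(rng, *dists[f"eh_{k}"], low=1.0) for k in CUSP_KEYS},
        sov={k: _draw_positive(rng, *dists[f"sov_{k}"], low=20.0) for k in CUSP_KEYS},
        ar_grade=ar,
        noise_sd=noise_sd,
        seed=seed,
    )


def make_cohort(
    n: int,
    param_distributions="ct_group",
    seed: int = 0,
    noise_sd: float = 0.0,
) -> list:
    """Draw *n* independent synthetic roots.

    *param_distributions* is a preset name (``ct_group``/``control_group``)
    or a distribution dict in the same shape.  Returns a list of
    ``(RootGeometry, RootMeasurements)`` pairs; reproducible per seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    dists = (
        PRESETS[param_distributions]()
        if isinstance(param_distributions, str)
        else dict(param_distributions)
    )
    rng = np.random.default_rng(seed)
    roots = []
    for i in range(n):
        params = sample_params(
            dists, rng, noise_sd=noise_sd, seed=int(rng.integers(0, 2**31 - 1))
        )
        roots.append(make_root(params))
    return roots


def truth_table(roots) -> pd.DataFrame:
    """Flat ground-truth table (one row per root) for a generated cohort."""
    from .io import measurements_to_record

    return pd.DataFrame([measurements_to_record(truth) for _, truth in roots])


def make_rater_tables(
    n_cases: int,
    true_sd: float,
    bias: float,
    noise_sd_a: float,
    noise_sd_b: float,
    seed: int = 0,
    mean: float = 28.0,
    parameter: str = "estimated_vbr_diameter",
) -> pd.DataFrame:
    """Simulated paired two-rater measurements with known variance
    components.

    Case truth ~ Normal(mean, true_sd); rater a measures truth +
    Normal(0, noise_sd_a); rater b adds a systematic *bias* plus
    Normal(0, noise_sd_b).  With equal noise SDs s and no bias the expected
    ICC(2,1) is ``true_sd**2 / (true_sd**2 + s**2)``.
    """
    if n_cases < 3:
        raise ValueError("need at least 3 cases")
    rng = np.random.default_rng(seed)
    truth = rng.normal(mean, true_sd, n_cases)
    a = truth + rng.normal(0.0, noise_sd_a, n_cases) if noise_sd_a > 0 else truth.copy()
    b = truth + bias + (
        rng.normal(0.0, noise_sd_b, n_cases) if noise_sd_b > 0 else 0.0
    )
    return pd.DataFrame(
        {
            "case_id": [f"case{i:03d}" for i in range(n_cases)],
            "parameter": parameter,
            "rater_a": a,
            "rater_b": b,
        }
    )
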