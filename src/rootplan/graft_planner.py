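"""Quantitative graft planning for David reimplantation.

Turns a :class:`~rootplan.root_measure.RootMeasurements` into a concrete
surgical plan: target (possibly downsized) basal-ring diameter, tube-graft
size from the available inventory, graft-bottom plication diameter,
horizontal commissural marks along the graft circumference, vertical
commissural heights expressed both in mm and in graft crimps, and the
sinotubular-junction plication needed to bring the distal graft back to the
basal-ring diameter.

Sizing rules
------------
* downsizing: if the measured VBR exceeds 30 mm or regurgitation is more
  than mild, the planned VBR is reduced by 2-4 mm (default 3) to restore
  cusp coaptation;
* graft: 6-8 mm larger than the planned VBR, chosen as the smallest
  available size meeting the minimum oversize;
* graft bottom plicated to planned VBR + 4 mm (aortic wall width);
* one fabric crimp ≈ 1.5 mm serves as the intraoperative height ruler;
* STJ plicated down to the planned VBR diameter, apportioned equally over
  the three inter-commissural panels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .root_measure import (
    AR_GRADES,
    COMMISSURE_KEYS,
    CUSP_KEYS,
    RootMeasurements,
    cusp_coaptation_height,
    predicted_commissural_height,
)

__all__ = [
    "PlannerConfig",
    "GraftPlan",
    "PlanningError",
    "plan_target_vbr",
    "select_graft_size",
    "mm_per_degree",
    "commissure_marks",
    "crimp_count",
    "stj_plication",
    "build_graft_plan",
]

# warning codes carried on a GraftPlan
SOV_GT_50 = "SOV_GT_50"            # large sinuses degrade CP prediction accuracy
LOW_CCH = "LOW_CCH"                # coaptation reserve below threshold
OVERSIZE_EXCEEDED = "OVERSIZE_EXCEEDED"
NEGATIVE_CCH = "NEGATIVE_CCH"


class PlanningError(ValueError):
    """No admissible plan exists for the given measurements/config."""


@dataclass(frozen=True)
class PlannerConfig:
    """Tunable planning rules; defaults encode the published protocol."""

    available_graft_sizes: tuple = (30.0, 32.0, 34.0)   # mm, ascending
    oversize_min: float = 6.0                           # mm over planned VBR
    oversize_max: float = 8.0
    bottom_margin: float = 4.0                          # graft bottom = VBR + 4
    downsizing_trigger_vbr: float = 30.0                # mm
    downsizing_mm: float = 3.0                          # within the 2-4 mm range
    crimp_height: float = 1.5                           # mm per fabric crimp
    cch_warn_threshold: float = 4.0                     # mm
    sov_warning_threshold: float = 50.0                 # mm (mean of 3 sinuses)
    reference_commissure: str = "NL"

    def __post_init__(self):
        sizes = tuple(float(s) for s in self.available_graft_sizes)
        if list(sizes) != sorted(sizes) or not sizes:
            raise ValueError("available_graft_sizes must be non-empty and ascending")
        object.__setattr__(self, "available_graft_sizes", sizes)
        if not self.crimp_height > 0:
            raise ValueError("crimp_height must be positive")
        if self.oversize_min > self.oversize_max:
            raise ValueError("oversize_min must not exceed oversize_max")
        if self.reference_commissure not in COMMISSURE_KEYS:
            raise ValueError(f"reference_commissure must be one of {COMMISSURE_KEYS}")


@dataclass
class GraftPlan:
    """Complete quantitative plan for one root."""

    target_vbr_diameter: float
    downsizing_applied: float
    graft_size: float
    graft_bottom_diameter: float
    mm_per_degree: float
    commissure_marks: dict       # per commissure: {"angle_from_reference": deg,
                                 #                  "arc_position": mm}
    predicted_ch: dict           # per commissure, mm
    crimp_count: dict            # per commissure, whole crimps
    stj_target_diameter: float
    stj_circumferential_reduction: float
    stj_reduction_per_panel: float
    cch: dict                    # per cusp at the target VBR
    warnings: list = field(default_factory=list)


def plan_target_vbr(
    measured_vbr: float,
    ar_grade: str,
    gh: dict,
    config: PlannerConfig = PlannerConfig(),
) -> tuple[float, float]:
    """Planned (possibly downsized) VBR diameter.

    Downsizing triggers when the measured VBR exceeds the trigger (30 mm) or
    the AR grade is worse than mild; the reduction is ``config.downsizing_mm``.
    Returns ``(target, downsizing_applied)``.
    """
    if not measured_vbr > 0:
        raise ValueError("measured VBR must be positive")
    if ar_grade not in AR_GRADES:
        raise ValueError(f"unknown AR grade {ar_grade!r}")
    trigger = (
        measured_vbr > config.downsizing_trigger_vbr
        or AR_GRADES.index(ar_grade) > AR_GRADES.index("mild")
    )
    downsizing = config.downsizing_mm if trigger else 0.0
    return measured_vbr - downsizing, downsizing


def select_graft_size(target_vbr: float, config: PlannerConfig = PlannerConfig()) -> float:
    """Smallest available graft at least ``oversize_min`` larger than the
    planned VBR; raises :class:`PlanningError` when the inventory has none."""
    if not target_vbr > 0:
        raise ValueError("target VBR must be positive")
    for size in config.available_graft_sizes:
        if size >= target_vbr + config.oversize_min:
            return size
    raise PlanningError(
        f"no graft in {config.available_graft_sizes} is >= "
        f"{target_vbr + config.oversize_min:.1f} mm (planned VBR "
        f"{target_vbr:.1f} + {config.oversize_min:.0f} mm oversize)"
    )


def mm_per_degree(graft_size: float) -> float:
    """Arc length of one degree on the graft circumference:
    ``pi * size / 360`` (≈ 0.3 mm for a 34 mm graft)."""
    if not graft_size > 0:
        raise ValueError("graft size must be positive")
    return math.pi * graft_size / 360.0


def commissure_marks(
    cusp_angles: tuple,
    graft_size: float,
    config: PlannerConfig = PlannerConfig(),
) -> dict:
    """Horizontal commissural positions on the graft.

    The reference commissure sits at arc position 0; walking NL -> (alpha)
    -> LR -> (beta) -> RN, each subsequent commissure sits at the cumulative
    cusp angle converted to arc length.  Returned per commissure as angle
    from reference (degrees) and arc position (mm).
    """
    alpha, beta, gamma = (float(v) for v in cusp_angles)
    if abs(alpha + beta + gamma - 360.0) > 1e-6:
        raise ValueError("cusp angles must sum to 360 degrees")
    scale = mm_per_degree(graft_size)
    circumference = math.pi * graft_size
    order = ("NL", "LR", "RN")
    cumulative = {"NL": 0.0, "LR": alpha, "RN": alpha + beta}
    ref = config.reference_commissure
    shift = cumulative[ref]
    marks = {}
    for k in order:
        angle = (cumulative[k] - shift) % 360.0
        marks[k] = {
            "angle_from_reference": angle,
            "arc_position": (angle * scale) % circumference,
        }
    return marks


def crimp_count(predicted_ch: float, config: PlannerConfig = PlannerConfig()) -> int:
    """Commissural height expressed in whole graft crimps (half-up
    rounding of ``predicted_ch / crimp_height``)."""
    if predicted_ch < 0:
        raise ValueError("predicted CH must be >= 0")
    return int(math.floor(predicted_ch / config.crimp_height + 0.5))


def stj_plication(target_vbr: float, graft_size: float) -> tuple[float, float]:
    """STJ reduction plan: the distal graft is plicated back to the planned
    VBR diameter.  Returns ``(stj_target_diameter,
    circumferential_reduction)``; the reduction is spread equally over the
    three inter-commissural panels."""
    if graft_size < target_vbr:
        raise ValueError("graft size must be at least the target VBR")
    return target_vbr, math.pi * (graft_size - target_vbr)


def build_graft_plan(
    measurements: RootMeasurements,
    ar_grade: Optional[str] = None,
    config: PlannerConfig = PlannerConfig(),
) -> GraftPlan:
    """Assemble the full plan from a root's measurements.

    Predicted CHs and cCHs are recomputed against the *target* VBR diameter
    so that downsizing is reflected in the commissural heights and the
    coaptation check.  Deterministic: identical inputs yield an identical
    plan.
    """
    grade = ar_grade if ar_grade is not None else measurements.ar_grade
    warnings_: list[str] = []

    target, downsizing = plan_target_vbr(
        measurements.estimated_vbr_diameter, grade, measurements.geometric_height, config
    )
    graft = select_graft_size(target, config)
    if graft > target + config.oversize_max:
        warnings_.append(OVERSIZE_EXCEEDED)

    predicted = {
        k: predicted_commissural_height(measurements.ch[k], measurements.cca, target)
        for k in COMMISSURE_KEYS
    }
    crimps = {k: crimp_count(predicted[k], config) for k in COMMISSURE_KEYS}

    angles = tuple(measurements.cusp_angle[k] for k in CUSP_KEYS)
    marks = commissure_marks(angles, graft, config)

    cch = {
        k: cusp_coaptation_height(measurements.geometric_height[k], target)
        for k in CUSP_KEYS
    }
    if min(cch.values()) < 0:
        warnings_.append(NEGATIVE_CCH)
    if min(cch.values()) < config.cch_warn_threshold:
        warnings_.append(LOW_CCH)

    sov = measurements.sov_diameter
    if sov and sum(sov.values()) / len(sov) > config.sov_warning_threshold:
        warnings_.append(SOV_GT_50)

    stj_target, stj_reduction = stj_plication(target, graft)
    return GraftPlan(
        target_vbr_diameter=target,
        downsizing_applied=downsizing,
        graft_size=graft,
        graft_bottom_diameter=target + config.bottom_margin,
        mm_per_degree=mm_per_degree(graft),
        commissure_marks=marks,
        predicted_ch=predicted,
        crimp_count=crimps,
        stj_target_diameter=stj_target,
        stj_circumferential_reduction=stj_reduction,
        stj_reduction_per_panel=stj_reduction / 3.0,
        cch=cch,
        warnings=warnings_,
    )
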