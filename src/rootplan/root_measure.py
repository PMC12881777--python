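"""Aortic-root morphometry from 3D landmark data.

Converts a set of CT-derived landmarks (ordered annulus contour, three cusp
nadirs, three commissure apices, per-cusp geometric/effective heights) into
the full panel of root measurements used for valve-sparing root replacement
planning: virtual basal ring (VBR) area/perimeter and circle-equivalent
diameter, ellipticity, commissure circle area (CCA), intercommissural
distances (ICDs), commissural heights (CHs), cusp angles, predicted CHs,
cusp coaptation heights (cCHs) and disproportionate ratios.

All coordinates are millimetres in an arbitrary right-handed frame; every
derived scalar is invariant under rigid motion of the landmark set.

Conventions
-----------
Commissures are keyed ``NL``, ``LR``, ``RN`` (the commissure between the
non/left-, left/right-, right/non-coronary sinuses); cusps are keyed ``L``,
``R``, ``N``.  ICD ``a`` spans NL-LR and subtends the left-coronary cusp,
``b`` spans LR-RN (right cusp), ``c`` spans RN-NL (non-coronary cusp).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "COMMISSURE_KEYS",
    "CUSP_KEYS",
    "AR_GRADES",
    "DegenerateGeometryError",
    "MeasurementWarning",
    "Plane",
    "RootGeometry",
    "RootMeasurements",
    "fit_vbr_plane",
    "project_to_plane",
    "polygon_area_perimeter",
    "estimated_vbr_diameter",
    "ellipse_axes",
    "commissure_circle",
    "intercommissural_distances",
    "commissural_heights",
    "cusp_angles",
    "radial_offset_e",
    "predicted_commissural_height",
    "cusp_coaptation_height",
    "disproportionate_ratio",
    "measure_root",
]

COMMISSURE_KEYS = ("NL", "LR", "RN")
CUSP_KEYS = ("L", "R", "N")
AR_GRADES = ("none_trivial", "mild", "moderate", "severe")

#: ellipticity index above which the annulus is considered oval
OVAL_THRESHOLD = 1.2


class DegenerateGeometryError(ValueError):
    """Raised when landmarks do not define the required geometry
    (collinear points, empty contour, ...)."""


class MeasurementWarning(UserWarning):
    """Non-fatal anomaly in the landmark data (e.g. commissure below the
    annular plane, commissure circle smaller than the basal ring)."""


def _as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float).reshape(3)
    if not np.all(np.isfinite(a)):
        raise ValueError(f"non-finite coordinate: {p!r}")
    return a


def _collinear(p, q, r, tol: float = 1e-9) -> bool:
    cross = np.cross(q - p, r - p)
    scale = max(np.linalg.norm(q - p) * np.linalg.norm(r - p), 1.0)
    return bool(np.linalg.norm(cross) <= tol * scale)


@dataclass(frozen=True)
class Plane:
    """A plane ``{p : unit_normal . p = offset}`` in mm units.

    ``offset`` is the signed distance of the plane from the origin along the
    unit normal.  For the VBR plane the normal points toward the aortic
    (commissure) side.
    """

    unit_normal: np.ndarray
    offset: float

    def __post_init__(self):
        n = _as_point(self.unit_normal)
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise ValueError("plane normal must be unit length")
        object.__setattr__(self, "unit_normal", n)
        object.__setattr__(self, "offset", float(self.offset))

    def signed_distance(self, points) -> np.ndarray:
        """Signed perpendicular distance (mm); positive on the normal side."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.unit_normal - self.offset


@dataclass
class RootGeometry:
    """Raw 3D landmark set of one aortic root.

    Parameters
    ----------
    annulus_contour : (N, 3) array
        Ordered points along the basal attachment line, N >= 3.
    nadirs : dict
        Lowest insertion point of each cusp, keyed ``L``/``R``/``N``.
    commissures : dict
        Commissure apices, keyed ``NL``/``LR``/``RN``.
    geometric_height, effective_height : dict
        Per-cusp gH (> 0) and eH (>= 0) in mm, keyed ``L``/``R``/``N``.
    sov_diameter : dict, optional
        Per-sinus sinus-of-Valsalva diameter in mm.
    ar_grade : str
        Aortic-regurgitation grade, one of ``none_trivial``, ``mild``,
        ``moderate``, ``severe``.
    """

    annulus_contour: np.ndarray
    nadirs: dict
    commissures: dict
    geometric_height: dict
    effective_height: dict
    sov_diameter: Optional[dict] = None
    ar_grade: str = "none_trivial"

    def __post_init__(self):
        contour = np.asarray(self.annulus_contour, dtype=float)
        if contour.ndim != 2 or contour.shape[1] != 3 or contour.shape[0] < 3:
            raise ValueError("annulus_contour must be an (N>=3, 3) array")
        if not np.all(np.isfinite(contour)):
            raise ValueError("annulus_contour contains non-finite values")
        self.annulus_contour = contour

        self.nadirs = {k: _as_point(self.nadirs[k]) for k in CUSP_KEYS}
        self.commissures = {k: _as_point(self.commissures[k]) for k in COMMISSURE_KEYS}
        if _collinear(*(self.nadirs[k] for k in CUSP_KEYS)):
            raise DegenerateGeometryError("nadirs are collinear")
        if _collinear(*(self.commissures[k] for k in COMMISSURE_KEYS)):
            raise DegenerateGeometryError("commissures are collinear")

        self.geometric_height = {k: float(self.geometric_height[k]) for k in CUSP_KEYS}
        self.effective_height = {k: float(self.effective_height[k]) for k in CUSP_KEYS}
        for k in CUSP_KEYS:
            if not self.geometric_height[k] > 0:
                raise ValueError(f"geometric_height.{k} must be > 0")
            if self.effective_height[k] < 0:
                raise ValueError(f"effective_height.{k} must be >= 0")
        if self.sov_diameter is not None:
            self.sov_diameter = {k: float(self.sov_diameter[k]) for k in CUSP_KEYS}
        if self.ar_grade not in AR_GRADES:
            raise ValueError(f"ar_grade must be one of {AR_GRADES}, got {self.ar_grade!r}")


@dataclass
class RootMeasurements:
    """All derived morphometric parameters of one root (mm, mm², degrees)."""

    vbr_area: float
    vbr_perimeter: float
    estimated_vbr_diameter: float
    major_diameter: float
    minor_diameter: float
    ellipticity_index: float
    cca: float
    cca_radius: float
    icd: dict                 # {"a": NL-LR, "b": LR-RN, "c": RN-NL}
    ch: dict                  # per commissure NL/LR/RN (symbol d)
    horizontal_offset_e: float
    predicted_ch: dict        # per commissure (symbol f)
    cusp_angle: dict          # per cusp L/R/N in degrees (alpha/beta/gamma)
    cch: dict                 # per cusp, cusp coaptation height
    disproportionate_ratio_icd: float
    disproportionate_ratio_ch: float
    disproportionate_ratio_sov: Optional[float] = None
    geometric_height: dict = field(default_factory=dict)
    effective_height: dict = field(default_factory=dict)
    sov_diameter: Optional[dict] = None
    ar_grade: str = "none_trivial"

    @property
    def oval_vbr(self) -> bool:
        """True when the annulus is oval (ellipticity index > 1.2)."""
        return self.ellipticity_index > OVAL_THRESHOLD


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def fit_vbr_plane(geometry: RootGeometry) -> Plane:
    """Plane of the virtual basal ring: the exact plane through the three
    cusp nadirs, with the normal oriented toward the commissures."""
    p_l, p_r, p_n = (geometry.nadirs[k] for k in CUSP_KEYS)
    normal = np.cross(p_r - p_l, p_n - p_l)
    norm = np.linalg.norm(normal)
    if norm <= 1e-12 * max(np.linalg.norm(p_r - p_l) * np.linalg.norm(p_n - p_l), 1.0):
        raise DegenerateGeometryError("nadirs are collinear; VBR plane undefined")
    normal = normal / norm
    com_centroid = np.mean([geometry.commissures[k] for k in COMMISSURE_KEYS], axis=0)
    if (com_centroid - p_l) @ normal < 0:
        normal = -normal
    return Plane(unit_normal=normal, offset=float(normal @ p_l))


def _plane_basis(plane: Plane) -> tuple[np.ndarray, np.ndarray]:
    # deterministic in-plane orthonormal basis: seed with the world axis
    # least aligned with the normal
    n = plane.unit_normal
    axis = np.zeros(3)
    axis[int(np.argmin(np.abs(n)))] = 1.0
    u = axis - (axis @ n) * n
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


def project_to_plane(points, plane: Plane) -> np.ndarray:
    """Orthogonally project 3D points onto *plane*, returned as (N, 2)
    coordinates in an orthonormal in-plane basis (mm).

    In-plane distances are preserved exactly for coplanar inputs.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    u, v = _plane_basis(plane)
    origin = plane.offset * plane.unit_normal
    rel = pts - origin
    return np.column_stack([rel @ u, rel @ v])


def polygon_area_perimeter(points2d) -> tuple[float, float]:
    """Shoelace area (orientation-independent) and edge-sum perimeter of the
    implicitly-closed polygon through *points2d*."""
    pts = np.atleast_2d(np.asarray(points2d, dtype=float))
    if pts.shape[0] < 3:
        raise ValueError("polygon needs at least 3 points")
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    area = 0.5 * abs(np.sum(x * yn - xn * y))
    perimeter = float(np.sum(np.hypot(xn - x, yn - y)))
    return float(area), perimeter


def estimated_vbr_diameter(area: float, perimeter: float) -> float:
    """Circle-equivalent VBR diameter (mm).

    The annulus is treated as a circle and sized from both printed
    quantities: the area-equivalent diameter ``2*sqrt(A/pi)`` and the
    perimeter-equivalent diameter ``P/pi``; the estimate is their arithmetic
    mean.  For a true circle the two coincide.
    """
    if not (area > 0 and perimeter > 0):
        raise ValueError("area and perimeter must be positive")
    d_area = 2.0 * math.sqrt(area / math.pi)
    d_perim = perimeter / math.pi
    return 0.5 * (d_area + d_perim)


def ellipse_axes(points2d) -> tuple[float, float]:
    """Major and minor VBR diameters (mm): the extremal lengths of chords
    through the contour centroid, matching the clinical caliper convention.

    Returns ``(major, minor)`` with ``major >= minor``; the ellipticity
    index is their ratio.
    """
    pts = np.atleast_2d(np.asarray(points2d, dtype=float))
    n = pts.shape[0]
    if n < 3:
        raise DegenerateGeometryError("contour needs at least 3 points")
    c = pts.mean(axis=0)
    rel = pts - c
    radii = np.linalg.norm(rel, axis=1)
    if np.any(radii <= 1e-12):
        raise DegenerateGeometryError("contour passes through its own centroid")

    # edges of the implicitly closed polygon, relative to the centroid
    e0 = rel
    e1 = np.roll(rel, -1, axis=0)
    chords = np.empty(n)
    for i in range(n):
        u = rel[i] / radii[i]
        # distance from centroid to the boundary in direction -u:
        # solve c + t*(-u) = e0 + s*(e1-e0), t > 0, s in [0, 1]
        d = e1 - e0
        denom = (-u[0]) * (-d[:, 1]) - (-u[1]) * (-d[:, 0])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (e0[:, 0] * (-d[:, 1]) - e0[:, 1] * (-d[:, 0])) / denom
            s = ((-u[0]) * e0[:, 1] - (-u[1]) * e0[:, 0]) / denom
        valid = np.isfinite(t) & (t > 1e-9) & (s >= -1e-9) & (s <= 1 + 1e-9)
        if not np.any(valid):
            raise DegenerateGeometryError("degenerate contour: no opposite boundary")
        chords[i] = radii[i] + np.min(t[valid])
    return float(np.max(chords)), float(np.min(chords))


def commissure_circle(commissures: dict) -> tuple[np.ndarray, float, float]:
    """Circumcircle of the three commissure apices in their common plane.

    Returns ``(center, radius, cca)`` with the commissure circle area
    CCA = pi * radius**2 (mm²).
    """
    pa, pb, pc = (_as_point(commissures[k]) for k in COMMISSURE_KEYS)
    a = pa - pc
    b = pb - pc
    axb = np.cross(a, b)
    denom = 2.0 * (axb @ axb)
    if denom <= 1e-12 * max((a @ a) * (b @ b), 1.0):
        raise DegenerateGeometryError("commissures are collinear; circle undefined")
    center = pc + np.cross((a @ a) * b - (b @ b) * a, axb) / denom
    radius = float(np.linalg.norm(center - pa))
    return center, radius, math.pi * radius**2


def intercommissural_distances(commissures: dict) -> tuple[float, float, float]:
    """Straight-line 3D distances between adjacent commissures:
    ``a`` = NL-LR, ``b`` = LR-RN, ``c`` = RN-NL (mm)."""
    p = {k: _as_point(commissures[k]) for k in COMMISSURE_KEYS}
    a = float(np.linalg.norm(p["NL"] - p["LR"]))
    b = float(np.linalg.norm(p["LR"] - p["RN"]))
    c = float(np.linalg.norm(p["RN"] - p["NL"]))
    return a, b, c


def commissural_heights(commissures: dict, vbr_plane: Plane) -> dict:
    """Perpendicular distance of each commissure apex from the VBR plane
    (symbol d), signed positive on the aortic side.

    A negative height means the landmark lies below the annulus — almost
    certainly mislabeled — and triggers a :class:`MeasurementWarning`.
    """
    heights = {}
    for k in COMMISSURE_KEYS:
        d = float(vbr_plane.signed_distance(commissures[k])[0])
        if d < 0:
            warnings.warn(
                f"commissure {k} lies {-d:.2f} mm below the VBR plane; "
                "landmark may be mislabeled",
                MeasurementWarning,
                stacklevel=2,
            )
        heights[k] = d
    return heights


def cusp_angles(a: float, b: float, c: float) -> tuple[float, float, float]:
    """Convert the three ICDs to cusp angles (degrees) by proportional
    allocation of the 360° circumference:

        alpha = 360 a / (a+b+c)   (LCC, between NL and LR)
        beta  = 360 b / (a+b+c)   (RCC)
        gamma = 360 c / (a+b+c)   (NCC)

    The three angles sum to 360 exactly.
    """
    if not (a > 0 and b > 0 and c > 0):
        raise ValueError("ICDs must be positive")
    total = a + b + c
    alpha = 360.0 * a / total
    beta = 360.0 * b / total
    # subtracting the pre-summed (alpha + beta) makes the closure
    # (alpha + beta) + gamma == 360.0 exact in floating point
    gamma = 360.0 - (alpha + beta)
    return alpha, beta, gamma


def radial_offset_e(cca: float, vbr_diameter: float) -> float:
    """Horizontal offset ``e`` (mm): how far the commissure circle radius
    stands outside the basal-ring radius, ``sqrt(CCA/pi) - VBR/2``.

    Floored at zero (with a warning) when the commissure circle is smaller
    than the basal ring, which real roots do not exhibit.
    """
    if not (cca > 0 and vbr_diameter > 0):
        raise ValueError("cca and vbr_diameter must be positive")
    e = math.sqrt(cca / math.pi) - vbr_diameter / 2.0
    if e < 0:
        warnings.warn(
            f"commissure circle radius below VBR radius (e = {e:.2f} mm); "
            "clamping radial offset to 0",
            MeasurementWarning,
            stacklevel=2,
        )
        return 0.0
    return e


def predicted_commissural_height(d: float, cca: float, vbr_diameter: float) -> float:
    """Predicted commissural height ``f`` (mm) after reimplantation.

    Inside a straight tube graft the commissure travels from its native
    position (radial offset ``e`` outside the basal ring, height ``d`` above
    it) onto the graft wall, so the height along the wall follows the
    Pythagorean relation ``f = sqrt(d^2 + e^2)`` with
    ``e = sqrt(CCA/pi) - VBR/2``.
    """
    if d < 0:
        raise ValueError("measured CH must be >= 0")
    e = radial_offset_e(cca, vbr_diameter)
    return math.hypot(d, e)


def cusp_coaptation_height(gh: float, vbr_diameter: float) -> float:
    """Cusp coaptation height cCH = gH - VBR/2 (mm); may be negative,
    flagging insufficient coaptation reserve."""
    if not gh > 0:
        raise ValueError("geometric height must be positive")
    return gh - vbr_diameter / 2.0


def disproportionate_ratio(values) -> float:
    """Asymmetry of three paired measurements:
    ``(max - min) / min * 100`` (%)."""
    vals = [float(v) for v in values]
    if len(vals) != 3 or any(v <= 0 for v in vals):
        raise ValueError("disproportionate ratio needs 3 positive values")
    return (max(vals) - min(vals)) / min(vals) * 100.0


# ---------------------------------------------------------------------------
# composite measurement
# ---------------------------------------------------------------------------

def measure_root(geometry: RootGeometry) -> RootMeasurements:
    """Compute every morphometric parameter of a root from its landmarks.

    Deterministic for fixed input; all scalars are rigid-motion invariant.
    """
    plane = fit_vbr_plane(geometry)
    contour2d = project_to_plane(geometry.annulus_contour, plane)
    area, perimeter = polygon_area_perimeter(contour2d)
    est_d = estimated_vbr_diameter(area, perimeter)
    major, minor = ellipse_axes(contour2d)

    _, cca_radius, cca = commissure_circle(geometry.commissures)
    a, b, c = intercommissural_distances(geometry.commissures)
    ch = commissural_heights(geometry.commissures, plane)
    alpha, beta, gamma = cusp_angles(a, b, c)

    e = radial_offset_e(cca, est_d)
    predicted = {k: math.hypot(ch[k], e) for k in COMMISSURE_KEYS}
    cch = {k: cusp_coaptation_height(geometry.geometric_height[k], est_d) for k in CUSP_KEYS}

    sov = geometry.sov_diameter
    return RootMeasurements(
        vbr_area=area,
        vbr_perimeter=perimeter,
        estimated_vbr_diameter=est_d,
        major_diameter=major,
        minor_diameter=minor,
        ellipticity_index=major / minor,
        cca=cca,
        cca_radius=cca_radius,
        icd={"a": a, "b": b, "c": c},
        ch=dict(ch),
        horizontal_offset_e=e,
        predicted_ch=predicted,
        cusp_angle={"L": alpha, "R": beta, "N": gamma},
        cch=cch,
        disproportionate_ratio_icd=disproportionate_ratio((a, b, c)),
        disproportionate_ratio_ch=disproportionate_ratio(
            tuple(abs(ch[k]) for k in COMMISSURE_KEYS)
        ) if all(ch[k] > 0 for k in COMMISSURE_KEYS) else float("nan"),
        disproportionate_ratio_sov=(
            disproportionate_ratio(tuple(sov[k] for k in CUSP_KEYS)) if sov else None
        ),
        geometric_height=dict(geometry.geometric_height),
        effective_height=dict(geometry.effective_height),
        sov_diameter=dict(sov) if sov else None,
        ar_grade=geometry.ar_grade,
    )
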