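"""Reading and writing landmark files, measurement tables, plans and
agreement reports.

JSON is the canonical, lossless format; CSV is a display/export dialect
whose numbers are rounded to a configurable precision (default one decimal,
the convention of clinical tables).  All coordinates and lengths are
millimetres; a landmark file declaring any other unit is rejected.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .agreement_stats import AgreementReport
from .graft_planner import GraftPlan
from .root_measure import (
    AR_GRADES,
    COMMISSURE_KEYS,
    CUSP_KEYS,
    RootGeometry,
    RootMeasurements,
)

__all__ = [
    "SchemaError",
    "read_root_geometry",
    "write_root_geometry",
    "measurements_to_record",
    "measurements_from_record",
    "write_measurements",
    "read_measurements",
    "plan_to_record",
    "write_plan",
    "write_agreement",
]

DISPLAY_DECIMALS = 1


class SchemaError(ValueError):
    """A landmark or measurement file does not match the expected schema."""


# ---------------------------------------------------------------------------
# root geometry
# ---------------------------------------------------------------------------

def _require(mapping: dict, key: str, context: str):
    if key not in mapping:
        raise SchemaError(f"missing field {context}.{key}" if context else f"missing field {key}")
    return mapping[key]


def _keyed_points(obj, keys, context: str) -> dict:
    out = {}
    for k in keys:
        p = _require(obj, k, context)
        try:
            vec = [float(v) for v in p]
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"non-numeric coordinates in {context}.{k}") from exc
        if len(vec) != 3:
            raise SchemaError(f"{context}.{k} must have 3 coordinates")
        out[k] = vec
    return out


def _keyed_scalars(obj, keys, context: str) -> dict:
    out = {}
    for k in keys:
        v = _require(obj, k, context)
        try:
            out[k] = float(v)
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"non-numeric value in {context}.{k}") from exc
    return out


def _geometry_from_dict(data: dict) -> RootGeometry:
    if data.get("units", "mm") != "mm":
        raise SchemaError(f"unsupported units {data['units']!r}; coordinates must be mm")
    contour = _require(data, "annulus_contour", "")
    try:
        contour = np.asarray(contour, dtype=float)
    except ValueError as exc:
        raise SchemaError("non-numeric values in annulus_contour") from exc
    geometry = dict(
        annulus_contour=contour,
        nadirs=_keyed_points(_require(data, "nadirs", ""), CUSP_KEYS, "nadirs"),
        commissures=_keyed_points(
            _require(data, "commissures", ""), COMMISSURE_KEYS, "commissures"
        ),
        geometric_height=_keyed_scalars(_require(data, "gh", ""), CUSP_KEYS, "gh"),
        effective_height=_keyed_scalars(_require(data, "eh", ""), CUSP_KEYS, "eh"),
        ar_grade=data.get("ar_grade", "none_trivial"),
    )
    if data.get("sov") is not None:
        geometry["sov_diameter"] = _keyed_scalars(data["sov"], CUSP_KEYS, "sov")
    if geometry["ar_grade"] not in AR_GRADES:
        raise SchemaError(
            f"ar_grade must be one of {AR_GRADES}, got {geometry['ar_grade']!r}"
        )
    try:
        return RootGeometry(**geometry)
    except ValueError as exc:
        raise SchemaError(str(exc)) from exc


def _geometry_from_csv(path: Path) -> RootGeometry:
    # rows: role,label,x,y,z — roles contour/nadir/commissure carry points
    # (contour ordered by row); roles gh/eh/sov carry a value in the x column;
    # role ar_grade carries the grade in the label column
    contour, nadirs, commissures = [], {}, {}
    gh, eh, sov = {}, {}, {}
    ar_grade = "none_trivial"
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, start=2):
            role = (row.get("role") or "").strip()
            label = (row.get("label") or "").strip()
            try:
                if role == "contour":
                    contour.append([float(row["x"]), float(row["y"]), float(row["z"])])
                elif role == "nadir":
                    nadirs[label] = [float(row["x"]), float(row["y"]), float(row["z"])]
                elif role == "commissure":
                    commissures[label] = [float(row["x"]), float(row["y"]), float(row["z"])]
                elif role == "gh":
                    gh[label] = float(row["x"])
                elif role == "eh":
                    eh[label] = float(row["x"])
                elif role == "sov":
                    sov[label] = float(row["x"])
                elif role == "ar_grade":
                    ar_grade = label
                else:
                    raise SchemaError(f"unknown role {role!r} at line {lineno}")
            except (TypeError, ValueError, KeyError) as exc:
                raise SchemaError(f"bad value at line {lineno}: {exc}") from exc
    data = {
        "annulus_contour": contour,
        "nadirs": nadirs,
        "commissures": commissures,
        "gh": gh,
        "eh": eh,
        "ar_grade": ar_grade,
    }
    if sov:
        data["sov"] = sov
    return _geometry_from_dict(data)


def read_root_geometry(path) -> RootGeometry:
    """Load a landmark file (JSON canonical; CSV with role,label,x,y,z)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return _geometry_from_csv(path)
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path}: invalid JSON ({exc})") from exc
    return _geometry_from_dict(data)


def write_root_geometry(geometry: RootGeometry, path) -> None:
    """Write a landmark JSON that round-trips losslessly."""
    data = {
        "units": "mm",
        "annulus_contour": geometry.annulus_contour.tolist(),
        "nadirs": {k: geometry.nadirs[k].tolist() for k in CUSP_KEYS},
        "commissures": {k: geometry.commissures[k].tolist() for k in COMMISSURE_KEYS},
        "gh": geometry.geometric_height,
        "eh": geometry.effective_height,
        "sov": geometry.sov_diameter,
        "ar_grade": geometry.ar_grade,
    }
    with open(path, "w") as fh:
        json.dump(data, fh)


# ---------------------------------------------------------------------------
# measurements
# ---------------------------------------------------------------------------

_ICD_KEYS = ("a", "b", "c")


def measurements_to_record(m: RootMeasurements) -> dict:
    """Flatten a RootMeasurements into one row of scalar columns."""
    rec = {
        "vbr_area": m.vbr_area,
        "vbr_perimeter": m.vbr_perimeter,
        "estimated_vbr_diameter": m.estimated_vbr_diameter,
        "major_diameter": m.major_diameter,
        "minor_diameter": m.minor_diameter,
        "ellipticity_index": m.ellipticity_index,
        "oval_vbr": m.oval_vbr,
        "cca": m.cca,
        "cca_radius": m.cca_radius,
        "horizontal_offset_e": m.horizontal_offset_e,
        "disproportionate_ratio_icd": m.disproportionate_ratio_icd,
        "disproportionate_ratio_ch": m.disproportionate_ratio_ch,
        "disproportionate_ratio_sov": m.disproportionate_ratio_sov,
        "ar_grade": m.ar_grade,
    }
    for k in _ICD_KEYS:
        rec[f"icd_{k}"] = m.icd[k]
    for k in COMMISSURE_KEYS:
        rec[f"ch_{k}"] = m.ch[k]
        rec[f"predicted_ch_{k}"] = m.predicted_ch[k]
    for k in CUSP_KEYS:
        rec[f"cusp_angle_{k}"] = m.cusp_angle[k]
        rec[f"cch_{k}"] = m.cch[k]
        rec[f"geometric_height_{k}"] = m.geometric_height.get(k)
        rec[f"effective_height_{k}"] = m.effective_height.get(k)
        rec[f"sov_diameter_{k}"] = (m.sov_diameter or {}).get(k)
    return rec


def measurements_from_record(rec: dict) -> RootMeasurements:
    """Rebuild a RootMeasurements from a flat record (inverse of
    :func:`measurements_to_record`)."""
    def f(key):
        v = rec.get(key)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return None
        return float(v)

    sov = {k: f(f"sov_diameter_{k}") for k in CUSP_KEYS}
    sov = sov if all(v is not None for v in sov.values()) else None
    return RootMeasurements(
        vbr_area=f("vbr_area"),
        vbr_perimeter=f("vbr_perimeter"),
        estimated_vbr_diameter=f("estimated_vbr_diameter"),
        major_diameter=f("major_diameter"),
        minor_diameter=f("minor_diameter"),
        ellipticity_index=f("ellipticity_index"),
        cca=f("cca"),
        cca_radius=f("cca_radius"),
        icd={k: f(f"icd_{k}") for k in _ICD_KEYS},
        ch={k: f(f"ch_{k}") for k in COMMISSURE_KEYS},
        horizontal_offset_e=f("horizontal_offset_e"),
        predicted_ch={k: f(f"predicted_ch_{k}") for k in COMMISSURE_KEYS},
        cusp_angle={k: f(f"cusp_angle_{k}") for k in CUSP_KEYS},
        cch={k: f(f"cch_{k}") for k in CUSP_KEYS},
        disproportionate_ratio_icd=f("disproportionate_ratio_icd"),
        disproportionate_ratio_ch=f("disproportionate_ratio_ch"),
        disproportionate_ratio_sov=f("disproportionate_ratio_sov"),
        geometric_height={k: f(f"geometric_height_{k}") for k in CUSP_KEYS},
        effective_height={k: f(f"effective_height_{k}") for k in CUSP_KEYS},
        sov_diameter=sov,
        ar_grade=str(rec.get("ar_grade", "none_trivial")),
    )


def _round_record(rec: dict, decimals: int) -> dict:
    out = {}
    for k, v in rec.items():
        out[k] = round(v, decimals) if isinstance(v, float) else v
    return out


def write_measurements(
    measurements, path, format: Optional[str] = None, decimals: int = DISPLAY_DECIMALS
) -> None:
    """Write one or more RootMeasurements; JSON keeps full precision,
    CSV rounds to *decimals* (display convention)."""
    if isinstance(measurements, RootMeasurements):
        measurements = [measurements]
    records = [measurements_to_record(m) for m in measurements]
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "json")
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(records if len(records) > 1 else records[0], fh, indent=2)
    elif fmt == "csv":
        pd.DataFrame([_round_record(r, decimals) for r in records]).to_csv(
            path, index=False
        )
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_measurements(path) -> list:
    """Read measurements written by :func:`write_measurements`."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        return [measurements_from_record(rec) for rec in df.to_dict("records")]
    with open(path) as fh:
        data = json.load(fh)
    if isinstance(data, dict):
        data = [data]
    return [measurements_from_record(rec) for rec in data]


# ---------------------------------------------------------------------------
# plans and agreement reports
# ---------------------------------------------------------------------------

def plan_to_record(plan: GraftPlan) -> dict:
    return dataclasses.asdict(plan)


def write_plan(plan: GraftPlan, path, format: Optional[str] = None,
               decimals: int = DISPLAY_DECIMALS) -> None:
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "json")
    rec = plan_to_record(plan)
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(rec, fh, indent=2)
    elif fmt == "csv":
        flat = {}
        for k, v in rec.items():
            if isinstance(v, dict):
                for k2, v2 in v.items():
                    if isinstance(v2, dict):
                        for k3, v3 in v2.items():
                            flat[f"{k}_{k2}_{k3}"] = v3
                    else:
                        flat[f"{k}_{k2}"] = v2
            elif isinstance(v, list):
                flat[k] = ";".join(str(x) for x in v)
            else:
                flat[k] = v
        pd.DataFrame([_round_record(flat, decimals)]).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")


#: CSV column layout mirroring clinical agreement tables
AGREEMENT_COLUMNS = [
    "parameter", "n", "mean_a", "mean_b", "difference_mean", "difference_sd",
    "AE_mean", "AE_se", "ER_mean", "ER_se", "ICC", "ICC_CI_low", "ICC_CI_high",
    "BA_bias", "BA_LoA_low", "BA_LoA_high", "fixed_error_p",
]


def _agreement_record(rep: AgreementReport) -> dict:
    return {
        "parameter": rep.parameter,
        "n": rep.n,
        "mean_a": rep.mean_a,
        "mean_b": rep.mean_b,
        "difference_mean": rep.difference_mean,
        "difference_sd": rep.difference_sd,
        "AE_mean": rep.ae_mean,
        "AE_se": rep.ae_se,
        "ER_mean": rep.er_mean,
        "ER_se": rep.er_se,
        "ICC": rep.icc,
        "ICC_CI_low": rep.icc_ci_low,
        "ICC_CI_high": rep.icc_ci_high,
        "BA_bias": rep.ba_bias,
        "BA_LoA_low": rep.ba_loa_low,
        "BA_LoA_high": rep.ba_loa_high,
        "fixed_error_p": rep.fixed_error_p,
    }


def write_agreement(reports, path, format: Optional[str] = None,
                    decimals: int = 3) -> None:
    """Write agreement reports (a single report, list, or dict keyed by
    parameter) as JSON (full precision) or CSV (rounded)."""
    if isinstance(reports, AgreementReport):
        reports = [reports]
    elif isinstance(reports, dict):
        reports = list(reports.values())
    records = [_agreement_record(r) for r in reports]
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "json")
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(records, fh, indent=2)
    elif fmt == "csv":
        pd.DataFrame(
            [_round_record(r, decimals) for r in records], columns=AGREEMENT_COLUMNS
        ).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")
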