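"""Measurement-agreement statistics for algorithm-vs-expert validation.

Given paired per-case measurements from two raters (e.g. an automated
landmark algorithm and an expert reader) this module computes the standard
method-comparison panel: absolute error (AE) and error rate (ER) with
standard errors, the two-way random-effects absolute-agreement single-
measure intraclass correlation ICC(2,1) with its F-based 95% CI,
Bland-Altman bias and limits of agreement, and a one-sample t-test of the
differences against zero (the "fixed error" check).

Conventions: differences are rater_b - rater_a; ER uses rater_a (the
reference/expert) in the denominator, so AE and ER are *not* symmetric
under swapping raters, while bias merely changes sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "AgreementReport",
    "absolute_error",
    "error_rate",
    "icc",
    "bland_altman",
    "fixed_error_test",
    "agreement_report",
    "agreement_by_parameter",
    "multi_rater_reports",
]


@dataclass
class AgreementReport:
    """Full agreement panel for one parameter (native units: mm or mm²)."""

    n: int
    mean_a: float
    mean_b: float
    difference_mean: float
    difference_sd: float
    ae_mean: float
    ae_se: float
    er_mean: float          # %
    er_se: float            # %
    icc: float
    icc_ci_low: float
    icc_ci_high: float
    ba_bias: float
    ba_loa_low: float
    ba_loa_high: float
    fixed_error_p: float
    parameter: Optional[str] = None


def _pairs(table) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(table, pd.DataFrame):
        a = table["rater_a"].to_numpy(dtype=float)
        b = table["rater_b"].to_numpy(dtype=float)
    else:
        a, b = (np.asarray(x, dtype=float) for x in table)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("rater columns must be 1-D and equal length")
    if np.any(~np.isfinite(a)) or np.any(~np.isfinite(b)):
        raise ValueError("missing or non-finite measurements")
    return a, b


def absolute_error(table) -> tuple[float, float]:
    """Mean and standard error (SD/sqrt(n)) of |rater_b - rater_a|."""
    a, b = _pairs(table)
    if a.size < 2:
        raise ValueError("need at least 2 paired cases")
    ae = np.abs(b - a)
    return float(ae.mean()), float(ae.std(ddof=1) / np.sqrt(ae.size))


def error_rate(table) -> tuple[float, float]:
    """Mean and SE of the percentage error |b - a| / a * 100.

    The reference (rater_a) value is the denominator; rows with a zero
    reference are excluded with a warning.
    """
    a, b = _pairs(table)
    keep = a != 0
    if not np.all(keep):
        warnings.warn(
            f"excluding {np.sum(~keep)} case(s) with zero reference value",
            UserWarning,
            stacklevel=2,
        )
    a, b = a[keep], b[keep]
    if a.size < 2:
        raise ValueError("need at least 2 paired cases with nonzero reference")
    er = np.abs(b - a) / np.abs(a) * 100.0
    return float(er.mean()), float(er.std(ddof=1) / np.sqrt(er.size))


def icc(table) -> tuple[float, float, float]:
    """ICC(2,1): two-way random effects, absolute agreement, single
    measure, with the F-based 95% confidence interval.

    This form treats the two measurement systems as interchangeable
    absolute measurements, penalizing systematic offsets — the appropriate
    model when asking whether an algorithm can replace an expert.
    """
    import pingouin as pg

    a, b = _pairs(table)
    if a.size < 3:
        raise ValueError("ICC needs at least 3 cases")
    if np.var(np.concatenate([a, b])) == 0:
        raise ValueError("zero total variance; ICC undefined")
    long = pd.DataFrame(
        {
            "case": np.tile(np.arange(a.size), 2),
            "rater": np.repeat(["a", "b"], a.size),
            "value": np.concatenate([a, b]),
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # pingouin warns on edge-case F stats
        res = pg.intraclass_corr(
            data=long, targets="case", raters="rater", ratings="value"
        ).set_index("Type")
    # two-way random, absolute agreement, single measure; label varies
    # across pingouin versions
    key = "ICC(A,1)" if "ICC(A,1)" in res.index else "ICC2"
    row = res.loc[key]
    ci_col = "CI95" if "CI95" in res.columns else "CI95%"
    ci_low, ci_high = (float(x) for x in row[ci_col])
    return float(row["ICC"]), ci_low, ci_high


def bland_altman(table) -> tuple[float, float, float, np.ndarray]:
    """Bland-Altman analysis of the differences b - a.

    Returns ``(bias, loa_low, loa_high, outlier_indices)`` where the limits
    of agreement are bias ± 1.96 SD and outliers are the case indices whose
    difference falls strictly outside them.
    """
    a, b = _pairs(table)
    if a.size < 2:
        raise ValueError("need at least 2 paired cases")
    diff = b - a
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    loa_low, loa_high = bias - 1.96 * sd, bias + 1.96 * sd
    outliers = np.flatnonzero((diff < loa_low) | (diff > loa_high))
    return bias, loa_low, loa_high, outliers


def fixed_error_test(table) -> float:
    """Two-sided one-sample t-test of the differences against zero.

    A small p indicates a systematic (fixed) offset between the raters.
    Degenerate zero-variance differences give p = 1 when the shared
    difference is 0 and p = 0 otherwise.
    """
    a, b = _pairs(table)
    if a.size < 2:
        raise ValueError("need at least 2 paired cases")
    diff = b - a
    if np.ptp(diff) == 0:
        return 1.0 if diff[0] == 0 else 0.0
    return float(scipy.stats.ttest_1samp(diff, 0.0).pvalue)


def agreement_report(table, parameter: Optional[str] = None) -> AgreementReport:
    """Compute the complete agreement panel for one parameter."""
    a, b = _pairs(table)
    ae_mean, ae_se = absolute_error((a, b))
    er_mean, er_se = error_rate((a, b))
    icc_val, ci_lo, ci_hi = icc((a, b))
    bias, loa_lo, loa_hi, _ = bland_altman((a, b))
    diff = b - a
    return AgreementReport(
        n=int(a.size),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        difference_mean=float(diff.mean()),
        difference_sd=float(diff.std(ddof=1)),
        ae_mean=ae_mean,
        ae_se=ae_se,
        er_mean=er_mean,
        er_se=er_se,
        icc=icc_val,
        icc_ci_low=ci_lo,
        icc_ci_high=ci_hi,
        ba_bias=bias,
        ba_loa_low=loa_lo,
        ba_loa_high=loa_hi,
        fixed_error_p=fixed_error_test((a, b)),
        parameter=parameter,
    )


def agreement_by_parameter(table: pd.DataFrame) -> dict:
    """Per-parameter reports from a table with columns
    case_id, parameter, rater_a, rater_b."""
    return {
        name: agreement_report(group, parameter=str(name))
        for name, group in table.groupby("parameter", sort=True)
    }


def multi_rater_reports(wide: pd.DataFrame, algorithm_col: str) -> dict:
    """Agreement of several expert raters with an algorithm.

    *wide* holds one column per rater (cases as rows).  Returns pairwise
    reports between every pair of columns, keyed ``"x_vs_y"``, plus the
    mean-of-experts vs algorithm comparison keyed ``"experts_mean_vs_<algo>"``.
    """
    cols = list(wide.columns)
    if algorithm_col not in cols:
        raise ValueError(f"{algorithm_col!r} not among columns {cols}")
    reports = {}
    for i, x in enumerate(cols):
        for y in cols[i + 1:]:
            reports[f"{x}_vs_{y}"] = agreement_report(
                (wide[x].to_numpy(), wide[y].to_numpy()), parameter=f"{x}_vs_{y}"
            )
    experts = [c for c in cols if c != algorithm_col]
    mean_experts = wide[experts].mean(axis=1).to_numpy()
    key = f"experts_mean_vs_{algorithm_col}"
    reports[key] = agreement_report(
        (mean_experts, wide[algorithm_col].to_numpy()), parameter=key
    )
    return reports
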