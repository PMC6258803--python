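"""Validation statistics: Pearson correlation, OLS, Welch comparison,
and cohort-level summary reports.

The estimators are written in their closed forms (product-moment sums for
Pearson r, normal-equation solutions for OLS, the Welch–Satterthwaite
statistic for two-group comparisons); only the t-distribution tail
probabilities come from scipy. Two-tailed p-values use the exact transform
t = r·√((n−2)/(1−r²)) with n−2 degrees of freedom.

:func:`build_validation_report` assembles the full cohort analysis — per-
variable means ± SD overall and per BMI category, the pairwise correlation
matrix with p-values, a BMI→D_E regression refit, and BMI-group dose
comparisons — as a JSON-serializable report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _sps

from .errors import ValidationError
from .size_metrics import bmi_category

__all__ = [
    "CorrelationResult",
    "OLSResult",
    "ValidationReport",
    "pearson",
    "ols",
    "welch_two_sample",
    "build_validation_report",
]

#: Variables summarised and correlated in a validation report, in column order.
REPORT_VARIABLES = (
    "bmi",
    "d_ap_cm",
    "d_lat_cm",
    "d_e_cm",
    "d_ratio",
    "ctdi_vol_mgy",
    "dlp_mgycm",
    "ssde_mgy",
)


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson product-moment correlation with a two-tailed p-value."""

    r: float
    n: int
    p_two_tailed: float


@dataclass(frozen=True)
class OLSResult:
    """Simple linear regression y = slope·x + intercept."""

    slope: float
    intercept: float
    r_squared: float
    n: int


def _as_clean_array(seq: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(seq, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    if np.any(~np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation between two equal-length sequences (n ≥ 3).

    The p-value is two-tailed, from t = r·√((n−2)/(1−r²)) on n−2 degrees
    of freedom; for |r| = 1 it is exactly 0.
    """
    xa = _as_clean_array(x, "x")
    ya = _as_clean_array(y, "y")
    if len(xa) != len(ya):
        raise ValidationError(f"length mismatch: x has {len(xa)}, y has {len(ya)}")
    n = len(xa)
    if n < 3:
        raise ValidationError(f"need at least 3 observations, got {n}")
    dx = xa - xa.mean()
    dy = ya - ya.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0.0:
        raise ValidationError("x is constant: correlation undefined")
    if syy == 0.0:
        raise ValidationError("y is constant: correlation undefined")
    r = float(dx @ dy) / math.sqrt(sxx * syy)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * float(_sps.t.sf(abs(t), n - 2))
    return CorrelationResult(r=r, n=n, p_two_tailed=p)


def ols(x: Sequence[float], y: Sequence[float]) -> OLSResult:
    """Ordinary least squares fit of y on x (closed form, n ≥ 3).

    The fitted line passes through (x̄, ȳ) by construction.
    """
    xa = _as_clean_array(x, "x")
    ya = _as_clean_array(y, "y")
    if len(xa) != len(ya):
        raise ValidationError(f"length mismatch: x has {len(xa)}, y has {len(ya)}")
    n = len(xa)
    if n < 3:
        raise ValidationError(f"need at least 3 observations, got {n}")
    dx = xa - xa.mean()
    dy = ya - ya.mean()
    sxx = float(dx @ dx)
    if sxx == 0.0:
        raise ValidationError("x is constant: regression undefined")
    slope = float(dx @ dy) / sxx
    intercept = float(ya.mean() - slope * xa.mean())
    syy = float(dy @ dy)
    if syy == 0.0:
        r_squared = 1.0  # y constant and reproduced exactly by slope 0
    else:
        resid = ya - (slope * xa + intercept)
        r_squared = 1.0 - float(resid @ resid) / syy
        r_squared = max(0.0, min(1.0, r_squared))
    return OLSResult(slope=slope, intercept=intercept, r_squared=r_squared, n=n)


def welch_two_sample(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sample comparison.

    Returns (t, degrees of freedom, two-tailed p). Welch's form is used
    because group spreads in size-stratified dose data differ several-fold.
    Identical groups give t = 0, p = 1.
    """
    aa = _as_clean_array(a, "a")
    ba = _as_clean_array(b, "b")
    if len(aa) < 2 or len(ba) < 2:
        raise ValidationError("each group needs at least 2 observations")
    na, nb = len(aa), len(ba)
    va = float(aa.var(ddof=1))
    vb = float(ba.var(ddof=1))
    se2 = va / na + vb / nb
    if se2 == 0.0:
        return 0.0, float(na + nb - 2), 1.0
    t = (float(aa.mean()) - float(ba.mean())) / math.sqrt(se2)
    df = se2 * se2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * float(_sps.t.sf(abs(t), df))
    return t, df, min(p, 1.0)


def _mean_sd(values: np.ndarray) -> dict[str, float]:
    return {
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)) if len(values) > 1 else 0.0,
        "n": int(len(values)),
    }


@dataclass(frozen=True)
class ValidationReport:
    """Cohort validation summary.

    ``summary`` maps variable → {mean, sd, n}; ``by_category`` nests the
    same per BMI category; ``correlations`` holds the symmetric r matrix and
    p matrix keyed by variable pairs; ``bmi_de_fit`` is the refit of the
    BMI→D_E regression; ``group_comparison`` compares dose metrics between
    BMI < 25 and BMI ≥ 25 (Welch, two-tailed).
    """

    n: int
    summary: Mapping[str, Mapping[str, float]]
    by_category: Mapping[str, Mapping[str, Mapping[str, float]]]
    correlations: Mapping[str, Mapping[str, float]]
    bmi_de_fit: OLSResult
    group_comparison: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        fit = self.bmi_de_fit
        return {
            "n": self.n,
            "summary": {k: dict(v) for k, v in self.summary.items()},
            "by_category": {
                c: {k: dict(v) for k, v in vars_.items()}
                for c, vars_ in self.by_category.items()
            },
            "correlations": {k: dict(v) for k, v in self.correlations.items()},
            "bmi_de_fit": {
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r_squared": fit.r_squared,
                "n": fit.n,
            },
            "group_comparison": {k: dict(v) for k, v in self.group_comparison.items()},
        }


def _columns_from_cohort(cohort) -> dict[str, np.ndarray]:
    """Accept either a pandas DataFrame (cohort CSV schema) or a sequence of
    objects with the simulator's attribute names."""
    import pandas as pd

    if isinstance(cohort, pd.DataFrame):
        missing = [c for c in REPORT_VARIABLES if c not in cohort.columns]
        if missing:
            raise ValidationError(f"cohort is missing required columns: {', '.join(missing)}")
        return {c: cohort[c].to_numpy(dtype=float) for c in REPORT_VARIABLES}

    attr_map = {
        "bmi": "bmi",
        "d_ap_cm": "d_ap",
        "d_lat_cm": "d_lat",
        "d_e_cm": "d_e",
        "d_ratio": "d_ratio",
        "ctdi_vol_mgy": "ctdi_vol",
        "dlp_mgycm": "dlp",
        "ssde_mgy": "ssde",
    }
    rows = list(cohort)
    if not rows:
        raise ValidationError("cohort is empty")
    first = rows[0]
    missing = [a for a in attr_map.values() if not hasattr(first, a)]
    if missing:
        raise ValidationError(f"cohort rows are missing required fields: {', '.join(missing)}")
    return {
        col: np.asarray([getattr(r, attr) for r in rows], dtype=float)
        for col, attr in attr_map.items()
    }


def build_validation_report(cohort) -> ValidationReport:
    """Run the full cohort validation analysis.

    ``cohort`` may be a DataFrame in the cohort CSV schema or a sequence of
    simulated patients. Requires at least 3 complete rows. The correlation
    matrix is stored flat under "var1|var2" keys (r and p side by side);
    the group comparison tests each dose metric between the BMI < 25 and
    BMI ≥ 25 strata.
    """
    cols = _columns_from_cohort(cohort)
    n = len(cols["bmi"])
    if n < 3:
        raise ValidationError(f"need at least 3 complete rows, got {n}")

    summary = {name: _mean_sd(vals) for name, vals in cols.items()}

    categories = np.asarray([bmi_category(b) for b in cols["bmi"]])
    by_category: dict[str, dict[str, dict[str, float]]] = {}
    for cat in ("underweight", "normal", "overweight", "obese"):
        mask = categories == cat
        if mask.any():
            by_category[cat] = {name: _mean_sd(vals[mask]) for name, vals in cols.items()}

    correlations: dict[str, dict[str, float]] = {}
    for i, vi in enumerate(REPORT_VARIABLES):
        for vj in REPORT_VARIABLES[i + 1:]:
            try:
                res = pearson(cols[vi], cols[vj])
                correlations[f"{vi}|{vj}"] = {"r": res.r, "p": res.p_two_tailed}
            except ValidationError:
                correlations[f"{vi}|{vj}"] = {"r": float("nan"), "p": float("nan")}

    fit = ols(cols["bmi"], cols["d_e_cm"])

    group_comparison: dict[str, dict[str, float]] = {}
    low = cols["bmi"] < 25.0
    if low.sum() >= 2 and (~low).sum() >= 2:
        for metric in ("ctdi_vol_mgy", "dlp_mgycm", "ssde_mgy"):
            lo_vals, hi_vals = cols[metric][low], cols[metric][~low]
            t, df, p = welch_two_sample(lo_vals, hi_vals)
            group_comparison[metric] = {
                "mean_bmi_lt_25": float(lo_vals.mean()),
                "mean_bmi_ge_25": float(hi_vals.mean()),
                "t": t,
                "df": df,
                "p_two_tailed": p,
            }

    return ValidationReport(
        n=n,
        summary=summary,
        by_category=by_category,
        correlations=correlations,
        bmi_de_fit=fit,
        group_comparison=group_comparison,
    )
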