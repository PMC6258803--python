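"""CTDIvol→SSDE conversion from BMI.

The core method: estimate the abdominal effective diameter D_E (cm) from BMI
via a linear regression (D_E = 0.76·BMI + 9.4, fitted on an adult abdominal
CT cohort over BMI 17.4–38.8 kg/m²), map D_E to a dimensionless conversion
factor f with a two-parameter exponential f(D_E) = a·exp(−b·D_E), and obtain
the size-specific dose estimate SSDE = f · CTDIvol.

The exponential coefficients are not hard-coded: they are calibrated by
log-linear least squares to the packaged 36-row BMI→D_E→factor reference
table for the 32-cm body phantom (the table's own source is the AAPM
size-correction lookup). The calibrated curve reproduces every packaged
factor within ±0.01, which is the fidelity standard adopted throughout.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import NamedTuple, Sequence

import numpy as np

from .errors import ValidationError

__all__ = [
    "RegressionLine",
    "ConversionModel",
    "DoseRecord",
    "ConversionTableRow",
    "DiameterEstimate",
    "DEFAULT_REGRESSION",
    "de_from_bmi",
    "fit_conversion_model",
    "conversion_factor",
    "ssde_from_ctdi",
    "dlp_from_ctdi",
    "generate_conversion_table",
    "load_reference_table",
    "default_conversion_model",
    "round_half_away",
]

logger = logging.getLogger(__name__)

_REFERENCE_TABLE_RESOURCE = "conversion_table_32cm.csv"


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention used for table output;
    Python's built-in ``round`` is half-to-even).

    Operates on the shortest decimal representation of ``x`` so that values
    that print as exact halves (e.g. 1.005) round up as a reader expects,
    regardless of their binary representation.
    """
    import decimal

    q = decimal.Decimal(1).scaleb(-ndigits)
    d = decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    return float(d)


def _positive(value: float, name: str) -> float:
    v = float(value)
    if not math.isfinite(v) or v <= 0:
        raise ValidationError(f"{name} must be a positive finite number, got {value!r}")
    return v


@dataclass(frozen=True)
class RegressionLine:
    """A linear BMI→D_E mapping: d_e = slope·bmi + intercept.

    ``valid_bmi_range`` records the BMI interval observed in the calibration
    cohort; estimates outside it are extrapolations and are flagged, not
    refused (the reference table itself spans BMI 15–50).
    """

    slope: float = 0.76  # cm per kg/m²
    intercept: float = 9.4  # cm
    valid_bmi_range: tuple[float, float] = (17.4, 38.8)  # kg/m²

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValidationError(f"slope must be positive, got {self.slope}")
        lo, hi = self.valid_bmi_range
        if not lo < hi:
            raise ValidationError(f"valid_bmi_range must be increasing, got {self.valid_bmi_range}")


#: The shipped default regression (cohort BMI range 17.4–38.8 kg/m²).
DEFAULT_REGRESSION = RegressionLine()


class DiameterEstimate(NamedTuple):
    """Effective-diameter estimate with an extrapolation flag."""

    d_e: float  # cm
    extrapolated: bool


def de_from_bmi(bmi: float, line: RegressionLine = DEFAULT_REGRESSION) -> DiameterEstimate:
    """Estimate the effective diameter (cm) from BMI (kg/m²).

    Returns the regression value slope·bmi + intercept together with a flag
    that is True when ``bmi`` lies outside the regression's cohort validity
    range; extrapolated estimates are still returned (and logged) rather
    than refused.
    """
    b = _positive(bmi, "bmi")
    lo, hi = line.valid_bmi_range
    extrapolated = not (lo <= b <= hi)
    if extrapolated:
        logger.warning(
            "BMI %.2f outside regression validity range [%.1f, %.1f]; "
            "effective diameter is an extrapolation", b, lo, hi,
        )
    return DiameterEstimate(line.slope * b + line.intercept, extrapolated)


@dataclass(frozen=True)
class ConversionModel:
    """Calibrated exponential conversion curve f(d_e) = a·exp(−b·d_e).

    ``a`` is the dimensionless amplitude (factor extrapolated to d_e = 0),
    ``b`` the decay rate per cm; both positive, so the factor is strictly
    decreasing in patient size. ``calibration_residual_max`` stores the
    largest absolute deviation between the fitted curve and the calibration
    factors on the original (un-logged) scale.
    """

    a: float
    b: float
    phantom_diameter: int = 32  # cm; 32 = body, 16 = head
    calibration_residual_max: float = 0.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValidationError(f"a and b must be positive, got a={self.a}, b={self.b}")
        if self.phantom_diameter not in (16, 32):
            raise ValidationError(f"phantom_diameter must be 16 or 32, got {self.phantom_diameter}")
        if self.calibration_residual_max < 0:
            raise ValidationError("calibration_residual_max must be >= 0")

    def factor(self, d_e: float) -> float:
        return conversion_factor(d_e, self)

    @property
    def unity_diameter(self) -> float:
        """The d_e (cm) at which the conversion factor equals 1 (SSDE =
        CTDIvol): ln(a)/b."""
        return math.log(self.a) / self.b


def fit_conversion_model(
    rows: Sequence[tuple[float, float]], phantom: int = 32
) -> ConversionModel:
    """Calibrate a :class:`ConversionModel` from (d_e, factor) pairs.

    Ordinary least squares on ln(factor) against d_e; exact for noiseless
    exponential data and closed-form. Requires at least three rows with
    distinct d_e and positive factors.
    """
    if len(rows) < 3:
        raise ValidationError(f"need at least 3 calibration rows, got {len(rows)}")
    d_e = np.asarray([r[0] for r in rows], dtype=float)
    f = np.asarray([r[1] for r in rows], dtype=float)
    if np.any(~np.isfinite(d_e)) or np.any(~np.isfinite(f)):
        raise ValidationError("calibration rows contain non-finite values")
    if np.any(f <= 0):
        raise ValidationError("all conversion factors must be positive")
    if np.any(d_e <= 0):
        raise ValidationError("all d_e values must be positive")
    if len(np.unique(d_e)) != len(d_e):
        raise ValidationError("d_e values must be distinct")
    slope, intercept = np.polyfit(d_e, np.log(f), 1)
    a = float(np.exp(intercept))
    b = float(-slope)
    if b <= 0:
        raise ValidationError("calibration data imply a non-decreasing factor curve")
    resid = float(np.max(np.abs(a * np.exp(-b * d_e) - f)))
    return ConversionModel(a=a, b=b, phantom_diameter=phantom, calibration_residual_max=resid)


def conversion_factor(d_e: float, model: ConversionModel | None = None) -> float:
    """Conversion factor f = a·exp(−b·d_e) for an effective diameter (cm).

    With ``model=None`` the default 32-cm body-phantom model (calibrated to
    the packaged reference table) is used.
    """
    d = _positive(d_e, "d_e")
    m = model if model is not None else default_conversion_model()
    return m.a * math.exp(-m.b * d)


def ssde_from_ctdi(ctdi_vol: float, factor: float) -> float:
    """Size-specific dose estimate (mGy): CTDIvol × conversion factor."""
    c = _positive(ctdi_vol, "ctdi_vol")
    f = _positive(factor, "factor")
    return c * f


def dlp_from_ctdi(ctdi_vol: float, scan_length: float) -> float:
    """Dose-length product (mGy·cm): CTDIvol × irradiated scan length (cm)."""
    c = _positive(ctdi_vol, "ctdi_vol")
    s = _positive(scan_length, "scan_length")
    return c * s


@dataclass(frozen=True)
class DoseRecord:
    """Scanner dose outputs for one exam, plus derived SSDE fields.

    ``ssde`` and ``conversion_factor``, when set, must satisfy
    ssde = ctdi_vol × conversion_factor. Effective dose (mSv) is deliberately
    not modelled — it requires organ-dose software outside this package's
    scope.
    """

    ctdi_vol: float  # mGy
    phantom_diameter: int = 32  # cm
    dlp: float | None = None  # mGy·cm
    conversion_factor: float | None = None
    ssde: float | None = None  # mGy

    def __post_init__(self) -> None:
        _positive(self.ctdi_vol, "ctdi_vol")
        if self.phantom_diameter not in (16, 32):
            raise ValidationError(f"phantom_diameter must be 16 or 32, got {self.phantom_diameter}")
        for name in ("dlp", "conversion_factor", "ssde"):
            v = getattr(self, name)
            if v is not None:
                _positive(v, name)
        if self.ssde is not None and self.conversion_factor is not None:
            expected = self.ctdi_vol * self.conversion_factor
            if abs(self.ssde - expected) > 1e-9 * max(1.0, expected):
                raise ValidationError(
                    f"ssde ({self.ssde}) != ctdi_vol × conversion_factor ({expected})"
                )

    @classmethod
    def from_ctdi(
        cls,
        ctdi_vol: float,
        d_e: float,
        model: ConversionModel | None = None,
        dlp: float | None = None,
    ) -> "DoseRecord":
        """Derive factor and SSDE for a given effective diameter."""
        m = model if model is not None else default_conversion_model()
        f = conversion_factor(d_e, m)
        return cls(
            ctdi_vol=ctdi_vol,
            phantom_diameter=m.phantom_diameter,
            dlp=dlp,
            conversion_factor=f,
            ssde=ssde_from_ctdi(ctdi_vol, f),
        )


@dataclass(frozen=True)
class ConversionTableRow:
    """One presentation-rounded row of a BMI→D_E→factor table."""

    bmi: int  # kg/m²
    d_e: float  # cm, 1 decimal
    factor: float  # dimensionless, 2 decimals


def generate_conversion_table(
    bmi_min: int = 15,
    bmi_max: int = 50,
    step: int = 1,
    line: RegressionLine = DEFAULT_REGRESSION,
    model: ConversionModel | None = None,
) -> list[ConversionTableRow]:
    """Generate a BMI-indexed conversion table.

    For each BMI the effective diameter is computed unrounded from the
    regression, the factor is evaluated at that unrounded d_e, and only then
    are both presentation-rounded (d_e to 1 decimal, factor to 2, half away
    from zero). Rounding the diameter first would propagate up to half a
    millimetre of error into the factor.
    """
    if step < 1:
        raise ValidationError(f"step must be >= 1, got {step}")
    if bmi_min > bmi_max:
        raise ValidationError(f"bmi_min ({bmi_min}) exceeds bmi_max ({bmi_max})")
    if bmi_min <= 0:
        raise ValidationError(f"bmi_min must be positive, got {bmi_min}")
    m = model if model is not None else default_conversion_model()
    rows = []
    for bmi in range(int(bmi_min), int(bmi_max) + 1, int(step)):
        d_e = line.slope * bmi + line.intercept  # unrounded
        f = m.a * math.exp(-m.b * d_e)
        rows.append(
            ConversionTableRow(
                bmi=bmi,
                d_e=round_half_away(d_e, 1),
                factor=round_half_away(f, 2),
            )
        )
    return rows


def load_reference_table() -> list[tuple[int, float, float]]:
    """Load the packaged 32-cm-phantom reference table.

    Returns (bmi, d_e, factor) triples exactly as printed: BMI 15–50 kg/m²,
    d_e to 1 decimal (cm), factor to 2 decimals.
    """
    text = resources.files("bmissde.data").joinpath(_REFERENCE_TABLE_RESOURCE).read_text("utf-8")
    reader = csv.DictReader(text.splitlines())
    return [
        (int(r["bmi"]), float(r["d_e_cm"]), float(r["conversion_factor"]))
        for r in reader
    ]


@lru_cache(maxsize=2)
def default_conversion_model(phantom: int = 32) -> ConversionModel:
    """The shipped conversion model for the given phantom.

    Only the 32-cm body phantom has packaged calibration data; a 16-cm model
    must be fitted from user-supplied (d_e, factor) rows via
    :func:`fit_conversion_model` — coefficients are never fabricated.
    """
    if phantom != 32:
        raise ValidationError(
            "no packaged calibration data for the 16-cm phantom; fit a model "
            "from your own (d_e, factor) rows with fit_conversion_model()"
        )
    rows = [(d_e, f) for _, d_e, f in load_reference_table()]
    return fit_conversion_model(rows, phantom=32)
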