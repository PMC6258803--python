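"""Body-size metrics for CT dosimetry.

Pure scalar computations on patient anthropometrics: body mass index (BMI,
kg/m²) and its WHO weight categories, the effective diameter D_E (cm) as the
geometric mean of the anteroposterior and lateral skin-to-skin diameters
measured on localiser images, the inner effective diameter D_IN (excluding
subcutaneous adipose tissue) and the outer/inner diameter ratio D_RATIO — a
body-fat-distribution metric.

Units are fixed throughout the package: diameters in cm, height in m, weight
in kg, BMI in kg/m². No rounding happens inside these functions;
presentation rounding belongs at I/O boundaries only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ValidationError

__all__ = [
    "PatientSize",
    "DerivedDiameters",
    "compute_bmi",
    "bmi_category",
    "effective_diameter",
    "inner_effective_diameter",
    "diameter_ratio",
    "derive_diameters",
    "BMI_CATEGORIES",
]

#: Half-open BMI bins [lower, upper) in kg/m², lower-inclusive.
BMI_CATEGORIES: tuple[tuple[str, float, float], ...] = (
    ("underweight", 0.0, 18.5),
    ("normal", 18.5, 25.0),
    ("overweight", 25.0, 30.0),
    ("obese", 30.0, math.inf),
)


def _require_positive(value: float, name: str) -> float:
    try:
        v = float(value)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{name} must be a number, got {value!r}") from exc
    if not math.isfinite(v) or v <= 0:
        raise ValidationError(f"{name} must be a positive finite number, got {value!r}")
    return v


def compute_bmi(weight: float, height: float) -> float:
    """Body mass index from weight (kg) and height (m).

    Parameters
    ----------
    weight : float
        Body weight in kilograms, > 0.
    height : float
        Standing height in metres, > 0.

    Returns
    -------
    float
        BMI in kg/m² (weight / height²).
    """
    w = _require_positive(weight, "weight")
    h = _require_positive(height, "height")
    return w / (h * h)


def bmi_category(bmi: float) -> str:
    """WHO weight category for a BMI value (kg/m²).

    Bins are half-open and lower-inclusive: underweight [0, 18.5),
    normal [18.5, 25), overweight [25, 30), obese [30, ∞).
    """
    b = _require_positive(bmi, "bmi")
    for label, lo, hi in BMI_CATEGORIES:
        if lo <= b < hi:
            return label
    raise AssertionError("unreachable: BMI bins cover (0, inf)")  # pragma: no cover


def effective_diameter(d_ap: float, d_lat: float) -> float:
    """Effective diameter D_E (cm): geometric mean of the anteroposterior
    and lateral skin-to-skin diameters.

    D_E is the diameter of the circle whose area equals the patient's
    cross-sectional area at the measurement level, approximated by
    √(D_AP · D_LAT). Symmetric in its arguments.
    """
    a = _require_positive(d_ap, "d_ap")
    b = _require_positive(d_lat, "d_lat")
    return math.sqrt(a * b)


def inner_effective_diameter(d_ap_in: float, d_lat_in: float) -> float:
    """Inner effective diameter D_IN (cm) from the inner diameters measured
    excluding the subcutaneous adipose tissue: √(D_AP(IN) · D_LAT(IN))."""
    a = _require_positive(d_ap_in, "d_ap_in")
    b = _require_positive(d_lat_in, "d_lat_in")
    return math.sqrt(a * b)


def diameter_ratio(d_out: float, d_in: float) -> float:
    """Outer/inner effective-diameter ratio D_RATIO = D_OUT / D_IN (≥ 1).

    The outer envelope contains the inner one, so d_in > d_out is a
    validation error rather than a ratio < 1.
    """
    o = _require_positive(d_out, "d_out")
    i = _require_positive(d_in, "d_in")
    if i > o:
        raise ValidationError(
            f"d_in ({i}) exceeds d_out ({o}): inner envelope cannot exceed outer"
        )
    return o / i


@dataclass(frozen=True)
class PatientSize:
    """Anthropometrics for one patient.

    All fields optional except ``bmi``; if ``height`` and ``weight`` are both
    given, ``bmi`` must agree with weight/height² to 1e-9. Diameters are
    skin-to-skin measurements in cm; the ``*_in`` pair excludes subcutaneous
    fat and must not exceed its outer counterpart.
    """

    bmi: float
    height: float | None = None  # m
    weight: float | None = None  # kg
    d_ap: float | None = None  # cm
    d_lat: float | None = None  # cm
    d_ap_in: float | None = None  # cm
    d_lat_in: float | None = None  # cm

    def __post_init__(self) -> None:
        _require_positive(self.bmi, "bmi")
        for name in ("height", "weight", "d_ap", "d_lat", "d_ap_in", "d_lat_in"):
            v = getattr(self, name)
            if v is not None:
                _require_positive(v, name)
        if self.height is not None and self.weight is not None:
            implied = self.weight / (self.height * self.height)
            if abs(implied - self.bmi) > 1e-9 * max(1.0, abs(self.bmi)):
                raise ValidationError(
                    f"bmi ({self.bmi}) inconsistent with weight/height² ({implied})"
                )
        for inner, outer in (("d_ap_in", "d_ap"), ("d_lat_in", "d_lat")):
            iv, ov = getattr(self, inner), getattr(self, outer)
            if iv is not None and ov is not None and iv > ov:
                raise ValidationError(f"{inner} ({iv}) exceeds {outer} ({ov})")

    @classmethod
    def from_height_weight(cls, height: float, weight: float, **diameters: float) -> "PatientSize":
        """Build from height (m) and weight (kg), computing BMI."""
        return cls(bmi=compute_bmi(weight, height), height=height, weight=weight, **diameters)


@dataclass(frozen=True)
class DerivedDiameters:
    """Diameters derived from a :class:`PatientSize`.

    ``d_e`` is always present; ``d_in`` and ``d_ratio`` only when the inner
    diameters were measured.
    """

    d_e: float
    d_in: float | None = None
    d_ratio: float | None = None

    def __post_init__(self) -> None:
        _require_positive(self.d_e, "d_e")
        if self.d_in is not None:
            _require_positive(self.d_in, "d_in")
        if self.d_ratio is not None and self.d_ratio < 1.0:
            raise ValidationError(f"d_ratio must be >= 1, got {self.d_ratio}")


def derive_diameters(size: PatientSize) -> DerivedDiameters:
    """Compute D_E (and D_IN, D_RATIO when inner diameters are present)
    from measured diameters in a :class:`PatientSize`."""
    if size.d_ap is None or size.d_lat is None:
        raise ValidationError("d_ap and d_lat are required to derive diameters")
    d_e = effective_diameter(size.d_ap, size.d_lat)
    if size.d_ap_in is not None and size.d_lat_in is not None:
        d_in = inner_effective_diameter(size.d_ap_in, size.d_lat_in)
        return DerivedDiameters(d_e=d_e, d_in=d_in, d_ratio=diameter_ratio(d_e, d_in))
    return DerivedDiameters(d_e=d_e)
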