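# Methods

## The problem

The dose a CT scanner reports (CTDI<sub>vol</sub>, in mGy) is a machine
output normalised to an acrylic phantom, not an estimate of patient dose:
for the same scanner output a small patient absorbs more dose than a large
one. The size-specific dose estimate (SSDE) corrects for this by
multiplying CTDI<sub>vol</sub> by a conversion factor *f* that depends on
the patient's effective diameter D<sub>E</sub> — the diameter of the circle
with the same cross-sectional area as the patient at the middle of the scan
range,

D<sub>E</sub> = √(D<sub>AP</sub> · D<sub>LAT</sub>),

the geometric mean of the anteroposterior and lateral skin-to-skin
diameters. Measuring those diameters with electronic callipers on localiser
images is slow and operator-dependent. This package implements the
alternative: estimate D<sub>E</sub> from the body mass index, which is
routinely measured anyway,

D<sub>E</sub> = 0.76 · BMI + 9.4   (cm, BMI in kg/m²),

a regression fitted on an adult abdominal CT cohort (n = 50, BMI
17.4–38.8 kg/m²), then convert

SSDE = f(D<sub>E</sub>) · CTDI<sub>vol</sub>,   f(d) = a · e<sup>−b·d</sup>.

## Calibration of the conversion curve

The coefficients (a, b) are not free parameters of the method; they are
recovered from the packaged 36-row reference table
(`bmissde/data/conversion_table_32cm.csv`, BMI 15–50 kg/m², 32-cm body
phantom, factors printed to 2 decimals) by ordinary least squares of
ln f on d — closed-form, deterministic, and exact for noiseless exponential
data. The fit gives

a = 3.6944, b = 0.036626 per cm, max |residual| = 0.0058

over all 36 rows, and leave-one-out refits predict every held-out factor
within 0.0061. Since the print precision of the table is 0.005, a single
two-parameter exponential explains the entire table to within its own
rounding — this is the package's fidelity standard (±0.01 on factors,
±0.05 cm on diameters). One consequence worth knowing: at BMI 15 the fitted
curve gives f(20.8) = 1.7248, which rounds to 1.72 where the reference
table prints 1.73 — one print unit, inside the ±0.01 standard. The shipped
default model is refitted from the packaged table at import time rather
than stored as magic numbers.

Table generation computes the factor from the *unrounded* regression
diameter and rounds only for presentation (half away from zero, diameters
to 1 decimal, factors to 2): rounding the diameter first would inject up to
0.05 cm ≈ 0.002 of factor error for no benefit. No calibration data exist
for the 16-cm head phantom, so requesting a default 16-cm model is an error;
users must supply their own (d, f) rows.

BMI estimates outside the calibration cohort's range (17.4–38.8 kg/m²) are
flagged as extrapolations and logged, but still returned — the reference
table itself spans BMI 15–50.

## Statistics

Pearson r, OLS, and Welch's two-sample comparison are implemented in their
closed forms; only t-distribution tail probabilities come from scipy.
Two-tailed p-values for r use t = r·√((n−2)/(1−r²)) on n−2 df. Welch's
unequal-variance form is used for BMI-group comparisons because dose
spreads differ several-fold between size strata. No multiple-testing
correction is applied. p-values are stored at full precision; any "0.000"
is a presentation choice, never a stored value.

## The synthetic cohort generator

No per-patient data accompany the method, so validation runs on synthetic
cohorts built to match the published cohort's marginal moments and
correlation structure. Defaults (all overridable in `CohortParams`):

| parameter | default | origin |
|---|---|---|
| BMI mean ± SD | 24.6 ± 4.8 kg/m² on [15, 50] | published cohort moments |
| D_E regression | slope 0.76, intercept 9.4 | published regression |
| D_E noise SD | 1.969 cm | closed form from r(BMI, D_E) = 0.88 |
| aspect split μ | ½·ln(31.5/24.8) | published mean LAT/AP diameters |
| aspect log-SD, coupling | 0.0507, −0.0289 | calibrated to r = (0.78, 0.96, 0.92) |
| D_RATIO mean ± SD | 1.23 ± 0.13, BMI loading r = 0.48 | published ratio moments/correlation |
| CTDI proxy | 5.5 mGy · e^(0.15·(D_E−27.8)), CV 15%, clip [1.8, 30] mGy | tuned to group means 4.33/9.68 mGy |
| scan length | 47.5 ± 3 cm | implied by published DLP/CTDI ratios |

Generation order is fixed (BMI, D_E noise, aspect noise, ratio noise, CTDI
noise, scan length) from a single seeded `numpy.random.Generator`;
identical parameters and seed reproduce a cohort bit-for-bit. Changing `n`
changes all draws.

**Truncated BMI moments.** The published 24.6 ± 4.8 are *observed* cohort
moments, so the generator treats them as the moments of the truncated
distribution it draws from: it solves numerically for the underlying normal
(loc 24.107, scale 5.270) whose truncation to [15, 50] has exactly those
moments. Naively truncating Normal(24.6, 4.8) at −2σ would shrink the
sample SD to ≈ 4.53 and shift the mean to ≈ 24.87, which would also drag
r(BMI, D_E) down to ≈ 0.868; with matched moments the closed-form noise
derivation lands the correlation at 0.880 as intended.

**Diameter noise.** With D_E = slope·BMI + ε, the target correlation
inverts to σ_ε = slope·σ_BMI·√(1/r² − 1) = 1.969 cm for r = 0.88; the
implied marginal D_E SD, √((0.76·4.8)² + 1.969²) = 4.15 cm, is consistent
with the published 27.79 ± 4.12 cm.

**Aspect split.** D_AP = D_E·e^(−s), D_LAT = D_E·e^(s) with
s ~ Normal(μ + c·z, σ_s), z the standardised log D_E. The lognormal split
keeps both diameters positive and D_E = √(D_AP·D_LAT) exact by
construction. The three pairwise correlations among (ln D_AP, ln D_LAT,
ln D_E) are closed-form in (c, σ_s, Var ln D_E); calibration minimises the
summed squared deviation from the targets (0.78, 0.96, 0.92) by a coarse
grid plus Nelder–Mead. Two parameters cannot hit three targets exactly: the
calibrated optimum achieves (0.779, 0.962, 0.921) on the log scale and
about (0.77, 0.96, 0.92) in raw-scale Pearson terms at n = 5000 — residuals
are reported, and any residual above 0.05 raises a calibration error. The
negative coupling reflects that larger patients gain proportionally more
lateral than AP diameter.

**Dose proxy.** CTDI<sub>vol</sub> grows exponentially with D_E — the
standard behaviour of attenuation-driven tube-current modulation — with
multiplicative Gaussian noise and clipping standing in for the scanner's
50–350 mA modulation limits. Only the two BMI-stratified group means
constrain it (no per-patient mA data exist), so it is an emulation held to
±20%, not a calibrated quantity: at the defaults the simulated BMI < 25 and
BMI ≥ 25 group means are ≈ 4.2 and ≈ 10.3 mGy against the published
4.33 and 9.68.

**What the simulator does not emulate.** Sex and age structure (no formula
uses them), the 16-cm phantom pathway, effective dose (requires organ-dose
software), intra-patient diameter asymmetry, and scanner-specific dose
quirks. Passing validation on synthetic cohorts shows the pipeline is
internally consistent and recovers its generating parameters — it cannot
show the BMI regression generalises to other populations or protocols.

## Numerical choices and degenerate inputs

- Presentation rounding is half-away-from-zero on the shortest decimal
  representation, applied only at output; all internal values are unrounded.
- Floors (D_E ≥ 12 cm, D_RATIO ≥ 1.01, scan length ≥ 1 cm) prevent
  physically impossible rows in far tails; the D_E floor sits below any
  plausible adult abdomen.
- Derived cohort columns are recomputed from their stored primitives so
  each row satisfies d_e = √(d_ap·d_lat), d_ratio = d_e/d_in,
  dlp = ctdi·length and ssde = ctdi·f bit-exactly.
- Validation errors name the offending field; constant inputs to
  correlation/regression are rejected rather than returning NaN.
- Problem sizes: simulation-based tests use n = 5000 for correlation checks
  (sampling SE of r ≈ 0.004 at r ≈ 0.88) and n = 100 000 for moment/
  parameter-recovery checks (SE of the slope ≈ 0.002).

## Known limitations

The regression and conversion table were derived on a single scanner,
protocol and adult population; the package reproduces and validates that
method, it does not revalidate it clinically. SSDE itself estimates the
mean dose at the centre of the scan volume with 10–20% stated variability
even when size is measured directly. The ±0.01 factor standard applies to
the 32-cm body phantom table only.
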