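"""Log-linear calibration of the paper-based iron assay.

The assay response (mean inverted-gray pixel intensity, 0-255) is linear in
the base-10 logarithm of iron concentration over the working range:

    intensity = slope * log10(concentration [ug/mL]) + intercept

This module fits that line by ordinary least squares on the per-level mean
intensities, locates the working range (the widest contiguous run of
standard levels with R^2 > 0.95 and positive slope), derives the limit of
detection from blank replicates (blank mean + 3 sigma mapped through the
curve), and inverts the curve to quantify unknown samples, including the
dilution correction from extract (ug/mL) to food (ug/g).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import stats

from .errors import (
    InsufficientDataError,
    InvalidInputError,
    NoWorkingRangeError,
    UnusableCurveError,
)
from .imaging import IntensityMeasurement

#: R^2 rule defining the working range.
WORKING_RANGE_R2 = 0.95
#: Minimum number of contiguous levels that can form a working range.
MIN_RANGE_LEVELS = 3


@dataclass(frozen=True)
class CalibrationStandard:
    """One concentration level with its replicate intensity readings."""

    concentration: float  # ug Fe/mL
    intensities: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise InvalidInputError("standard concentration must be >= 0")
        vals = tuple(float(v) for v in self.intensities)
        if len(vals) < 1:
            raise InvalidInputError("standard needs at least one replicate")
        object.__setattr__(self, "intensities", vals)

    @property
    def mean_intensity(self) -> float:
        return float(np.mean(self.intensities))


@dataclass
class CalibrationCurve:
    """The assay's transfer function and its figures of merit.

    ``slope`` is intensity per decade of concentration; ``intercept`` the
    intensity at 1 ug/mL.  ``range_low``/``range_high`` bound the working
    range in ug/mL; ``lod`` is the limit of detection in ug/mL.  The log
    base and grayscale method are stored so a saved curve fully determines
    a quantification.
    """

    slope: float
    intercept: float
    r_squared: float
    range_low: float | None = None
    range_high: float | None = None
    lod: float | None = None
    log_base: float = 10.0
    grayscale_method: str = "unweighted_mean"

    @property
    def usable(self) -> bool:
        return self.slope > 0

    def predict(self, concentration: float) -> float:
        """Forward model: expected intensity at a concentration (> 0)."""
        if concentration <= 0:
            raise InvalidInputError("concentration must be > 0 for prediction")
        return self.slope * np.emath.logn(self.log_base, concentration) + self.intercept

    def in_range(self, concentration: float) -> bool:
        """True when the concentration lies inside the working range.

        A curve without a determined range accepts everything.
        """
        if self.range_low is None or self.range_high is None:
            return True
        return self.range_low <= concentration <= self.range_high

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationCurve":
        data = json.loads(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in data.items() if k in known})


@dataclass(frozen=True)
class SamplePrep:
    """Sample preparation quantities converting extract to food concentration.

    A mass of food (``sample_mass``, g) is extracted into
    ``extraction_volume`` mL of dilute acid; the extract may be further
    diluted by ``extra_dilution`` before deposition of ``deposition_volume``
    uL onto the paper.  Food iron (ug/g) = extract iron (ug/mL) x
    (extraction_volume / sample_mass) x extra_dilution.
    """

    sample_mass: float = 2.5  # g
    extraction_volume: float = 10.0  # mL
    extra_dilution: float = 1.0
    deposition_volume: float = 5.0  # uL

    def __post_init__(self) -> None:
        for name in ("sample_mass", "extraction_volume", "extra_dilution",
                     "deposition_volume"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be strictly positive")
        if self.extra_dilution < 1:
            raise InvalidInputError("extra_dilution must be >= 1")

    @property
    def dilution_factor(self) -> float:
        """Multiplier from extract ug/mL to food ug/g."""
        return self.extraction_volume / self.sample_mass * self.extra_dilution


@dataclass(frozen=True)
class QuantResult:
    """Quantification of one sample from replicate intensity measurements."""

    extract_concentration: float  # ug Fe/mL, mean over replicates
    food_concentration: float  # ug Fe/g
    replicate_concentrations: tuple[float, ...]
    cv_percent: float
    in_range: bool


def _level_means(standards: list[CalibrationStandard]) -> tuple[np.ndarray, np.ndarray]:
    """Sorted distinct nonzero concentrations and their mean intensities.

    Replicate intensities of duplicate levels are pooled before averaging.
    """
    pooled: dict[float, list[float]] = {}
    for s in standards:
        if s.concentration > 0:
            pooled.setdefault(float(s.concentration), []).extend(s.intensities)
    concs = np.array(sorted(pooled))
    means = np.array([np.mean(pooled[c]) for c in concs])
    return concs, means


def _ols(logc: np.ndarray, means: np.ndarray) -> tuple[float, float, float]:
    """OLS fit of mean intensity on log concentration -> slope, intercept, R^2."""
    res = stats.linregress(logc, means)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def fit_calibration(standards: list[CalibrationStandard]) -> CalibrationCurve:
    """Fit the log10-linear calibration line by ordinary least squares.

    The regression is of per-level mean intensity on log10(concentration).
    Zero-concentration (blank) standards are excluded from the fit -- the
    log is undefined there -- but remain available for the LOD.  At least
    three distinct nonzero levels are required.  A non-positive slope
    yields a curve flagged unusable (with a warning) rather than an error,
    so the caller can inspect it.
    """
    concs, means = _level_means(standards)
    if concs.size < 3:
        raise InsufficientDataError(
            f"need >= 3 distinct nonzero concentration levels, got {concs.size}"
        )
    slope, intercept, r2 = _ols(np.log10(concs), means)
    if slope <= 0:
        warnings.warn(
            f"calibration slope {slope:.4g} is not positive; the curve "
            "cannot be inverted for quantification",
            UserWarning,
            stacklevel=2,
        )
    return CalibrationCurve(slope=slope, intercept=intercept, r_squared=r2)


def determine_working_range(
    standards: list[CalibrationStandard],
    r2_threshold: float = WORKING_RANGE_R2,
) -> tuple[float, float]:
    """Find the working range: linear response against log concentration.

    A contiguous run of >= 3 distinct nonzero levels qualifies when its
    OLS fit of level means on log10(concentration) has R^2 >
    ``r2_threshold`` with positive slope, and the same holds for *every*
    contiguous sub-run of >= 3 levels inside it.  The sub-run condition
    makes the linearity requirement local: a saturated (flat) shoulder at
    the edge of a long run cannot be masked by the high global R^2 its
    many truly linear points produce.  The widest qualifying run (largest
    concentration span) wins; ties break toward more levels, then toward
    the lower starting concentration.  Returns (range_low, range_high) in
    ug/mL.
    """
    concs, means = _level_means(standards)
    if concs.size < MIN_RANGE_LEVELS:
        raise InsufficientDataError(
            f"need >= {MIN_RANGE_LEVELS} distinct nonzero levels, got {concs.size}"
        )
    logc = np.log10(concs)
    n = concs.size
    ok = np.zeros((n, n), dtype=bool)  # ok[i, j]: run i..j fits the rule
    for i in range(n):
        for j in range(i + MIN_RANGE_LEVELS - 1, n):
            slope, _, r2 = _ols(logc[i : j + 1], means[i : j + 1])
            ok[i, j] = slope > 0 and r2 > r2_threshold
    best: tuple[float, int, float] | None = None  # (width, n_levels, -low)
    best_range: tuple[float, float] | None = None
    for i in range(n):
        for j in range(i + MIN_RANGE_LEVELS - 1, n):
            hereditary = all(
                ok[a, b]
                for a in range(i, j - MIN_RANGE_LEVELS + 2)
                for b in range(a + MIN_RANGE_LEVELS - 1, j + 1)
            )
            if hereditary:
                key = (concs[j] - concs[i], j - i + 1, -concs[i])
                if best is None or key > best:
                    best = key
                    best_range = (float(concs[i]), float(concs[j]))
    if best_range is None:
        raise NoWorkingRangeError(
            f"no contiguous run of >= {MIN_RANGE_LEVELS} levels has "
            f"R^2 > {r2_threshold} with positive slope"
        )
    return best_range


def compute_lod(
    blank_intensities: list[float] | np.ndarray, curve: CalibrationCurve
) -> float:
    """Limit of detection from blank replicates: blank mean + 3 sigma.

    The intensity threshold T = mean(blank) + 3 * sd(blank) (sample SD,
    n-1) is mapped through the inverse calibration, LOD =
    10^((T - intercept)/slope), giving the lowest concentration reliably
    distinguishable from the reagent-only background.
    """
    blanks = np.asarray(blank_intensities, dtype=float)
    if blanks.size < 2:
        raise InsufficientDataError("need >= 2 blank replicates for an SD")
    if not curve.usable:
        raise UnusableCurveError("cannot compute LOD with a non-positive slope")
    threshold = float(blanks.mean() + 3.0 * blanks.std(ddof=1))
    return inverse_predict(curve, threshold)


def lod_mass(lod_concentration: float, deposition_volume: float) -> float:
    """Detectable iron mass in the dried spot, in ng (3 significant figures).

    A concentration of c ug/mL deposited as v uL carries c*v ng of iron,
    since 1 ug/mL = 1 ng/uL.
    """
    if lod_concentration <= 0 or deposition_volume <= 0:
        raise InvalidInputError("concentration and volume must be positive")
    mass_ng = lod_concentration * deposition_volume
    return float(np.format_float_positional(
        mass_ng, precision=3, unique=False, fractional=False
    ))


def sensitivity(
    standards: list[CalibrationStandard], working_range: tuple[float, float]
) -> float:
    """Response change per unit concentration across the working range.

    Computed from the observed level means at the two range endpoints:
    (mean(high) - mean(low)) / (high - low), in intensity per (ug/mL).
    """
    lo, hi = working_range
    concs, means = _level_means(standards)
    lookup = dict(zip(concs.tolist(), means.tolist()))
    if lo not in lookup or hi not in lookup:
        raise InvalidInputError(
            "working-range endpoints must be measured standard levels"
        )
    return (lookup[hi] - lookup[lo]) / (hi - lo)


def inverse_predict(curve: CalibrationCurve, intensity: float) -> float:
    """Invert the calibration: intensity -> concentration in ug/mL.

    c = base^((intensity - intercept) / slope).  The caller is responsible
    for checking :meth:`CalibrationCurve.in_range` on the result; values
    outside the working range are extrapolations.
    """
    if not curve.usable:
        raise UnusableCurveError("calibration slope must be positive")
    return float(curve.log_base ** ((intensity - curve.intercept) / curve.slope))


def quantify_sample(
    curve: CalibrationCurve,
    measurements: list[IntensityMeasurement] | list[float],
    prep: SamplePrep,
    average_in: str = "concentration",
) -> QuantResult:
    """Quantify a food sample from replicate spot measurements.

    Each replicate intensity is inverted through the calibration curve;
    replicate concentrations are averaged (in concentration space by
    default, mirroring how the app averages replicate results; pass
    ``average_in='intensity'`` to average the raw intensities first).  The
    mean extract concentration is scaled by the dilution factor
    (extraction_volume / sample_mass x extra_dilution) to ug Fe per g of
    food.  ``cv_percent`` is the replicate CV; ``in_range`` is True only
    when every replicate falls inside the curve's working range.
    """
    if len(measurements) == 0:
        raise InsufficientDataError("need at least one replicate measurement")
    if average_in not in ("concentration", "intensity"):
        raise InvalidInputError("average_in must be 'concentration' or 'intensity'")
    intensities = [
        m.mean_intensity if isinstance(m, IntensityMeasurement) else float(m)
        for m in measurements
    ]
    reps = tuple(inverse_predict(curve, i) for i in intensities)
    if average_in == "concentration":
        extract = float(np.mean(reps))
    else:
        extract = inverse_predict(curve, float(np.mean(intensities)))
    sd = float(np.std(reps, ddof=1)) if len(reps) > 1 else 0.0
    cv = 100.0 * sd / float(np.mean(reps)) if np.mean(reps) != 0 else 0.0
    return QuantResult(
        extract_concentration=extract,
        food_concentration=extract * prep.dilution_factor,
        replicate_concentrations=reps,
        cv_percent=cv,
        in_range=all(curve.in_range(c) for c in reps),
    )
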