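"""Figures of merit and error analysis for the assay.

Implements the standard analytical-validation toolbox used to characterise
the paper-based method: apparent spike recovery, interference bias from
competing minerals, within-day replication (random error, %CV), and
method comparison against a gold-standard instrument (Pearson r, mean-
difference bias, Bland-Altman limits of agreement, paired t-test).

All standard deviations use the sample (n-1) denominator, the spreadsheet
default.  Report tables round to 2 decimals; raw values are retained on
the result objects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, InvalidInputError


@dataclass(frozen=True)
class RecoveryResult:
    """Apparent recovery of a known spike: (spiked - original) / spike."""

    r_a: float
    spike_level: float

    @property
    def percent(self) -> float:
        return 100.0 * self.r_a


@dataclass(frozen=True)
class InterferenceResult:
    """Bias introduced by one interfering mineral.

    ``difference`` = mean with interferent - mean without, in ug Fe/g; a
    positive value means the interferent inflates the apparent iron.
    """

    interferent: str
    amount: float  # ug interferent / g matrix
    mean_with: float
    mean_without: float

    @property
    def difference(self) -> float:
        return self.mean_with - self.mean_without

    @property
    def difference_2dp(self) -> float:
        return round(self.difference, 2)


@dataclass(frozen=True)
class ReplicationResult:
    """Within-day replicate summary; cv_percent is the random error."""

    mean: float
    sd: float
    cv_percent: float
    n: int


@dataclass(frozen=True)
class MethodComparisonResult:
    """Agreement between the test method and a reference method.

    ``bias`` is the mean of (test - reference): the systematic error.
    ``loa_low``/``loa_high`` are the Bland-Altman limits of agreement
    bias -/+ k * sd_diff.  The paired t-test is two-sided.
    """

    pearson_r: float
    bias: float
    sd_diff: float
    loa_k: float
    t_statistic: float
    p_value: float
    n: int

    @property
    def loa_low(self) -> float:
        return self.bias - self.loa_k * self.sd_diff

    @property
    def loa_high(self) -> float:
        return self.bias + self.loa_k * self.sd_diff


def apparent_recovery(
    original_plus_spike: float, original: float, spike: float
) -> RecoveryResult:
    """Fraction of a known spike recovered by the assay.

    R_A = (x(O+S) - x(O)) / x(S), where x(O+S) is the measured output of
    the spiked sample, x(O) of the original sample, and x(S) the known
    spike amount.  1.0 means the full spike was recovered; values above
    1.0 indicate positive proportional bias.
    """
    if spike == 0:
        raise InvalidInputError("spike must be nonzero")
    return RecoveryResult(r_a=(original_plus_spike - original) / spike,
                          spike_level=spike)


def interference_bias(
    with_interferent: list[float] | np.ndarray,
    without_interferent: list[float] | np.ndarray,
    interferent: str = "",
    amount: float = float("nan"),
) -> InterferenceResult:
    """Difference of mean measured iron with vs. without an interferent.

    Both arguments are replicate measurements (ug Fe/g) of the same
    fortified matrix; the difference of their means estimates the
    systematic error attributable to the interfering mineral.
    """
    w = np.asarray(with_interferent, dtype=float)
    wo = np.asarray(without_interferent, dtype=float)
    if w.size == 0 or wo.size == 0:
        raise InsufficientDataError("need >= 1 replicate in each group")
    return InterferenceResult(
        interferent=interferent,
        amount=amount,
        mean_with=float(w.mean()),
        mean_without=float(wo.mean()),
    )


def average_interference(results: list[InterferenceResult]) -> float:
    """Mean interference bias over several minerals, in ug Fe/g."""
    if len(results) == 0:
        raise InsufficientDataError("need >= 1 interference result")
    return float(np.mean([r.difference for r in results]))


def within_day_replication(values: list[float] | np.ndarray) -> ReplicationResult:
    """Random error of the assay: %CV of within-day replicates.

    %CV = (SD / mean) * 100 with the sample (n-1) SD.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise InsufficientDataError("need >= 2 replicates for a CV")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    cv = 100.0 * sd / mean if mean != 0 else float("inf")
    return ReplicationResult(mean=mean, sd=sd, cv_percent=cv, n=int(vals.size))


def method_comparison(
    test_values: list[float] | np.ndarray,
    reference_values: list[float] | np.ndarray,
    loa_k: float = 2.0,
) -> MethodComparisonResult:
    """Compare the assay against a reference method on paired samples.

    Computes the Pearson correlation, the mean-difference bias
    (test - reference) with its SD, Bland-Altman limits of agreement
    bias +/- loa_k * SD (k = 2 by default; 1.96 for the exact normal
    quantile), and a two-sided paired t-test of zero mean difference.
    Mean-difference bias is the appropriate systematic-error summary when
    r < 0.99 (Westgard's rule); regression-based bias is out of scope.
    """
    test = np.asarray(test_values, dtype=float)
    ref = np.asarray(reference_values, dtype=float)
    if test.size != ref.size:
        raise InvalidInputError(
            f"paired vectors must match in length ({test.size} vs {ref.size})"
        )
    if test.size < 3:
        raise InsufficientDataError("need >= 3 pairs")
    if np.ptp(test) == 0 or np.ptp(ref) == 0:
        raise InvalidInputError("zero variance: Pearson correlation undefined")
    diffs = test - ref
    r = float(stats.pearsonr(test, ref).statistic)
    tres = stats.ttest_rel(test, ref)
    return MethodComparisonResult(
        pearson_r=r,
        bias=float(diffs.mean()),
        sd_diff=float(diffs.std(ddof=1)),
        loa_k=float(loa_k),
        t_statistic=float(tres.statistic),
        p_value=float(tres.pvalue),
        n=int(test.size),
    )
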