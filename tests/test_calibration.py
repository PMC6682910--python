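"""Calibration fitting, working range, LOD, inverse prediction, quantification."""

import numpy as np
import pytest

from colorassay import (
    CalibrationCurve,
    CalibrationStandard,
    InsufficientDataError,
    InvalidInputError,
    NoWorkingRangeError,
    SamplePrep,
    UnusableCurveError,
    compute_lod,
    determine_working_range,
    fit_calibration,
    generate_calibration_dataset,
    inverse_predict,
    lod_mass,
    quantify_sample,
    sensitivity,
)
from conftest import REF_INTERCEPT, REF_LEVELS, REF_SLOPE


def line(c, slope=REF_SLOPE, intercept=REF_INTERCEPT):
    return slope * np.log10(c) + intercept


def noiseless_standards(levels=REF_LEVELS, reps=5):
    return [CalibrationStandard(c, (line(c),) * reps) for c in levels]


class TestFitCalibration:
    def test_noiseless_recovery_exact(self):
        curve = fit_calibration(noiseless_standards())
        assert curve.slope == pytest.approx(REF_SLOPE, rel=1e-12)
        assert curve.intercept == pytest.approx(REF_INTERCEPT, rel=1e-12)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_two_levels_insufficient(self):
        with pytest.raises(InsufficientDataError):
            fit_calibration(noiseless_standards(levels=[5.0, 100.0]))

    def test_blanks_excluded_from_fit(self):
        stds = noiseless_standards() + [CalibrationStandard(0.0, (120.0,) * 20)]
        curve = fit_calibration(stds)
        assert curve.slope == pytest.approx(REF_SLOPE, rel=1e-12)

    def test_noisy_fit_matches_closed_form_ols(self):
        """Fit on noisy replicates equals the textbook normal-equation OLS
        computed independently on the same level means."""
        stds = generate_calibration_dataset(
            REF_LEVELS, reps=5, noise_sd=3.0, seed=42
        )
        curve = fit_calibration(stds)
        x = np.log10([s.concentration for s in stds])
        y = np.array([np.mean(s.intensities) for s in stds])
        sxx = np.sum((x - x.mean()) ** 2)
        slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
        intercept = y.mean() - slope * x.mean()
        ss_res = np.sum((y - (slope * x + intercept)) ** 2)
        r2 = 1 - ss_res / np.sum((y - y.mean()) ** 2)
        assert curve.slope == pytest.approx(slope, rel=1e-12)
        assert curve.intercept == pytest.approx(intercept, rel=1e-12)
        assert curve.r_squared == pytest.approx(r2, rel=1e-9)

    def test_negative_slope_warns_and_is_unusable(self):
        stds = [CalibrationStandard(c, (300.0 - line(c),)) for c in REF_LEVELS]
        with pytest.warns(UserWarning, match="not positive"):
            curve = fit_calibration(stds)
        assert not curve.usable
        with pytest.raises(UnusableCurveError):
            inverse_predict(curve, 150.0)

    def test_slope_ci_covers_truth(self):
        """95% CI of the fitted slope covers the generating slope in >= 90%
        of 200 seeded noisy datasets."""
        from scipy import stats as sps

        hits = 0
        for seed in range(200):
            stds = generate_calibration_dataset(
                REF_LEVELS, reps=5, noise_sd=5.0, seed=seed
            )
            x = np.log10([s.concentration for s in stds])
            y = np.array([np.mean(s.intensities) for s in stds])
            res = sps.linregress(x, y)
            tcrit = sps.t.ppf(0.975, len(x) - 2)
            lo, hi = res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr
            hits += lo <= REF_SLOPE <= hi
        assert hits / 200 >= 0.90


class TestWorkingRange:
    def test_flat_below_linear_above(self):
        """Response saturated at the blank level below 5 ug/mL, linear in
        log c above: the R^2 > 0.95 rule recovers (5, 100)."""
        levels = [0.5, 1.0, 2.5] + REF_LEVELS
        stds = generate_calibration_dataset(
            levels, reps=5, noise_sd=0.0, seed=0, flat_below=5.0
        )
        assert determine_working_range(stds) == (5.0, 100.0)

    def test_fully_linear_gives_full_span(self):
        levels = [0.5, 1.0, 2.5] + REF_LEVELS
        stds = generate_calibration_dataset(levels, reps=3, noise_sd=0.0, seed=0)
        assert determine_working_range(stds) == (0.5, 100.0)

    def test_flat_response_has_no_range(self):
        stds = [CalibrationStandard(c, (150.0,) * 3) for c in REF_LEVELS]
        with pytest.raises(NoWorkingRangeError):
            determine_working_range(stds)

    def test_too_few_levels(self):
        with pytest.raises(InsufficientDataError):
            determine_working_range(noiseless_standards(levels=[5.0, 10.0]))


class TestLod:
    def test_constant_blanks_at_intercept(self, reference_curve):
        # sd 0, threshold = intercept -> log c = 0 -> 1 ug/mL
        assert compute_lod([126.18] * 20, reference_curve) == pytest.approx(1.0)

    def test_blank_spread_closed_form(self, reference_curve):
        # two points mean 126.18, sample sd exactly 10
        x = 10 / np.sqrt(2)
        blanks = [126.18 - x, 126.18 + x]
        expected = 10 ** (30.0 / 47.01)
        assert compute_lod(blanks, reference_curve) == pytest.approx(expected, rel=1e-12)

    def test_zero_blanks_zero_intercept(self):
        curve = CalibrationCurve(slope=50.0, intercept=0.0, r_squared=1.0)
        assert compute_lod([0.0, 0.0, 0.0], curve) == pytest.approx(1.0)

    def test_single_blank_insufficient(self, reference_curve):
        with pytest.raises(InsufficientDataError):
            compute_lod([126.18], reference_curve)

    def test_monotone_in_blank_mean_and_sd(self, reference_curve):
        rng = np.random.default_rng(7)
        base = rng.normal(126.18, 4.0, size=20)
        lod0 = compute_lod(base, reference_curve)
        assert compute_lod(base + 5.0, reference_curve) > lod0  # higher mean
        centered = base - base.mean()
        widened = base.mean() + 2.0 * centered  # doubles the sd
        assert compute_lod(widened, reference_curve) > lod0


class TestLodMass:
    @pytest.mark.parametrize(
        "conc, vol, expected",
        [(3.691, 5.0, 18.5), (1.0, 1.0, 1.0), (10.0, 5.0, 50.0)],
    )
    def test_values(self, conc, vol, expected):
        assert lod_mass(conc, vol) == expected

    def test_positive_required(self):
        with pytest.raises(InvalidInputError):
            lod_mass(0.0, 5.0)


class TestSensitivity:
    def test_unit_slope_example(self):
        stds = [
            CalibrationStandard(5.0, (150.0,)),
            CalibrationStandard(50.0, (200.0,)),
            CalibrationStandard(100.0, (245.0,)),
        ]
        assert sensitivity(stds, (5.0, 100.0)) == pytest.approx(1.0)

    def test_flat_response_zero(self):
        stds = [CalibrationStandard(c, (150.0,)) for c in REF_LEVELS]
        assert sensitivity(stds, (5.0, 100.0)) == 0.0

    def test_noiseless_generator_closed_form(self):
        stds = noiseless_standards()
        expected = (line(100.0) - line(5.0)) / 95.0
        assert sensitivity(stds, (5.0, 100.0)) == pytest.approx(expected, rel=1e-12)

    def test_missing_endpoint_errors(self):
        with pytest.raises(InvalidInputError):
            sensitivity(noiseless_standards(), (5.0, 75.0))


class TestInversePredict:
    def test_intensity_at_intercept_is_unity(self, reference_curve):
        assert inverse_predict(reference_curve, REF_INTERCEPT) == pytest.approx(1.0)

    @pytest.mark.parametrize("c", [5.0, 20.0, 100.0])
    def test_round_trip_identity(self, reference_curve, c):
        assert inverse_predict(reference_curve, line(c)) == pytest.approx(c, rel=1e-9)

    def test_closed_form_check(self, reference_curve):
        # 220.20 -> 10^(94.02/47.01) = 100
        assert inverse_predict(reference_curve, 220.20) == pytest.approx(100.0, rel=1e-9)


class TestQuantifySample:
    def test_reference_prep_dilution(self, reference_curve):
        """A 10 ug/mL extract with 2.5 g extracted into 10 mL -> 40 ug/g."""
        prep = SamplePrep(sample_mass=2.5, extraction_volume=10.0)
        res = quantify_sample(reference_curve, [line(10.0)], prep)
        assert res.extract_concentration == pytest.approx(10.0, rel=1e-9)
        assert res.food_concentration == pytest.approx(40.0, rel=1e-9)
        assert res.in_range

    def test_identical_replicates_zero_cv(self, reference_curve):
        res = quantify_sample(reference_curve, [line(20.0)] * 4, SamplePrep())
        assert res.cv_percent == 0.0

    def test_replicate_cv_hand_computed(self, reference_curve):
        """Replicates at 9/10/11 ug/mL extract -> 36/40/44 ug/g food, mean 40,
        CV = sd/mean*100 computed by hand on the concentrations."""
        prep = SamplePrep(sample_mass=2.5, extraction_volume=10.0)
        res = quantify_sample(reference_curve, [line(c) for c in (9, 10, 11)], prep)
        assert res.food_concentration == pytest.approx(40.0, rel=1e-9)
        expected_cv = np.std([9, 10, 11], ddof=1) / 10 * 100
        assert res.cv_percent == pytest.approx(expected_cv, rel=1e-9)

    def test_scales_with_dilution_factors(self, reference_curve):
        base = quantify_sample(
            reference_curve, [line(10.0)], SamplePrep(2.5, 10.0, 1.0)
        ).food_concentration
        doubled_dilution = quantify_sample(
            reference_curve, [line(10.0)], SamplePrep(2.5, 10.0, 2.0)
        ).food_concentration
        doubled_volume = quantify_sample(
            reference_curve, [line(10.0)], SamplePrep(2.5, 20.0, 1.0)
        ).food_concentration
        assert doubled_dilution == pytest.approx(2 * base)
        assert doubled_volume == pytest.approx(2 * base)

    def test_out_of_range_flagged_not_rejected(self, reference_curve):
        res = quantify_sample(reference_curve, [line(200.0)], SamplePrep())
        assert not res.in_range
        assert res.extract_concentration == pytest.approx(200.0, rel=1e-9)

    def test_zero_replicates_error(self, reference_curve):
        with pytest.raises(InsufficientDataError):
            quantify_sample(reference_curve, [], SamplePrep())

    def test_intensity_space_averaging_option(self, reference_curve):
        intensities = [line(5.0), line(50.0)]
        conc_avg = quantify_sample(reference_curve, intensities, SamplePrep())
        int_avg = quantify_sample(
            reference_curve, intensities, SamplePrep(), average_in="intensity"
        )
        # geometric vs arithmetic mean of {5, 50}
        assert int_avg.extract_concentration == pytest.approx(
            np.sqrt(5 * 50), rel=1e-9
        )
        assert conc_avg.extract_concentration == pytest.approx(27.5, rel=1e-9)


class TestCurveSerialization:
    def test_json_round_trip(self, tmp_path, reference_curve):
        reference_curve.lod = 3.691
        p = tmp_path / "curve.json"
        reference_curve.to_json(p)
        loaded = CalibrationCurve.from_json(p)
        assert loaded == reference_curve

    def test_prep_validation(self):
        with pytest.raises(InvalidInputError):
            SamplePrep(sample_mass=0.0)
        with pytest.raises(InvalidInputError):
            SamplePrep(extra_dilution=0.5)
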