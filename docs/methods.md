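# Methods

## The assay model

The Ferrozine reagent forms a magenta Fe(II) complex on a hydrophobic
paper substrate. A 5 µL aliquot of sample extract deposited on the
detection zone develops a spot whose darkness increases with iron. The
photographed spot is reduced to a scalar in three fixed steps: 8-bit
grayscale conversion, inversion (v → 255 − v, so the signal *increases*
with iron), and the mean pixel value inside a circular region of interest
(ROI). That mean inverted-gray intensity I is modelled as linear in the
logarithm of iron concentration c (µg/mL):

    I = a·log10(c) + b

Log-linearization is the standard trick for colorimetric paper assays,
whose raw response saturates; it holds over a finite *working range*
outside which the curve must not be inverted. Quantification is inverse
prediction, c = 10^((I − b)/a), followed by the dilution correction

    food µg Fe/g = extract µg/mL × (extraction volume mL / sample mass g)
                   × extra dilution,

with the reference preparation (2.5 g extracted into 10 mL of 0.25 M HCl)
giving a factor of 4. Replicates are inverted individually and averaged in
concentration space — matching how the companion phone app averages
replicate results; averaging in intensity space (equivalent to a geometric
mean of concentrations) is available as an option.

## Grayscale conversion

Two conversions are provided and recorded on the curve object, because a
curve is only valid for samples measured the same way:

* `unweighted_mean` (default): round((R+G+B)/3) — the plain channel
  average common in scientific image-analysis tools;
* `luma`: round(0.299R + 0.587G + 0.114B) — the Rec. 601 weighting.

Both round half away from zero. Desktop software and phone-camera
pipelines genuinely differ here, and neither variant claims bit-exact
agreement with any particular app. ROI membership is pixel-center within
Euclidean distance ≤ radius, with 0-based row/column coordinates; this
makes measurements bit-exact reproducible. 16-bit inputs are rescaled by
integer division by 257; alpha channels are dropped.

Automatic spot detection (Otsu threshold on the inverted image, largest
connected component, equal-area-circle radius clamped to an expected
range) is a convenience; the reference procedure is manual circle
selection, and callers should fall back to it when detection fails.

## Calibration and figures of merit

**Fit.** Ordinary least squares of per-level *mean* intensity on
log10(c). Blanks (c = 0) are excluded from the fit — their log is
undefined — and feed only the LOD. At least three distinct nonzero levels
are required. Weighted or robust regression is out of scope.

**Working range.** The range rule is "a reliable signal linear against
log concentration with R² > 0.95", evaluated over contiguous standard
levels only. A candidate run qualifies when its OLS fit has R² > 0.95
with positive slope **and the same holds for every contiguous sub-run of
at least three levels inside it**. The sub-run condition makes linearity
a local requirement: without it, a run that drags two or three saturated
sub-range levels along with five exactly-linear ones can keep a global
R² of 0.95–0.97, and the rule would report a range the curve cannot
actually invert at its low end. The widest qualifying run (largest
concentration span) wins; ties break toward more levels, then the lower
starting level. With paper-like noise (intensity SD ≈ 3–5, n = 5) the
3-level sub-fits sit near R² ≈ 0.997, so the local condition does not
spuriously reject real linear ranges.

**Limit of detection.** Blank-based: the intensity threshold is
mean(blank) + 3·SD(blank) (sample SD), mapped through the inverse curve.
The LOD is monotone in both blank mean and blank SD. The detectable mass
in a dried spot is LOD (µg/mL) × deposition volume (µL), in ng (1 µg/mL ≡
1 ng/µL), reported to 3 significant figures.

**Sensitivity.** Δresponse/Δconcentration across the working range,
computed from the *observed* level means at the two endpoints. Note this
intensity-per-(µg/mL) number is small because the response is linear in
log c, not in c; it is reported as defined, with no claim that any
particular published sensitivity value is derivable from a published
curve by this formula.

**Out-of-range samples** are flagged, never rejected: the practical remedy
is re-assaying at a higher initial dilution, which the dilution correction
then absorbs.

## Validation statistics

* Apparent recovery R_A = (x(O+S) − x(O)) / x(S); scale-invariant.
* Interference bias: difference of group means (with − without
  interferent) on the same fortified matrix; the average over minerals
  summarises total interference. Report tables round to 2 decimals.
* Random error: within-day replicate %CV = 100·SD/mean.
* Method comparison: Pearson r, mean-difference bias (test − reference)
  with its SD, Bland–Altman limits of agreement bias ± k·SD (k = 2 by
  default, 1.96 available), and a two-sided paired t-test. Mean-difference
  bias is the appropriate systematic-error summary when r < 0.99
  (Westgard); Deming/Passing–Bablok regression is deliberately out of
  scope.

All SDs use the n−1 denominator throughout.

## Synthetic data generator

The generator exists so every pipeline stage is testable without a real
photograph. It emulates:

* **Spot images**: a disc whose inverted-gray expectation equals the
  transfer function at the scene's true concentration (default curve
  a = 47.01, b = 126.18, the reference assay's), on a bright-paper
  background (inverted-gray 20), with iid Gaussian pixel noise added on
  the inverted-gray field before clipping to [0, 255]. The magenta
  rendering depresses the green channel by d and raises red and blue by
  d/2 (d ≤ 60, clamped to channel bounds and kept even), so R+G+B = 3v
  exactly and the unweighted-mean pipeline reads back the intended gray
  value bit-for-bit. `streaky` heterogeneity multiplies the spot by a
  seeded low-frequency sinusoid (default amplitude 0.15, wavelength one
  spot radius), emulating the uneven color development of capillary
  filter papers as opposed to hydrophobic ones.
* **Calibration tables**: seeded Gaussian replicate intensities around the
  line at each level (default n = 5 per level, matching the reference
  protocol). Levels below `flat_below` saturate at `flat_value`
  (default: the intercept, i.e. a blank that reads like 1 µg/mL — below
  the assay's LOD), which is how the flat sub-range response of the real
  assay enters fixtures.
* **Method-comparison tables**: reference values uniform over 20–80 µg/g
  (the span of fortified-food samples, fortification targets being
  ~20–60 mg Fe/kg) with 4.24% multiplicative reference noise; test =
  reference + Normal(bias, sd_diff), defaults bias = 8.65 µg/g,
  sd_diff = 18.0 µg/g — the error structure observed for the real assay
  against atomic emission spectroscopy.

What the generator does *not* emulate: camera optics, JPEG compression,
illumination gradients, the in-frame reference strip, or any real paper
chemistry. Passing round-trip tests therefore demonstrates the
correctness of the arithmetic pipeline, not field performance of the
physical assay.

## Numerical choices and problem sizes

* Rounding: grayscale conversion rounds half away from zero; report
  tables round to 2 decimals; LOD mass to 3 significant figures; raw
  values are always retained on result objects.
* Monte-Carlo checks (slope bias, bias/SD/CV parameter recovery,
  limits-of-agreement coverage) use 200 seeded replicates of the
  study-sized datasets (n = 35 pairs, n = 9 replicates, 5 levels × 5),
  sizes at which the averaged estimates have standard errors a few
  percent of the generating values — small enough to detect real defects,
  cheap enough to run routinely.
* Degenerate inputs: uniform images fail spot detection (by design);
  identical paired vectors make the paired t statistic undefined (NaN)
  while bias and limits are still reported; a non-positive fitted slope
  yields a usable=false curve that refuses inversion.

## Known limitations

* No color calibration against an in-photo reference strip, and no
  illumination-field or lens-distortion correction: a light-box captures
  is assumed.
* The working-range and LOD rules operate on the printed standard levels;
  interpolating a range boundary between levels is not attempted.
* Single-session curves only: no drift correction across imaging
  sessions.
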