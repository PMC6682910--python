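# File formats

All tabular inputs are plain CSV with a header row; configuration is YAML;
the persisted calibration curve is JSON. Units are fixed: extracts in
µg Fe/mL, foods in µg Fe/g (≡ mg/kg ≡ ppm), intensities on the 0–255
inverted-grayscale scale.

## Standards CSV (`colorassay calibrate`)

One row per replicate, either with intensities measured elsewhere:

```csv
concentration_ug_per_ml,intensity
5.0,159.2
5.0,157.8
10.0,173.5
```

or with image paths (relative to the CSV) and ROIs, measured by the
pipeline at calibration time:

```csv
concentration_ug_per_ml,image,roi
5.0,spot_c5_r0.png,"120,120,48"
```

`roi` is `ROW,COL,RADIUS` in pixels (0-based row/column of the circle
center); omit the column to auto-detect the spot. Rows with
`concentration_ug_per_ml = 0` are blank (reagent-only) replicates: they
are excluded from the regression and used for the limit of detection.

## Calibration curve JSON

```json
{
  "slope": 47.01,
  "intercept": 126.18,
  "r_squared": 0.9932,
  "range_low": 5.0,
  "range_high": 100.0,
  "lod": 3.691,
  "log_base": 10.0,
  "grayscale_method": "unweighted_mean"
}
```

The log base and grayscale method are stored so a saved curve fully
reproduces a quantification.

## Sample-prep YAML (`colorassay quantify --prep`)

```yaml
sample_mass_g: 2.5
extraction_volume_ml: 10
extra_dilution: 1        # optional, >= 1
deposition_volume_ul: 5  # optional
```

## Validation CSVs (`colorassay validate MODE`)

* `recovery` — columns `original_plus_spike, original, spike` (one row per
  spike experiment, all in the same output units).
* `interference` — columns `interferent, amount_ug_per_g,
  measurement_ug_per_g`; baseline (no-interferent) replicates use
  interferent `none`.
* `replication` — column `measurement_ug_per_g`, one row per within-day
  replicate.
* `comparison` — columns `sample_id, paper_ug_per_g, reference_ug_per_g`.

## Simulator manifest (`colorassay simulate`)

`manifest.csv` with columns `image, concentration_ug_per_ml, roi`; it is
itself a valid standards CSV, so simulated images can be fed straight back
into `colorassay calibrate`.
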