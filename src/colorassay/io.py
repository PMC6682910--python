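"""Readers for the documented CSV/YAML interchange formats.

Schemas (see docs/formats.md):

* standards CSV — ``concentration_ug_per_ml, intensity`` with one row per
  replicate, or ``concentration_ug_per_ml, image, roi`` where ``roi`` is
  ``ROW,COL,RADIUS`` and intensities are measured from the image files;
* method-comparison CSV — ``sample_id, paper_ug_per_g, reference_ug_per_g``;
* interference CSV — ``interferent, amount_ug_per_g, measurement_ug_per_g``
  with the baseline replicates under interferent ``none``;
* sample-prep YAML — ``sample_mass_g, extraction_volume_ml, extra_dilution,
  deposition_volume_ul``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .calibration import CalibrationStandard, SamplePrep
from .errors import InvalidInputError
from .imaging import (
    CircularROI,
    GrayscaleMethod,
    RGBImage,
    invert,
    mean_roi_intensity,
    to_grayscale,
)


def _require_columns(df: pd.DataFrame, cols: set[str], what: str) -> None:
    missing = cols - set(df.columns)
    if missing:
        raise InvalidInputError(
            f"{what} is missing required column(s): {', '.join(sorted(missing))}"
        )


def measure_image(
    path: str | Path,
    roi: CircularROI | None = None,
    grayscale_method: GrayscaleMethod = "unweighted_mean",
):
    """Run the full imaging pipeline on one photograph.

    grayscale -> invert -> ROI mean; when ``roi`` is None the spot is
    auto-detected on the inverted image.
    """
    from .imaging import detect_spot

    gray = invert(to_grayscale(RGBImage.from_file(path), grayscale_method))
    if roi is None:
        roi = detect_spot(gray)
    return mean_roi_intensity(gray, roi)


def read_standards_csv(
    path: str | Path,
    grayscale_method: GrayscaleMethod = "unweighted_mean",
) -> list[CalibrationStandard]:
    """Read calibration standards, measuring images when given paths + ROIs."""
    df = pd.read_csv(path)
    _require_columns(df, {"concentration_ug_per_ml"}, "standards CSV")
    if "intensity" in df.columns:
        intensities = df["intensity"].astype(float)
    elif "image" in df.columns:
        base = Path(path).parent
        rois = df["roi"] if "roi" in df.columns else [None] * len(df)
        intensities = pd.Series(
            [
                measure_image(
                    base / img,
                    CircularROI.parse(str(r)) if r is not None else None,
                    grayscale_method,
                ).mean_intensity
                for img, r in zip(df["image"], rois)
            ],
            index=df.index,
        )
    else:
        raise InvalidInputError(
            "standards CSV needs an 'intensity' or an 'image' column"
        )
    grouped = intensities.groupby(df["concentration_ug_per_ml"].astype(float))
    return [
        CalibrationStandard(conc, tuple(vals))
        for conc, vals in sorted(grouped.groups.items(), key=lambda kv: kv[0])
        for vals in [grouped.get_group(conc).tolist()]
    ]


def read_method_comparison_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(
        df, {"paper_ug_per_g", "reference_ug_per_g"}, "method-comparison CSV"
    )
    return df


def read_interference_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(
        df,
        {"interferent", "amount_ug_per_g", "measurement_ug_per_g"},
        "interference CSV",
    )
    if not (df["interferent"].astype(str).str.lower() == "none").any():
        raise InvalidInputError(
            "interference CSV needs a baseline group with interferent 'none'"
        )
    return df


def read_prep_yaml(path: str | Path) -> SamplePrep:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise InvalidInputError("sample-prep YAML must be a mapping")
    try:
        return SamplePrep(
            sample_mass=float(data["sample_mass_g"]),
            extraction_volume=float(data["extraction_volume_ml"]),
            extra_dilution=float(data.get("extra_dilution", 1.0)),
            deposition_volume=float(data.get("deposition_volume_ul", 5.0)),
        )
    except KeyError as exc:
        raise InvalidInputError(f"sample-prep YAML missing key {exc}") from exc
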