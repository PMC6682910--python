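"""Turn an assay photograph into a scalar signal.

The paper-based Ferrozine assay produces a magenta spot whose darkness
increases with iron concentration.  The measurement pipeline is fixed:

1. convert the RGB photograph to 8-bit grayscale,
2. invert it (so more iron -> larger numbers),
3. average the pixel values inside a circular detection zone (ROI).

The mean inverted-gray intensity inside the ROI is the assay's output
signal and the response variable of the calibration curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
from PIL import Image
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .errors import DetectionFailureError, InvalidInputError, NoPixelsError

GrayscaleMethod = Literal["unweighted_mean", "luma"]

#: Rec. 601 luma weights, the classic broadcast-video grayscale.
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (values here are non-negative)."""
    return np.floor(x + 0.5)


@dataclass(frozen=True)
class RGBImage:
    """An 8-bit RGB raster, shape (H, W, 3), values in [0, 255]."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise InvalidInputError(
                f"RGB image must have shape (H, W, 3), got {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise InvalidInputError("image must contain at least one pixel")
        if px.min() < 0 or px.max() > 255:
            raise InvalidInputError("channel values must lie in [0, 255]")
        object.__setattr__(self, "pixels", px.astype(np.uint8, copy=False))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @classmethod
    def from_file(cls, path: str | Path) -> "RGBImage":
        """Read a PNG/JPEG/TIFF photograph.

        Alpha channels are dropped; 16-bit images are rescaled to 8-bit
        (integer division by 257, so 65535 -> 255).
        """
        with Image.open(path) as im:
            arr = np.asarray(im)
        if arr.ndim == 2:  # grayscale file: replicate into three channels
            arr = np.stack([arr] * 3, axis=-1)
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        if arr.dtype == np.uint16 or (
            np.issubdtype(arr.dtype, np.integer) and arr.max() > 255
        ):
            arr = (arr // 257).astype(np.uint8)
        elif np.issubdtype(arr.dtype, np.integer):
            arr = arr.astype(np.uint8)
        else:
            raise InvalidInputError(f"unsupported image dtype {arr.dtype}")
        return cls(arr)


@dataclass(frozen=True)
class GrayImage:
    """An 8-bit grayscale raster with a flag recording whether it is inverted.

    The calibration signal is defined on the *inverted* image (255 - gray),
    so that darker (higher-iron) spots give larger values.
    """

    pixels: np.ndarray
    inverted: bool = False

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise InvalidInputError(f"gray image must be 2-D, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise InvalidInputError("image must contain at least one pixel")
        if px.min() < 0 or px.max() > 255:
            raise InvalidInputError("gray values must lie in [0, 255]")
        object.__setattr__(self, "pixels", px.astype(np.uint8, copy=False))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def save(self, path: str | Path) -> None:
        Image.fromarray(self.pixels, mode="L").save(path)


@dataclass(frozen=True)
class CircularROI:
    """Circular detection zone: 0-based (row, col) center and radius in pixels.

    A pixel belongs to the ROI when its center lies within Euclidean
    distance <= radius of the ROI center.  This membership rule is part of
    the contract so that intensity measurements are bit-exact reproducible.
    """

    center_row: float
    center_col: float
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise InvalidInputError("ROI radius must be > 0")

    def mask(self, height: int, width: int) -> np.ndarray:
        """Boolean membership mask clipped to an image of the given size."""
        rr, cc = np.ogrid[0:height, 0:width]
        d2 = (rr - self.center_row) ** 2 + (cc - self.center_col) ** 2
        return d2 <= self.radius**2

    @classmethod
    def parse(cls, text: str) -> "CircularROI":
        """Parse the CLI form ``ROW,COL,RADIUS``."""
        parts = text.split(",")
        if len(parts) != 3:
            raise InvalidInputError(f"ROI must be ROW,COL,RADIUS, got {text!r}")
        try:
            row, col, radius = (float(p) for p in parts)
        except ValueError as exc:
            raise InvalidInputError(f"non-numeric ROI component in {text!r}") from exc
        return cls(row, col, radius)


@dataclass(frozen=True)
class IntensityMeasurement:
    """Mean and SD of inverted-gray values over an ROI.

    ``mean_intensity`` is the assay output used throughout calibration and
    quantification; ``sd_intensity`` uses the sample (n-1) denominator and
    is 0 for a single pixel.
    """

    mean_intensity: float
    sd_intensity: float
    n_pixels: int


def to_grayscale(
    image: RGBImage, method: GrayscaleMethod = "unweighted_mean"
) -> GrayImage:
    """Convert an RGB photograph to 8-bit grayscale.

    ``unweighted_mean`` (default) is round((R+G+B)/3), the plain channel
    average.  ``luma`` is the Rec. 601 weighting
    round(0.299 R + 0.587 G + 0.114 B).  Both round half away from zero.
    The two conversions differ slightly; the curve used for quantification
    must have been built with the same method as the sample measurements.
    """
    px = image.pixels.astype(np.float64)
    if method == "unweighted_mean":
        gray = _round_half_away(px.sum(axis=2) / 3.0)
    elif method == "luma":
        gray = _round_half_away(px @ _LUMA_WEIGHTS)
    else:
        raise InvalidInputError(f"unknown grayscale method {method!r}")
    return GrayImage(gray.astype(np.uint8), inverted=False)


def invert(image: GrayImage) -> GrayImage:
    """Invert a grayscale image: v -> 255 - v.

    The raw photograph gets *darker* with iron, so the gray values fall;
    inversion makes the signal increase with concentration, which is the
    orientation the calibration curve assumes.  Involution: applying it
    twice returns the original image.
    """
    return GrayImage(255 - image.pixels, inverted=not image.inverted)


def mean_roi_intensity(image: GrayImage, roi: CircularROI) -> IntensityMeasurement:
    """Mean and SD of pixel values inside a circular detection zone.

    The ROI is clipped to the image bounds; membership is pixel-center
    within Euclidean distance <= radius.  Warns when called on a
    non-inverted image, since the calibration signal is defined on the
    inverted scale.
    """
    if not image.inverted:
        warnings.warn(
            "measuring a non-inverted image; the calibration response is "
            "defined on the inverted grayscale",
            UserWarning,
            stacklevel=2,
        )
    mask = roi.mask(image.height, image.width)
    values = image.pixels[mask]
    if values.size == 0:
        raise NoPixelsError("ROI does not cover any image pixel")
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return IntensityMeasurement(mean, sd, int(values.size))


def detect_spot(
    image: GrayImage,
    expected_radius_range: tuple[float, float] = (5.0, 200.0),
    threshold: float | None = None,
) -> CircularROI:
    """Locate the assay spot automatically.

    Convenience fallback for the manual circle selection: thresholds the
    inverted image (Otsu by default), keeps the largest connected bright
    region, and returns the ROI centered on its centroid with the radius of
    the equal-area circle, clamped to ``expected_radius_range``.

    Raises :class:`DetectionFailureError` when no bright region exists
    (e.g. a uniform blank image); callers should then fall back to a
    manually supplied ROI.
    """
    px = image.pixels
    if px.min() == px.max():
        raise DetectionFailureError("image is uniform; no spot to detect")
    thr = float(threshold_otsu(px)) if threshold is None else float(threshold)
    bright = px > thr
    if not bright.any():
        raise DetectionFailureError("no pixels above threshold")
    labels = label(bright)
    regions = regionprops(labels)
    best = max(regions, key=lambda r: r.area)
    row, col = best.centroid
    radius = float(np.sqrt(best.area / np.pi))
    lo, hi = expected_radius_range
    radius = min(max(radius, lo), hi)
    return CircularROI(float(row), float(col), radius)
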