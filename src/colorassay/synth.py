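"""Synthetic fixtures with the statistical structure the assay assumes.

Renders magenta paper-spot images and draws tabular calibration /
method-comparison datasets so that every pipeline stage can be exercised
without a real photograph.  The generating model is the assay's own:
inverted-gray spot intensity = slope * log10(concentration) + intercept
plus iid Gaussian pixel noise, with an optional low-frequency "streaky"
multiplicative field emulating the heterogeneous color development seen on
capillary (non-hydrophobic) papers.

Everything is seeded and bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .calibration import CalibrationStandard
from .errors import InvalidInputError, UnrepresentableSceneError
from .imaging import RGBImage

#: How far the green channel is pushed below the red/blue channels when
#: rendering the magenta spot.  The split keeps (R+G+B)/3 exactly equal to
#: the gray target, so the unweighted-mean pipeline sees the intended
#: intensity bit-for-bit.
MAGENTA_DEPTH = 60


@dataclass(frozen=True)
class SpotScene:
    """Parameters of one synthetic spot photograph.

    ``curve_params`` = (slope, intercept) is the generating transfer
    function on the inverted-gray scale; ``background_intensity`` is the
    inverted-gray value of the bare paper around the spot (small = bright
    white paper); ``noise_sd`` is iid Gaussian pixel noise in intensity
    units; ``heterogeneity='streaky'`` adds a seeded sinusoidal
    multiplicative field inside the spot.
    """

    true_concentration: float  # ug Fe/mL
    curve_params: tuple[float, float] = (47.01, 126.18)
    height: int = 240
    width: int = 240
    spot_center: tuple[float, float] = (120.0, 120.0)
    spot_radius: float = 60.0
    background_intensity: float = 20.0
    noise_sd: float = 0.0
    heterogeneity: Literal["uniform", "streaky"] = "uniform"
    streak_amplitude: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be >= 0")
        if self.true_concentration <= 0:
            raise InvalidInputError("true_concentration must be > 0")
        r, c = self.spot_center
        if not (0 <= r - self.spot_radius and r + self.spot_radius < self.height
                and 0 <= c - self.spot_radius and c + self.spot_radius < self.width):
            raise InvalidInputError("spot must lie fully inside the canvas")

    @property
    def target_intensity(self) -> float:
        """Expected inverted-gray value inside the spot."""
        slope, intercept = self.curve_params
        return slope * np.log10(self.true_concentration) + intercept


def _magenta_from_inverted_gray(inverted: np.ndarray) -> np.ndarray:
    """Map an inverted-gray field to a magenta-tinted RGB image.

    For each pixel with inverted value G (gray value v = 255 - G), the
    channels are chosen so R + G_chan + B = 3v exactly: the green channel
    is depressed by d and red/blue raised by d/2 each, with d limited so
    no channel leaves [0, 255].  The unweighted-mean grayscale of the
    result therefore reproduces v (hence G after inversion) exactly, while
    the pixel looks magenta, like the Fe(II)-Ferrozine complex.
    """
    v = np.rint(np.clip(255.0 - inverted, 0, 255)).astype(np.int64)
    # d even so v +/- d/2 stays integral; bounded by both clip limits
    d = np.minimum(np.minimum(v, 2 * (255 - v)), MAGENTA_DEPTH)
    d -= d % 2
    rgb = np.stack([v + d // 2, v - d, v + d // 2], axis=-1)
    return rgb.astype(np.uint8)


def render_spot(scene: SpotScene) -> RGBImage:
    """Render a magenta assay spot on paper as an 8-bit RGB image.

    The inverted-grayscale expectation inside the spot disc equals the
    scene's transfer function at its true concentration; outside it is the
    background.  Gaussian noise (sd = ``noise_sd``) is added on the
    inverted-gray field before clipping to [0, 255].
    """
    target = scene.target_intensity
    if not (0.0 <= target <= 255.0):
        raise UnrepresentableSceneError(
            f"target intensity {target:.1f} outside [0, 255]; "
            "scene cannot be rendered in 8 bits"
        )
    rng = np.random.default_rng(scene.seed)
    rr, cc = np.ogrid[0 : scene.height, 0 : scene.width]
    row0, col0 = scene.spot_center
    disc = (rr - row0) ** 2 + (cc - col0) ** 2 <= scene.spot_radius**2

    field = np.full((scene.height, scene.width), scene.background_intensity,
                    dtype=float)
    spot = np.full(disc.sum(), float(target))
    if scene.heterogeneity == "streaky":
        # low-frequency multiplicative streaks: capillary flow patterns
        theta = rng.uniform(0, np.pi)
        phase = rng.uniform(0, 2 * np.pi)
        wavelength = scene.spot_radius  # one stripe pair across the spot
        rows, cols = np.nonzero(disc)
        proj = rows * np.cos(theta) + cols * np.sin(theta)
        spot *= 1.0 + scene.streak_amplitude * np.sin(
            2 * np.pi * proj / wavelength + phase
        )
    field[disc] = spot
    if scene.noise_sd > 0:
        field = field + rng.normal(0.0, scene.noise_sd, size=field.shape)
    field = np.clip(field, 0.0, 255.0)
    return RGBImage(_magenta_from_inverted_gray(field))


def generate_calibration_dataset(
    levels: list[float],
    reps: int,
    curve_params: tuple[float, float] = (47.01, 126.18),
    noise_sd: float = 0.0,
    seed: int = 0,
    flat_below: float | None = None,
    flat_value: float | None = None,
) -> list[CalibrationStandard]:
    """Draw replicate intensities for each standard level.

    The generating mean at concentration c > 0 is
    slope * log10(c) + intercept.  With ``flat_below`` set, levels under
    that concentration respond at the constant ``flat_value`` instead,
    emulating the saturation of the assay beneath its working range, where
    spots are indistinguishable from blank; ``flat_value`` defaults to the
    intercept (the blank-like response).  Zero-concentration (blank)
    levels likewise take ``flat_value`` and require it (directly or via
    ``flat_below``).  Gaussian noise with sd ``noise_sd`` is added per
    replicate; draws are seeded.
    """
    if reps < 1:
        raise InvalidInputError("reps must be >= 1")
    slope, intercept = curve_params
    if flat_below is not None and flat_value is None:
        flat_value = intercept
    rng = np.random.default_rng(seed)
    standards = []
    for c in levels:
        if c > 0 and (flat_below is None or c >= flat_below):
            mean = slope * np.log10(c) + intercept
        elif flat_value is not None:
            mean = flat_value
        else:
            raise InvalidInputError(
                "blank (0) levels need flat_value to define their mean"
            )
        draws = mean + rng.normal(0.0, noise_sd, size=reps) if noise_sd > 0 \
            else np.full(reps, float(mean))
        standards.append(CalibrationStandard(float(c), tuple(draws.tolist())))
    return standards


def generate_method_comparison_dataset(
    n: int,
    concentration_range: tuple[float, float] = (20.0, 80.0),
    bias: float = 8.65,
    sd_diff: float = 18.0,
    reference_cv: float = 4.24,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired (test, reference) measurements with a known error structure.

    Reference values are uniform over ``concentration_range`` (ug/g) with
    multiplicative measurement noise at ``reference_cv`` %; test values are
    reference + Normal(bias, sd_diff).  The defaults mirror the error
    structure observed when the paper assay was compared against atomic
    emission spectroscopy.
    """
    if n < 3:
        raise InvalidInputError("need n >= 3 pairs")
    rng = np.random.default_rng(seed)
    lo, hi = concentration_range
    true = rng.uniform(lo, hi, size=n)
    ref = true * (1.0 + rng.normal(0.0, reference_cv / 100.0, size=n))
    test = ref + rng.normal(bias, sd_diff, size=n) if sd_diff > 0 \
        else ref + bias
    return pd.DataFrame(
        {
            "sample_id": [f"S{i+1:03d}" for i in range(n)],
            "paper_ug_per_g": test,
            "reference_ug_per_g": ref,
        }
    )
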