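import numpy as np
import pytest
from hypothesis import settings

from colorassay import CalibrationCurve

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

#: Transfer function of the reference assay: intensity = 47.01*log10(c) + 126.18
REF_SLOPE = 47.01
REF_INTERCEPT = 126.18
REF_LEVELS = [5.0, 10.0, 25.0, 50.0, 100.0]


@pytest.fixture
def reference_curve() -> CalibrationCurve:
    """The assay transfer function with its working range attached."""
    return CalibrationCurve(
        slope=REF_SLOPE,
        intercept=REF_INTERCEPT,
        r_squared=0.9932,
        range_low=5.0,
        range_high=100.0,
    )


def roi_mean_oracle(pixels: np.ndarray, row0: float, col0: float,
                    radius: float):
    """Exhaustive per-pixel ROI membership enumeration.

    Independent of the vectorised implementation: loops over every pixel
    and applies the membership rule (center within Euclidean distance
    <= radius) literally.  Returns (mean, sd_n-1, count) or None when no
    pixel qualifies.
    """
    vals = []
    for r in range(pixels.shape[0]):
        for c in range(pixels.shape[1]):
            if (r - row0) ** 2 + (c - col0) ** 2 <= radius**2:
                vals.append(float(pixels[r, c]))
    if not vals:
        return None
    arr = np.array(vals)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd, len(vals)
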