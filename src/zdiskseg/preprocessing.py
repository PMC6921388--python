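"""Pre-processing: clipped linear contrast stretch followed by Gaussian smoothing.

The contrast stretch maps the 8-bit intensity window ``[min, max]`` onto the
full ``[0, 255]`` range,

    I_out = 255 * (I_in - min) / (max - min),

clipped to ``[0, 255]``.  With ``max`` placed near the average of the
myofibril and Z-disk intensity means, everything at or above the myofibril
regime saturates to white while the dark I-bands land mid-range — the
light-dark transitions that the directional Sobel templates then detect.
The stretch is followed by a Gaussian smoothing pass (sigma = 1.2 px for the
SBF-SEM regime, sigma = 2 px for FIB-SEM).

With fixed bounds the "sliding kernel" formulation of the stretch reduces to
a global pixel-wise rescale, which is what :func:`lcs_stretch` implements; a
true per-window variant (local min/max inside a sliding window) is available
as :func:`lcs_stretch_windowed` for data whose background level drifts.

All intermediate images are kept at float precision; quantization back to
8 bits only happens on file write.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class LCSParams:
    """Clipping bounds of the contrast stretch (8-bit intensity units)."""

    max: float
    min: float = 0.0

    def __post_init__(self) -> None:
        if not self.min < self.max:
            raise ValueError(f"need min < max, got min={self.min}, max={self.max}")


def lcs_stretch(image: np.ndarray, params: LCSParams) -> np.ndarray:
    """Clipped linear contrast stretch of a grayscale slice.

    Pixels at or below ``params.min`` map to 0, pixels at or above
    ``params.max`` saturate to 255, and the window in between is stretched
    linearly.  Returns a float64 image.
    """
    image = np.asarray(image, dtype=np.float64)
    out = 255.0 * (image - params.min) / (params.max - params.min)
    return np.clip(out, 0.0, 255.0)


def lcs_stretch_windowed(image: np.ndarray, window_size: int = 65) -> np.ndarray:
    """Per-window contrast stretch: each pixel is rescaled by the min/max of
    its surrounding ``window_size`` x ``window_size`` neighborhood.

    Degenerate (constant) neighborhoods map to 0.
    """
    if window_size < 3 or window_size % 2 == 0:
        raise ValueError("window_size must be an odd integer >= 3")
    image = np.asarray(image, dtype=np.float64)
    lo = ndimage.minimum_filter(image, size=window_size, mode="nearest")
    hi = ndimage.maximum_filter(image, size=window_size, mode="nearest")
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(span > 0, 255.0 * (image - lo) / span, 0.0)
    return np.clip(out, 0.0, 255.0)


def gaussian_smooth(image: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian smoothing with replicate-padded borders.

    Kernel weights sum to 1 (constant images are fixed points); the kernel is
    truncated at 4 sigma.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    image = np.asarray(image, dtype=np.float64)
    return ndimage.gaussian_filter(image, sigma=sigma, mode="nearest", truncate=4.0)


def preprocess_slice(image: np.ndarray, config) -> np.ndarray:
    """Full pre-processing of one slice: stretch first, then smooth."""
    if config.lcs_windowed:
        stretched = lcs_stretch_windowed(image, config.lcs_window_size)
    else:
        stretched = lcs_stretch(image, LCSParams(max=config.lcs_max, min=config.lcs_min))
    return gaussian_smooth(stretched, config.gaussian_sigma)
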