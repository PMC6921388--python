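"""Z-disk candidate detection with directional Sobel templates.

In the pre-processed slices the Z-disk is a narrow bright vertical line
centered inside a dark I-band.  Its left flank is a dark-to-bright
transition (fires the right-edge template T_RE) and its right flank a
bright-to-dark transition (fires the left-edge template T_LE, named for
the I-band edge it detects).  Because T_LE = -T_RE the two signed
responses are exact negatives, so their positive parts flank a bright
line on opposite sides without ever sharing a pixel.  The intersection
is therefore taken on the structures the edges bound: each binarized
edge mask is extended one pixel toward its bright side (T_RE rightward,
T_LE leftward) and the extended masks are ANDed.  Pixels that survive
are bright-side-adjacent to both a rising and a falling edge — narrow
bright lines.  Wide structures (flanks far apart) and narrow dark bands
(edge order reversed) both drop out.

Templates are applied as printed (correlation, the imfilter convention):
T_RE responds positively exactly on dark-to-bright left-to-right
transitions.  Because T_LE = -T_RE, flipping the kernels would merely
swap the two roles and leave the intersection unchanged.
"""

from __future__ import annotations

from typing import NamedTuple, Optional

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu


class SobelTemplate(NamedTuple):
    name: str
    weights: np.ndarray  # 3x3, integer, zero-sum


_TX = np.array([[-1, 0, 1],
                [-2, 0, 2],
                [-1, 0, 1]], dtype=np.int64)
_TY = np.array([[-1, -2, -1],
                [0, 0, 0],
                [1, 2, 1]], dtype=np.int64)

#: Horizontal-gradient template (columns): fires on dark->bright left->right.
T_X = SobelTemplate("T_x", _TX)
#: Vertical-gradient template (rows): fires on dark(top)->bright(bottom).
T_Y = SobelTemplate("T_y", _TY)
#: Right edge of the I-band (dark I-band -> bright neighbor, going right).
T_RE = SobelTemplate("T_RE", _TX)
#: Left edge of the I-band (bright neighbor -> dark I-band, going right).
T_LE = SobelTemplate("T_LE", -_TX)
#: Lower membrane edge template (dark above -> bright below).
T_LME = SobelTemplate("T_LME", _TY)
#: Upper membrane edge template (bright above -> dark below).
T_UME = SobelTemplate("T_UME", -_TY)

TEMPLATES = {t.name: t for t in (T_X, T_Y, T_RE, T_LE, T_LME, T_UME)}


def convolve_template(image: np.ndarray, template: SobelTemplate) -> np.ndarray:
    """Apply a 3x3 directional template with replicate-padded borders.

    Returns the signed float response; zero everywhere on constant images
    (the templates are zero-sum) and linear in the input.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.shape[0] < 3 or image.shape[1] < 3:
        raise ValueError(f"image must be 2-D and at least 3x3, got shape {image.shape}")
    return ndimage.correlate(image, template.weights.astype(np.float64), mode="nearest")


def binarize_response(resp: np.ndarray, method: str = "otsu",
                      tau: Optional[float] = None) -> np.ndarray:
    """Binarize a signed edge response: foreground = response > threshold > 0.

    ``method="fixed"`` uses the supplied positive ``tau``; ``method="otsu"``
    derives the threshold from the strictly positive response values of the
    slice, so the sign convention of the template decides which transition
    polarity survives.  A response with no positive values yields an empty
    mask.
    """
    resp = np.asarray(resp, dtype=np.float64)
    if method == "fixed":
        if tau is None or tau <= 0:
            raise ValueError("method='fixed' requires tau > 0")
        return resp > tau
    if method != "otsu":
        raise ValueError(f"unknown binarization method {method!r}")
    positive = resp[resp > 0]
    if positive.size == 0:
        return np.zeros(resp.shape, dtype=bool)
    if np.unique(positive).size == 1:
        # Otsu is undefined on a single level; keep the (unique) positives.
        return resp > 0.5 * positive[0]
    thr = threshold_otsu(positive)
    return resp > thr


def _extend_right(mask: np.ndarray) -> np.ndarray:
    out = mask.copy()
    out[:, 1:] |= mask[:, :-1]
    return out


def _extend_left(mask: np.ndarray) -> np.ndarray:
    out = mask.copy()
    out[:, :-1] |= mask[:, 1:]
    return out


def segment_slice(image: np.ndarray, config, report=None) -> np.ndarray:
    """Candidate Z-disk mask of one pre-processed slice.

    Convolves with T_RE and T_LE, binarizes both responses, grants each
    edge one pixel of lateral support toward its bright side and
    intersects; exactly two convolutions and one intersection, tallied
    on ``report`` when given.
    """
    resp_re = convolve_template(image, T_RE)
    resp_le = convolve_template(image, T_LE)
    mask_re = binarize_response(resp_re, config.binarize_method, config.binarize_tau)
    mask_le = binarize_response(resp_le, config.binarize_method, config.binarize_tau)
    candidate = _extend_right(mask_re) & _extend_left(mask_le)
    if report is not None:
        report.directional_convolutions += 2
        report.intersection_ops += 1
    return candidate
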