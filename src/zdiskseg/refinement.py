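"""Refinement: restrict Z-disk candidates to the cell interior.

The intersection mask from the segmentation stage still contains
artifacts: weak edges from organelle boundaries, fixed edge patterns at
the black-background / grey-resin interface, and densely packed response
clusters.  Refinement removes them by

1. detecting the upper and lower cell-membrane edges with the
   vertical-gradient Sobel templates,
2. eroding the binarized membrane-edge images with a 2x2 structuring
   element to drop weak edges,
3. clearing the fixed background-interface patterns,
4. tracing each membrane edge column-by-column with a rule-based
   tracker that bridges short discontinuities horizontally and long
   ones by linear interpolation,
5. keeping only candidate pixels between the traced upper and lower
   membranes, after dense (blob-like) clusters have been subtracted via
   a 5x5 morphological opening,
6. optionally dilating the surviving Z-disk mask (FIB-SEM regime).

Coordinates are 0-based ``(row, column)`` with row 0 at the top.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage.morphology import disk as disk_se

from .segmentation import T_LME, T_UME, binarize_response, convolve_template

logger = logging.getLogger(__name__)

_ONES3 = np.ones((3, 3), dtype=bool)
_ONES5 = np.ones((5, 5), dtype=bool)


class TraceError(RuntimeError):
    """Raised when an edge trace cannot be started (empty edge mask)."""


class GeometryError(ValueError):
    """Raised when band traces or plane volumes are geometrically inconsistent."""


# ---------------------------------------------------------------------------
# membrane responses and artifact removal
# ---------------------------------------------------------------------------

def detect_membrane_responses(image: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Signed responses of the two horizontal membrane templates.

    Returns ``(lme, ume)`` where ``lme`` is positive on dark(top)->bright
    (bottom) transitions — the upper boundary of a bright cell on dark
    surroundings — and ``ume = -lme`` marks the opposite polarity, i.e. the
    lower boundary.
    """
    lme = convolve_template(image, T_LME)
    ume = convolve_template(image, T_UME)
    return lme, ume


def suppress_weak_edges(mask: np.ndarray) -> np.ndarray:
    """Erode a binary edge image with a 2x2 all-ones structuring element.

    A pixel survives iff the 2x2 block anchored at it (SE origin at its
    top-left corner) is entirely foreground, so 1-px-thin weak edges vanish
    while the target membrane edges, several pixels thick, persist.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    padded = np.zeros((h + 1, w + 1), dtype=bool)
    padded[:h, :w] = mask
    return padded[:h, :w] & padded[:h, 1:] & padded[1:, :w] & padded[1:, 1:]


def remove_fixed_patterns(edge_mask: np.ndarray, raw_slice: np.ndarray,
                          background_threshold: float, pad: int = 3) -> np.ndarray:
    """Clear edge pixels on the black-background / grey-resin interface.

    The black background (raw intensity below ``background_threshold``,
    connected components touching the image border) produces strong but
    fixed edge patterns along its boundary.  Those boundary pixels, dilated
    by ``pad`` to cover the smoothed response width, are removed from
    ``edge_mask``.  Result is a subset of the input.
    """
    edge_mask = np.asarray(edge_mask, dtype=bool)
    raw_slice = np.asarray(raw_slice, dtype=np.float64)
    if edge_mask.shape != raw_slice.shape:
        raise ValueError("edge_mask and raw_slice must share a footprint")
    background = raw_slice < background_threshold
    if not background.any():
        return edge_mask.copy()
    labels, n = ndimage.label(background)
    border_labels = np.unique(np.concatenate([
        labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]))
    border_labels = border_labels[border_labels > 0]
    if border_labels.size == 0:
        return edge_mask.copy()
    bg = np.isin(labels, border_labels)
    if bg.all():
        logger.warning("slice is entirely background; no interface to remove")
        return edge_mask.copy()
    # boundary band around the interface, widened to the response width
    grown = ndimage.binary_dilation(bg, structure=_ONES3, iterations=pad)
    shrunk = ndimage.binary_erosion(bg, structure=_ONES3, iterations=pad,
                                    border_value=1)
    return edge_mask & ~(grown & ~shrunk)


def remove_dense_clusters(mask: np.ndarray) -> np.ndarray:
    """Subtract densely packed clusters isolated by a 5x5 erosion-dilation.

    The opening (erode then dilate with a 5x5 all-ones SE) reconstructs only
    structures that contain a 5x5 solid core — the blob-like artifact
    clusters — which are then subtracted, while thin linear structures such
    as Z-disks pass through untouched.
    """
    mask = np.asarray(mask, dtype=bool)
    clusters = ndimage.binary_dilation(
        ndimage.binary_erosion(mask, structure=_ONES5), structure=_ONES5)
    return mask & ~clusters


# ---------------------------------------------------------------------------
# rule-based edge tracing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EdgeTrace:
    """One traced membrane edge: a row coordinate for every column.

    ``rows[j]`` is the traced row at column ``j``; the trace spans the full
    column range of its slice after gap bridging.
    """

    rows: np.ndarray  # int, shape (ncols,)
    role: str  # "upper" or "lower"

    def __post_init__(self) -> None:
        if self.role not in ("upper", "lower"):
            raise ValueError(f"role must be 'upper' or 'lower', got {self.role!r}")

    @property
    def points(self) -> List[Tuple[int, int]]:
        return [(int(r), j) for j, r in enumerate(self.rows)]

    def paint(self, shape: Tuple[int, int]) -> np.ndarray:
        """The trace painted at 255 into a zero raster, for inspection."""
        canvas = np.zeros(shape, dtype=np.uint8)
        cols = np.arange(len(self.rows))
        rows = np.clip(self.rows, 0, shape[0] - 1)
        canvas[rows, cols] = 255
        return canvas


@dataclass(frozen=True)
class BandRegion:
    """The shaded region between an upper and a lower membrane trace."""

    upper: EdgeTrace
    lower: EdgeTrace


def trace_edge(edge_mask: np.ndarray, role: str, config) -> EdgeTrace:
    """Trace one membrane edge through a binary edge image, column by column.

    Starting from the first foreground pixel (scanning columns left to
    right, rows top to bottom — bottom to top for ``role="lower"``), the
    tracker advances one column at a time, re-centering on the first
    (``upper``) or last (``lower``) foreground row inside a vertical window
    of ``2 * track_half_window + 1`` rows.  Where the window is empty it
    looks ahead for the nearest column holding foreground within
    ``track_search_radius`` rows: gaps shorter than ``track_gap_threshold``
    are bridged horizontally at the current row, longer ones by the floor of
    a linear row interpolation between the gap endpoints.  Columns left of
    the seed are backfilled horizontally so the trace covers every column.
    """
    edge_mask = np.asarray(edge_mask, dtype=bool)
    if not edge_mask.any():
        raise TraceError("cannot trace an empty edge mask")
    if role not in ("upper", "lower"):
        raise ValueError(f"role must be 'upper' or 'lower', got {role!r}")

    nrows, ncols = edge_mask.shape
    hw = config.track_half_window
    search_radius = config.track_search_radius
    gap_threshold = config.track_gap_threshold
    pick = (lambda idx: idx[0]) if role == "upper" else (lambda idx: idx[-1])

    # seed: first nonempty column; topmost row for upper, bottommost for lower
    col_any = edge_mask.any(axis=0)
    seed_col = int(np.argmax(col_any))
    seed_row = int(pick(np.flatnonzero(edge_mask[:, seed_col])))

    rows = np.empty(ncols, dtype=np.int64)
    rows[: seed_col + 1] = seed_row  # horizontal backfill left of the seed
    r, j = seed_row, seed_col

    while j < ncols - 1:
        nj = j + 1
        lo, hi = max(0, r - hw), min(nrows, r + hw + 1)
        hits = np.flatnonzero(edge_mask[lo:hi, nj])
        if hits.size:
            r = int(lo + pick(hits))
            rows[nj] = r
            j = nj
            continue
        # discontinuity: search ahead for the next chunk near the current row
        slo, shi = max(0, r - search_radius), min(nrows, r + search_radius + 1)
        ahead = edge_mask[slo:shi, nj:]
        chunk_cols = np.flatnonzero(ahead.any(axis=0))
        if chunk_cols.size == 0:
            rows[nj:] = r  # nothing ahead: continue horizontally to the end
            break
        j_s = nj + int(chunk_cols[0])
        if j_s - j < gap_threshold:
            rows[nj] = r  # horizontal bridge, one column at a time
            j = nj
            continue
        r_s = int(slo + pick(np.flatnonzero(edge_mask[slo:shi, j_s])))
        span = np.arange(nj, j_s + 1)
        rows[span] = np.floor(r + (r_s - r) * (span - j) / (j_s - j)).astype(np.int64)
        r, j = r_s, j_s

    return EdgeTrace(rows=rows, role=role)


def build_band_mask(bands: Sequence[BandRegion],
                    footprint: Tuple[int, int]) -> np.ndarray:
    """Union of the regions enclosed by each band's upper/lower traces.

    Foreground at ``(i, j)`` iff ``upper.rows[j] <= i <= lower.rows[j]`` for
    some band.  Traces must span the full column range and never cross.
    """
    nrows, ncols = footprint
    mask = np.zeros(footprint, dtype=bool)
    row_idx = np.arange(nrows)[:, None]
    for band in bands:
        upper, lower = band.upper.rows, band.lower.rows
        if len(upper) != ncols or len(lower) != ncols:
            raise GeometryError("band traces must span the full column range")
        if np.any(upper > lower):
            bad = int(np.flatnonzero(upper > lower)[0])
            raise GeometryError(
                f"upper trace below lower trace at column {bad} "
                f"({int(upper[bad])} > {int(lower[bad])})")
        mask |= (row_idx >= upper[None, :]) & (row_idx <= lower[None, :])
    return mask


# ---------------------------------------------------------------------------
# mask post-processing and slice-level driver
# ---------------------------------------------------------------------------

def _parse_se(descriptor: str) -> np.ndarray:
    kind, _, arg = descriptor.partition(":")
    try:
        size = int(arg)
    except ValueError:
        raise ValueError(f"bad structuring element descriptor {descriptor!r}")
    if kind == "disk":
        return disk_se(size).astype(bool)
    if kind == "square":
        return np.ones((size, size), dtype=bool)
    raise ValueError(f"unknown structuring element kind {kind!r}")


def dilate_zdisks(mask: np.ndarray, se: str = "disk:1") -> np.ndarray:
    """Morphological dilation of the final Z-disk mask (input is a subset of
    the output).  ``se`` is a descriptor such as ``"disk:1"`` (3x3 cross)."""
    mask = np.asarray(mask, dtype=bool)
    return ndimage.binary_dilation(mask, structure=_parse_se(se))


def refine_slice(candidate: np.ndarray, preprocessed: np.ndarray,
                 raw: np.ndarray, config, return_detail: bool = False):
    """Full refinement of one slice's candidate mask.

    Order: membrane responses -> binarize -> 2x2 erosion -> fixed-pattern
    removal -> trace upper/lower edges -> band mask; the candidate (after
    dense-cluster subtraction) is intersected with the band.  Optional
    dilation is applied last and clipped back to the band so no foreground
    ever leaves the membrane-bounded region.

    If either membrane is untraceable the band falls back to the whole
    slice with a logged warning.  With ``return_detail`` the band mask and
    traces are returned alongside the refined mask.
    """
    candidate = np.asarray(candidate, dtype=bool)
    if candidate.shape != preprocessed.shape or candidate.shape != raw.shape:
        raise ValueError("candidate, preprocessed and raw must share a footprint")

    lme_resp, ume_resp = detect_membrane_responses(preprocessed)
    traces: Tuple[Optional[EdgeTrace], Optional[EdgeTrace]] = (None, None)
    band = None
    try:
        upper_mask = _membrane_edge_mask(lme_resp, raw, config)
        lower_mask = _membrane_edge_mask(ume_resp, raw, config)
        upper = trace_edge(upper_mask, "upper", config)
        lower = trace_edge(lower_mask, "lower", config)
        band = build_band_mask([BandRegion(upper, lower)], candidate.shape)
        traces = (upper, lower)
    except (TraceError, GeometryError) as exc:
        logger.warning("membranes untraceable (%s); falling back to full-slice band",
                       exc)
        band = np.ones(candidate.shape, dtype=bool)

    refined = remove_dense_clusters(candidate) & band
    if config.dilate_zdisks:
        refined = dilate_zdisks(refined, config.dilate_se) & band
    if return_detail:
        return refined, band, traces
    return refined


def _membrane_edge_mask(resp: np.ndarray, raw: np.ndarray, config) -> np.ndarray:
    mask = binarize_response(resp, config.binarize_method, config.binarize_tau)
    mask = suppress_weak_edges(mask)
    return remove_fixed_patterns(mask, raw, config.background_threshold)


# ---------------------------------------------------------------------------
# orthogonal-plane fusion
# ---------------------------------------------------------------------------

def fuse_orthogonal(masks_xy: np.ndarray, masks_xz: np.ndarray,
                    masks_yz: np.ndarray, mode: str = "union") -> np.ndarray:
    """Combine per-plane mask volumes voxel-wise after re-alignment.

    Volumes are passed as produced by slicing the canonical ``(z, y, x)``
    volume along each axis: ``masks_xy`` with axes ``(z, y, x)``,
    ``masks_xz`` with axes ``(y, z, x)`` and ``masks_yz`` with axes
    ``(x, z, y)``.  ``mode`` is ``"union"`` or ``"intersection"``.
    """
    a = np.asarray(masks_xy, dtype=bool)
    b = np.moveaxis(np.asarray(masks_xz, dtype=bool), 0, 1)
    c = np.moveaxis(np.asarray(masks_yz, dtype=bool), 0, 2)
    if not (a.shape == b.shape == c.shape):
        raise GeometryError(
            f"plane volumes disagree after transposition: "
            f"{a.shape}, {b.shape}, {c.shape}")
    if mode == "union":
        return a | b | c
    if mode == "intersection":
        return a & b & c
    raise ValueError(f"unknown fusion mode {mode!r}")
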