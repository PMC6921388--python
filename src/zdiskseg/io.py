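"""Reading and writing multi-page TIFF image stacks and mask stacks.

Serial-section stacks travel as multi-page grayscale TIFFs, one page per
section, page order = slice order.  Intensities are handled at 8-bit scale
internally; 16-bit input is linearly min-max rescaled to [0, 255] on read.
Binary masks are stored with foreground = 255, background = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import tifffile


class StackFormatError(ValueError):
    """Raised for TIFFs the pipeline cannot consume (color, ragged pages...)."""


@dataclass(frozen=True)
class ImageStack:
    """An ordered stack of equally sized grayscale sections.

    ``data`` has axes ``(slice, row, column)`` with intensities in [0, 255].
    """

    data: np.ndarray
    voxel_size_nm: Optional[Tuple[float, float, float]] = None
    axis_labels: Tuple[str, str, str] = ("slice", "row", "column")

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError(f"stack data must be 3-D, got shape {self.data.shape}")
        if self.data.size and (self.data.min() < 0 or self.data.max() > 255):
            raise ValueError("stack intensities must lie in [0, 255]")
        if self.voxel_size_nm is not None and any(v <= 0 for v in self.voxel_size_nm):
            raise ValueError("voxel sizes must be positive")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def slice_shape(self) -> Tuple[int, int]:
        return self.data.shape[1:]

    def __iter__(self):
        return iter(self.data)


def _rescale_to_8bit(pages: np.ndarray) -> np.ndarray:
    pages = np.asarray(pages)
    if pages.dtype == np.uint8:
        return pages.astype(np.float64)
    data = pages.astype(np.float64)
    lo, hi = data.min(), data.max()
    if hi == lo:
        return np.zeros_like(data)
    return 255.0 * (data - lo) / (hi - lo)


def read_stack(path, format: str = "tiff",
               voxel_size_nm: Optional[Tuple[float, float, float]] = None
               ) -> ImageStack:
    """Read a multi-page grayscale TIFF into an ImageStack.

    Pages must share a footprint and be single-channel; 16-bit data is
    min-max rescaled to the 8-bit range.
    """
    if format != "tiff":
        raise ValueError(f"unsupported format {format!r}; only 'tiff' is accepted")
    try:
        with tifffile.TiffFile(path) as tif:
            pages = [page.asarray() for page in tif.pages]
    except (OSError, tifffile.TiffFileError) as exc:
        raise OSError(f"cannot read TIFF stack {path}: {exc}") from exc
    if not pages:
        raise StackFormatError(f"{path} contains no pages")
    shapes = {page.shape for page in pages}
    if any(page.ndim != 2 for page in pages):
        raise StackFormatError(
            f"{path} is not single-channel grayscale (page shapes {sorted(shapes)})")
    if len(shapes) != 1:
        raise StackFormatError(f"{path} has inconsistent page sizes {sorted(shapes)}")
    data = _rescale_to_8bit(np.stack(pages))
    return ImageStack(data=data, voxel_size_nm=voxel_size_nm)


def write_stack(stack: ImageStack, path) -> str:
    """Write an ImageStack as an 8-bit multi-page TIFF (values rounded)."""
    data = np.clip(np.round(stack.data), 0, 255).astype(np.uint8)
    tifffile.imwrite(path, data, photometric="minisblack")
    return str(path)


def write_mask_stack(masks: Sequence[np.ndarray], path) -> str:
    """Write binary masks as a multi-page TIFF, foreground 255 / background 0."""
    if len(masks) == 0:
        raise ValueError("mask list is empty")
    shapes = {np.asarray(m).shape for m in masks}
    if len(shapes) != 1:
        raise ValueError(f"masks have mixed sizes: {sorted(shapes)}")
    pages = np.stack([np.where(np.asarray(m) != 0, 255, 0).astype(np.uint8)
                      for m in masks])
    tifffile.imwrite(path, pages, photometric="minisblack")
    return str(path)


def read_mask_stack(path) -> List[np.ndarray]:
    """Read a 0/255 mask TIFF back into a list of boolean masks."""
    stack = read_stack(path)
    return [page > 0 for page in stack.data]
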