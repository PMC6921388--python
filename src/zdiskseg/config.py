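"""Pipeline configuration and the two published parameter presets.

The segmentation scheme has two printed parameterizations: one for the
SBF-SEM regime (50 nm voxels, Z-disks 1-2 px wide) and one for the
finer FIB-SEM regime (Z-disks 5-7 px wide).  Everything else — the
rule-base constants of the edge tracker, the background threshold used
to locate the black/resin interface, the binarization method for the
Sobel responses — is shared between the two.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional


class ConfigError(ValueError):
    """Raised when a PipelineConfig violates its invariants."""


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable parameters of the Z-disk segmentation pipeline.

    Parameters
    ----------
    lcs_max, lcs_min : float
        Clipping bounds of the linear contrast stretch, in 8-bit
        intensity units.  ``lcs_max`` is chosen near the average of the
        myofibril and Z-disk intensity means so that the stretch
        separates the dark I-bands from everything brighter.
    gaussian_sigma : float
        Standard deviation (pixels) of the smoothing kernel applied
        after the contrast stretch.
    binarize_method : {"otsu", "fixed"}
        How the signed Sobel responses are turned into binary masks.
        ``"otsu"`` thresholds the strictly positive response values of
        each slice; ``"fixed"`` uses ``binarize_tau``.
    binarize_tau : float, optional
        Fixed positive threshold, required when ``binarize_method`` is
        ``"fixed"``.
    track_half_window : int
        Half-height of the column vector the edge tracker scans at the
        next column (window height ``2 * half_window + 1``).
    track_search_radius : int
        Row radius searched ahead for the next edge chunk when the
        tracker hits a discontinuity.
    track_gap_threshold : int
        Column gaps shorter than this are bridged horizontally; longer
        gaps are closed by linear interpolation.
    dilate_zdisks : bool
        Whether the final mask is dilated (the FIB-SEM regime benefits
        because Z-disks there are wider than the response overlap).
    dilate_se : str
        Structuring element descriptor, ``"disk:R"`` or ``"square:N"``.
    plane_fusion : {"xy_only", "union", "intersection"}
        How per-plane volumes are combined when the pipeline is also
        run on the orthogonal planes.
    background_threshold : float
        Raw intensity below which a border-connected region counts as
        black background for fixed-pattern removal.
    lcs_windowed : bool
        Use the per-window (sliding min/max) variant of the contrast
        stretch instead of the global clipped rescale.
    lcs_window_size : int
        Window size of the windowed variant.
    seed : int
        Recorded for provenance; the pipeline itself is deterministic.
    """

    lcs_max: float = 59.0
    lcs_min: float = 0.0
    gaussian_sigma: float = 1.2
    binarize_method: str = "otsu"
    binarize_tau: Optional[float] = None
    track_half_window: int = 10
    track_search_radius: int = 20
    track_gap_threshold: int = 10
    dilate_zdisks: bool = False
    dilate_se: str = "disk:1"
    plane_fusion: str = "xy_only"
    background_threshold: float = 10.0
    lcs_windowed: bool = False
    lcs_window_size: int = 65
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.lcs_min < self.lcs_max <= 255:
            raise ConfigError(
                f"need lcs_min < lcs_max <= 255, got ({self.lcs_min}, {self.lcs_max})"
            )
        if self.gaussian_sigma <= 0:
            raise ConfigError("gaussian_sigma must be > 0")
        for name in ("track_half_window", "track_search_radius", "track_gap_threshold"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.binarize_method not in ("otsu", "fixed"):
            raise ConfigError(f"unknown binarize_method {self.binarize_method!r}")
        if self.binarize_method == "fixed":
            if self.binarize_tau is None or self.binarize_tau <= 0:
                raise ConfigError("binarize_method='fixed' requires binarize_tau > 0")
        if self.plane_fusion not in ("xy_only", "union", "intersection"):
            raise ConfigError(f"unknown plane_fusion {self.plane_fusion!r}")

    def replace(self, **changes) -> "PipelineConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, mapping: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)


def sbfsem_preset(**overrides) -> PipelineConfig:
    """The SBF-SEM parameterization: max=59, min=0, sigma=1.2, no dilation."""
    cfg = PipelineConfig(lcs_max=59.0, lcs_min=0.0, gaussian_sigma=1.2,
                         dilate_zdisks=False)
    return cfg.replace(**overrides) if overrides else cfg


def fibsem_preset(**overrides) -> PipelineConfig:
    """The FIB-SEM parameterization: max=160, min=0, sigma=2, disk dilation."""
    cfg = PipelineConfig(lcs_max=160.0, lcs_min=0.0, gaussian_sigma=2.0,
                         dilate_zdisks=True, dilate_se="disk:1")
    return cfg.replace(**overrides) if overrides else cfg


PRESETS = {"sbfsem": sbfsem_preset, "fibsem": fibsem_preset}
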