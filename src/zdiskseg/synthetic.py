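"""Seeded synthetic EM-like fixtures with known Z-disk / band / membrane truth.

The generator emulates the geometry the segmentation pipeline relies on: a
longitudinal cardiomyocyte section whose sarcomeres repeat along the column
axis as vertical stripes ``[myofibril | I-band | Z-disk | I-band]``, bounded
above and below by smooth curved membrane edges, with grey embedding resin
and a black background outside the cell.  Intensities are drawn per class
from normal distributions clipped to [0, 255]; the four classes the source
dataset quantifies use its printed statistics (nuclei 71.17 +- 12.53,
myofibrils 55.57 +- 6.19, I-bands 24.87 +- 8.25, Z-disks 63.57 +- 11.07).

Densely textured artifact blobs can be planted inside the cell to exercise
the refinement stage's cluster removal; their pixels are excluded from the
Z-disk truth.  Everything is deterministic given the model seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .refinement import EdgeTrace

#: Intensity statistics of the SBF-SEM dataset (mean, sd per class).
#: background / embedding / mitochondrion are fixture conventions (the source
#: data quantify only the other four classes).  The embedding mean sits between
#: background and I-band so the membrane transition keeps one sign along the cell.
SBFSEM_CLASS_STATS: Dict[str, Tuple[float, float]] = {
    "background": (3.0, 1.5),
    "embedding": (16.0, 3.0),
    "myofibril": (55.57, 6.19),
    "iband": (24.87, 8.25),
    "zdisk": (63.57, 11.07),
    "nucleus": (71.17, 12.53),
    "mitochondrion": (40.0, 8.0),
}

#: FIB-SEM regime conventions (no per-class statistics are printed for that
#: dataset); myofibril/Z-disk means average to 160.32, the value that
#: motivates the regime's contrast-stretch bound max = 160.
FIBSEM_CLASS_STATS: Dict[str, Tuple[float, float]] = {
    "background": (3.0, 1.5),
    "embedding": (40.0, 6.0),
    "myofibril": (152.64, 8.0),
    "iband": (60.0, 10.0),
    "zdisk": (168.00, 10.0),
    "nucleus": (180.0, 12.0),
    "mitochondrion": (100.0, 10.0),
}


@dataclass(frozen=True)
class TissueModel:
    """Parameters of one synthetic striated-muscle slice family.

    ``sarcomere_period`` is the stripe repeat length in pixels; one period is
    ``[myofibril | I-band | Z-disk | I-band]`` so the myofibril width is
    ``period - 2 * iband_width - zdisk_width``.  Membranes are sinusoidal row
    curves a ``membrane_margin`` inside the slice; a ``grey_margin``-thick
    embedding band separates them from the black background.
    """

    slice_shape: Tuple[int, int] = (180, 400)
    sarcomere_period: int = 41
    zdisk_width: int = 1
    iband_width: int = 5
    class_stats: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(SBFSEM_CLASS_STATS))
    membrane_margin: int = 30
    membrane_amplitude: float = 6.0
    membrane_wavelength: float = 220.0
    grey_margin: int = 12
    n_cells: int = 1
    n_artifacts: int = 2
    artifact_size: int = 12
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.zdisk_width < self.iband_width < self.sarcomere_period:
            raise ValueError(
                "need zdisk_width < iband_width < sarcomere_period, got "
                f"{self.zdisk_width}, {self.iband_width}, {self.sarcomere_period}")
        if self.myofibril_width <= 0:
            raise ValueError("sarcomere_period leaves no room for the myofibril")
        for name, (mean, sd) in self.class_stats.items():
            if not 0 <= mean <= 255:
                raise ValueError(f"class {name!r} mean {mean} outside [0, 255]")
            if sd < 0:
                raise ValueError(f"class {name!r} has negative sd")
        if self.n_cells != 1:
            raise NotImplementedError("only single-cell geometry is generated")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    @property
    def myofibril_width(self) -> int:
        return self.sarcomere_period - 2 * self.iband_width - self.zdisk_width


@dataclass(frozen=True)
class Fixture:
    """A synthetic slice or stack with exact ground truth.

    For stacks every array gains a leading slice axis and the membrane
    traces become per-slice lists.
    """

    image: np.ndarray
    zdisk_truth: np.ndarray
    band_truth: np.ndarray
    membranes: object  # (upper, lower) EdgeTrace pair, or list of pairs
    artifact_mask: np.ndarray
    class_map: np.ndarray  # codes: 0 bg, 1 embedding, 2 myofibril, 3 iband, 4 zdisk, 5 artifact
    model: TissueModel


def _column_classes(model: TissueModel, phase: int) -> Tuple[np.ndarray, np.ndarray]:
    """Per-column class codes (0 myofibril, 1 iband, 2 zdisk) and the
    boolean z-disk column indicator."""
    ncols = model.slice_shape[1]
    pos = (np.arange(ncols) + phase) % model.sarcomere_period
    wm, wi, wz = model.myofibril_width, model.iband_width, model.zdisk_width
    codes = np.full(ncols, 1, dtype=np.int8)  # default: iband
    codes[pos < wm] = 0
    codes[(pos >= wm + wi) & (pos < wm + wi + wz)] = 2
    return codes, codes == 2


def _membrane_curves(model: TissueModel, rng: np.random.Generator,
                     upper_offset: int = 0, lower_offset: int = 0
                     ) -> Tuple[np.ndarray, np.ndarray]:
    nrows, ncols = model.slice_shape
    x = np.arange(ncols)
    phase_u, phase_l = rng.uniform(0, 2 * np.pi, size=2)
    wave = 2 * np.pi / model.membrane_wavelength
    upper = (model.membrane_margin + upper_offset
             + model.membrane_amplitude * np.sin(wave * x + phase_u))
    lower = (nrows - 1 - model.membrane_margin + lower_offset
             + model.membrane_amplitude * np.sin(wave * x + phase_l))
    upper = np.clip(np.round(upper), 1, nrows - 3).astype(np.int64)
    lower = np.clip(np.round(lower), 1, nrows - 2).astype(np.int64)
    lower = np.maximum(lower, upper + 1)
    return upper, lower


def _sample_intensities(class_map: np.ndarray, stats: Dict[str, Tuple[float, float]],
                        class_names: List[str], noise_sd: float,
                        rng: np.random.Generator) -> np.ndarray:
    image = np.zeros(class_map.shape, dtype=np.float64)
    for code, name in enumerate(class_names):
        sel = class_map == code
        if not sel.any():
            continue
        mean, sd = stats[name]
        image[sel] = rng.normal(mean, sd, size=int(sel.sum())) if sd > 0 else mean
    if noise_sd > 0:
        image += rng.normal(0.0, noise_sd, size=image.shape)
    return np.clip(image, 0.0, 255.0)


_CLASS_NAMES = ["background", "embedding", "myofibril", "iband", "zdisk"]
_ARTIFACT_CODE = 5  # textured blob; intensities sampled separately


def _paint_slice(model: TissueModel, rng: np.random.Generator,
                 phase: int, upper: np.ndarray, lower: np.ndarray
                 ) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    nrows, ncols = model.slice_shape
    codes, zdisk_cols = _column_classes(model, phase)
    rows = np.arange(nrows)[:, None]

    band = (rows >= upper[None, :]) & (rows <= lower[None, :])
    grey = ((rows >= upper[None, :] - model.grey_margin)
            & (rows <= lower[None, :] + model.grey_margin) & ~band)

    class_map = np.zeros((nrows, ncols), dtype=np.int8)  # background
    class_map[grey] = 1
    stripe_codes = np.array([2, 3, 4], dtype=np.int8)[codes]  # myo/iband/zdisk
    class_map[band] = np.broadcast_to(stripe_codes[None, :], (nrows, ncols))[band]

    # textured artifact blobs strictly inside the band
    artifact = np.zeros((nrows, ncols), dtype=bool)
    size = model.artifact_size
    for _ in range(model.n_artifacts):
        top_min = int(upper.max()) + 3
        top_max = int(lower.min()) - 3 - size
        if top_max <= top_min or size >= ncols - 8:
            break
        r0 = int(rng.integers(top_min, top_max + 1))
        c0 = int(rng.integers(4, ncols - 4 - size))
        artifact[r0:r0 + size, c0:c0 + size] = True
    class_map[artifact] = _ARTIFACT_CODE

    # bright line artifacts in the embedding (dirt/knife marks outside the
    # cell) — candidate lookalikes that only the membrane band can reject
    outside = np.zeros((nrows, ncols), dtype=bool)
    mu_z, sd_z = model.class_stats["zdisk"]
    for k in range(model.n_artifacts):
        c = int(rng.integers(6, ncols - 6))
        width = int(rng.integers(1, 3))
        if k % 2 == 0:
            r1 = int(upper[c]) - 3
            r0 = max(int(upper[c]) - model.grey_margin + 2, r1 - 6)
        else:
            r0 = int(lower[c]) + 3
            r1 = min(int(lower[c]) + model.grey_margin - 2, r0 + 6)
        if r1 > r0:
            outside[r0:r1, c:c + width] = True
    outside &= grey
    class_map[outside] = _ARTIFACT_CODE
    artifact = artifact | outside

    image = _sample_intensities(np.where(class_map == _ARTIFACT_CODE, 0, class_map),
                                model.class_stats, _CLASS_NAMES,
                                model.noise_sd, rng)
    if artifact.any():
        tex = _artifact_texture(artifact, model, rng)
        image[artifact] = tex[artifact]
        image[outside] = np.clip(
            rng.normal(mu_z, sd_z, size=int(outside.sum())), 0.0, 255.0)

    zdisk_truth = band & zdisk_cols[None, :] & ~artifact
    return image, zdisk_truth, band, artifact, class_map


def _artifact_texture(artifact: np.ndarray, model: TissueModel,
                      rng: np.random.Generator) -> np.ndarray:
    """Dense high-frequency texture: 2x2 cells alternating randomly between
    the I-band and Z-disk intensity regimes, so both directional templates
    fire throughout the blob."""
    nrows, ncols = artifact.shape
    cell = rng.integers(0, 2, size=((nrows + 1) // 2, (ncols + 1) // 2))
    coarse = np.repeat(np.repeat(cell, 2, axis=0), 2, axis=1)[:nrows, :ncols]
    mu_i, sd_i = model.class_stats["iband"]
    mu_z, sd_z = model.class_stats["zdisk"]
    tex = np.where(coarse == 1,
                   rng.normal(mu_z, sd_z, size=(nrows, ncols)),
                   rng.normal(mu_i, sd_i, size=(nrows, ncols)))
    return np.clip(tex, 0.0, 255.0)


def generate_slice(model: TissueModel) -> Fixture:
    """One synthetic slice with exact Z-disk, band and membrane truth."""
    rng = np.random.default_rng(model.seed)
    phase = int(rng.integers(0, model.sarcomere_period))
    upper, lower = _membrane_curves(model, rng)
    image, zdisk_truth, band, artifact, class_map = _paint_slice(
        model, rng, phase, upper, lower)
    membranes = (EdgeTrace(rows=upper, role="upper"),
                 EdgeTrace(rows=lower, role="lower"))
    return Fixture(image=image, zdisk_truth=zdisk_truth, band_truth=band,
                   membranes=membranes, artifact_mask=artifact,
                   class_map=class_map, model=model)


def generate_stack(model: TissueModel, n_slices: int, drift: int = 0) -> Fixture:
    """A serial stack whose membranes random-walk from slice to slice.

    Per-slice membrane offsets take integer steps uniform in
    ``[-drift, drift]``, emulating the section-to-section shape changes of
    serial EM data; ``drift=0`` repeats the same geometry.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    rng = np.random.default_rng(model.seed)
    phase = int(rng.integers(0, model.sarcomere_period))
    base_upper, base_lower = _membrane_curves(model, rng)

    images, zt, bt, art, cms, membranes = [], [], [], [], [], []
    off_u = off_l = 0
    for _ in range(n_slices):
        upper = np.clip(base_upper + off_u, 1, model.slice_shape[0] - 3)
        lower = np.clip(base_lower + off_l, 1, model.slice_shape[0] - 2)
        lower = np.maximum(lower, upper + 1)
        image, z, b, a, cm = _paint_slice(model, rng, phase, upper, lower)
        images.append(image)
        zt.append(z)
        bt.append(b)
        art.append(a)
        cms.append(cm)
        membranes.append((EdgeTrace(rows=upper, role="upper"),
                          EdgeTrace(rows=lower, role="lower")))
        if drift > 0:
            off_u += int(rng.integers(-drift, drift + 1))
            off_l += int(rng.integers(-drift, drift + 1))
    return Fixture(image=np.stack(images), zdisk_truth=np.stack(zt),
                   band_truth=np.stack(bt), membranes=membranes,
                   artifact_mask=np.stack(art), class_map=np.stack(cms),
                   model=model)


def sbfsem_like(seed: int = 0, slice_shape: Tuple[int, int] = (180, 400),
                **overrides) -> TissueModel:
    """SBF-SEM regime: 1-2 px Z-disks, printed class statistics."""
    rng = np.random.default_rng(seed)
    zw = int(rng.integers(1, 3))
    params = dict(slice_shape=slice_shape, zdisk_width=zw, iband_width=5,
                  sarcomere_period=30 + 2 * 5 + zw,
                  class_stats=dict(SBFSEM_CLASS_STATS), seed=seed)
    params.update(overrides)
    return TissueModel(**params)


def fibsem_like(seed: int = 0, slice_shape: Tuple[int, int] = (180, 440),
                **overrides) -> TissueModel:
    """FIB-SEM regime: 5-7 px Z-disks at finer effective resolution."""
    rng = np.random.default_rng(seed)
    zw = int(rng.integers(5, 8))
    params = dict(slice_shape=slice_shape, zdisk_width=zw, iband_width=14,
                  sarcomere_period=70 + 2 * 14 + zw,
                  class_stats=dict(FIBSEM_CLASS_STATS), seed=seed)
    params.update(overrides)
    return TissueModel(**params)
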