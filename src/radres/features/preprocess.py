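"""Volume preprocessing: isotropic resampling, unit normalization, margin
ROIs and gray-level discretization."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ..masks import BinaryMask3D

__all__ = [
    "PreprocessedChannel",
    "ROIPair",
    "DiscretizedROI",
    "resample_isotropic",
    "normalize_unit",
    "margin_mask",
    "discretize",
]


@dataclass(frozen=True)
class PreprocessedChannel:
    volume: np.ndarray
    spacing_mm: float
    norm_min: float | None = None
    norm_max: float | None = None


@dataclass(frozen=True)
class ROIPair:
    tumour: BinaryMask3D
    margin: BinaryMask3D

    def __post_init__(self) -> None:
        if (self.tumour.voxels & self.margin.voxels).any():
            raise ValueError("tumour and margin ROIs must be disjoint")


@dataclass(frozen=True)
class DiscretizedROI:
    """Integer gray levels 1..n_bins on ROI voxels, 0 elsewhere."""

    levels: np.ndarray  # int array, 0 = background
    n_bins: int

    @property
    def roi_mask(self) -> np.ndarray:
        return self.levels > 0

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.levels))


def resample_isotropic(
    volume: np.ndarray,
    in_spacing: tuple[float, float, float],
    out_spacing: float,
    is_mask: bool = False,
) -> np.ndarray:
    """Resample to an isotropic grid: trilinear for images, nearest-neighbour
    for masks.  Output dimensions are round(in_dim * in_spacing / out_spacing).
    """
    in_spacing = np.asarray(in_spacing, dtype=float)
    if np.any(in_spacing <= 0) or out_spacing <= 0:
        raise ValueError("spacings must be positive")
    vol = np.asarray(volume)
    out_shape = np.maximum(1, np.round(np.array(vol.shape) * in_spacing / out_spacing)).astype(int)
    if np.all(out_shape == np.array(vol.shape)) and np.allclose(in_spacing, out_spacing):
        return vol.astype(bool if is_mask else np.float64, copy=True)
    coords = np.meshgrid(
        *[np.arange(n) * out_spacing / s for n, s in zip(out_shape, in_spacing)],
        indexing="ij",
    )
    order = 0 if is_mask else 1
    out = ndimage.map_coordinates(
        vol.astype(np.float64), np.stack(coords), order=order, mode="nearest"
    )
    return out > 0.5 if is_mask else out


def normalize_unit(volume: np.ndarray, spacing_mm: float = 1.0) -> PreprocessedChannel:
    """Min-max normalize the whole volume to [0, 1], recording (min, max)."""
    vol = np.asarray(volume, dtype=np.float64)
    vmin, vmax = float(vol.min()), float(vol.max())
    if vmax <= vmin:
        raise ValueError("cannot normalize a constant volume (zero range)")
    return PreprocessedChannel(
        volume=(vol - vmin) / (vmax - vmin),
        spacing_mm=spacing_mm,
        norm_min=vmin,
        norm_max=vmax,
    )


def margin_mask(tumour: BinaryMask3D, width_mm: float = 5.0) -> ROIPair:
    """Peritumoural shell: voxels with Euclidean distance-to-tumour in
    (0, width_mm], clipped at the grid bounds."""
    if tumour.is_empty():
        raise ValueError("tumour mask is empty")
    if width_mm <= 0:
        raise ValueError("margin width must be positive")
    dist = ndimage.distance_transform_edt(~tumour.voxels, sampling=tumour.spacing_mm)
    shell = (dist > 0) & (dist <= width_mm)
    if not shell.any():
        raise ValueError("margin is empty after clipping at the grid bounds")
    return ROIPair(tumour=tumour, margin=BinaryMask3D(shell, tumour.spacing_mm))


def discretize(volume: np.ndarray, roi: np.ndarray, n_bins: int = 32) -> DiscretizedROI:
    """Equal-width discretization of ROI intensities into levels 1..n_bins.

    level = min(floor((v - min) / w) + 1, n_bins); a constant ROI maps every
    voxel to level 1.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("ROI is empty")
    vals = np.asarray(volume, dtype=np.float64)[roi]
    vmin, vmax = vals.min(), vals.max()
    levels = np.zeros(roi.shape, dtype=np.int32)
    if vmax <= vmin:
        levels[roi] = 1
    else:
        w = (vmax - vmin) / n_bins
        lv = np.floor((vals - vmin) / w).astype(np.int32) + 1
        levels[roi] = np.minimum(lv, n_bins)
    return DiscretizedROI(levels=levels, n_bins=n_bins)
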