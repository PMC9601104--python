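"""Cascade segmentation orchestration over pluggable backends.

Slice-wise detection masks are OR-reduced to a 2D upper bound of the tumour
areas; connected-component centres drive nested crops; the final two-channel
crop is fed to two volume segmenters whose probability maps are averaged and
thresholded.  A classical smoothed-intensity backend is provided for
desk-scale use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .cohort import ImagingStudy
from .masks import BinaryMask3D, _STRUCT_26

__all__ = [
    "CascadeConfig",
    "or_reduce_slices",
    "component_centres",
    "crop_about",
    "fuse_probability_maps",
    "run_cascade",
    "ClassicalSliceSegmenter",
    "ClassicalVolumeSegmenter",
]

logger = logging.getLogger(__name__)

#: 2D components use 8-connectivity, 3D components 26-connectivity
_STRUCT_8_2D = ndimage.generate_binary_structure(2, 2)


@dataclass(frozen=True)
class CascadeConfig:
    crop_sizes: tuple[int, int, int] = (64, 32, 32)  # full -> mid (2D), final (3D cube)
    fusion_threshold: float = 0.5
    slice_threshold: float = 0.5

    def __post_init__(self) -> None:
        # the cascade narrows: full -> mid -> final (the last two stages may
        # share a size, e.g. 64 -> 32 -> 32)
        if not all(a >= b for a, b in zip(self.crop_sizes, self.crop_sizes[1:])):
            raise ValueError(f"crop sizes must be non-increasing, got {self.crop_sizes}")
        if not (0.0 < self.fusion_threshold < 1.0):
            raise ValueError("fusion threshold must lie in (0, 1)")


def or_reduce_slices(slice_masks: list[np.ndarray]) -> np.ndarray:
    """Elementwise OR of a stack of same-shape 2D masks."""
    if len(slice_masks) == 0:
        raise ValueError("empty slice stack")
    shape = slice_masks[0].shape
    for m in slice_masks:
        if m.shape != shape:
            raise ValueError("slice masks must share a shape")
    return np.any(np.stack([m.astype(bool) for m in slice_masks]), axis=0)


def component_centres(mask: np.ndarray) -> list[tuple[int, int]]:
    """Rounded centroid of each 8-connected component; [] for an empty mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    labels, n = ndimage.label(mask, structure=_STRUCT_8_2D)
    centres = []
    for c in ndimage.center_of_mass(mask, labels, range(1, n + 1)):
        centres.append(tuple(int(np.floor(x + 0.5)) for x in c))
    return centres


def crop_about(volume: np.ndarray, centre, size) -> tuple[np.ndarray, tuple[slice, ...]]:
    """Fixed-size window about ``centre``, shifted inward at boundaries so it
    never pads; the slice record allows exact back-placement."""
    size = (size,) * volume.ndim if np.isscalar(size) else tuple(size)
    if any(s > n for s, n in zip(size, volume.shape)):
        raise ValueError(f"crop size {size} exceeds volume shape {volume.shape}")
    slices = []
    for c, s, n in zip(centre, size, volume.shape):
        start = int(round(c)) - s // 2
        start = max(0, min(start, n - s))
        slices.append(slice(start, start + s))
    slices = tuple(slices)
    return volume[slices], slices


def fuse_probability_maps(p1: np.ndarray, p2: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary mask where the average of two probability maps reaches the
    threshold."""
    if p1.shape != p2.shape:
        raise ValueError(f"probability map shapes differ: {p1.shape} vs {p2.shape}")
    for p in (p1, p2):
        if p.min() < 0 or p.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")
    return (p1 + p2) / 2.0 >= threshold


def run_cascade(
    study: ImagingStudy,
    slice_seg,
    vol_seg_a,
    vol_seg_b,
    config: CascadeConfig = CascadeConfig(),
) -> list[BinaryMask3D]:
    """Full cascade: slice detection -> OR-reduction -> per-component nested
    crops on the T1 channel -> two-channel volume segmentation + fusion ->
    back-placement.  Returns one full-grid mask per detected lesion."""
    t1, t2 = study.channel_T1, study.channel_T2FLAIR
    full_shape = t1.shape
    mid, final = config.crop_sizes[1], config.crop_sizes[2]

    detect = [slice_seg(t1[:, :, z]) >= config.slice_threshold for z in range(full_shape[2])]
    union = or_reduce_slices(detect)
    centres = component_centres(union)
    if not centres:
        logger.info("cascade detected no component in study %s", study.patient_id)
        return []

    results: list[BinaryMask3D] = []
    for cx, cy in centres:
        # mid-size in-plane crop, re-detect to refine the centre
        _, mid_slices = crop_about(t1[:, :, 0], (cx, cy), mid)
        sub = t1[mid_slices[0], mid_slices[1], :]
        sub_detect = [slice_seg(sub[:, :, z]) >= config.slice_threshold for z in range(sub.shape[2])]
        sub_union = or_reduce_slices(sub_detect)
        area = np.array([m.sum() for m in sub_detect], dtype=float)
        cz = float(np.sum(area * np.arange(len(area))) / area.sum()) if area.sum() else full_shape[2] / 2
        sub_centres = component_centres(sub_union)
        if sub_centres:
            # nearest refined centre to the original detection
            orig = (cx - mid_slices[0].start, cy - mid_slices[1].start)
            rx, ry = min(sub_centres, key=lambda c: (c[0] - orig[0]) ** 2 + (c[1] - orig[1]) ** 2)
        else:
            rx, ry = cx - mid_slices[0].start, cy - mid_slices[1].start
        centre3 = (mid_slices[0].start + rx, mid_slices[1].start + ry, int(round(cz)))

        crop_t1, slices3 = crop_about(t1, centre3, final)
        crop_t2 = t2[slices3]
        stacked = np.stack([crop_t1, crop_t2])
        p = fuse_probability_maps(vol_seg_a(stacked), vol_seg_b(stacked), config.fusion_threshold)
        labels, n = ndimage.label(p, structure=_STRUCT_26)
        if n > 1:
            counts = np.bincount(labels.ravel())
            counts[0] = 0
            p = labels == int(np.argmax(counts))
        full = np.zeros(full_shape, dtype=bool)
        full[slices3] = p
        if full.any():
            results.append(BinaryMask3D(full, (study.spacing_mm,) * 3))
    return results


def _intensity_ramp(sm: np.ndarray, cut: float, ramp: float) -> np.ndarray:
    """Probability 0.5 at the absolute intensity ``cut``, reaching 0/1 over
    ``ramp`` intensity units."""
    return np.clip((sm - cut) / ramp + 0.5, 0.0, 1.0)


class ClassicalSliceSegmenter:
    """Smoothed absolute-intensity detector: p >= 0.5 where the Gaussian-
    smoothed image exceeds ``intensity_cut``."""

    def __init__(self, sigma: float = 1.0, intensity_cut: float = 0.5, ramp: float = 0.2):
        self.sigma = sigma
        self.intensity_cut = intensity_cut
        self.ramp = ramp

    def __call__(self, image: np.ndarray) -> np.ndarray:
        sm = ndimage.gaussian_filter(image.astype(np.float64), self.sigma)
        return _intensity_ramp(sm, self.intensity_cut, self.ramp)


class ClassicalVolumeSegmenter:
    """3D analogue of the classical slice detector over a 2-channel crop
    (uses the first channel)."""

    def __init__(self, sigma: float = 1.0, intensity_cut: float = 0.5, ramp: float = 0.2):
        self.sigma = sigma
        self.intensity_cut = intensity_cut
        self.ramp = ramp

    def __call__(self, crop: np.ndarray) -> np.ndarray:
        sm = ndimage.gaussian_filter(crop[0].astype(np.float64), self.sigma)
        return _intensity_ramp(sm, self.intensity_cut, self.ramp)
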