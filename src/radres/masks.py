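"""Binary 3D masks, segmentation-quality metrics and controlled degradation.

Quality metrics (Dice, Hausdorff distance, volume estimation error) operate
on :class:`BinaryMask3D`.  :func:`perturb_to_target_dice` produces degraded
masks whose Dice against the input hits a prescribed target, standing in for
segmentation models of differing accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "BinaryMask3D",
    "SegmentationQuality",
    "dice_coefficient",
    "hausdorff_distance",
    "volume_estimation_error",
    "evaluate_quality",
    "perturb_to_target_dice",
    "PerturbationError",
]

#: 6-connected structuring element used to find boundary voxels.
_STRUCT_6 = ndimage.generate_binary_structure(3, 1)
#: 26-connected structuring element (single-component filtering).
_STRUCT_26 = ndimage.generate_binary_structure(3, 3)


@dataclass(frozen=True)
class BinaryMask3D:
    """A voxel mask with spacing metadata (mm per axis)."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float] = (0.5, 0.5, 0.5)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=bool)
        object.__setattr__(self, "voxels", vox)
        if vox.ndim != 3:
            raise ValueError(f"mask must be 3D, got ndim={vox.ndim}")
        spacing = tuple(float(s) for s in self.spacing_mm)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing_mm}")
        object.__setattr__(self, "spacing_mm", spacing)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape

    @property
    def n_foreground(self) -> int:
        return int(self.voxels.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def volume_cc(self) -> float:
        """Foreground volume in cm^3."""
        return self.n_foreground * self.voxel_volume_mm3 / 1000.0

    def is_empty(self) -> bool:
        return not bool(self.voxels.any())


@dataclass(frozen=True)
class SegmentationQuality:
    dsc: float
    hd_mm: float
    vee_cc: float
    vee_pct: float


class PerturbationError(RuntimeError):
    """Raised when a Dice target cannot be reached; carries the achieved value."""

    def __init__(self, message: str, achieved: float):
        super().__init__(message)
        self.achieved = achieved


def _check_pair(a: BinaryMask3D, b: BinaryMask3D) -> None:
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    if a.spacing_mm != b.spacing_mm:
        raise ValueError(f"mask spacings differ: {a.spacing_mm} vs {b.spacing_mm}")


def dice_coefficient(a: BinaryMask3D, b: BinaryMask3D) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|)."""
    _check_pair(a, b)
    na, nb = a.n_foreground, b.n_foreground
    if na + nb == 0:
        raise ValueError("Dice undefined for two empty masks")
    inter = int(np.count_nonzero(a.voxels & b.voxels))
    return 2.0 * inter / (na + nb)


def _boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Foreground voxels with at least one 6-neighbour background voxel."""
    eroded = ndimage.binary_erosion(mask, structure=_STRUCT_6, border_value=0)
    return mask & ~eroded


def _surface_points_mm(mask: BinaryMask3D) -> np.ndarray:
    idx = np.argwhere(_boundary_voxels(mask.voxels))
    return idx * np.asarray(mask.spacing_mm)


def hausdorff_distance(a: BinaryMask3D, b: BinaryMask3D, percentile: float | None = None) -> float:
    """Maximum symmetric surface distance in mm between boundary voxel centres.

    ``percentile`` switches to the given percentile of directed surface
    distances (e.g. 95 for HD95); default is the classical maximum.
    """
    _check_pair(a, b)
    if a.is_empty() or b.is_empty():
        raise ValueError("Hausdorff distance requires two non-empty masks")
    pa, pb = _surface_points_mm(a), _surface_points_mm(b)
    d_ab, _ = cKDTree(pb).query(pa)
    d_ba, _ = cKDTree(pa).query(pb)
    if percentile is None:
        return float(max(d_ab.max(), d_ba.max()))
    return float(max(np.percentile(d_ab, percentile), np.percentile(d_ba, percentile)))


def volume_estimation_error(a: BinaryMask3D, b: BinaryMask3D) -> tuple[float, float]:
    """Absolute volume discrepancy of ``a`` versus ground truth ``b``: (cc, %)."""
    _check_pair(a, b)
    if b.is_empty():
        raise ValueError("volume estimation error undefined for empty ground truth")
    cc = abs(a.volume_cc() - b.volume_cc())
    return cc, 100.0 * cc / b.volume_cc()


def evaluate_quality(pred: BinaryMask3D, gt: BinaryMask3D) -> SegmentationQuality:
    """DSC, HD and VEE of ``pred`` against ground truth ``gt``."""
    vee_cc, vee_pct = volume_estimation_error(pred, gt)
    return SegmentationQuality(
        dsc=dice_coefficient(pred, gt),
        hd_mm=hausdorff_distance(pred, gt),
        vee_cc=vee_cc,
        vee_pct=vee_pct,
    )


# ---------------------------------------------------------------------------
# controlled degradation


def _signed_distance(mask: np.ndarray, spacing: tuple[float, float, float]) -> np.ndarray:
    """Positive inside the mask, negative outside, in mm."""
    inside = ndimage.distance_transform_edt(mask, sampling=spacing)
    outside = ndimage.distance_transform_edt(~mask, sampling=spacing)
    return inside - outside


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=_STRUCT_6)
    if n <= 1:
        return mask
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))


class _AmplitudeFamily:
    """Nested family of perturbations of one mask for one (mode, seed).

    The random fields are drawn once, so evaluating a new amplitude is a
    cheap threshold; for a fixed seed the perturbation grows with amplitude
    and Dice against the input decreases monotonically (before the final
    single-component filtering).
    """

    #: correlation length (voxels) of the deformation random field; larger
    #: values give smoother, more segmentation-like boundary errors
    DEFORMATION_SIGMA = 2.0

    def __init__(self, mask: BinaryMask3D, mode: str, seed: int):
        if mask.is_empty():
            raise ValueError("cannot perturb an empty mask")
        if mode not in ("boundary_noise", "morphological", "deformation"):
            raise ValueError(f"unknown perturbation mode {mode!r}")
        self.mask = mask
        self.mode = mode
        vox = mask.voxels
        rng = np.random.default_rng(seed)
        if mode == "boundary_noise":
            # flips live in the two-voxel shell around the surface; a fixed
            # uniform field makes the flip set grow with amplitude
            self.shell = ndimage.binary_dilation(vox, _STRUCT_6, iterations=2) & ~ndimage.binary_erosion(
                vox, _STRUCT_6, border_value=0, iterations=2
            )
            self.u = rng.random(vox.shape)
        elif mode == "morphological":
            # erosion or dilation by `amplitude` mm (sign drawn per seed);
            # sub-voxel jitter dithers the discrete distance levels so the
            # amplitude acts continuously
            self.sign = 1.0 if rng.random() < 0.5 else -1.0
            jitter = (rng.random(vox.shape) - 0.5) * min(mask.spacing_mm)
            self.sd = _signed_distance(vox, mask.spacing_mm) + jitter
        else:
            # boundary displaced by a smooth Gaussian random field (unit std)
            r = ndimage.gaussian_filter(rng.standard_normal(vox.shape), sigma=self.DEFORMATION_SIGMA)
            self.r = r / max(r.std(), 1e-12)
            self.sd = _signed_distance(vox, mask.spacing_mm)

    def at(self, amplitude: float, keep_largest: bool = True) -> BinaryMask3D:
        if amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        vox = self.mask.voxels
        if self.mode == "boundary_noise":
            out = vox ^ (self.shell & (self.u < amplitude))
        elif self.mode == "morphological":
            out = self.sd > self.sign * amplitude
        else:
            out = (self.sd + amplitude * self.r) > 0
        if keep_largest:
            out = _largest_component(out)
        return BinaryMask3D(out, self.mask.spacing_mm)


def perturb_amplitude(
    mask: BinaryMask3D,
    amplitude: float,
    mode: str,
    seed: int,
    keep_largest: bool = True,
) -> BinaryMask3D:
    """One perturbation of the given amplitude (mm-scale for the
    distance-based modes, flip probability for ``boundary_noise``)."""
    return _AmplitudeFamily(mask, mode, seed).at(amplitude, keep_largest=keep_largest)


def perturb_to_target_dice(
    mask: BinaryMask3D,
    target_dsc: float,
    mode: str = "deformation",
    seed: int = 0,
    tol: float = 0.01,
    max_iter: int = 60,
) -> BinaryMask3D:
    """Degrade ``mask`` until its Dice against the input equals ``target_dsc``.

    Bisection on the perturbation amplitude; raises
    :class:`PerturbationError` with the best achieved Dice if the target is
    not bracketed or reached within ``max_iter`` evaluations.
    """
    if not (0.0 < target_dsc <= 1.0):
        raise ValueError("target_dsc must be in (0, 1]")
    if mask.is_empty():
        raise ValueError("cannot perturb an empty mask")
    if target_dsc >= 1.0 - 1e-12:
        return BinaryMask3D(mask.voxels.copy(), mask.spacing_mm)

    family = _AmplitudeFamily(mask, mode, seed)

    def achieved(amplitude: float) -> tuple[float, BinaryMask3D]:
        m = family.at(amplitude)
        if m.is_empty():
            return 0.0, m
        return dice_coefficient(m, mask), m

    # bracket the target: grow amplitude geometrically until dice < target
    lo, hi = 0.0, float(min(mask.spacing_mm))
    evals = 0
    d_hi, m_hi = achieved(hi)
    evals += 1
    while d_hi > target_dsc and evals < max_iter:
        lo = hi
        hi *= 1.6
        d_hi, m_hi = achieved(hi)
        evals += 1
    best_d, best_m = d_hi, m_hi
    while evals < max_iter:
        if abs(best_d - target_dsc) <= tol and not best_m.is_empty():
            return best_m
        mid = 0.5 * (lo + hi)
        d_mid, m_mid = achieved(mid)
        evals += 1
        if abs(d_mid - target_dsc) < abs(best_d - target_dsc):
            best_d, best_m = d_mid, m_mid
        if d_mid > target_dsc:
            lo = mid
        else:
            hi = mid
    if abs(best_d - target_dsc) <= tol and not best_m.is_empty():
        return best_m
    raise PerturbationError(
        f"could not reach dice {target_dsc:.3f} (mode={mode}, seed={seed}); "
        f"best achieved {best_d:.4f}",
        achieved=best_d,
    )
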