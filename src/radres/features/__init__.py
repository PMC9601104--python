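"""Radiomic feature extraction.

Computes the full per-lesion-timepoint feature vector — first-order, shape,
and five texture families over the original image and its eight stationary
wavelet sub-bands, for two modalities and a tumour + margin ROI pair — plus
relative-difference (delta) vectors between timepoints.

Feature names follow ``<image>_<family>_<feature>_<modality>[_Margin]``
(e.g. ``wavelet-HHL_firstorder_Minimum_T1_Margin``); shape features are
mask-derived and appear once per ROI as ``original_shape_<feature>[_Margin]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..cohort import ImagingStudy
from ..masks import BinaryMask3D
from .firstorder import FIRSTORDER_NAMES, first_order_features
from .preprocess import (
    DiscretizedROI,
    PreprocessedChannel,
    ROIPair,
    discretize,
    margin_mask,
    normalize_unit,
    resample_isotropic,
)
from .shape import SHAPE_NAMES, shape_features
from .texture import (
    GLCM_NAMES,
    GLDM_NAMES,
    GLRLM_NAMES,
    GLSZM_NAMES,
    NGTDM_NAMES,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)
from .wavelet import SUBBAND_NAMES, wavelet_subbands

__all__ = [
    "FeatureConfig",
    "FeatureExtractionError",
    "feature_namespace",
    "extract_feature_vector",
    "extract_study_features",
    "delta_features",
    "expected_feature_count",
    "ROIPair",
    "PreprocessedChannel",
    "DiscretizedROI",
    "discretize",
    "margin_mask",
    "normalize_unit",
    "resample_isotropic",
    "first_order_features",
    "shape_features",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "ngtdm_features",
    "gldm_features",
    "wavelet_subbands",
]

_FAMILIES = (
    ("firstorder", FIRSTORDER_NAMES),
    ("glcm", GLCM_NAMES),
    ("glrlm", GLRLM_NAMES),
    ("glszm", GLSZM_NAMES),
    ("ngtdm", NGTDM_NAMES),
    ("gldm", GLDM_NAMES),
)


class FeatureExtractionError(RuntimeError):
    """Extraction failed for a specific family / image / ROI."""


@dataclass(frozen=True)
class FeatureConfig:
    n_bins: int = 32
    margin_mm: float = 5.0
    wavelet: bool = True
    modalities: tuple[str, str] = ("T1", "T2")
    gldm_alpha: int = 0

    @property
    def image_names(self) -> list[str]:
        names = ["original"]
        if self.wavelet:
            names += [f"wavelet-{b}" for b in SUBBAND_NAMES]
        return names


def feature_namespace(config: FeatureConfig = FeatureConfig()) -> list[str]:
    """The full ordered feature-name list for a configuration (the schema of
    every extracted vector)."""
    names: list[str] = []
    for suffix in ("", "_Margin"):
        names += [f"original_shape_{n}{suffix}" for n in SHAPE_NAMES]
    for mod in config.modalities:
        for img in config.image_names:
            for suffix in ("", "_Margin"):
                for family, fam_names in _FAMILIES:
                    names += [f"{img}_{family}_{n}_{mod}{suffix}" for n in fam_names]
    return names


def expected_feature_count(config: FeatureConfig) -> int:
    """Closed-form feature count for a configuration: 94 intensity features
    per image x modality x ROI, plus 26 shape features per ROI."""
    n_intensity = sum(len(names) for _, names in _FAMILIES)
    return n_intensity * len(config.image_names) * len(config.modalities) * 2 + len(SHAPE_NAMES) * 2


def _roi_suffixes(roi: ROIPair) -> list[tuple[str, BinaryMask3D]]:
    return [("", roi.tumour), ("_Margin", roi.margin)]


def extract_study_features(
    study: ImagingStudy,
    roi_pairs: dict[str, ROIPair],
    config: FeatureConfig = FeatureConfig(),
) -> dict[str, dict[str, float]]:
    """Extract one feature vector per lesion ROI pair of a study.

    Wavelet sub-bands are computed once per channel and shared across
    lesions; per lesion the shape family runs once per ROI and the intensity
    families run per image / modality / ROI.
    """
    channels = {
        config.modalities[0]: study.channel_T1,
        config.modalities[1]: study.channel_T2FLAIR,
    }
    images: dict[str, dict[str, np.ndarray]] = {}
    for mod, vol in channels.items():
        norm = normalize_unit(vol, spacing_mm=study.spacing_mm).volume
        imgs = {"original": norm}
        if config.wavelet:
            for band, sub in wavelet_subbands(norm).items():
                imgs[f"wavelet-{band}"] = sub
        images[mod] = imgs

    out: dict[str, dict[str, float]] = {}
    for lesion_id, roi in roi_pairs.items():
        fv: dict[str, float] = {}
        for suffix, mask in _roi_suffixes(roi):
            try:
                shp = shape_features(mask)
            except Exception as exc:
                raise FeatureExtractionError(
                    f"shape failed for lesion {lesion_id} ROI '{suffix or 'tumour'}': {exc}"
                ) from exc
            for name in SHAPE_NAMES:
                fv[f"original_shape_{name}{suffix}"] = shp[name]
        for mod in config.modalities:
            for img_name in config.image_names:
                vol = images[mod][img_name]
                for suffix, mask in _roi_suffixes(roi):
                    fv.update(
                        _intensity_families(
                            vol, mask, img_name, mod, suffix, config, lesion_id
                        )
                    )
        out[lesion_id] = fv
    return out


def _intensity_families(vol, mask, img_name, mod, suffix, config, lesion_id):
    roi = mask.voxels
    disc = discretize(vol, roi, n_bins=config.n_bins)
    fv = {}
    for family, names in _FAMILIES:
        try:
            if family == "firstorder":
                vals = first_order_features(
                    vol, roi, spacing_mm=mask.spacing_mm[0], n_bins=config.n_bins
                )
            elif family == "glcm":
                vals = glcm_features(disc)
            elif family == "glrlm":
                vals = glrlm_features(disc)
            elif family == "glszm":
                vals = glszm_features(disc)
            elif family == "ngtdm":
                vals = ngtdm_features(disc)
            else:
                vals = gldm_features(disc, alpha=config.gldm_alpha)
        except Exception as exc:
            raise FeatureExtractionError(
                f"{family} failed for lesion {lesion_id}, image {img_name}, "
                f"modality {mod}, ROI '{suffix or 'tumour'}': {exc}"
            ) from exc
        for name in names:
            fv[f"{img_name}_{family}_{name}_{mod}{suffix}"] = vals[name]
    return fv


def extract_feature_vector(
    study: ImagingStudy,
    roi: ROIPair,
    config: FeatureConfig = FeatureConfig(),
    lesion_id: str | None = None,
) -> dict[str, float]:
    """Full feature vector for a single lesion ROI pair of a study."""
    lid = lesion_id if lesion_id is not None else (study.lesion_ids[0] if study.lesion_ids else "lesion")
    return extract_study_features(study, {lid: roi}, config)[lid]


def delta_features(
    fv_bl: dict[str, float],
    fv_fu1: dict[str, float],
    eps: float = 1e-12,
) -> dict[str, float]:
    """Relative change per feature: (fu1 - bl) / max(|bl|, eps)."""
    if set(fv_bl) != set(fv_fu1):
        missing = set(fv_bl) ^ set(fv_fu1)
        raise ValueError(f"feature name sets differ ({len(missing)} mismatches)")
    return {
        name: (fv_fu1[name] - fv_bl[name]) / max(abs(fv_bl[name]), eps) for name in fv_bl
    }
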