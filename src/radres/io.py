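"""NIfTI / CSV / YAML interchange helpers."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort, CohortConfig
from .masks import BinaryMask3D

__all__ = [
    "save_volume",
    "load_volume",
    "save_mask",
    "load_mask",
    "save_cohort",
    "save_features_csv",
    "load_features_csv",
    "save_config_yaml",
    "load_config_yaml",
]


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def save_volume(volume: np.ndarray, spacing_mm, path: str | Path) -> Path:
    spacing = (spacing_mm,) * 3 if np.isscalar(spacing_mm) else tuple(spacing_mm)
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32), _affine(spacing))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def load_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.get_fdata(), dtype=np.float64), spacing


def save_mask(mask: BinaryMask3D, path: str | Path) -> Path:
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), _affine(mask.spacing_mm))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def load_mask(path: str | Path) -> BinaryMask3D:
    vol, spacing = load_volume(path)
    return BinaryMask3D(vol > 0.5, spacing)


def save_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write a cohort to disk: per-study NIfTI channels and masks, a lesion
    manifest CSV, a survival CSV and the YAML config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for pair in cohort.studies:
        for study in (pair.baseline, pair.followup):
            base = out / study.patient_id / study.timepoint
            save_volume(study.channel_T1, study.spacing_mm, base / "T1.nii.gz")
            save_volume(study.channel_T2FLAIR, study.spacing_mm, base / "T2FLAIR.nii.gz")
            for lid, mask in study.gt_masks.items():
                save_mask(mask, base / f"mask_{lid}.nii.gz")
    manifest = pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "lesion_id": r.lesion_id,
                "split": cohort.split[r.patient_id],
                "outcome": r.true_outcome,
                "bl_volume_cc": r.bl_volume_cc,
                "fu1_volume_cc": r.fu1_volume_cc,
            }
            for r in cohort.lesions
        ]
    )
    manifest.to_csv(out / "manifest.csv", index=False)
    surv = pd.DataFrame(
        [
            {"patient_id": s.patient_id, "time": s.pfs_time, "event": int(s.event)}
            for s in cohort.survival
        ]
    )
    surv.to_csv(out / "survival.csv", index=False)
    save_config_yaml(cohort.config, out / "config.yaml")
    return out


def save_features_csv(table: pd.DataFrame, path: str | Path) -> Path:
    """Rows = lesions (index), columns = feature names."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index_label="lesion_id")
    return path


def load_features_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="lesion_id")


def save_config_yaml(config, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(dataclasses.asdict(config)))
    return path


def load_config_yaml(path: str | Path, cls=CohortConfig):
    data = yaml.safe_load(Path(path).read_text())
    for f in dataclasses.fields(cls):
        if f.name in data and isinstance(data[f.name], list):
            data[f.name] = tuple(data[f.name])
    return cls(**data)
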