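"""Seeded synthetic imaging cohorts.

Generates paired baseline / first-follow-up two-channel lesion volumes with
ground-truth masks, class-dependent growth and texture change, a
patient-level train/validation/test split, and outcome-linked
progression-free-survival records.  Everything is a pure function of the
configuration (including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .masks import BinaryMask3D

__all__ = [
    "CohortConfig",
    "TextureParams",
    "ImagingStudy",
    "StudyPair",
    "LesionRecord",
    "SurvivalRecord",
    "Cohort",
    "GenerationError",
    "render_lesion",
    "generate_cohort",
    "assign_survival",
]

LC, LF = "LC", "LF"


class GenerationError(RuntimeError):
    """Configuration cannot be realised (e.g. lesions do not fit the volume)."""


@dataclass(frozen=True)
class CohortConfig:
    n_train_patients: int = 90
    n_val_patients: int = 10
    n_test_patients: int = 25
    lesions_per_patient: tuple[int, int] = (1, 2)
    lf_fraction: float = 63.0 / 156.0
    volume_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: float = 0.5
    lesion_radius_range: tuple[float, float] = (4.0, 7.0)
    lf_growth_factor_range: tuple[float, float] = (1.2, 2.0)
    lc_change_factor_range: tuple[float, float] = (0.5, 1.1)
    texture_effect_size: float = 0.5
    texture_effect_scale_range: tuple[float, float] = (1.0, 1.0)
    noise_sd: float = 0.05
    censor_time: float = 24.0
    hazard_lc: float = 0.05
    hazard_ratio_lf: float = 4.0
    margin_buffer_mm: float = 5.0
    seed: int = 0

    @property
    def n_patients(self) -> int:
        return self.n_train_patients + self.n_val_patients + self.n_test_patients

    def validate(self) -> None:
        if not (0.0 <= self.lf_fraction <= 1.0):
            raise ValueError("lf_fraction must lie in [0, 1]")
        for name in ("lesions_per_patient", "lesion_radius_range",
                     "lf_growth_factor_range", "lc_change_factor_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} has low > high: {(lo, hi)}")
        if self.lesion_radius_range[0] < 2.0:
            raise ValueError("lesion radii must be >= 2 voxels")
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be positive")
        # the largest follow-up lesion plus its margin buffer must fit
        max_growth = max(self.lf_growth_factor_range[1], self.lc_change_factor_range[1], 1.0)
        max_r = self.lesion_radius_range[1] * max_growth ** (1.0 / 3.0)
        buffer_vox = self.margin_buffer_mm / self.spacing_mm
        half_extent = max_r + buffer_vox + 1.0
        if 2.0 * half_extent >= min(self.volume_shape):
            raise GenerationError(
                f"lesion of radius {max_r:.1f} vox plus {buffer_vox:.1f} vox margin "
                f"buffer does not fit in volume of shape {self.volume_shape}"
            )


@dataclass(frozen=True)
class TextureParams:
    """Texture regime of a lesion interior and its surrounding shell."""

    interior_mean: float = 0.7
    interior_amp: float = 0.15
    interior_sigma: float = 1.5
    shell_mean: float = 0.4
    shell_amp: float = 0.1
    shell_sigma: float = 2.5
    shell_width_mm: float = 5.0


@dataclass
class ImagingStudy:
    patient_id: str
    lesion_ids: list[str]
    timepoint: str  # "BL" or "FU1"
    channel_T1: np.ndarray
    channel_T2FLAIR: np.ndarray
    gt_masks: dict[str, BinaryMask3D]
    spacing_mm: float

    def __post_init__(self) -> None:
        if self.channel_T1.shape != self.channel_T2FLAIR.shape:
            raise ValueError("channels must share shape")
        if self.timepoint not in ("BL", "FU1"):
            raise ValueError(f"timepoint must be BL or FU1, got {self.timepoint!r}")


@dataclass
class StudyPair:
    baseline: ImagingStudy
    followup: ImagingStudy


@dataclass(frozen=True)
class LesionRecord:
    lesion_id: str
    patient_id: str
    true_outcome: str  # LC / LF
    bl_volume_cc: float
    fu1_volume_cc: float
    growth_factor: float


@dataclass(frozen=True)
class SurvivalRecord:
    patient_id: str
    pfs_time: float
    event: bool  # True = progressed, False = censored


@dataclass
class Cohort:
    config: CohortConfig
    studies: list[StudyPair]
    lesions: list[LesionRecord]
    survival: list[SurvivalRecord]
    split: dict[str, str]  # patient_id -> train / val / test

    def patients_in_split(self, split: str) -> list[str]:
        return [p for p, s in self.split.items() if s == split]

    def lesions_in_split(self, split: str) -> list[LesionRecord]:
        return [r for r in self.lesions if self.split[r.patient_id] == split]


# ---------------------------------------------------------------------------
# rendering


def _grf(shape, sigma, rng) -> np.ndarray:
    """Gaussian random field: white noise smoothed to correlation length sigma,
    rescaled to unit standard deviation."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    sd = f.std()
    return f / sd if sd > 0 else f


def ellipsoid_mask(shape, centre, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    q = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, centre, radii))
    return q <= 1.0


def render_lesion(
    shape: tuple[int, int, int],
    spacing_mm: float,
    centre: tuple[float, float, float],
    radii: tuple[float, float, float],
    texture: TextureParams,
    seed: int,
) -> tuple[np.ndarray, BinaryMask3D]:
    """Render one ellipsoidal lesion into an otherwise-zero volume.

    The interior is a Gaussian random field added to a constant plateau; the
    shell (within ``texture.shell_width_mm`` of the surface) gets a distinct
    texture regime so margin features are informative.  Returns the additive
    intensity contribution and the discretised ellipsoid mask.
    """
    if min(radii) < 2.0:
        raise ValueError(f"lesion radii must be >= 2 voxels, got {radii}")
    for c, r, s in zip(centre, radii, shape):
        if c - r < 0 or c + r > s - 1:
            raise GenerationError(f"ellipsoid centre={centre} radii={radii} exceeds shape {shape}")
    rng = np.random.default_rng(seed)
    mask = ellipsoid_mask(shape, centre, radii)
    spacing = (spacing_mm,) * 3
    dist = ndimage.distance_transform_edt(~mask, sampling=spacing)
    shell = (dist > 0) & (dist <= texture.shell_width_mm)

    vol = np.zeros(shape, dtype=np.float64)
    interior_field = _grf(shape, texture.interior_sigma, rng)
    shell_field = _grf(shape, texture.shell_sigma, rng)
    vol[mask] = texture.interior_mean + texture.interior_amp * interior_field[mask]
    vol[shell] = texture.shell_mean + texture.shell_amp * shell_field[shell]
    return vol, BinaryMask3D(mask, spacing)


def _lesion_texture(base: TextureParams, outcome: str, timepoint: str, effect: float) -> TextureParams:
    """Class-dependent texture: LF lesions shift their interior correlation
    length and contrast at follow-up; at effect 0 all regimes coincide."""
    if timepoint == "FU1" and outcome == LF:
        return TextureParams(
            interior_mean=base.interior_mean,
            interior_amp=base.interior_amp * (1.0 + effect),
            interior_sigma=base.interior_sigma * (1.0 + effect),
            shell_mean=base.shell_mean,
            shell_amp=base.shell_amp * (1.0 + 0.5 * effect),
            shell_sigma=base.shell_sigma,
            shell_width_mm=base.shell_width_mm,
        )
    return base


# ---------------------------------------------------------------------------
# cohort generation


def _place_centres(cfg: CohortConfig, n_lesions: int, max_radii: list[float], rng) -> list[np.ndarray]:
    """Non-overlapping lesion centres with margin buffer from volume faces."""
    buffer_vox = cfg.margin_buffer_mm / cfg.spacing_mm
    centres: list[np.ndarray] = []
    for i in range(n_lesions):
        half = max_radii[i] + buffer_vox + 1.0
        lo = np.ceil(half)
        hi = np.array(cfg.volume_shape) - 1 - lo
        if np.any(hi < lo):
            raise GenerationError("lesion does not fit inside the volume with its margin buffer")
        for _ in range(200):
            c = rng.uniform(lo, hi)
            ok = all(
                np.linalg.norm(c - c2) > max_radii[i] + max_radii[j] + 3.0
                for j, c2 in enumerate(centres)
            )
            if ok:
                centres.append(c)
                break
        else:
            raise GenerationError("could not place non-overlapping lesions after 200 attempts")
    return centres


def _background(shape, rng) -> np.ndarray:
    return 0.2 + 0.04 * _grf(shape, sigma=8.0, rng=rng)


_T1_TEXTURE = TextureParams()
_T2_TEXTURE = TextureParams(interior_mean=0.6, interior_amp=0.12, interior_sigma=2.0,
                            shell_mean=0.45, shell_amp=0.12, shell_sigma=2.0)


def _render_study(cfg, patient_id, lesion_ids, outcomes, centres, radii_list, timepoint, seed,
                  effect_scales=None):
    shape = cfg.volume_shape
    ss = np.random.SeedSequence(seed)
    s_t1, s_t2, s_n1, s_n2 = ss.spawn(4)
    rng_t1 = np.random.default_rng(s_t1)
    rng_t2 = np.random.default_rng(s_t2)
    t1 = _background(shape, rng_t1)
    t2 = _background(shape, rng_t2)
    masks: dict[str, BinaryMask3D] = {}
    for i, lid in enumerate(lesion_ids):
        effect = cfg.texture_effect_size * (1.0 if effect_scales is None else effect_scales[i])
        tex1 = _lesion_texture(_T1_TEXTURE, outcomes[i], timepoint, effect)
        tex2 = _lesion_texture(_T2_TEXTURE, outcomes[i], timepoint, effect)
        seed1 = int(rng_t1.integers(0, 2**31))
        seed2 = int(rng_t2.integers(0, 2**31))
        v1, m = render_lesion(shape, cfg.spacing_mm, centres[i], radii_list[i], tex1, seed1)
        v2, _ = render_lesion(shape, cfg.spacing_mm, centres[i], radii_list[i], tex2, seed2)
        region = (v1 != 0) | (v2 != 0)
        t1 = np.where(region, v1, t1)
        t2 = np.where(region, v2, t2)
        masks[lid] = m
    t1 = t1 + cfg.noise_sd * np.random.default_rng(s_n1).standard_normal(shape)
    t2 = t2 + cfg.noise_sd * np.random.default_rng(s_n2).standard_normal(shape)
    return ImagingStudy(
        patient_id=patient_id,
        lesion_ids=list(lesion_ids),
        timepoint=timepoint,
        channel_T1=t1,
        channel_T2FLAIR=t2,
        gt_masks=masks,
        spacing_mm=cfg.spacing_mm,
    )


def generate_cohort(cfg: CohortConfig) -> Cohort:
    """Generate a complete seeded cohort (studies, lesion records, survival,
    patient-level split).  Bit-identical for identical configurations."""
    cfg.validate()
    root = np.random.SeedSequence(cfg.seed)
    s_split, s_patients, s_survival = root.spawn(3)

    n = cfg.n_patients
    patient_ids = [f"P{i:03d}" for i in range(n)]
    order = np.random.default_rng(s_split).permutation(n)
    split: dict[str, str] = {}
    for rank, idx in enumerate(order):
        if rank < cfg.n_train_patients:
            split[patient_ids[idx]] = "train"
        elif rank < cfg.n_train_patients + cfg.n_val_patients:
            split[patient_ids[idx]] = "val"
        else:
            split[patient_ids[idx]] = "test"

    studies: list[StudyPair] = []
    lesions: list[LesionRecord] = []
    patient_seeds = s_patients.spawn(n)
    for pid, pseed in zip(patient_ids, patient_seeds):
        rng = np.random.default_rng(pseed)
        n_les = int(rng.integers(cfg.lesions_per_patient[0], cfg.lesions_per_patient[1] + 1))
        lesion_ids = [f"{pid}_L{j}" for j in range(n_les)]
        outcomes = [LF if rng.random() < cfg.lf_fraction else LC for _ in range(n_les)]
        bl_radii, fu_radii, factors = [], [], []
        for outcome in outcomes:
            r = rng.uniform(*cfg.lesion_radius_range)
            anis = rng.uniform(0.85, 1.15, size=3)
            # clamp at the 2-voxel rendering floor (matters for shrinking
            # follow-up lesions at the small end of the radius range)
            radii = np.maximum(r * anis / anis.prod() ** (1.0 / 3.0), 2.0)
            rng_range = cfg.lf_growth_factor_range if outcome == LF else cfg.lc_change_factor_range
            f = float(rng.uniform(*rng_range))
            bl_radii.append(tuple(radii))
            fu_radii.append(tuple(np.maximum(radii * f ** (1.0 / 3.0), 2.0)))
            factors.append(f)
        max_r = [max(max(b), max(f)) for b, f in zip(bl_radii, fu_radii)]
        centres = _place_centres(cfg, n_les, max_r, rng)
        # per-lesion response heterogeneity: the texture shift of an LF lesion
        # is scaled by a lesion-specific factor so class separation is graded
        effect_scales = [float(rng.uniform(*cfg.texture_effect_scale_range)) for _ in range(n_les)]
        seed_bl = int(rng.integers(0, 2**31))
        seed_fu = int(rng.integers(0, 2**31))
        bl = _render_study(cfg, pid, lesion_ids, outcomes, centres, bl_radii, "BL", seed_bl,
                           effect_scales)
        fu = _render_study(cfg, pid, lesion_ids, outcomes, centres, fu_radii, "FU1", seed_fu,
                           effect_scales)
        studies.append(StudyPair(bl, fu))
        for lid, outcome, f in zip(lesion_ids, outcomes, factors):
            lesions.append(
                LesionRecord(
                    lesion_id=lid,
                    patient_id=pid,
                    true_outcome=outcome,
                    bl_volume_cc=bl.gt_masks[lid].volume_cc(),
                    fu1_volume_cc=fu.gt_masks[lid].volume_cc(),
                    growth_factor=f,
                )
            )

    survival = assign_survival(
        lesions,
        hazard_lc=cfg.hazard_lc,
        hazard_ratio_lf=cfg.hazard_ratio_lf,
        censor_time=cfg.censor_time,
        seed=s_survival,
    )
    return Cohort(config=cfg, studies=studies, lesions=lesions, survival=survival, split=split)


def assign_survival(
    lesion_records: list[LesionRecord],
    hazard_lc: float,
    hazard_ratio_lf: float,
    censor_time: float,
    seed,
) -> list[SurvivalRecord]:
    """Exponential PFS times per patient with a proportional hazard for
    LF-bearing patients; administrative censoring at ``censor_time``."""
    if hazard_lc <= 0 or hazard_ratio_lf <= 0:
        raise ValueError("hazards must be positive")
    rng = np.random.default_rng(seed)
    patients: dict[str, bool] = {}
    for rec in lesion_records:
        patients[rec.patient_id] = patients.get(rec.patient_id, False) or rec.true_outcome == LF
    out = []
    for pid, has_lf in patients.items():
        h = hazard_lc * (hazard_ratio_lf if has_lf else 1.0)
        t = float(rng.exponential(1.0 / h))
        if t > censor_time:
            out.append(SurvivalRecord(pid, censor_time, False))
        else:
            out.append(SurvivalRecord(pid, t, True))
    return out
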