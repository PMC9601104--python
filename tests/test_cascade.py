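import numpy as np
import pytest

from radres.cascade import (
    CascadeConfig,
    ClassicalSliceSegmenter,
    ClassicalVolumeSegmenter,
    component_centres,
    crop_about,
    fuse_probability_maps,
    or_reduce_slices,
    run_cascade,
)
from radres.cohort import CohortConfig, generate_cohort
from radres.masks import dice_coefficient

from conftest import small_cohort_config


class TestOrReduce:
    def test_all_empty(self):
        out = or_reduce_slices([np.zeros((4, 4), bool)] * 3)
        assert not out.any()

    def test_single_pixel(self):
        slices = [np.zeros((6, 6), bool) for _ in range(4)]
        slices[2][3, 4] = True
        out = or_reduce_slices(slices)
        assert out[3, 4] and out.sum() == 1

    def test_matches_elementwise_any_oracle(self, rng):
        stack = [rng.random((5, 7)) < 0.3 for _ in range(6)]
        expected = np.zeros((5, 7), bool)
        for m in stack:
            for i in range(5):
                for j in range(7):
                    expected[i, j] |= m[i, j]
        assert np.array_equal(or_reduce_slices(stack), expected)

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            or_reduce_slices([])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            or_reduce_slices([np.zeros((3, 3), bool), np.zeros((4, 4), bool)])


class TestComponentCentres:
    def test_square_centroid(self):
        mask = np.zeros((8, 8), bool)
        mask[2:5, 2:5] = True  # rows/cols 2..4 -> centre (3,3)
        assert component_centres(mask) == [(3, 3)]

    def test_two_blobs(self):
        mask = np.zeros((12, 12), bool)
        mask[1:3, 1:3] = True
        mask[8:11, 8:11] = True
        centres = component_centres(mask)
        assert len(centres) == 2
        assert any(1 <= x <= 2 and 1 <= y <= 2 for x, y in centres)
        assert any(8 <= x <= 10 and 8 <= y <= 10 for x, y in centres)

    def test_diagonal_is_single_8connected_component(self):
        mask = np.zeros((4, 4), bool)
        mask[0, 0] = mask[1, 1] = mask[2, 2] = True
        assert len(component_centres(mask)) == 1

    def test_empty_mask(self):
        assert component_centres(np.zeros((5, 5), bool)) == []


class TestCropAbout:
    def test_centred_window(self):
        vol = np.arange(4096, dtype=float).reshape(16, 16, 16)
        crop, slices = crop_about(vol, (8, 8, 8), 8)
        assert crop.shape == (8, 8, 8)
        assert slices == (slice(4, 12), slice(4, 12), slice(4, 12))

    def test_clamped_at_face(self):
        vol = np.zeros((64, 64, 64))
        crop, slices = crop_about(vol, (2, 30, 30), 32)
        assert crop.shape == (32, 32, 32)
        assert slices[0] == slice(0, 32)  # flush to the face, never padded

    def test_roundtrip_backplacement(self, rng):
        vol = rng.random((20, 20, 20))
        mask = vol > 0.7
        crop, slices = crop_about(mask, (10, 10, 10), 12)
        rebuilt = np.zeros_like(mask)
        rebuilt[slices] = crop
        assert np.array_equal(rebuilt[slices], mask[slices])
        outside = np.ones_like(mask)
        outside[slices] = False
        assert not rebuilt[outside].any()

    def test_oversize_rejected(self):
        with pytest.raises(ValueError):
            crop_about(np.zeros((8, 8, 8)), (4, 4, 4), 16)


class TestFusion:
    def test_mean_above_threshold(self):
        p1 = np.full((3, 3, 3), 0.4)
        p2 = np.full((3, 3, 3), 0.8)
        assert fuse_probability_maps(p1, p2, 0.5).all()

    def test_mean_below_threshold(self):
        p = np.full((3, 3, 3), 0.49)
        assert not fuse_probability_maps(p, p, 0.5).any()

    def test_identical_maps_equal_single_threshold(self, rng):
        p = rng.random((4, 4, 4))
        assert np.array_equal(fuse_probability_maps(p, p, 0.5), p >= 0.5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fuse_probability_maps(np.zeros((2, 2, 2)), np.zeros((3, 3, 3)))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fuse_probability_maps(np.full((2, 2, 2), 1.5), np.zeros((2, 2, 2)))


def _gt_union(study):
    union = np.zeros(study.channel_T1.shape, bool)
    for m in study.gt_masks.values():
        union |= m.voxels
    return union


class _OracleSliceSegmenter:
    """Returns the ground-truth mask for the exact sub-region of the T1
    volume it is handed (located by content search)."""

    def __init__(self, study):
        self.t1 = study.channel_T1
        self.gt = _gt_union(study).astype(float)

    def __call__(self, image):
        nx, ny, nz = self.t1.shape
        h, w = image.shape
        for z in range(nz):
            if h == nx and w == ny:
                if np.array_equal(self.t1[:, :, z], image):
                    return self.gt[:, :, z]
            else:
                for x0 in range(nx - h + 1):
                    for y0 in range(ny - w + 1):
                        if self.t1[x0, y0, z] == image[0, 0] and np.array_equal(
                            self.t1[x0 : x0 + h, y0 : y0 + w, z], image
                        ):
                            return self.gt[x0 : x0 + h, y0 : y0 + w, z]
        raise AssertionError("slice not found in study volume")


class _OracleVolumeSegmenter:
    def __init__(self, study):
        self.t1 = study.channel_T1
        self.gt = _gt_union(study).astype(float)

    def __call__(self, crop):
        vol = crop[0]
        nx, ny, nz = self.t1.shape
        h, w, d = vol.shape
        for x0 in range(nx - h + 1):
            for y0 in range(ny - w + 1):
                for z0 in range(nz - d + 1):
                    if self.t1[x0, y0, z0] == vol[0, 0, 0] and np.array_equal(
                        self.t1[x0 : x0 + h, y0 : y0 + w, z0 : z0 + d], vol
                    ):
                        return self.gt[x0 : x0 + h, y0 : y0 + w, z0 : z0 + d]
        raise AssertionError("crop not found in study volume")


@pytest.fixture(scope="module")
def single_lesion_study():
    cohort = generate_cohort(small_cohort_config(seed=6, lesions_per_patient=(1, 1)))
    return cohort.studies[0].baseline


class TestRunCascade:
    CFG = CascadeConfig(crop_sizes=(40, 24, 20))

    def test_oracle_passthrough_is_identity(self, single_lesion_study):
        study = single_lesion_study
        masks = run_cascade(
            study,
            _OracleSliceSegmenter(study),
            _OracleVolumeSegmenter(study),
            _OracleVolumeSegmenter(study),
            self.CFG,
        )
        assert len(masks) == 1
        gt = next(iter(study.gt_masks.values()))
        assert np.array_equal(masks[0].voxels, gt.voxels)

    def test_classical_backend_dice_floor(self):
        # fixed high-contrast phantom: bright radius-6 ellipsoid on a dark
        # background with mild noise
        from radres.cohort import ImagingStudy, ellipsoid_mask
        from radres.masks import BinaryMask3D

        g = np.random.default_rng(0)
        vox = ellipsoid_mask((40, 40, 40), (20, 20, 20), (6, 6, 6))
        t1 = np.where(vox, 0.85, 0.15) + 0.02 * g.standard_normal((40, 40, 40))
        t2 = np.where(vox, 0.75, 0.2) + 0.02 * g.standard_normal((40, 40, 40))
        study = ImagingStudy(
            patient_id="phantom", lesion_ids=["L0"], timepoint="BL",
            channel_T1=t1, channel_T2FLAIR=t2,
            gt_masks={"L0": BinaryMask3D(vox, (1.0, 1.0, 1.0))}, spacing_mm=1.0,
        )
        masks = run_cascade(
            study,
            ClassicalSliceSegmenter(sigma=1.0, intensity_cut=0.5),
            ClassicalVolumeSegmenter(sigma=1.0, intensity_cut=0.5),
            ClassicalVolumeSegmenter(sigma=1.5, intensity_cut=0.5),
            self.CFG,
        )
        assert len(masks) == 1
        assert dice_coefficient(masks[0], study.gt_masks["L0"]) >= 0.8

    def test_two_lesions_give_two_disjoint_masks(self):
        cohort = generate_cohort(small_cohort_config(seed=8, lesions_per_patient=(2, 2)))
        study = cohort.studies[0].baseline
        masks = run_cascade(
            study,
            _OracleSliceSegmenter(study),
            _OracleVolumeSegmenter(study),
            _OracleVolumeSegmenter(study),
            self.CFG,
        )
        assert len(masks) == 2
        assert not (masks[0].voxels & masks[1].voxels).any()

    def test_no_detection_returns_empty_list(self, single_lesion_study):
        study = single_lesion_study
        zero = lambda img: np.zeros_like(img, dtype=float)
        masks = run_cascade(study, zero, zero, zero, self.CFG)
        assert masks == []

    def test_determinism(self, single_lesion_study):
        study = single_lesion_study
        args = (
            ClassicalSliceSegmenter(),
            ClassicalVolumeSegmenter(),
            ClassicalVolumeSegmenter(sigma=2.0),
            self.CFG,
        )
        m1 = run_cascade(study, *args)
        m2 = run_cascade(study, *args)
        assert len(m1) == len(m2)
        for a, b in zip(m1, m2):
            assert np.array_equal(a.voxels, b.voxels)
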