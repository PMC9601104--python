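import numpy as np
import pytest

from radres.cohort import ellipsoid_mask
from radres.masks import (
    BinaryMask3D,
    PerturbationError,
    dice_coefficient,
    evaluate_quality,
    hausdorff_distance,
    perturb_amplitude,
    perturb_to_target_dice,
    volume_estimation_error,
)

S05 = (0.5, 0.5, 0.5)


def _mask(voxels, spacing=S05):
    return BinaryMask3D(np.asarray(voxels, dtype=bool), spacing)


def _random_mask(rng, shape=(8, 8, 8), p=0.4, spacing=S05):
    return _mask(rng.random(shape) < p, spacing)


class TestDice:
    def test_identity(self, ball_mask):
        assert dice_coefficient(ball_mask, ball_mask) == 1.0

    def test_disjoint(self):
        a = np.zeros((6, 6, 6), bool)
        b = np.zeros((6, 6, 6), bool)
        a[0, 0, 0] = True
        b[5, 5, 5] = True
        assert dice_coefficient(_mask(a), _mask(b)) == 0.0

    def test_shifted_block(self):
        # 2x2x1 block vs same block shifted 1 voxel along x: overlap 2 of 4
        a = np.zeros((5, 5, 1), bool)
        b = np.zeros((5, 5, 1), bool)
        a[1:3, 1:3, 0] = True
        b[2:4, 1:3, 0] = True
        assert dice_coefficient(_mask(a), _mask(b)) == pytest.approx(0.5)

    def test_matches_set_intersection_oracle(self, rng):
        for _ in range(20):
            a, b = _random_mask(rng), _random_mask(rng)
            if a.is_empty() and b.is_empty():
                continue
            set_a = {tuple(i) for i in np.argwhere(a.voxels)}
            set_b = {tuple(i) for i in np.argwhere(b.voxels)}
            expected = 2 * len(set_a & set_b) / (len(set_a) + len(set_b))
            assert dice_coefficient(a, b) == pytest.approx(expected)

    def test_symmetry(self, rng):
        a, b = _random_mask(rng), _random_mask(rng)
        assert dice_coefficient(a, b) == dice_coefficient(b, a)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            dice_coefficient(_mask(np.ones((3, 3, 3))), _mask(np.ones((4, 4, 4))))

    def test_both_empty_raises(self):
        e = _mask(np.zeros((3, 3, 3)))
        with pytest.raises(ValueError, match="empty"):
            dice_coefficient(e, e)


class TestHausdorff:
    def test_identity_zero(self, ball_mask):
        assert hausdorff_distance(ball_mask, ball_mask) == 0.0

    def test_single_voxels_three_apart(self):
        a = np.zeros((8, 8, 8), bool)
        b = np.zeros((8, 8, 8), bool)
        a[2, 4, 4] = True
        b[5, 4, 4] = True  # 3 voxels apart at 0.5 mm spacing -> 1.5 mm
        assert hausdorff_distance(_mask(a), _mask(b)) == pytest.approx(1.5)

    def test_symmetric_max_of_directed(self, rng):
        from scipy.spatial import cKDTree

        from radres.masks import _surface_points_mm

        a = _random_mask(rng, p=0.3)
        b = _random_mask(rng, p=0.3)
        hd = hausdorff_distance(a, b)
        pa, pb = _surface_points_mm(a), _surface_points_mm(b)
        directed_ab = cKDTree(pb).query(pa)[0].max()
        directed_ba = cKDTree(pa).query(pb)[0].max()
        assert hd == pytest.approx(max(directed_ab, directed_ba))
        assert hd >= directed_ab and hd >= directed_ba
        assert hd == pytest.approx(hausdorff_distance(b, a))


class TestVolumeError:
    def test_identity(self, ball_mask):
        assert volume_estimation_error(ball_mask, ball_mask) == (0.0, 0.0)

    def test_80_vs_100_voxels(self):
        # 20 missing voxels x 0.125 mm^3 = 2.5 mm^3 = 0.0025 cc; 20% of gt
        a = np.zeros((10, 10, 10), bool)
        b = np.zeros((10, 10, 10), bool)
        a.ravel()[:80] = True
        b.ravel()[:100] = True
        cc, pct = volume_estimation_error(_mask(a), _mask(b))
        assert cc == pytest.approx(0.0025)
        assert pct == pytest.approx(20.0)

    def test_spacing_scale_covariance(self, rng):
        a_vox = rng.random((8, 8, 8)) < 0.4
        b_vox = rng.random((8, 8, 8)) < 0.4
        cc1, pct1 = volume_estimation_error(_mask(a_vox), _mask(b_vox))
        cc2, pct2 = volume_estimation_error(
            _mask(a_vox, (1.0, 1.0, 1.0)), _mask(b_vox, (1.0, 1.0, 1.0))
        )
        assert cc2 == pytest.approx(8 * cc1)
        assert pct2 == pytest.approx(pct1)

    def test_empty_gt_raises(self, ball_mask):
        with pytest.raises(ValueError):
            volume_estimation_error(ball_mask, _mask(np.zeros((32, 32, 32))))


def test_quality_identities(ball_mask):
    q = evaluate_quality(ball_mask, ball_mask)
    assert q.dsc == 1.0 and q.hd_mm == 0.0 and q.vee_cc == 0.0 and q.vee_pct == 0.0


class TestPerturbation:
    def test_target_one_returns_input(self, ball_mask):
        out = perturb_to_target_dice(ball_mask, 1.0, seed=5)
        assert np.array_equal(out.voxels, ball_mask.voxels)

    @pytest.mark.parametrize("mode", ["boundary_noise", "morphological", "deformation"])
    def test_target_085_twenty_seeds(self, ball_mask, mode):
        for seed in range(20):
            out = perturb_to_target_dice(ball_mask, 0.85, mode=mode, seed=seed)
            assert 0.84 <= dice_coefficient(out, ball_mask) <= 0.86

    @pytest.mark.parametrize("mode", ["boundary_noise", "morphological", "deformation"])
    def test_amplitude_monotonicity(self, ball_mask, mode):
        # nested family: larger amplitude never increases dice (same seed)
        amplitudes = np.linspace(0.05, 1.2, 8)
        for seed in (0, 1):
            dices = [
                dice_coefficient(
                    perturb_amplitude(ball_mask, a, mode, seed, keep_largest=False), ball_mask
                )
                for a in amplitudes
            ]
            assert all(d1 >= d2 - 1e-12 for d1, d2 in zip(dices, dices[1:]))

    def test_single_connected_component(self, ball_mask):
        from scipy import ndimage

        for seed in range(5):
            out = perturb_to_target_dice(ball_mask, 0.8, mode="deformation", seed=seed)
            _, n = ndimage.label(out.voxels, structure=ndimage.generate_binary_structure(3, 1))
            assert n == 1
            assert not out.is_empty()

    def test_boundary_noise_preserves_centroid(self, ball_mask):
        c0 = np.argwhere(ball_mask.voxels).mean(axis=0)
        for seed in range(10):
            out = perturb_to_target_dice(ball_mask, 0.85, mode="boundary_noise", seed=seed)
            c1 = np.argwhere(out.voxels).mean(axis=0)
            assert np.linalg.norm(c1 - c0) < 2.0

    def test_unreachable_target_reports_achieved(self):
        # a 2-voxel mask cannot hit dice 0.93 within +-0.01
        vox = np.zeros((8, 8, 8), bool)
        vox[3:5, 4, 4] = True
        with pytest.raises(PerturbationError) as exc:
            perturb_to_target_dice(_mask(vox), 0.93, mode="morphological", seed=0)
        assert 0.0 <= exc.value.achieved <= 1.0

    def test_invalid_target(self, ball_mask):
        with pytest.raises(ValueError):
            perturb_to_target_dice(ball_mask, 0.0)
        with pytest.raises(ValueError):
            perturb_to_target_dice(ball_mask, 1.2)
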