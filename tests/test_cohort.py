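import dataclasses

import numpy as np
import pytest
from scipy import stats

from radres.cohort import (
    LC,
    LF,
    CohortConfig,
    GenerationError,
    LesionRecord,
    TextureParams,
    assign_survival,
    ellipsoid_mask,
    generate_cohort,
    render_lesion,
)
from radres.survival import km_curve

from conftest import small_cohort_config


class TestConfig:
    def test_defaults_valid(self):
        CohortConfig().validate()

    def test_lesion_too_large_rejected(self):
        cfg = small_cohort_config(lesion_radius_range=(10.0, 14.0))
        with pytest.raises(GenerationError):
            cfg.validate()

    def test_bad_range_rejected(self):
        with pytest.raises(ValueError):
            small_cohort_config(lesion_radius_range=(6.0, 3.0)).validate()

    def test_tiny_radius_rejected(self):
        with pytest.raises(ValueError):
            small_cohort_config(lesion_radius_range=(1.0, 3.0)).validate()


class TestRenderLesion:
    def test_sphere_voxel_count_matches_lattice_enumeration(self):
        shape, centre, r = (24, 24, 24), (12, 12, 12), 5.0
        _, mask = render_lesion(shape, 1.0, centre, (r, r, r), TextureParams(), seed=0)
        count = 0
        for x in range(shape[0]):
            for y in range(shape[1]):
                for z in range(shape[2]):
                    if (x - 12) ** 2 + (y - 12) ** 2 + (z - 12) ** 2 <= r**2:
                        count += 1
        assert mask.n_foreground == count

    def test_same_seed_identical(self):
        a, _ = render_lesion((20, 20, 20), 1.0, (10, 10, 10), (4, 4, 4), TextureParams(), seed=9)
        b, _ = render_lesion((20, 20, 20), 1.0, (10, 10, 10), (4, 4, 4), TextureParams(), seed=9)
        assert np.array_equal(a, b)

    def test_small_radii_rejected(self):
        with pytest.raises(ValueError):
            render_lesion((20, 20, 20), 1.0, (10, 10, 10), (1.5, 4, 4), TextureParams(), seed=0)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(GenerationError):
            render_lesion((20, 20, 20), 1.0, (2, 10, 10), (4, 4, 4), TextureParams(), seed=0)

    def test_shell_has_distinct_regime(self):
        vol, mask = render_lesion(
            (24, 24, 24), 1.0, (12, 12, 12), (5, 5, 5), TextureParams(), seed=0
        )
        from scipy import ndimage

        dist = ndimage.distance_transform_edt(~mask.voxels)
        shell = (dist > 0) & (dist <= 5.0)
        assert abs(vol[mask.voxels].mean() - vol[shell].mean()) > 0.1


class TestGenerateCohort:
    def test_seed_determinism(self):
        cfg = small_cohort_config(seed=7)
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        assert np.array_equal(a.studies[0].baseline.channel_T1, b.studies[0].baseline.channel_T1)
        assert np.array_equal(
            a.studies[-1].followup.channel_T2FLAIR, b.studies[-1].followup.channel_T2FLAIR
        )
        assert [r.true_outcome for r in a.lesions] == [r.true_outcome for r in b.lesions]
        assert a.split == b.split

    def test_lf_fraction_zero_all_lc(self):
        cohort = generate_cohort(small_cohort_config(lf_fraction=0.0))
        assert all(r.true_outcome == LC for r in cohort.lesions)

    def test_lf_count_within_binomial_interval(self):
        # default patient count (125) at the 63/156 rate, desk-scale volumes
        cfg = small_cohort_config(
            n_train_patients=90, n_val_patients=10, n_test_patients=25, seed=11
        )
        cohort = generate_cohort(cfg)
        n = len(cohort.lesions)
        n_lf = sum(r.true_outcome == LF for r in cohort.lesions)
        p = cfg.lf_fraction
        lo, hi = stats.binom.ppf([0.025, 0.975], n, p)
        assert lo <= n_lf <= hi

    def test_split_is_patient_partition(self):
        cohort = generate_cohort(small_cohort_config())
        cfg = cohort.config
        assert len(cohort.split) == cfg.n_patients
        assert sorted(cohort.split.values()).count("train") == cfg.n_train_patients
        assert sorted(cohort.split.values()).count("val") == cfg.n_val_patients
        assert sorted(cohort.split.values()).count("test") == cfg.n_test_patients
        # every lesion of a patient lives in that patient's single split
        for rec in cohort.lesions:
            assert cohort.split[rec.patient_id] in ("train", "val", "test")

    def test_studies_paired_and_masks_consistent(self):
        cohort = generate_cohort(small_cohort_config(seed=3))
        for pair in cohort.studies:
            assert pair.baseline.timepoint == "BL"
            assert pair.followup.timepoint == "FU1"
            assert pair.baseline.lesion_ids == pair.followup.lesion_ids
            for study in (pair.baseline, pair.followup):
                union = np.zeros(study.channel_T1.shape, dtype=int)
                for mask in study.gt_masks.values():
                    assert not mask.is_empty()
                    assert mask.shape == study.channel_T1.shape
                    union += mask.voxels
                assert union.max() <= 1  # pairwise disjoint

    def test_growth_factor_realised_in_mask_volumes(self):
        cohort = generate_cohort(small_cohort_config(seed=5))
        for rec in cohort.lesions:
            assert rec.bl_volume_cc > 0 and rec.fu1_volume_cc > 0
            ratio = rec.fu1_volume_cc / rec.bl_volume_cc
            # discretization error of roughly one voxel layer on small lesions
            assert ratio == pytest.approx(rec.growth_factor, rel=0.25)
            if rec.true_outcome == LF:
                assert rec.fu1_volume_cc > rec.bl_volume_cc

    def test_null_texture_effect_indistinguishable(self):
        # with effect 0 and equal growth ranges, LF and LC FU1 interiors are
        # draws from the same distribution (pooled two-sample KS)
        lc_vals, lf_vals = [], []
        for seed in range(10):
            cfg = small_cohort_config(
                seed=seed,
                texture_effect_size=0.0,
                lf_fraction=0.5,
                lf_growth_factor_range=(0.9, 1.1),
                lc_change_factor_range=(0.9, 1.1),
            )
            cohort = generate_cohort(cfg)
            outcome = {r.lesion_id: r.true_outcome for r in cohort.lesions}
            for pair in cohort.studies:
                fu = pair.followup
                for lid, mask in fu.gt_masks.items():
                    vals = fu.channel_T1[mask.voxels]
                    (lf_vals if outcome[lid] == LF else lc_vals).append(vals)
        ks = stats.ks_2samp(np.concatenate(lc_vals)[::20], np.concatenate(lf_vals)[::20])
        assert ks.pvalue > 0.01


class TestAssignSurvival:
    @staticmethod
    def _records(n_lc, n_lf):
        recs = []
        for i in range(n_lc):
            recs.append(LesionRecord(f"lc{i}_L0", f"lc{i}", LC, 1.0, 1.0, 1.0))
        for i in range(n_lf):
            recs.append(LesionRecord(f"lf{i}_L0", f"lf{i}", LF, 1.0, 2.0, 2.0))
        return recs

    def test_null_hazard_ratio_logrank_chi2_mean_near_one(self):
        from radres.survival import logrank_test

        stats_ = []
        for seed in range(50):
            recs = self._records(30, 30)
            surv = assign_survival(recs, 0.05, 1.0, censor_time=1e9, seed=seed)
            is_lf = [r.patient_id.startswith("lf") for r in surv]
            res = logrank_test([r.pfs_time for r in surv], [r.event for r in surv], is_lf)
            stats_.append(res.statistic)
        assert np.mean(stats_) == pytest.approx(1.0, abs=0.4)

    def test_tiny_censor_time_censors_everything(self):
        surv = assign_survival(self._records(5, 5), 0.05, 4.0, censor_time=1e-9, seed=0)
        assert all(not r.event for r in surv)
        assert all(r.pfs_time == 1e-9 for r in surv)

    def test_km_median_matches_exponential_closed_form(self):
        # hazard 0.05 * ratio 4 = 0.2/month -> median ln2 / 0.2
        recs = self._records(0, 1000)
        surv = assign_survival(recs, 0.05, 4.0, censor_time=1e9, seed=42)
        curve = km_curve([r.pfs_time for r in surv], [r.event for r in surv])
        median = curve.times[np.searchsorted(-curve.survival, -0.5)]
        assert median == pytest.approx(np.log(2) / 0.2, rel=0.10)

    def test_nonpositive_hazard_rejected(self):
        with pytest.raises(ValueError):
            assign_survival(self._records(1, 1), 0.0, 1.0, 10.0, seed=0)
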