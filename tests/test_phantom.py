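import dataclasses

import numpy as np
import pytest

from petoverlap.imageio import Image3D
from petoverlap.phantom import (
    LABELS,
    CohortParams,
    PhantomParams,
    Study,
    build_anatomy,
    generate_case,
    generate_cohort,
    ideal_uptake,
    misalign,
    plant_recurrence,
    sample_organs,
    synthesize_pet,
    tumor_truth_masks,
)
from petoverlap.registration import RigidTransform

SHAPE = (48, 48, 48)


class TestParamsValidation:
    def test_unordered_suv_levels_rejected(self):
        with pytest.raises(ValueError, match="ordered"):
            PhantomParams(grid_shape=SHAPE, suv_tumor_low=25.0)

    @pytest.mark.parametrize("frac", [0.0, 1.0, 1.4])
    def test_v1_fraction_bounds(self, frac):
        with pytest.raises(ValueError, match="v1_fraction"):
            PhantomParams(grid_shape=SHAPE, v1_fraction=frac)

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError, match="16"):
            PhantomParams(grid_shape=(12, 48, 48))

    def test_negative_psf_rejected(self):
        with pytest.raises(ValueError, match="psf"):
            PhantomParams(grid_shape=SHAPE, psf_fwhm_mm=-1.0)


class TestAnatomy:
    def test_all_organs_present_and_disjoint_labels(self, default_params):
        labels, hu, _ = build_anatomy(default_params, seed=1)
        present = set(np.unique(labels.values))
        for name in ("soft_tissue", "bone", "bladder", "rectum_air", "tumor"):
            assert LABELS[name] in present, f"{name} missing"
        # HU rendering is consistent with the label map
        assert np.all(hu.values[labels.values == LABELS["bone"]] == 700.0)
        assert np.all(hu.values[labels.values == LABELS["exterior"]] == -1000.0)

    def test_seeded_determinism(self, default_params):
        a1, _, _ = build_anatomy(default_params, seed=5)
        a2, _, _ = build_anatomy(default_params, seed=5)
        assert np.array_equal(a1.values, a2.values)

    def test_bladder_fill_scales_voxel_count(self, default_params):
        organs = sample_organs(default_params, np.random.default_rng(2))
        base, _, _ = build_anatomy(default_params, 0, bladder_scale=1.0, organs=organs)
        full, _, _ = build_anatomy(default_params, 0, bladder_scale=1.5, organs=organs)
        n0 = (base.values == LABELS["bladder"]).sum()
        n1 = (full.values == LABELS["bladder"]).sum()
        assert n1 / n0 == pytest.approx(1.5, rel=0.05)


class TestPetSynthesis:
    def test_noise_free_blur_free_equals_ideal(self, default_params):
        params = dataclasses.replace(
            default_params, class_sd=(0.0, 0.0, 0.0), psf_fwhm_mm=0.0
        )
        rng = np.random.default_rng(3)
        organs = sample_organs(params, rng)
        vt, v1 = tumor_truth_masks(params, organs, rng)
        pet = synthesize_pet(organs, {"vt": vt, "v1": v1}, params, seed=1)
        ideal, _ = ideal_uptake(organs, {"vt": vt, "v1": v1}, params)
        assert np.array_equal(pet.values, ideal.values.astype(np.float32))
        assert pet.values[v1].min() == pytest.approx(params.suv_tumor_high)

    def test_fixed_seed_bit_identical(self, default_params):
        rng = np.random.default_rng(4)
        organs = sample_organs(default_params, rng)
        vt, v1 = tumor_truth_masks(default_params, organs, rng)
        a = synthesize_pet(organs, {"vt": vt, "v1": v1}, default_params, seed=9)
        b = synthesize_pet(organs, {"vt": vt, "v1": v1}, default_params, seed=9)
        assert np.array_equal(a.values, b.values)


class TestPlantRecurrence:
    def _setup(self, seed=5, **kw):
        params = PhantomParams(grid_shape=SHAPE, seed=seed, **kw)
        rng = np.random.default_rng(seed)
        organs = sample_organs(params, rng)
        _, v1 = tumor_truth_masks(params, organs, rng)
        return params, organs, v1

    def test_requested_x_y_achieved(self):
        params, organs, v1 = self._setup()
        v1_cc = v1.sum() * 0.064
        v2_cc = 0.70 * v1_cc / 0.77  # consistent with X=0.70, Y=0.77
        params = dataclasses.replace(
            params, overlap_target_x=0.70, overlap_target_y=0.77, v2_target_cc=v2_cc
        )
        v2, ach = plant_recurrence(v1, params, organs, np.random.default_rng(1))
        assert 0.68 <= ach["x"] <= 0.72
        assert 0.75 <= ach["y"] <= 0.79

    def test_full_containment_when_x_is_one(self):
        params, organs, v1 = self._setup()
        v1_cc = v1.sum() * 0.064
        params = dataclasses.replace(
            params, overlap_target_x=1.0, overlap_target_y=None,
            v2_target_cc=1.3 * v1_cc,
        )
        v2, ach = plant_recurrence(v1, params, organs, np.random.default_rng(1))
        assert not np.any(v1 & ~v2), "V2 must contain V1 entirely"
        assert ach["x"] == pytest.approx(1.0)

    def test_zero_targets_give_disjoint_masks(self):
        params, organs, v1 = self._setup()
        params = dataclasses.replace(
            params, overlap_target_x=0.0, overlap_target_y=0.0
        )
        v2, ach = plant_recurrence(v1, params, organs, np.random.default_rng(1))
        assert not np.any(v1 & v2)
        assert ach["dice"] == 0.0

    def test_inconsistent_targets_rejected(self):
        params, organs, v1 = self._setup()
        # X*|V1| far exceeds |V2| while Y demands a small intersection
        params = dataclasses.replace(
            params, overlap_target_x=0.9, overlap_target_y=0.2, v2_target_cc=5.0
        )
        with pytest.raises(ValueError, match="infeasible"):
            plant_recurrence(v1, params, organs, np.random.default_rng(1))


class TestMisalign:
    def _crisp_study(self):
        vals = np.zeros((40, 40, 40), np.float32)
        vals[16:24, 16:24, 16:24] = 10.0
        pet = Image3D(vals, (2, 2, 2), origin_mm=(-39, -39, -39), units="SUV")
        ct = Image3D(vals * 10 - 500, (2, 2, 2), origin_mm=(-39, -39, -39), units="HU")
        return Study(pet=pet, ct=ct)

    def test_identity_transform_is_noop_up_to_interpolation(self):
        study = self._crisp_study()
        out = misalign(study, RigidTransform())
        assert np.allclose(out.pet.values, study.pet.values, atol=1e-3)

    def test_translation_moves_centroid(self):
        study = self._crisp_study()
        t = RigidTransform(translation_mm=(5.0, 0.0, 0.0))
        out = misalign(study, t)

        def centroid(img):
            w = img.values.astype(float)
            idx = np.indices(img.shape).reshape(3, -1).T
            return (w.reshape(-1, 1) * idx).sum(0) / w.sum() * 2.0  # mm

        shift = centroid(out.pet) - centroid(study.pet)
        # resampling through the inverse moves content by +t in world space,
        # so registering the moved study recovers t itself
        assert shift[0] == pytest.approx(5.0, abs=0.5)
        assert abs(shift[1]) < 0.5 and abs(shift[2]) < 0.5


class TestGenerateCase:
    def test_truth_volumes_near_targets(self, default_case, default_params):
        _, _, truth = default_case
        voxvol = truth.vt_mask.voxel_volume_cc
        vt_cc = truth.vt_mask.values.sum() * voxvol
        v1_cc = truth.v1_mask.values.sum() * voxvol
        assert vt_cc == pytest.approx(default_params.vt_target_cc, rel=0.2)
        # 43% of 41.9 cc: the high-uptake sub-volume lands near 18 cc
        assert v1_cc == pytest.approx(18.0, rel=0.2)

    def test_v1_inside_vt_and_masks_nonempty(self, default_case):
        _, _, truth = default_case
        v1 = truth.v1_mask.values > 0
        vt = truth.vt_mask.values > 0
        assert not np.any(v1 & ~vt)
        assert v1.sum() > 0 and truth.v2_mask.values.sum() > 0

    def test_achieved_indices_match_mask_counts(self, default_case):
        _, _, truth = default_case
        v1 = truth.v1_mask.values > 0
        v2 = truth.v2_mask.values > 0
        inter = (v1 & v2).sum()
        assert truth.achieved_x == pytest.approx(inter / v1.sum())
        assert truth.achieved_y == pytest.approx(inter / v2.sum())

    def test_bit_identical_on_repeat(self, default_params):
        b1, r1, _ = generate_case(default_params)
        b2, r2, _ = generate_case(default_params)
        assert np.array_equal(b1.pet.values, b2.pet.values)
        assert np.array_equal(r1.ct.values, r2.ct.values)

    def test_different_seeds_differ_but_share_topology(self, default_params):
        p2 = dataclasses.replace(default_params, seed=99)
        b1, _, t1 = generate_case(default_params)
        b2, _, t2 = generate_case(p2)
        assert not np.array_equal(b1.pet.values, b2.pet.values)
        for t in (t1, t2):
            assert not np.any((t.v1_mask.values > 0) & ~(t.vt_mask.values > 0))


class TestCohort:
    def test_flag_allocation_deterministic(self):
        cp = CohortParams(base=PhantomParams(grid_shape=SHAPE), v2_gt_v1_fraction=1 / 3)
        _, manifest = generate_cohort(21, cp, seed=5)
        flags = sum(r["v2_gt_v1_planted"] for r in manifest["cases"])
        assert flags == 7

    def test_manifest_reproducible(self):
        cp = CohortParams(base=PhantomParams(grid_shape=SHAPE))
        _, m1 = generate_cohort(4, cp, seed=8)
        _, m2 = generate_cohort(4, cp, seed=8)
        assert m1 == m2

    def test_single_case_cohort(self):
        cases, manifest = generate_cohort(1, CohortParams(base=PhantomParams(grid_shape=SHAPE)), seed=0)
        assert len(cases) == 1 and manifest["cases"][0]["case_id"] == "case_000"

    @pytest.mark.parametrize("n", [0, -3])
    def test_empty_cohort_rejected(self, n):
        with pytest.raises(ValueError, match="at least 1"):
            generate_cohort(n, CohortParams(), seed=0)

    def test_planted_flag_matches_ground_truth(self):
        cp = CohortParams(base=PhantomParams(grid_shape=SHAPE), v2_gt_v1_fraction=0.5)
        cases, manifest = generate_cohort(4, cp, seed=2)
        for rec, params in zip(manifest["cases"], cases):
            _, _, truth = generate_case(params)
            is_gt = truth.v2_mask.values.sum() > truth.v1_mask.values.sum()
            assert bool(is_gt) == rec["v2_gt_v1_planted"]
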