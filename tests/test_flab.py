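import numpy as np
import pytest

from petoverlap.flab import (
    BoxROI,
    FlabModel,
    FlabOptions,
    SegmentationResult,
    estimate_local_priors,
    flab_segment,
    init_params,
    label_density,
    masks_from_segmentation,
    select_roi,
    threshold_segment,
)
from petoverlap.imageio import Image3D
from petoverlap.overlap import overlap_metrics


def _suv_image(vals, spacing=(4, 4, 4)):
    return Image3D(np.asarray(vals, np.float32), spacing, units="SUV")


def _three_level_image(rng=None, shape=(26, 26, 26), levels=(2.0, 8.0, 16.0), sd=0.0):
    """Nested-sphere test image: background, shell, core.

    Proportioned like a tight tumor ROI box (the sphere nearly fills the
    box), which is what automatic ROI selection hands the segmenter."""
    vals = np.full(shape, levels[0])
    idx = np.indices(shape, dtype=float)
    r2 = sum((idx[i] - (shape[i] - 1) / 2) ** 2 for i in range(3))
    shell = r2 <= 10.5**2
    core = r2 <= 6.5**2
    vals[shell] = levels[1]
    vals[core] = levels[2]
    if sd > 0:
        vals = vals + rng.normal(0, sd, shape)
    return _suv_image(vals), shell, core


class TestInitParams:
    def test_bimodal_sample_initialises_at_modes(self):
        y = np.array([2.0] * 200 + [8.0] * 200)
        means, sds = init_params(y, 2)
        assert means[0] == pytest.approx(2.0, abs=0.5)
        assert means[1] == pytest.approx(8.0, abs=0.5)
        assert np.all(sds > 0)

    def test_three_level_sample_gives_ascending_means(self):
        y = np.array([1.0] * 300 + [6.0] * 100 + [19.0] * 60)
        means, _ = init_params(y, 3)
        assert np.all(np.diff(means) > 0)

    def test_too_few_voxels_rejected(self):
        with pytest.raises(ValueError, match="voxels"):
            init_params(np.arange(5.0), 2)

    def test_constant_roi_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            init_params(np.full(100, 3.0), 2)


class TestLabelDensity:
    def _model(self, means=(0.0, 10.0), sds=(1.0, 1.0)):
        return FlabModel(
            n_classes=2, fuzzy_levels=(0.25, 0.5, 0.75),
            class_means=np.array(means), class_sds=np.array(sds),
            labels=[(0, 0.0), (0, 0.25), (0, 0.5), (0, 0.75), (1, 0.0)],
            iterations=0, final_rel_change=0.0, converged=True,
        )

    def test_eps_limits_reduce_to_hard_classes(self):
        m = self._model()
        y = 3.7
        assert label_density(y, (0, 1e-12), m) == pytest.approx(
            label_density(y, (0, 0.0), m), rel=1e-6
        )
        # eps -> 1 approaches the upper class density
        near_one = label_density(y, (0, 1 - 1e-9), m)
        upper = label_density(y, (1, 0.0), m)
        assert near_one == pytest.approx(upper, rel=1e-6)

    def test_half_blend_mean_and_variance(self):
        m = self._model()
        # mean 5, variance 0.25+0.25 = 0.5
        dens = label_density(5.0, (0, 0.5), m)
        expected = 1.0 / np.sqrt(2 * np.pi * 0.5)
        assert dens == pytest.approx(expected, rel=1e-9)

    def test_symmetry_under_class_swap(self):
        m = self._model()
        y = np.linspace(-3, 13, 33)
        d1 = label_density(y, (0, 0.25), m)
        d2 = label_density(10.0 - y, (0, 0.75), m)
        assert np.allclose(d1, d2)

    def test_positive_within_float_range(self):
        m = self._model()
        assert label_density(20.0, (0, 0.5), m) > 0


class TestLocalPriors:
    def test_uniform_posteriors_are_a_fixed_point(self):
        post = np.full((5, 5, 5, 4), 0.25)
        prior = estimate_local_priors(post)
        assert np.allclose(prior, 0.25)

    def test_priors_sum_to_one(self):
        rng = np.random.default_rng(0)
        post = rng.dirichlet(np.ones(5), size=(6, 6, 6))
        prior = estimate_local_priors(post)
        assert np.allclose(prior.sum(axis=-1), 1.0, atol=1e-9)

    def test_homogeneous_neighbourhood_dominates(self):
        lam = 0.1
        post = np.zeros((5, 5, 5, 2))
        post[..., 1] = 1.0  # everything class 1
        prior = estimate_local_priors(post, lam)
        # blend of full local support and the global frequency (also 1)
        assert np.all(prior[..., 1] >= 0.9 * (1 - lam) + lam * 0.0)


class TestSelectRoi:
    def test_roi_contains_ground_truth_tumor(self, default_case):
        baseline, _, truth = default_case
        roi = select_roi(baseline.pet, "auto",
                         exclude_box=truth.bladder_exclusion_box())
        assert roi.contains_mask(truth.vt_mask.values)

    def test_user_box_too_small_rejected(self):
        with pytest.raises(ValueError, match="3 voxels"):
            BoxROI((0, 0, 0), (2, 5, 5))

    def test_background_only_image_rejected(self):
        img = _suv_image(np.ones((16, 16, 16)))
        with pytest.raises(ValueError, match="no uptake"):
            select_roi(img, "auto")

    def test_requires_suv_units(self):
        img = Image3D(np.ones((16, 16, 16)), (4, 4, 4), units="HU")
        with pytest.raises(ValueError, match="SUV"):
            select_roi(img, "auto")


class TestFlabSegment:
    def test_noiseless_two_level_recovered_exactly(self):
        img, shell, _ = _three_level_image(levels=(1.0, 12.0, 12.0))
        roi = BoxROI((0, 0, 0), img.shape)
        seg = flab_segment(img, roi, K=2)
        assert seg.model.class_means == pytest.approx([1.0, 12.0], abs=1e-6)
        assert np.array_equal(seg.v2_mask.values > 0, shell)

    def test_three_class_parameter_and_mask_recovery(self):
        rng = np.random.default_rng(7)
        img, shell, core = _three_level_image(rng, sd=1.0)
        roi = BoxROI((0, 0, 0), img.shape)
        seg = flab_segment(img, roi, K=3)
        assert np.allclose(seg.model.class_means, (2.0, 8.0, 16.0), atol=0.5)
        dice_v1 = overlap_metrics(
            seg.v1_mask.values, core, spacing_mm=img.spacing_mm
        ).dice
        assert dice_v1 >= 0.85

    def test_v1_nested_in_vt(self):
        rng = np.random.default_rng(8)
        img, _, _ = _three_level_image(rng, sd=1.0)
        seg = flab_segment(img, BoxROI((0, 0, 0), img.shape), K=3)
        v1 = seg.v1_mask.values > 0
        vt = seg.vt_mask.values > 0
        assert not np.any(v1 & ~vt)

    def test_deterministic(self):
        rng = np.random.default_rng(9)
        img, _, _ = _three_level_image(rng, sd=1.0)
        roi = BoxROI((0, 0, 0), img.shape)
        s1 = flab_segment(img, roi, K=3)
        s2 = flab_segment(img, roi, K=3)
        assert np.array_equal(s1.label_volume, s2.label_volume)

    def test_invalid_k_rejected(self):
        img, _, _ = _three_level_image()
        with pytest.raises(ValueError, match="K"):
            flab_segment(img, BoxROI((0, 0, 0), img.shape), K=4)


class TestMasksFromLabels:
    def _crafted_seg(self, label_idx, K=3, shape=(6, 6, 6)):
        """Segmentation with every ROI voxel carrying one fixed label."""
        levels = (0.25, 0.5, 0.75)
        labels = []
        for k in range(K - 1):
            labels.append((k, 0.0))
            labels.extend((k, e) for e in levels)
        labels.append((K - 1, 0.0))
        model = FlabModel(
            n_classes=K, fuzzy_levels=levels,
            class_means=np.arange(1.0, K + 1), class_sds=np.ones(K),
            labels=labels, iterations=1, final_rel_change=0.0, converged=True,
        )
        vol = np.full(shape, label_idx, dtype=np.int16)
        return SegmentationResult(
            label_volume=vol, model=model, roi=BoxROI((0, 0, 0), shape)
        ), labels

    def test_all_top_class_makes_v1_equal_vt_equal_roi(self):
        seg, labels = self._crafted_seg(label_idx=8)  # hard class 3
        img = _suv_image(np.full((6, 6, 6), 10.0))
        out = masks_from_segmentation(seg, img, K=3)
        assert np.all(out.v1_mask.values == 1)
        assert np.all(out.vt_mask.values == 1)

    def test_low_fuzzy_level_excluded_from_v1_included_in_vt(self):
        seg, labels = self._crafted_seg(label_idx=5)  # fuzzy(2,3) eps=0.25
        # give one voxel the top class so V1 is non-empty and holds the seed
        seg.label_volume[3, 3, 3] = 8
        img = _suv_image(np.full((6, 6, 6), 5.0))
        img.values[3, 3, 3] = 10.0
        out = masks_from_segmentation(seg, img, K=3)
        assert out.v1_mask.values.sum() == 1  # only the seeded top-class voxel
        assert np.all(out.vt_mask.values == 1)  # fuzzy tumor voxels all in VT


class TestThresholdSegment:
    def test_uniform_roi_selects_everything(self):
        img = _suv_image(np.full((8, 8, 8), 5.0))
        roi = BoxROI((0, 0, 0), (8, 8, 8))
        mask = threshold_segment(img, roi, 40.0)
        assert np.all(mask.values == 1)

    def test_masks_nest_with_increasing_percentage(self, default_case):
        baseline, _, truth = default_case
        roi = select_roi(baseline.pet, "auto",
                         exclude_box=truth.bladder_exclusion_box())
        m40 = threshold_segment(baseline.pet, roi, 40.0).values > 0
        m70 = threshold_segment(baseline.pet, roi, 70.0).values > 0
        assert not np.any(m70 & ~m40)

    @pytest.mark.parametrize("pct", [0.0, 100.0, -5.0])
    def test_percentage_bounds(self, pct):
        img = _suv_image(np.full((8, 8, 8), 5.0))
        with pytest.raises(ValueError):
            threshold_segment(img, BoxROI((0, 0, 0), (8, 8, 8)), pct)
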