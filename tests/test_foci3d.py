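"""Focus detection against brute-force oracles, plus volumetric invariants."""

import numpy as np
import pytest

from _oracles import flood_fill_components
from otoquant.errors import (
    BackgroundEstimationError,
    DegenerateThresholdWarning,
    EmptyMaskError,
)
from otoquant.foci3d import (
    BackgroundModel,
    classify_pan_stained,
    colocalize,
    detect_foci,
    estimate_background,
    summarize_foci,
)
from otoquant.synthetic_data import SimulationConfig, make_coloc_stack, make_nucleus_stack
from otoquant.types import ImageStack3D, NucleusMask


def full_mask(stack):
    return NucleusMask(np.ones(stack.intensities.shape[1:], dtype=bool))


class TestEstimateBackground:
    def test_constant_stack(self):
        stack = ImageStack3D(np.full((4, 4, 4), 7.0), (0.1, 0.1, 0.1))
        with pytest.warns(DegenerateThresholdWarning):
            m = estimate_background(stack, full_mask(stack), k=3)
        assert m.f0_mean == 7.0
        assert m.f0_sd == 0.0
        assert m.threshold > 7.0

    def test_gaussian_background_threshold(self):
        rng = np.random.default_rng(0)
        img = rng.normal(10.0, 2.0, size=(20, 20, 20))
        stack = ImageStack3D(img, (0.1, 0.1, 0.1))
        m = estimate_background(stack, full_mask(stack), k=3)
        assert m.f0_mean == pytest.approx(10.0, abs=0.2)
        assert m.f0_sd == pytest.approx(2.0, abs=0.2)
        assert m.threshold == pytest.approx(16.0, abs=0.8)

    def test_robust_to_bright_foci_minority(self, noisy_config):
        stack, mask, _ = make_nucleus_stack(5, config=noisy_config)
        m = estimate_background(stack, mask, k=3)
        assert m.f0_mean == pytest.approx(noisy_config.background_mean, abs=1.5)

    def test_empty_mask_raises(self):
        stack = ImageStack3D(np.zeros((4, 4, 4)), (0.1, 0.1, 0.1))
        with pytest.raises(EmptyMaskError):
            estimate_background(stack, NucleusMask(np.zeros((4, 4, 4), bool)))

    def test_no_background_support_raises(self):
        # tiny mask of strictly increasing bright values: nothing at/below
        # the robust threshold support
        img = np.zeros((2, 2, 2))
        img.flat = [100, 200, 300, 400, 500, 600, 700, 800]
        stack = ImageStack3D(img, (0.1, 0.1, 0.1))
        with pytest.raises(BackgroundEstimationError):
            estimate_background(stack, full_mask(stack), k=0.1)


class TestDetectFoci:
    def test_all_zero_stack_no_foci(self):
        stack = ImageStack3D(np.zeros((6, 6, 6)), (0.1, 0.1, 0.1))
        model = BackgroundModel(0.0, 0.0, 3.0, 0.5)
        assert detect_foci(stack, full_mask(stack), model=model) == []

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle_random_stacks(self, connectivity):
        """Voxel sets equal an independent BFS flood fill on random stacks."""
        rng = np.random.default_rng(42)
        for _ in range(10):
            img = rng.random((10, 12, 11))
            stack = ImageStack3D(img, (0.2, 0.1, 0.1))
            model = BackgroundModel(0.0, 0.0, 0.0, 0.7)
            foci = detect_foci(stack, full_mask(stack), model=model,
                               min_voxels=1, connectivity=connectivity)
            oracle = flood_fill_components(img > 0.7, connectivity)
            got = {frozenset(f.voxel_set()) for f in foci}
            expect = {frozenset((int(z), int(y), int(x)) for z, y, x in c)
                      for c in oracle}
            assert got == expect

    def test_synthetic_spheres_recovered_exactly(self, clean_config):
        stack, mask, truth = make_nucleus_stack(5, config=clean_config)
        model = estimate_background(stack, mask, k=3)
        foci = detect_foci(stack, mask, model=model)
        assert len(foci) == truth.true_count
        assert sorted(f.n_voxels for f in foci) == sorted(truth.foci_voxel_counts)

    def test_corner_touching_spheres_merge_under_26(self):
        img = np.zeros((6, 6, 6))
        img[1, 1, 1] = img[2, 2, 2] = 1.0  # corner-adjacent voxels
        stack = ImageStack3D(img, (0.1, 0.1, 0.1))
        model = BackgroundModel(0.0, 0.0, 0.0, 0.5)
        assert len(detect_foci(stack, full_mask(stack), model=model, min_voxels=1)) == 1
        assert len(detect_foci(stack, full_mask(stack), model=model,
                               min_voxels=1, connectivity=6)) == 2

    def test_min_voxels_filters_singletons(self):
        img = np.zeros((6, 6, 6))
        img[1, 1, 1] = 1.0
        img[4, 4, 3:5] = 1.0
        stack = ImageStack3D(img, (0.1, 0.1, 0.1))
        model = BackgroundModel(0.0, 0.0, 0.0, 0.5)
        foci = detect_foci(stack, full_mask(stack), model=model, min_voxels=2)
        assert len(foci) == 1
        assert foci[0].n_voxels == 2

    def test_volume_conservation_at_min_voxels_1(self, clean_config):
        """Sum of per-focus volumes equals total suprathreshold in-mask volume."""
        stack, mask, _ = make_nucleus_stack(7, config=clean_config)
        model = estimate_background(stack, mask, k=3)
        foci = detect_foci(stack, mask, model=model, min_voxels=1)
        supra = ((stack.channel(0) > model.threshold) & mask.mask).sum()
        total = sum(f.volume_um3 for f in foci)
        assert total == pytest.approx(supra * stack.voxel_volume_um3)

    def test_raising_threshold_never_increases_volume(self, noisy_config):
        stack, mask, _ = make_nucleus_stack(5, config=noisy_config)
        vols = []
        for thr in [20.0, 50.0, 80.0, 110.0]:
            model = BackgroundModel(10.0, 1.0, 0.0, thr)
            foci = detect_foci(stack, mask, model=model, min_voxels=1)
            vols.append(sum(f.volume_um3 for f in foci))
        assert all(a >= b for a, b in zip(vols, vols[1:]))


class TestSummaries:
    def test_empty_summary(self):
        s = summarize_foci([], nucleus_id=3)
        assert (s.count, s.total_volume_um3) == (0, 0.0)

    def test_cube_volume_arithmetic(self):
        img = np.zeros((5, 5, 5))
        img[1:4, 1:4, 1:4] = 1.0  # 27-voxel cube
        stack = ImageStack3D(img, (0.1, 0.1, 0.1))
        model = BackgroundModel(0.0, 0.0, 0.0, 0.5)
        foci = detect_foci(stack, full_mask(stack), model=model)
        s = summarize_foci(foci)
        assert s.total_volume_um3 == pytest.approx(0.027)

    def test_matches_ground_truth_noiseless(self, clean_config):
        stack, mask, truth = make_nucleus_stack(8, config=clean_config)
        model = estimate_background(stack, mask, k=3)
        s = summarize_foci(detect_foci(stack, mask, model=model))
        assert s.count == truth.true_count
        assert s.total_volume_um3 == pytest.approx(truth.true_total_volume_um3)


class TestPanStaining:
    def _stack_with_fraction(self, frac):
        img = np.zeros((10, 10, 10))
        n = int(frac * 1000)
        img.flat[:n] = 100.0
        return ImageStack3D(img, (0.1, 0.1, 0.1))

    def test_fully_positive_nucleus(self):
        stack = self._stack_with_fraction(1.0)
        model = BackgroundModel(0.0, 1.0, 3.0, 3.0)
        c = classify_pan_stained(stack, full_mask(stack), model=model)
        assert c.pan_stained and c.positive_fraction == 1.0

    def test_negative_nucleus(self):
        stack = self._stack_with_fraction(0.0)
        model = BackgroundModel(0.0, 1.0, 3.0, 3.0)
        c = classify_pan_stained(stack, full_mask(stack), model=model)
        assert not c.pan_stained and c.positive_fraction == 0.0

    def test_partial_fraction_cutoff(self):
        stack = self._stack_with_fraction(0.6)
        model = BackgroundModel(0.0, 1.0, 3.0, 3.0)
        c = classify_pan_stained(stack, full_mask(stack), model=model,
                                 fraction_cutoff=0.5)
        assert c.pan_stained and c.positive_fraction == pytest.approx(0.6)

    def test_raising_threshold_never_raises_fraction(self, noisy_config):
        stack, mask, _ = make_nucleus_stack(5, config=noisy_config)
        fracs = []
        for thr in [15.0, 50.0, 115.0]:
            model = BackgroundModel(10.0, 1.0, 0.0, thr)
            fracs.append(classify_pan_stained(stack, mask, model=model).positive_fraction)
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))


class TestColocalization:
    def _detect_both(self, stack, mask):
        ma = estimate_background(stack, mask, "A", k=3)
        mb = estimate_background(stack, mask, "B", k=3)
        return (detect_foci(stack, mask, "A", ma), detect_foci(stack, mask, "B", mb))

    def test_identity_100pct(self, clean_config):
        stack, mask, _ = make_nucleus_stack(4, config=clean_config)
        model = estimate_background(stack, mask, k=3)
        foci = detect_foci(stack, mask, model=model)
        assert colocalize(foci, foci).fraction_pct == 100.0

    def test_disjoint_0pct(self, clean_config):
        stack, mask, _ = make_coloc_stack(5, 5, 0, config=clean_config)
        fa, fb = self._detect_both(stack, mask)
        assert colocalize(fa, fb).fraction_pct == 0.0

    def test_designed_30pct(self, clean_config):
        stack, mask, _ = make_coloc_stack(10, 10, 3, config=clean_config)
        fa, fb = self._detect_both(stack, mask)
        res = colocalize(fa, fb)
        assert res.fraction_pct == 30.0

    def test_empty_a_is_undefined_not_zero(self):
        assert colocalize([], []).fraction_pct is None

    def test_monotone_in_overlap_and_order_invariant(self, clean_config):
        fracs = []
        for k in (0, 2, 4):
            stack, mask, _ = make_coloc_stack(6, 6, k, config=clean_config)
            fa, fb = self._detect_both(stack, mask)
            res = colocalize(fa, fb)
            assert res.fraction_pct == colocalize(fa[::-1], fb[::-1]).fraction_pct
            fracs.append(res.fraction_pct)
        assert fracs == sorted(fracs)
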