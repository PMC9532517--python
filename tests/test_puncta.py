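import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from skimage.draw import disk

from synquant.puncta import (
    PunctaResult,
    ThresholdSpec,
    colocalize,
    detect_puncta,
    quantify_image,
    synapse_density,
    threshold_mask,
)


from _oracles import flood_fill_count, pixel_loop_and


class TestThresholdMask:
    def test_ten_pixel_arithmetic_example(self):
        # nine pixels of 10 and one of 110: mean 20, population SD 30,
        # threshold at k=2 is 80, so exactly the 110 pixel is selected
        img = np.array([[10.0] * 9 + [110.0]])
        assert img.mean() == 20 and img.std() == 30
        mask = threshold_mask(img, k=2, sd_kind="population")
        assert mask.sum() == 1 and mask[0, 9]

    def test_constant_image_empty_mask(self):
        img = np.full((16, 16), 42.0)
        for k in (0.0, 1.0, 2.0):
            assert not threshold_mask(img, k).any()

    def test_sample_vs_population_sd(self):
        img = np.array([[10.0] * 9 + [110.0]])
        # sample SD is larger, so the threshold rises but the outlier stays
        assert threshold_mask(img, 2, "sample").sum() == 1

    @given(
        a=st.floats(min_value=0.1, max_value=50.0),
        b=st.floats(min_value=-100.0, max_value=100.0),
        k=st.floats(min_value=0.0, max_value=3.0),
    )
    def test_affine_intensity_invariance(self, a, b, k):
        rng = np.random.default_rng(7)
        img = rng.normal(100.0, 20.0, (24, 24))
        np.testing.assert_array_equal(
            threshold_mask(img, k), threshold_mask(a * img + b, k)
        )

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            threshold_mask(np.empty((0, 0)), 2)


class TestColocalize:
    def test_idempotent_on_identical_masks(self, rng):
        m = rng.random((16, 16)) > 0.5
        np.testing.assert_array_equal(colocalize(m, m, m), m)

    def test_disjoint_masks_empty(self):
        a = np.zeros((8, 8), dtype=bool)
        b = np.zeros((8, 8), dtype=bool)
        a[:4], b[4:] = True, True
        assert not colocalize(a, b).any()

    def test_matches_pixel_loop_oracle(self, rng):
        masks = [rng.random((64, 64)) > 0.4 for _ in range(3)]
        np.testing.assert_array_equal(colocalize(*masks), pixel_loop_and(*masks))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            colocalize(np.zeros((4, 4), bool), np.zeros((5, 4), bool))


class TestDetectPuncta:
    def test_disk_below_size_limit_retained(self):
        mask = np.zeros((200, 200), dtype=bool)
        rr, cc = disk((100, 100), 12.5)  # 5 μm diameter at 0.2 μm/px
        mask[rr, cc] = True
        objs = detect_puncta(mask, pixel_size=0.2)
        assert len(objs) == 1
        assert objs[0].equivalent_diameter_um == pytest.approx(5.0, rel=0.05)

    def test_disk_above_size_limit_filtered(self):
        mask = np.zeros((200, 200), dtype=bool)
        rr, cc = disk((100, 100), 30)  # 12 μm diameter at 0.2 μm/px
        mask[rr, cc] = True
        assert detect_puncta(mask, pixel_size=0.2) == []

    def test_exact_boundary_diameter_removed(self):
        # equivalent diameter exactly at the limit is excluded (strictly-below rule)
        side = 25  # square of 625 px: eq. diameter = sqrt(4*625/pi) px
        px = 10.0 / np.sqrt(4 * side**2 / np.pi)  # pixel size making it exactly 10 μm
        mask = np.zeros((40, 40), dtype=bool)
        mask[5 : 5 + side, 5 : 5 + side] = True
        assert detect_puncta(mask, pixel_size=px, size_limit=10.0) == []
        # and it is retained under any slightly larger limit
        assert len(detect_puncta(mask, pixel_size=px, size_limit=10.0 + 1e-9)) == 1

    def test_min_area_filter(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[2, 2] = True
        mask[5:7, 5:7] = True
        assert len(detect_puncta(mask, 0.2, min_area_px=2)) == 1
        assert len(detect_puncta(mask, 0.2, min_area_px=1)) == 2

    def test_count_matches_flood_fill_oracle(self, rng):
        mask = rng.random((64, 64)) > 0.7
        objs = detect_puncta(mask, pixel_size=0.2)
        assert len(objs) == flood_fill_count(mask)


class TestSynapseDensity:
    def test_division(self):
        objs = detect_puncta(np.eye(12, dtype=bool), 1.0)  # one diagonal component
        result = synapse_density(objs * 12, dendrite_length=50.0)
        assert result.density == pytest.approx(12 / 50.0)

    def test_zero_objects(self):
        assert synapse_density([], 30.0).density == 0.0

    def test_rejects_nonpositive_length(self):
        with pytest.raises(ValueError):
            synapse_density([], 0.0)


class TestQuantifyImage:
    def test_recovers_density_within_tolerance(self, rendered_small, small_sim_config):
        image_set, truth = rendered_small
        result = quantify_image(image_set, truth.to_trace())
        assert isinstance(result, PunctaResult)
        assert result.density == pytest.approx(truth.true_density, rel=0.15)

    def test_deterministic(self, rendered_small):
        image_set, truth = rendered_small
        r1 = quantify_image(image_set, truth.to_trace())
        r2 = quantify_image(image_set, truth.to_trace())
        assert r1.count == r2.count and r1.density == r2.density

    def test_dual_mode_counts_at_least_triple(self, rendered_small):
        image_set, truth = rendered_small
        triple = quantify_image(image_set, truth.to_trace(), mode="triple")
        dual = quantify_image(image_set, truth.to_trace(), mode="dual")
        assert dual.count >= triple.count

    def test_density_monotone_in_truth(self):
        # mean estimate strictly increasing over true densities at default SNR
        from synquant.simulate import SimConfig, generate_neuron_image

        means = []
        for dens in (0.1, 0.25, 0.5):
            ests = []
            for seed in range(3):
                cfg = SimConfig(
                    image_shape=(512, 512), n_branches=4,
                    branch_length_range=(25.0, 40.0), true_density=dens, seed=seed,
                )
                image_set, truth = generate_neuron_image(cfg)
                ests.append(quantify_image(image_set, truth.to_trace()).density)
            means.append(np.mean(ests))
        assert means[0] < means[1] < means[2]

    def test_bad_mode(self, rendered_small):
        image_set, truth = rendered_small
        with pytest.raises(ValueError):
            quantify_image(image_set, truth.to_trace(), mode="quadruple")


def test_threshold_spec_validation():
    with pytest.raises(ValueError):
        ThresholdSpec(k_puncta=-1)
    with pytest.raises(ValueError):
        ThresholdSpec(sd_kind="robust")
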