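"""Simulator tests: weight masks, survival-time law, censoring, bag building."""

import numpy as np
import pytest

from dalan.simulator import (
    ROIImage, SimulationConfig, WeightMask, apply_censoring, build_simulation,
    generate_weight_mask, oracle_patient_risk, patient_survival_time,
    roi_survival_time, synth_digit_images, synth_texture_images,
)
from dalan.survival import concordance_index


class TestWeightMask:
    def test_deterministic_given_seed(self):
        a = generate_weight_mask((28, 28, 1), seed=7)
        b = generate_weight_mask((28, 28, 1), seed=7)
        np.testing.assert_array_equal(a.weights, b.weights)
        assert not np.array_equal(a.weights, generate_weight_mask((28, 28, 1), 8).weights)

    def test_uniform_mean_large_sample(self):
        m = generate_weight_mask((100, 100, 100), seed=1)
        assert m.weights.mean() == pytest.approx(0.5, abs=0.01)
        assert m.weights.min() >= 0.0 and m.weights.max() <= 1.0

    def test_nonpositive_dimension_errors(self):
        with pytest.raises(ValueError):
            generate_weight_mask((0, 28, 1), seed=0)


class TestRoiSurvivalTime:
    def test_zero_image_monte_carlo_median(self):
        # T = exp(noise_scale * eps) with eps log-normal; median eps = 1
        img = ROIImage(np.zeros((8, 8, 1)))
        mask = generate_weight_mask((8, 8, 1), seed=0)
        rng = np.random.default_rng(123)
        draws = [roi_survival_time(img, mask, 0.001, rng) for _ in range(100_000)]
        assert np.median(draws) == pytest.approx(np.exp(0.001), abs=0.002)

    def test_all_ones_no_noise_gives_e(self):
        img = ROIImage(np.ones((4, 4, 1)))
        mask = WeightMask(weights=np.ones((4, 4, 1)), seed=0)
        t = roi_survival_time(img, mask, noise_scale=0.0, rng=np.random.default_rng(0))
        assert t == pytest.approx(np.e, rel=1e-12)

    def test_monotone_in_pixelwise_dominance(self):
        rng = np.random.default_rng(5)
        mask = generate_weight_mask((6, 6, 1), seed=2)
        a = rng.uniform(0.0, 0.5, size=(6, 6, 1))
        b = a.copy()
        b[2, 3, 0] += 0.3
        eps = 1.3
        ta = roi_survival_time(ROIImage(a), mask, 0.001, rng, eps=eps)
        tb = roi_survival_time(ROIImage(b), mask, 0.001, rng, eps=eps)
        assert ta < tb

    def test_deterministic_given_fixed_eps(self):
        img = ROIImage(np.full((5, 5, 1), 0.3))
        mask = generate_weight_mask((5, 5, 1), seed=9)
        rng = np.random.default_rng(0)
        t1 = roi_survival_time(img, mask, 0.01, rng, eps=2.0)
        t2 = roi_survival_time(img, mask, 0.01, rng, eps=2.0)
        assert t1 == t2 == pytest.approx(
            np.exp((img.pixels * mask.weights).mean() + 0.01 * 2.0), rel=1e-12)

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            roi_survival_time(ROIImage(np.zeros((4, 4, 1))),
                              generate_weight_mask((5, 5, 1), 0), 0.001,
                              np.random.default_rng(0))


class TestPatientTime:
    def test_mean_of_roi_times(self):
        assert patient_survival_time([2.0, 4.0]) == 3.0
        assert patient_survival_time([7.0]) == 7.0
        assert patient_survival_time([1.5] * 5) == 1.5

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            patient_survival_time([])


class TestCensoring:
    def test_fraction_zero_keeps_everything(self):
        times = np.linspace(1, 10, 20)
        recs = apply_censoring(times, 0.0, np.random.default_rng(0))
        assert all(r.event == 1 for r in recs)
        np.testing.assert_allclose([r.time for r in recs], times)

    def test_fraction_one_censors_below_truth(self):
        times = np.linspace(1, 10, 20)
        recs = apply_censoring(times, 1.0, np.random.default_rng(0))
        assert all(r.event == 0 for r in recs)
        assert all(r.time < t for r, t in zip(recs, times))

    def test_exactly_half_censored(self):
        times = np.random.default_rng(1).uniform(1, 5, size=1000)
        recs = apply_censoring(times, 0.5, np.random.default_rng(2))
        assert sum(r.event == 0 for r in recs) == 500
        assert all(r.time <= t for r, t in zip(recs, times))


class TestImageGenerators:
    def test_digit_images_shape_range_determinism(self):
        a = synth_digit_images("zero-like", 5, seed=3)
        b = synth_digit_images("zero-like", 5, seed=3)
        for ia, ib in zip(a, b):
            assert ia.pixels.shape == (28, 28, 1)
            assert ia.pixels.min() >= 0 and ia.pixels.max() <= 1
            np.testing.assert_array_equal(ia.pixels, ib.pixels)

    def test_digit_classes_differ_in_ink_mass(self):
        from scipy.stats import ranksums
        zeros = synth_digit_images("zero-like", 500, seed=10)
        sixes = synth_digit_images("six-like", 500, seed=11)
        tz = [im.pixels.sum() for im in zeros]
        ts = [im.pixels.sum() for im in sixes]
        assert ranksums(tz, ts).pvalue < 0.01

    def test_unknown_class_errors(self):
        with pytest.raises(ValueError):
            synth_digit_images("nine-like", 1, seed=0)

    def test_texture_brightness_span(self):
        imgs = synth_texture_images(1000, shape=(16, 16, 3), heterogeneity=1.0, seed=4)
        means = np.array([im.pixels.mean() for im in imgs])
        assert means.min() <= 0.2 and means.max() >= 0.8

    def test_texture_zero_heterogeneity_constant_mean(self):
        imgs = synth_texture_images(50, shape=(16, 16, 3), heterogeneity=0.0, seed=5)
        means = np.array([im.pixels.mean() for im in imgs])
        np.testing.assert_allclose(means, 0.5, atol=0.02)

    def test_texture_determinism(self):
        a = synth_texture_images(3, shape=(8, 8, 3), seed=6)
        b = synth_texture_images(3, shape=(8, 8, 3), seed=6)
        for ia, ib in zip(a, b):
            np.testing.assert_array_equal(ia.pixels, ib.pixels)


class TestBuildSimulation:
    def test_split_sizes_and_disjoint_ids(self):
        ds = build_simulation(SimulationConfig(n_patients=100, seed=0))
        assert len(ds.train_bags) == 80 and len(ds.test_bags) == 20
        train_ids = {b.patient_id for b in ds.train_bags}
        test_ids = {b.patient_id for b in ds.test_bags}
        assert not train_ids & test_ids

    def test_half_the_cohort_censored(self):
        ds = build_simulation(SimulationConfig(n_patients=100, seed=1))
        bags = ds.train_bags + ds.test_bags
        assert sum(b.record.event == 0 for b in bags) == 50

    def test_digit_bags_have_one_of_each_class(self):
        ds = build_simulation(SimulationConfig(n_patients=10, seed=2))
        for bag in ds.train_bags + ds.test_bags:
            classes = sorted(r.source_class for r in bag.rois)
            assert classes == ["six-like", "zero-like"]

    def test_observed_time_below_truth_iff_censored(self):
        ds = build_simulation(SimulationConfig(n_patients=60, seed=3))
        for b in ds.train_bags + ds.test_bags:
            if b.record.event == 1:
                assert b.record.time == pytest.approx(b.true_time)
            else:
                assert b.record.time < b.true_time

    def test_reproducible_under_fixed_seed(self):
        d1 = build_simulation(SimulationConfig(n_patients=20, seed=5))
        d2 = build_simulation(SimulationConfig(n_patients=20, seed=5))
        assert [b.patient_id for b in d1.train_bags] == [b.patient_id for b in d2.train_bags]
        np.testing.assert_array_equal(d1.mask.weights, d2.mask.weights)
        np.testing.assert_allclose([b.true_time for b in d1.test_bags],
                                   [b.true_time for b in d2.test_bags])

    def test_texture_design_roi_counts(self):
        cfg = SimulationConfig(design="multi_roi_texture", image_shape=(16, 16, 3),
                               n_patients=20, rois_per_patient=(2, 5), seed=6)
        ds = build_simulation(cfg)
        counts = [len(b.rois) for b in ds.train_bags + ds.test_bags]
        assert min(counts) >= 2 and max(counts) <= 5

    def test_oracle_risk_orders_noise_free_cohort(self):
        # with vanishing noise the mask-weighted intensity determines the order
        # up to Jensen's gap (patient time averages exp(m_k), the oracle
        # averages m_k), so concordance is near-perfect but not exactly 1
        cfg = SimulationConfig(n_patients=80, censor_fraction=0.0,
                               noise_scale=0.0, seed=7)
        ds = build_simulation(cfg)
        bags = ds.train_bags + ds.test_bags
        risks = [oracle_patient_risk(b, ds.mask) for b in bags]
        ci = concordance_index(risks, [b.record for b in bags])
        assert ci >= 0.99

    def test_bag_time_is_mean_of_roi_times(self):
        # recompute ROI times from stored images at zero noise and compare
        cfg = SimulationConfig(n_patients=10, noise_scale=0.0, censor_fraction=0.0,
                               seed=8)
        ds = build_simulation(cfg)
        for b in ds.train_bags:
            times = [np.exp((r.pixels * ds.mask.weights).mean()) for r in b.rois]
            assert b.true_time == pytest.approx(np.mean(times), abs=1e-12)

    def test_invalid_config_errors(self):
        with pytest.raises(ValueError):
            SimulationConfig(censor_fraction=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(design="bogus")
        with pytest.raises(ValueError):
            SimulationConfig(design="multi_roi_texture", image_shape=(16, 16, 1))
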