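import math

import numpy as np
import pytest

from colonyquant import (
    GridSpec,
    MixtureFit,
    build_histogram,
    fit_mixture,
    mixture_density,
    segment_plate,
    solve_threshold,
)
from colonyquant.mixture import (
    DegenerateHistogramError,
    IntensityHistogram,
    _moment_init,
    _neg_loglik,
)


def hist_from_samples(samples):
    counts = np.bincount(np.clip(np.round(samples), 0, 255).astype(int), minlength=256)
    fit_counts = counts.copy()
    fit_counts[0] = 0
    fit_counts[255] = 0
    return IntensityHistogram(counts=counts, fit_counts=fit_counts, n_total=int(counts.sum()))


def sample_mixture(rng, mu1, s1, mu2, s2, w1, n):
    n1 = int(round(w1 * n))
    return np.concatenate([rng.normal(mu1, s1, n1), rng.normal(mu2, s2, n - n1)])


def make_fit(mu1, s1, mu2, s2, theta):
    fit = MixtureFit(mu1=mu1, sigma1=s1, mu2=mu2, sigma2=s2, theta=theta,
                     loglik=0.0, x_thresh=0.0)
    return MixtureFit(**{**fit.__dict__, "x_thresh": solve_threshold(fit)})


class TestHistogram:
    def test_constant_image_is_a_delta(self):
        grid = GridSpec(2, 2, 10, 10, 30, 30)
        img = np.full((50, 50), 100.0)
        h = build_histogram(img, grid)
        assert h.counts[100] == h.n_total
        assert h.counts.sum() == h.n_total

    def test_two_valued_image_gives_two_spikes(self):
        grid = GridSpec(2, 2, 10, 10, 30, 30)
        img = np.full((50, 50), 60.0)
        img[:, 25:] = 180.0
        h = build_histogram(img, grid)
        occupied = np.flatnonzero(h.counts)
        assert set(occupied) == {60, 180}

    def test_saturated_bins_trimmed_from_fit_but_kept_raw(self):
        grid = GridSpec(2, 2, 10, 10, 30, 30)
        img = np.full((50, 50), 255.0)
        img[20:25, 20:25] = 128.0
        h = build_histogram(img, grid)
        assert h.counts[255] > 0
        assert h.fit_counts[255] == 0
        assert h.n_fit == h.counts[128]


class TestMixtureDensity:
    def test_matches_direct_formula(self, rng):
        for _ in range(5):
            mu1, mu2 = rng.uniform(10, 240, 2)
            s1, s2 = rng.uniform(1, 30, 2)
            theta = rng.uniform(0.01, 100)
            x = rng.uniform(0, 255, 7)
            expected = theta * np.exp(-((x - mu1) ** 2) / (2 * s1**2)) + np.exp(
                -((x - mu2) ** 2) / (2 * s2**2)
            )
            np.testing.assert_allclose(
                mixture_density(x, mu1, s1, mu2, s2, theta), expected
            )

    def test_peak_height_reading(self):
        # well-separated components: g at mu1 reads the peak-height ratio
        assert mixture_density(50, 50, 5, 200, 5, 2.0) == pytest.approx(2.0, abs=1e-8)
        assert mixture_density(200, 50, 5, 200, 5, 2.0) == pytest.approx(1.0, abs=1e-8)


class TestFitMixture:
    def test_parameter_recovery(self, rng):
        samples = sample_mixture(rng, 80, 8, 170, 15, 0.8, 1_000_000)
        fit = fit_mixture(hist_from_samples(samples), seed=3)
        assert fit.mu1 == pytest.approx(80, abs=1.0)
        assert fit.mu2 == pytest.approx(170, abs=1.0)
        assert fit.sigma1 == pytest.approx(8, rel=0.10)
        assert fit.sigma2 == pytest.approx(15, rel=0.10)
        # peak-height relation: theta = (w1/s1)/(w2/s2) = (0.8/8)/(0.2/15)
        assert fit.theta == pytest.approx(7.5, rel=0.15)

    def test_symmetric_case(self, rng):
        samples = sample_mixture(rng, 64, 10, 192, 10, 0.5, 400_000)
        fit = fit_mixture(hist_from_samples(samples), seed=3)
        assert fit.mu1 + fit.mu2 == pytest.approx(256, abs=2.0)
        assert fit.x_thresh == pytest.approx(128, abs=2.0)

    def test_same_seed_is_bit_identical(self, rng):
        samples = sample_mixture(rng, 90, 6, 140, 9, 0.7, 50_000)
        h = hist_from_samples(samples)
        f1 = fit_mixture(h, seed=11)
        f2 = fit_mixture(h, seed=11)
        assert f1 == f2

    def test_loglik_beats_moment_initialisation(self, rng):
        for i in range(3):
            r = np.random.default_rng(100 + i)
            samples = sample_mixture(
                r, r.uniform(60, 100), r.uniform(3, 10),
                r.uniform(140, 200), r.uniform(5, 15), r.uniform(0.6, 0.95), 50_000,
            )
            h = hist_from_samples(samples)
            fit = fit_mixture(h, seed=i)
            mom_ll = -_neg_loglik(_moment_init(h.fit_counts), h.fit_counts)
            assert fit.loglik >= mom_ll - 1e-6

    def test_single_bin_histogram_is_degenerate(self):
        counts = np.zeros(256, dtype=int)
        counts[100] = 1000
        h = IntensityHistogram(counts=counts, fit_counts=counts.copy(), n_total=1000)
        with pytest.raises(DegenerateHistogramError):
            fit_mixture(h, seed=0)

    def test_single_population_flagged_on_unimodal_data(self, rng):
        samples = rng.normal(120, 4, 200_000)
        fit = fit_mixture(hist_from_samples(samples), seed=5)
        assert fit.single_population

    def test_shift_equivariance_of_threshold(self, rng):
        samples = sample_mixture(rng, 90, 5, 130, 8, 0.8, 200_000)
        f0 = fit_mixture(hist_from_samples(samples), seed=7)
        f1 = fit_mixture(hist_from_samples(samples + 10), seed=7)
        assert f1.x_thresh - f0.x_thresh == pytest.approx(10, abs=0.5)


class TestSolveThreshold:
    def test_symmetric_midpoint(self):
        fit = make_fit(64, 10, 192, 10, 1.0)
        assert fit.x_thresh == pytest.approx(128.0, abs=1e-9)

    def test_against_dense_scan(self):
        fit = make_fit(50, 10, 150, 20, 1.0)
        x = np.arange(50, 150, 0.001)
        c1 = fit.theta * np.exp(-((x - 50) ** 2) / (2 * 10.0**2))
        c2 = np.exp(-((x - 150) ** 2) / (2 * 20.0**2))
        scan = x[np.argmin(np.abs(np.log(c1) - np.log(c2)))]
        assert fit.x_thresh == pytest.approx(scan, abs=0.01)

    def test_equal_sigma_shift_formula(self):
        # theta=4, equal sigmas: threshold moves toward mu2 by s^2 ln4 / (mu2-mu1)
        s, mu1, mu2, theta = 12.0, 80.0, 180.0, 4.0
        fit = make_fit(mu1, s, mu2, s, theta)
        expected = (mu1 + mu2) / 2 + s**2 * math.log(theta) / (mu2 - mu1)
        assert fit.x_thresh == pytest.approx(expected, abs=1e-9)

    def test_components_equal_at_threshold(self):
        fit = make_fit(70, 7, 160, 18, 3.5)
        x = fit.x_thresh
        c1 = fit.theta * math.exp(-((x - fit.mu1) ** 2) / (2 * fit.sigma1**2))
        c2 = math.exp(-((x - fit.mu2) ** 2) / (2 * fit.sigma2**2))
        assert c1 == pytest.approx(c2, rel=1e-6)

    def test_nested_components_fall_back_to_midpoint(self):
        fit = MixtureFit(mu1=100, sigma1=5, mu2=120, sigma2=50, theta=1e-4,
                         loglik=0.0, x_thresh=0.0)
        # component 1 is everywhere below component 2: no real intersection
        x = solve_threshold(fit)
        assert 0 <= x <= 255

    def test_equal_probability_at_threshold(self, rng):
        # pixels simulated from the fitted mixture misclassify at equal
        # rates on both sides of the threshold, within Monte-Carlo error
        fit = make_fit(90, 6, 130, 10, 4.0)
        n = 400_000
        w1 = fit.theta * fit.sigma1 / (fit.theta * fit.sigma1 + fit.sigma2)
        n1 = int(round(w1 * n))
        a = rng.normal(fit.mu1, fit.sigma1, n1)
        b = rng.normal(fit.mu2, fit.sigma2, n - n1)
        # misclassified mass on each side of the threshold
        mass_1_above = (a > fit.x_thresh).sum() / n
        mass_2_below = (b < fit.x_thresh).sum() / n
        assert mass_1_above == pytest.approx(mass_2_below, abs=0.005)


class TestSegmentPlate:
    def test_threshold_rule(self):
        fit = make_fit(64, 10, 192, 10, 1.0)
        img = np.array([[100.0, 150.0], [128.0, 200.0]])
        mask = segment_plate(img, fit)
        np.testing.assert_array_equal(mask, [[False, True], [False, True]])

    def test_single_population_yields_empty_mask(self):
        fit = MixtureFit(mu1=100, sigma1=5, mu2=101, sigma2=5, theta=1.0,
                         loglik=0.0, x_thresh=100.5, single_population=True)
        assert not segment_plate(np.full((4, 4), 200.0), fit).any()
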