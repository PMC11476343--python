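"""Lifetime estimation: decay fits, FastFLIM, distributions, deconvolution."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from memquant import flim, synthetic
from memquant.flim import (DecayHistogram, FitError, GaussianComponent,
                           LifetimeDistribution, LifetimeFit, accumulate_roi,
                           fast_lifetime, fit_decay, fit_gaussians,
                           lifetime_distribution)


def _single_exp_hist(tau_ns=2.0, n=10 ** 6, seed=0, **kwargs):
    model = synthetic.PhotonModel([(1.0, tau_ns)], irf_fwhm_ps=0.0, **kwargs)
    return synthetic.simulate_decay(model, n, rng_seed=seed)


class TestFitDecay:
    def test_single_exponential_recovery(self):
        hist = _single_exp_hist(tau_ns=2.0)
        fit = fit_decay(hist, n_components=1)
        assert fit.mean_lifetime_ns == pytest.approx(2.0, rel=0.01)
        assert fit.chi_squared_reduced < 1.1

    def test_agrees_with_fast_lifetime_for_monoexponential(self):
        hist = _single_exp_hist(tau_ns=1.5, seed=3)
        fit = fit_decay(hist, n_components=1)
        fast = fast_lifetime(hist)
        assert fit.mean_lifetime_ns == pytest.approx(fast, rel=0.01)

    def test_two_component_amplitude_weighted_mean(self):
        # oracle: sum(a tau)/sum(a) on the generative parameters = 2.25 ns
        model = synthetic.PhotonModel([(0.5, 0.5), (0.5, 4.0)])
        hist = synthetic.simulate_decay(model, 10 ** 6, rng_seed=4)
        fit = fit_decay(hist, n_components="auto")
        assert fit.mean_lifetime_ns == pytest.approx(2.25, rel=0.02)

    def test_auto_mode_respects_chi_squared_gate(self):
        model = synthetic.hybrid_model()
        hist = synthetic.simulate_decay(model, 10 ** 6, rng_seed=5)
        fit = fit_decay(hist, n_components="auto")
        assert fit.chi_squared_reduced < 1.1
        assert 1 <= fit.n_components <= 3

    def test_rescaling_invariance(self):
        hist = _single_exp_hist(tau_ns=2.0, seed=6)
        scaled = DecayHistogram(hist.counts * 10, hist.bin_edges_ps,
                                irf_fwhm_ps=hist.irf_fwhm_ps,
                                irf_center_ps=hist.irf_center_ps)
        f1 = fit_decay(hist, n_components=1)
        f2 = fit_decay(scaled, n_components=1)
        assert f2.mean_lifetime_ns == pytest.approx(f1.mean_lifetime_ns,
                                                    rel=0.01)

    def test_too_few_photons_rejected(self):
        hist = _single_exp_hist(n=200, seed=7)
        with pytest.raises(FitError, match="photons"):
            fit_decay(hist, n_components=2)

    def test_background_estimated_from_prepulse_bins(self):
        model = synthetic.PhotonModel([(1.0, 2.0)], background_rate=5.0)
        hist = synthetic.simulate_decay(model, 10 ** 6, rng_seed=8)
        hist.background_per_bin = None  # force estimation
        assert hist.estimate_background() == pytest.approx(5.0, rel=0.2)
        fit = fit_decay(hist, n_components=1)
        assert fit.mean_lifetime_ns == pytest.approx(2.0, rel=0.02)

    def test_mean_lifetime_consistency_enforced(self):
        with pytest.raises(ValueError, match="inconsistent"):
            LifetimeFit(components=[(1.0, 1.0), (1.0, 3.0)],
                        mean_lifetime_ns=1.0, chi_squared_reduced=1.0,
                        background_per_bin=0.0, shift_ps=0.0)

    def test_parameter_recovery_median_error_under_two_percent(self):
        # 50 seeded replicates at 1e5 photons for each ground truth
        for model, truth in ((synthetic.thylakoid_model(), 0.40),
                             (synthetic.hybrid_model(), 4.06)):
            errors = []
            for seed in range(50):
                hist = synthetic.simulate_decay(model, 10 ** 5,
                                                rng_seed=1000 + seed)
                fit = fit_decay(hist, n_components=2)
                errors.append(abs(fit.mean_lifetime_ns - truth) / truth)
            assert np.median(errors) < 0.02


class TestFastLifetime:
    def test_first_moment_of_ideal_exponential(self):
        hist = _single_exp_hist(tau_ns=1.0, seed=9)
        assert fast_lifetime(hist) == pytest.approx(1.0, rel=0.01)

    def test_irf_centroid_shift_invariance(self):
        model = synthetic.PhotonModel([(1.0, 1.0)], irf_fwhm_ps=0.0)
        a = synthetic.simulate_decay(model, 10 ** 5, rng_seed=10, t0_ns=0.5)
        b = synthetic.simulate_decay(model, 10 ** 5, rng_seed=10, t0_ns=2.0)
        assert fast_lifetime(a) == pytest.approx(fast_lifetime(b), rel=0.01)

    def test_starved_pixel_flagged_undefined(self):
        hist = _single_exp_hist(n=10, seed=11)
        assert np.isnan(fast_lifetime(hist))

    def test_all_background_pixel_flagged_undefined(self):
        edges = np.arange(0, 1000 + 25, 25.0)
        counts = np.full(len(edges) - 1, 5)
        hist = DecayHistogram(counts, edges, background_per_bin=5.0)
        assert np.isnan(fast_lifetime(hist))


class TestRoiAndDistribution:
    def test_single_pixel_mask_preserves_histogram(self, two_population_image):
        image, _, _, _ = two_population_image
        mask = np.zeros(image.shape, dtype=bool)
        mask[10, 10] = True
        hist = accumulate_roi(image, mask)
        np.testing.assert_array_equal(hist.counts, image.counts[10, 10])

    def test_full_mask_conserves_counts(self, two_population_image):
        image, _, _, _ = two_population_image
        hist = accumulate_roi(image, np.ones(image.shape, dtype=bool))
        assert hist.n_photons == image.counts.sum()

    def test_empty_mask_rejected(self, two_population_image):
        image, _, _, _ = two_population_image
        with pytest.raises(ValueError, match="empty"):
            accumulate_roi(image, np.zeros(image.shape, dtype=bool))

    def test_corral_roi_fit_recovers_hybrid_lifetime(self,
                                                     two_population_image):
        image, labels, _, truth = two_population_image
        hist = accumulate_roi(image, labels == 1)
        fit = fit_decay(hist, n_components="auto")
        expected = truth.region_models["hybrid"].mean_lifetime_ns
        assert fit.mean_lifetime_ns == pytest.approx(expected, rel=0.03)

    def test_identical_pixels_occupy_single_bin(self, ideal_single_exp_image):
        dist = lifetime_distribution(ideal_single_exp_image)
        assert (dist.frequency > 0).sum() == 1

    def test_peak_normalization(self, ideal_single_exp_image):
        dist = lifetime_distribution(ideal_single_exp_image, normalize=True)
        assert dist.frequency.max() == pytest.approx(1.0)

    def test_flim_container_roundtrip(self, tmp_path, two_population_image):
        image, _, _, _ = two_population_image
        image.save(tmp_path / "frame")
        loaded = flim.FlimImage.load(tmp_path / "frame")
        np.testing.assert_array_equal(loaded.counts, image.counts)
        assert loaded.irf_fwhm_ps == image.irf_fwhm_ps
        assert loaded.meta["channel"] == "Chl"

    def test_two_population_distribution_is_bimodal(self,
                                                    two_population_image):
        image, labels, _, _ = two_population_image
        dist = lifetime_distribution(image, mask=labels > 0)
        comps, r2 = fit_gaussians(dist, n=2)
        assert comps[0].center_ns < 1.0
        assert comps[1].center_ns > 3.0
        assert r2 > 0.9


class TestFitGaussians:
    def test_exact_gaussian_recovered_to_numerical_precision(self):
        x = np.arange(0.0125, 8.0, 0.025)
        truth = GaussianComponent(center_ns=2.0, fwhm_ns=0.5, amplitude=100.0)
        dist = LifetimeDistribution(x, truth(x))
        comps, r2 = fit_gaussians(dist, n=1)
        assert comps[0].center_ns == pytest.approx(2.0, abs=1e-6)
        assert comps[0].fwhm_ns == pytest.approx(0.5, abs=1e-6)
        assert r2 == pytest.approx(1.0)

    def test_two_population_centers_recovered(self):
        rng = np.random.default_rng(12)
        s = flim.FWHM_TO_SIGMA
        taus = np.concatenate([rng.normal(0.57, 0.15 * s, 5000),
                               rng.normal(4.58, 2.31 * s, 5000)])
        taus = taus[taus > 0]
        edges = np.arange(0, taus.max() + 0.025, 0.025)
        freq, _ = np.histogram(taus, bins=edges)
        dist = LifetimeDistribution(0.5 * (edges[:-1] + edges[1:]),
                                    freq.astype(float))
        comps, r2 = fit_gaussians(dist, n=2)
        assert comps[0].center_ns == pytest.approx(0.57, rel=0.05)
        assert comps[1].center_ns == pytest.approx(4.58, rel=0.05)
        assert comps[1].fwhm_ns == pytest.approx(2.31, rel=0.05)
        assert r2 > 0.9

    def test_amplitude_ratio_recovered(self):
        x = np.arange(0.0125, 8.0, 0.025)
        g1 = GaussianComponent(1.0, 0.4, 200.0)
        g2 = GaussianComponent(4.0, 1.0, 100.0)
        rng = np.random.default_rng(13)
        y = g1(x) + g2(x) + rng.normal(0, 1.0, x.size)
        comps, _ = fit_gaussians(LifetimeDistribution(x, np.clip(y, 0, None)),
                                 n=2)
        assert comps[0].amplitude / comps[1].amplitude == pytest.approx(
            2.0, rel=0.05)

    def test_unimodal_input_never_yields_two_real_components(self):
        # anti-overfitting: a unimodal distribution must either raise the
        # degeneracy flag or report one component as negligible (< 10% of
        # the peak amplitude)
        x = np.arange(0.0125, 8.0, 0.025)
        g = GaussianComponent(2.0, 1.0, 100.0)
        rng = np.random.default_rng(14)
        y = np.clip(g(x) + rng.normal(0, 0.5, x.size), 0, None)
        try:
            comps, _ = fit_gaussians(LifetimeDistribution(x, y), n=2)
        except FitError:
            return
        amps = sorted(c.amplitude for c in comps)
        sep = abs(comps[1].center_ns - comps[0].center_ns)
        well_separated = sep >= max(c.fwhm_ns for c in comps)
        assert not (well_separated and amps[0] > 0.1 * amps[1])

    def test_sparse_distribution_rejected(self):
        x = np.arange(0.0125, 0.2, 0.025)
        y = np.zeros_like(x)
        y[2] = 1.0
        with pytest.raises(FitError):
            fit_gaussians(LifetimeDistribution(x, y), n=2)


class TestLifetimeFitInvariant:
    @given(st.lists(st.tuples(st.floats(0.1, 10.0), st.floats(0.05, 10.0)),
                    min_size=1, max_size=3))
    @settings(max_examples=50, deadline=None)
    def test_mean_is_amplitude_weighted_mean_of_components(self, comps):
        amps = np.array([a for a, _ in comps])
        taus = np.array([t for _, t in comps])
        mean = float(np.sum(amps * taus) / np.sum(amps))
        fit = LifetimeFit(components=comps, mean_lifetime_ns=mean,
                          chi_squared_reduced=1.0, background_per_bin=0.0,
                          shift_ps=0.0)
        recomputed = sum(a * t for a, t in fit.components) / sum(
            a for a, _ in fit.components)
        assert fit.mean_lifetime_ns == pytest.approx(recomputed, rel=1e-12)
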