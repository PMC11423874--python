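"""TCSPC decay fitting: initialisation, recovery, chi-square, quality rule."""

import numpy as np
import pytest

from flimmet import (
    DecayParams,
    FitConfig,
    TimeAxis,
    classify_fit_quality,
    evaluate_decay,
    expected_histogram,
    fit_decay,
    fit_pixelwise,
    initialize_params,
    reduced_chi_square,
    simulate_decay_histogram,
)
from flimmet.errors import (
    DegenerateDofError,
    InsufficientSignalError,
)


class TestInitializeParams:
    def test_all_zero_histogram_rejected(self, axis):
        with pytest.raises(InsufficientSignalError):
            initialize_params(np.zeros(axis.n_bins), axis)

    def test_mono_exponential_tail_estimate(self, axis):
        truth = DecayParams(alpha1=1000.0, tau1=2.0)
        hist = evaluate_decay(truth, axis.bin_centers)
        init = initialize_params(hist, axis)
        assert init.tau2 == pytest.approx(2.0, rel=0.05)

    def test_flat_histogram_handled_by_clipping(self, axis):
        hist = np.full(axis.n_bins, 7.0)
        init = initialize_params(hist, axis)
        assert np.isfinite(init.tau2) and 0.02 <= init.tau2 <= 10.0
        assert init.alpha1 + init.alpha2 > 0

    def test_background_from_pre_peak_bins(self, axis):
        truth = DecayParams(alpha1=500.0, tau1=1.5, background=4.0)
        hist = evaluate_decay(truth, axis.bin_centers - 1.0)
        hist[axis.bin_centers < 1.0] = 4.0  # pre-peak: background only
        init = initialize_params(hist, axis)
        assert init.background == pytest.approx(4.0, rel=0.05)


class TestReducedChiSquare:
    def test_perfect_fit_is_zero(self, rng):
        obs = rng.poisson(50, 20).astype(float)
        assert reduced_chi_square(obs, obs, 5) == 0.0

    def test_hand_arithmetic_with_neyman_weights(self):
        obs = np.array([4.0, 1.0] + [10.0] * 8)
        model = np.array([2.0, 2.0] + [10.0] * 8)
        # ((4-2)^2/4 + (1-2)^2/1) / (10 - 5) = 2/5
        assert reduced_chi_square(obs, model, 5) == pytest.approx(0.4, abs=1e-15)

    def test_degenerate_dof_rejected(self):
        with pytest.raises(DegenerateDofError):
            reduced_chi_square(np.ones(5), np.ones(5), 5)

    def test_calibrated_near_one_for_poisson_data(self, rng):
        """Mean over correctly-specified Poisson replicates stays near 1."""
        mu = np.linspace(5, 200, 64)
        vals = [
            reduced_chi_square(rng.poisson(mu).astype(float), mu, 5)
            for _ in range(200)
        ]
        assert 0.85 <= np.mean(vals) <= 1.15


class TestClassifyFitQuality:
    @pytest.mark.parametrize(
        "chi2, expected",
        [(1.29, True), (1.30, False), (0.5, True), (np.nan, False), (np.inf, False)],
    )
    def test_strict_threshold(self, chi2, expected):
        assert classify_fit_quality(chi2, FitConfig()) is expected

    def test_custom_threshold(self):
        assert classify_fit_quality(1.8, FitConfig(chi2_threshold=2.0))


class TestFitDecay:
    def test_noiseless_recovery_to_tenth_percent(self, axis):
        truth = DecayParams(alpha1=0.7 * 4000, tau1=0.5, alpha2=0.3 * 4000, tau2=2.8)
        hist = evaluate_decay(truth, axis.bin_centers)
        res = fit_decay(hist, axis)
        assert res.converged
        assert res.params.tau1 == pytest.approx(0.5, rel=1e-3)
        assert res.params.tau2 == pytest.approx(2.8, rel=1e-3)
        assert res.bound_fraction == pytest.approx(0.3, rel=1e-3)
        assert res.params.alpha1 == pytest.approx(2800, rel=1e-3)
        assert res.tau_avg == pytest.approx(1.19, rel=1e-3)

    def test_poisson_1e5_within_five_percent(self, axis, reference_params):
        hist = simulate_decay_histogram(reference_params, 100_000, axis, 7)
        res = fit_decay(hist, axis)
        assert res.tau_avg == pytest.approx(1.19, rel=0.05)
        assert res.quality_pass

    def test_below_min_photons_raises(self, axis, reference_params):
        hist = simulate_decay_histogram(reference_params, 50, axis, 0)
        with pytest.raises(InsufficientSignalError):
            fit_decay(hist, axis, FitConfig(min_photons=100))

    def test_canonical_ordering_and_consistency(self, axis, rng):
        """tau1 <= tau2 and tau_avg consistent with params for every fit."""
        from flimmet import average_lifetime

        for _ in range(10):
            f = rng.uniform(0.1, 0.6)
            truth = DecayParams(alpha1=1 - f, tau1=rng.uniform(0.2, 0.6),
                                alpha2=f, tau2=rng.uniform(2.0, 3.5))
            hist = simulate_decay_histogram(truth, 20_000, axis, rng)
            res = fit_decay(hist, axis)
            assert res.params.tau1 <= res.params.tau2
            assert res.tau_avg == pytest.approx(average_lifetime(res.params))
            assert res.quality_pass == (res.converged and res.reduced_chi2 < 1.3)

    def test_poisson_mle_objective_agrees(self, axis, reference_params):
        hist = simulate_decay_histogram(reference_params, 50_000, axis, 3)
        wls = fit_decay(hist, axis, FitConfig(objective="neyman_wls"))
        mle = fit_decay(hist, axis, FitConfig(objective="poisson_mle"))
        assert mle.tau_avg == pytest.approx(wls.tau_avg, rel=0.05)

    def test_misspecified_mono_fit_fails_quality(self, axis, reference_params):
        """A mono-exponential fit to strongly bi-exponential data is rejected."""
        chis = [
            fit_decay(
                simulate_decay_histogram(reference_params, 10_000, axis, seed),
                axis,
                FitConfig(n_components=1),
            ).reduced_chi2
            for seed in range(20)
        ]
        assert np.mean(chis) > 1.3


class TestGridSearchOracle:
    def test_fitter_matches_brute_force_on_toy_histograms(self):
        """On 8-bin toys, a coarse grid search never clearly beats the fitter."""
        axis = TimeAxis(n_bins=8, period=12.5)
        t = axis.bin_centers

        taus = np.arange(0.05, 4.0001, 0.05)
        fracs = np.arange(0.0, 1.0001, 0.05)
        backgrounds = np.arange(0.0, 5.0001, 0.05)

        rng = np.random.default_rng(99)
        for case in range(3):
            f = rng.uniform(0.2, 0.5)
            truth = DecayParams(
                alpha1=(1 - f), tau1=rng.uniform(0.3, 0.7),
                alpha2=f, tau2=rng.uniform(2.0, 3.0),
            )
            hist = simulate_decay_histogram(truth, 5000, axis, rng)
            res = fit_decay(hist, axis, FitConfig(min_photons=1))

            w = 1.0 / np.maximum(hist, 1.0)
            amp = float(hist.max())

            def objective(a1, t1, a2, t2, c):
                model = a1 * np.exp(-t / t1) + a2 * np.exp(-t / t2) + c
                return float(np.sum((hist - model) ** 2 * w))

            fit_obj = objective(
                res.params.alpha1, res.params.tau1,
                res.params.alpha2, res.params.tau2, res.params.background,
            )

            # grid over (tau1, tau2, bound fraction, C); total amplitude
            # anchored at the histogram peak height
            best = np.inf
            e1 = np.exp(-t[None, :] / taus[:, None])  # tau x bin
            cgrid = backgrounds[None, :, None]
            for i1 in range(len(taus)):
                for i2 in range(i1, len(taus)):
                    base = amp * (
                        np.outer(1 - fracs, e1[i1]) + np.outer(fracs, e1[i2])
                    )  # frac x bin
                    resid = hist[None, None, :] - base[:, None, :] - cgrid
                    m = np.sum(resid**2 * w, axis=2).min()
                    if m < best:
                        best = m
            # tolerance: objective variation across one grid step
            assert fit_obj <= best * 1.05 + 1.0


class TestFitPixelwise:
    def _small_cube(self, axis, rng, shape=(6, 6), photons=10_000):
        truth = DecayParams(alpha1=0.7, tau1=0.5, alpha2=0.3, tau2=2.8)
        counts = np.zeros(shape + (axis.n_bins,), dtype=np.int64)
        mask = np.zeros(shape, bool)
        mask[1:5, 1:5] = True
        for i, j in zip(*np.nonzero(mask)):
            counts[i, j] = simulate_decay_histogram(truth, photons, axis, rng)
        return counts, mask

    def test_masked_pixels_fitted_accurately(self, axis, rng):
        counts, mask = self._small_cube(axis, rng)
        lmap = fit_pixelwise(counts, axis, mask)
        assert lmap.fitted.sum() == mask.sum()
        passing = lmap.quality_pass
        err = np.abs(lmap.tau_avg[passing] - 1.19) / 1.19
        assert (err < 0.10).mean() >= 0.95

    def test_unfitted_pixels_are_nan_not_zero(self, axis, rng):
        counts, mask = self._small_cube(axis, rng)
        lmap = fit_pixelwise(counts, axis, mask)
        outside = ~mask
        assert np.all(np.isnan(lmap.tau_avg[outside]))
        assert not lmap.fitted[outside].any()

    def test_empty_mask_yields_empty_map(self, axis):
        counts = np.zeros((4, 4, axis.n_bins), dtype=np.int64)
        lmap = fit_pixelwise(counts, axis, np.zeros((4, 4), bool))
        assert not lmap.fitted.any()
        assert np.all(np.isnan(lmap.tau_avg))

    def test_deterministic_rerun_is_bit_identical(self, axis):
        rng = np.random.default_rng(5)
        counts, mask = self._small_cube(axis, rng, shape=(5, 5), photons=5000)
        a = fit_pixelwise(counts, axis, mask)
        b = fit_pixelwise(counts, axis, mask)
        np.testing.assert_array_equal(a.tau_avg, b.tau_avg)
        np.testing.assert_array_equal(a.reduced_chi2, b.reduced_chi2)
        np.testing.assert_array_equal(a.quality_pass, b.quality_pass)

    def test_low_photon_pixels_binned_3x3(self, axis):
        rng = np.random.default_rng(8)
        truth = DecayParams(alpha1=0.7, tau1=0.5, alpha2=0.3, tau2=2.8)
        counts = np.zeros((3, 3, axis.n_bins), dtype=np.int64)
        for i in range(3):
            for j in range(3):
                counts[i, j] = simulate_decay_histogram(truth, 40, axis, rng)
        mask = np.ones((3, 3), bool)
        skipped = fit_pixelwise(counts, axis, mask, FitConfig(min_photons=100))
        binned = fit_pixelwise(
            counts, axis, mask, FitConfig(min_photons=100, bin_low_photon_pixels=True)
        )
        assert not skipped.fitted.any()
        assert binned.fitted[1, 1]
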