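"""The bi-exponential decay model and its derived metabolic readouts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flimmet import (
    DecayParams,
    TimeAxis,
    average_lifetime,
    bound_fraction,
    evaluate_decay,
    free_fraction,
    optical_redox_ratio,
)
from flimmet.errors import (
    UndefinedRatioError,
    ValidationError,
)

finite_pos = st.floats(0.05, 8.0, allow_nan=False)


class TestDecayParams:
    def test_canonical_ordering_swaps_components(self):
        p = DecayParams(alpha1=0.3, tau1=2.8, alpha2=0.7, tau2=0.5)
        assert (p.alpha1, p.tau1, p.alpha2, p.tau2) == (0.7, 0.5, 0.3, 2.8)

    def test_mono_exponential_defaults_tau2_to_tau1(self):
        p = DecayParams(alpha1=1.0, tau1=1.0)
        assert p.tau2 == p.tau1 and p.alpha2 == 0.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(alpha1=-0.1, tau1=1.0),
            dict(alpha1=0.0, tau1=1.0, alpha2=0.0),
            dict(alpha1=1.0, tau1=0.0),
            dict(alpha1=1.0, tau1=1.0, background=-1.0),
            dict(alpha1=np.nan, tau1=1.0),
            dict(alpha1=1.0, tau1=np.inf),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            DecayParams(**kwargs)


class TestTimeAxis:
    def test_default_axis_is_80mhz_256_bins(self, axis):
        assert axis.n_bins == 256
        assert axis.period == 12.5
        assert axis.bin_width == pytest.approx(12.5 / 256)

    def test_bin_centers_increasing_within_period(self, axis):
        c = axis.bin_centers
        assert np.all(np.diff(c) > 0)
        assert c[0] >= 0 and c[-1] < axis.period

    def test_bins_must_fit_in_period(self):
        with pytest.raises(ValidationError):
            TimeAxis(n_bins=256, period=12.5, bin_width=0.1)


class TestEvaluateDecay:
    @pytest.mark.parametrize(
        "params, t, expected",
        [
            (DecayParams(alpha1=1, tau1=1), 0.0, 1.0),
            (DecayParams(alpha1=0.5, tau1=2, alpha2=0.5, tau2=2, background=0.1), 0.0, 1.1),
            (DecayParams(alpha1=1, tau1=1), 1.0, np.exp(-1.0)),
        ],
    )
    def test_analytic_values(self, params, t, expected):
        assert evaluate_decay(params, t) == pytest.approx(expected, rel=1e-12)

    def test_t0_equals_total_amplitude_plus_background(self):
        p = DecayParams(alpha1=0.7, tau1=0.5, alpha2=0.3, tau2=2.8, background=0.2)
        assert evaluate_decay(p, 0.0) == pytest.approx(1.2, abs=0)

    def test_large_t_limit_is_background(self):
        p = DecayParams(alpha1=0.7, tau1=0.5, alpha2=0.3, tau2=2.8, background=0.2)
        assert evaluate_decay(p, 1e6) == pytest.approx(0.2)

    def test_strictly_decreasing_in_time(self, reference_params, axis):
        vals = evaluate_decay(reference_params, axis.bin_centers)
        assert np.all(np.diff(vals) < 0)


class TestAverageLifetime:
    def test_hand_computed_example(self):
        p = DecayParams(alpha1=0.6, tau1=0.4, alpha2=0.4, tau2=2.5)
        assert average_lifetime(p) == pytest.approx(1.24, rel=1e-12)

    def test_single_component_returns_its_lifetime(self):
        assert average_lifetime(DecayParams(alpha1=2.0, tau1=0.7)) == 0.7

    def test_equal_lifetimes_degenerate(self):
        p = DecayParams(alpha1=0.4, tau1=1.5, alpha2=0.6, tau2=1.5)
        assert average_lifetime(p) == pytest.approx(1.5)

    def test_matches_arithmetic_oracle_on_random_draws(self, rng):
        """alpha-weighted mean oracle, 1000 random parameter draws."""
        for _ in range(1000):
            a1, a2 = rng.uniform(0.01, 5, 2)
            t1 = rng.uniform(0.05, 5)
            t2 = rng.uniform(t1, 8)
            p = DecayParams(alpha1=a1, tau1=t1, alpha2=a2, tau2=t2)
            oracle = (t1 * a1 + t2 * a2) / (a1 + a2)
            assert abs(average_lifetime(p) - oracle) <= 1e-12 * oracle

    @given(
        a1=st.floats(0.01, 5), a2=st.floats(0.0, 5),
        t1=finite_pos, t2=finite_pos,
    )
    @settings(max_examples=200, deadline=None)
    def test_bracketed_by_component_lifetimes(self, a1, a2, t1, t2):
        p = DecayParams(alpha1=a1, tau1=t1, alpha2=a2, tau2=t2)
        tau = average_lifetime(p)
        assert min(t1, t2) - 1e-12 <= tau <= max(t1, t2) + 1e-12

    def test_monotone_in_bound_amplitude(self):
        """For fixed tau1 < tau2, tau_avg never decreases as alpha2 grows."""
        grid = np.linspace(0.0, 4.0, 41)
        prev = -np.inf
        for a2 in grid:
            p = DecayParams(alpha1=1.0, tau1=0.4, alpha2=a2, tau2=2.5)
            tau = average_lifetime(p)
            assert tau >= prev - 1e-15
            prev = tau


class TestBoundFraction:
    @pytest.mark.parametrize(
        "a1, a2, expected",
        [(0.7, 0.3, 0.3), (0.0, 0.5, 1.0), (1.3, 1.3, 0.5)],
    )
    def test_normalization(self, a1, a2, expected):
        kwargs = dict(alpha1=a1, tau1=0.4, alpha2=a2, tau2=2.5)
        assert bound_fraction(DecayParams(**kwargs)) == pytest.approx(expected)

    def test_free_plus_bound_is_one(self, reference_params):
        total = free_fraction(reference_params) + bound_fraction(reference_params)
        assert total == pytest.approx(1.0, abs=1e-15)


class TestOpticalRedoxRatio:
    @pytest.mark.parametrize("fad, nadph, expected", [(100, 100, 1.0), (200, 100, 2.0)])
    def test_ratio(self, fad, nadph, expected):
        assert optical_redox_ratio(fad, nadph) == expected

    def test_zero_nadph_raises(self):
        with pytest.raises(UndefinedRatioError):
            optical_redox_ratio(50, 0)

    @given(scale=st.floats(1e-3, 1e3), fad=st.floats(0.1, 1e4), nadph=st.floats(0.1, 1e4))
    @settings(max_examples=200, deadline=None)
    def test_scale_invariance(self, scale, fad, nadph):
        base = optical_redox_ratio(fad, nadph)
        scaled = optical_redox_ratio(fad * scale, nadph * scale)
        assert scaled == pytest.approx(base, rel=1e-9)
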