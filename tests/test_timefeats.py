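"""TimeFeats registry and the individual time-domain descriptors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from statefeats.spectral import DEFAULT_BANDS
from statefeats.timefeats import (
    TIMEFEATS_NAMES,
    compute_timefeats,
    compute_timefeats_banded,
    distribution_stats,
    entropy_features,
    higuchi_fd,
    hjorth_params,
    hurst_exponent,
    lempel_ziv_complexity,
    mean_curve_length,
    permutation_entropy,
    sample_entropy,
    zero_crossings,
)

FS = 256.0


class TestMeanCurveLength:
    def test_constant_is_zero(self):
        assert mean_curve_length(np.array([5.0, 5, 5, 5])) == 0.0

    def test_alternating_unit_signal(self):
        assert mean_curve_length(np.array([1.0, -1, 1, -1, 1])) == 2.0

    def test_unit_10hz_sine_matches_analytic_value(self, tone):
        # mean |diff| of a sine of amplitude A: (2/pi) * 2A sin(pi f / fs)
        analytic = (2 / np.pi) * 2 * np.sin(np.pi * 10 / FS)
        assert mean_curve_length(tone) == pytest.approx(analytic, rel=0.01)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            mean_curve_length(np.array([1.0]))


class TestHjorth:
    def test_white_noise_mobility_is_sqrt_two(self):
        rng = np.random.default_rng(0)
        mob, _ = hjorth_params(rng.standard_normal(10_000))
        assert mob == pytest.approx(np.sqrt(2), rel=0.05)

    def test_sine_mobility_matches_difference_amplitude(self, tone):
        mob, comp = hjorth_params(tone)
        assert mob == pytest.approx(2 * np.sin(np.pi * 10 / FS), rel=0.01)
        assert comp == pytest.approx(1.0, rel=0.02)

    def test_zero_variance_gives_nan_pair(self):
        mob, comp = hjorth_params(np.full(100, 3.0))
        assert np.isnan(mob) and np.isnan(comp)


class TestZeroCrossings:
    def test_10hz_cosine_crosses_twenty_times(self):
        t = np.arange(int(FS)) / FS
        assert zero_crossings(np.cos(2 * np.pi * 10 * t)) == 20

    def test_constant_and_two_sample_cases(self):
        assert zero_crossings(np.full(50, 2.0)) == 0
        assert zero_crossings(np.array([1.0, -1.0])) == 1


class TestDistributionStats:
    def test_hand_computed_values(self):
        mean, median, sd, _, _ = distribution_stats(np.array([1.0, 2, 3, 4, 5]))
        assert mean == 3 and median == 3
        assert sd == pytest.approx(1.5811, abs=1e-4)

    def test_sinusoid_has_zero_skewness(self, tone):
        assert distribution_stats(tone)[3] == pytest.approx(0.0, abs=1e-10)

    def test_normal_sample_kurtosis_is_three(self):
        x = np.random.default_rng(2).standard_normal(100_000)
        assert distribution_stats(x)[4] == pytest.approx(3.0, abs=0.1)


class TestHurst:
    def test_white_noise_near_half(self):
        rng = np.random.default_rng(0)
        vals = [hurst_exponent(rng.standard_normal(8192)) for _ in range(20)]
        assert np.mean(vals) == pytest.approx(0.5, abs=0.1)

    def test_random_walk_is_persistent(self):
        rng = np.random.default_rng(1)
        vals = [hurst_exponent(np.cumsum(rng.standard_normal(8192))) for _ in range(10)]
        assert np.mean(vals) > 0.8

    def test_short_input_and_determinism(self):
        assert np.isnan(hurst_exponent(np.arange(32.0)))
        x = np.random.default_rng(3).standard_normal(1024)
        assert hurst_exponent(x) == hurst_exponent(x.copy())


class TestEntropies:
    def test_periodic_sawtooth_matches_enumerated_pattern_distribution(self):
        # period-4 ramp, order 3: windows cycle through (0,1,2)->asc,
        # (1,2,3)->asc, (2,3,0)->rank 120, (3,0,1)->rank 201; brute-force
        # probabilities (1/2, 1/4, 1/4) give H = 1.5 bits / log2(6)
        x = np.tile([0.0, 1.0, 2.0, 3.0], 64)
        expected = 1.5 / np.log2(6)
        assert permutation_entropy(x) == pytest.approx(expected, abs=0.01)
        # longer ramps are dominated by the ascending pattern: near-zero PE
        assert permutation_entropy(np.tile(np.arange(16.0), 16)) <= 0.35

    def test_white_noise_permutation_entropy_near_one(self):
        x = np.random.default_rng(4).standard_normal(4096)
        assert permutation_entropy(x) > 0.99

    def test_constant_gives_nan_for_tolerance_based_measures(self):
        feats = entropy_features(np.full(256, 1.0), FS)
        assert np.isnan(feats["sample_entropy"])
        assert np.isnan(feats["approximate_entropy"])
        assert np.isnan(feats["spectral_entropy"])

    def test_regular_vs_noise_sample_entropy_ordering(self, tone):
        noise = np.random.default_rng(5).standard_normal(256)
        assert sample_entropy(tone) < sample_entropy(noise)

    def test_lempel_ziv_alternating_vs_noise(self):
        alternating = np.tile([0.0, 1.0], 512)
        noise = np.random.default_rng(6).standard_normal(1024)
        assert lempel_ziv_complexity(alternating) < lempel_ziv_complexity(noise)

    def test_higuchi_fd_of_line_near_one_and_noise_near_two(self):
        line = np.linspace(0, 1, 1024)
        noise = np.random.default_rng(7).standard_normal(1024)
        assert higuchi_fd(line) == pytest.approx(1.0, abs=0.05)
        assert higuchi_fd(noise) == pytest.approx(2.0, abs=0.15)


class TestAssembly:
    def test_registry_has_exactly_41_unique_names(self):
        assert len(TIMEFEATS_NAMES) == 41
        assert len(set(TIMEFEATS_NAMES)) == 41

    def test_feature_vector_has_one_value_per_entry(self, tone):
        fv = compute_timefeats(tone + 0.1 * np.random.default_rng(8).standard_normal(256), FS)
        assert tuple(fv.values) == TIMEFEATS_NAMES
        assert fv.as_array().shape == (41,)

    def test_constant_epoch_nans_only_documented_features(self):
        fv = compute_timefeats(np.full(256, 2.0), FS)
        vals = fv.values
        # degenerate by definition on constant input
        for k in ("hjorth_mobility", "hjorth_complexity", "hurst_exponent",
                  "sample_entropy", "approximate_entropy", "spectral_entropy",
                  "skewness", "kurtosis", "higuchi_fd", "aperiodic_slope",
                  "aperiodic_offset"):
            assert np.isnan(vals[k]), k
        for k in ("mean", "median", "std", "zero_crossings", "mean_curve_length"):
            assert np.isfinite(vals[k]), k

    def test_scale_invariant_and_scale_covariant_features(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(256)
        a = compute_timefeats(x, FS).values
        b = compute_timefeats(2 * x, FS).values
        for k in ("zero_crossings", "permutation_entropy", "hjorth_mobility"):
            assert a[k] == pytest.approx(b[k], rel=1e-9), k
        assert b["std"] == pytest.approx(2 * a["std"], rel=1e-9)
        assert b["mean_curve_length"] == pytest.approx(2 * a["mean_curve_length"], rel=1e-9)

    def test_determinism_of_full_vector(self):
        x = np.random.default_rng(10).standard_normal(256)
        a = compute_timefeats(x, FS).as_array()
        b = compute_timefeats(x.copy(), FS).as_array()
        np.testing.assert_array_equal(a, b)

    def test_banded_features_filter_before_computing(self):
        t = np.arange(int(FS)) / FS
        x = np.sin(2 * np.pi * 10 * t) + np.sin(2 * np.pi * 70 * t)
        alpha = DEFAULT_BANDS[2]
        banded = compute_timefeats_banded(x, FS, alpha)
        pure10 = compute_timefeats(np.sin(2 * np.pi * 10 * t), FS)
        assert banded.band == "alpha"
        assert abs(banded.values["zero_crossings"] - pure10.values["zero_crossings"]) <= 2

    def test_banded_noise_loses_variance(self):
        x = np.random.default_rng(11).standard_normal(256)
        for band in DEFAULT_BANDS:
            banded = compute_timefeats_banded(x, FS, band)
            assert banded.values["std"] < np.std(x, ddof=1)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_parseval_identity_for_random_epochs(seed):
    """Non-DC untapered spectral power equals sd^2 (N-1)/N to 1e-8."""
    from statefeats.spectral import power_spectrum

    rng = np.random.default_rng(seed)
    x = rng.standard_normal(256) * rng.uniform(0.1, 5)
    spec = power_spectrum(x, FS, taper="none")
    lhs = np.sum(spec.power[1:])
    rhs = np.var(x, ddof=1) * (len(x) - 1) / len(x)
    assert lhs == pytest.approx(rhs, rel=1e-8)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_nan_policy_never_raises_on_degenerate_inputs(seed):
    """Every registered feature maps degenerate input to NaN, not an exception."""
    rng = np.random.default_rng(seed)
    x = np.full(256, float(rng.uniform(-10, 10)))
    fv = compute_timefeats(x, FS)
    assert len(fv.values) == 41
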