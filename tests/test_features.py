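"""The 115-dimension reduction: counts, closed-form checks, invariances."""

import math

import numpy as np
import pytest
from scipy.signal import periodogram

import leafflow as lf
from leafflow.features import GROUP_SIZES, PA_WINDOWS_HOURS


def _aggregates(n=640, lag=36):
    """Frame aggregates for k = lag+1..n with simple deterministic content."""
    out = []
    for k in range(lag + 1, n + 1):
        t = (k - lag - 1) / 3.0
        out.append(lf.FrameAggregate(
            frame_index=k, n_sum=(t, 0.0), n_mean=(t, 0.0),
            magnitude=float(t), theta=0.1, s=int(100 + k)))
    return out


T604 = np.arange(604) / 3.0


class TestBuildTimeseries:
    def test_full_protocol_yields_604_points(self):
        ts = lf.build_timeseries(_aggregates())
        assert ts.n_points == 604
        assert ts.raw_dimension == 1812
        assert ts.t[0] == 0.0 and ts.t[-1] == pytest.approx(201.0)

    def test_ld_labels_follow_schedule(self):
        ts = lf.build_timeseries(_aggregates())
        assert ts.ld_label[np.searchsorted(ts.t, 10.0)] == "L"
        assert ts.ld_label[np.searchsorted(ts.t, 20.0)] == "D"

    def test_duplicate_or_empty_input_rejected(self):
        aggs = _aggregates(40)
        with pytest.raises(ValueError, match="duplicate"):
            lf.build_timeseries(aggs + [aggs[0]])
        with pytest.raises(ValueError):
            lf.build_timeseries([])


class TestShiftCorrelation:
    def test_pure_24h_sinusoid_self_similar_at_24h(self):
        x = np.sin(2 * np.pi * T604 / 24.0)
        corr = lf.shift_correlation(x, T604)
        assert corr[0] >= 0.99
        assert len(corr) == 6

    def test_zero_shift_is_unity(self):
        x = np.sin(T604)
        assert lf.shift_correlation(x, T604, (0.0,))[0] == pytest.approx(1.0)

    def test_white_noise_decorrelates(self):
        x = np.random.default_rng(0).standard_normal(604)
        assert np.all(np.abs(lf.shift_correlation(x, T604)) < 0.15)

    def test_affine_invariance(self):
        x = np.sin(2 * np.pi * T604 / 24.0) + 0.1 * np.cos(T604 / 7)
        a = lf.shift_correlation(x, T604)
        b = lf.shift_correlation(3.0 * x - 7.0, T604)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_short_overlap_gives_missing(self):
        t = np.arange(80) / 3.0  # ~26 h span; 24-h shift leaves 8 points
        x = np.full(80, np.nan)
        x[:5] = 1.0
        corr = lf.shift_correlation(x, t, (24.0,))
        assert math.isnan(corr[0])


class TestPAWindows:
    def test_constant_series(self):
        vals = lf.pa_window_average(np.full(604, 7.5), T604)
        np.testing.assert_allclose(vals, 7.5)
        assert len(vals) == 9

    def test_linear_series_matches_closed_form(self):
        vals = lf.pa_window_average(T604.copy(), T604)
        for i, (lo, hi) in enumerate(PA_WINDOWS_HOURS):
            pts = T604[(T604 >= lo) & ((T604 <= hi) if i == 8 else (T604 < hi))]
            assert vals[i] == pytest.approx((pts[0] + pts[-1]) / 2.0)

    def test_empty_window_is_missing(self):
        t = np.arange(30) / 3.0  # only the first window populated
        vals = lf.pa_window_average(np.ones(30), t)
        assert not math.isnan(vals[0]) and math.isnan(vals[3])


class TestPhaseAverages:
    def test_counts_over_full_protocol(self):
        l_means, d_means = lf.phase_averages(np.ones(604), T604)
        assert len(l_means) == 9 and len(d_means) == 8

    def test_constant_series_all_means_equal(self):
        l_means, d_means = lf.phase_averages(np.full(604, 2.5), T604)
        np.testing.assert_allclose(l_means, 2.5)
        np.testing.assert_allclose(d_means, 2.5)

    def test_indicator_series_separates_phases(self):
        ind = (np.mod(T604, 24.0) < 15.0).astype(float)
        l_means, d_means = lf.phase_averages(ind, T604)
        np.testing.assert_allclose(l_means, 1.0)
        np.testing.assert_allclose(d_means, 0.0)


class TestLDDiffs:
    def test_length_is_23(self):
        out = lf.ld_diff_features(np.arange(9.0), np.zeros(8))
        assert len(out) == 23

    def test_constant_means_give_zero_diffs(self):
        np.testing.assert_allclose(
            lf.ld_diff_features(np.full(9, 3.0), np.full(8, 3.0)), 0.0)

    def test_hand_computed_pattern(self):
        l_means = np.arange(9.0)  # period index
        d_means = np.zeros(8)
        out = lf.ld_diff_features(l_means, d_means)
        np.testing.assert_allclose(out[:8], 1.0)  # consecutive-light diffs
        np.testing.assert_allclose(out[8:15], 0.0)  # consecutive-dark diffs
        np.testing.assert_allclose(out[15:], np.arange(8.0))  # within-cycle

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            lf.ld_diff_features(np.ones(8), np.ones(8))

    def test_invariant_to_additive_constant(self):
        rng = np.random.default_rng(0)
        series = rng.random(604)
        l1, d1 = lf.phase_averages(series, T604)
        l2, d2 = lf.phase_averages(series + 11.0, T604)
        np.testing.assert_allclose(
            lf.ld_diff_features(l1, d1), lf.ld_diff_features(l2, d2), atol=1e-9)


def _toy_series(rng, n=120):
    t = np.arange(n) / 3.0
    return lf.PlantTimeSeries(
        t=t, magnitude=rng.random(n), angle=rng.uniform(-np.pi, np.pi, n),
        pa=100 + rng.random(n), ld_label=np.where(np.mod(t, 24) < 15, "L", "D"))


class TestPCABlocks:
    def test_twenty_scores_per_plant(self):
        rng = np.random.default_rng(0)
        train = [_toy_series(rng) for _ in range(10)]
        pca = lf.PCABlockExtractor(5).fit(train)
        assert pca.transform(train[:3]).shape == (3, 20)

    def test_duplicate_plants_get_identical_scores(self):
        rng = np.random.default_rng(1)
        train = [_toy_series(rng) for _ in range(8)]
        pca = lf.PCABlockExtractor(5).fit(train)
        scores = pca.transform([train[0], train[0]])
        np.testing.assert_array_equal(scores[0], scores[1])

    def test_training_scores_are_centered(self):
        rng = np.random.default_rng(2)
        train = [_toy_series(rng) for _ in range(12)]
        pca = lf.PCABlockExtractor(5).fit(train)
        np.testing.assert_allclose(pca.transform(train).mean(axis=0), 0.0, atol=1e-9)

    def test_too_few_training_plants_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            lf.PCABlockExtractor(5).fit([_toy_series(rng) for _ in range(4)])

    def test_nan_angles_are_imputed(self):
        rng = np.random.default_rng(4)
        train = [_toy_series(rng) for _ in range(8)]
        train[0].angle[10:20] = np.nan
        pca = lf.PCABlockExtractor(5).fit(train)
        assert np.all(np.isfinite(pca.transform(train)))


class TestEnvironmentFeatures:
    def test_baseline_track_has_zero_indicators(self):
        np.testing.assert_array_equal(lf.environment_features(200.0, 1),
                                      [200.0, 0, 0, 0, 0])

    def test_track_three_sets_single_indicator(self):
        out = lf.environment_features(180.0, 3)
        assert len(out) == 5 and out[2] == 1.0 and out[1:].sum() == 1.0

    def test_unknown_track_rejected(self):
        with pytest.raises(ValueError):
            lf.environment_features(200.0, 6)


class TestAssembly:
    def test_group_sizes_sum_to_115(self):
        assert sum(GROUP_SIZES.values()) == 115
        assert len(lf.FEATURE_NAMES) == 115
        for name, size in GROUP_SIZES.items():
            sl = lf.FEATURE_GROUPS[name]
            assert sl.stop - sl.start == size

    def test_full_synthetic_plant_vector(self, analytic_cohort, pipeline_result):
        assert pipeline_result.features.shape[1] == 115
        assert list(pipeline_result.features.columns) == lf.FEATURE_NAMES

    def test_identical_plants_identical_vectors(self):
        rng = np.random.default_rng(5)
        train = [_toy_series(rng, n=604) for _ in range(8)]
        pca = lf.PCABlockExtractor(5).fit(train)
        a = lf.extract_features(train[0], 200.0, 2, pca)
        b = lf.extract_features(train[0], 200.0, 2, pca)
        np.testing.assert_array_equal(a.values, b.values)

    def test_wrong_block_length_rejected(self):
        with pytest.raises(ValueError, match="block"):
            lf.assemble_features(np.zeros(5), np.zeros(19), np.zeros(6),
                                 np.zeros(6), np.zeros(9), np.zeros(23),
                                 np.zeros(23), np.zeros(23))


class TestMovingAverageDiff:
    def test_constant_series_gives_zeros(self):
        _, out = lf.moving_average_diff(np.full(604, 5.0), T604)
        np.testing.assert_allclose(out, 0.0)

    def test_linear_series_gives_constant(self):
        _, out = lf.moving_average_diff(2.0 * T604 + 1.0, T604)
        np.testing.assert_allclose(out, 2.0 / 3.0, atol=1e-9)  # slope * dt

    def test_nutation_period_recovered_from_pa(self, analytic_cohort):
        _, cohort = analytic_cohort
        truth = cohort.plants[0]
        pa = cohort.series[0].pa * (1 + 0.02 * np.sin(
            2 * np.pi * cohort.series[0].t / truth.nutation_period))
        t_mid, out = lf.moving_average_diff(pa, cohort.series[0].t)
        detrended = out - np.polyval(np.polyfit(t_mid, out, 2), t_mid)
        freqs, power = periodogram(detrended, fs=3.0)  # samples per hour
        peak = 1.0 / freqs[1:][np.argmax(power[1:])]
        assert abs(peak - 24.0) <= 2.0
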