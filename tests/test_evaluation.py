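"""Tests for the sliding-window evaluation protocol and its metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fretcast.evaluation import (
    EXPERIMENTS,
    FretForecaster,
    ModelSummary,
    WindowConfig,
    evaluate_series,
    nrmse,
    performance_distance,
    repeat_evaluation,
    rescale_forecast,
    summarize_cohort,
    zscore_window,
)
from fretcast.exceptions import DegenerateWindowError


class OracleForecaster:
    """Upper-bound fixture: reads the true continuation off the full series."""

    name = "oracle"

    def __init__(self, series: np.ndarray, input_len: int):
        self.series = series
        self.input_len = input_len
        self.calls = 0

    def forecast(self, window, horizon):
        start = self.calls + self.input_len
        self.calls += 1
        return self.series[start : start + horizon]


class TestScaling:
    def test_zscore_example(self):
        scaled, mean, sd = zscore_window([1.0, 2.0, 3.0])
        assert (mean, sd) == (2.0, 1.0)
        np.testing.assert_allclose(scaled, [-1.0, 0.0, 1.0])

    @given(st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=50, unique=True))
    @settings(max_examples=50, derandomize=True)
    def test_round_trip_to_machine_precision(self, values):
        w = np.asarray(values)
        scaled, mean, sd = zscore_window(w)
        np.testing.assert_allclose(rescale_forecast(scaled, mean, sd), w,
                                   rtol=1e-12, atol=1e-9)

    def test_constant_window_rejected(self):
        with pytest.raises(DegenerateWindowError):
            zscore_window(np.full(10, 3.0))

    @pytest.mark.parametrize("scaled, mean, sd, expected", [
        ([0.0, 0.0], 7.0, 2.0, [7.0, 7.0]),
        ([-1.0, 1.0], 0.0, 3.0, [-3.0, 3.0]),
    ])
    def test_rescale_examples(self, scaled, mean, sd, expected):
        np.testing.assert_allclose(rescale_forecast(scaled, mean, sd), expected)

    def test_rescale_rejects_nonpositive_sd(self):
        with pytest.raises(ValueError):
            rescale_forecast([1.0], 0.0, 0.0)


class TestNrmse:
    def test_perfect_forecast_is_zero(self):
        assert nrmse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_frozen_example(self):
        # RMSE = sqrt(2/3), observed range = 2
        assert nrmse([1, 2, 3], [1, 3, 2]) == pytest.approx(np.sqrt(2 / 3) / 2, abs=1e-4)
        assert nrmse([1, 2, 3], [1, 3, 2]) == pytest.approx(0.4082, abs=1e-4)

    @given(st.floats(0.1, 50.0), st.floats(-100.0, 100.0), st.integers(0, 1000))
    @settings(max_examples=50, derandomize=True)
    def test_joint_affine_invariance(self, a, b, seed):
        rng = np.random.default_rng(seed)
        f, o = rng.normal(size=12), rng.normal(size=12)
        base = nrmse(f, o)
        np.testing.assert_allclose(nrmse(a * f + b, a * o + b), base, rtol=1e-9)

    def test_zero_range_rejected(self):
        with pytest.raises(DegenerateWindowError):
            nrmse([1.0, 2.0], [5.0, 5.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            nrmse([1.0], [1.0, 2.0])


class TestEvaluateSeries:
    @pytest.mark.parametrize("test_len, input_len, horizon", [
        (300, 50, 15),   # experiment-1 geometry on a 300-sample test half
        (300, 80, 20),   # experiment-2 geometry
        (100, 10, 5),
        (66, 50, 15),
    ])
    def test_window_count_formula(self, test_len, input_len, horizon, subject_series):
        rng = np.random.default_rng(0)
        series = np.tile(subject_series, 2)[:test_len] + rng.normal(0, 1e-6, test_len)
        cfg = WindowConfig(input_len, horizon)
        records = evaluate_series(series, FretForecaster(), cfg)
        assert len(records) == test_len - input_len - horizon + 1

    def test_experiment_presets(self):
        assert (EXPERIMENTS[1].input_len, EXPERIMENTS[1].horizon) == (50, 15)
        assert (EXPERIMENTS[2].input_len, EXPERIMENTS[2].horizon) == (80, 20)
        assert EXPERIMENTS[1].n_windows(300) == 236

    def test_oracle_forecaster_scores_zero_everywhere(self, train_test):
        _, test = train_test
        cfg = EXPERIMENTS[1]
        records = evaluate_series(test, OracleForecaster(test, cfg.input_len), cfg)
        assert all(r.nrmse == 0.0 for r in records if not r.skipped)

    def test_stride_one_consecutive_starts(self, train_test):
        _, test = train_test
        records = evaluate_series(test[:150], FretForecaster(), EXPERIMENTS[1])
        starts = [r.start for r in records]
        assert starts == list(range(len(records)))

    def test_degenerate_windows_skipped_without_forecaster_call(self):
        series = np.concatenate([np.full(30, 1.0), np.sin(np.arange(70.0))])
        cfg = WindowConfig(20, 5)

        class Exploding:
            name = "exploding"

            def forecast(self, window, horizon):
                assert np.std(window, ddof=1) > 0
                return window[:horizon]

        records = evaluate_series(series, Exploding(), cfg)
        skipped = [r.start for r in records if r.skipped]
        assert skipped and all(np.isnan(r.nrmse) for r in records if r.skipped)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            evaluate_series(np.arange(20.0), FretForecaster(), EXPERIMENTS[1])


class TestRepeatEvaluation:
    def test_deterministic_forecaster_zero_dispersion(self, train_test):
        _, test = train_test
        summary = repeat_evaluation(test, lambda seed: FretForecaster(),
                                    EXPERIMENTS[1], iterations=10, seed_base=1)
        assert summary.dispersion == 0.0
        assert summary.iterations == 10

    def test_identical_seeds_zero_dispersion(self, train_test):
        """A stochastic forecaster rerun with one frozen seed cannot disperse."""
        from fretcast.nnet import NNetSpec, fit_nnet
        from fretcast.evaluation import NNetForecaster

        train, test = train_test
        frozen = fit_nnet(train, NNetSpec(m=2, hidden=(2,)), seed=42)
        summary = repeat_evaluation(test, lambda seed: NNetForecaster(frozen),
                                    EXPERIMENTS[1], iterations=3, seed_base=0)
        assert summary.dispersion == 0.0

    def test_single_iteration_rejected(self, train_test):
        with pytest.raises(ValueError):
            repeat_evaluation(train_test[1], lambda s: FretForecaster(),
                              EXPERIMENTS[1], iterations=1)


def _summary(name, n, d, t):
    return ModelSummary(name=name, mean_nrmse=n, dispersion=d, mean_time=t, iterations=10)


class TestPerformanceDistance:
    def test_perfect_model_sits_on_the_ideal(self):
        points = performance_distance([
            _summary("perfect", 0.0, 0.0, 0.0),
            _summary("other", 0.2, 0.01, 0.05),
        ])
        assert points[0].distance_to_ideal == pytest.approx(0.0, abs=1e-12)
        assert points[1].distance_to_ideal > 0

    def test_symmetric_pair_hand_computed(self):
        # raw (1,1,1) and (3,3,3): per-variable mean 2, sample sd sqrt(2)
        # z = -+1/sqrt(2) each; ideal = -2/sqrt(2); distances sqrt(3)*(1/sqrt 2)
        # and sqrt(3)*(3/sqrt 2)
        points = performance_distance([
            _summary("a", 1.0, 1.0, 1.0), _summary("b", 3.0, 3.0, 3.0),
        ])
        assert points[0].distance_to_ideal == pytest.approx(np.sqrt(3 / 2))
        assert points[1].distance_to_ideal == pytest.approx(3 * np.sqrt(3 / 2))

    def test_invariant_to_per_variable_affine_rescaling(self):
        summaries = [_summary("a", 0.1, 0.01, 0.5), _summary("b", 0.3, 0.05, 0.2),
                     _summary("c", 0.2, 0.02, 0.9)]
        base = [p.distance_to_ideal for p in performance_distance(summaries)]
        scaled = [_summary(s.name, 1e3 * s.mean_nrmse, 50 * s.dispersion,
                           0.1 * s.mean_time) for s in summaries]
        rescaled = [p.distance_to_ideal for p in performance_distance(scaled)]
        np.testing.assert_allclose(rescaled, base, rtol=1e-9)

    def test_zero_cross_model_variance_rejected_with_guidance(self):
        with pytest.raises(ValueError, match="dispersion"):
            performance_distance([_summary("a", 0.1, 0.0, 0.5),
                                  _summary("b", 0.3, 0.0, 0.2)])

    def test_single_model_rejected(self):
        with pytest.raises(ValueError):
            performance_distance([_summary("a", 0.1, 0.0, 0.5)])


class TestSummarizeCohort:
    def test_identical_subjects_zero_spread(self):
        assert summarize_cohort([0.2] * 5).sd == 0.0

    def test_balanced_mean_is_grand_mean(self):
        vals = [0.1, 0.2, 0.3, 0.4]
        assert summarize_cohort(vals).mean == pytest.approx(np.mean(vals))

    def test_fifteen_subjects_give_fifteen_entries(self):
        assert len(summarize_cohort(list(np.linspace(0.05, 0.3, 15))).values) == 15

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            summarize_cohort([0.1])
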