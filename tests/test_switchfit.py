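"""Switch-model fitting, steepness, classification and delay statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from insightnet.switchfit import (
    InsightClassifier,
    bin_accuracy,
    classify_cohort,
    corrected_steepness,
    delay_and_alignment,
    fit_sigmoid,
    fit_switch_models,
    sigmoid,
    steepness,
    SwitchFit,
)
from tests.conftest import make_series


class TestBinAccuracy:
    @staticmethod
    def _table(correct):
        n = len(correct)
        return pd.DataFrame(
            {
                "trial": np.arange(n),
                "phase": ["motion"] * (n // 2) + ["colour"] * (n - n // 2),
                "coherence_pct": 5,
                "correct": correct,
            }
        )

    def test_all_correct_gives_unit_bins(self):
        s = bin_accuracy(self._table(np.ones(200, dtype=int)), bin_size=50)
        assert np.all(s.values == 1.0)
        assert s.y_min == 1.0

    def test_alternating_gives_half(self):
        s = bin_accuracy(self._table(np.tile([1, 0], 100)), bin_size=50)
        assert np.all(s.values == 0.5)

    def test_default_network_binning(self, trials):
        t = trials.copy()
        t["correct"] = 1
        s = bin_accuracy(t, bin_size=50)
        # motion + colour window = 700 trials -> 14 bins holding the 210
        # hardest trials (30 per block, split between half-blocks)
        assert len(s.values) == 14
        assert s.n_per_bin.sum() == 210
        assert np.all((s.n_per_bin >= 5) & (s.n_per_bin <= 25))
        assert s.onset_bin == 4.0

    def test_empty_bin_is_named(self):
        t = self._table(np.ones(200, dtype=int))
        t.loc[(t["trial"] >= 50) & (t["trial"] < 100), "coherence_pct"] = 45
        with pytest.raises(ValueError, match="bin 1"):
            bin_accuracy(t, bin_size=50, coherence=5)


class TestSwitchModels:
    def test_linear_data_prefers_linear(self):
        t = np.arange(14, dtype=float)
        s = make_series(0.02 * t + 0.6)
        fits = fit_switch_models(s)
        assert fits["linear"].bic == min(f.bic for f in fits.values())
        assert fits["linear"].params["m"] == pytest.approx(0.02, abs=1e-9)

    def test_step_data_recovers_step(self):
        y = np.where(np.arange(14) < 8, 0.6, 0.95)
        fits = fit_switch_models(make_series(y))
        assert fits["step"].params["t_s"] == 8
        assert fits["step"].params["y_max"] == pytest.approx(0.95)
        assert fits["step"].params["s"] == pytest.approx(0.35)
        assert fits["step"].sse < 1e-20

    def test_sigmoid_is_step_limit(self):
        # on exact step data the sigmoid SSE approaches the step SSE
        y = np.where(np.arange(14) < 8, 0.6, 0.95)
        s = make_series(y)
        fits = fit_switch_models(s)
        assert fits["sigmoid"].sse <= fits["step"].sse + 1e-3
        assert fits["sigmoid"].params["m"] > 5

    def test_needs_six_bins(self):
        with pytest.raises(ValueError):
            fit_sigmoid(make_series([0.6, 0.7, 0.8]))

    def test_parameter_recovery_under_noise(self):
        # generating model: m=4, t_s=10, y_max=0.95, y_min=0.6, 20 bins,
        # Gaussian noise SD 0.02; median recovery over 100 replicates
        rng = np.random.default_rng(99)
        t = np.arange(20, dtype=float)
        truth = sigmoid(t, 4.0, 10.0, 0.95, 0.6)
        ts_err, m_err, sse_gap = [], [], []
        for _ in range(100):
            y = truth + rng.normal(0, 0.02, len(t))
            f = fit_sigmoid(make_series(y, y_min=0.6))
            ts_err.append(abs(f.params["t_s"] - 10.0))
            m_err.append(abs(f.params["m"] - 4.0) / 4.0)
            sse_gap.append(f.sse - float(np.sum((truth - y) ** 2)))
        assert np.median(ts_err) <= 1.0
        # the optimiser always attains at least the truth's SSE; the slope's
        # remaining error is the ML estimator's sampling spread at this
        # noise level
        assert max(sse_gap) <= 1e-9
        assert np.median(m_err) <= 0.40


class TestSteepness:
    def test_closed_form_value(self):
        f = SwitchFit("sigmoid", {"m": 2.0, "t_s": 5.0, "y_max": 1.0, "y_min": 0.5},
                      sse=0.0, bic=0.0, n_bins=14)
        assert steepness(f) == pytest.approx(0.25)

    def test_flat_sigmoid_has_zero_slope(self):
        f = SwitchFit("sigmoid", {"m": 0.0, "t_s": 5.0, "y_max": 0.9, "y_min": 0.5},
                      sse=0.0, bic=0.0, n_bins=14)
        assert steepness(f) == 0.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_matches_numeric_derivative_at_inflection(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.uniform(0.1, 25)
        t_s = rng.uniform(0, 14)
        y_min = rng.uniform(0.4, 0.7)
        y_max = rng.uniform(y_min + 0.05, 1.0)
        f = SwitchFit("sigmoid", {"m": m, "t_s": t_s, "y_max": y_max, "y_min": y_min},
                      sse=0.0, bic=0.0, n_bins=14)
        h = 1e-4
        num = (sigmoid(t_s + h, m, t_s, y_max, y_min)
               - sigmoid(t_s - h, m, t_s, y_max, y_min)) / (2 * h)
        assert steepness(f) == pytest.approx(num, rel=1e-6, abs=1e-6)

    def test_corrected_steepness_penalties(self):
        s = make_series(np.full(14, 0.6))
        f = SwitchFit("sigmoid", {"m": 2.0, "t_s": 5.0, "y_max": 1.0, "y_min": 0.5},
                      sse=0.0, bic=0.0, n_bins=14, steepness=0.25)
        assert corrected_steepness(f, s, penalty="rmse") == pytest.approx(0.25)
        f.sse = 14 * 0.05**2  # RMSE 0.05
        assert corrected_steepness(f, s, penalty="rmse") == pytest.approx(0.20)
        assert corrected_steepness(f, s, penalty="none") == pytest.approx(0.25)

    def test_equal_rmse_preserves_ranking(self):
        vals = [0.1, 0.5, 0.3]
        fits = []
        for v in vals:
            f = SwitchFit("sigmoid", {}, sse=14 * 0.04**2, bic=0.0, n_bins=14,
                          steepness=v)
            fits.append(f)
        s = make_series(np.full(14, 0.6))
        none = [corrected_steepness(f, s, "none") for f in fits]
        rmse = [corrected_steepness(f, s, "rmse") for f in fits]
        assert np.argsort(none).tolist() == np.argsort(rmse).tolist()


class TestClassification:
    def test_threshold_is_control_max(self):
        clf = InsightClassifier().fit([0.02, 0.1, 0.05])
        assert clf.threshold_ == pytest.approx(0.1)
        assert clf.predict([0.05, 0.2]).tolist() == [False, True]

    def test_empty_control_rejected(self):
        with pytest.raises(ValueError):
            InsightClassifier().fit([])

    def test_self_thresholding_flags_nothing(self, rng):
        # strict inequality: a cohort classified against its own maximum
        # yields zero false positives
        vals = rng.normal(0.1, 0.05, 99)
        clf = InsightClassifier().fit(vals)
        assert not clf.predict(vals).any()

    def test_order_invariance(self, rng):
        exp = [_fit_with(cs) for cs in rng.normal(0.3, 0.2, 30)]
        ctl = [_fit_with(cs) for cs in rng.normal(0.1, 0.05, 30)]
        calls = classify_cohort(exp, ctl)
        perm = rng.permutation(30)
        calls_p = classify_cohort([exp[i] for i in perm], ctl)
        assert np.array_equal(
            calls["insight"].to_numpy()[perm], calls_p["insight"].to_numpy()
        )

    def test_independent_control_false_positive_rate(self, rng):
        # exchangeability: P(any of n values exceeds the max of n independent
        # controls) gives about n/(n+1) expected flagged ~ 1 per cohort
        n, reps, flagged = 50, 400, []
        for _ in range(reps):
            a = rng.normal(0, 1, n)
            b = rng.normal(0, 1, n)
            flagged.append(np.sum(a > b.max()))
        assert 0.5 < np.mean(flagged) < 2.0


def _fit_with(cs):
    return SwitchFit("sigmoid", {"t_s": 6.0}, sse=0.0, bic=0.0, n_bins=14,
                     steepness=cs, corrected_steepness=cs, switch_point=6.0)


class TestDelays:
    @staticmethod
    def _calls(delays, onset=4.0):
        exp = [_fit_with(1.0) for _ in delays]
        for f, d in zip(exp, delays):
            f.switch_point = onset + d
        calls = classify_cohort(exp, [_fit_with(0.0)])
        return calls

    def test_point_mass_rejects_uniformity(self):
        delays = np.full(49, 3.0)
        calls = self._calls(delays)
        series = [make_series(np.full(14, 0.6)) for _ in delays]
        out = delay_and_alignment(calls, series)
        assert out["n_insight"] == 49
        assert out["mean_delay_bins"] == pytest.approx(3.0)
        assert out["mean_delay_trials"] == pytest.approx(150.0)
        assert out["ks_pvalue"] < 0.05

    def test_uniform_delays_type_one_error(self, rng):
        # KS at alpha=.05 rejects ~5% of truly uniform delay samples
        n_post = 10.0
        rejections = 0
        reps = 400
        for _ in range(reps):
            delays = rng.uniform(0, n_post, 49)
            calls = self._calls(delays)
            series = [make_series(np.full(14, 0.6)) for _ in delays]
            out = delay_and_alignment(calls, series)
            rejections += out["ks_pvalue"] < 0.05
        assert 0.02 <= rejections / reps <= 0.09

    def test_no_insight_is_empty_not_error(self):
        calls = classify_cohort([_fit_with(0.0)], [_fit_with(1.0)])
        out = delay_and_alignment(calls, [make_series(np.full(14, 0.6))])
        assert out["n_insight"] == 0
        assert np.isnan(out["mean_delay_bins"])
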