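"""Gated linear network: forward rule, updates, gradients, replay."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from insightnet.network import (
    GatedLinearNetwork,
    Hyperparams,
    NetState,
    PARAM_NAMES,
    TraceOverflowError,
    data_gradients,
    forward,
    sgd_step,
)
from insightnet.task import sample_inputs


class TestForward:
    def test_noise_only_output(self):
        z, y_hat = forward(NetState(0, 0, 0, 0), x_m=1.0, x_c=1.0, eta=0.03)
        assert z == 0.03 and y_hat == 1

    def test_single_channel(self):
        z, y_hat = forward(NetState(1, 0, 1, 0), x_m=0.5, x_c=9.9, eta=0.0)
        assert z == 0.5 and y_hat == 1

    def test_hand_evaluated_output(self):
        # 0.5*2*(-0.3) + 0.1*1*0.22 = -0.278
        z, y_hat = forward(NetState(w_m=2, w_c=1, g_m=0.5, g_c=0.1), -0.3, 0.22, 0.0)
        assert z == pytest.approx(-0.278)
        assert y_hat == -1

    def test_sign_zero_is_positive(self):
        _, y_hat = forward(NetState(0, 0, 0, 0), 0.0, 0.0, 0.0)
        assert y_hat == 1


class TestSgdStep:
    HYPER = Hyperparams(l1_mode="subgradient", noise_scale="update")

    def test_hand_evaluated_l1_update(self):
        # all params 0.01, x=(0.3, 0.22), y=1: shared residual
        # r = 1e-4*0.3 + 1e-4*0.22 - 1 = -0.999948
        state = NetState(0.01, 0.01, 0.01, 0.01)
        new, grads = sgd_step(state, 0.3, 0.22, 1.0, self.HYPER, xi=np.zeros(4))
        r = 0.01 * 0.01 * 0.3 + 0.01 * 0.01 * 0.22 - 1.0
        assert new.w_m - 0.01 == pytest.approx(-0.6 * 0.3 * 0.01 * r, abs=1e-12)
        assert new.g_m - 0.01 == pytest.approx(
            -0.6 * 0.3 * 0.01 * r - 0.6 * 0.07 * 1.0, abs=1e-12
        )
        assert new.g_m - 0.01 == pytest.approx(-0.0402001, abs=1e-7)
        assert grads[0] == pytest.approx(0.3 * 0.01 * r)

    def test_proximal_pins_small_gate_to_zero(self):
        hyper = Hyperparams(l1_mode="proximal", noise_scale="update")
        state = NetState(0.01, 0.01, 0.01, 0.01)
        new, _ = sgd_step(state, 0.3, 0.22, 1.0, hyper, xi=np.zeros(4))
        assert new.g_m == 0.0 and new.g_c == 0.0
        assert new.w_m > 0.01  # weights are not thresholded

    def test_zero_inputs_zero_lambda_is_identity(self):
        hyper = Hyperparams(lam=0.0, l1_mode="subgradient")
        state = NetState(0.3, -0.2, 0.5, -0.1)
        new, grads = sgd_step(state, 0.0, 0.0, 1.0, hyper, xi=np.zeros(4))
        assert np.allclose(new.as_array(), state.as_array())
        assert np.allclose(grads, 0.0)

    def test_l2_penalty_weaker_than_l1_for_small_gates(self):
        state = NetState(0.5, 0.5, 0.3, -0.3)  # |g| < 1
        l1 = Hyperparams(regularizer="l1", l1_mode="subgradient")
        l2 = Hyperparams(regularizer="l2")
        xi = np.zeros(4)
        n1, g1 = sgd_step(state, 0.1, 0.1, 1.0, l1, xi=xi)
        n2, g2 = sgd_step(state, 0.1, 0.1, 1.0, l2, xi=xi)
        data_step = -l1.alpha * g1[2]
        pen1 = abs((n1.g_m - state.g_m) - data_step)
        pen2 = abs((n2.g_m - state.g_m) - data_step)
        assert pen2 == pytest.approx(l2.alpha * l2.lam * abs(state.g_m), abs=1e-12)
        assert pen2 < pen1

    def test_synchronous_update(self):
        # the gate update must use the pre-update weight (shared residual)
        state = NetState(2.0, 0.5, 0.7, 0.2)
        hyper = Hyperparams(lam=0.0, l1_mode="subgradient")
        new, grads = sgd_step(state, 0.4, -0.2, 1.0, hyper, xi=np.zeros(4))
        z = 0.7 * 2.0 * 0.4 + 0.2 * 0.5 * (-0.2)
        r = z - 1.0
        assert new.g_m == pytest.approx(state.g_m - 0.6 * 0.4 * 2.0 * r)

    def test_overflow_raises(self, trials):
        net = GatedLinearNetwork(alpha=1e6, sigma_xi=0.0)
        with pytest.raises(TraceOverflowError):
            net.fit(trials, rng=0)


def _loss(arr, x_m, x_c, y, eta, hyper):
    w_m, w_c, g_m, g_c = arr
    r = g_m * w_m * x_m + g_c * w_c * x_c + eta - y
    if hyper.regularizer == "l1":
        pen = hyper.lam * (abs(g_m) + abs(g_c))
    elif hyper.regularizer == "l2":
        pen = 0.5 * hyper.lam * (g_m**2 + g_c**2)
    else:
        pen = 0.0
    return 0.5 * r**2 + pen


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(0, 10**6), st.sampled_from(["l1", "l2", "none"]))
def test_analytic_gradients_match_finite_differences(seed, reg):
    """Central finite differences of the penalised loss vs the analytic
    update direction, to 1e-6 relative error (L1 sign frozen away from 0)."""
    rng = np.random.default_rng(seed)
    arr = rng.uniform(0.2, 2.0, 4) * rng.choice([-1, 1], 4)  # away from |g|=0
    x_m, x_c = rng.uniform(-0.5, 0.5, 2)
    y = rng.choice([-1.0, 1.0])
    eta = rng.normal(0, 0.05)
    hyper = Hyperparams(regularizer=reg, l1_mode="subgradient")

    state = NetState.from_array(arr)
    grads = data_gradients(state, x_m, x_c, y, eta)
    analytic = grads.copy()
    if reg == "l1":
        analytic[2:] += hyper.lam * np.sign(arr[2:])
    elif reg == "l2":
        analytic[2:] += hyper.lam * arr[2:]

    h = 1e-6
    for i in range(4):
        hi, lo = arr.copy(), arr.copy()
        hi[i] += h
        lo[i] -= h
        fd = (_loss(hi, x_m, x_c, y, eta, hyper) - _loss(lo, x_m, x_c, y, eta, hyper)) / (2 * h)
        denom = max(abs(fd), abs(analytic[i]), 1e-8)
        assert abs(fd - analytic[i]) / denom < 1e-5


class TestTraining:
    def test_identical_seeds_identical_traces(self, trials):
        a = GatedLinearNetwork().fit(trials, rng=5)
        b = GatedLinearNetwork().fit(trials, rng=5)
        pd.testing.assert_frame_equal(a.trace_, b.trace_)

    def test_replay_is_bit_exact(self, trials):
        net = GatedLinearNetwork().fit(trials, rng=6)
        rep = net.replay(trials)
        assert np.array_equal(
            rep.trace_[list(PARAM_NAMES)].to_numpy(),
            net.trace_[list(PARAM_NAMES)].to_numpy(),
        )
        assert np.array_equal(rep.correct_, net.correct_)

    def test_zero_noise_keeps_gates_silent(self, trials):
        # proximal L1 with no gradient noise: gates collapse to exactly 0 on
        # the first update and the weights stay frozen thereafter
        net = GatedLinearNetwork(sigma_xi=0.0).fit(trials, rng=1)
        tr = net.trace_
        assert np.all(tr["g_c"].to_numpy()[1:] == 0.0)
        assert np.all(tr["g_m"].to_numpy()[1:] == 0.0)
        # weights move only on the first trial (while the gates are nonzero)
        assert abs(net.state_.w_c - tr["w_c"].iloc[1]) < 1e-15
        assert abs(net.state_.w_c - 0.01) < 0.01
        assert abs(net.state_.g_c) < 0.01  # an uninformative gate ends below init

    def test_uninformative_gate_shrinks_under_l1(self, curriculum, input_model, rng):
        # colour never predictive, modest noise: |g_c| stays far below the
        # motion gate, which carries task information
        trials = sample_inputs(curriculum, input_model, rng, colour_predictive=False)
        net = GatedLinearNetwork(sigma_xi=0.01).fit(trials, rng=11)
        tr = net.trace_
        colour_phase = (trials["phase"] == "colour").to_numpy()
        assert np.abs(tr.loc[colour_phase, "g_c"]).mean() < 0.05

    def test_gateless_colour_growth_after_onset(self, input_model):
        # simplified model without gates, zero noise, colour predictive from
        # the start: |w_c| grows from its small initial value, fastest while
        # the residual is still large (the exponential-growth regime)
        from insightnet.task import CurriculumSpec, build_curriculum

        spec = CurriculumSpec(n_training_blocks=0, n_motion_blocks=0,
                              n_colour_blocks=5)
        trials = build_curriculum(spec, rng=3)
        trials = sample_inputs(trials, input_model, rng=3, colour_predictive=True)
        net = GatedLinearNetwork(
            gated=False, sigma_xi=0.0, sigma_eta=0.0, lam=0.0
        ).fit(trials, rng=3)
        wc = net.trace_["w_c"].to_numpy()
        early = wc[:60]
        assert np.all(np.diff(early) > 0)
        assert abs(net.state_.w_c) > 10 * abs(wc[0])

    def test_score_and_predict(self, trials):
        net = GatedLinearNetwork().fit(trials, rng=8)
        colour = trials[trials["phase"] == "colour"]
        assert net.score(colour) == pytest.approx(
            np.mean(net.predict(colour) == colour["y"]), abs=1e-12
        )

    def test_sklearn_param_interface(self):
        net = GatedLinearNetwork()
        params = net.get_params()
        assert params["lam"] == 0.07 and params["alpha"] == 0.6
        net.set_params(lam=0.02, regularizer="l2")
        assert net.get_params()["lam"] == 0.02
        with pytest.raises(ValueError):
            net.set_params(unknown=1)
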