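"""Hidden-layer variant: 2 inputs -> 48 ReLU units -> 2 outputs.

Each input-to-hidden weight carries one multiplicative gate; the L1 penalty
acts on the gates only, as in the scalar model.  The network is trained
per-trial on the cross-entropy of a softmax readout, with Gaussian noise on
the output logits (the analogue of the scalar model's output noise) and on
every gradient update.

The input-to-hidden weights are W1 (n_hidden x 2, column 0 = motion,
column 1 = colour) with gates G of the same shape applied elementwise; the
readout is W2 (n_hidden x 2).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .network import TraceOverflowError

__all__ = ["HiddenLayerNetwork", "ce_forward", "ce_gradients"]


def ce_forward(W1, G, W2, x, eta):
    """Forward pass; returns (hidden pre-activation, hidden, logits, probs)."""
    pre = (G * W1) @ x
    h = np.maximum(pre, 0.0)
    logits = W2.T @ h + eta
    e = np.exp(logits - logits.max())
    p = e / e.sum()
    return pre, h, logits, p


def ce_gradients(W1, G, W2, x, y_class, eta):
    """Loss and analytic gradients of the gated cross-entropy.

    ``y_class`` is 0 or 1.  Returns ``(loss, p, dW1, dG, dW2)``; the gate and
    weight gradients share the factor ``outer(dpre, x)`` so that, exactly as
    in the scalar model, the weight gradient carries the gate and vice versa.
    """
    pre, h, logits, p = ce_forward(W1, G, W2, x, eta)
    loss = -float(np.log(max(p[y_class], 1e-300)))
    dlogits = p.copy()
    dlogits[y_class] -= 1.0
    dW2 = np.outer(h, dlogits)
    dh = W2 @ dlogits
    dpre = dh * (pre > 0)
    common = np.outer(dpre, x)
    dW1 = G * common
    dG = W1 * common
    return loss, p, dW1, dG, dW2


class HiddenLayerNetwork:
    """Gated two-layer ReLU network trained by noisy online SGD.

    scikit-learn style estimator; see :class:`~insightnet.network.
    GatedLinearNetwork` for the conventions.  Defaults follow the deep
    variant of the study: 48 hidden units, ``lam = 0.002`` on the gates,
    ``alpha = 0.1``.

    The first-layer weights are initialised Kaiming-uniform
    (``U(+-sqrt(6 / fan_in))``); the gates start at the same small constant
    as the scalar model's (0.01), which preserves the silent-knowledge
    mechanism: weights can drift while gating suppresses their effect.

    Attributes set by :meth:`fit`: ``correct_``, ``state_`` (dict of final
    ``W1, G, W2``), ``trace_`` (per-trial loss, correctness and per-channel
    mean absolute gates/weights/gradients).
    """

    def __init__(
        self,
        n_hidden: int = 48,
        alpha: float = 0.1,
        lam: float = 0.002,
        sigma_eta: float = 0.05,
        sigma_xi: float = 0.01,
        l1_mode: str = "proximal",
        gate_init: float = 0.01,
    ):
        self.n_hidden = n_hidden
        self.alpha = alpha
        self.lam = lam
        self.sigma_eta = sigma_eta
        self.sigma_xi = sigma_xi
        self.l1_mode = l1_mode
        self.gate_init = gate_init

    _param_names = (
        "n_hidden", "alpha", "lam", "sigma_eta", "sigma_xi", "l1_mode",
        "gate_init",
    )

    def get_params(self, deep: bool = True) -> dict:
        return {p: getattr(self, p) for p in self._param_names}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def _init_state(self, rng: np.random.Generator):
        nh = self.n_hidden
        lim1 = np.sqrt(6.0 / 2.0)
        lim2 = np.sqrt(6.0 / nh)
        W1 = rng.uniform(-lim1, lim1, (nh, 2))
        G = np.full((nh, 2), self.gate_init)
        W2 = rng.uniform(-lim2, lim2, (nh, 2))
        return W1, G, W2

    def fit(
        self,
        trials: pd.DataFrame,
        y=None,
        rng: np.random.Generator | int | None = None,
        record_trace: bool = True,
    ) -> "HiddenLayerNetwork":
        rng = np.random.default_rng(rng)
        n = len(trials)
        X = trials[["x_m", "x_c"]].to_numpy(dtype=float)
        y_class = ((trials["y"].to_numpy() + 1) // 2).astype(int)

        W1, G, W2 = self._init_state(rng)
        a, lam = self.alpha, self.lam
        thr = a * lam
        prox = self.l1_mode == "proximal"
        correct = np.empty(n, dtype=bool)
        if record_trace:
            cols = np.empty((n, 9))

        for t in range(n):
            eta = rng.normal(0.0, self.sigma_eta, 2) if self.sigma_eta > 0 else np.zeros(2)
            loss, p, dW1, dG, dW2 = ce_gradients(W1, G, W2, X[t], y_class[t], eta)
            correct[t] = int(np.argmax(p)) == y_class[t]
            if record_trace:
                cols[t] = (
                    loss,
                    np.abs(G[:, 0]).mean(), np.abs(G[:, 1]).mean(),
                    np.abs(W1[:, 0]).mean(), np.abs(W1[:, 1]).mean(),
                    np.abs(dG[:, 0]).mean(), np.abs(dG[:, 1]).mean(),
                    np.abs(dW1[:, 0]).mean(), np.abs(dW1[:, 1]).mean(),
                )
            s = self.sigma_xi
            W1 = W1 - a * dW1 + rng.normal(0.0, s, W1.shape)
            W2 = W2 - a * dW2 + rng.normal(0.0, s, W2.shape)
            Gn = G - a * dG + rng.normal(0.0, s, G.shape)
            if prox:
                G = np.sign(Gn) * np.maximum(np.abs(Gn) - thr, 0.0)
            else:
                G = Gn - thr * np.sign(G)
            if not (np.all(np.isfinite(W1)) and np.all(np.isfinite(W2))
                    and np.all(np.isfinite(G))):
                raise TraceOverflowError(f"non-finite parameters at trial {t}")

        self.state_ = {"W1": W1, "G": G, "W2": W2}
        self.correct_ = correct
        self.n_trials_ = n
        if record_trace:
            trace = trials.reset_index(drop=True).copy()
            for j, name in enumerate(
                ["loss", "abs_g_m", "abs_g_c", "abs_w_m", "abs_w_c",
                 "abs_grad_g_m", "abs_grad_g_c", "abs_grad_w_m", "abs_grad_w_c"]
            ):
                trace[name] = cols[:, j]
            trace["correct"] = correct
            self.trace_ = trace
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Noise-free decisions (+-1) for a table with ``x_m, x_c``."""
        if not hasattr(self, "state_"):
            raise RuntimeError("fit the network first")
        s = self.state_
        out = np.empty(len(X), dtype=int)
        for i, x in enumerate(X[["x_m", "x_c"]].to_numpy(dtype=float)):
            _, _, _, p = ce_forward(s["W1"], s["G"], s["W2"], x, np.zeros(2))
            out[i] = 2 * int(np.argmax(p)) - 1
        return out

    def score(self, X: pd.DataFrame, y=None) -> float:
        lab = X["y"].to_numpy() if y is None else np.asarray(y)
        return float(np.mean(self.predict(X) == lab))
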