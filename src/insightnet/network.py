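"""The gated linear network family trained by noisy online SGD.

The base model has four learnable scalars: input weights ``w_m, w_c`` and
multiplicative gates ``g_m, g_c``.  Its continuous output on a trial is

    z = g_m w_m x_m + g_c w_c x_c + eta,      eta ~ N(0, sigma_eta)

and the decision is ``sign(z)``.  Learning minimises the squared error of
``z`` against the label ``y = +-1`` with a penalty on the gates only
(L1, L2 or none), one online update per trial, with Gaussian noise injected
into every parameter update.  The noise is specified as a per-gradient SD
and by default enters the update scaled by the learning rate
(``noise_scale="gradient"``, effective SD ``alpha * sigma_xi``);
``"update"`` applies it unscaled.  For the L1 penalty two applications are
available:

- ``"proximal"`` (default): soft-thresholding of the gates after the data
  step (the ISTA-style application of the penalty).  Sub-threshold gates are
  pinned at exactly zero between updates, which produces the sustained
  suppression ("silent knowledge") regime and makes gradient noise necessary
  for a colour switch.
- ``"subgradient"``: the literal update ``-alpha * lam * sign(g)`` added to
  the data gradient.  Because the penalty step overshoots zero, a gate then
  oscillates in a small limit cycle instead of staying at zero, which lets
  networks bootstrap the suppressed input even without gradient noise.

A gateless variant (``gated=False``) trains the weights alone with no
penalty and is the simplified model whose colour weights grow exponentially
after onset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "PARAM_NAMES",
    "NOISE_GROUPS",
    "NetState",
    "Hyperparams",
    "forward",
    "data_gradients",
    "sgd_step",
    "GatedLinearNetwork",
    "TraceOverflowError",
]

#: Order of the learnable parameters in all array representations.
PARAM_NAMES = ("w_m", "w_c", "g_m", "g_c")

#: Named parameter groups accepted when specifying per-group gradient-noise
#: SDs (used by the component-wise noise sweeps).
NOISE_GROUPS = {
    "all": PARAM_NAMES,
    "weights_only": ("w_m", "w_c"),
    "gates_only": ("g_m", "g_c"),
    "motion_params": ("w_m", "g_m"),
    "colour_params": ("w_c", "g_c"),
}


class TraceOverflowError(FloatingPointError):
    """A parameter became non-finite during training."""


@dataclass
class NetState:
    """The four learnable scalars of the gated linear network."""

    w_m: float = 0.01
    w_c: float = 0.01
    g_m: float = 0.01
    g_c: float = 0.01

    def as_array(self) -> np.ndarray:
        return np.array([self.w_m, self.w_c, self.g_m, self.g_c], dtype=float)

    @classmethod
    def from_array(cls, a) -> "NetState":
        return cls(*(float(v) for v in a))


def _sigma_xi_array(sigma_xi) -> np.ndarray:
    """Normalise a scalar or per-parameter mapping of noise SDs to an array."""
    if isinstance(sigma_xi, Mapping):
        return np.array([float(sigma_xi.get(p, 0.0)) for p in PARAM_NAMES])
    return np.full(4, float(sigma_xi))


@dataclass(frozen=True)
class Hyperparams:
    """Training hyperparameters.

    ``sigma_xi`` may be a scalar (same gradient-noise SD for all four
    parameters) or a mapping from parameter name to SD, which supports the
    component-wise noise manipulations.  ``noise_scale`` selects whether the
    noise SD applies to the raw gradient, so that the learning rate scales
    it into the update (``"gradient"``, effective SD ``alpha * sigma_xi``,
    the default), or directly to the update (``"update"``).
    """

    alpha: float = 0.6
    lam: float = 0.07
    sigma_eta: float = 0.05
    sigma_xi: float | Mapping[str, float] = 0.05
    regularizer: str = "l1"  # "l1" | "l2" | "none"
    gated: bool = True
    l1_mode: str = "proximal"  # "proximal" | "subgradient"
    noise_scale: str = "gradient"  # "gradient" | "update"
    init: float = 0.01

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.lam < 0 or self.sigma_eta < 0:
            raise ValueError("lam and sigma_eta must be >= 0")
        if self.regularizer not in ("l1", "l2", "none"):
            raise ValueError(f"unknown regularizer {self.regularizer!r}")
        if self.l1_mode not in ("proximal", "subgradient"):
            raise ValueError(f"unknown l1_mode {self.l1_mode!r}")
        if self.noise_scale not in ("update", "gradient"):
            raise ValueError(f"unknown noise_scale {self.noise_scale!r}")
        if np.any(_sigma_xi_array(self.sigma_xi) < 0):
            raise ValueError("sigma_xi must be >= 0")

    def as_kwargs(self) -> dict:
        return {
            "alpha": self.alpha,
            "lam": self.lam,
            "sigma_eta": self.sigma_eta,
            "sigma_xi": self.sigma_xi,
            "regularizer": self.regularizer,
            "gated": self.gated,
            "l1_mode": self.l1_mode,
            "noise_scale": self.noise_scale,
            "init": self.init,
        }


def forward(state: NetState, x_m: float, x_c: float, eta: float = 0.0):
    """Continuous output and decision for one trial.

    Returns ``(z, y_hat)`` with ``y_hat = sign(z)`` and ``sign(0)`` defined
    as ``+1`` (a tie-break on a measure-zero event).
    """
    z = state.g_m * state.w_m * x_m + state.g_c * state.w_c * x_c + eta
    return z, (1 if z >= 0 else -1)


def data_gradients(
    state: NetState, x_m: float, x_c: float, y: float, eta: float = 0.0,
    gated: bool = True,
) -> np.ndarray:
    """Raw gradients of the squared data loss w.r.t. (w_m, w_c, g_m, g_c).

    All four components are evaluated at the same (pre-update) state and
    share the residual ``r = z - y``; the output noise realisation ``eta``
    used in the forward pass enters the residual.  The penalty term is not
    included.  For the gateless model the weight gradients omit the gate
    factors and the gate gradients are zero.
    """
    if gated:
        z = state.g_m * state.w_m * x_m + state.g_c * state.w_c * x_c + eta
        r = z - y
        return np.array(
            [
                x_m * state.g_m * r,
                x_c * state.g_c * r,
                x_m * state.w_m * r,
                x_c * state.w_c * r,
            ]
        )
    z = state.w_m * x_m + state.w_c * x_c + eta
    r = z - y
    return np.array([x_m * r, x_c * r, 0.0, 0.0])


def _soft_threshold(v: float, thr: float) -> float:
    if v > thr:
        return v - thr
    if v < -thr:
        return v + thr
    return 0.0


def sgd_step(
    state: NetState,
    x_m: float,
    x_c: float,
    y: float,
    hyper: Hyperparams,
    xi: np.ndarray | None = None,
    eta: float = 0.0,
    rng: np.random.Generator | None = None,
):
    """One synchronous noisy SGD update.

    All four parameters are updated from the same pre-update state.  ``xi``
    supplies the four noise draws (for replay); if absent they are drawn
    from ``rng``.  The regulariser acts on the gates only.  Returns
    ``(new_state, raw_gradients)`` where the raw gradients exclude noise and
    penalty.

    Raises ``TraceOverflowError`` if any parameter becomes non-finite.
    """
    if xi is None:
        sd = _sigma_xi_array(hyper.sigma_xi)
        if hyper.noise_scale == "gradient":
            sd = hyper.alpha * sd
        xi = (rng or np.random.default_rng()).normal(0.0, 1.0, 4) * sd
    grads = data_gradients(state, x_m, x_c, y, eta, gated=hyper.gated)
    a = hyper.alpha
    new = state.as_array() - a * grads + np.asarray(xi, dtype=float)
    if hyper.gated and hyper.regularizer == "l1":
        if hyper.l1_mode == "proximal":
            new[2] = _soft_threshold(new[2], a * hyper.lam)
            new[3] = _soft_threshold(new[3], a * hyper.lam)
        else:
            new[2] -= a * hyper.lam * np.sign(state.g_m)
            new[3] -= a * hyper.lam * np.sign(state.g_c)
    elif hyper.gated and hyper.regularizer == "l2":
        new[2] -= a * hyper.lam * state.g_m
        new[3] -= a * hyper.lam * state.g_c
    if not np.all(np.isfinite(new)):
        raise TraceOverflowError(f"non-finite parameters after update: {new}")
    return NetState.from_array(new), grads


class GatedLinearNetwork:
    """Gated linear network trained per-trial by noisy online SGD.

    A scikit-learn style estimator: hyperparameters are constructor
    arguments, :meth:`fit` consumes a trial table (from
    :func:`insightnet.task.sample_inputs`) and exposes fitted attributes
    with trailing underscores.

    Attributes set by :meth:`fit`
    -----------------------------
    state_ : NetState
        Final parameter values.
    correct_ : ndarray of bool, shape (n_trials,)
        Per-trial correctness.
    trace_ : pandas.DataFrame (when ``record_trace``)
        Per-trial pre-update parameters, raw data gradients, injected noise
        (``eta``, per-parameter ``xi``), continuous output ``z``, prediction
        and correctness, alongside the trial metadata; the raw material for
        the switch-locked dynamics analyses.  Re-running with the stored
        noise reproduces the trace bit-identically (see :meth:`replay`).
    """

    def __init__(
        self,
        alpha: float = 0.6,
        lam: float = 0.07,
        sigma_eta: float = 0.05,
        sigma_xi: float | Mapping[str, float] = 0.05,
        regularizer: str = "l1",
        gated: bool = True,
        l1_mode: str = "proximal",
        noise_scale: str = "gradient",
        init: float = 0.01,
    ):
        self.alpha = alpha
        self.lam = lam
        self.sigma_eta = sigma_eta
        self.sigma_xi = sigma_xi
        self.regularizer = regularizer
        self.gated = gated
        self.l1_mode = l1_mode
        self.noise_scale = noise_scale
        self.init = init

    # -- sklearn plumbing ---------------------------------------------------
    _param_names = (
        "alpha", "lam", "sigma_eta", "sigma_xi", "regularizer", "gated",
        "l1_mode", "noise_scale", "init",
    )

    def get_params(self, deep: bool = True) -> dict:
        return {p: getattr(self, p) for p in self._param_names}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def _hyper(self) -> Hyperparams:
        return Hyperparams(**self.get_params())

    # -- training -----------------------------------------------------------
    def fit(
        self,
        trials: pd.DataFrame,
        y=None,
        rng: np.random.Generator | int | None = None,
        init_state: NetState | None = None,
        record_trace: bool = True,
        noise: tuple[np.ndarray, np.ndarray] | None = None,
        intervention=None,
    ) -> "GatedLinearNetwork":
        """Train on a trial table, one update per trial in order.

        Parameters
        ----------
        trials : DataFrame with columns ``x_m, x_c, y`` (and metadata).
        rng : seed or Generator for the noise draws.
        noise : optional ``(eta, xi)`` arrays of shapes (n,) and (n, 4); when
            given, no randomness is consumed (used for bit-exact replay).
        intervention : optional callable ``f(t, state) -> NetState`` applied
            before the forward pass of trial ``t`` (used by the weight
            intervention experiment).
        """
        hyper = self._hyper()
        n = len(trials)
        x_m = trials["x_m"].to_numpy(dtype=float)
        x_c = trials["x_c"].to_numpy(dtype=float)
        lab = trials["y"].to_numpy(dtype=float)

        if noise is not None:
            eta, xi = noise
            eta = np.asarray(eta, dtype=float)
            xi = np.asarray(xi, dtype=float)
            if eta.shape != (n,) or xi.shape != (n, 4):
                raise ValueError("noise arrays have wrong shape")
        else:
            gen = np.random.default_rng(rng)
            eta = gen.normal(0.0, hyper.sigma_eta, n) if hyper.sigma_eta > 0 else np.zeros(n)
            sd = _sigma_xi_array(hyper.sigma_xi)
            if hyper.noise_scale == "gradient":
                sd = hyper.alpha * sd
            xi = gen.normal(0.0, 1.0, (n, 4)) * sd

        a = hyper.alpha
        lam = hyper.lam
        reg = hyper.regularizer
        prox = hyper.l1_mode == "proximal"
        gated = hyper.gated
        thr = a * lam

        s = (init_state or NetState(*([hyper.init] * 4))).as_array()
        w_m, w_c, g_m, g_c = s
        correct = np.empty(n, dtype=bool)
        z_out = np.empty(n)
        if record_trace:
            states = np.empty((n, 4))
            grads = np.empty((n, 4))

        for t in range(n):
            if intervention is not None:
                st = intervention(t, NetState(w_m, w_c, g_m, g_c))
                if st is not None:
                    w_m, w_c, g_m, g_c = st.w_m, st.w_c, st.g_m, st.g_c
            xm, xc, yt = x_m[t], x_c[t], lab[t]
            if gated:
                z = g_m * w_m * xm + g_c * w_c * xc + eta[t]
            else:
                z = w_m * xm + w_c * xc + eta[t]
            z_out[t] = z
            correct[t] = (z >= 0) == (yt > 0)
            r = z - yt
            if gated:
                d_wm = xm * g_m * r
                d_wc = xc * g_c * r
                d_gm = xm * w_m * r
                d_gc = xc * w_c * r
            else:
                d_wm = xm * r
                d_wc = xc * r
                d_gm = 0.0
                d_gc = 0.0
            if record_trace:
                states[t] = (w_m, w_c, g_m, g_c)
                grads[t] = (d_wm, d_wc, d_gm, d_gc)
            n_wm = w_m - a * d_wm + xi[t, 0]
            n_wc = w_c - a * d_wc + xi[t, 1]
            n_gm = g_m - a * d_gm + xi[t, 2]
            n_gc = g_c - a * d_gc + xi[t, 3]
            if gated and reg == "l1":
                if prox:
                    n_gm = _soft_threshold(n_gm, thr)
                    n_gc = _soft_threshold(n_gc, thr)
                else:
                    n_gm -= thr * np.sign(g_m)
                    n_gc -= thr * np.sign(g_c)
            elif gated and reg == "l2":
                n_gm -= thr * g_m
                n_gc -= thr * g_c
            w_m, w_c, g_m, g_c = n_wm, n_wc, n_gm, n_gc
            if not (
                np.isfinite(w_m) and np.isfinite(w_c)
                and np.isfinite(g_m) and np.isfinite(g_c)
            ):
                raise TraceOverflowError(
                    f"non-finite parameters at trial {t}: "
                    f"{(w_m, w_c, g_m, g_c)}"
                )

        self.state_ = NetState(w_m, w_c, g_m, g_c)
        self.correct_ = correct
        self.z_ = z_out
        self.n_trials_ = n
        if record_trace:
            trace = trials.reset_index(drop=True).copy()
            for j, p in enumerate(PARAM_NAMES):
                trace[p] = states[:, j]
            for j, p in enumerate(PARAM_NAMES):
                trace[f"grad_{p}"] = grads[:, j]
            for j, p in enumerate(PARAM_NAMES):
                trace[f"xi_{p}"] = xi[:, j]
            trace["eta"] = eta
            trace["z"] = z_out
            trace["y_hat"] = np.where(z_out >= 0, 1, -1)
            trace["correct"] = correct
            self.trace_ = trace
        return self

    def replay(self, trials: pd.DataFrame, trace: pd.DataFrame | None = None):
        """Re-run training from a stored trace's noise; returns a new fit.

        With the same trial table and the stored ``eta``/``xi`` columns the
        resulting trace is bit-identical to the original.
        """
        trace = trace if trace is not None else self.trace_
        eta = trace["eta"].to_numpy(dtype=float)
        xi = trace[[f"xi_{p}" for p in PARAM_NAMES]].to_numpy(dtype=float)
        clone = GatedLinearNetwork(**self.get_params())
        return clone.fit(trials, noise=(eta, xi))

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Decisions for a table with ``x_m, x_c`` columns (no output noise)."""
        if not hasattr(self, "state_"):
            raise RuntimeError("fit the network first")
        s = self.state_
        if self.gated:
            z = s.g_m * s.w_m * X["x_m"].to_numpy() + s.g_c * s.w_c * X["x_c"].to_numpy()
        else:
            z = s.w_m * X["x_m"].to_numpy() + s.w_c * X["x_c"].to_numpy()
        return np.where(z >= 0, 1, -1)

    def score(self, X: pd.DataFrame, y=None) -> float:
        """Fraction of correct decisions against the ``y`` column of ``X``."""
        lab = X["y"].to_numpy() if y is None else np.asarray(y)
        return float(np.mean(self.predict(X) == lab))
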