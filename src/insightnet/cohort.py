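"""Cohort-level experiments: matched cohorts, sweeps, interventions, dynamics.

Every simulated cohort pairs ``n`` experimental networks (colour becomes
predictive at onset) with ``n`` control networks (colour never predictive).
The two cohorts share the accuracy-matched motion means and curriculum
structure and differ only in colour predictiveness; the control cohort
defines the steepness threshold for the insight classification.

Seeding: one master seed determines every stream.  Child generators are
created as ``default_rng((master_seed, network_index, stream_tag))`` so a
cohort can be extended without reshuffling existing networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .network import GatedLinearNetwork, Hyperparams, NOISE_GROUPS, PARAM_NAMES
from .deep import HiddenLayerNetwork
from .switchfit import (
    AccuracySeries,
    SwitchFit,
    bin_accuracy,
    fit_sigmoid,
    classify_cohort,
    delay_and_alignment,
)
from .task import (
    COHERENCE_LEVELS,
    CurriculumSpec,
    InputModel,
    build_curriculum,
    fit_motion_means,
    sample_inputs,
    synth_target_profiles,
)

__all__ = [
    "CohortResult",
    "SweepResult",
    "fit_cohort_means",
    "run_cohort",
    "run_noise_sweep",
    "run_lambda_sweep",
    "weight_intervention",
    "dynamics_analysis",
    "change_point",
]

# Stream tags for child-seed derivation.
_STREAM_PROFILES = 0xA
_STREAM_MATCH = 0xB
_STREAM_EXP_TASK = 1
_STREAM_EXP_TRAIN = 2
_STREAM_CTL_TASK = 3
_STREAM_CTL_TRAIN = 4


@dataclass
class CohortResult:
    """Matched experimental + control cohorts with classification results."""

    n: int
    seed: int
    hyper: dict
    profiles: np.ndarray
    means: list[dict]
    calls: pd.DataFrame  # per-network: corrected_steepness, insight, switch_point, delay_bins
    threshold: float
    exp_fits: list[SwitchFit]
    ctl_fits: list[SwitchFit]
    series_exp: list[AccuracySeries]
    series_ctl: list[AccuracySeries]
    summary: pd.DataFrame  # per-network accuracy and parameter summaries
    delay_stats: dict
    traces: list[pd.DataFrame] | None = None
    spec: CurriculumSpec = field(default_factory=CurriculumSpec)

    @property
    def insight_fraction(self) -> float:
        return float(self.calls["insight"].mean())

    @property
    def n_insight(self) -> int:
        return int(self.calls["insight"].sum())

    def group_mean(self, column: str, insight: bool) -> float:
        sel = self.calls["insight"] == insight
        if not sel.any():
            return float("nan")
        return float(self.summary.loc[sel.to_numpy(), column].mean())


@dataclass
class SweepResult:
    """Insight fraction (and delay) over a hyperparameter grid."""

    parameter: str
    grid: np.ndarray
    fractions: np.ndarray  # (len(grid), reps)
    mean_delays: np.ndarray  # (len(grid), reps), NaN where no insight nets
    reps: int

    @property
    def mean_fraction(self) -> np.ndarray:
        return self.fractions.mean(axis=1)

    def trend(self) -> dict:
        """Spearman trend of fraction (and delay) against the grid."""
        g = np.repeat(self.grid, self.reps)
        rho_f, p_f = stats.spearmanr(g, self.fractions.ravel())
        d = self.mean_delays.ravel()
        ok = np.isfinite(d)
        if ok.sum() >= 3 and np.unique(g[ok]).size > 1:
            rho_d, p_d = stats.spearmanr(g[ok], d[ok])
        else:
            rho_d, p_d = np.nan, np.nan
        return {
            "fraction_rho": float(rho_f),
            "fraction_p": float(p_f),
            "delay_rho": float(rho_d),
            "delay_p": float(p_d),
        }


def fit_cohort_means(
    profiles: np.ndarray,
    hyper: Hyperparams,
    spec: CurriculumSpec,
    seed: int,
    **fit_kwargs,
) -> list[dict]:
    """Accuracy-match motion means for every profile in a cohort."""
    return [
        fit_motion_means(
            profiles[i], hyper, spec,
            seed=int(np.random.default_rng((seed, i, _STREAM_MATCH)).integers(2**31)),
            **fit_kwargs,
        ).means
        for i in range(len(profiles))
    ]


def _train_one(
    i: int,
    seed: int,
    means: dict,
    hyper: Hyperparams,
    spec: CurriculumSpec,
    colour_predictive: bool,
    task_tag: int,
    train_tag: int,
    record_trace: bool,
    input_model_kwargs: dict | None = None,
    intervention=None,
    estimator: str = "linear",
):
    model = InputModel(M_m=means, **(input_model_kwargs or {}))
    trials = build_curriculum(spec, np.random.default_rng((seed, i, task_tag)))
    trials = sample_inputs(
        trials, model, np.random.default_rng((seed, i, task_tag, 1)),
        colour_predictive=colour_predictive,
    )
    if estimator == "hidden":
        net = HiddenLayerNetwork(**(hyper if isinstance(hyper, dict) else {}))
        net.fit(trials, rng=np.random.default_rng((seed, i, train_tag)),
                record_trace=record_trace)
    else:
        net = GatedLinearNetwork(**hyper.as_kwargs())
        net.fit(trials, rng=np.random.default_rng((seed, i, train_tag)),
                record_trace=record_trace, intervention=intervention)
    trials = trials.copy()
    trials["correct"] = net.correct_
    return net, trials


def _summarise(net, trials, spec: CurriculumSpec, hidden: bool) -> dict:
    lowest = min(COHERENCE_LEVELS)
    ph = trials["phase"]
    coh = trials["coherence_pct"]
    correct = trials["correct"]
    onset = spec.colour_onset_trial
    out = {
        "training_acc": float(correct[ph == "training"].mean()),
        "motion_acc_lowest": float(
            correct[(ph == "motion") & (coh == lowest)].mean()
        ),
        "colour_acc_lowest": float(
            correct[(ph == "colour") & (coh == lowest)].mean()
        ),
        "colour_acc_all": float(correct[ph == "colour"].mean()),
    }
    if hidden:
        tr = net.trace_
        out.update(
            onset_abs_w_c=float(tr["abs_w_c"].iloc[onset]),
            onset_abs_g_c=float(tr["abs_g_c"].iloc[onset]),
            end_abs_g_c=float(tr["abs_g_c"].iloc[-1]),
            end_abs_g_m=float(tr["abs_g_m"].iloc[-1]),
        )
    else:
        tr = net.trace_
        out.update(
            onset_abs_w_m=float(abs(tr["w_m"].iloc[onset])),
            onset_abs_w_c=float(abs(tr["w_c"].iloc[onset])),
            onset_abs_g_m=float(abs(tr["g_m"].iloc[onset])),
            onset_abs_g_c=float(abs(tr["g_c"].iloc[onset])),
            end_abs_g_m=float(abs(tr["g_m"].iloc[-1])),
            end_abs_g_c=float(abs(tr["g_c"].iloc[-1])),
            end_abs_w_m=float(abs(tr["w_m"].iloc[-1])),
            end_abs_w_c=float(abs(tr["w_c"].iloc[-1])),
        )
    return out


def run_cohort(
    n: int = 99,
    seed: int = 0,
    hyper: Hyperparams | None = None,
    spec: CurriculumSpec | None = None,
    profiles: np.ndarray | None = None,
    means: list[dict] | None = None,
    bin_size: int = 50,
    keep_traces: bool = True,
    input_model_kwargs: dict | None = None,
    intervention=None,
    estimator: str = "linear",
    match_kwargs: dict | None = None,
) -> CohortResult:
    """Simulate a matched cohort with its control and classify switches.

    Trains ``n`` experimental networks (colour predictive after onset) and
    ``n`` controls (never predictive) on accuracy-matched inputs, fits the
    sigmoid switch model to the lowest-coherence binned accuracy of every
    network, thresholds the experimental corrected steepness at the control
    maximum, and collects delays and accuracy/parameter summaries.

    ``means`` (or ``profiles``) may be passed to reuse an existing matching;
    otherwise profiles are drawn and means fitted from the master seed.
    ``intervention`` is applied to experimental and control networks alike.
    ``estimator="hidden"`` trains the hidden-layer variant (``hyper`` is then
    a dict of :class:`HiddenLayerNetwork` kwargs).
    """
    hidden = estimator == "hidden"
    if hyper is None:
        hyper = {} if hidden else Hyperparams()
    spec = spec or CurriculumSpec()
    if means is None:
        if profiles is None:
            profiles = synth_target_profiles(
                n, np.random.default_rng((seed, _STREAM_PROFILES))
            )
        match_hyper = hyper if not hidden else Hyperparams()
        means = fit_cohort_means(
            profiles, match_hyper, spec, seed, **(match_kwargs or {})
        )
    else:
        profiles = profiles if profiles is not None else np.full((n, 5), np.nan)

    exp_fits, ctl_fits = [], []
    series_exp, series_ctl = [], []
    rows = []
    traces: list[pd.DataFrame] | None = [] if keep_traces else None
    for i in range(n):
        net_e, tr_e = _train_one(
            i, seed, means[i], hyper, spec, True,
            _STREAM_EXP_TASK, _STREAM_EXP_TRAIN, True,
            input_model_kwargs, intervention, estimator,
        )
        net_c, tr_c = _train_one(
            i, seed, means[i], hyper, spec, False,
            _STREAM_CTL_TASK, _STREAM_CTL_TRAIN, True,
            input_model_kwargs, intervention, estimator,
        )
        se = bin_accuracy(tr_e, bin_size=bin_size, subject_id=i)
        sc = bin_accuracy(tr_c, bin_size=bin_size, subject_id=i)
        series_exp.append(se)
        series_ctl.append(sc)
        exp_fits.append(fit_sigmoid(se))
        ctl_fits.append(fit_sigmoid(sc))
        rows.append(_summarise(net_e, tr_e, spec, hidden))
        if keep_traces:
            traces.append(net_e.trace_)

    calls = classify_cohort(exp_fits, ctl_fits)
    onset_bin = series_exp[0].onset_bin
    calls["delay_bins"] = calls["switch_point"] - onset_bin
    calls["delay_trials"] = calls["delay_bins"] * bin_size
    delay_stats = delay_and_alignment(calls, series_exp)
    return CohortResult(
        n=n,
        seed=seed,
        hyper=(hyper if isinstance(hyper, dict) else hyper.as_kwargs()),
        profiles=np.asarray(profiles),
        means=means,
        calls=calls,
        threshold=calls.attrs["threshold"],
        exp_fits=exp_fits,
        ctl_fits=ctl_fits,
        series_exp=series_exp,
        series_ctl=series_ctl,
        summary=pd.DataFrame(rows),
        delay_stats=delay_stats,
        traces=traces,
        spec=spec,
    )


def _sigma_dict(component: str, sigma: float, base: float = 0.0) -> dict:
    """Per-parameter noise SDs: ``sigma`` on the component group, ``base``
    elsewhere."""
    if component not in NOISE_GROUPS:
        raise ValueError(
            f"unknown component {component!r}; choose from {sorted(NOISE_GROUPS)}"
        )
    group = NOISE_GROUPS[component]
    return {p: (sigma if p in group else base) for p in PARAM_NAMES}


def run_noise_sweep(
    component: str = "all",
    sigma_grid=(0.0, 0.01, 0.02, 0.03, 0.04, 0.05, 0.06),
    reps: int = 10,
    n: int = 99,
    seed: int = 0,
    hyper: Hyperparams | None = None,
    means: list[dict] | None = None,
    **cohort_kwargs,
) -> SweepResult:
    """Insight fraction as a function of gradient-noise SD.

    ``component`` selects which parameter group receives the swept noise
    (``all``, ``weights_only``, ``gates_only``, ``motion_params``,
    ``colour_params``); the remaining parameters receive no gradient noise,
    isolating the contribution of the swept component.  Grid values are
    *effective* per-update SDs (``noise_scale="update"`` is forced for the
    swept cohorts), so sweep curves are comparable across learning rates.
    Each grid point and repetition trains a fresh experimental + control
    cohort pair and re-derives the control threshold.  Motion means are
    matched once under the base hyperparameters and shared across the grid.
    """
    base = hyper or Hyperparams()
    base = Hyperparams(**{**base.as_kwargs(), "noise_scale": "update"})
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    if means is None:
        profiles = synth_target_profiles(
            n, np.random.default_rng((seed, _STREAM_PROFILES))
        )
        means = fit_cohort_means(profiles, base, CurriculumSpec(), seed)
    fractions = np.empty((len(sigma_grid), reps))
    delays = np.full((len(sigma_grid), reps), np.nan)
    for gi, sig in enumerate(sigma_grid):
        h = Hyperparams(**{**base.as_kwargs(), "sigma_xi": _sigma_dict(component, sig)})
        for rep in range(reps):
            res = run_cohort(
                n=n, seed=int(np.random.default_rng((seed, gi, rep, 0xC)).integers(2**31)),
                hyper=h, means=means, keep_traces=False, **cohort_kwargs,
            )
            fractions[gi, rep] = res.insight_fraction
            if res.n_insight:
                delays[gi, rep] = res.delay_stats["mean_delay_bins"]
    return SweepResult(
        parameter=f"sigma_xi[{component}]",
        grid=sigma_grid, fractions=fractions, mean_delays=delays, reps=reps,
    )


def run_lambda_sweep(
    lambda_grid=(0.01, 0.03, 0.05, 0.07, 0.09, 0.11, 0.13, 0.15),
    reps: int = 3,
    n: int = 99,
    seed: int = 0,
    hyper: Hyperparams | None = None,
    means: list[dict] | None = None,
    min_insight_for_delay: int = 5,
    **cohort_kwargs,
) -> SweepResult:
    """Insight fraction and mean switch delay as a function of the
    regularisation strength.

    Motion means are matched once at the base hyperparameters and shared, so
    the sweep isolates the effect of the penalty on the colour switch.
    Delays enter the trend only for grid points with at least
    ``min_insight_for_delay`` insight networks.
    """
    base = hyper or Hyperparams()
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if np.any(lambda_grid < 0):
        raise ValueError("lambda must be >= 0")
    if means is None:
        profiles = synth_target_profiles(
            n, np.random.default_rng((seed, _STREAM_PROFILES))
        )
        means = fit_cohort_means(profiles, base, CurriculumSpec(), seed)
    fractions = np.empty((len(lambda_grid), reps))
    delays = np.full((len(lambda_grid), reps), np.nan)
    for gi, lam in enumerate(lambda_grid):
        h = Hyperparams(**{**base.as_kwargs(), "lam": float(lam)})
        for rep in range(reps):
            res = run_cohort(
                n=n, seed=int(np.random.default_rng((seed, gi, rep, 0xD)).integers(2**31)),
                hyper=h, means=means, keep_traces=False, **cohort_kwargs,
            )
            fractions[gi, rep] = res.insight_fraction
            if res.n_insight >= min_insight_for_delay:
                delays[gi, rep] = res.delay_stats["mean_delay_bins"]
    return SweepResult(
        parameter="lambda",
        grid=lambda_grid, fractions=fractions, mean_delays=delays, reps=reps,
    )


def weight_intervention(
    base_cohort: CohortResult,
    n: int = 99,
    seed: int = 1,
    hyper: Hyperparams | None = None,
    **cohort_kwargs,
) -> CohortResult:
    """Pre-onset weight adjustment experiment.

    Extracts the mean absolute colour and motion weights of the base
    cohort's insight networks at the first colour-phase trial, then trains a
    fresh cohort in which, at that trial, each network's ``|w_c|`` and
    ``|w_m|`` are set to those donor means (signs preserved, gates
    untouched).  The intervention is part of the pipeline, so experimental
    and control networks are treated identically and the threshold is
    re-derived.
    """
    if base_cohort.n_insight == 0:
        raise ValueError("base cohort has no insight networks to define donor means")
    ins = base_cohort.calls["insight"].to_numpy()
    donor_wc = float(base_cohort.summary.loc[ins, "onset_abs_w_c"].mean())
    donor_wm = float(base_cohort.summary.loc[ins, "onset_abs_w_m"].mean())
    onset = base_cohort.spec.colour_onset_trial

    def intervene(t, state):
        if t != onset:
            return None
        state.w_c = float(np.copysign(donor_wc, state.w_c))
        state.w_m = float(np.copysign(donor_wm, state.w_m))
        return state

    return run_cohort(
        n=n,
        seed=seed,
        hyper=hyper or Hyperparams(**base_cohort.hyper),
        means=base_cohort.means[:n] if len(base_cohort.means) >= n else None,
        profiles=base_cohort.profiles,
        spec=base_cohort.spec,
        intervention=intervene,
        **cohort_kwargs,
    )


# ---------------------------------------------------------------------------
# Learning-dynamics analyses
# ---------------------------------------------------------------------------

def change_point(series, exclude: int = 10) -> dict | None:
    """Single change point by two-segment Gaussian cost minimisation.

    Both segment mean and variance are free; the cost of a segment of length
    ``k`` with ML variance ``v`` is ``k * log(v)``.  The first and last
    ``exclude`` points are not admissible split points.  Returns ``None``
    when no split improves on the single-segment cost by more than the
    BIC-style penalty for the three extra parameters, or for degenerate
    (constant) input.
    """
    x = np.asarray(series, dtype=float)
    nmax = len(x)
    if nmax < 2 * exclude + 2:
        return None

    def cost(seg):
        v = max(float(np.var(seg)), 1e-18)
        return len(seg) * np.log(v)

    full = cost(x)
    if np.ptp(x) == 0.0:
        return None
    best = None
    for k in range(exclude, nmax - exclude):
        c = cost(x[:k]) + cost(x[k:])
        if best is None or c < best[0]:
            best = (c, k)
    penalty = 3.0 * np.log(nmax)
    if best is None or full - best[0] <= penalty:
        return None
    k = best[1]
    return {
        "index": k,
        "mean_before": float(x[:k].mean()),
        "mean_after": float(x[k:].mean()),
        "mean_diff": float(x[k:].mean() - x[:k].mean()),
        "cost_improvement": float(full - best[0]),
    }


def dynamics_analysis(
    cohort: CohortResult,
    align_window: int = 200,
    gradient_columns: tuple[str, ...] = ("grad_g_c", "grad_g_m", "grad_w_c", "grad_w_m"),
) -> dict:
    """Switch-locked gradient curves, parameter summaries and change points.

    Requires ``cohort.traces``.  Produces (a) group mean +- SEM of absolute
    gradients aligned on each network's fitted switch trial and on colour
    onset, (b) gate/weight magnitude tables at the first and last
    colour-phase trial and at the switch, split by insight group, and (c) a
    change point of each network's absolute colour-gate gradient series
    around onset.
    """
    if cohort.traces is None:
        raise ValueError("cohort was run with keep_traces=False")
    onset = cohort.spec.colour_onset_trial
    bin_size = cohort.series_exp[0].bin_size
    ins = cohort.calls["insight"].to_numpy()
    n_trials = cohort.spec.n_trials

    def aligned_curves(anchor_trials: np.ndarray) -> dict:
        offs = np.arange(-align_window, align_window + 1)
        curves = {}
        for col in gradient_columns:
            mat = np.full((cohort.n, len(offs)), np.nan)
            for i, tr in enumerate(cohort.traces):
                a = int(anchor_trials[i])
                lo, hi = a - align_window, a + align_window + 1
                src_lo, src_hi = max(lo, 0), min(hi, n_trials)
                vals = np.abs(tr[col].to_numpy()[src_lo:src_hi])
                mat[i, src_lo - lo: src_lo - lo + len(vals)] = vals
            curves[col] = pd.DataFrame(
                {
                    "offset": offs,
                    "insight_mean": np.nanmean(mat[ins], axis=0) if ins.any() else np.nan,
                    "insight_sem": _nansem(mat[ins]) if ins.any() else np.nan,
                    "noinsight_mean": np.nanmean(mat[~ins], axis=0) if (~ins).any() else np.nan,
                    "noinsight_sem": _nansem(mat[~ins]) if (~ins).any() else np.nan,
                }
            )
        return curves

    switch_trials = np.clip(
        onset + (cohort.calls["switch_point"].to_numpy() - cohort.series_exp[0].onset_bin)
        * bin_size,
        0, n_trials - 1,
    ).astype(int)
    onset_trials = np.full(cohort.n, onset, dtype=int)

    # parameter magnitude tables at landmark trials
    landmarks = {
        "onset": onset_trials,
        "switch": switch_trials,
        "end": np.full(cohort.n, n_trials - 1, dtype=int),
    }
    rows = []
    for name, anchors in landmarks.items():
        for i, tr in enumerate(cohort.traces):
            t = int(anchors[i])
            rows.append(
                {
                    "landmark": name,
                    "network": i,
                    "insight": bool(ins[i]),
                    "abs_g_m": abs(float(tr["g_m"].iloc[t])),
                    "abs_g_c": abs(float(tr["g_c"].iloc[t])),
                    "abs_w_m": abs(float(tr["w_m"].iloc[t])),
                    "abs_w_c": abs(float(tr["w_c"].iloc[t])),
                }
            )
    params_table = pd.DataFrame(rows)

    cps = []
    for i, tr in enumerate(cohort.traces):
        g = np.abs(tr["grad_g_c"].to_numpy())
        # window around onset: motion phase + colour phase
        cp = change_point(g[onset - 200: onset + 300])
        cps.append(
            {
                "network": i,
                "insight": bool(ins[i]),
                "change_point": (cp["index"] + onset - 200) if cp else None,
                "mean_diff": cp["mean_diff"] if cp else np.nan,
            }
        )
    return {
        "switch_aligned": aligned_curves(switch_trials),
        "onset_aligned": aligned_curves(onset_trials),
        "params": params_table,
        "param_group_means": params_table.groupby(["landmark", "insight"])[
            ["abs_g_m", "abs_g_c", "abs_w_m", "abs_w_c"]
        ].mean(),
        "change_points": pd.DataFrame(cps),
    }


def _nansem(mat: np.ndarray) -> np.ndarray:
    n = np.sum(np.isfinite(mat), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.nanstd(mat, axis=0, ddof=1) / np.sqrt(np.maximum(n, 1))
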