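"""Task generation: curriculum, scalar inputs and accuracy matching.

The task is a two-alternative forced choice about a stimulus with two
features.  The *motion* feature has five signal-to-noise levels (nominal
coherences 5/10/20/30/45%); the *colour* feature is easy to perceive
throughout but carries no label information until the final task phase.
Each simulated subject sees 13 blocks of 100 trials:

======== ======= ==========================================================
blocks   phase   contents
======== ======= ==========================================================
0-5      training  the three highest coherence levels only, colour random
6-7      motion    all five coherences, colour random
8-12     colour    all five coherences, colour fully predictive of the label
======== ======= ==========================================================

Inputs are scalar: given the label ``y = +-1``, the motion input is
``x_m ~ N(y * M_m(coherence), sigma_m)`` and the colour input is
``x_c ~ N(c * M_c, sigma_c)`` where ``c = y`` once colour is predictive and
an independent fair coin otherwise (the stimulus always shows one of two
colours; pre-onset the shown colour is simply unrelated to the label).

Per-coherence motion mean shifts ``M_m`` are fitted per subject with a
derivative-free optimiser so that simulated motion-phase accuracy matches a
target accuracy profile, mirroring the per-participant performance matching
of the original experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import erf

__all__ = [
    "COHERENCE_LEVELS",
    "PHASES",
    "CurriculumSpec",
    "InputModel",
    "TargetAccuracyProfile",
    "build_curriculum",
    "sample_inputs",
    "closed_form_accuracy",
    "synth_target_profiles",
    "fit_motion_means",
    "MotionMeanFit",
]

#: The five nominal motion coherence levels (percent), in increasing order.
COHERENCE_LEVELS: tuple[int, ...] = (5, 10, 20, 30, 45)

PHASES = ("training", "motion", "colour")

# Default per-block trial counts per coherence.  The hardest condition is
# oversampled (30/100) to stabilise the low-coherence accuracy series; the
# training phase uses only the three easiest levels, as equally as 100
# trials allow.
_MOTION_PROPORTIONS = {5: 30, 10: 10, 20: 20, 30: 20, 45: 20}
_TRAINING_PROPORTIONS = {20: 34, 30: 33, 45: 33}


class ConfigurationError(ValueError):
    """Raised for invalid curriculum or input-model specifications."""


@dataclass(frozen=True)
class CurriculumSpec:
    """Block structure of the task.

    Defaults reproduce the 13-block network curriculum: six training blocks,
    two motion-phase blocks and five motion-and-colour blocks of 100 trials
    each (1300 trials total).
    """

    n_training_blocks: int = 6
    n_motion_blocks: int = 2
    n_colour_blocks: int = 5
    trials_per_block: int = 100
    coherence_levels: tuple[int, ...] = COHERENCE_LEVELS
    motion_proportions: dict[int, int] = field(
        default_factory=lambda: dict(_MOTION_PROPORTIONS)
    )
    training_proportions: dict[int, int] = field(
        default_factory=lambda: dict(_TRAINING_PROPORTIONS)
    )

    def __post_init__(self) -> None:
        for name, props in (
            ("motion_proportions", self.motion_proportions),
            ("training_proportions", self.training_proportions),
        ):
            total = sum(props.values())
            if total != self.trials_per_block:
                raise ConfigurationError(
                    f"{name} sum to {total}, expected {self.trials_per_block}"
                )
            unknown = set(props) - set(self.coherence_levels)
            if unknown:
                raise ConfigurationError(
                    f"{name} contain unknown coherence levels {sorted(unknown)}"
                )

    @property
    def n_blocks(self) -> int:
        return self.n_training_blocks + self.n_motion_blocks + self.n_colour_blocks

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    @property
    def colour_onset_trial(self) -> int:
        """First trial index of the colour (motion-and-colour) phase."""
        return (self.n_training_blocks + self.n_motion_blocks) * self.trials_per_block

    def phase_of_block(self, block: int) -> str:
        if block < self.n_training_blocks:
            return "training"
        if block < self.n_training_blocks + self.n_motion_blocks:
            return "motion"
        return "colour"


@dataclass(frozen=True)
class InputModel:
    """Gaussian scalar input distributions for the two features.

    ``M_m`` maps each coherence level to its motion mean shift; the colour
    mean shift ``M_c`` is fixed across a cohort.  Standard deviations model
    perceptual noise (motion is the noisy channel, colour the clean one).
    """

    M_m: dict[int, float]
    M_c: float = 0.22
    sigma_m: float = 0.1
    sigma_c: float = 0.01

    def __post_init__(self) -> None:
        if self.sigma_m <= 0 or self.sigma_c <= 0:
            raise ConfigurationError("input SDs must be positive")
        if any(v < 0 for v in self.M_m.values()):
            raise ConfigurationError("motion mean shifts must be non-negative")

    def motion_means(self, levels: Sequence[int] = COHERENCE_LEVELS) -> np.ndarray:
        return np.array([self.M_m[c] for c in levels], dtype=float)


#: Per-coherence target accuracies for one simulated subject, ordered by
#: coherence level.  Values must lie in (0.5, 1) and be non-decreasing.
TargetAccuracyProfile = np.ndarray


def build_curriculum(
    spec: CurriculumSpec | None = None, rng: np.random.Generator | int | None = None
) -> pd.DataFrame:
    """Build the ordered trial list (metadata only, no inputs).

    Per block, labels are exactly balanced (half ``+1``, half ``-1``) and
    per-coherence trial counts match the phase proportions exactly; both are
    shuffled within the block.

    Returns a DataFrame with columns ``trial, block, phase, coherence_pct, y``.
    """
    spec = spec or CurriculumSpec()
    rng = np.random.default_rng(rng)
    if spec.trials_per_block % 2:
        raise ConfigurationError("trials_per_block must be even for label balance")

    blocks = []
    for b in range(spec.n_blocks):
        phase = spec.phase_of_block(b)
        props = (
            spec.training_proportions if phase == "training" else spec.motion_proportions
        )
        coh = np.repeat(
            [lvl for lvl in spec.coherence_levels if lvl in props],
            [props[lvl] for lvl in spec.coherence_levels if lvl in props],
        )
        y = np.repeat([1, -1], spec.trials_per_block // 2)
        blocks.append(
            pd.DataFrame(
                {
                    "block": b,
                    "phase": phase,
                    "coherence_pct": rng.permutation(coh),
                    "y": rng.permutation(y),
                }
            )
        )
    out = pd.concat(blocks, ignore_index=True)
    out.insert(0, "trial", np.arange(len(out)))
    return out


def sample_inputs(
    trials: pd.DataFrame,
    input_model: InputModel,
    rng: np.random.Generator | int | None = None,
    colour_predictive: bool = True,
) -> pd.DataFrame:
    """Sample scalar inputs ``x_m, x_c`` for a trial table.

    The motion input mean follows the label in every phase.  The colour input
    mean follows the label only in the colour phase and only if
    ``colour_predictive`` is true (false for control subjects); otherwise its
    sign is an independent fair coin per trial.
    """
    rng = np.random.default_rng(rng)
    mm = trials["coherence_pct"].map(input_model.M_m).to_numpy(dtype=float)
    y = trials["y"].to_numpy(dtype=float)
    x_m = rng.normal(y * mm, input_model.sigma_m)
    coin = rng.choice([-1.0, 1.0], size=len(trials))
    predictive = (trials["phase"] == "colour").to_numpy() & colour_predictive
    c = np.where(predictive, y, coin)
    x_c = rng.normal(c * input_model.M_c, input_model.sigma_c)
    out = trials.copy()
    out["x_m"] = x_m
    out["x_c"] = x_c
    return out


def closed_form_accuracy(
    g_m: float,
    w_m: float,
    g_c: float,
    w_c: float,
    M_m: float,
    M_c: float,
    sigma_m: float,
    sigma_c: float,
    sigma_eta: float,
    colour_label_corr: float = 0.0,
) -> float:
    """Probability of a correct decision for a fixed network state.

    The decision is ``sign(g_m w_m x_m + g_c w_c x_c + eta)``.  Conditional
    on the trial's colour sign ``c`` the output is Gaussian, so

    ``P(correct | c) = 1/2 * [1 + erf( (e_m M_m + e_c M_c c y) / sqrt(2 v) )]``

    with effective weights ``e_m = g_m w_m``, ``e_c = g_c w_c`` and variance
    ``v = (e_m sigma_m)^2 + (e_c sigma_c)^2 + sigma_eta^2``.  The
    unconditional accuracy averages over the colour-label agreement: with
    ``rho = colour_label_corr`` (1 when colour is fully predictive, 0 when
    its sign is an independent coin), ``c = y`` with probability
    ``(1 + rho) / 2``.  An uncorrelated colour channel therefore brings no
    mean benefit — only output variability — and the mixture form stays
    exact even when ``e_c M_c`` dominates the output, where a pooled-
    Gaussian approximation fails.

    Returns 0.5 when both the signal and the variance vanish (pure
    guessing).
    """
    rho = float(colour_label_corr)
    em, ec = g_m * w_m, g_c * w_c
    var = (em * sigma_m) ** 2 + (ec * sigma_c) ** 2 + sigma_eta**2
    mu_match = em * M_m + ec * M_c  # colour sign agrees with the label
    mu_mismatch = em * M_m - ec * M_c

    def phi(mu: float) -> float:
        if var == 0.0:
            return 0.5 if mu == 0.0 else (1.0 if mu > 0 else 0.0)
        return 0.5 * (1.0 + float(erf(mu / np.sqrt(2.0 * var))))

    return (1.0 + rho) / 2.0 * phi(mu_match) + (1.0 - rho) / 2.0 * phi(mu_mismatch)


# ---------------------------------------------------------------------------
# Synthetic per-subject accuracy targets and motion-mean matching
# ---------------------------------------------------------------------------

#: Group-level motion-phase accuracy anchors for the five coherence levels.
#: The end points are the reported group accuracies at the extreme
#: coherences; the middle values interpolate the reported gradient.
DEFAULT_ANCHORS: tuple[float, ...] = (0.60, 0.63, 0.78, 0.85, 0.91)


def synth_target_profiles(
    n: int,
    rng: np.random.Generator | int | None = None,
    anchors: Sequence[float] = DEFAULT_ANCHORS,
    between_subject_sd: float = 0.04,
    lo: float = 0.52,
    hi: float = 0.98,
) -> np.ndarray:
    """Draw ``n`` synthetic per-subject accuracy profiles.

    Each profile is drawn around the group anchors with independent Gaussian
    between-subject variability, truncated to ``(lo, hi)`` and monotonised by
    sorting, standing in for the per-participant motion-phase accuracies that
    the original matching procedure used.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng)
    raw = rng.normal(np.asarray(anchors, dtype=float), between_subject_sd, (n, len(anchors)))
    return np.sort(np.clip(raw, lo, hi), axis=1)


@dataclass
class MotionMeanFit:
    """Result of matching motion means to a target accuracy profile."""

    means: dict[int, float]
    targets: np.ndarray
    achieved: np.ndarray
    n_evaluations: int
    converged: bool

    @property
    def max_abs_error(self) -> float:
        return float(np.max(np.abs(self.achieved - self.targets)))


# Starting point for the mean search, on the scale that the default input
# noise and accuracy anchors imply.
_MEANS_X0 = np.array([0.02, 0.03, 0.06, 0.09, 0.13])


def fit_motion_means(
    targets: TargetAccuracyProfile,
    hyper=None,
    spec: CurriculumSpec | None = None,
    seed: int = 0,
    input_model_kwargs: dict | None = None,
    n_replicates: int = 3,
    maxiter: int = 70,
    tol: float = 1e-4,
    x0: np.ndarray | None = None,
) -> MotionMeanFit:
    """Fit per-coherence motion mean shifts to a target accuracy profile.

    Minimises, with COBYLA, the squared deviation between the target profile
    and the motion-phase per-coherence accuracy of networks trained through
    the training and motion phases, averaged over ``n_replicates`` seeded
    replicates.  Means are constrained non-negative (by absolute value) and
    returned sorted, which enforces monotonicity in coherence.

    Parameters
    ----------
    targets : array of 5 probabilities in (0.5, 1), ordered by coherence.
    hyper : network hyperparameters (default ``Hyperparams()``).
    seed : base seed for the training replicates; the same seeds are reused
        at every objective evaluation so the objective is deterministic.
    """
    from .network import GatedLinearNetwork, Hyperparams

    targets = np.asarray(targets, dtype=float)
    if np.any(targets <= 0.5) or np.any(targets >= 1.0):
        raise ValueError("targets must lie in (0.5, 1)")
    spec = spec or CurriculumSpec()
    hyper = hyper or Hyperparams()
    levels = spec.coherence_levels
    imk = dict(input_model_kwargs or {})

    pre_spec = replace(spec, n_colour_blocks=0)
    n_eval = 0

    def motion_accuracy(means_vec: np.ndarray) -> np.ndarray:
        nonlocal n_eval
        n_eval += 1
        model = InputModel(M_m=dict(zip(levels, np.abs(means_vec))), **imk)
        acc = np.zeros(len(levels))
        for rep in range(n_replicates):
            rng = np.random.default_rng((seed, rep))
            trials = build_curriculum(pre_spec, rng)
            trials = sample_inputs(trials, model, rng, colour_predictive=True)
            net = GatedLinearNetwork(**hyper.as_kwargs())
            net.fit(trials, rng=rng, record_trace=False)
            motion = trials["phase"] == "motion"
            for i, lvl in enumerate(levels):
                sel = motion & (trials["coherence_pct"] == lvl)
                acc[i] += net.correct_[sel.to_numpy()].mean()
        return acc / n_replicates

    def objective(means_vec: np.ndarray) -> float:
        return float(np.sum((motion_accuracy(means_vec) - targets) ** 2))

    start = np.asarray(x0 if x0 is not None else _MEANS_X0, dtype=float)
    res = minimize(
        objective,
        start,
        method="COBYLA",
        options={"rhobeg": 0.02, "maxiter": maxiter, "tol": tol},
    )
    means = np.sort(np.abs(res.x))
    achieved = motion_accuracy(means)
    return MotionMeanFit(
        means=dict(zip(levels, means)),
        targets=targets,
        achieved=achieved,
        n_evaluations=n_eval,
        converged=bool(res.success) or res.fun < 25e-4 * len(levels),
    )
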