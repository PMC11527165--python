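"""Configuration, validation, serialisation and fixture generation."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .network import Hyperparams
from .switchfit import sigmoid
from .task import (
    COHERENCE_LEVELS,
    CurriculumSpec,
    DEFAULT_ANCHORS,
    build_curriculum,
)

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "config_hash",
    "BEHAVIOUR_COLUMNS",
    "validate_behaviour_table",
    "read_behaviour_csv",
    "write_behaviour_csv",
    "make_fixture",
    "save_cohort_summary",
]

BEHAVIOUR_COLUMNS = ("subject_id", "trial", "block", "phase", "coherence_pct", "correct")


class ValidationError(ValueError):
    """A table violates the behaviour schema."""


@dataclass
class RunConfig:
    """Serialisable description of one simulation run."""

    n_networks: int = 99
    seed: int = 0
    curriculum: dict = field(default_factory=lambda: asdict(CurriculumSpec()))
    hyper: dict = field(default_factory=lambda: Hyperparams().as_kwargs())
    input_model: dict = field(
        default_factory=lambda: {"M_c": 0.22, "sigma_m": 0.1, "sigma_c": 0.01}
    )
    anchors: tuple = DEFAULT_ANCHORS
    between_subject_sd: float = 0.04
    bin_size: int = 50

    def curriculum_spec(self) -> CurriculumSpec:
        return CurriculumSpec(**self.curriculum)

    def hyperparams(self) -> Hyperparams:
        return Hyperparams(**self.hyper)


def _canonical(obj) -> str:
    return json.dumps(obj, sort_keys=True, default=_jsonable)


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (tuple, set)):
        return list(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


def config_hash(config: RunConfig) -> str:
    """Stable hash of a config; changes iff any field changes."""
    return hashlib.sha256(_canonical(asdict(config)).encode()).hexdigest()[:16]


def _plain(obj):
    """Recursively convert to YAML-safe builtins, keeping integer dict keys."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (tuple, list, np.ndarray)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    return obj


def save_config(config: RunConfig, path) -> None:
    path = Path(path)
    payload = _plain(asdict(config))
    payload["config_hash"] = config_hash(config)
    path.write_text(yaml.safe_dump(payload, sort_keys=True))


def load_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text())
    data.pop("config_hash", None)
    if "anchors" in data:
        data["anchors"] = tuple(data["anchors"])
    cur = data.get("curriculum", {})
    if "coherence_levels" in cur:
        cur["coherence_levels"] = tuple(cur["coherence_levels"])
    return RunConfig(**data)


def validate_behaviour_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a behavioural trial table against the expected schema.

    Required columns: ``subject_id, trial, block, phase, coherence_pct,
    correct``; ``correct`` must be 0/1 and ``coherence_pct`` one of the five
    task levels.  Raises :class:`ValidationError` listing every offence.
    """
    problems = []
    missing = [c for c in BEHAVIOUR_COLUMNS if c not in df.columns]
    if missing:
        problems.append(f"missing columns: {missing}")
    if not missing:
        bad_coh = set(df["coherence_pct"].unique()) - set(COHERENCE_LEVELS)
        if bad_coh:
            problems.append(f"invalid coherence_pct values: {sorted(bad_coh)}")
        vals = set(pd.unique(df["correct"]))
        if not vals <= {0, 1, True, False}:
            problems.append(f"correct must be 0/1, found {sorted(map(str, vals))[:5]}")
    if problems:
        raise ValidationError("; ".join(problems))
    return df


def read_behaviour_csv(path) -> pd.DataFrame:
    return validate_behaviour_table(pd.read_csv(path))


def write_behaviour_csv(df: pd.DataFrame, path) -> None:
    validate_behaviour_table(df).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Fixture generation: Bernoulli subjects realising the three switch models
# ---------------------------------------------------------------------------

def _fixture_probability(kind: str, params: dict, bin_idx: np.ndarray) -> np.ndarray:
    if kind == "sigmoid_subject":
        p = sigmoid(bin_idx, params["m"], params["t_s"], params["y_max"], params["y_min"])
    elif kind == "linear_subject":
        p = params["m"] * bin_idx + params["y0"]
    elif kind == "step_subject":
        p = np.where(bin_idx < params["t_s"], params["y_max"] - params["s"], params["y_max"])
    elif kind == "null_subject":
        p = np.full_like(bin_idx, float(params.get("p", 0.6)), dtype=float)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("fixture parameters produce probabilities outside [0, 1]")
    return p


def make_fixture(
    kind: str,
    params: dict,
    rng: np.random.Generator | int | None = None,
    subject_id: object = 0,
    spec: CurriculumSpec | None = None,
    bin_size: int = 50,
    easy_accuracy: float = 0.9,
) -> pd.DataFrame:
    """Generate a synthetic behaviour table from a known switch model.

    Correctness on lowest-coherence trials of the motion + colour window is
    Bernoulli with probability given by the chosen model evaluated at the
    trial's bin; other trials use ``easy_accuracy``.  The resulting table
    passes :func:`validate_behaviour_table` and can be pushed through the
    classification pipeline to test recovery of the generating model.
    """
    rng = np.random.default_rng(rng)
    spec = spec or CurriculumSpec()
    trials = build_curriculum(spec, rng)
    lowest = min(spec.coherence_levels)
    window_start = trials.loc[trials["phase"] != "training", "trial"].min()
    bin_idx = np.maximum(trials["trial"].to_numpy() - window_start, 0) // bin_size
    p = np.where(
        trials["coherence_pct"].to_numpy() == lowest,
        _fixture_probability(kind, params, bin_idx.astype(float)),
        easy_accuracy,
    )
    out = trials.copy()
    out.insert(0, "subject_id", subject_id)
    out["correct"] = (rng.random(len(out)) < p).astype(int)
    return out


def save_cohort_summary(cohort, path) -> None:
    """Write a cohort's headline numbers and per-network table."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    calls = cohort.calls.copy()
    pd.concat([calls, cohort.summary], axis=1).to_csv(
        path / "networks.csv", index_label="network"
    )
    headline = {
        "n": cohort.n,
        "seed": cohort.seed,
        "insight_fraction": cohort.insight_fraction,
        "threshold": cohort.threshold,
        "mean_delay_bins": cohort.delay_stats.get("mean_delay_bins"),
        "mean_delay_trials": cohort.delay_stats.get("mean_delay_trials"),
        "training_accuracy": float(cohort.summary["training_acc"].mean()),
        "hyper": cohort.hyper,
    }
    (path / "summary.json").write_text(json.dumps(headline, indent=2, default=_jsonable))
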