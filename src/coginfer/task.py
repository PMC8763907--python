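"""Generative model of the cue-combination task.

Observers categorise a sequence of oriented bars as drawn from one of two
von Mises distributions whose means are orthogonal (axial orientations,
period pi).  The categorisation axis ``theta_star`` sits 45 degrees between
the two category means; each stimulus orientation ``theta`` carries a
log-likelihood ratio

    l = 2 * kappa * sin(2 * (theta - theta_star))

for category A versus B, where ``kappa`` is the concentration (coherence)
of the generative distributions.  The Bayes-optimal observer sums these
log-likelihood ratios and answers with the sign of the total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# the task uses sequences of up to 12 stimuli; the extra headroom lets
# extrapolation experiments run longer sequences through the same machinery
MAX_SEQ_LEN = 24
CSV_SEQ_LEN = 12

__all__ = [
    "TaskConfig",
    "TrialSet",
    "evidence_llr",
    "sample_trials",
    "write_behavior_csv",
    "read_behavior_csv",
]


@dataclass(frozen=True)
class TaskConfig:
    """Task parameters.

    Parameters
    ----------
    kappa : float
        von Mises concentration of the generative orientation
        distributions; the task-difficulty knob.
    sequence_lengths : tuple of int
        Admissible numbers of stimuli per trial.
    lottery_probs : tuple of float
        Success probabilities of the end-of-trial lotteries, drawn
        uniformly and independently of everything else.
    trials_per_block : int
        Trials in one experimental block.
    target_accuracy : float
        Accuracy the online titration aims for.
    """

    kappa: float = 0.5
    sequence_lengths: tuple[int, ...] = (4, 8, 12)
    lottery_probs: tuple[float, ...] = (0.6, 0.7, 0.8, 0.9)
    trials_per_block: int = 72
    target_accuracy: float = 0.75

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if not self.sequence_lengths or any(n < 1 for n in self.sequence_lengths):
            raise ValueError("sequence_lengths must be non-empty, all >= 1")
        if max(self.sequence_lengths) > MAX_SEQ_LEN:
            raise ValueError(f"sequence lengths above {MAX_SEQ_LEN} unsupported")
        if any(not 0.5 < p < 1 for p in self.lottery_probs):
            raise ValueError("lottery_probs must lie in (0.5, 1)")
        if not 0.5 < self.target_accuracy < 1:
            raise ValueError("target_accuracy must lie in (0.5, 1)")


def evidence_llr(theta, theta_star, kappa):
    """Log-likelihood ratio carried by orientation ``theta``.

    Equal to the exact log-density ratio of the two von Mises categories
    with orthogonal means ``theta_star +/- pi/4`` (on the doubled-angle
    circle) and concentration ``kappa``.  Positive values favour
    category A (mean at ``theta_star + pi/4``).
    """
    if np.any(np.asarray(kappa) < 0):
        raise ValueError("kappa must be >= 0")
    return 2.0 * np.asarray(kappa) * np.sin(2.0 * (np.asarray(theta) - theta_star))


@dataclass
class TrialSet:
    """A set of task trials in packed array form.

    Stimulus-level arrays have shape ``(n_trials, MAX_SEQ_LEN)`` and are
    zero-padded past each trial's length; ``mask`` marks real stimuli.
    ``category`` is +1 for A, -1 for B.  All orientations are axial,
    stored in [0, pi).
    """

    config: TaskConfig
    theta_star: np.ndarray          # (n_trials,)
    category: np.ndarray            # (n_trials,) +1/-1
    n_stimuli: np.ndarray           # (n_trials,)
    theta: np.ndarray               # (n_trials, MAX_SEQ_LEN)
    llr: np.ndarray                 # (n_trials, MAX_SEQ_LEN)
    lottery_prob: np.ndarray        # (n_trials,)
    condition: np.ndarray = field(default=None)  # object array of labels
    kappa_trial: np.ndarray = field(default=None)  # per-trial kappa (titration)

    def __post_init__(self) -> None:
        if self.condition is None:
            self.condition = np.full(len(self.theta_star), "placebo-like", dtype=object)
        if self.kappa_trial is None:
            self.kappa_trial = np.full(len(self.theta_star), self.config.kappa)

    def __len__(self) -> int:
        return len(self.theta_star)

    @property
    def mask(self) -> np.ndarray:
        return np.arange(MAX_SEQ_LEN)[None, :] < self.n_stimuli[:, None]

    @property
    def cumulative_llr(self) -> np.ndarray:
        """Leak-free accumulated evidence L_k = sum_{j<=k} l_j."""
        return np.cumsum(self.llr, axis=1)

    @property
    def total_llr(self) -> np.ndarray:
        return self.llr.sum(axis=1)

    def subset(self, idx) -> "TrialSet":
        return TrialSet(
            config=self.config,
            theta_star=self.theta_star[idx],
            category=self.category[idx],
            n_stimuli=self.n_stimuli[idx],
            theta=self.theta[idx],
            llr=self.llr[idx],
            lottery_prob=self.lottery_prob[idx],
            condition=self.condition[idx],
            kappa_trial=self.kappa_trial[idx],
        )


def sample_trials(
    config: TaskConfig,
    n_trials: int,
    rng: np.random.Generator,
    condition: str = "placebo-like",
    kappa: float | None = None,
) -> TrialSet:
    """Sample ``n_trials`` task trials.

    The categorisation axis and generative category are uniform per
    trial; orientations are drawn so the doubled angle ``2*theta``
    follows a von Mises with concentration ``kappa`` about the doubled
    category mean.  Evidence is computed with the convention that
    positive log-likelihood ratios favour category A
    (``mu_A = theta_star + pi/4``).
    """
    kap = config.kappa if kappa is None else float(kappa)
    if kap < 0:
        raise ValueError("kappa must be >= 0")
    theta_star = rng.uniform(0.0, np.pi, size=n_trials)
    category = rng.choice([1, -1], size=n_trials)
    n_stim = rng.choice(config.sequence_lengths, size=n_trials)
    lottery = rng.choice(config.lottery_probs, size=n_trials)

    mu = theta_star + category * np.pi / 4.0  # category mean orientation
    # doubled-angle deviation from the category mean
    dev2 = rng.vonmises(0.0, kap, size=(n_trials, MAX_SEQ_LEN)) if kap > 0 else (
        rng.uniform(-np.pi, np.pi, size=(n_trials, MAX_SEQ_LEN))
    )
    theta = np.mod(mu[:, None] + dev2 / 2.0, np.pi)
    llr = evidence_llr(theta, theta_star[:, None], kap)
    mask = np.arange(MAX_SEQ_LEN)[None, :] < n_stim[:, None]
    theta = np.where(mask, theta, 0.0)
    llr = np.where(mask, llr, 0.0)
    return TrialSet(
        config=config,
        theta_star=theta_star,
        category=category,
        n_stimuli=n_stim,
        theta=theta,
        llr=llr,
        lottery_prob=lottery,
        condition=np.full(n_trials, condition, dtype=object),
        kappa_trial=np.full(n_trials, kap),
    )


def to_dataframe(trials: TrialSet, choices: np.ndarray | None = None) -> pd.DataFrame:
    """Tabular view of a TrialSet (one row per trial)."""
    n = len(trials)
    df = pd.DataFrame(
        {
            "trial_id": np.arange(n),
            "condition": trials.condition,
            "n_stimuli": trials.n_stimuli,
            "category_axis_rad": trials.theta_star,
            "generative_category": np.where(trials.category > 0, "A", "B"),
            "lottery_prob": trials.lottery_prob,
            "kappa": trials.kappa_trial,
        }
    )
    mask = trials.mask
    n_cols = max(CSV_SEQ_LEN, int(trials.n_stimuli.max(initial=0)))
    for k in range(n_cols):
        df[f"theta_{k + 1}"] = np.where(mask[:, k], trials.theta[:, k], np.nan)
        df[f"llr_{k + 1}"] = np.where(mask[:, k], trials.llr[:, k], np.nan)
    if choices is not None:
        df["choice"] = np.where(choices > 0, "A", "B")
        df["correct"] = (choices == trials.category).astype(int)
    return df


def from_dataframe(df: pd.DataFrame, config: TaskConfig) -> tuple[TrialSet, np.ndarray | None]:
    """Rebuild a TrialSet (and choices, if present) from the tabular form."""
    n = len(df)
    theta = np.zeros((n, MAX_SEQ_LEN))
    llr = np.zeros((n, MAX_SEQ_LEN))
    for k in range(MAX_SEQ_LEN):
        if f"theta_{k + 1}" not in df:
            break
        theta[:, k] = np.nan_to_num(df[f"theta_{k + 1}"].to_numpy(float))
        llr[:, k] = np.nan_to_num(df[f"llr_{k + 1}"].to_numpy(float))
    trials = TrialSet(
        config=config,
        theta_star=df["category_axis_rad"].to_numpy(float),
        category=np.where(df["generative_category"].to_numpy() == "A", 1, -1),
        n_stimuli=df["n_stimuli"].to_numpy(int),
        theta=theta,
        llr=llr,
        lottery_prob=df["lottery_prob"].to_numpy(float),
        condition=df["condition"].to_numpy(object),
        kappa_trial=df["kappa"].to_numpy(float) if "kappa" in df else None,
    )
    choices = None
    if "choice" in df:
        choices = np.where(df["choice"].to_numpy() == "A", 1, -1)
    return trials, choices


def write_behavior_csv(path, trials: TrialSet, choices: np.ndarray | None = None) -> None:
    """Write a behavioural dataset to CSV with a JSON sidecar for the config."""
    import dataclasses
    import json
    from pathlib import Path

    path = Path(path)
    to_dataframe(trials, choices).to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    cfg = dataclasses.asdict(trials.config)
    sidecar.write_text(json.dumps(cfg, indent=2))


def read_behavior_csv(path) -> tuple[TrialSet, np.ndarray | None]:
    import json
    from pathlib import Path

    path = Path(path)
    cfg = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    cfg["sequence_lengths"] = tuple(cfg["sequence_lengths"])
    cfg["lottery_probs"] = tuple(cfg["lottery_probs"])
    return from_dataframe(pd.read_csv(path), TaskConfig(**cfg))
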