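"""Premature-commitment simulator and its downstream signatures.

A committing observer may, with a flat per-stimulus hazard after at
least ``n0`` stimuli, covertly select the category currently supported
by its belief.  From then on only evidence whose internal (noisy) sign
agrees with the committed category is integrated; conflicting stimuli
contribute nothing, and the final response always follows the committed
category.  The module quantifies three consequences: the apparent
(best-fitting) inference noise, the model-internal coding precision of
consistent versus conflicting evidence by position, and the compensatory
reduction in opt-out rate produced by the inflated post-commitment
belief.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .observer import ObserverParams, ObserverTrace, simulate_observer
from .task import MAX_SEQ_LEN, TaskConfig, TrialSet, evidence_llr, sample_trials

__all__ = [
    "CommitmentConfig",
    "CommitmentTrace",
    "simulate_commitment",
    "apparent_inference_noise",
    "model_coding_precision",
    "commitment_optout",
]

Z_CAP = np.arctanh(1.0 - 1e-12)


@dataclass(frozen=True)
class CommitmentConfig:
    hazard: float = 0.05      # per-stimulus commitment probability
    n0: int = 4               # first eligible stimulus index (1-based)
    obs_noise: float = 3.0    # additive observation noise for model coding precision
    include_last: bool = True  # allow commitment after the final stimulus

    def __post_init__(self) -> None:
        if not 0.0 <= self.hazard <= 1.0:
            raise ValueError("hazard must lie in [0, 1]")
        if self.n0 < 1:
            raise ValueError("n0 must be >= 1")
        if self.obs_noise < 0:
            raise ValueError("obs_noise must be >= 0")


@dataclass
class CommitmentTrace:
    committed: np.ndarray          # (n_trials,) bool
    commit_position: np.ndarray    # (n_trials,) 1-based, -1 if uncommitted
    committed_category: np.ndarray  # (n_trials,) +1/-1, 0 if uncommitted
    integrated_mask: np.ndarray    # (n_trials, MAX_SEQ_LEN) bool


def simulate_commitment(
    trials: TrialSet,
    observer_params: ObserverParams,
    config: CommitmentConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, CommitmentTrace, ObserverTrace]:
    """Simulate the committing observer.

    Noise draws consume the parent stream in the same order as
    ``simulate_observer``; commitment events use a spawned child stream,
    so at hazard 0 the choices reproduce the plain observer exactly for
    the same seed.
    """
    commit_rng = rng.spawn(1)[0]
    n = len(trials)
    mask = trials.mask
    theta_hat = trials.theta + observer_params.sigma_sen * rng.standard_normal((n, MAX_SEQ_LEN))
    llr_hat = evidence_llr(theta_hat, trials.theta_star[:, None], trials.kappa_trial[:, None])
    llr_hat = llr_hat + observer_params.sigma_inf * rng.standard_normal((n, MAX_SEQ_LEN))
    llr_hat = np.where(mask, llr_hat, 0.0)
    theta_hat = np.where(mask, theta_hat, 0.0)

    leak = observer_params.leak
    acc = np.zeros((n, MAX_SEQ_LEN))
    prev = np.zeros(n)
    committed = np.zeros(n, dtype=bool)
    commit_pos = np.full(n, -1)
    commit_cat = np.zeros(n, dtype=int)
    integrated = mask.copy()

    for k in range(MAX_SEQ_LEN):
        contrib = llr_hat[:, k].copy()
        # post-commitment: discard internally conflicting evidence
        conflict = committed & (np.sign(contrib) != commit_cat) & mask[:, k]
        contrib[conflict] = 0.0
        integrated[conflict, k] = False
        cur = (1.0 - leak) * prev + contrib
        cur = np.where(mask[:, k], cur, prev)
        acc[:, k] = cur
        prev = cur
        # commitment opportunity after stimulus k (1-based index k+1)
        pos = k + 1
        eligible = (~committed) & mask[:, k] & (pos >= config.n0)
        if not config.include_last:
            eligible &= pos < trials.n_stimuli
        u = commit_rng.random(n)
        commit_now = eligible & (u < config.hazard)
        if commit_now.any():
            cat = np.sign(cur[commit_now]).astype(int)
            ties = cat == 0
            if ties.any():
                cat[ties] = commit_rng.choice([1, -1], size=ties.sum())
            committed[commit_now] = True
            commit_pos[commit_now] = pos
            commit_cat[commit_now] = cat

    final = acc[np.arange(n), trials.n_stimuli - 1]
    if observer_params.beta_softmax is not None:
        p_a = expit(observer_params.beta_softmax * final)
        free_choice = np.where(rng.random(n) < p_a, 1, -1)
    else:
        noisy = final + observer_params.sigma_sel * rng.standard_normal(n)
        free_choice = np.sign(noisy).astype(int)
        ties = free_choice == 0
        if ties.any():
            free_choice[ties] = rng.choice([1, -1], size=ties.sum())
    choices = np.where(committed, commit_cat, free_choice)
    ctrace = CommitmentTrace(committed, commit_pos, commit_cat, integrated)
    otrace = ObserverTrace(theta_hat, llr_hat, acc, choices)
    return choices, ctrace, otrace


def apparent_inference_noise(
    observer_params: ObserverParams,
    hazard_grid,
    cohort_shape: tuple[int, int],
    rng: np.random.Generator,
    config: TaskConfig | None = None,
    commit_config: CommitmentConfig | None = None,
    n_starts: int = 4,
) -> pd.DataFrame:
    """Best-fitting inference noise of the committing observer per hazard.

    The generator's inference noise is held fixed across the grid; each
    hazard level is simulated as a cohort and refit with the
    inference-only model.
    """
    from .fitting import ModelSpec, NoisyInferenceModel

    if config is None:
        config = TaskConfig()
    base = commit_config if commit_config is not None else CommitmentConfig()
    n_subj, n_trials = cohort_shape
    spec = ModelSpec(active_sources=frozenset({"inference"}))
    rows = []
    for hz in hazard_grid:
        cc = CommitmentConfig(hazard=float(hz), n0=base.n0,
                              obs_noise=base.obs_noise, include_last=base.include_last)
        sig = []
        for _ in range(n_subj):
            trials = sample_trials(config, n_trials, rng)
            choices, _, _ = simulate_commitment(trials, observer_params, cc, rng)
            fit = NoisyInferenceModel(trials, choices, spec).fit(
                seed=int(rng.integers(2**31 - 1)), n_starts=n_starts)
            sig.append(fit.params.sigma_inf)
        sig = np.asarray(sig)
        rows.append({"hazard": float(hz), "sigma_hat_mean": sig.mean(),
                     "sigma_hat_sd": sig.std(ddof=1) if n_subj > 1 else 0.0})
    return pd.DataFrame(rows)


def _fisher_z(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    r = np.corrcoef(x, y)[0, 1]
    return float(np.clip(np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15)), -Z_CAP, Z_CAP))


def model_coding_precision(
    trials: TrialSet,
    otrace: ObserverTrace,
    ctrace: CommitmentTrace,
    config: CommitmentConfig,
    rng: np.random.Generator,
    choices: np.ndarray | None = None,
    n_boot: int = 100,
    min_cell: int = 10,
) -> pd.DataFrame:
    """Fisher-z coding precision of model evidence by consistency x position.

    The internal representation |l_hat_k| (zeroed for discarded stimuli)
    plus additive observation noise is correlated with the objective
    evidence strength |l_k| within each (consistency, position) cell.
    Consistency is whether sign(l_k) matches the final choice.  Standard
    errors come from trial-level bootstrap resampling; cells with fewer
    than ``min_cell`` stimuli return NaN.
    """
    if choices is None:
        choices = otrace.choice
    mask = trials.mask
    eff = np.where(ctrace.integrated_mask, otrace.noisy_llr, 0.0)
    x_all = np.abs(eff) + config.obs_noise * rng.standard_normal(eff.shape)
    y_all = np.abs(trials.llr)
    consistent = (np.sign(trials.llr) * choices[:, None]) > 0
    rows = []
    n_trials = len(trials)
    boot_idx = rng.integers(0, n_trials, size=(n_boot, n_trials))
    for pos in range(1, int(trials.n_stimuli.max()) + 1):
        k = pos - 1
        valid = mask[:, k]
        for cons in (True, False):
            cell = valid & (consistent[:, k] == cons)
            if cell.sum() < min_cell:
                rows.append({"position": pos, "consistent": cons, "n": int(cell.sum()),
                             "fisher_z": np.nan, "se": np.nan})
                continue
            z = _fisher_z(x_all[cell, k], y_all[cell, k])
            zb = []
            for b in range(n_boot):
                sel = boot_idx[b]
                c = cell[sel]
                if c.sum() >= 3:
                    zb.append(_fisher_z(x_all[sel, k][c], y_all[sel, k][c]))
            se = float(np.nanstd(zb, ddof=1)) if len(zb) > 1 else np.nan
            rows.append({"position": pos, "consistent": cons, "n": int(cell.sum()),
                         "fisher_z": z, "se": se})
    return pd.DataFrame(rows)


def commitment_optout(
    observer_params: ObserverParams,
    hazard_grid,
    criterion_grid,
    cohort_shape: tuple[int, int] | int,
    seed: int,
    config: TaskConfig | None = None,
    beta1: float = 1.2,
    beta2: float = 1.0,
    commit_config: CommitmentConfig | None = None,
) -> pd.DataFrame:
    """Expected opt-out rate surface over (hazard, opt-out criterion).

    Expected accuracy is the calibrated logistic of the magnitude of the
    post-commitment belief |L_n| (discarded stimuli excluded), so the
    belief on committed trials is inflated and the opt-out rate drops.
    The calibration shift is fixed at the zero-hazard baseline; noise
    draws are shared across hazard levels (common random numbers) so
    rates are directly comparable.
    """
    from .optout import P_CLAMP_HI, P_CLAMP_LO

    if config is None:
        config = TaskConfig()
    base = commit_config if commit_config is not None else CommitmentConfig()
    n_trials = cohort_shape if isinstance(cohort_shape, int) else cohort_shape[0] * cohort_shape[1]
    trials = sample_trials(config, n_trials, np.random.default_rng(seed))
    l_lot = logit(trials.lottery_prob)

    delta = None
    rows = []
    for hz in sorted(hazard_grid):
        cc = CommitmentConfig(hazard=float(hz), n0=base.n0,
                              obs_noise=base.obs_noise, include_last=base.include_last)
        rng = np.random.default_rng(seed + 1)  # identical noise across hazards
        choices, ctrace, otrace = simulate_commitment(trials, observer_params, cc, rng)
        final = otrace.accumulated[np.arange(n_trials), trials.n_stimuli - 1]
        strength = np.abs(final)
        if delta is None:
            # calibrate at the zero-hazard baseline to mean lottery probability
            from scipy.optimize import brentq

            target = float(np.mean(trials.lottery_prob))
            f = lambda d: np.mean(np.clip(expit(strength + d), P_CLAMP_LO, P_CLAMP_HI)) - target
            delta = brentq(f, -60, 60, xtol=1e-10)
        p_cor = np.clip(expit(strength + delta), P_CLAMP_LO, P_CLAMP_HI)
        l_cor = logit(p_cor)
        for b0 in criterion_grid:
            p_opt = expit(-(b0 + beta1 * l_cor - beta2 * l_lot))
            com = ctrace.committed
            rows.append({
                "hazard": float(hz), "criterion": float(b0),
                "optout_rate": float(p_opt.mean()),
                "optout_rate_committed": float(p_opt[com].mean()) if com.any() else np.nan,
                "optout_rate_uncommitted": float(p_opt[~com].mean()) if (~com).any() else np.nan,
                "frac_committed": float(com.mean()),
            })
    return pd.DataFrame(rows)
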