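"""Suboptimal-inference observer for the cue-combination task.

The observer corrupts the Bayes-optimal computation at up to three
stages:

* sensory:    noisy percepts  theta_hat_k = theta_k + eps,  eps ~ N(0, sigma_sen^2)
* inference:  noisy evidence  l_hat_k = l(theta_hat_k) + eps,  eps ~ N(0, sigma_inf^2)
* selection:  Gaussian noise on the final belief (sd sigma_sel), or
              equivalently a softmax policy with inverse temperature beta.

Evidence is accumulated with optional leak,
``L_k = (1 - leak) * L_{k-1} + l_hat_k``, and the response is the sign of
the final (noise-corrupted) belief.

``choice_probability`` gives the exact marginal probability of choosing
category A under this noise model.  Sensory noise is propagated through
the sinusoidal evidence mapping with the closed-form Gaussian moments

    E[sin 2(d + e)] = exp(-2 s^2) sin 2d
    E[cos 4(d + e)] = exp(-8 s^2) cos 4d      (e ~ N(0, s^2))

so each noisy log-likelihood ratio has known mean and variance; the
accumulated belief is treated as Gaussian (exact when sigma_sen = 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .task import MAX_SEQ_LEN, TrialSet, evidence_llr

LAPSE_FLOOR = 1e-6

__all__ = [
    "ObserverParams",
    "ObserverTrace",
    "simulate_observer",
    "choice_probability",
    "posterior_stats",
    "psychophysical_kernel",
    "decision_variability",
]


@dataclass(frozen=True)
class ObserverParams:
    """Noise parameters of the suboptimal observer.

    ``sigma_sel`` (Gaussian selection noise) and ``beta_softmax``
    (softmax policy) are alternative parameterisations of the selection
    stage; at most one may be active.
    """

    sigma_sen: float = 0.0   # radians
    sigma_inf: float = 0.0   # log-odds per stimulus
    sigma_sel: float = 0.0   # log-odds
    beta_softmax: float | None = None
    leak: float = 0.0

    def __post_init__(self) -> None:
        if min(self.sigma_sen, self.sigma_inf, self.sigma_sel) < 0:
            raise ValueError("noise s.d. must be >= 0")
        if not 0.0 <= self.leak <= 1.0:
            raise ValueError("leak must lie in [0, 1]")
        if self.beta_softmax is not None and self.sigma_sel > 0:
            raise ValueError("at most one of sigma_sel / beta_softmax may be active")
        if self.beta_softmax is not None and self.beta_softmax < 0:
            raise ValueError("beta_softmax must be >= 0")


@dataclass
class ObserverTrace:
    """Internal variables of a simulated observer run (packed arrays)."""

    noisy_percepts: np.ndarray   # (n_trials, MAX_SEQ_LEN)
    noisy_llr: np.ndarray        # (n_trials, MAX_SEQ_LEN)
    accumulated: np.ndarray      # (n_trials, MAX_SEQ_LEN) leaky cumulative belief
    choice: np.ndarray           # (n_trials,) +1 (A) / -1 (B)

    @property
    def belief_strength(self) -> np.ndarray:
        return np.abs(self.accumulated)


def leak_weights(n_stimuli: np.ndarray, leak: float) -> np.ndarray:
    """Weights (1-leak)^(n-k) of each stimulus in the final belief; 0 past n."""
    k = np.arange(1, MAX_SEQ_LEN + 1)[None, :]
    n = np.asarray(n_stimuli)[:, None]
    expo = (n - k).astype(float)
    w = np.where(k <= n, (1.0 - leak) ** np.maximum(expo, 0.0), 0.0)
    return w


def _accumulate_leaky(llr_hat: np.ndarray, mask: np.ndarray, leak: float) -> np.ndarray:
    acc = np.zeros_like(llr_hat)
    prev = np.zeros(llr_hat.shape[0])
    for k in range(llr_hat.shape[1]):
        cur = (1.0 - leak) * prev + llr_hat[:, k]
        cur = np.where(mask[:, k], cur, prev)
        acc[:, k] = cur
        prev = cur
    return acc


def simulate_observer(
    trials: TrialSet,
    params: ObserverParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, ObserverTrace]:
    """Simulate choices; returns (choices, trace).

    Ties at a final belief of exactly zero are broken by a fair coin
    from the same stream.
    """
    n = len(trials)
    if n == 0:
        empty = np.zeros((0, MAX_SEQ_LEN))
        return np.zeros(0, dtype=int), ObserverTrace(empty, empty.copy(), empty.copy(), np.zeros(0, dtype=int))
    mask = trials.mask
    theta_hat = trials.theta + params.sigma_sen * rng.standard_normal((n, MAX_SEQ_LEN))
    llr_hat = evidence_llr(theta_hat, trials.theta_star[:, None], trials.kappa_trial[:, None])
    llr_hat = llr_hat + params.sigma_inf * rng.standard_normal((n, MAX_SEQ_LEN))
    llr_hat = np.where(mask, llr_hat, 0.0)
    theta_hat = np.where(mask, theta_hat, 0.0)
    acc = _accumulate_leaky(llr_hat, mask, params.leak)
    final = acc[np.arange(n), trials.n_stimuli - 1]
    if params.beta_softmax is not None:
        p_a = expit(params.beta_softmax * final)
        choice = np.where(rng.random(n) < p_a, 1, -1)
    else:
        noisy = final + params.sigma_sel * rng.standard_normal(n)
        choice = np.sign(noisy).astype(int)
        ties = choice == 0
        if ties.any():
            choice[ties] = rng.choice([1, -1], size=ties.sum())
    return choice, ObserverTrace(theta_hat, llr_hat, acc, choice)


def _design(trials: TrialSet) -> dict:
    """Cached per-dataset sufficient statistics for the belief moments.

    With the closed-form sensory propagation, the per-stimulus moments
    are elementwise functions of l_k = 2k sin(2 d_k), (2k)^2 cos(4 d_k)
    and (2k)^2; for a leak-free observer only their per-trial sums are
    needed, which makes a likelihood evaluation O(n_trials).
    """
    d = getattr(trials, "_design_cache", None)
    if d is not None:
        return d
    mask = trials.mask
    delta = trials.theta - trials.theta_star[:, None]
    amp = 2.0 * trials.kappa_trial[:, None] * np.ones_like(delta)
    llr = np.where(mask, amp * np.sin(2.0 * delta), 0.0)
    amp2 = np.where(mask, amp ** 2, 0.0)
    amp2cos4 = np.where(mask, amp ** 2 * np.cos(4.0 * delta), 0.0)
    d = {
        "mask": mask,
        "llr": llr,
        "llr2": llr ** 2,
        "amp2": amp2,
        "amp2cos4": amp2cos4,
        "n": trials.n_stimuli.astype(float),
        "sum_llr": llr.sum(axis=1),
        "sum_llr2": (llr ** 2).sum(axis=1),
        "sum_amp2": amp2.sum(axis=1),
        "sum_amp2cos4": amp2cos4.sum(axis=1),
    }
    object.__setattr__(trials, "_design_cache", d)
    return d


def posterior_stats(
    trials: TrialSet,
    params: ObserverParams,
    include_selection: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and s.d. of the final belief L under the observer's noise model."""
    d = _design(trials)
    s2 = params.sigma_sen ** 2
    if params.leak == 0.0:
        if s2 > 0:
            mu = np.exp(-2.0 * s2) * d["sum_llr"]
            var = (0.5 * (d["sum_amp2"] - np.exp(-8.0 * s2) * d["sum_amp2cos4"])
                   - np.exp(-4.0 * s2) * d["sum_llr2"])
            var = np.maximum(var, 0.0)
        else:
            mu = d["sum_llr"]
            var = np.zeros_like(mu)
        var = var + params.sigma_inf ** 2 * d["n"]
    else:
        w = leak_weights(trials.n_stimuli, params.leak)
        if s2 > 0:
            m = np.exp(-2.0 * s2) * d["llr"]
            v = np.maximum(0.5 * (d["amp2"] - np.exp(-8.0 * s2) * d["amp2cos4"])
                           - np.exp(-4.0 * s2) * d["llr2"], 0.0)
        else:
            m = d["llr"]
            v = np.zeros_like(m)
        v = v + params.sigma_inf ** 2 * d["mask"]
        mu = (w * m).sum(axis=1)
        var = (w ** 2 * v).sum(axis=1)
    if include_selection and params.beta_softmax is None:
        var = var + params.sigma_sel ** 2
    return mu, np.sqrt(var)


_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(61)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


def choice_probability(trials: TrialSet, params: ObserverParams) -> np.ndarray:
    """Exact marginal probability of choosing category A, per trial.

    Clamped to [LAPSE_FLOOR, 1 - LAPSE_FLOOR] so deterministic observers
    retain a finite log-likelihood.
    """
    if not np.all(np.isfinite(trials.llr)):
        raise ValueError("non-finite evidence")
    if params.beta_softmax is not None:
        mu, sd = posterior_stats(trials, params, include_selection=False)
        z = mu[:, None] + sd[:, None] * _GH_NODES[None, :]
        p = expit(params.beta_softmax * z) @ _GH_WEIGHTS
    else:
        mu, sd = posterior_stats(trials, params, include_selection=True)
        stochastic = sd > 0
        p = np.where(mu > 0, 1.0, np.where(mu < 0, 0.0, 0.5))
        if stochastic.any():
            from scipy.special import ndtr

            p = np.where(stochastic, ndtr(mu / np.where(stochastic, sd, 1.0)), p)
    return np.clip(p, LAPSE_FLOOR, 1.0 - LAPSE_FLOOR)


def choice_loglik(trials: TrialSet, choices: np.ndarray, params: ObserverParams) -> float:
    p_a = choice_probability(trials, params)
    p = np.where(choices > 0, p_a, 1.0 - p_a)
    return float(np.log(p).sum())


def psychophysical_kernel(
    trials: TrialSet,
    choices: np.ndarray,
    stratify_by_length: bool = True,
) -> dict[int, pd.DataFrame]:
    """Per-position logistic-regression weights of evidence on choice.

    Returns, per sequence-length stratum, a frame with columns
    ``weight`` and ``se`` (index = stimulus position, 1-based).  On a
    separable or non-converging design the fit falls back to a ridge
    penalty (flagged in the frame attrs with the penalty used).
    """
    import statsmodels.api as sm

    lengths = sorted(set(trials.n_stimuli)) if stratify_by_length else [None]
    out: dict[int, pd.DataFrame] = {}
    for n_len in lengths:
        idx = slice(None) if n_len is None else trials.n_stimuli == n_len
        sub = trials.subset(idx) if n_len is not None else trials
        ch = choices[idx] if n_len is not None else choices
        n_pos = n_len if n_len is not None else int(trials.n_stimuli.max())
        X = sm.add_constant(sub.llr[:, :n_pos])
        y = (ch > 0).astype(float)
        ridge_penalty = None
        try:
            with np.errstate(all="ignore"):
                res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            if not res.mle_retvals.get("converged", False) or not np.all(np.isfinite(res.bse)):
                raise ValueError("non-converged")
            w, se = res.params[1:], res.bse[1:]
        except Exception:
            from sklearn.linear_model import LogisticRegression

            ridge_penalty = 1.0
            lr = LogisticRegression(penalty="l2", C=1.0 / ridge_penalty, solver="lbfgs", max_iter=500)
            lr.fit(X[:, 1:], y)
            w = lr.coef_.ravel()
            se = np.full(n_pos, np.nan)
        frame = pd.DataFrame({"weight": w, "se": se}, index=pd.RangeIndex(1, n_pos + 1, name="position"))
        frame.attrs["ridge_penalty"] = ridge_penalty
        out[n_len if n_len is not None else 0] = frame
    return out


def decision_variability(trials: TrialSet, choices: np.ndarray) -> pd.DataFrame:
    """Inverse sensitivity (1 / probit slope on total evidence) per length."""
    import statsmodels.api as sm

    rows = []
    for n_len in sorted(set(trials.n_stimuli)):
        idx = trials.n_stimuli == n_len
        sub = trials.subset(idx)
        y = (choices[idx] > 0).astype(float)
        X = sm.add_constant(sub.total_llr)
        try:
            with np.errstate(all="ignore"):
                res = sm.Probit(y, X).fit(disp=0, maxiter=200)
            slope = res.params[1]
            se = res.bse[1]
        except Exception:
            slope, se = 0.0, np.nan
        var = 1.0 / slope if slope > 0 else np.inf
        rows.append({"n_stimuli": n_len, "slope": slope, "slope_se": se, "variability": var})
    return pd.DataFrame(rows).set_index("n_stimuli")


def softmax_beta_for_sigma(sigma_sel: float) -> float:
    """Probit-to-logit scale map (display only).

    Softmax inverse temperature whose choice curve best matches Gaussian
    selection noise of s.d. ``sigma_sel``: logistic(1.702 x) ~ Phi(x).
    """
    if sigma_sel <= 0:
        return np.inf
    return 1.702 / sigma_sel
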