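"""Online Bayesian titration of task coherence.

The coherence kappa is adjusted during the session so that the
noisy-inference observer's predicted accuracy matches a target (75%).
Every 36 trials the inference-noise estimate is refit by maximum
likelihood on all accumulated trials and kappa is re-solved.

Predicted accuracy for the inference-only observer is computed
deterministically: conditional on the correct category, each stimulus
contributes evidence l = 2*kappa*cos(d) with d ~ von Mises(0, kappa)
(doubled-angle deviation from the category mean).  The distribution of
the n-stimulus sum is obtained by discretising the single-stimulus law
on a grid and raising its characteristic function to the n-th power
(FFT convolution); accuracy is then E[Phi(L / (sigma*sqrt(n)))] under
that law.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .observer import LAPSE_FLOOR, ObserverParams, simulate_observer
from .task import TaskConfig, sample_trials

KAPPA_BOUNDS = (0.01, 4.0)

__all__ = ["predicted_accuracy", "titrate_kappa", "run_titration", "TitrationState"]


def _sum_evidence_pmf(kappa: float, n: int, n_grid: int = 1024):
    """Grid and pmf of the summed correct-category evidence L_n."""
    x = np.linspace(-np.pi, np.pi, 4096, endpoint=False)
    w = np.exp(kappa * np.cos(x))
    w /= w.sum()
    ell = 2.0 * kappa * np.cos(x)
    lo, hi = -2.0 * kappa, 2.0 * kappa
    edges = np.linspace(lo, hi, n_grid + 1)
    pmf1, _ = np.histogram(ell, bins=edges, weights=w)
    h = edges[1] - edges[0]
    n_fft = int(2 ** np.ceil(np.log2(n_grid * n + 1)))
    f = np.fft.rfft(pmf1, n_fft)
    pmf_n = np.fft.irfft(f ** n, n_fft)[: n_grid * n - (n - 1)]
    pmf_n = np.maximum(pmf_n, 0.0)
    pmf_n /= pmf_n.sum()
    centers0 = 0.5 * (edges[:-1] + edges[1:])
    grid = centers0[0] * n + h * np.arange(len(pmf_n))
    return grid, pmf_n


def predicted_accuracy(kappa: float, sigma_inf: float, lengths, n_grid: int = 1024) -> float:
    """Model-implied P(correct) of the inference-only observer,
    averaged uniformly over sequence lengths."""
    accs = []
    for n in lengths:
        grid, pmf = _sum_evidence_pmf(kappa, int(n), n_grid)
        s = sigma_inf * np.sqrt(n)
        if s > 0:
            p_correct = stats.norm.cdf(grid / s)
        else:
            p_correct = (grid > 0).astype(float) + 0.5 * (grid == 0)
        accs.append(float(pmf @ p_correct))
    return float(np.mean(accs))


def titrate_kappa(
    sigma_inf_hat: float,
    target_accuracy: float,
    config: TaskConfig,
    bounds: tuple[float, float] = KAPPA_BOUNDS,
    tol: float = 1e-3,
) -> float:
    """Coherence at which predicted accuracy hits the target (bisection)."""
    if not 0.5 < target_accuracy < 1:
        raise ValueError("target must lie in (0.5, 1)")
    if sigma_inf_hat < 0:
        raise ValueError("sigma_inf_hat must be >= 0")
    lengths = config.sequence_lengths

    def f(k):
        return predicted_accuracy(k, sigma_inf_hat, lengths) - target_accuracy

    lo, hi = bounds
    f_lo, f_hi = f(lo), f(hi)
    if f_lo >= 0:
        if f_lo > tol:
            warnings.warn("target below reachable accuracy range; kappa clamped low")
        return lo
    if f_hi <= 0:
        if -f_hi > tol:
            warnings.warn("target above reachable accuracy range; kappa clamped high")
        return hi
    return float(optimize.brentq(f, lo, hi, xtol=1e-4, rtol=1e-6, maxiter=100))


def fit_sigma_inf(total_llr, n_stimuli, choices, bounds=(1e-4, 5.0)) -> float:
    """One-parameter MLE of inference noise from probit choice behaviour."""
    L = np.asarray(total_llr, dtype=float)
    sq = np.sqrt(np.asarray(n_stimuli, dtype=float))
    y = np.asarray(choices, dtype=float)

    def neg(sig):
        p = stats.norm.cdf(y * L / (sig * sq))
        return -np.log(np.clip(p, LAPSE_FLOOR, 1.0 - LAPSE_FLOOR)).sum()

    res = optimize.minimize_scalar(neg, bounds=bounds, method="bounded",
                                   options={"xatol": 1e-5})
    return float(res.x)


@dataclass
class TitrationState:
    """Closed-loop titration state."""

    sigma_inf_hat: float = 0.5
    kappa_current: float = 0.0
    update_every: int = 36
    history_llr: list = field(default_factory=list)
    history_n: list = field(default_factory=list)
    history_choice: list = field(default_factory=list)


def run_titration(
    observer_params: ObserverParams,
    config: TaskConfig,
    n_blocks: int,
    rng: np.random.Generator,
    sigma_init: float = 0.5,
) -> pd.DataFrame:
    """Run a closed-loop titrated session.

    Returns one row per 36-trial update step: kappa used, realised
    accuracy of the step, and the refitted sigma estimate.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    state = TitrationState(sigma_inf_hat=sigma_init, update_every=36)
    state.kappa_current = titrate_kappa(sigma_init, config.target_accuracy, config)
    steps_per_block = max(1, config.trials_per_block // state.update_every)
    rows = []
    for step in range(n_blocks * steps_per_block):
        trials = sample_trials(config, state.update_every, rng, kappa=state.kappa_current)
        choices, _ = simulate_observer(trials, observer_params, rng)
        acc = float(np.mean(choices == trials.category))
        state.history_llr.append(trials.total_llr)
        state.history_n.append(trials.n_stimuli)
        state.history_choice.append(choices)
        kappa_used = state.kappa_current
        try:
            state.sigma_inf_hat = fit_sigma_inf(
                np.concatenate(state.history_llr),
                np.concatenate(state.history_n),
                np.concatenate(state.history_choice),
            )
            state.kappa_current = titrate_kappa(state.sigma_inf_hat,
                                                config.target_accuracy, config)
        except Exception as exc:  # hold kappa on a failed refit
            warnings.warn(f"titration refit failed at step {step}: {exc}")
        rows.append({"step": step, "block": step // steps_per_block,
                     "kappa": kappa_used, "accuracy": acc,
                     "sigma_hat": state.sigma_inf_hat})
    return pd.DataFrame(rows)
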