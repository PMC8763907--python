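"""Bayesian model selection over subjects (fixed and random effects).

Random-effects selection treats the model identity as a random effect
across subjects and estimates a Dirichlet posterior over model
frequencies by the standard variational update; exceedance
probabilities (the posterior probability that a model is the most
frequent in the population) are computed by seeded Monte-Carlo sampling
of the Dirichlet.  Family-wise selection aggregates model probabilities
over the members containing each noise source.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma

__all__ = ["BMSResult", "rfx_bms", "family_bms"]


@dataclass
class BMSResult:
    model_names: list[str]
    alpha: np.ndarray                 # Dirichlet concentrations
    expected_prob: np.ndarray         # posterior mean model frequencies
    exceedance_prob: np.ndarray
    exceedance_mc_se: np.ndarray
    fixed_effects_log_ev: np.ndarray  # summed log evidence per model
    subject_posteriors: np.ndarray    # subjects x models assignment probs
    family_names: list[str] = field(default_factory=list)
    family_prob: np.ndarray | None = None
    family_exceedance: np.ndarray | None = None

    @property
    def fixed_effects_posterior(self) -> np.ndarray:
        z = self.fixed_effects_log_ev - self.fixed_effects_log_ev.max()
        w = np.exp(z)
        return w / w.sum()


def rfx_bms(
    log_evidence: np.ndarray,
    model_names: list[str] | None = None,
    alpha0: float = 1.0,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    n_draws: int = 1_000_000,
    seed: int = 0,
) -> BMSResult:
    """Random-effects BMS from a subjects x models log-evidence matrix."""
    log_ev = np.asarray(log_evidence, dtype=float)
    if log_ev.ndim != 2:
        raise ValueError("log_evidence must be subjects x models")
    n_subj, n_models = log_ev.shape
    if n_models < 1 or n_subj < 1:
        raise ValueError("need >= 1 subject and >= 1 model")
    bad = ~np.isfinite(log_ev)
    if bad.any():
        s, m = np.argwhere(bad)[0]
        name = model_names[m] if model_names else str(m)
        raise ValueError(f"non-finite log evidence for subject {s}, model {name}")
    if model_names is None:
        model_names = [f"m{i}" for i in range(n_models)]

    alpha = np.full(n_models, alpha0, dtype=float)
    u = np.zeros((n_subj, n_models))
    for _ in range(max_iter):
        log_u = log_ev + (digamma(alpha) - digamma(alpha.sum()))[None, :]
        log_u -= log_u.max(axis=1, keepdims=True)
        u = np.exp(log_u)
        u /= u.sum(axis=1, keepdims=True)
        alpha_new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new

    rng = np.random.default_rng(seed)
    if n_models == 1:
        exc = np.array([1.0])
        se = np.array([0.0])
    else:
        counts = np.zeros(n_models)
        chunk = 200_000
        done = 0
        while done < n_draws:
            k = min(chunk, n_draws - done)
            draws = rng.dirichlet(alpha, size=k)
            counts += np.bincount(np.argmax(draws, axis=1), minlength=n_models)
            done += k
        exc = counts / n_draws
        se = np.sqrt(exc * (1.0 - exc) / n_draws)

    return BMSResult(
        model_names=list(model_names),
        alpha=alpha,
        expected_prob=alpha / alpha.sum(),
        exceedance_prob=exc,
        exceedance_mc_se=se,
        fixed_effects_log_ev=log_ev.sum(axis=0),
        subject_posteriors=u,
    )


def family_bms(
    bms: BMSResult,
    families: dict[str, np.ndarray],
    n_draws: int = 1_000_000,
    seed: int = 0,
) -> BMSResult:
    """Per-source family probabilities and exceedance from a BMSResult.

    ``families`` maps a family name to a boolean membership vector over
    the model set.  Each family must split the model set evenly (both
    levels of the factor present with equal counts), as in a factorized
    model set; family probability is the summed model frequency over
    members, family exceedance the posterior probability that this
    frequency exceeds one half.
    """
    n_models = len(bms.model_names)
    fam_names = list(families)
    members = np.vstack([np.asarray(families[f], dtype=bool) for f in fam_names])
    for name, m in zip(fam_names, members):
        if m.sum() == 0 or m.sum() == n_models or 2 * m.sum() != n_models:
            raise ValueError(f"family '{name}' does not split the model set evenly")

    fam_prob = members @ bms.expected_prob
    rng = np.random.default_rng(seed)
    counts = np.zeros(len(fam_names))
    chunk = 200_000
    done = 0
    while done < n_draws:
        k = min(chunk, n_draws - done)
        draws = rng.dirichlet(bms.alpha, size=k)
        counts += (draws @ members.T > 0.5).sum(axis=0)
        done += k
    fam_exc = counts / n_draws

    out = BMSResult(
        model_names=bms.model_names,
        alpha=bms.alpha,
        expected_prob=bms.expected_prob,
        exceedance_prob=bms.exceedance_prob,
        exceedance_mc_se=bms.exceedance_mc_se,
        fixed_effects_log_ev=bms.fixed_effects_log_ev,
        subject_posteriors=bms.subject_posteriors,
        family_names=fam_names,
        family_prob=fam_prob,
        family_exceedance=fam_exc,
    )
    return out


def source_families(specs) -> dict[str, np.ndarray]:
    """Membership vectors of the three noise-source families for a spec list."""
    from .fitting import SOURCES

    return {s: np.array([s in sp.active_sources for sp in specs]) for s in SOURCES}
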