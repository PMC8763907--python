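"""Opt-out (decision-uncertainty) modelling.

After each categorisation the agent may opt out of its decision and be
rewarded by a lottery of known success probability instead.  The
probability of opting out is modelled by a logistic in two log-odds
regressors, the expected accuracy of the decision and the lottery
probability:

    p(opt out) = 1 / (1 + exp(b0 + b1 * l_cor - b2 * l_lot))

with l_cor = logit(p_cor_hat), l_lot = logit(p_lot).  A lower criterion
b0 means more opting out; higher expected accuracy (b1 > 0) less; a
better lottery (b2 > 0) more.

The expected accuracy p_cor_hat derives from the observer's belief: the
final log-posterior L is Normal(mu, sd^2) under the fitted noise model,
and conditioning on the chosen side gives a truncated-normal mean m;
then p_cor_hat = logistic(|m| + delta), with delta calibrated so the
mean expected accuracy matches the mean lottery probability (0.75).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

P_CLAMP_LO = 0.5 + 1e-6
P_CLAMP_HI = 1.0 - 1e-6

__all__ = [
    "OptOutParams",
    "expected_accuracy",
    "calibrate_expected_accuracy",
    "build_observations",
    "OptOutModel",
    "OptOutResults",
    "simulate_optout",
    "psychometric_optout",
]


@dataclass(frozen=True)
class OptOutParams:
    beta0: float = 0.0        # opt-out criterion (log-odds)
    beta1: float = 1.0        # sensitivity to expected accuracy
    beta2: float = 1.0        # sensitivity to lottery probability
    calib_shift: float = 0.0  # delta, additive log-odds calibration


def _truncated_mean(mu, sd, choice):
    """E[L | sign(L) matches choice], L ~ N(mu, sd^2); choice +1/-1."""
    mu = np.asarray(mu, dtype=float)
    sd = np.asarray(sd, dtype=float)
    ch = np.asarray(choice, dtype=float)
    if np.any(sd < 0):
        raise ValueError("posterior_sd must be >= 0")
    degenerate = (sd == 0) & (mu == 0)
    if np.any(degenerate):
        raise ValueError("undefined conditioning: sd = 0 and mean = 0")
    a = np.where(sd > 0, ch * mu / np.where(sd > 0, sd, 1.0), np.inf)
    # hazard ratio phi/Phi, numerically stable via scipy logpdf/logcdf
    lam = np.exp(stats.norm.logpdf(a) - stats.norm.logcdf(a))
    m = np.where(sd > 0, mu + ch * sd * lam, mu)
    return m


def expected_accuracy(posterior_mean, posterior_sd, choice, calib_shift=0.0):
    """Expected accuracy p_cor_hat of the decision, in [0.5+eps, 1-eps]."""
    m = _truncated_mean(posterior_mean, posterior_sd, choice)
    return np.clip(expit(np.abs(m) + calib_shift), P_CLAMP_LO, P_CLAMP_HI)


def calibrate_expected_accuracy(posterior_mean, posterior_sd, choice,
                                target: float = 0.75, tol: float = 1e-10) -> float:
    """Additive log-odds shift delta such that mean p_cor_hat = target."""
    m = np.abs(_truncated_mean(posterior_mean, posterior_sd, choice))

    def mean_p(delta):
        return float(np.mean(np.clip(expit(m + delta), P_CLAMP_LO, P_CLAMP_HI)))

    lo, hi = -60.0, 60.0
    if not mean_p(lo) <= target <= mean_p(hi):
        raise ValueError("calibration target unreachable within clamp range")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if mean_p(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def build_observations(
    trials,
    choices,
    observer_params,
    calibrate: bool = True,
    target: float | None = None,
) -> pd.DataFrame:
    """Per-trial opt-out regressors from a fitted observer.

    Posterior mean/sd use the same noise propagation as the observer's
    choice probability (sensory, inference, selection contributions).
    """
    from .observer import posterior_stats

    mu, sd = posterior_stats(trials, observer_params, include_selection=True)
    if target is None:
        target = float(np.mean(trials.lottery_prob))
    delta = calibrate_expected_accuracy(mu, sd, choices, target=target) if calibrate else 0.0
    p_cor = expected_accuracy(mu, sd, choices, calib_shift=delta)
    df = pd.DataFrame(
        {
            "trial_id": np.arange(len(trials)),
            "p_cor_hat": p_cor,
            "l_cor_hat": logit(p_cor),
            "p_lot": trials.lottery_prob,
            "l_lot": logit(trials.lottery_prob),
        }
    )
    df.attrs["calib_shift"] = delta
    return df


def optout_probability(params: OptOutParams, l_cor, l_lot):
    return expit(-(params.beta0 + params.beta1 * np.asarray(l_cor)
                   - params.beta2 * np.asarray(l_lot)))


def simulate_optout(params: OptOutParams, observations: pd.DataFrame,
                    rng: np.random.Generator) -> np.ndarray:
    p = optout_probability(params, observations["l_cor_hat"], observations["l_lot"])
    return rng.random(len(observations)) < p


@dataclass
class OptOutResults:
    params: OptOutParams
    bse: np.ndarray           # se of (beta0, beta1, beta2)
    llf: float
    nobs: int
    ridge_penalty: float | None = None

    def predict(self, l_cor, l_lot):
        return optout_probability(self.params, l_cor, l_lot)

    def summary(self) -> pd.DataFrame:
        tab = pd.DataFrame(
            {"estimate": [self.params.beta0, self.params.beta1, self.params.beta2],
             "se": self.bse},
            index=pd.Index(["beta0", "beta1", "beta2"], name="parameter"),
        )
        tab.attrs.update(llf=self.llf, nobs=self.nobs, ridge_penalty=self.ridge_penalty)
        return tab


class OptOutModel:
    """Logistic opt-out model bound to per-trial observations.

    ``observations`` needs columns l_cor_hat, l_lot and opted_out.
    """

    def __init__(self, observations: pd.DataFrame):
        req = {"l_cor_hat", "l_lot", "opted_out"}
        if not req <= set(observations.columns):
            raise ValueError(f"observations must have columns {sorted(req)}")
        y = observations["opted_out"].to_numpy()
        if y.all() or not y.any():
            raise ValueError("both opt-out outcomes must be present")
        self.observations = observations

    def fit(self) -> OptOutResults:
        import statsmodels.api as sm

        obs = self.observations
        X = sm.add_constant(obs[["l_cor_hat", "l_lot"]].to_numpy())
        y = obs["opted_out"].to_numpy(float)
        ridge = None
        try:
            with np.errstate(all="ignore"):
                res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            if not np.all(np.isfinite(res.bse)):
                raise ValueError("separation")
            coefs, bse, llf = res.params, res.bse, res.llf
        except Exception:
            from sklearn.linear_model import LogisticRegression

            ridge = 1.0
            lr = LogisticRegression(C=1.0 / ridge, solver="lbfgs", max_iter=500)
            lr.fit(X[:, 1:], y)
            coefs = np.r_[lr.intercept_, lr.coef_.ravel()]
            bse = np.full(3, np.nan)
            p = lr.predict_proba(X[:, 1:])[:, 1]
            llf = float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))
        # model: p(optout) = logistic(-b0 - b1*lcor + b2*llot)
        params = OptOutParams(beta0=-coefs[0], beta1=-coefs[1], beta2=coefs[2])
        return OptOutResults(params, np.asarray(bse), llf, len(obs), ridge)


def psychometric_optout(
    observations: pd.DataFrame,
    results: OptOutResults | None = None,
    n_bins: int = 6,
    by: str = "p_cor_hat",
) -> pd.DataFrame:
    """Binned opt-out rates (with binomial se) and fitted-model overlay.

    ``by`` is 'p_cor_hat' (expected-accuracy bins) or 'p_lot' (lottery
    levels, one bin per distinct probability).  Empty bins get NaN.
    """
    obs = observations
    y = obs["opted_out"].to_numpy(float)
    x = obs[by].to_numpy(float)
    if by == "p_lot":
        edges = None
        levels = np.unique(x)
        groups = [np.isclose(x, v) for v in levels]
        centers = levels
    else:
        edges = np.quantile(x, np.linspace(0, 1, n_bins + 1))
        edges[0] -= 1e-9
        which = np.searchsorted(edges, x, side="right") - 1
        which = np.clip(which, 0, n_bins - 1)
        groups = [which == b for b in range(n_bins)]
        centers = np.array([x[g].mean() if g.any() else np.nan for g in groups])
    rows = []
    for c, g in zip(centers, groups):
        n = int(g.sum())
        if n == 0:
            rows.append({"bin_center": c, "n": 0, "rate": np.nan, "se": np.nan, "model_rate": np.nan})
            continue
        r = y[g].mean()
        se = np.sqrt(max(r * (1 - r), 1e-12) / n)
        model_rate = np.nan
        if results is not None:
            model_rate = float(np.mean(results.predict(obs["l_cor_hat"].to_numpy()[g],
                                                       obs["l_lot"].to_numpy()[g])))
        rows.append({"bin_center": c, "n": n, "rate": r, "se": se, "model_rate": model_rate})
    return pd.DataFrame(rows)
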