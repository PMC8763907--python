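"""Maximum-likelihood fitting of the suboptimal observer.

The public surface follows the Model/Results pattern:
``NoisyInferenceModel(trials, choices, spec).fit()`` returns a
``NoisyInferenceResults`` carrying the estimates, standard errors (from
the numerical Hessian at the optimum), log-likelihood and BIC, with a
``summary()`` table.  ``ConditionDifferenceModel`` fits two datasets
jointly with a single noise source allowed to differ between them.
Model evidence is approximated by -BIC/2 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import qmc

from .observer import ObserverParams, choice_loglik, simulate_observer
from .task import TaskConfig, TrialSet, sample_trials

SOURCES = ("sensory", "inference", "selection")
_BOUNDS = {"sensory": (0.0, 1.0), "inference": (0.0, 5.0), "selection": (0.0, 5.0), "leak": (0.0, 1.0)}
_PARAM_OF = {"sensory": "sigma_sen", "inference": "sigma_inf", "selection": "sigma_sel"}

__all__ = [
    "ModelSpec",
    "NoisyInferenceModel",
    "NoisyInferenceResults",
    "ConditionDifferenceModel",
    "fit_observer",
    "fit_condition_difference",
    "factorized_model_set",
    "model_recovery",
]


@dataclass(frozen=True)
class ModelSpec:
    """Which noise sources are free parameters.

    ``condition_varying_source`` marks the single source allowed to
    differ between two conditions in a joint fit.  ``kappa_fixed`` is
    the concentration used as the model's scaling parameter (set to the
    generative value, never fitted).
    """

    active_sources: frozenset = frozenset({"inference"})
    fit_leak: bool = False
    condition_varying_source: str | None = None
    kappa_fixed: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "active_sources", frozenset(self.active_sources))
        if not self.active_sources <= set(SOURCES):
            raise ValueError(f"unknown source in {self.active_sources}")
        if self.condition_varying_source is not None and self.condition_varying_source not in SOURCES:
            raise ValueError("condition_varying_source must be one of " + ", ".join(SOURCES))
        if self.kappa_fixed <= 0:
            raise ValueError("kappa_fixed must be > 0")

    @property
    def name(self) -> str:
        short = {"sensory": "sen", "inference": "inf", "selection": "sel"}
        parts = [short[s] for s in SOURCES if s in self.active_sources] or ["none"]
        if self.fit_leak:
            parts.append("leak")
        if self.condition_varying_source:
            parts.append(f"vary-{short[self.condition_varying_source]}")
        return "+".join(parts)

    @property
    def param_names(self) -> list[str]:
        names = [_PARAM_OF[s] for s in SOURCES if s in self.active_sources]
        if self.fit_leak:
            names.append("leak")
        return names


def _params_from_vec(spec: ModelSpec, vec: np.ndarray) -> ObserverParams:
    kw = dict(zip(spec.param_names, vec))
    return ObserverParams(**kw)


def _bounds(spec: ModelSpec) -> list[tuple[float, float]]:
    out = [_BOUNDS[s] for s in SOURCES if s in spec.active_sources]
    if spec.fit_leak:
        out.append(_BOUNDS["leak"])
    return out


def _multistart(negloglik, bounds, seed: int, n_starts: int):
    """Bounded multi-start minimisation; deterministic given seed."""
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    d = len(bounds)
    starts = [lo + 0.15 * (hi - lo)]  # heuristic small-noise start
    if n_starts > 1 and d > 0:
        lhs = qmc.LatinHypercube(d=d, seed=seed).random(n_starts - 1)
        starts.extend(lo + lhs * (hi - lo))
    best = None
    converged = False
    for x0 in starts:
        res = optimize.minimize(
            negloglik, x0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-9, "gtol": 1e-6, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
        converged = converged or res.success
    return best, converged


@dataclass
class NoisyInferenceResults:
    """Results of a maximum-likelihood observer fit."""

    spec: ModelSpec
    params: ObserverParams
    params_vec: np.ndarray
    param_names: list[str]
    llf: float
    nobs: int
    bse: np.ndarray = field(default=None)
    converged: bool = True

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def bic(self) -> float:
        return self.n_params * np.log(self.nobs) - 2.0 * self.llf

    @property
    def log_evidence(self) -> float:
        """BIC approximation to log p(data | model)."""
        return -0.5 * self.bic

    def summary(self) -> pd.DataFrame:
        tab = pd.DataFrame(
            {"estimate": self.params_vec, "se": self.bse},
            index=pd.Index(self.param_names, name="parameter"),
        )
        tab.attrs.update(
            model=self.spec.name, llf=self.llf, bic=self.bic,
            nobs=self.nobs, converged=self.converged,
        )
        return tab

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        pars = ", ".join(f"{n}={v:.4g}" for n, v in zip(self.param_names, self.params_vec))
        return (f"<NoisyInferenceResults {self.spec.name}: {pars}; "
                f"llf={self.llf:.2f}, bic={self.bic:.2f}, n={self.nobs}>")


class NoisyInferenceModel:
    """Suboptimal-observer model bound to one behavioural dataset."""

    def __init__(self, trials: TrialSet, choices: np.ndarray, spec: ModelSpec | None = None):
        if len(trials) == 0:
            raise ValueError("empty dataset")
        self.trials = trials
        self.choices = np.asarray(choices)
        self.spec = spec if spec is not None else ModelSpec()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, config: TaskConfig, spec: ModelSpec | None = None):
        from .task import from_dataframe

        trials, choices = from_dataframe(df, config)
        if choices is None:
            raise ValueError("dataframe has no 'choice' column")
        return cls(trials, choices, spec)

    def loglike(self, vec: np.ndarray) -> float:
        return choice_loglik(self.trials, self.choices, _params_from_vec(self.spec, vec))

    def fit(self, seed: int = 0, n_starts: int = 6) -> NoisyInferenceResults:
        bounds = _bounds(self.spec)
        if not bounds:  # no-noise member of the factorized set
            llf = self.loglike(np.zeros(0))
            return NoisyInferenceResults(self.spec, ObserverParams(), np.zeros(0), [],
                                         llf, len(self.trials), np.zeros(0), True)
        neg = lambda v: -self.loglike(v)
        best, converged = _multistart(neg, bounds, seed, n_starts)
        bse = _hessian_bse(neg, best.x, bounds)
        return NoisyInferenceResults(
            self.spec, _params_from_vec(self.spec, best.x), best.x,
            self.spec.param_names, -best.fun, len(self.trials), bse, converged,
        )


def _hessian_bse(negloglik, x: np.ndarray, bounds) -> np.ndarray:
    """Standard errors from the numerical Hessian; NaN at active bounds."""
    from statsmodels.tools.numdiff import approx_hess1

    at_bound = np.array([not (b[0] + 1e-6 < xi < b[1] - 1e-6) for xi, b in zip(x, bounds)])
    bse = np.full(len(x), np.nan)
    free = ~at_bound
    if free.any():
        def f(sub):
            full = x.copy()
            full[free] = sub
            return negloglik(full)
        try:
            H = approx_hess1(x[free], f)
            cov = np.linalg.inv(H)
            d = np.diag(cov)
            bse[free] = np.sqrt(np.where(d > 0, d, np.nan))
        except np.linalg.LinAlgError:
            pass
    return bse


class ConditionDifferenceModel:
    """Joint fit of two conditions with one source allowed to vary.

    All three noise sources are included; the non-varying sources share
    a single parameter across conditions, the varying one has two.
    """

    def __init__(self, trials_a: TrialSet, choices_a, trials_b: TrialSet, choices_b,
                 varying: str, active_sources=frozenset(SOURCES), fit_leak: bool = False):
        if varying not in SOURCES:
            raise ValueError("varying must be one of " + ", ".join(SOURCES))
        self.spec = ModelSpec(active_sources=active_sources, fit_leak=fit_leak,
                              condition_varying_source=varying)
        self.trials_a, self.choices_a = trials_a, np.asarray(choices_a)
        self.trials_b, self.choices_b = trials_b, np.asarray(choices_b)
        self.varying = varying

    @property
    def param_names(self) -> list[str]:
        names = []
        for s in SOURCES:
            if s not in self.spec.active_sources:
                continue
            if s == self.varying:
                names += [_PARAM_OF[s] + "_a", _PARAM_OF[s] + "_b"]
            else:
                names.append(_PARAM_OF[s])
        if self.spec.fit_leak:
            names.append("leak")
        return names

    def _split(self, vec: np.ndarray) -> tuple[ObserverParams, ObserverParams]:
        kw_a, kw_b = {}, {}
        i = 0
        for s in SOURCES:
            if s not in self.spec.active_sources:
                continue
            if s == self.varying:
                kw_a[_PARAM_OF[s]] = vec[i]
                kw_b[_PARAM_OF[s]] = vec[i + 1]
                i += 2
            else:
                kw_a[_PARAM_OF[s]] = kw_b[_PARAM_OF[s]] = vec[i]
                i += 1
        if self.spec.fit_leak:
            kw_a["leak"] = kw_b["leak"] = vec[i]
        return ObserverParams(**kw_a), ObserverParams(**kw_b)

    def loglike(self, vec: np.ndarray) -> float:
        pa, pb = self._split(vec)
        return (choice_loglik(self.trials_a, self.choices_a, pa)
                + choice_loglik(self.trials_b, self.choices_b, pb))

    def fit(self, seed: int = 0, n_starts: int = 6) -> NoisyInferenceResults:
        bounds = []
        for s in SOURCES:
            if s not in self.spec.active_sources:
                continue
            bounds += [_BOUNDS[s]] * (2 if s == self.varying else 1)
        if self.spec.fit_leak:
            bounds.append(_BOUNDS["leak"])
        neg = lambda v: -self.loglike(v)
        best, converged = _multistart(neg, bounds, seed, n_starts)
        bse = _hessian_bse(neg, best.x, bounds)
        nobs = len(self.trials_a) + len(self.trials_b)
        res = NoisyInferenceResults(self.spec, self._split(best.x)[0], best.x,
                                    self.param_names, -best.fun, nobs, bse, converged)
        return res


def fit_observer(trials: TrialSet, choices, spec: ModelSpec | None = None,
                 seed: int = 0, n_starts: int = 6) -> NoisyInferenceResults:
    """Functional wrapper around NoisyInferenceModel(...).fit()."""
    return NoisyInferenceModel(trials, choices, spec).fit(seed=seed, n_starts=n_starts)


def fit_condition_difference(trials_a, choices_a, trials_b, choices_b,
                             seed: int = 0, n_starts: int = 6):
    """Fit the three single-source-varying joint models and select among them.

    Returns (results dict keyed by varying source, BMSResult over the three).
    """
    from .bms import rfx_bms

    results = {}
    for src in SOURCES:
        m = ConditionDifferenceModel(trials_a, choices_a, trials_b, choices_b, varying=src)
        results[src] = m.fit(seed=seed, n_starts=n_starts)
    log_ev = np.array([[results[s].log_evidence for s in SOURCES]])
    bms = rfx_bms(log_ev, model_names=list(SOURCES), seed=seed)
    return results, bms


def factorized_model_set(fit_leak: bool = False) -> list[ModelSpec]:
    """The 2^3 factorized model set over the three noise sources."""
    specs = []
    for i in range(8):
        active = frozenset(s for b, s in zip((i & 1, i & 2, i & 4), SOURCES) if b)
        specs.append(ModelSpec(active_sources=active, fit_leak=fit_leak))
    return specs


def generating_params_for(spec: ModelSpec, magnitudes: dict | None = None) -> ObserverParams:
    """Default generating parameters for a spec (recovery simulations).

    Magnitudes chosen so each single-source observer performs near the
    titrated accuracy at the generative coherence.
    """
    mags = {"sensory": 0.4, "inference": 0.5, "selection": 2.0}
    if magnitudes:
        mags.update(magnitudes)
    kw = {_PARAM_OF[s]: (mags[s] if s in spec.active_sources else 0.0) for s in SOURCES}
    return ObserverParams(**kw)


def model_recovery(
    specs: list[ModelSpec],
    generating_params: list[ObserverParams],
    cohort_shape: tuple[int, int],
    rng: np.random.Generator,
    config: TaskConfig | None = None,
    n_reps: int = 1,
    n_starts: int = 6,
) -> pd.DataFrame:
    """Confusion matrix of model recovery.

    Rows = generating spec, columns = spec selected by random-effects
    BMS (highest expected probability); entries are selection fractions
    over ``n_reps`` simulated cohorts of ``(n_subjects, n_trials)``.
    """
    from .bms import rfx_bms

    if config is None:
        config = TaskConfig()
    n_subj, n_trials = cohort_shape
    counts = np.zeros((len(specs), len(specs)))
    errors: list[str] = []
    for gi, (gspec, gpar) in enumerate(zip(specs, generating_params)):
        for _ in range(n_reps):
            log_ev = np.zeros((n_subj, len(specs)))
            for s in range(n_subj):
                trials = sample_trials(config, n_trials, rng)
                choices, _ = simulate_observer(trials, gpar, rng)
                for mi, mspec in enumerate(specs):
                    seed = int(rng.integers(2**31 - 1))
                    try:
                        fit = NoisyInferenceModel(trials, choices, mspec).fit(seed=seed, n_starts=n_starts)
                        log_ev[s, mi] = fit.log_evidence
                    except Exception as exc:  # pragma: no cover - defensive
                        errors.append(f"gen={gspec.name} fit={mspec.name}: {exc}")
                        log_ev[s, mi] = -np.inf
            bms = rfx_bms(log_ev, model_names=[sp.name for sp in specs],
                          seed=int(rng.integers(2**31 - 1)))
            counts[gi, np.argmax(bms.expected_prob)] += 1
    mat = pd.DataFrame(counts / n_reps, index=[s.name for s in specs],
                       columns=[s.name for s in specs])
    mat.attrs["errors"] = errors
    return mat
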