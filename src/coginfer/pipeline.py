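"""End-to-end study runners and configuration.

``run_behavioral_study`` simulates a two-condition cohort, fits the
factorized observer model set per subject, runs family-wise and
condition-difference Bayesian model selection, and fits the opt-out
model.  ``run_neural_study`` generates synthetic epochs from the
behavioural run, decodes the planted orientation and evidence codes,
splits precision by condition and consistency, runs cluster statistics
and latency estimation, and projects pre-response power onto the
response axis.  Every output file carries the configuration hash; a
run is reconstructable from config + seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bms import family_bms, rfx_bms, source_families
from .commitment import CommitmentConfig
from .fitting import (ModelSpec, NoisyInferenceModel, factorized_model_set,
                      fit_condition_difference)
from .observer import ObserverParams, simulate_observer
from .optout import OptOutModel, OptOutParams, build_observations, simulate_optout
from .synth_eeg import SynthSpec, generate_response_power, generate_stimulus_epochs
from .task import TaskConfig, sample_trials, write_behavior_csv

log = logging.getLogger("coginfer")

__all__ = ["RunConfig", "run_behavioral_study", "run_neural_study"]

DEFAULT_STAGES = ("simulate", "fit", "bms", "optout")


@dataclass
class RunConfig:
    seed: int
    out_dir: str = "runs/out"
    n_subjects: int = 18
    trials_per_subject: int = 360
    task: TaskConfig = field(default_factory=TaskConfig)
    observer_by_condition: dict = field(default_factory=lambda: {
        "placebo-like": ObserverParams(sigma_inf=0.474),
        "drug-like": ObserverParams(sigma_inf=0.562),
    })
    optout_params: OptOutParams = field(default_factory=lambda: OptOutParams(
        beta0=0.5, beta1=1.2, beta2=1.0))
    commitment: CommitmentConfig = field(default_factory=CommitmentConfig)
    synth: SynthSpec = field(default_factory=SynthSpec)
    stages: tuple = DEFAULT_STAGES
    # neural scale knobs
    n_subjects_eeg: int = 6
    trials_per_subject_eeg: int = 48
    cutoff_orientation: float = 16.0
    cutoff_evidence: float = 8.0

    def config_hash(self) -> str:
        payload = _as_jsonable(self)
        payload.pop("out_dir", None)  # where outputs land is not part of the science
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        if "seed" not in raw:
            raise ValueError("seed is mandatory")
        kw = dict(raw)
        if "task" in kw:
            t = dict(kw["task"])
            if "sequence_lengths" in t:
                t["sequence_lengths"] = tuple(t["sequence_lengths"])
            if "lottery_probs" in t:
                t["lottery_probs"] = tuple(t["lottery_probs"])
            kw["task"] = TaskConfig(**t)
        if "observer_by_condition" in kw:
            kw["observer_by_condition"] = {
                k: ObserverParams(**v) for k, v in kw["observer_by_condition"].items()}
        if "optout_params" in kw:
            kw["optout_params"] = OptOutParams(**kw["optout_params"])
        if "commitment" in kw:
            kw["commitment"] = CommitmentConfig(**kw["commitment"])
        if "synth" in kw:
            s = dict(kw["synth"])
            for key in ("stim_window", "resp_window", "evidence_centers"):
                if key in s:
                    s[key] = tuple(s[key])
            if "response_lateralization" in s:
                s["response_lateralization"] = {
                    tuple(k.split("|")): tuple(v)
                    for k, v in s["response_lateralization"].items()}
            kw["synth"] = SynthSpec(**s)
        if "stages" in kw:
            kw["stages"] = tuple(kw["stages"])
        return cls(**kw)


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {"|".join(k) if isinstance(k, tuple) else str(k): _as_jsonable(v)
                for k, v in obj.items()}
    if isinstance(obj, (tuple, list)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _write_log(out: Path, config: RunConfig, stages_run, t0: float) -> None:
    (out / "run_log.txt").write_text(
        "coginfer run log\n"
        f"version: {__version__}\n"
        f"numpy: {np.__version__}\n"
        f"seed: {config.seed}\n"
        f"config_hash: {config.config_hash()}\n"
        f"stages: {', '.join(stages_run)}\n"
        f"elapsed_s: {time.time() - t0:.1f}\n"
    )


def run_behavioral_study(config: RunConfig) -> dict:
    """Simulate, fit, select and model opt-outs; writes CSV/JSON outputs."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    rng = np.random.default_rng(config.seed)
    results: dict = {"config_hash": h}
    conditions = list(config.observer_by_condition)

    cohort: dict = {c: [] for c in conditions}
    if "simulate" in config.stages:
        frames = []
        for cond in conditions:
            pars = config.observer_by_condition[cond]
            for s in range(config.n_subjects):
                trials = sample_trials(config.task, config.trials_per_subject, rng,
                                       condition=cond)
                choices, trace = simulate_observer(trials, pars, rng)
                cohort[cond].append((trials, choices, trace))
                from .task import to_dataframe

                df = to_dataframe(trials, choices)
                df.insert(0, "subject", s)
                frames.append(df)
        big = pd.concat(frames, ignore_index=True)
        big.insert(0, "config_hash", h)
        big.to_csv(out / "behavior.csv", index=False)
        results["behavior"] = big

    if "fit" in config.stages or "bms" in config.stages:
        if not cohort[conditions[0]]:
            raise RuntimeError("stage 'fit': simulate stage must run first")
        specs = factorized_model_set()
        log_ev = {c: np.zeros((config.n_subjects, len(specs))) for c in conditions}
        fit_rows = []
        for cond in conditions:
            for s, (trials, choices, _) in enumerate(cohort[cond]):
                for mi, spec in enumerate(specs):
                    fit = NoisyInferenceModel(trials, choices, spec).fit(
                        seed=int(rng.integers(2**31 - 1)))
                    log_ev[cond][s, mi] = fit.log_evidence
                    fit_rows.append({"condition": cond, "subject": s,
                                     "model": spec.name, "loglik": fit.llf,
                                     "bic": fit.bic,
                                     **dict(zip(fit.param_names, fit.params_vec))})
        fits = pd.DataFrame(fit_rows)
        fits.insert(0, "config_hash", h)
        fits.to_csv(out / "fits.csv", index=False)
        results["fits"] = fits
        for cond in conditions:
            pd.DataFrame(log_ev[cond], columns=[sp.name for sp in specs]).to_csv(
                out / f"evidence_{cond}.csv", index=False)

        if "bms" in config.stages:
            bms_out = {}
            fams = source_families(specs)
            for cond in conditions:
                bms = rfx_bms(log_ev[cond], [sp.name for sp in specs],
                              seed=config.seed)
                fam = family_bms(bms, fams, seed=config.seed)
                bms_out[cond] = {
                    "expected_prob": dict(zip(bms.model_names, bms.expected_prob)),
                    "exceedance_prob": dict(zip(bms.model_names, bms.exceedance_prob)),
                    "family_prob": dict(zip(fam.family_names, fam.family_prob)),
                    "family_exceedance": dict(zip(fam.family_names, fam.family_exceedance)),
                }
            if len(conditions) == 2:
                diff_ev = []
                for s in range(config.n_subjects):
                    ta, ca, _ = cohort[conditions[0]][s]
                    tb, cb, _ = cohort[conditions[1]][s]
                    res, _ = fit_condition_difference(ta, ca, tb, cb,
                                                      seed=int(rng.integers(2**31 - 1)))
                    diff_ev.append([res[src].log_evidence for src in res])
                bms_diff = rfx_bms(np.asarray(diff_ev),
                                   list(res), seed=config.seed)
                bms_out["condition_difference"] = {
                    "exceedance_prob": dict(zip(bms_diff.model_names,
                                                bms_diff.exceedance_prob))}
            (out / "bms.json").write_text(json.dumps(
                {"config_hash": h, **_as_jsonable(bms_out)}, indent=2, default=float))
            results["bms"] = bms_out

    if "optout" in config.stages:
        if not cohort[conditions[0]]:
            raise RuntimeError("stage 'optout': simulate stage must run first")
        oo_rows = []
        for cond in conditions:
            pars = config.observer_by_condition[cond]
            for s, (trials, choices, _) in enumerate(cohort[cond]):
                obs = build_observations(trials, choices, pars)
                obs["opted_out"] = simulate_optout(config.optout_params, obs, rng)
                fit = OptOutModel(obs).fit()
                oo_rows.append({"condition": cond, "subject": s,
                                "beta0": fit.params.beta0, "beta1": fit.params.beta1,
                                "beta2": fit.params.beta2,
                                "optout_rate": float(obs["opted_out"].mean())})
        oo = pd.DataFrame(oo_rows)
        oo.insert(0, "config_hash", h)
        oo.to_csv(out / "optout.csv", index=False)
        results["optout"] = oo

    _write_log(out, config, list(config.stages), t0)
    return results


def run_neural_study(config: RunConfig) -> dict:
    """Generate epochs, decode, split, test, and project response power."""
    from .neural import (cluster_permutation, coding_precision, decode_cv,
                         jackknife_latency, prepare_features, response_activity,
                         write_epochs_h5)

    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    rng = np.random.default_rng(config.seed + 1)
    conditions = list(config.observer_by_condition)
    windows = {"orientation": (0.05, 0.15), "evidence": (0.25, 0.45)}

    per_subject = {"orientation": {c: [] for c in conditions},
                   "evidence": {c: [] for c in conditions}}
    window_rows = []
    onset_series = {c: [] for c in conditions}
    times = None
    for s in range(config.n_subjects_eeg):
        for cond in conditions:
            pars = config.observer_by_condition[cond]
            trials = sample_trials(config.task, config.trials_per_subject_eeg, rng,
                                   condition=cond)
            choices, trace = simulate_observer(trials, pars, rng)
            epochs = generate_stimulus_epochs(config.synth, trials, choices, trace, rng)
            if s == 0 and cond == conditions[0]:
                write_epochs_h5(out / "epochs_example.h5", epochs)
            for code, regs, cutoff in (
                ("orientation", ["cos2t", "sin2t"], config.cutoff_orientation),
                ("evidence", ["evidence"], config.cutoff_evidence),
            ):
                feats = prepare_features(epochs, cutoff)
                preds = decode_cv(feats, epochs.metadata, regs)
                tc = coding_precision(preds, epochs.metadata[regs].to_numpy(float),
                                      epochs.times, windows={code: windows[code]})
                per_subject[code][cond].append(tc.precision)
                window_rows.append({"subject": s, "condition": cond, "code": code,
                                    "window_precision": tc.window_precision[code]})
                times = tc.times
            # pre-response power and response activity
            sides = np.where(rng.random(len(trials)) < 0.5, "left", "right")
            outcomes = np.where(rng.random(len(trials)) < 0.35, "opt-out", "validated")
            power = generate_response_power(config.synth, sides,
                                            np.full(len(trials), cond, dtype=object),
                                            outcomes, rng)
            ra = response_activity(power, n_folds=4, estimate_onset=False)
            onset_series[cond].append(ra.projection)

    summary: dict = {"config_hash": h}
    rows = []
    for code in ("orientation", "evidence"):
        for cond in conditions:
            arr = np.vstack(per_subject[code][cond])
            for t, (m, sd) in enumerate(zip(arr.mean(axis=0), arr.std(axis=0, ddof=1))):
                rows.append({"code": code, "condition": cond, "time": times[t],
                             "precision_mean": m, "precision_sd": sd})
        if len(conditions) == 2:
            a = np.vstack(per_subject[code][conditions[0]])
            b = np.vstack(per_subject[code][conditions[1]])
            res = cluster_permutation(a, b, n_perm=1000, seed=config.seed)
            summary[f"{code}_condition_clusters"] = [
                {"start_s": float(times[c.start]), "stop_s": float(times[c.stop]),
                 "mass": c.mass, "p": c.p} for c in res.clusters]
            lat = jackknife_latency(np.vstack([a, b]), times, mode="peak")
            summary[f"{code}_peak_latency_s"] = lat.estimate
            summary[f"{code}_peak_latency_se"] = lat.se
    pd.DataFrame(rows).assign(config_hash=h).to_csv(out / "coding_precision.csv", index=False)
    pd.DataFrame(window_rows).assign(config_hash=h).to_csv(out / "window_precision.csv",
                                                           index=False)

    resp_times = SynthSpec.times(config.synth, config.synth.resp_window)
    for cond in conditions:
        arr = np.vstack(onset_series[cond])
        lat = jackknife_latency(arr, resp_times, mode="onset", lock_time=0.0)
        summary[f"response_onset_{cond}_s"] = lat.estimate
        summary[f"response_onset_{cond}_se"] = lat.se
    (out / "neural_summary.json").write_text(json.dumps(_as_jsonable(summary),
                                                        indent=2, default=float))
    _write_log(out, config, ["neural"], t0)
    return summary
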