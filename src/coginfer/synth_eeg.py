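"""Synthetic multichannel epochs with planted neural codes.

Stand-in for scalp recordings in the cue-combination task: each
stimulus-locked epoch carries

* an orientation code (amplitude proportional to cos 2theta and
  sin 2theta) on an occipital topography, as a temporal bump around
  100 ms after stimulus onset;
* an evidence code (amplitude proportional to the observer's internal
  noisy evidence strength |l_hat|) on a parietal/frontal topography,
  peaking around 300 ms;
* 1/f background noise plus an alpha-band oscillation.

A drug-like condition scales the evidence code's SNR down and applies a
gain on conflicting-stimulus evidence that falls off with position in
the sequence.  Pre-response band-power epochs carry a lateralised
suppression over motor channels whose onset depends on condition and
trial outcome.  Driving the evidence code by the internal |l_hat|
rather than the objective |l| makes the decoder's residuals predictive
of the upcoming choice, as the brain-behaviour analysis expects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .neural.epochs import EpochSet
from .observer import ObserverTrace
from .task import TrialSet

__all__ = ["SynthSpec", "generate_stimulus_epochs", "generate_response_power"]


@dataclass
class SynthSpec:
    """Parameters of the synthetic epoch generator.

    Rostro-caudal coordinate runs 0 (frontal) to 1 (occipital);
    channels alternate hemispheres.  SNRs are code amplitudes relative
    to unit noise s.d.
    """

    n_channels: int = 64
    sample_rate: float = 256.0
    stim_window: tuple[float, float] = (-0.2, 0.8)
    resp_window: tuple[float, float] = (-2.5, 0.5)
    code_latency_orientation: float = 0.1
    code_latency_evidence: float = 0.3
    bump_sd: float = 0.05
    occipital_center: float = 0.9
    occipital_width: float = 0.12
    evidence_centers: tuple[float, ...] = (0.15, 0.45)  # frontal + parietal
    evidence_width: float = 0.12
    snr_orientation: dict = field(default_factory=lambda: {"placebo-like": 1.0, "drug-like": 1.0})
    snr_evidence: dict = field(default_factory=lambda: {"placebo-like": 1.0, "drug-like": 0.6})
    consistency_gain: dict = field(default_factory=lambda: {"placebo-like": 1.0, "drug-like": 0.3})
    noise_sd: float = 1.0
    one_over_f_exponent: float = 1.0
    alpha_amp: float = 0.5
    alpha_freq: float = 10.0
    # (condition, outcome) -> (amplitude, onset seconds before t=0)
    response_lateralization: dict = field(default_factory=lambda: {
        ("placebo-like", "validated"): (1.0, -0.3),
        ("placebo-like", "opt-out"): (1.0, -0.3),
        ("drug-like", "validated"): (1.0, -1.8),
        ("drug-like", "opt-out"): (1.0, -0.3),
    })
    seed_patterns: int = 7

    def __post_init__(self) -> None:
        t0, t1 = self.stim_window
        for lat in (self.code_latency_orientation, self.code_latency_evidence):
            if not t0 < lat < t1:
                raise ValueError("code latency outside the epoch window")
        if any(v < 0 for v in self.snr_orientation.values()):
            raise ValueError("snr must be >= 0")
        if any(v < 0 for v in self.snr_evidence.values()):
            raise ValueError("snr must be >= 0")
        if any(not 0 <= v <= 1 for v in self.consistency_gain.values()):
            raise ValueError("consistency_gain must lie in [0, 1]")

    def channel_table(self) -> pd.DataFrame:
        caudal = np.linspace(0.0, 1.0, self.n_channels)
        hemi = np.where(np.arange(self.n_channels) % 2 == 0, -1, 1)
        return pd.DataFrame({
            "label": [f"ch{i:02d}" for i in range(self.n_channels)],
            "caudal": caudal,
            "hemisphere": hemi,
        })

    def times(self, window) -> np.ndarray:
        t0, t1 = window
        n = int(round((t1 - t0) * self.sample_rate))
        return t0 + np.arange(n) / self.sample_rate


def _gauss_topo(caudal: np.ndarray, center: float, width: float) -> np.ndarray:
    g = np.exp(-0.5 * ((caudal - center) / width) ** 2)
    return g / np.linalg.norm(g)


def _noise(spec: SynthSpec, shape, rng: np.random.Generator) -> np.ndarray:
    """1/f-shaped noise plus a random-phase alpha oscillation."""
    n_t = shape[-1]
    white = rng.standard_normal(shape)
    freqs = np.fft.rfftfreq(n_t, d=1.0 / spec.sample_rate)
    shape_f = np.ones_like(freqs)
    shape_f[1:] = freqs[1:] ** (-spec.one_over_f_exponent / 2.0)
    spec_w = np.fft.rfft(white, axis=-1) * shape_f
    pink = np.fft.irfft(spec_w, n_t, axis=-1)
    pink *= spec.noise_sd / max(pink.std(), 1e-12)
    t = np.arange(n_t) / spec.sample_rate
    phase = rng.uniform(0, 2 * np.pi, size=shape[:-1])[..., None]
    alpha = spec.alpha_amp * np.sin(2 * np.pi * spec.alpha_freq * t + phase)
    return pink + alpha


def generate_stimulus_epochs(
    spec: SynthSpec,
    trials: TrialSet,
    choices: np.ndarray,
    trace: ObserverTrace,
    rng: np.random.Generator,
) -> EpochSet:
    """Stimulus-locked epochs, one per (trial, stimulus position)."""
    if trace is None:
        raise ValueError("observer traces required (evidence code uses internal |l_hat|)")
    ch = spec.channel_table()
    caudal = ch["caudal"].to_numpy()
    times = spec.times(spec.stim_window)
    pat_rng = np.random.default_rng(spec.seed_patterns)
    occ = _gauss_topo(caudal, spec.occipital_center, spec.occipital_width)
    # two linearly independent occipital patterns for the cos/sin pair
    p_cos = occ * pat_rng.choice([-1.0, 1.0], size=len(caudal))
    p_sin = occ * pat_rng.choice([-1.0, 1.0], size=len(caudal))
    p_cos /= np.linalg.norm(p_cos)
    p_sin /= np.linalg.norm(p_sin)
    ev = sum(_gauss_topo(caudal, c, spec.evidence_width) for c in spec.evidence_centers)
    p_ev = ev / np.linalg.norm(ev)

    bump_o = np.exp(-0.5 * ((times - spec.code_latency_orientation) / spec.bump_sd) ** 2)
    bump_e = np.exp(-0.5 * ((times - spec.code_latency_evidence) / spec.bump_sd) ** 2)

    mask = trials.mask
    tr_idx, pos_idx = np.nonzero(mask)
    n_ep = len(tr_idx)
    theta = trials.theta[tr_idx, pos_idx]
    llr = trials.llr[tr_idx, pos_idx]
    llr_hat = trace.noisy_llr[tr_idx, pos_idx]
    cond = trials.condition[tr_idx]
    position = pos_idx + 1
    n_of_trial = trials.n_stimuli[tr_idx]
    consistent = (np.sign(llr) * choices[tr_idx]) > 0

    snr_o = np.array([spec.snr_orientation[c] for c in cond])
    snr_e = np.array([spec.snr_evidence[c] for c in cond])
    cg = np.array([spec.consistency_gain[c] for c in cond])
    # conflicting-stimulus gain declines linearly with position toward cg
    frac = (position - 1) / np.maximum(n_of_trial - 1, 1)
    gain = np.where(consistent, 1.0, 1.0 - (1.0 - cg) * frac)

    data = _noise(spec, (n_ep, spec.n_channels, len(times)), rng)
    amp_cos = snr_o * np.cos(2 * theta)
    amp_sin = snr_o * np.sin(2 * theta)
    amp_ev = snr_e * gain * np.abs(llr_hat)
    data += amp_cos[:, None, None] * p_cos[None, :, None] * bump_o[None, None, :]
    data += amp_sin[:, None, None] * p_sin[None, :, None] * bump_o[None, None, :]
    data += amp_ev[:, None, None] * p_ev[None, :, None] * bump_e[None, None, :]

    meta = pd.DataFrame({
        "trial_id": tr_idx,
        "position": position,
        "cos2t": np.cos(2 * theta),
        "sin2t": np.sin(2 * theta),
        "evidence": np.abs(llr),
        "evidence_signed": llr,
        "evidence_internal": np.abs(llr_hat),
        "condition": cond,
        "consistent": consistent,
        "choice": choices[tr_idx],
    })
    return EpochSet(data=data, times=times, channels=ch, metadata=meta)


def generate_response_power(
    spec: SynthSpec,
    response_sides: np.ndarray,
    conditions: np.ndarray,
    outcomes: np.ndarray,
    rng: np.random.Generator,
    trial_ids: np.ndarray | None = None,
) -> EpochSet:
    """Pre-response band-power epochs with lateralised motor suppression.

    Power over the hemisphere contralateral to the response hand is
    suppressed from an onset that depends on (condition, outcome),
    ramping linearly to full amplitude at the lock event.
    """
    n_ep = len(response_sides)
    ch = spec.channel_table()
    caudal = ch["caudal"].to_numpy()
    hemi = ch["hemisphere"].to_numpy()
    times = spec.times(spec.resp_window)
    motor = _gauss_topo(caudal, 0.4, 0.1)

    data = 1.0 + 0.5 * _noise(spec, (n_ep, spec.n_channels, len(times)), rng)
    amp = np.zeros(n_ep)
    onset = np.zeros(n_ep)
    for i, (c, o) in enumerate(zip(conditions, outcomes)):
        a, t0 = spec.response_lateralization[(c, o)]
        amp[i], onset[i] = a, t0
    ramp = np.clip((times[None, :] - onset[:, None]) / np.maximum(-onset[:, None], 1e-9), 0.0, 1.0)
    contra = np.where(np.asarray(response_sides) == "left", 1.0, -1.0)
    # suppression on the contralateral hemisphere, facilitation ipsilateral
    lat_topo = motor * hemi  # +right/-left weighting
    data -= (amp * contra)[:, None, None] * lat_topo[None, :, None] * ramp[:, None, :]

    meta = pd.DataFrame({
        "trial_id": np.arange(n_ep) if trial_ids is None else np.asarray(trial_ids),
        "response_side": np.asarray(response_sides, dtype=object),
        "condition": np.asarray(conditions, dtype=object),
        "outcome": np.asarray(outcomes, dtype=object),
    })
    return EpochSet(data=data, times=times, channels=ch, metadata=meta)
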