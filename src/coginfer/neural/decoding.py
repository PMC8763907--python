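"""Inverted-encoding-model decoding.

A linear encoding model D = W_enc C maps stimulus characteristics
(regressors C) to data features D at each time point; W_enc is the
ordinary-least-squares solution

    W_enc = D C^T (C C^T)^-1

and its pseudoinverse

    W_dec = (W_enc^T W_enc)^-1 W_enc^T

turns held-out data into neural predictions C_hat = W_dec D.  Data
features are the real and imaginary parts of the analytic (Hilbert)
representation of low-pass-filtered signals, doubling the channel
count.  Decoding precision is the Fisher z of the Pearson correlation
between predictions and ground truth on epochs never used for
training (interleaved cross-validation with folds assigned at the
trial level).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .epochs import EpochSet

Z_CAP = np.arctanh(1.0 - 1e-12)

__all__ = [
    "EncodingModel", "CodingTimecourse", "prepare_features",
    "fit_invert_encoder", "decode_cv", "coding_precision", "trial_folds",
]


def prepare_features(epochs: EpochSet, cutoff: float, order: int = 4) -> np.ndarray:
    """Analytic-signal features: (epochs, 2*channels, times).

    Low-pass Butterworth filter (zero-phase) then Hilbert transform;
    features are the real and imaginary parts stacked channel-wise.
    """
    fs = epochs.sfreq
    if cutoff >= fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz >= Nyquist {fs / 2} Hz")
    sos = signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
    n_warm = 3 * (2 * order + 1)
    if epochs.data.shape[2] <= n_warm:
        raise ValueError("epoch shorter than filter warm-up")
    filt = signal.sosfiltfilt(sos, epochs.data, axis=2)
    analytic = signal.hilbert(filt, axis=2)
    return np.concatenate([analytic.real, analytic.imag], axis=1)


@dataclass
class EncodingModel:
    w_enc: np.ndarray  # features x regressors
    w_dec: np.ndarray  # regressors x features
    fold_id: int = -1

    def predict(self, D: np.ndarray) -> np.ndarray:
        """Neural predictions C_hat = W_dec D (D: features x epochs)."""
        return self.w_dec @ D


def fit_invert_encoder(D: np.ndarray, C: np.ndarray, max_cond: float = 1e10) -> EncodingModel:
    """OLS encoder and its pseudoinverse decoder.

    D : features x epochs, C : regressors x epochs.
    """
    D = np.atleast_2d(D)
    C = np.atleast_2d(C)
    m, n = C.shape
    if D.shape[1] != n:
        raise ValueError("D and C must have the same number of epochs")
    if n <= m:
        raise ValueError("need more epochs than regressors")
    G = C @ C.T
    cond = np.linalg.cond(G)
    if cond > max_cond:
        raise ValueError(f"design matrix C rank-deficient (cond={cond:.3g})")
    w_enc = D @ C.T @ np.linalg.inv(G)
    H = w_enc.T @ w_enc
    cond_h = np.linalg.cond(H)
    if cond_h > max_cond:
        raise ValueError(f"encoding weights rank-deficient (cond={cond_h:.3g})")
    w_dec = np.linalg.inv(H) @ w_enc.T
    return EncodingModel(w_enc=w_enc, w_dec=w_dec)


def trial_folds(trial_ids: np.ndarray, n_folds: int) -> np.ndarray:
    """Interleaved fold assignment at the trial level.

    All epochs sharing a trial_id land in the same fold; successive
    trials cycle through folds."""
    ids = np.asarray(trial_ids)
    uniq, first = np.unique(ids, return_index=True)
    order = uniq[np.argsort(first)]  # order of appearance
    fold_of = {tid: i % n_folds for i, tid in enumerate(order)}
    return np.array([fold_of[t] for t in ids])


def _zscore_train(x: np.ndarray, train_mask: np.ndarray, axis: int = 0):
    mu = x[train_mask].mean(axis=axis, keepdims=True)
    sd = x[train_mask].std(axis=axis, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return (x - mu) / sd


def decode_cv(
    features: np.ndarray,
    metadata: pd.DataFrame,
    regressor_names: list[str],
    n_folds: int = 10,
    train_filter: np.ndarray | None = None,
    test_filter: np.ndarray | None = None,
    standardize: bool = True,
) -> np.ndarray:
    """Cross-validated neural predictions (epochs x regressors x times).

    Per fold and time point the encoder is fitted on
    ``train_filter`` epochs outside the fold and inverted to predict
    ``test_filter`` epochs inside it, so test epochs are never used for
    training; ``train_filter != test_filter`` gives cross-condition
    generalisation.  Features and regressors are z-scored with
    train-fold statistics only.  Untested epochs hold NaN.
    """
    n_ep, n_feat, n_t = features.shape
    if train_filter is None:
        train_filter = np.ones(n_ep, dtype=bool)
    if test_filter is None:
        test_filter = np.ones(n_ep, dtype=bool)
    train_filter = np.asarray(train_filter, dtype=bool)
    test_filter = np.asarray(test_filter, dtype=bool)
    C_raw = metadata[regressor_names].to_numpy(float)  # epochs x m
    folds = trial_folds(metadata["trial_id"].to_numpy(), n_folds)
    preds = np.full((n_ep, len(regressor_names), n_t), np.nan)
    for f in range(n_folds):
        tr = train_filter & (folds != f)
        te = test_filter & (folds == f)
        if tr.sum() <= len(regressor_names):
            raise ValueError(f"fold {f}: empty or too-small training set after filtering")
        if not te.any():
            raise ValueError(f"fold {f}: empty test set after filtering")
        C = _zscore_train(C_raw, tr) if standardize else C_raw - C_raw[tr].mean(axis=0)
        for t in range(n_t):
            X = (_zscore_train(features[:, :, t], tr) if standardize
                 else features[:, :, t] - features[tr, :, t].mean(axis=0))
            model = fit_invert_encoder(X[tr].T, C[tr].T)
            preds[te, :, t] = model.predict(X[te].T).T
    return preds


@dataclass
class CodingTimecourse:
    times: np.ndarray
    precision: np.ndarray                  # Fisher z per time point (combined)
    se: np.ndarray
    per_regressor: np.ndarray              # regressors x times
    window_precision: dict = field(default_factory=dict)
    zero_variance_flag: bool = False


def _fisher_z(r: np.ndarray) -> np.ndarray:
    return np.clip(np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15)), -Z_CAP, Z_CAP)


def _corr_cols(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Column-wise Pearson r between pred (n x m) and truth (n x m)."""
    p = pred - pred.mean(axis=0)
    t = truth - truth.mean(axis=0)
    sp = np.sqrt((p ** 2).sum(axis=0))
    st = np.sqrt((t ** 2).sum(axis=0))
    denom = sp * st
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (p * t).sum(axis=0) / np.where(denom > 0, denom, 1.0), 0.0)
    return r


def coding_precision(
    predictions: np.ndarray,
    truth: np.ndarray,
    times: np.ndarray,
    windows: dict[str, tuple[float, float]] | None = None,
    combine: str = "mean",
) -> CodingTimecourse:
    """Fisher-z coding precision of decoded predictions.

    ``predictions`` is epochs x regressors x times (NaN rows ignored),
    ``truth`` epochs x regressors.  Multi-regressor precision (e.g. the
    cos/sin pair of an orientation code) is the mean Fisher z across
    regressors.  For named time windows, predictions are averaged over
    the window before correlating.
    """
    valid = ~np.isnan(predictions[:, 0, 0])
    pred = predictions[valid]
    tru = np.asarray(truth)[valid]
    n, m, n_t = pred.shape
    if n < 3:
        raise ValueError("need >= 3 prediction/truth pairs")
    per_reg = np.zeros((m, n_t))
    zero_var = False
    for t in range(n_t):
        r = _corr_cols(pred[:, :, t], tru)
        if np.any(pred[:, :, t].std(axis=0) == 0):
            zero_var = True
        per_reg[:, t] = _fisher_z(r)
    combined = per_reg.mean(axis=0)
    se = np.full(n_t, 1.0 / np.sqrt(max(n - 3, 1)))
    wins = {}
    if windows:
        for name, (t0, t1) in windows.items():
            sel = (times >= t0) & (times <= t1)
            if not sel.any():
                raise ValueError(f"window {name} outside the time axis")
            avg = pred[:, :, sel].mean(axis=2)
            wins[name] = float(_fisher_z(_corr_cols(avg, tru)).mean())
    return CodingTimecourse(times=np.asarray(times), precision=combined, se=se,
                            per_regressor=per_reg, window_precision=wins,
                            zero_variance_flag=zero_var)
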