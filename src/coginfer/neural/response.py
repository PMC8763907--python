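"""Response-preparation activity and brain-behaviour coupling.

Response activity projects band-power epochs on the spatial axis
separating left- from right-handed responses (difference of side-mean
topographies in a training window at response execution, estimated on
held-out folds), signed so that positive values predict the provided
response.  The brain-behaviour link asks whether single-stimulus
decoding residuals (decoded minus true evidence strength, signed
toward the stimulus' category) predict the upcoming choice beyond the
true evidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decoding import trial_folds
from .epochs import EpochSet
from .latency import onset_of_series

__all__ = ["ResponseActivitySeries", "response_activity", "brain_behavior_link"]


@dataclass
class ResponseActivitySeries:
    times: np.ndarray
    projection: np.ndarray       # grand-average signed projection per time
    per_epoch: np.ndarray        # epochs x times signed projections
    onset: float | None = None   # seconds (negative = before the lock event)
    onset_flagged: bool = False


def response_activity(
    power_epochs: EpochSet,
    train_window: tuple[float, float] = (-0.2, 0.0),
    n_folds: int = 10,
    estimate_onset: bool = True,
) -> ResponseActivitySeries:
    """Cross-validated signed response-activity projection.

    The spatial filter for each fold is the difference of the left- and
    right-response mean topographies, averaged over ``train_window``,
    computed on training trials only; held-out epochs are projected over
    the whole epoch and signed toward their provided response.
    """
    meta = power_epochs.metadata
    side = meta["response_side"].to_numpy()
    if len(np.unique(side)) < 2:
        raise ValueError("both response sides must be present")
    times = power_epochs.times
    win = (times >= train_window[0]) & (times <= train_window[1])
    if not win.any():
        raise ValueError("train window outside the epoch")
    folds = trial_folds(meta["trial_id"].to_numpy(), n_folds)
    n_ep = len(power_epochs)
    proj = np.zeros((n_ep, len(times)))
    for f in range(n_folds):
        tr = folds != f
        te = folds == f
        left = tr & (side == "left")
        right = tr & (side == "right")
        if not left.any() or not right.any():
            raise ValueError(f"fold {f}: a response side is missing from training data")
        topo = (power_epochs.data[left][:, :, win].mean(axis=(0, 2))
                - power_epochs.data[right][:, :, win].mean(axis=(0, 2)))
        norm = np.linalg.norm(topo)
        if norm > 0:
            topo = topo / norm
        proj[te] = np.einsum("c,ect->et", topo, power_epochs.data[te])
    signed = proj * np.where(side == "left", 1.0, -1.0)[:, None]
    series = signed.mean(axis=0)
    onset, flagged = (None, False)
    if estimate_onset:
        onset, flagged = onset_of_series(series, times, lock_time=0.0)
    return ResponseActivitySeries(times=times, projection=series, per_epoch=signed,
                                  onset=onset, onset_flagged=flagged)


def brain_behavior_link(
    decoded_evidence: np.ndarray,
    metadata: pd.DataFrame,
    choices_by_trial: dict | pd.Series,
) -> pd.DataFrame:
    """Logistic weight of signed decoding residuals on the upcoming choice.

    Per stimulus epoch the residual is decoded minus true evidence
    strength, signed toward the stimulus' category (sign of its true
    log-likelihood ratio).  Choice (+1/-1 per trial) is regressed on
    the trial-summed true signed evidence and the trial-summed signed
    residual; the residual weight beta quantifies how strongly
    over-represented evidence pulls the decision.
    """
    import statsmodels.api as sm

    df = pd.DataFrame({
        "trial_id": metadata["trial_id"].to_numpy(),
        "true_signed": metadata["evidence_signed"].to_numpy(float),
        "residual": (np.asarray(decoded_evidence, dtype=float)
                     - metadata["evidence"].to_numpy(float)),
    })
    df["residual_signed"] = df["residual"] * np.sign(df["true_signed"])
    agg = df.groupby("trial_id").agg(
        true_evidence=("true_signed", "sum"),
        signed_residual=("residual_signed", "sum"),
    )
    ch = pd.Series(choices_by_trial)
    agg["choice"] = ch.reindex(agg.index).to_numpy()
    agg = agg.dropna()
    X = sm.add_constant(agg[["true_evidence", "signed_residual"]].to_numpy())
    y = (agg["choice"].to_numpy() > 0).astype(float)
    cond = np.linalg.cond(X.T @ X)
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        beta, bse = res.params, res.bse
        if not np.all(np.isfinite(bse)):
            raise ValueError("separation")
    except Exception:  # separable design: weakly regularised fallback
        from sklearn.linear_model import LogisticRegression

        lr = LogisticRegression(C=10.0, solver="lbfgs", max_iter=500)
        lr.fit(X[:, 1:], y)
        beta = np.r_[lr.intercept_, lr.coef_.ravel()]
        bse = np.full(3, np.nan)
    out = pd.DataFrame(
        {"beta": beta, "se": bse},
        index=["intercept", "true_evidence", "signed_residual"],
    )
    out.attrs["collinearity_flag"] = bool(cond > 1e8)
    out.attrs["condition_number"] = float(cond)
    return out
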