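"""Inverted encoding model: features, encoder algebra, cross-validation."""

import numpy as np
import pandas as pd
import pytest

from coginfer.neural import (EpochSet, coding_precision, decode_cv,
                             fit_invert_encoder, prepare_features)
from coginfer.neural.decoding import trial_folds
from coginfer.observer import ObserverParams, simulate_observer
from coginfer.synth_eeg import SynthSpec, generate_stimulus_epochs
from coginfer.task import sample_trials


def _epochs(n_channels=8, n_epochs=20, n_times=64, sfreq=128.0, seed=0):
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((n_epochs, n_channels, n_times))
    times = np.arange(n_times) / sfreq - 0.2
    ch = pd.DataFrame({"label": [f"c{i}" for i in range(n_channels)],
                       "caudal": np.linspace(0, 1, n_channels)})
    meta = pd.DataFrame({"trial_id": np.arange(n_epochs)})
    return EpochSet(data, times, ch, meta)


SPEC = SynthSpec(n_channels=16, sample_rate=128.0)


@pytest.fixture(scope="module")
def planted_epochs(task_config):
    rng = np.random.default_rng(1)
    trials = sample_trials(task_config, 120, rng)
    choices, trace = simulate_observer(trials, ObserverParams(sigma_inf=0.474), rng)
    return generate_stimulus_epochs(SPEC, trials, choices, trace, rng)


class TestPrepareFeatures:
    def test_doubles_channel_count(self):
        ep = _epochs(n_channels=64)
        assert prepare_features(ep, 16.0).shape[1] == 128

    def test_constant_signal_has_zero_imaginary_part(self):
        ep = _epochs(n_channels=2)
        ep.data[:] = 3.0
        feats = prepare_features(ep, 8.0)
        assert np.allclose(feats[:, :2, :], 3.0, atol=1e-8)
        assert np.allclose(feats[:, 2:, :], 0.0, atol=1e-6)

    def test_analytic_magnitude_of_sine_is_constant(self):
        ep = _epochs(n_channels=1, n_times=256)
        t = np.arange(256) / 128.0
        ep.data[:] = np.sin(2 * np.pi * 5.0 * t)[None, None, :]
        feats = prepare_features(EpochSet(ep.data, np.arange(256) / 128.0 - 0.2,
                                          ep.channels.iloc[:1], ep.metadata), 8.0)
        mag = np.hypot(feats[0, 0], feats[0, 1])[60:-60]
        assert np.allclose(mag, 1.0, atol=0.05)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            prepare_features(_epochs(), 70.0)

    def test_short_epoch_rejected(self):
        with pytest.raises(ValueError):
            prepare_features(_epochs(n_times=16), 8.0)


class TestEncoderAlgebra:
    def test_decoder_inverts_encoder(self):
        rng = np.random.default_rng(2)
        D = rng.standard_normal((32, 100))
        C = rng.standard_normal((2, 100))
        model = fit_invert_encoder(D, C)
        assert np.allclose(model.w_dec @ model.w_enc, np.eye(2), atol=1e-10)

    def test_recovers_generative_weights(self):
        rng = np.random.default_rng(3)
        W = rng.standard_normal((32, 2))
        C = rng.standard_normal((2, 400))
        D = W @ C + 0.01 * rng.standard_normal((32, 400))
        model = fit_invert_encoder(D, C)
        assert np.allclose(model.w_enc, W, atol=0.01)
        C_hat = model.predict(D)
        r = np.corrcoef(C_hat[0], C[0])[0, 1]
        assert r > 0.99

    def test_single_regressor_reduces_to_univariate_ols(self):
        rng = np.random.default_rng(4)
        D = rng.standard_normal((16, 200))
        C = rng.standard_normal((1, 200))
        model = fit_invert_encoder(D, C)
        slopes = np.array([np.polyfit(C[0], D[i], 1)[0] for i in range(16)])
        # OLS through the origin vs polyfit with intercept: agree closely
        ols = (D @ C[0]) / (C[0] @ C[0])
        assert np.allclose(model.w_enc[:, 0], ols, atol=1e-12)
        assert np.allclose(model.w_enc[:, 0], slopes, atol=0.05)

    def test_rank_deficient_design_rejected(self):
        rng = np.random.default_rng(5)
        D = rng.standard_normal((8, 50))
        C = np.vstack([np.ones(50), np.ones(50)])
        with pytest.raises(ValueError, match="cond"):
            fit_invert_encoder(D, C)

    def test_too_few_epochs_rejected(self):
        with pytest.raises(ValueError):
            fit_invert_encoder(np.zeros((4, 2)), np.zeros((2, 2)))


class TestDecodeCV:
    def test_trial_level_interleaved_folds(self):
        ids = np.repeat([10, 11, 12, 13, 14], 3)
        folds = trial_folds(ids, 2)
        # all epochs of one trial share a fold; successive trials alternate
        assert np.array_equal(folds, np.repeat([0, 1, 0, 1, 0], 3))

    def test_planted_code_peaks_at_planted_latency(self, planted_epochs):
        feats = prepare_features(planted_epochs, 16.0)
        preds = decode_cv(feats, planted_epochs.metadata, ["cos2t", "sin2t"])
        tc = coding_precision(preds, planted_epochs.metadata[["cos2t", "sin2t"]].to_numpy(float),
                              planted_epochs.times)
        peak = planted_epochs.times[np.argmax(tc.precision)]
        assert peak == pytest.approx(SPEC.code_latency_orientation, abs=0.04)
        assert tc.precision.max() > 0.2

    def test_shuffled_test_metadata_destroys_precision(self, planted_epochs):
        """Leakage control: predictions cannot correlate with shuffled truth."""
        feats = prepare_features(planted_epochs, 16.0)
        preds = decode_cv(feats, planted_epochs.metadata, ["cos2t", "sin2t"])
        truth = planted_epochs.metadata[["cos2t", "sin2t"]].to_numpy(float).copy()
        rng = np.random.default_rng(6)
        truth = truth[rng.permutation(len(truth))]
        tc = coding_precision(preds, truth, planted_epochs.times)
        assert np.abs(tc.precision).max() < 0.12

    def test_invariant_to_orthogonal_feature_mixing(self, planted_epochs):
        """The encoder/pseudoinverse-decoder chain is unchanged by a
        common orthogonal mixing of the features (a sensor rotation);
        the inversion step is not invariant to arbitrary invertible
        mixings, which re-weight the feature metric."""
        feats = prepare_features(planted_epochs, 16.0)
        sel = planted_epochs.times < 0.3  # restrict times for speed
        feats = feats[:, :, sel]
        rng = np.random.default_rng(7)
        M, _ = np.linalg.qr(rng.standard_normal((feats.shape[1], feats.shape[1])))
        mixed = np.einsum("fg,egt->eft", M, feats)
        truth = planted_epochs.metadata[["cos2t", "sin2t"]].to_numpy(float)
        p1 = decode_cv(feats, planted_epochs.metadata, ["cos2t", "sin2t"],
                       standardize=False)
        p2 = decode_cv(mixed, planted_epochs.metadata, ["cos2t", "sin2t"],
                       standardize=False)
        z1 = coding_precision(p1, truth, planted_epochs.times[sel]).precision
        z2 = coding_precision(p2, truth, planted_epochs.times[sel]).precision
        assert np.allclose(z1, z2, atol=1e-8)

    def test_empty_fold_after_filtering_rejected(self, planted_epochs):
        feats = prepare_features(planted_epochs, 16.0)
        with pytest.raises(ValueError, match="fold"):
            decode_cv(feats[:, :, :4], planted_epochs.metadata, ["cos2t"],
                      test_filter=np.zeros(len(planted_epochs), dtype=bool))

    def test_rostro_caudal_profile_of_planted_codes(self, planted_epochs):
        """Orientation encoder weights peak caudally, evidence weights
        rostrally of the orientation peak."""
        caudal = planted_epochs.channels["caudal"].to_numpy()
        win_o = (planted_epochs.times >= 0.05) & (planted_epochs.times <= 0.15)
        win_e = (planted_epochs.times >= 0.25) & (planted_epochs.times <= 0.45)
        d_o = planted_epochs.data[:, :, win_o].mean(axis=2)
        d_e = planted_epochs.data[:, :, win_e].mean(axis=2)
        meta = planted_epochs.metadata
        c_o = meta[["cos2t", "sin2t"]].to_numpy(float)
        c_e = meta[["evidence_internal"]].to_numpy(float)
        w_o = fit_invert_encoder(d_o.T, c_o.T).w_enc
        w_e = fit_invert_encoder(d_e.T, c_e.T).w_enc
        peak_o = caudal[np.argmax(np.abs(w_o).sum(axis=1))]
        peak_e = caudal[np.argmax(np.abs(w_e[:, 0]))]
        assert peak_o > 0.75
        assert peak_e < peak_o


class TestCodingPrecision:
    def test_fisher_transform_identities(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(500)
        noise = rng.standard_normal(500)
        # construct predictions with known correlation 0.5
        y = 0.5 * x + np.sqrt(1 - 0.25) * noise
        y = (y - y.mean())
        preds = y[:, None, None]
        tc = coding_precision(preds, x[:, None], np.array([0.0]))
        r = np.corrcoef(x, y)[0, 1]
        assert tc.precision[0] == pytest.approx(np.arctanh(r), abs=1e-12)

    def test_zero_variance_predictions_flagged(self):
        preds = np.zeros((10, 1, 2))
        truth = np.arange(10.0)[:, None]
        tc = coding_precision(preds, truth, np.array([0.0, 0.1]))
        assert tc.zero_variance_flag
        assert np.allclose(tc.precision, 0.0)

    def test_window_average_beats_single_timepoint_for_sustained_code(self):
        rng = np.random.default_rng(9)
        truth = rng.standard_normal(300)
        # sustained noisy code across 8 time points
        preds = truth[:, None, None] + 1.5 * rng.standard_normal((300, 1, 8))
        times = np.linspace(0, 0.7, 8)
        tc = coding_precision(preds, truth[:, None], times, windows={"win": (0.0, 0.7)})
        assert tc.window_precision["win"] > tc.precision.max()

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            coding_precision(np.zeros((2, 1, 1)), np.zeros((2, 1)), np.array([0.0]))
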