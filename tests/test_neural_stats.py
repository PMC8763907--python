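"""Cluster permutation statistics, jackknife latencies, response activity."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coginfer.neural import (cluster_permutation, jackknife_adjusted_t,
                             jackknife_latency, response_activity,
                             brain_behavior_link)
from coginfer.neural.epochs import EpochSet
from coginfer.synth_eeg import SynthSpec, generate_response_power


class TestClusterPermutation:
    def test_tiny_case_matches_exhaustive_enumeration(self):
        """Brute-force oracle over all 2^3 sign patterns."""
        rng = np.random.default_rng(0)
        x = rng.standard_normal((3, 5)) + 1.5
        res = cluster_permutation(x, n_perm=1000, seed=1)
        assert res.exhaustive
        thresh = stats.t.ppf(0.975, 2)

        def max_mass(data):
            t = data.mean(axis=0) / (data.std(axis=0, ddof=1) / np.sqrt(3))
            best = 0.0
            for sign in (1, -1):
                run = 0.0
                for v in t:
                    if sign * v > thresh:
                        run += sign * v
                        best = max(best, run)
                    else:
                        run = 0.0
            return best

        null = [max_mass(np.array(s)[:, None] * x)
                for s in itertools.product([1, -1], repeat=3)]
        for c in res.clusters:
            oracle_p = np.mean(np.array(null) >= abs(c.mass))
            assert c.p == pytest.approx(oracle_p, abs=1e-12)

    def test_single_planted_effect_yields_one_significant_cluster(self):
        rng = np.random.default_rng(2)
        x = 0.3 * rng.standard_normal((16, 60))
        x[:, 20:30] += 1.0
        res = cluster_permutation(x, n_perm=1000, seed=3)
        sig = res.significant
        assert len(sig) == 1
        assert sig[0].start >= 18 and sig[0].stop <= 32

    def test_too_few_permutations_refused(self):
        with pytest.raises(ValueError):
            cluster_permutation(np.zeros((4, 5)), n_perm=50)

    def test_paired_difference_design(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal((12, 30))
        b = a + 0.0  # no difference
        res = cluster_permutation(a, b, n_perm=500, seed=5)
        assert len(res.significant) == 0

    def test_type_one_error_controlled(self):
        """Family-wise false-positive rate near the nominal level on
        null data (reduced simulation count; the full calibration runs
        in the acceptance suite)."""
        rng = np.random.default_rng(6)
        fp = sum(bool(cluster_permutation(rng.standard_normal((10, 30)),
                                          n_perm=256, seed=i).significant)
                 for i in range(150))
        assert fp / 150 == pytest.approx(0.05, abs=0.05)


class TestJackknife:
    def test_identical_subjects_have_zero_se(self):
        t = np.linspace(-1, 1, 50)
        series = np.tile(np.exp(-((t - 0.2) ** 2) / 0.01), (5, 1))
        jl = jackknife_latency(series, t, mode="peak")
        assert jl.se == 0.0
        assert jl.estimate == pytest.approx(0.2, abs=0.03)

    def test_onset_recovery_on_planted_trajectory(self):
        """The derivative of a V-shaped trajectory crosses zero exactly
        at the minimum; the estimator should recover it."""
        t = np.linspace(-2.5, 0.5, 100)
        sig = np.abs(t + 1.5) / 1.5
        rng = np.random.default_rng(7)
        subs = sig[None, :] + 0.05 * rng.standard_normal((18, 100))
        jl = jackknife_latency(subs, t, mode="onset", lock_time=0.0)
        assert jl.estimate == pytest.approx(-1.5, abs=0.1)

    def test_no_crossing_flags_window_start(self):
        t = np.linspace(-2.0, 0.5, 80)
        series = np.tile(np.exp(t), (4, 1))  # monotone rise, no crossing
        jl = jackknife_latency(series, t, mode="onset", lock_time=0.0)
        assert jl.flagged
        assert jl.estimate == t[0]

    def test_adjusted_t_equals_hand_computation(self):
        loo = np.array([0.11, 0.13, 0.12])
        n = 3
        t_naive = loo.mean() / (loo.std(ddof=1) / np.sqrt(n))
        assert jackknife_adjusted_t(loo) == pytest.approx(t_naive / (n - 1))

    def test_fewer_than_three_subjects_rejected(self):
        with pytest.raises(ValueError):
            jackknife_latency(np.zeros((2, 10)), np.arange(10.0), mode="peak")


SPEC = SynthSpec(n_channels=16, sample_rate=64.0)


def _power_epochs(amplitude=1.0, n=80, seed=8, condition="drug-like", outcome="validated"):
    spec = SynthSpec(n_channels=16, sample_rate=64.0,
                     response_lateralization={
                         ("drug-like", "validated"): (amplitude, -1.8),
                         ("drug-like", "opt-out"): (amplitude, -0.3),
                         ("placebo-like", "validated"): (amplitude, -0.3),
                         ("placebo-like", "opt-out"): (amplitude, -0.3)})
    rng = np.random.default_rng(seed)
    sides = np.where(rng.random(n) < 0.5, "left", "right")
    return spec, generate_response_power(
        spec, sides, np.full(n, condition, dtype=object),
        np.full(n, outcome, dtype=object), rng)


class TestResponseActivity:
    def test_planted_lateralization_is_positive_before_lock(self):
        _, ep = _power_epochs(amplitude=1.0)
        ra = response_activity(ep, n_folds=4)
        pre = (ep.times > -1.2) & (ep.times < -0.2)
        assert ra.projection[pre].mean() > 0.1

    def test_zero_amplitude_control_is_flat(self):
        _, ep = _power_epochs(amplitude=0.0)
        ra = response_activity(ep, n_folds=4, estimate_onset=False)
        assert np.abs(ra.projection).max() < 0.2

    def test_flipping_labels_preserves_signed_series(self):
        _, ep = _power_epochs(amplitude=1.0)
        ra = response_activity(ep, n_folds=4, estimate_onset=False)
        flipped_meta = ep.metadata.copy()
        flipped_meta["response_side"] = np.where(
            ep.metadata["response_side"] == "left", "right", "left")
        ep_fl = EpochSet(ep.data, ep.times, ep.channels, flipped_meta)
        ra_fl = response_activity(ep_fl, n_folds=4, estimate_onset=False)
        # relabelling flips the filter and the signing; their product is stable
        assert np.allclose(ra.projection, ra_fl.projection, atol=1e-10)

    def test_single_side_rejected(self):
        _, ep = _power_epochs()
        meta = ep.metadata.copy()
        meta["response_side"] = "left"
        with pytest.raises(ValueError):
            response_activity(EpochSet(ep.data, ep.times, ep.channels, meta))

    def test_early_onset_condition_rises_earlier(self):
        _, ep_drug = _power_epochs(condition="drug-like", outcome="validated", seed=9)
        _, ep_plac = _power_epochs(condition="placebo-like", outcome="validated", seed=9)
        ra_d = response_activity(ep_drug, n_folds=4, estimate_onset=False)
        ra_p = response_activity(ep_plac, n_folds=4, estimate_onset=False)
        early = (ep_drug.times > -1.5) & (ep_drug.times < -0.6)
        assert ra_d.projection[early].mean() > ra_p.projection[early].mean() + 0.1


class TestBrainBehaviorLink:
    def _meta(self, n_trials=400, stims=4, seed=10):
        rng = np.random.default_rng(seed)
        ev = np.abs(rng.normal(0, 0.8, size=n_trials * stims))
        sign = rng.choice([-1.0, 1.0], size=n_trials * stims)
        return pd.DataFrame({
            "trial_id": np.repeat(np.arange(n_trials), stims),
            "evidence": ev,
            "evidence_signed": ev * sign,
        }), rng

    def test_closed_loop_residuals_predict_choice(self):
        meta, rng = self._meta()
        shared = rng.normal(0, 0.4, size=len(meta))   # representational noise
        extra = rng.normal(0, 0.4, size=len(meta))    # decoder observation noise
        decoded = meta["evidence"].to_numpy() + shared + extra
        # the shared noise also drives the simulated choice
        internal = meta["evidence_signed"] + shared * np.sign(meta["evidence_signed"])
        tot = pd.Series(internal.to_numpy()).groupby(meta["trial_id"]).sum()
        choices = np.sign(tot + 0.5 * rng.standard_normal(len(tot)) + 1e-9)
        out = brain_behavior_link(decoded, meta, choices)
        beta = out.loc["signed_residual", "beta"]
        assert beta > 2 * out.loc["signed_residual", "se"]

    def test_independent_decoder_noise_gives_null_weight(self):
        meta, rng = self._meta(seed=11)
        decoded = meta["evidence"].to_numpy() + rng.normal(0, 0.4, size=len(meta))
        tot = meta.groupby("trial_id")["evidence_signed"].sum()
        choices = np.sign(tot + 0.5 * rng.standard_normal(len(tot)))
        out = brain_behavior_link(decoded, meta, choices)
        beta = out.loc["signed_residual", "beta"]
        assert abs(beta) < 3 * out.loc["signed_residual", "se"]
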