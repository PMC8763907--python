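"""Premature-commitment simulator and its behavioural signatures."""

import numpy as np
import pytest

from coginfer.commitment import (CommitmentConfig, apparent_inference_noise,
                                 commitment_optout, model_coding_precision,
                                 simulate_commitment)
from coginfer.observer import ObserverParams, simulate_observer
from coginfer.task import TaskConfig, sample_trials

PARS = ObserverParams(sigma_inf=0.474)


class TestSimulateCommitment:
    def test_zero_hazard_reproduces_plain_observer(self, task_config):
        trials = sample_trials(task_config, 1500, np.random.default_rng(0))
        ch_plain, _ = simulate_observer(trials, PARS, np.random.default_rng(1))
        ch_commit, ctrace, _ = simulate_commitment(
            trials, PARS, CommitmentConfig(hazard=0.0), np.random.default_rng(1))
        assert np.array_equal(ch_plain, ch_commit)
        assert not ctrace.committed.any()

    def test_full_hazard_commits_at_first_opportunity(self, task_config):
        trials = sample_trials(task_config, 400, np.random.default_rng(2))
        ch, ctrace, otrace = simulate_commitment(
            trials, PARS, CommitmentConfig(hazard=1.0, n0=4), np.random.default_rng(3))
        assert ctrace.committed.all()
        assert np.all(ctrace.commit_position == 4)
        # response always equals the committed category
        assert np.array_equal(ch, ctrace.committed_category)
        # committed category is the sign of the belief after stimulus 4
        l4 = otrace.accumulated[:, 3]
        nz = l4 != 0
        assert np.array_equal(np.sign(l4[nz]).astype(int), ctrace.committed_category[nz])

    def test_committed_fraction_matches_geometric_hazard(self, task_config):
        """1 - (1-p)^m opportunities per length; lengths uniform over
        {4, 8, 12} with n0 = 4 give m = 1, 5, 9."""
        trials = sample_trials(task_config, 30_000, np.random.default_rng(4))
        _, ctrace, _ = simulate_commitment(
            trials, PARS, CommitmentConfig(hazard=0.05), np.random.default_rng(5))
        expect = np.mean([1 - 0.95 ** m for m in (1, 5, 9)])
        assert ctrace.committed.mean() == pytest.approx(expect, abs=0.01)

    def test_discarded_are_conflicting_only(self, task_config):
        trials = sample_trials(task_config, 800, np.random.default_rng(6))
        _, ctrace, otrace = simulate_commitment(
            trials, PARS, CommitmentConfig(hazard=0.3), np.random.default_rng(7))
        discarded = trials.mask & ~ctrace.integrated_mask
        rows, cols = np.nonzero(discarded)
        assert len(rows) > 0
        # every discarded stimulus is post-commitment and internally conflicting
        assert np.all(cols + 1 > ctrace.commit_position[rows])
        signs = np.sign(otrace.noisy_llr[rows, cols])
        assert np.all(signs != ctrace.committed_category[rows])

    def test_commitment_inflates_accumulated_evidence(self, task_config):
        """Filtering conflicting evidence raises mean |L_n| on committed
        trials relative to matched uncommitted trials."""
        trials = sample_trials(task_config, 20_000, np.random.default_rng(8))
        _, ctrace, otrace = simulate_commitment(
            trials, PARS, CommitmentConfig(hazard=0.1), np.random.default_rng(9))
        final = np.abs(otrace.accumulated[np.arange(len(trials)), trials.n_stimuli - 1])
        long = trials.n_stimuli == 12  # match on length; commitment needs time to act
        assert final[long & ctrace.committed].mean() > final[long & ~ctrace.committed].mean()

    def test_config_validation(self):
        with pytest.raises(ValueError):
            CommitmentConfig(hazard=1.5)
        with pytest.raises(ValueError):
            CommitmentConfig(n0=0)


class TestApparentInferenceNoise:
    def test_recovers_generative_noise_then_rises_with_hazard(self, task_config):
        df = apparent_inference_noise(PARS, [0.0, 0.05, 0.10, 0.15], (8, 360),
                                      np.random.default_rng(10), task_config,
                                      n_starts=2)
        sig = df["sigma_hat_mean"].to_numpy()
        assert sig[0] == pytest.approx(0.474, abs=0.05)
        assert np.all(np.diff(sig) >= -0.01)  # non-decreasing up to fit noise
        assert sig[1] - sig[0] < 0.2          # the hazard-0.05 rise is moderate


class TestModelCodingPrecision:
    def _run(self, hazard, obs_noise=3.0, n_trials=12_000, pars=PARS, seed=11):
        cfg = TaskConfig()
        trials = sample_trials(cfg, n_trials, np.random.default_rng(seed))
        cc = CommitmentConfig(hazard=hazard, obs_noise=obs_noise)
        ch, ctrace, otrace = simulate_commitment(trials, pars, cc,
                                                 np.random.default_rng(seed + 1))
        return trials, ch, ctrace, otrace, cc

    def test_balanced_without_commitment(self, task_config):
        trials, ch, ctrace, otrace, cc = self._run(0.0)
        prec = model_coding_precision(trials, otrace, ctrace, cc,
                                      np.random.default_rng(12), n_boot=40)
        wide = prec.pivot(index="position", columns="consistent", values="fisher_z")
        se = prec.pivot(index="position", columns="consistent", values="se")
        gap = (wide[True] - wide[False]).abs()
        tol = 3 * np.sqrt(se[True] ** 2 + se[False] ** 2)
        assert (gap < tol).mean() > 0.8

    def test_conflicting_precision_falls_with_position_under_hazard(self, task_config):
        trials, ch, ctrace, otrace, cc = self._run(0.15)
        prec = model_coding_precision(trials, otrace, ctrace, cc,
                                      np.random.default_rng(13), n_boot=20)
        wide = prec.pivot(index="position", columns="consistent", values="fisher_z")
        late, early = [8, 9, 10, 11, 12], [1, 2, 3, 4]
        drop_conflict = wide[False][early].mean() - wide[False][late].mean()
        drop_consist = wide[True][early].mean() - wide[True][late].mean()
        assert drop_conflict > 0.02
        assert drop_conflict > 2 * abs(drop_consist)

    def test_noiseless_representation_correlates_perfectly(self, task_config):
        trials, ch, ctrace, otrace, cc = self._run(
            0.0, obs_noise=0.0, n_trials=400, pars=ObserverParams(), seed=14)
        prec = model_coding_precision(trials, otrace, ctrace,
                                      CommitmentConfig(hazard=0.0, obs_noise=0.0),
                                      np.random.default_rng(15), n_boot=5)
        from coginfer.commitment import Z_CAP

        assert np.allclose(prec["fisher_z"].dropna(), Z_CAP)


class TestExtrapolationAndAdditivity:
    def test_long_sequences_show_overconfidence_transition(self):
        """Extrapolating to long sequences: committed trials accumulate
        ever more (filtered) evidence while their objective accuracy
        stalls — the belief outgrows the performance it reflects."""
        pars = ObserverParams(sigma_inf=0.474)
        stats = {}
        for n_len in (8, 24):
            cfg = TaskConfig(sequence_lengths=(n_len,))
            trials = sample_trials(cfg, 15_000, np.random.default_rng(30))
            _, ctrace, otrace = simulate_commitment(
                trials, pars, CommitmentConfig(hazard=0.3), np.random.default_rng(31))
            com = ctrace.committed
            final = np.abs(otrace.accumulated[np.arange(len(trials)), trials.n_stimuli - 1])
            acc = np.mean(ctrace.committed_category[com] == trials.category[com])
            stats[n_len] = (final[com].mean(), acc)
        belief_8, acc_8 = stats[8]
        belief_24, acc_24 = stats[24]
        assert belief_24 > 1.5 * belief_8       # confidence keeps growing
        assert acc_24 < acc_8 + 0.02            # accuracy does not follow

    def test_commitment_and_outcome_effects_on_imbalance_are_additive(self):
        """Coding imbalance (consistent minus conflicting precision, late
        positions) responds to the hazard but shows no hazard-by-outcome
        interaction when trials are split by simulated opt-out."""
        from scipy.special import expit, logit

        pars = ObserverParams(sigma_inf=0.474)
        rng_all = np.random.default_rng(32)
        imb = {}
        for hazard in (0.0, 0.12):
            cfg = TaskConfig()
            trials = sample_trials(cfg, 25_000, np.random.default_rng(33))
            cc = CommitmentConfig(hazard=hazard)
            _, ctrace, otrace = simulate_commitment(trials, pars, cc,
                                                    np.random.default_rng(34))
            final = np.abs(otrace.accumulated[np.arange(len(trials)), trials.n_stimuli - 1])
            p_cor = np.clip(expit(final - 1.0), 0.5 + 1e-6, 1 - 1e-6)
            p_opt = expit(-(0.2 + 1.2 * logit(p_cor) - 1.0 * logit(trials.lottery_prob)))
            opted = rng_all.random(len(trials)) < p_opt
            for outcome, sel in (("validated", ~opted), ("opt-out", opted)):
                prec = model_coding_precision(trials.subset(sel),
                                              _subset_trace(otrace, sel),
                                              _subset_ctrace(ctrace, sel), cc,
                                              np.random.default_rng(35), n_boot=0)
                wide = prec.pivot(index="position", columns="consistent",
                                  values="fisher_z")
                late = wide.loc[7:]
                imb[(hazard, outcome)] = (late[True] - late[False]).mean()
        hazard_effect = np.mean([imb[(0.12, o)] - imb[(0.0, o)]
                                 for o in ("validated", "opt-out")])
        interaction = ((imb[(0.12, "validated")] - imb[(0.12, "opt-out")])
                       - (imb[(0.0, "validated")] - imb[(0.0, "opt-out")]))
        assert hazard_effect > 0.02
        assert abs(interaction) < 0.5 * hazard_effect


def _subset_trace(otrace, sel):
    from coginfer.observer import ObserverTrace

    return ObserverTrace(otrace.noisy_percepts[sel], otrace.noisy_llr[sel],
                         otrace.accumulated[sel], otrace.choice[sel])


def _subset_ctrace(ctrace, sel):
    from coginfer.commitment import CommitmentTrace

    return CommitmentTrace(ctrace.committed[sel], ctrace.commit_position[sel],
                           ctrace.committed_category[sel], ctrace.integrated_mask[sel])


class TestCommitmentOptOut:
    def test_surface_monotone_and_committed_reduction(self, task_config):
        surf = commitment_optout(PARS, [0.0, 0.05, 0.10, 0.15],
                                 [-0.5, 0.0, 0.5, 1.0], 6000, seed=16)
        pivot = surf.pivot(index="hazard", columns="criterion", values="optout_rate")
        assert np.all(np.diff(pivot.to_numpy(), axis=0) <= 1e-12)
        base = pivot.loc[0.0]
        committed = surf.query("hazard == 0.05").set_index("criterion")["optout_rate_committed"]
        assert np.all(committed.to_numpy() < base.to_numpy() - 0.05)

    def test_zero_hazard_reduces_to_base_rates(self, task_config):
        surf = commitment_optout(PARS, [0.0], [0.0], 4000, seed=17)
        row = surf.iloc[0]
        assert row["frac_committed"] == 0.0
        assert np.isnan(row["optout_rate_committed"])
        assert row["optout_rate"] == row["optout_rate_uncommitted"]
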