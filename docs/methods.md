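# Methods

This note documents the models implemented in `coginfer`, the choices
made where the design was genuinely open, and what the synthetic-data
generators do and do not emulate.

## Task and evidence

Stimulus orientations are axial (identified with their value mod π);
all trigonometry runs on the doubled angle. The two categories are von
Mises distributions on the doubled-angle circle with concentration κ
and orthogonal means placed at θ\* ± π/4, where θ\* is the
categorisation axis resampled uniformly per trial. With that geometry
the log-likelihood ratio of a stimulus is exactly
l = 2κ sin(2(θ − θ\*)); the sign convention is that positive values
favour category A (mean at θ\* + π/4). Sequence length is uniform over
{4, 8, 12} and the lottery probability uniform over
{0.6, 0.7, 0.8, 0.9}, independent of everything else. The generative
κ defaults to 0.5, the value the online titration targets. All
stochastic operations take an explicit seeded `numpy` Generator; there
is no hidden global state.

## The noisy observer and its likelihood

The observer corrupts the ideal computation with up to three Gaussian
noise sources (sensory, on orientations; inference, on per-stimulus
evidence; selection, on the final belief) and accumulates with optional
leak, L̂_k = (1−λ)L̂_{k−1} + l̂_k. The selection stage may
equivalently be expressed as a softmax policy; a logistic with
β = 1.702/σ_sel matches the Gaussian-noise choice curve to within 0.01
everywhere, so the Gaussian form is fitted and β is a display-only
reparameterisation.

The likelihood of a choice is computed analytically. Sensory noise is
propagated through the sinusoidal evidence map with closed-form
moments, E[sin 2(Δ+ε)] = e^(−2σ²) sin 2Δ and
E[cos 4(Δ+ε)] = e^(−8σ²) cos 4Δ, giving each noisy evidence sample a
known mean and variance; the accumulated belief is then treated as
Gaussian (exact when σ_sen = 0, and verified against Monte-Carlo
simulation to within 3 standard errors at 10⁵ draws across the
parameter grid used in the tests). With no leak the per-trial belief
moments reduce to sufficient statistics precomputed once per dataset,
which makes a likelihood evaluation O(n_trials) and keeps cohort-scale
model selection fast. All choice probabilities are clamped to
[10⁻⁶, 1−10⁻⁶] so the deterministic members of the factorized model
set keep finite log-likelihoods. Exact ties of the belief at zero are
broken by a fair coin from the trial's stream.

Fitting maximises the summed log choice probability with bounded
L-BFGS-B from six starts (one fixed heuristic point plus a seeded
Latin hypercube); bounds are σ_sen ∈ [0,1] rad, σ_inf, σ_sel ∈ [0,5],
λ ∈ [0,1]. Across recovery experiments the 1–4-parameter likelihoods
proved unimodal (two starts find the same optimum to 10⁻⁸), so
cohort-scale routines default to two starts. Standard errors come from
the numerical Hessian at interior optima and are NaN at active bounds.
Model evidence is approximated by −BIC/2 throughout; no fuller
marginal-likelihood integration is attempted.

## Model selection

Random-effects selection uses the standard variational Dirichlet
update (prior α₀ = 1 per model, convergence 10⁻⁸); exceedance
probabilities come from 10⁶ seeded Dirichlet draws and are reported
with their Monte-Carlo standard error. Family probabilities over the
2³ factorized set sum model frequencies over the four members
containing a source; family exceedance is the posterior probability
that this frequency exceeds one half. The no-noise member of the set
is retained. Condition differences are fitted jointly with all three
sources active and shared across conditions except the single varying
source.

**Identifiability caveat.** At accuracy-matched magnitudes, sensory
noise on the sinusoidal evidence map induces choice probabilities
almost identical to inference noise (per-trial differences ~0.01, a
per-subject log-Bayes-factor of only ~0.5 at 360 trials, for any
σ_sen in [0.2, 0.7]). Only selection noise — whose effect does not
grow with sequence length — is sharply separated. Consequently
family-wise exceedance for a sensory or inference generator, and the
condition-difference winner for a pure inference-noise increase,
fluctuate across simulated cohorts rather than being reliably
decisive; single cohorts can still produce decisive exceedances. The
acceptance suite measures and reports these rates; the generating
magnitudes (σ_sen = 0.4 rad, σ_inf = 0.5, σ_sel = 2.0) were fixed in
advance to produce roughly the titrated 75% accuracy, mirroring how
participant-fitted values would be accuracy-matched by construction.

## Opt-out model

Expected accuracy conditions the belief L ~ N(μ, s²) (with the same
noise propagation as the choice likelihood, selection noise included)
on the chosen side via the closed-form truncated-normal mean m, maps
it through p̂ = logistic(|m| + δ), and clamps to [0.5+10⁻⁶, 1−10⁻⁶].
The additive log-odds shift δ is solved by bisection (tolerance 10⁻¹⁰)
so the mean expected accuracy equals the mean lottery probability; the
calibrated value is used in the regressor. The opt-out logistic is fit
by maximum likelihood (ridge fallback, flagged, under separation).

## Titration

Predicted accuracy of the inference-only observer is computed
deterministically: conditional on the correct category each stimulus
contributes l = 2κ cos(d) with d ~ von Mises(0, κ); the single-stimulus
law is discretised by quadrature and the n-fold sum obtained by raising
its characteristic function to the n-th power (FFT), then averaged over
Φ(L/(σ√n)). This replaces Monte-Carlo roll-outs, is validated against
brute-force simulation in the tests, and makes the κ bisection
(brentq on [0.01, 4]) exact and fast. The closed loop simulates 36
trials per step, refits σ by one-parameter MLE on all accumulated
trials (initialised at 0.5), and re-solves κ; only inference noise is
estimated online.

## Premature commitments

Commitment opportunities follow each stimulus from position n₀ = 4
(including the last) with flat hazard p; the committed category is the
sign of the current belief, and subsequent stimuli whose *internal*
noisy sign conflicts with it contribute nothing (their representation
is zeroed; belief still leaks if λ > 0). Consistency cells for coding
precision are defined by the *objective* evidence sign versus the
final choice, matching the neural analyses; the internal/objective
distinction for the discarding rule is switchable. Model coding
precision correlates |l̂| (plus additive observation noise, default
s.d. 3.0, chosen so baseline Fisher-z sits near the 0.1 scale of the
neural decoding) with the unsigned objective |l| per cell, with
trial-bootstrap standard errors. The opt-out surface uses the
magnitude of the post-commitment belief inside the calibrated logistic
and expected (not sampled) opt-out rates, with common random numbers
across hazard levels so the monotone compensation effect is exact
rather than statistical.

## Neural decoding and statistics

Features are the real and imaginary parts of the analytic signal of
low-pass-filtered epochs (4th-order zero-phase Butterworth; cutoffs 16
Hz for orientation, 8 Hz for evidence), doubling the channel count.
The encoder is OLS (W_enc = D Cᵀ(CCᵀ)⁻¹) and the decoder its
pseudoinverse; folds are interleaved at the trial level so all epochs
of a trial share a fold, and features/regressors are standardised with
train-fold statistics only. Precision is the Fisher z of the Pearson
correlation between predictions and truth (z capped at
atanh(1−10⁻¹²)); orientation precision averages the cos/sin regressor
z values; window precision averages predictions over the window before
correlating. The encoder-inversion chain is invariant to *orthogonal*
feature mixings; unlike direct OLS decoding it is not invariant to
arbitrary invertible mixings, which re-weight the feature metric — the
property tests reflect that distinction.

Cluster tests threshold pointwise one-sample t values at two-sided
p < 0.05, score contiguous clusters by mass, and build the null from
whole-subject sign flips (exhaustive enumeration whenever 2^S does not
exceed the requested permutation count, giving exact tiny-case p
values; 10⁴ seeded draws otherwise). Jackknife latencies use
leave-one-out grand averages; onsets are the last zero-crossing of the
2 Hz low-passed (6th-order Butterworth) derivative before the lock
event, and t statistics on jackknife series are divided by n−1. Note
the onset estimator carries a ~0.1 s early bias on trajectories that
are flat before a sharp rise (zero-phase smoothing leaks the corner
backward); the estimator-validation tests therefore plant V-shaped
trajectories whose derivative genuinely crosses zero at the planted
time, and condition comparisons rely on onset differences, where the
bias cancels. Response activity projects held-out band-power epochs on
the unit-norm difference of side-mean topographies in a training
window at response execution, signed toward the provided response.
The response-power projections are taken at the alpha-band centre
(10 Hz oscillation in the generator) rather than averaged over a band.

## Synthetic epoch generator

Epochs are 1/f noise plus a 10 Hz alpha oscillation, with Gaussian
temporal bumps (s.d. 50 ms) carrying the codes: an orientation code
(amplitude ∝ cos 2θ, sin 2θ on two fixed occipital patterns) at 100
ms, and an evidence code (amplitude ∝ the observer's internal |l̂|, on
a parietal+frontal topography) at 300 ms. Driving the evidence code by
|l̂| rather than |l| is what makes decoding residuals predictive of
the upcoming choice. The drug-like condition lowers the evidence SNR
and applies a gain on conflicting-stimulus evidence that declines
linearly with position. Channels carry only a rostro-caudal coordinate
and alternating hemisphere labels; there is no electrode geometry,
volume conduction or biophysical forward model, so passing tests show
the *analysis chain* behaves correctly on data with the assumed
statistical structure, not that real recordings would yield these
effect sizes. The default sample rate is 256 Hz (above all analysis
cutoffs); tests run reduced configurations (16 channels, 128 Hz) for
speed, and the methods scale linearly in channels and epochs.

## Problem sizes

Cohort-scale checks use the study's shape: 18 subjects × 360 trials
per condition, 20 replicate cohorts for selection rates, 6 blocks × 72
trials for titration, 10⁵–10⁶ draws for Monte-Carlo oracles, 1000 null
cohorts for the cluster-test calibration, and ~2400 epochs for null
decoding. These sizes were chosen as the smallest that make the
statistical claims meaningful at their stated tolerances.

## Known limitations

* Sensory-noise likelihoods use Gaussian moment propagation; the true
  belief distribution under large sensory noise is lighter-tailed
  (evidence is bounded by ±2κ). The error is ≲0.01 in choice
  probability and ≲0.5 log-likelihood per 360 trials.
* BIC is the only evidence approximation, as in common practice for
  this model family.
* The generator does not emulate overlapping responses to successive
  stimuli, autocorrelated artifacts, or condition effects on the
  orientation code.
* Response-time modelling and raw-signal preprocessing are out of
  scope; the pipeline consumes epoched (band-power) arrays.
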