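# coginfer

Modelling toolkit for **cue-combination (weather-prediction) decisions
under internal noise**: a suboptimal Bayesian observer for sequences of
oriented stimuli, maximum-likelihood fitting with family-wise Bayesian
model selection, an opt-out model of decision uncertainty, closed-loop
difficulty titration, a premature-commitment simulator, and
inverted-encoding-model decoding of synthetic multichannel neural
epochs. It is written for computational cognitive neuroscientists who
want to simulate, fit and stress-test every stage of this paradigm on
synthetic data at desk scale.

## The model

On each trial the agent sees *n* oriented bars drawn from one of two
von Mises distributions with orthogonal (axial) means and concentration
κ. For a categorisation axis θ\*, the evidence carried by orientation
θ<sub>k</sub> is the exact log-likelihood ratio

```
l_k = 2 κ sin(2(θ_k − θ*))
```

and the Bayes-optimal observer answers with the sign of
L<sub>n</sub> = Σ l<sub>k</sub>. Internal errors can corrupt this
computation at three stages:

* **sensory** — noisy percepts θ̂<sub>k</sub> = θ<sub>k</sub> + ε,
  ε ~ N(0, σ²<sub>sen</sub>);
* **inference** — noisy evidence l̂<sub>k</sub> = l<sub>k</sub> + ε,
  ε ~ N(0, σ²<sub>inf</sub>), accumulated with optional leak
  L̂<sub>k</sub> = (1−λ)L̂<sub>k−1</sub> + l̂<sub>k</sub>;
* **selection** — Gaussian noise σ<sub>sel</sub> on the final belief
  (equivalently a softmax policy with inverse temperature β).

After each decision the agent may *opt out* and be rewarded by a
lottery of known success probability p<sub>lot</sub>; the opt-out
probability follows a logistic in two log-odds regressors,

```
p(opt out) = 1 / (1 + exp(β0 + β1·logit(p̂_cor) − β2·logit(p_lot)))
```

where the expected accuracy p̂<sub>cor</sub> comes from
truncated-normal conditioning of the belief on the chosen side,
calibrated so its mean matches the mean lottery probability (0.75).
A *premature commitment* perturbation covertly selects a category with
a flat per-stimulus hazard (from the 4th stimulus on) and thereafter
discards internally conflicting evidence. Neural analyses decode
planted orientation and evidence codes from multichannel epochs with an
OLS encoding model and its pseudoinverse
(W<sub>enc</sub> = D Cᵀ(CCᵀ)⁻¹, W<sub>dec</sub> = (W<sub>enc</sub>ᵀW<sub>enc</sub>)⁻¹W<sub>enc</sub>ᵀ),
scoring Fisher-z coding precision with cluster-permutation statistics
and jackknife latencies.

## Worked example

```python
import numpy as np
import coginfer as ci

cfg = ci.TaskConfig()                       # kappa 0.5, lengths {4,8,12}
rng = np.random.default_rng(0)
trials = ci.sample_trials(cfg, 360, rng)
observer = ci.ObserverParams(sigma_inf=0.5)
choices, trace = ci.simulate_observer(trials, observer, rng)

model = ci.NoisyInferenceModel(trials, choices, ci.ModelSpec())
res = model.fit(seed=0)
print(res.summary())
```

prints (numbers from this exact seed):

```
           estimate        se
parameter
sigma_inf  0.529641  0.048232
```

i.e. the inference-noise s.d. is recovered at 0.53 ± 0.05 from 360
choices of a σ = 0.5 generator; `res.bic` (≈ 232.9) is the score the
model-selection layer converts into evidence (−BIC/2). Running the
titration loop,

```python
session = ci.run_titration(observer, cfg, n_blocks=6, rng=np.random.default_rng(3))
print(session.tail(3)[["kappa", "accuracy", "sigma_hat"]])
```

```
       kappa  accuracy  sigma_hat
9   0.448195  0.777778   0.510870
10  0.447319  0.833333   0.504040
11  0.445579  0.750000   0.489126
```

shows the coherence settling near 0.45 while block accuracy fluctuates
around the 75% target and the online noise estimate converges to the
generative 0.5.

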