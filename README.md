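# latewave

Analysis chain for audiovisual change-detection experiments in mouse
primary visual cortex (V1).  In this task, head-fixed mice watch a
continuously drifting grating and hear a continuous harmonic ("Shepard")
tone; occasionally the orientation or the tone's frequency content jumps,
and the animal reports the change by licking a modality-specific spout.
V1 neurons respond to such changes twice: an early sensory transient
(0–200 ms) and, on detected (hit) trials only, a late wave of activity
that precedes the first lick.  `latewave` provides the statistical
machinery to characterize both waves and the behavior they support, plus
a synthetic-session generator with known ground truth for validating the
whole chain.

The package is for systems neuroscientists analyzing trial-based
electrophysiology with concurrent psychophysics: it covers behavioral
signal-detection modeling, single-neuron encoding models, time-resolved
discriminability, noise-correlation dynamics, and population decoding.

## Models and statistics

* **Psychometrics** — cumulative-normal curve
  f(x) = γ + (1 − γ − λ)Φ((x − μ)/σ), and a multi-alternative detection
  (m-ADC) model: bivariate standard-normal evidence (Ψ_v, Ψ_a), d′ added
  on the stimulated axis, report modality *m* iff Ψ_m ≥ c_m and
  Ψ_m − c_m ≥ Ψ_o − c_o.  Per-saliency d′ or a hyperbolic saturation
  d(x) = d_max·xⁿ/(xⁿ + s50ⁿ); d′ from rates as Φ⁻¹(hit) − Φ⁻¹(FA); a
  multinomial-logistic side-detection model for the visuotactile variant.
* **Encoding** — per-neuron Poisson GLM on 10-ms spike counts with
  raised-cosine temporal kernels for sensory, hit, licking, pupil and
  trial-number predictors (126 columns), elastic-net penalty (α = 0.95),
  five-fold CV over trials, λ by the one-standard-error rule, and
  cross-validated explained variance EV = 1 − var(Y − Ŷ)/var(Y) overall,
  per bin, or per predictor family.
* **Discriminability** — per-bin ROC AUC (= Mann–Whitney U/(n₁n₂),
  rectified to [0.5, 1]) with 1000-shuffle permutation tests, population
  coding fractions, onset estimates with neuron-resampling bootstraps,
  laminar depth × time maps, and onset-versus-reaction-time regression.
* **Population statistics** — pairwise noise correlations on residual
  rates, reaction-time-tertile decorrelation onsets, and chance-corrected
  random-forest decoding of the orientation pair.

Each fitted model follows the Model → Results pattern: build the model
from data, call `fit()`, read estimates and `summary()` off the results.

## Worked example

Simulate a multisensory-trained (MST) session, fit the detection model,
and locate the report-related coding onset:

```python
from latewave.simulate import CohortConfig, simulate_session
from latewave.behavior import fit_madc, response_table, session_filters
from latewave.analysis import session_auc_series, session_noise_correlations
from latewave.roc import coding_fraction, onset_from_fraction

cfg = CohortConfig.MST(n_trials=600, n_neurons=24, seed=7)
session = simulate_session(cfg, session_id="demo")

included, trimmed, reasons = session_filters(session.trials)
print(fit_madc(response_table(trimmed), variant="two-level", seed=0).summary())

series = session_auc_series(session, variable="hitmiss", saliency="thr",
                            n_shuffles=1000, seed=1)
onset = onset_from_fraction(coding_fraction(series))
nc = session_noise_correlations(session)
```

Output:

```
m-ADC fit (two-level variant), n=552
----------------------------------------------
criterion c_visual       1.002
criterion c_auditory     0.945
d'(auditory, max )    2.234
d'(auditory, thr )    1.038
d'(visual, max )    1.280
d'(visual, thr )    1.109
log-likelihood -495.30  valid=True
hit/miss coding onset: 450 ms (mean hit RT 628 ms)
baseline noise correlation: 0.052
```

The fitted criteria sit at the generative value (1.0); visual d′ at
maximal saliency (1.28 here, generative 1.5, single-session sampling
error ≈0.2) stays below auditory d′, as in trained mice.  The hit/miss coding onset (450 ms)
precedes the mean reaction time (628 ms) by roughly the generator's
280-ms report lag, and the baseline noise correlation sits near the
0.063 target.

The same operations are available from the shell:

```bash
latewave simulate --cohort MST --n-trials 600 --n-neurons 24 --seed 7 --out demo
latewave fit-behavior demo --variant two-level
latewave roc demo --variable hitmiss --nshuffle 1000
latewave noisecorr demo --align stim
latewave report --out report_dir
```

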