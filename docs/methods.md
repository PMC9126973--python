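# Methods

`latewave` implements the quantitative analysis chain for a rodent
audiovisual change-detection experiment: head-fixed mice watch a
continuous drifting grating and listen to a continuous harmonic complex
tone; occasionally the grating orientation or the tone's frequency content
jumps, and trained mice report the change by licking a modality-specific
spout within 1.5 s.  The analyses quantify (i) detection behavior with
signal-detection models, (ii) single-neuron encoding of task variables
with a kernel-based Poisson GLM, (iii) the time course and laminar
distribution of stimulus- and report-related information with ROC
analysis, (iv) trial-to-trial co-fluctuations with pairwise noise
correlations, and (v) population-level stimulus information with a
random-forest decoder.  Because the package is exercised on synthetic
sessions, every analysis can be validated against known ground truth.

## Stimulus space and trial statistics

The auditory stimulus is a five-tone harmonic complex (f/4, f/2, f, 2f,
4f) whose tone weights are a fixed Gaussian profile over log2-frequency
centered at 2^13.5 Hz (≈11585 Hz); because the weight profile is fixed
while the named center tone moves within [2^13, 2^14] Hz, the stimulus
space is circular on one octave, mirroring the circular orientation space
of the grating.  The weight-profile SD is not constrained by the design;
the default is 1 octave, which gives smoothly decaying flanking
harmonics.  Printed frequency conversions follow literal powers of two
(2^13.5 = 11585 Hz); musical-pitch roundings of the octave endpoints are
not used.

Recording sessions use four stimulus values per modality, A/B/C/D, with
AB and CD separated by the animal's perceptual threshold and AC/BD by the
maximal change (90° orientation, 1/2 octave).  Trial types are
block-shuffled in blocks of ten at 10% catch / 41% visual / 41% auditory
/ 8% multimodal; inter-change intervals are exponential with mean 6 s
(pre-truncation rate parameter 1/6), rejected outside [3, 20] s.  A bias
rule switches the upcoming modality with probability 0.95 when one spout
received strictly more than 90% of the licks over the last ten trials.
Multimodal (conflict) trials are carried through the tables but excluded
from every fit.

## Behavioral models

**Psychometric curve (threshold calibration).**  Response probability as
a function of change magnitude x is γ + (1 − γ − λ)Φ((x − μ)/σ), with
false-alarm rate γ, lapse rate λ, threshold μ and slope σ, fit by
binomial maximum likelihood.  Saliency levels are then fixed points of
the curve: sub = μ − σ, thr = μ, sup = μ + σ, plus the maximal change.

**Multi-alternative signal detection (m-ADC).**  Detection and modality
discrimination are modeled with a bivariate standard-normal decision
variable (Ψ_v, Ψ_a); the stimulated modality's axis gains its d′.  The
observer reports modality m iff Ψ_m ≥ c_m and Ψ_m − c_m ≥ Ψ_o − c_o,
i.e. the criterion-referenced evidence must both exceed threshold and
beat the competing modality.  Whether ties are resolved on the raw or
criterion-referenced axis is not empirically identifiable (ties have
measure zero); the criterion-referenced rule is this package's
definition.  Response probabilities are computed by 1-D Gauss-free
numerical integration (trapezoid on a 1001-point grid, accurate to
~1e-7 and verified against 10^6-draw Monte-Carlo simulation).  Two fit
variants exist: the two-level variant fits (d′_v, d′_a, c_v, c_a)
independently per saliency level against that level's change trials plus
the catch trials; the hyperbolic variant constrains d′(x) =
d_max·x^n/(x^n + s50^n) and fits eight parameters over all levels, and is
flagged invalid when the implied visual threshold s50 leaves [1°, 45°].
Optimization is multi-start bounded L-BFGS-B (10 restarts, fixed seed,
best likelihood wins).  Criteria are fitted per level; the results object
reports both the per-level values and their per-modality mean.

**Rate-based d′** is Φ⁻¹(hit) − Φ⁻¹(FA), with rates of exactly 0 or 1
pulled in by 1/(2N) before inversion.

**Side-detection model (visuotactile task).**  Choice probabilities
follow a multinomial logistic model with saturating stimulus terms:
log(p_side/p_nogo) = b_side + sL·cL^n + sR·cR^n with n ∈ (0, 1].

**Artificial catch trials.**  Catch events are inserted offline into long
inter-change intervals at times drawn from the session's inter-change
distribution (so temporal expectation matches real trials, with a 3-s
guard to the next real change), labeled FA/CR from the lick stream, and
FA latencies are subsampled by quantile-bin matching to the hit RT
distribution.

**Session rules.**  Sessions are trimmed from the first run of 20
consecutive no-response trials and excluded when the pooled
maximal-saliency hit rate is below 30%.  The optogenetic analysis
computes the relative d′ reduction (d′_ctrl − d′_opto)/d′_ctrl per
session, gates sessions on ≥50% early-silencing reduction (configurable
25/75%), and regresses the late-silencing effect on the median control
reaction time.

## Spike features

Rates are spike counts in 10-ms bins convolved with a causal
half-Gaussian (SD 50 ms by default, truncated at 4 SD, renormalized to
mass 1); the estimate at bin t never uses spikes after t.  Bin edges sit
on an integer grid so one edge falls exactly at the alignment event.
Z-scoring uses the −1 to −0.2 s baseline, pooling all trials × baseline
bins (per-trial-mean pooling was the alternative; all-bins pooling is
used and stated here because it also standardizes within-trial
variability).  Alternate kernel SDs are parameters: 10 ms for
high-resolution coding analyses, 100 ms for noise correlations.
Waveforms with peak-to-trough below 0.45 ms are narrow-spiking (putative
inhibitory), above 0.55 ms broad-spiking, intermediate unclassified;
values are capped at 1 ms upstream.  Cortical depth maps to laminar zones
with an inclusive granular band: SG < 400 μm ≤ G ≤ 550 μm < IG.
Inclusion rules: >0.5 Hz session-average rate for encoding fits, >1 Hz
for noise correlations, z > 2 at any stimulus-epoch bin for
responsiveness (with ≥3 trials per condition), and spikes in more than 90
of 100 session bins for stability.

## Encoding GLM

The design matrix stacks 10-ms bins of −0.5 to 2.5 s windows around every
change.  Temporal kernels are raised cosines,
bump(t) = ½(1 + cos(π(t − c)/w)), with centers evenly spaced and
half-width w equal to the spacing so interior bumps tile to exactly 1;
the "width" is exposed as this half-width parameter.  Families: sensory
(2 early bases on 0–0.2 s + 10 late on 0–2 s) × 2 modalities × 2 change
levels × 2 post-change feature pairs ({A,B} vs {C,D}) = 96; hit = 10
stimulus-aligned bases on hit trials + 10 reward-aligned (−0.5 to 1.5 s)
= 20 (the stimulus-aligned kernels are shared across modalities by
default; a 5 + 5 split layout is available behind a flag); movement = 3
bases (−0.2 to 0.4 s) around each lick × 2 sides = 6; pupil at lags
0/−400/−800 ms = 3; trial number = 1; total 126.  All columns are
normalized to unit maximum.  A null model has one uniform-random column.

Fits minimize mean Poisson deviance with an elastic-net penalty
(α = 0.95) via accelerated proximal gradient (FISTA) with warm starts
along a 100-value descending log-spaced λ path, monotone restarts, and a
curvature bound from the top eigenvalue of X′X; the path terminates once
the cross-validated deviance has risen for three consecutive λ past its
minimum.  Cross-validation assigns whole trials to 5 folds (never single
bins, to avoid leakage through smoothness).  λ is chosen by the
one-standard-error rule; the SE is computed on fold-centered deviances
(each fold's mean over λ subtracted) so between-fold difficulty offsets
do not inflate the SE of the relative CV curve — with raw fold SEs the
rule degenerates to the null model whenever folds differ more in
difficulty than the signal changes the deviance.  Explained variance is
EV = 1 − var(Y − Ŷ)/var(Y) on held-out predictions: overall over
concatenated single-trial bins, per time bin across trials, or on
concatenated condition-averaged PSTHs of the five most frequent
trial-type × choice conditions.  Family-subset EV zeroes all other
coefficients of each fold's model (intercept kept).

## ROC coding analysis

Per neuron and 25-ms bin, the AUC between two trial groups is computed
from midranks (identical to the Mann–Whitney U statistic, ties at 0.5)
and rectified to [0.5, 1].  Comparisons: orientation ({A,B} vs {C,D}),
occurrence (visual vs catch), and hit/miss (visual hits vs misses),
each analyzed per saliency level; each class needs ≥10 trials.
Significance per bin comes from 1000 label permutations; the p-value is
(1 + #{shuffled ≥ observed})/(1 + 1000), so it is never zero, and a bin
is significant at p < 0.01.  A neuron is classified as coding a variable
when ≥3 consecutive bins (75 ms) are significant within 0–1 s.

The population coding fraction is the share of significant neurons per
bin; it is baseline-subtracted and max-normalized only when it rises at
least 10 percentage points over baseline.  The coding onset is the first
post-stimulus bin whose fraction exceeds baseline mean + 2 SD (pooled
baseline SD over −0.5–0 s; robustness is reported for z ∈ {1, 2, 3}).
Two guards matter at the population sizes used here (~100 neurons,
versus thousands in large pooled datasets): the baseline SD is floored at
one neuron's worth of fraction, and the crossing must hold for two
(fraction) or three (bootstrap) consecutive bins; without them a single
noise-significant neuron can define an onset.  Onset uncertainty comes
from resampling neurons with replacement (1000 bootstraps, percentile
95% CI).  Per-session onsets use the same AUC machinery on the
neuron-averaged rate (sessions with ≥10 neurons), taking the first
sustained significant bin.  Laminar maps bin neurons in 50-μm depth bins
over 0–1150 μm × 25-ms bins, smoothed for display with a 2-D Gaussian of
1.3 bins; zone statistics require ≥10 neurons per session-zone.  The
onset-versus-reaction-time relation is summarized by OLS and by a
fixed-slope-1 offset, mean(RT − onset).

## Noise correlations and decoding

Noise correlations are Pearson correlations across trials of residual
rates (10-ms bins, 100-ms-SD smoothing, −1 to +1.5 s) after subtracting
each orientation's trial-mean time course (or the lick-aligned mean for
lick-aligned analyses); pairs need ≥10 trials and both neurons >1 Hz.
Pair summaries average Fisher-z-transformed correlations and
back-transform.  The report-related decorrelation is the first sustained
bin (5 × 10 ms) where the pair-mean NC falls below baseline mean − 2 SD;
the tested series is smoothed with a 50-ms boxcar while the threshold
uses the raw series' baseline SD.  Reaction-time tertiles of hit trials
are analyzed separately; stimulus-aligned onsets should order with RT
while lick-aligned onsets should coincide at the gain-quench lead.

Orientation decoding groups {A,B} vs {C,D}, takes spike counts in 200-ms
windows sliding by 50 ms (windows straddling the change are dropped),
subsamples ten neurons per session (≥15 required, ≥20 trials per class),
and uses a 200-tree random forest under 5 × 5 stratified
cross-validation.  Accuracy is chance-corrected by subtracting the mean
accuracy over label-permuted surrogates (each evaluated with one
stratified 5-fold pass; 50 surrogates by default).

## The synthetic-session generator

The generator produces full sessions (trials, choices, spikes, licks,
pupil) with the statistical structure the analyses assume, and returns
its parameters as ground truth.

*Behavior.*  Choices come from the same bivariate decision rule the
m-ADC model fits, so behavioral fits are exact model recovery.  Default
MST d′: visual {0.4, 0.9, 1.2, 1.5} and auditory {0.5, 1.1, 1.8, 2.2}
over sub/thr/sup/max, criteria 1.0 — chosen so maximal-saliency visual
d′ ≈ 1.5 and auditory d′ exceeds visual, with realistic hit and
false-alarm rates.  UST animals have zero auditory d′ and a high
auditory criterion; NE animals have zero contingent d′ throughout.
Reaction times are lognormal (median 0.62 s MST, 0.45 s UST, log-SD
0.12, clipped to the 0.1–1.5 s response window); cohort collections add
small across-session jitter (log-SD 0.03).  These spreads are tighter
than real rodent RT distributions; they are what makes timing parameters
recoverable at ~100-neuron populations, and wider spreads mainly blur the
left tail of onset estimates.

*Spiking.*  Inhomogeneous-Poisson spikes on a 10-ms grid over the whole
session.  Baselines are lognormal across neurons (median 4 Hz, log-SD
0.5).  An early transient (Gaussian bump at 100 ms, SD 40 ms, within
0–200 ms) appears on visual-change trials, scaled by saliency
(0.25/0.5/0.75/1), by laminar gain (largest granular/supragranular), and
by orientation preference (each neuron prefers {A,B} or {C,D};
tuning ±0.3 of the transient by default — strong enough to decode and to
drive orientation coding, weak enough that small-sample orientation
imbalances between hit and miss groups do not masquerade as early
report coding).  A late report-locked component appears on hit trials
only, strongest supra-/infragranularly, with amplitude 1.5 × baseline;
its nominal onset is reaction time − 280 ms, and its rise follows a
Gaussian CDF (SD 100 ms) reaching half amplitude 50 ms after the nominal
onset and truncated 50 ms before it.  This rise placement is a
calibration of the generator's contract: the lag parameter is defined as
the *detectable* coding onset, and with this waveform the analyses
recover the stated 280 ms within their tolerance; a rise placed entirely
after the nominal onset makes detection lag the parameter by the
detection threshold's position on the rise.  After the plateau (until
300 ms past the lick) the component decays with a 150-ms half-Gaussian.

*Shared gain and pupil.*  All neurons share a multiplicative lognormal
Ornstein–Uhlenbeck gain (τ = 1 s).  The log-gain SD is solved in closed
form from the target baseline noise correlation (default 0.063) using
the smoothing kernel's weight vector and the OU autocorrelation: for
equal rates λ, r = λσ²K/(S2/Δ + λσ²K) with S2 = Σw² and
K = Σ w_b w_b' exp(−|b−b′|Δ/τ); the population mean rate stands in for
λ.  The gain is clamped to 1 (variance quenched) from 200 ms before each
first lick until 1 s after it, producing the hit-specific decorrelation.
The pupil trace is a low-passed copy of the log-gain plus noise,
z-scored, at 20 Hz.

*Optogenetics.*  Photostimulated trials scale all rates to 5% of
baseline from the change (early) or from +200 ms (late) until the
choice.  Behaviorally, early silencing scales visual d′ to 15% of its
value; late silencing converts hits whose generated late onset falls at
or after +200 ms into misses — the operational form of the hypothesis
that the late wave is necessary for report, and the mechanism that makes
the late-silencing deficit grow with reaction time.

*What the generator does not emulate:* non-Poisson spike-train structure
(refractoriness, bursting), adaptation across the session, overlap of
movement- and reward-related activity beyond the hit component,
eye-movement artifacts, and realistic RT spread (see above).  Passing
recovery tests therefore shows the *analyses* are correct and calibrated
under the assumed statistical structure, not that real cortical data
satisfy that structure.

## Problem sizes and numerical choices

Validation runs use sizes chosen to give stable statistics at
single-machine scale: 600-trial sessions for behavioral recovery (100
replicates), 10 sessions × 10 neurons per cohort for onset recovery
(1000 bootstraps), 50 neurons × 300 trials for the NC baseline, four
600-trial sessions for decorrelation tertiles, and ~16–20 small sessions
for decoding chance calibration with 10 surrogates per window.
Degenerate inputs are handled explicitly: empty spike trains give
zero-rate tensors; zero-baseline-SD neurons are flagged and excluded
from z-scored outputs; zero-variance targets give NaN explained
variance; never-crossing onset series report no onset; tertiles that
never cross report no drop onset.  Ties: AUC uses midranks; "first
significant bin" is strictly the earliest bin index satisfying the
sustained-run rule.

## Known limitations

The m-ADC integration assumes independent evidence channels; correlated
channel noise is not modeled.  The FISTA elastic-net solver matches
unpenalized GLM fits to ~1e-6 but its penalized solutions can differ
from coordinate-descent implementations near the selection boundary of
weak predictors.  The spike-history-free Poisson likelihood overstates
the independence of adjacent 10-ms bins when rates are smoothed.  The
fixed-slope offset between coding onset and reaction time is only as
interpretable as the onset detector's threshold placement, which is why
the generator defines its lag at the detectable onset.
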