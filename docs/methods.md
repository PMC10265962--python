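# Methods

`vocdecode` implements a complete analysis chain for decoding the *content*
(vowel /u/ vs. /ə/) and *production form* (vocalized vs. imagined) of human
vocalization from epoched MEG-like data, together with a forward simulator of
the rule-based task that makes the chain testable end to end. This note
documents the models, the estimator, the numerical choices, and what the
synthetic data can and cannot establish.

## Task model

Each trial instructs the two binary variables sequentially with two visual
cues (forward/backward slash), each 100 ms long and followed by a 2 s delay;
a go cue 4200 ms after the first cue triggers the (overt or covert) response.
Which variable comes first and which glyph means which value is fixed per
block; 2 cue orders × 2 glyph assignments give 4 rules, hence
4 rules × 4 (vowel × production) cells = 16 conditions. A session holds one
80-trial block per rule, 20 trials per cell, 320 trials; the second session
replays the first session's block order reversed. Condition codes 1–16 are
lexicographic in (order, assignment) with codes 1–4 reserved for the
(vowel × production) cells of the first rule. The within-block trial order is
an unconstrained seeded shuffle (no run-length constraint is imposed).

## Synthetic data generator

Source space: a mirror-symmetric quasi-uniform (Fibonacci) shell of
`n_sources` locations (full scale 457, desk scale 60); hemispheres are the
sign of the lateral coordinate, immediate neighbours are sources within 1.6×
the median nearest-neighbour distance. The leadfield is a smooth
distance-decaying synthetic gain tensor (sources × 3 orientations ×
channels), RMS-normalized; it stands in for individual head modelling, which
is out of scope. Each source has a fixed random orientation that is part of
the subject's ground-truth geometry.

Planted representational structure (all pattern vectors unit norm over
sources, mutually orthogonal unless overlap is requested):

- **content axis** `u_content`, amplitude ±`a_content`, ramping from the
  content cue and stable thereafter;
- **early production axis** `u_prod_early`, ±`a_prod`, ramping from the
  production cue;
- **late motor-program axis** `u_prod_late`, ±`a_late`, ramping only from the
  *second* cue — once both variables are known — which makes the production
  representation transform between delays while content stays stable;
- **shared effort axis** `u_effort`, amplitude
  `a_effort · e(levels known so far)` with effort scalars
  e(/u/) = e(vocalized) = 1.6 > e(/ə/) = e(imagined) = 1.0. The amplitude is
  causal: during delay 1 it tracks the effort level of the first-instructed
  variable only, and moves to the product e(vowel)·e(production) after the
  second cue. This axis is the planted cause of content–production
  representational overlap and of the split-condition asymmetries
  (more content information when vocalized, more production information
  for /u/).

Ramps are logistic saturations `g(t) = 2/(1+exp(-t/τ)) − 1` with τ = 300 ms —
smooth, monotone, one parameter; the exact shape only needs to produce a
gradual information build-up.

The optional **cue-glyph confound** (`a_cue > 0`) adds a random pattern per
(glyph × block), redrawn every session, at each cue onset with an
alpha-function transient. A glyph pattern that is identical on every trial
cancels exactly in any zero-sum contrast (both glyph assignments are balanced
within a session), so the confound is modelled as the blocked-design ×
nonstationarity interaction it actually is: per-block pattern shifts inflate
within-session information, and cross-session decoding (reversed block order,
fresh shifts) cancels them in expectation.

Noise: sensor noise is AR(1) in time (φ = 0.9) mixed by a random
condition-number-capped spatial matrix; white-ish AR(1) source noise is
projected through the leadfield; each trial's condition mean gets a
multiplicative amplitude jitter (SD 0.15). Session 2 perturbs the forward
model by a small random rigid rotation of the source cloud about the vertical
axis (SD 3°) plus per-channel gain jitter (SD 3%) — a minimal head-
repositioning model that attenuates but does not destroy cross-session
decoding.

Audio: vocalized trials carry a vocalization burst whose onset is drawn
N(0.58 s, 0.12² s²) after the go cue (truncated at 0.05 s), at the
2343.75 Hz microphone rate the onset detector is specified for; imagined
trials carry only low-amplitude background noise.

**Amplitude working point.** The effect amplitudes
(`a_content = 0.12`, `a_prod = 0.18`, `a_late = 0.30`, `a_effort = 0.52`,
left-mass weight λ = 0.8, relative to unit sensor noise) are the package's
own calibration: they were chosen so that a 24-subject desk-scale experiment
robustly exhibits the qualitative significance pattern the task predicts (content
decodable from its cue onward and in both delays; production only after its
cue; higher information under stronger motor involvement; a transforming
production representation; early cross-variable overlap; left-lateralized
maps; cross-session stability). They are not measured physiological values —
no numeric effect sizes exist to match — and the absolute D scale of the
simulation is therefore arbitrary.

## Preprocessing

Canonical order (enforced by `preprocess`): channel-jump repair → 30 Hz
zero-phase sixth-order Butterworth low-pass (forward–backward) → polyphase
resampling to 300 Hz → 10 Hz low-pass of the same design → baseline
correction on the 500 ms before the first cue. A low-pass stage is skipped
when the data are already sampled below twice its cutoff. Jump repair
subtracts step offsets where a sample-to-sample difference exceeds
`factor × 1.4826·MAD` of the trace's differences (factor 20); the rule is our
construction, the real step is named but not specified. The ICA artifact
stage is an identity hook: the simulation contains no biological artifacts.
The onset detector rectifies the audio, median-filters it (42.66 ms window,
reflect padding — edge-replicating padding lets a single loud sample at the
epoch edge defeat the median), and thresholds at the RMS + 8 SD of a 1 s
imagined-trial reference envelope; manual per-subject threshold adjustment is
replaced by the configurable SD multiplier. Trial selection keeps trials with
the correct production type and, for vocalized trials, the correct vowel and
a post-go vocal onset (vowel correctness alone when a session has no audio).
The 137-of-273 sensor subset is a deterministic farthest-point (maximin)
selection started at the most superior sensor.

## The estimator

Cross-validated MANOVA estimates the pattern distinctness D of a zero-sum
condition contrast. Per fold, condition means B (GLM betas of an indicator
design) and the noise precision are estimated on the training split, B and
trial counts on the test split:

    D = (1/n_test) · tr( B_train' P  X'X_test  P B_test  Σ⁻¹ ),
    P = C (C'C)⁺ C'

with Σ⁻¹ = (fE − p − 1)(Ξ'Ξ)⁻¹ from the residuals Ξ of the *window-mean*
training data (window: first-cue offset to go-cue onset), fE = n_train −
rank(X). The correction makes Σ⁻¹ an unbiased inverse-covariance estimate and
requires fE − p − 1 > 0 — the reason for the sensor subset at full scale.
Because training and test estimates come from independent trials, E[D] = 0
in the absence of a true effect; D may be negative by sampling noise. D is
invariant to any fixed invertible channel mixing (the trace is a similarity
invariant once Σ⁻¹ is re-estimated on the mixed data).

When the training and test contrasts differ — cross-variable, split-condition
or cross-context decoding — the projector sandwich above degenerates (with
balanced stratified folds X'X_test ∝ I and orthogonal contrasts annihilate
each other), so the estimator switches to the contrast-aligned form

    v_i = (c_i'c_i)⁻¹ c_i' B_i,   w = sqrt((c₁'X'X c₁)(c₂'X'X c₂)),
    D₁₂ = (w / n_test) · v₁ Σ⁻¹ v₂',

which reduces exactly to the projector form when c₁ = c₂ and keeps the
benchmark consistency below. Both forms are oracle-checked in the tests.

Cross-validation is condition-stratified 5-fold, repeated 20 times with fresh
seeded assignments and averaged (every condition present in every fold; Σ⁻¹
is estimated per fold within each repetition). The 1/n prefactor counts the
test trials of conditions carrying test-contrast weight, which keeps D
scale-free across split and context-restricted analyses. Temporal
generalization uses B_train and B_test from all pairs of time points (the
matrix diagonal equals the per-time-point estimate by construction).
Cross-session decoding is a single twofold split — train on one session, test
on the other, alternately — with Σ⁻¹ from the training session. Pseudoinverses
(cutoff 1e-10 of the largest singular value) are used for contrast Grams.

**Expected cross-information.** E₁₂ = sign(D₁)·sign(D₂)·√|D₁·D₂| is the value
cross-decoding would reach if the two representations were identical up to
magnitude; the signed-√|·| form handles negative sampling-noise arguments.
Observed D₁₂ significantly below E₁₂ means the representations are not
identical. Within-delay expected values use the same formula with
D₁ = D₂ = the delay-averaged within information.

## Source analysis

A unit-gain LCMV beamformer, W = (L'C⁻¹L)⁻¹L'C⁻¹ per source with diagonal
loading at 5% of the mean sensor variance (no value is prescribed), projects
sensor epochs to three orientation traces per source (summed into one for
cross-session profiles). The searchlight repeats cvMANOVA per source over the
dipole directions of the source and its immediate graph neighbours; locations
whose channel count violates fE − p − 1 > 0 are marked NaN, while global
problems (stratification failure) propagate as errors. The lateralization
index is mean(left-hemisphere D) − mean(right-hemisphere D). Searchlight
Σ⁻¹ uses the same window-mean scheme as the sensor analysis.

## Statistics

Delay windows exclude the 250 ms after each cue (the window a visual
transient would contaminate): delay 1 = [350, 2100] ms, delay 2 =
[2450, 4200] ms on the canonical timeline. Cross-time window averages exclude
the diagonal band |t_train − t_test| ≤ 100 ms. Delay-1 cross-time pools only
relevant-cue-first conditions; the between-delay average pools
relevant-first plus the mixed-order matrices; delay-2 pools all orders.
Information > 0 uses one-tailed one-sample t tests; D < E uses one-tailed
paired t tests; split comparisons use two-tailed paired t tests. The two
sessions of a subject are averaged at the D level before group tests.
P-values are Benjamini–Hochberg FDR-corrected within per-analysis families of
tested time intervals (family membership is recorded in the output). The
100 ms-FWHM Hann smoother exists for visualization only and is never applied
before statistics. Note that BH-adjusted p-values are not idempotent in
general; the implementation is verified against a hand-rolled step-up oracle
instead.

## Pipeline and problem sizes

`run_experiment` simulates `n_subjects` (default 24) × 2 sessions, runs the
full decoding battery per subject and the group tests, and writes tidy
tables plus a JSON report whose flags state whether the qualitative result
pattern was reproduced. Every output embeds the config hash and seed; all
randomness derives from the experiment seed via stable per-subject streams.

Dimensional profiles are configuration, not behaviour: the desk-scale default
is 64 channels / 60 sources / 300 Hz; the full-scale geometry
(273 channels / 457 sources, 137-sensor subset) is available by config. The
acceptance script runs 24 subjects at 40 channels / 40 sources / 150 Hz with
8 cross-validation repetitions and decoding time steps of 75 ms (150 ms for
temporal generalization) — sizes chosen so a complete run stays at the
minutes scale on one core. The type-I-error meta-simulations use a batched
reimplementation of the within-session estimator (verified to machine
precision against the reference implementation) on noise epochs drawn at
analysis resolution from the same spatial/temporal noise model; filtering is
omitted there because it is linear and cannot affect the null.

## What the synthetic data do and do not show

Passing tests establish that the estimator is unbiased under the null, that
every cross-decoding variant measures what it claims on data with known
ground truth, that the confound-cancellation logic works, and that the
statistics are calibrated. They do not establish anything about real MEG:
the simulator has no realistic head geometry, no eye/heart/muscle artifacts,
no 1/f spectral structure, no behavioural errors (performance is perfect by
construction, so trial selection is exercised only through planted onset
times), and effect amplitudes are a calibrated working point rather than
measurements. Single-trial classification output, shrinkage covariance
estimators beyond the stated correction, atlas mapping and cortical-surface
rendering are out of scope.
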