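# Methods

`covis` simulates a two-person co-visibility perceptual decision
experiment and implements the analysis chain that looks for covert
neural and autonomic signatures of shared perception. This note
documents the generative model, the analysis conventions, the
numerical choices, and what the synthetic conditions do and do not
establish about real data.

## The experiment being emulated

An observer discriminates the net motion direction (left/right) of a
random-dot kinematogram at five coherence levels (3.2, 6.4, 12.8,
25.6, 51.2 %), rating confidence 1–6 after each choice. On each trial
a cue discloses whether the upcoming stimulus is *public* (also
visible to a co-present confederate) or *private*. The full design
crosses coherence × direction × context with 32 repeats — 640 trials
in four blocks of 160, all 20 trial types balanced within blocks. EEG
and binocular pupillometry are recorded throughout.

The scientific question is whether mere joint visibility — with no
interaction or feedback — leaves measurable traces. The expected
pattern, which the generator reproduces and the pipeline recovers, is:

* **behavior**: no context effect on accuracy, RT, confidence or
  metacognitive sensitivity;
* **univariate ERPs**: a coherence-scaled centro-parietal positivity
  (CPP), no context effect on its amplitude;
* **multivariate EEG**: a decodable social-context representation that
  begins *before* motion onset (the cue already carries the
  information) alongside a post-stimulus coherence representation;
* **pupil**: a small public > private dilation in an early
  post-stimulus window.

## Generative model

### Behavior

Accuracy is Bernoulli with the two-parameter Weibull success
probability

    P(x) = 1 − ½ exp(−(x/λ)^κ),

so P(0) = 0.5 (two-alternative chance) and P(λ) = 1 − 1/(2e) ≈ 0.816
(~82 %), which is what the threshold parameter λ *means*. Defaults
λ = 12.8 % and κ = 1.5 put the mid coherence near threshold. RT is a
shifted lognormal (shift 250 ms) whose median falls 125 ms per octave
of coherence from 950 ms at 3.2 %; responses are capped at the
5000 ms deadline. Confidence is a thresholded latent Gaussian,
z = 0.4·octaves + 0.8·(correct − ½) + ε, cut at fixed points into six
levels. Social context enters none of these models: the behavioral
null is true by construction, so any significant context contrast
downstream is a false positive. Exact RT/confidence forms are the
package's own choice; only their signs (RT falling, confidence rising
in coherence) are constrained by the phenomenon being emulated.

### EEG

Epochs are −1500…+3000 ms around motion onset at 250 Hz (the source
recordings this emulates used 1000 Hz and wider epochs; decimation is
benign for the window-mean and rank-correlation statistics used
here). The montage is the 41-electrode union of the five searchlight
ROIs. Three additive sources:

1. **Noise**: Gaussian, SD 10 µV per channel, with uniform
   inter-channel correlation 0.3 (a one-common-factor stand-in for
   volume conduction).
2. **CPP**: a ramp rising from motion onset, plateauing over
   400–600 ms and decaying by 1200 ms, projected onto centro-parietal
   channels (CPz strongest) with amplitude `cpp_gain` (default
   0.1 µV/% → 5.1 µV at the highest coherence).
3. **Context pattern**: one fixed random across-channel pattern per
   subject (unit RMS, scaled by `context_gain`, default 0.7 µV),
   added with sign +1 on public and −1 on private trials. Its time
   course ramps from zero at the window start (−900 ms, when the cue
   is on screen) to full amplitude at motion onset and is sustained
   to the epoch end — a representation that *builds up* before the
   stimulus. The ± symmetry leaves every univariate average
   unchanged, so ERP contrasts stay null while multivariate analyses
   can decode context.

A boxcar context time course would be a poor choice here: the RSA
baseline window (−500…0 ms) lies inside the context window, and
baseline correction of a time-constant pattern cancels it inside the
window while re-injecting its negation outside. The ramp keeps the
decodable signal where the representation actually is.

Cohort-level runs draw per-subject multiplicative lognormal factors
(SD 0.4 on the two gains, 0.25 on λ, 0.15 on noise) so that
between-subject variability is realistic and group-level effect sizes
come out at the order reported for human cohorts (within-subject
Cohen's d ≈ 1–1.7 for the RSA cluster means) rather than the
near-infinite d of a perfectly homogeneous group.

### Pupil

A continuous 200 Hz binocular recording spans all trials (onsets
spaced by RT + ~2.5 s inter-trial time; the recording starts 7 s
before the first onset so every epoch has its full 6 s history).
The deterministic trace is: 3.5 mm baseline + slow 0.02 Hz drift +
a canonical slow dilation response per trial (gamma-shaped, peak
~0.93 s) + coherence- and confidence-proportional components in a
late (1.5–3 s) window + `pupil_context_delta` (default 0.02 mm) on
public trials in the 0–1.8 s window. Windowed components use
raised-cosine 100 ms edges so the 4 Hz low-pass filter passes them
essentially unchanged, which is what makes the noiseless
chain-closure test meaningful. The right eye sits 0.15 mm below the
left. Artifacts are injected at per-minute rates: blinks (8/min,
150–300 ms, low confidence, shared across eyes and exported as an
event list), single-sample spikes (4/min, ±1–2.5 mm), and
out-of-physiological-range samples (2/min). The blink count is
exactly `round(rate × minutes)`.

## Analysis conventions

* **Psychometric fits**: unweighted nonlinear least squares on the
  five per-level accuracy proportions, start (λ, κ) = (25, 3), bounds
  λ ∈ [0.5, 200], κ ∈ [0.2, 10], five multistarts (best SSE wins,
  ties → first). Perfect accuracy at every level is flagged
  non-identifiable rather than fitted. Trial-level likelihood fitting
  was deliberately not made the default; with five proportions the
  curve-fit framing is the standard reading.
* **Type-2 ROC**: hit rate P(conf ≥ c | correct) vs false-alarm rate
  P(conf ≥ c | error), criterion swept over the observed rating
  values descending (identical to the 6…1 grid for 1–6 data, and
  invariant under strictly monotone relabelings); AUC by trapezoid
  over the polyline anchored at (0,0) and (1,1). Equals the
  pair-count statistic P(conf_hit > conf_fa) + ½P(tie).
* **Group contrasts**: two-stage summary statistics — a per-subject
  estimate per context, then a paired t-test and Cohen's
  d = mean(diff)/SD(diff). Full random-effects GLMMs are out of
  scope; for balanced designs the two approaches estimate the same
  contrast.
* **CPP**: mean of the baseline-corrected (−200…0 ms) CPz trace over
  the closed window 400–600 ms, samples mapped by nearest neighbour.
  Response-locked variant: baseline 0–200 ms *after* the response (as
  specified for the emulated analysis), measurement window
  configurable, default −200…0 ms before the response (no window is
  prescribed by the source analysis).
* **Pupil cleaning** (canonical order quality → blink → merge → MAD →
  smooth; any reordering is an explicit call-site choice, never
  silent): keep 1.0 ≤ d ≤ 7.0 mm and confidence > 0.99 (strict);
  blink spans padded ±100 ms; binocular merge via the interpolated
  inter-eye difference; dilation-speed filter at
  median + 16·MAD (the multiplier is unstated in the emulated
  protocol; 16 is common pupillometry practice) with the two-sided
  maximum speed; fourth-order Butterworth, 4 Hz, applied
  forward–backward (zero phase, so onset-locked effects are not
  delayed). Missing samples are always interpolated (linear interior,
  nearest-value at the edges), never dropped: the time base length is
  invariant through the whole chain.
* **Pupil epochs**: −6…+3 s at 200 Hz, baseline −1000…−500 ms;
  epochs > 50 % interpolated are flagged, not dropped. Response-locked
  windowed means support both layouts (1 s before the response vs
  500 ms baseline, or 1 s after vs the 500 ms before).
* **Time-resolved pupil regression**: per time point, OLS of pupil
  value on standardized coherence and confidence plus ±½-coded
  context (so the context coefficient is the public-minus-private
  difference in mm), with fixed per-subject intercepts implemented by
  within-subject centering; BH-FDR across time points separately per
  predictor. For balanced designs the coefficients coincide with the
  random-intercept mixed-model estimates; variance components are not
  estimated.
* **RSA** (per subject, per time point): baseline −500…0 ms → z-score
  each (channel, time) cell across trials → condition patterns from a
  regression with intercept + 10 condition indicators, solved by the
  minimum-norm pseudoinverse (the coding is rank-deficient by one;
  minimum norm resolves the intercept ambiguity, and all
  *between-condition differences* — the only thing the RDM uses — are
  invariant to that resolution) → remove the smallest nonzero
  singular component of the 10 × channels beta matrix (no centering;
  the SVD is taken of the betas as estimated, so a rank-1 pattern
  matrix passes through unchanged and a full-rank one loses exactly
  σ_min, per the Eckart–Young identity) → Mahalanobis distances
  whitened by the same-time-point residual covariance shrunk toward
  its diagonal (γ = 0.1; the covariance source is the package's
  choice — residual covariance is the standard for this distance) →
  Kendall Tau-A against each model RDM over the 45 lower-triangle
  entries with the full 990-pair denominator.
* **Model RDMs** (canonical condition order: context-major, coherence
  ascending): coherence model |cᵢ − cⱼ|/51.2; context model 0 within /
  1 between contexts. The emulated description also mentions a
  repeated 5 × 5 identity block, which conflicts with the 0/1
  wording; the 0/1 definition is implemented as default and the
  identity-block variant is available via
  `model_rdm_context(block="identity")`. Note the two default models
  are *not* Tau-A orthogonal: τ_A(coherence, context) = −0.101 by
  enumeration, so a strong context representation leaks a small
  negative coherence correlation. At realistic effect sizes this
  leak sits below the cluster-detection floor; it is the reason the
  generator calibration targets d ≈ 1 rather than larger.
* **Cluster inference**: pointwise one-sample t against zero,
  clusters = maximal runs of two-sided p < .05 (length-1 allowed),
  mass = Σ|t|; null = per-subject whole-series sign flips (the
  exchangeable transformation for a one-sample design — label
  permutation has no meaning here), max cluster mass per permutation;
  corrected p = (b + 1)/(m + 1), so p ∈ [1/(m+1), 1]. The
  implementation computes all flipped t series from the flipped means
  and the (flip-invariant) second moments — algebraically identical
  to the literal per-permutation recomputation, which the tests
  verify. Within-cluster effect sizes average the statistic per
  subject over the (sub-)window; CI via t-interval by default or
  subject-resampling bootstrap (1000 draws) when configured.

## Desk-scale sizes

The default configuration is the full study (33 subjects, 640
trials, stride 1). The bundled analysis scripts and the test suite
run reduced sizes chosen to keep the full chain at minutes on one
CPU while leaving every convention untouched: 16 subjects × 160
trials with RSA stride 4 (16 ms grid) and 500 permutations for the
cluster recovery; 8 subjects × 80 trials for the pupil regression;
100 seeded cohorts of 10 subjects for the null-mirroring rates; the
permutation-test calibration uses 20 subjects × 200 time points ×
500 noise replicates × 200 permutations.

## What the synthetic conditions do and do not show

Passing tests establish that the chain is *correct* (each statistic
matches an independent oracle), *calibrated* (the cluster test's
family-wise error sits at its nominal level on pure noise; the
behavioral/ERP nulls are not spuriously rejected) and *sensitive*
(injected effects are recovered in the right windows with the right
signs). They do not establish performance on real recordings: the
noise model is stationary Gaussian with uniform channel correlation
(no alpha rhythm, line noise, channel pops or non-stationarity),
blinks are clean rectangular dropouts, the context representation is
a single fixed linear pattern, and eye movements, gaze position and
luminance effects are absent by design (luminance was physically
constant in the emulated setup). The response-locked ERP and the
drift-diffusion account of the CPP are likewise out of scope.

## Known limitations

* `fit_weibull` reports the least-squares solution within bounds; for
  observers far above/below the tested range the threshold estimate
  saturates at a bound with `converged` still true — inspect `sse`.
* The MAD speed filter on *noise-free* traces flags genuine fast
  dilations (the MAD of a smooth signal is tiny); with any realistic
  noise floor it behaves as an artifact filter. The chain-closure
  test bounds the resulting distortion below 1 % RMS.
* The timewise regression treats trials as exchangeable given the
  subject intercept; slow autocorrelation between overlapping epochs
  is ignored (it inflates no context contrast because neighbouring
  trials' contexts are independent by design).
* Sign-flip inference assumes per-subject symmetric null
  distributions of the Tau-A series; Tau-A of a noise RDM against a
  fixed model is symmetric around zero only approximately, which is
  the usual (and here empirically adequate) approximation.
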