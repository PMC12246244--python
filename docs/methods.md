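# Methods

This note documents the models, algorithms, numerical conventions and design
choices behind `eegmultiverse`, and what the synthetic studies do and do not
establish about real EEG data.

## Synthetic ERP studies

Each participant's continuous recording is an additive superposition, in
microvolts, on a 28-channel schematic 10-20 layout (including Cz, Fp2 and
the near-mastoid pair P9/P10) plus three periocular source channels
(HEOG left/right, lower VEOG):

| source | model | default | why it is there |
|---|---|---|---|
| background | 1/f^α noise, α = 1, via spectral shaping of white noise | SD 4 µV | canonical EEG noise floor; sets decoding difficulty |
| drift | cumulative random walk, low-passed < 0.1 Hz | step SD 0.1 µV | gives HPF / detrending / baseline correction something to matter for |
| alpha | 10 Hz carrier, slow random envelope, posterior-weighted | 4 µV | dominant trial-to-trial variability; the target of the 6 Hz LPF option |
| line noise | common-phase sinusoid, per-channel gain ≈ 1 | 50 Hz, 2 µV | motivates the 45 Hz LPF ceiling |
| ERP components | Gaussian bumps, sparse topography, class-dependent amplitude | posterior component at 170 ms (2 vs 4.5 µV), centro-parietal at 400 ms (2.5 vs 4.5 µV) | the planted, decodable condition effect |
| ocular artifacts | blinks: ~300 ms half-sine, frontal corneo-retinal topography (positive scalp, negative below the eye); saccades: lateral step in HEOG with frontal-lateral projection | rate 0.25/trial, 80 µV, ρ = 0.3 | target of EOG-correlation ICA; the condition covariance makes artifact correction *cost* decoding performance |
| muscle bursts | 20–60 Hz band-limited noise, ~250 ms Hann envelope, sharp topography at one temporal/peripheral focus | rate 0.2/trial, 20 µV, ρ = 0.2 | target of the slope/peripherality/smoothness ICA criteria |

Event spacing is 1.5 s with ±50 ms jitter; labels are a shuffled balanced
sequence with configurable per-class counts.

Two calibration choices anchor the generator to realistic group statistics.
First, every participant scales all ERP amplitudes by an individual gain
factor, N(1, 0.3) truncated at 0.2 — between-subject ERP amplitude
variability of this order is ubiquitous, and without it across-participant
variance at strong-effect time points collapses and group t values become
implausibly large at moderate sample sizes (this is also why group-level
mixed models carry participant random slopes). Second, the default class
contrasts are set so that the group-mean peak decoding accuracy under the
reference forking path lands in the 0.55–0.7 range typical of published
within-participant ERP decoding; far stronger effects drive accuracies
toward the ceiling of the bounded accuracy scale, which again compresses
between-participant variance and distorts height-sensitive group
statistics.

**Artifact–condition covariance.** The trial-wise artifact indicator is
linked to the class label through a thresholded Gaussian copula: a latent
bivariate normal with correlation r, thresholded at the class and rate
quantiles. r is solved numerically (bivariate normal CDF + Brent's method)
so that the implied binary–binary (phi) correlation equals the requested ρ;
the class latent is drawn from the truncated normal consistent with each
trial's fixed label. Realized correlations converge to ρ (±0.05 at ≥1000
trials; property-tested). If ρ exceeds the Fréchet bound for the margins,
r saturates at ±0.999.

Null studies replace every class-dependent amplitude by its class mean and
force both covariances to zero; labels stay randomly assigned.

**What the generator does not emulate:** real head geometry and volume
conduction (topographies are schematic), non-stationary noise, channel
drop-outs, event-onset hardware delays, overlapping ERPs from fast
paradigms, and the amplitude ratios of any particular published benchmark. Passing tests therefore
establish the *statistical machinery* — calibration, directional effects,
recovery — under a plausible signal model, not quantitative agreement with
any particular real dataset.

## Preprocessing operators

Fixed step order: ocular ICA → muscle ICA → filtering → referencing →
epoching → detrending → baseline correction → peak-to-peak rejection.
"None" levels are identities; a config-driven ordered-step list allows
alternative orders but is not a tested deliverable.

**Filtering.** Linear-phase, odd-length FIR, Hamming window (nominal 0.0194
passband ripple, 53 dB stopband attenuation), applied once with group-delay
compensation (reflect padding, centred convolution) so the net phase shift
is zero. The configured cutoff is the passband edge; the −6 dB point sits
half a transition band outside it, with transition bandwidth
`min(max(0.25·f, 2 Hz), f)` (high-pass) or `min(max(0.25·f, 2 Hz),
Nyquist − f)` (low-pass) and length `3.3 / tb` seconds. This reproduces the
field-standard windowed-design filters tap-for-tap (verified against mne in
the test suite) with one deliberate refinement: the high-pass tap sum is
subtracted from the centre tap, which nulls the DC response exactly (firwin
normalises high-pass gain at Nyquist, which otherwise leaves a ~0.005 DC
leak) at a sub-ripple passband cost. Ripple/attenuation figures are
window-design quantities for the flat regions; the acceptance test measures
them over the passband and the deep stopband (≥3 transition bandwidths past
the edge), where the design meets them.

**Referencing** subtracts the reference signal (Cz, mean of P9/P10, or the
scalp-channel average) from scalp channels only. EOG channels are filtered
like scalp channels but never re-referenced, never enter ICA estimation and
are never interpolated. Referencing, detrending and baseline correction are
exact linear idempotent maps and are tested as such.

**Epoching** uses sample 0 = event onset, a time axis inclusive of both
endpoints (`round((t1−t0)·sfreq)+1` samples), and drops events whose window
leaves the recording. Default window −0.4…0.8 s (1.2 s), accommodating both
the 200 ms and 400 ms baseline options.

**ICA corrections.** Both fit an ICA (FastICA, 20 components, ≤500
iterations, seeded) on a 1 Hz high-passed copy of the scalp channels and
subtract flagged components from the *unfiltered* data. The strict
fixed-point convergence criterion rarely triggers on EEG-like data because
the background is Gaussian — the Gaussian subspace rotates freely without
affecting the non-Gaussian artifact components that get flagged — so a
solution is treated as usable whenever it is finite; a non-finite unmixing
is reported as non-convergence and the data pass through unchanged.

* *Ocular*: components are scored by their maximal absolute correlation with
  the (equally high-passed) bipolar HEOG/VEOG channels; flagging uses
  iterative adaptive z-scoring — flag scores > 3 SD of the unflagged
  remainder, re-score, repeat until stable.
* *Muscle*: three criteria per component — log-log Welch-PSD slope in
  7–45 Hz (muscle: rising spectrum; requires sfreq > 90 Hz, hence applied
  before any LPF), peripherality (|mixing|-weighted mean channel radius) and
  spatial smoothness (Moran-style autocorrelation of the topography over a
  Gaussian distance kernel). Each is z-scored across components; a component
  is flagged when the mean z exceeds 1.0 *and* its spectral slope is
  positive. The absolute-slope gate keeps pure-noise recordings flag-free
  (the 1/f background always has a clearly negative slope).

**Peak-to-peak rejection** (autoreject-style). Per-channel thresholds are
chosen by 5-fold CV on a 25% fitting subset (minimum 20 epochs so the
fold medians stay robust): for each candidate threshold (upper quantiles of
the peak-to-peak distribution plus a keep-everything candidate), the mean
signal of sub-threshold training trials is compared by RMSE with the median
signal of held-out trials; the 1-SE parsimony rule picks the largest
threshold within one SE of the minimum, so clean data selects no rejection.
*Interpolate* mode replaces every bad channel × trial entry by
inverse-distance interpolation over the 4 nearest scalp neighbours (trial
count unchanged). *Reject* mode grid-searches consensus (0.2…0.8) ×
n_interpolate (4…32): trials with more than consensus·n_channels bad
channels are dropped, otherwise up to n_interpolate worst channels are
interpolated; combinations are scored by the same cleaned-mean-vs-median CV
error. If a class falls below the downstream fold count, the forking path
is invalid for that participant and recorded as such (never silently
dropped). Spherical-spline interpolation is out of scope.

## Decoding

At each time point, features are the scalp-channel voltages, standardized
per (channel, time point) with *training-fold* statistics (population SD,
zero-variance features clamped to SD 1, i.e. mapped to zero). This is a
stricter contract than standardizing across all trials before CV; the two
differ only through the (small) train/test mean–variance coupling, and the
strict version removes a known leakage vector, so it is the default and the
only implemented variant. Class weights are inverse-frequency,
`w_c = n/(2 n_c)`, computed on the training fold.

The logistic solver is an in-package damped-Newton (IRLS) minimiser of
`Σ w_i·logloss + ‖β‖²/(2C)` (intercept unpenalized, C = 1), vectorised
across all time points of a fold, with gradient sup-norm tolerance 1e-4 and
at most 100 iterations; Newton steps are capped at sup-norm 10 for
stability on separable folds. It matches scikit-learn's LogisticRegression
to ≲1e-4 in the coefficients (unit-tested). Predicted probability 0.5 ties
break to class 0. Folds are stratified (10-fold time-resolved, 5-fold
trial-wise), shuffled under the config seed. Balanced accuracy is averaged
across folds; chance is 0.5 throughout.

Trial-wise decoding is a plug-in contract (`fit(trials, labels, weights)` /
`predict(trials)`), with a flattened-trial L2 logistic regression as the
reference plug-in standing in for neural-network decoders.

## Cluster statistics

Participant accuracy series are centered by subtracting chance before
anything else; "zero-centering" is thus realized as the standard exact
sign-flip construction (the alternative reading — flip the raw series, then
center the average — is not sign-symmetric under the null and was
discarded). The cluster-forming threshold is the one-tailed t critical
value at p = 0.05 with df = n−1. The Monte-Carlo null flips each centered
participant series by ±1 (1024 draws; the identity flip is not forced into
the sample), exploiting that sign flips leave per-participant squares
unchanged so the permuted t series follows from the flipped means and a
precomputed sum of squares. Cluster p-values use the (b+1)/(B+1)
convention; the `≥` comparison uses a 1e-9 relative tolerance because
identity flips rebuild the observed statistic through different float
arithmetic. Clusters with p ≤ 0.05 are retained; the total T-sum over
retained clusters is the path metric (0 when nothing is significant — with
fewer than ~6 participants no cluster can reach p ≤ 0.05, which is a
property of the test, not a bug). |t| values are clipped at 100, applied
identically to observed and permuted series (an order-preserving transform,
so the test stays exact); this guards against near-zero across-participant
variance, which fold-averaged accuracies can produce at small n.

TFCE uses E = 0.5, H = 2, dh = 0.1 (configurable), integrating
`extent^E · h^H · dh` over positive heights only and summing over time
points; the same t-clip applies.

A *baseline artifact* is any retained cluster whose start time is at or
before the baseline boundary (0 s for stimulus-locked designs; negative
boundaries support response-locked ones).

## Multiverse engine

Paths are enumerated as the Cartesian product of the step grid in
deterministic lexicographic order; the default grid reproduces the full
2·2·4·3·3·2·3·3 = 2592 factorial. The first level of each step is the
smallest intervention and serves as the factorial reference level; for the
referencing step (which has no "none") this is Cz, the single-channel
option. Execution is a pure function of (recordings, path, master seed):
per-stage child seeds are derived from the master seed plus the stage name
and participant — never from the full path id — so continuous-stage results
(ICA, filtering, referencing) can be memoised across paths sharing a level
prefix, and adding paths to a run never perturbs existing ones. Results
live in a long-format table with an explicit status column
(`ok`, `too_few_trials`, `too_few_participants`); group statistics require
a stated minimum number of valid participants. Ranking is dense descending
with ties broken by path id. Single-step substitution compares each
alternative level against a reference path (default: the P9/P10 + 0.1 Hz
HPF + both ICAs + interpolate + 200 ms baseline path).

## Factorial models

The OLS and mixed-model fits delegate to statsmodels behind the module
surface; design construction, EMM math, contrasts and likelihood-ratio
tests are package code. Factors are treatment-coded against the first grid
level; interactions are all two-way (never higher). EMMs are model
predictions averaged over the balanced grid of all other factors (so on a
complete balanced design the saturated model's EMMs equal raw level means
exactly); SEs come from the delta method on the fixed-effect covariance.
Omnibus tests are Wald F statistics on the joint EMM differences with
residual denominator df (the Kenward–Roger refinement for mixed models is
not implemented); pairwise contrasts use the studentized range distribution
(Tukey) within each step, reported alongside unadjusted p-values, with no
correction across steps. The mixed model uses REML with a participant
random intercept; diagonal random slopes (no correlations estimated) can be
switched on per spec but default off — at desk-scale path counts the slope
variance components are weakly identified and materially slow the fit, and
non-convergence is flagged on the result rather than silenced. The
baseline-artifact model is a main-effects binomial GLM (Newton, tol 1e-8,
≤25 iterations); all-equal outcomes and (quasi-)separation produce a
flagged degenerate result without LRTs; per-step LRTs refit without the
step (df = levels − 1, α = 0.01).

## Calibration experiments and problem sizes

`eegmultiverse.experiments` holds the self-contained calibration runs used
by the acceptance script and tests; their sizes are the package's choices
for stable yet portable desk-scale runs:

* **FWER**: 300 null group datasets of 20 participants × 100 time points of
  i.i.d. chance-level accuracy; the empirical rate of ≥1 retained cluster
  estimates the family-wise error, nominally 0.05.
* **T-sum/TFCE concordance**: one default-profile study with 16
  participants and 40 trials/class, run through a 128-path half fraction of
  the two-level grid (every step varies, every two-step combination
  balanced); Pearson r between the two per-path summaries. The two
  statistics weight cluster shape differently — TFCE is roughly quadratic
  in height and square-root in extent, the T-sum linear in both — so their
  linear concordance improves with participant count, which stabilises
  cluster shapes across paths; 16 participants is the largest study that
  keeps the experiment within a desk-scale run.
* **Direction of artifact correction**: a study with strongly
  condition-covarying blinks (ρ = 0.5, rate 0.4, 120 µV) run through an
  8-path grid varying ocular ICA against HPF and baseline; EMM(none) >
  EMM(ica) and a negative single-step substitution delta reproduce, in
  synthetic form, the finding that artifact correction reduces decoding
  performance when artifacts carry condition information.

## Known limitations

* Topographies, and hence interpolation and peripherality, live on a
  schematic 2-D layout; no spherical geometry.
* FastICA with 20 components stands in for picard; the flagging criteria,
  not the unmixing algorithm, carry the scientific content here, and the
  exact upstream z-scoring/thresholding internals are reimplemented from
  their described behaviour, not claimed equivalent.
* The rejection step reimplements the cross-validated peak-to-peak idea in
  simplified form (threshold CV on a proxy statistic, fixed hyperparameter
  grids); it reproduces the contracts (interpolate mode preserves trial
  counts; reject mode can invalidate a path) rather than the reference
  package's exact decisions.
* Group statistics are purely temporal; no channel-adjacency clustering,
  no cluster-depth inference.
* The mixed model's random-slope variant is available but not the default;
  EMM F-tests use residual df.
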