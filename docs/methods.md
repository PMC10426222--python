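# Methods

`angerppg` implements an end-to-end analysis of whether wrist
photoplethysmography (PPG) can distinguish anger from non-anger states in a
heterogeneous multi-day cohort, plus the synthetic data needed to test every
stage of that analysis without access to any private recordings.  This note
documents the models, the parameters that matter, and the design choices made
where the design was genuinely open.

## Synthetic cohort model (`synthetic_cohort`)

Each cohort consists of `n_participants` subjects, a fraction of whom carry a
TBI (traumatic brain injury) metadata flag, each recorded in two day sessions
(`A`, `B`).  A session walks through a scripted elicitation protocol:
resting baselines (300 s), four seated picture sections and four walking
picture sections (120 s each: 20 pictures x 6 s), two self-statement sections
(~7 s per phrase; 50 anger statements, 53 elation statements), a ~15-min
block of nine video clips played back to back, and two 2-min personal-recall
sections.  Emotion sections outside the video block are framed by a 30-s
neutral lead-in and a 90-s neutral tail.  Sections target quadrants of the
circumplex model of affect (valence x arousal); the low-valence/high-arousal
quadrant is the anger target.

**Waveform model.**  PPG is rendered as a train of beat templates: a Gaussian
systolic lobe (delay 0.18 s, width 0.065 s) plus a delayed, scaled Gaussian
dicrotic wave (delay 0.42 s, width 0.09 s, 35 % of systolic amplitude).  The
interbeat interval follows `IBI(t) = 60/HR(t) + sigma(t) * [0.8 sin(2 pi 0.1
t) + 0.5 sin(2 pi f_resp t) + 0.3 N(0,1)]` — a low-frequency (0.1 Hz) and a
respiratory component plus white jitter, the simplest model whose variability
can be scaled up or down.  Respiration also modulates pulse amplitude
(15 % depth) and adds a slow baseline oscillation.  A small white sensor
noise floor (SD 0.02 of unit pulse amplitude) is part of the clean truth.

**Anger effect.**  Anger-state sections shift the ground-truth physiology in
the directions reported for anger in the psychophysiology literature: heart
rate up (`anger_hr_delta`, default +8 bpm), IBI variability down
(`anger_hrv_scale`, default 0.6), pulse amplitude down (`anger_amp_scale`,
default 0.75).  These defaults are order-of-magnitude choices: the
literature reports direction reliably but not a canonical magnitude, and no
per-method intensity is available; they were fixed once as plausible
moderate effects.  A `tbi_effect_scale` multiplier can blunt the effect for
the TBI group; the default (1.0) treats groups identically.

**Non-stationarity.**  Subject parameters (base HR 62–86 bpm, IBI SD
0.03–0.08 s, respiration 0.20–0.33 Hz, amplitude 0.8–1.2) are drawn once per
participant; each day multiplies HR, amplitude, and noise floor by
independent log-normal factors (`day_drift_sd`, default 0.05), emulating
day-to-day physiological and sensor-interface drift without claiming its
mechanism.

**Motion artifacts.**  Accelerometer channels carry resting tremor noise
(SD 0.02 g) everywhere; walking sections add a per-session gait component at
1.5–2.2 Hz plus a second harmonic.  The PPG artifact is a 5-tap causal FIR
mixture of the mean-removed accelerometer channels (resampled to 64 Hz),
scaled so that `motion_gain` equals the artifact-to-signal RMS ratio
(`motion_gain = 1` is 0 dB SNR).  The artifact is linear in the
accelerometer so that a reference-based canceller can in principle remove
it; this is a modelling choice, not a claim about real sensors.

**Labels.**  The valence slider trace (4 Hz — the hardware rate is not
documented anywhere, so a plausible low rate was fixed) is a first-order lag
(tau = 3 s) tracking of each section's target valence plus smoothed noise.
Retrospective words are drawn from the target quadrant's vocabulary; with
probability `miscorroboration_rate` (default 0.08) an emotion section's word
is drawn from a quadrant of opposite valence sign, so the downstream
corroboration screen rejects ~8 % of sections — the order of the 91–93 %
per-group corroboration the study conditions describe.

**What the generator does not emulate:** optics and photon transport, real
beat morphology variation, TBI-specific autonomic mechanisms, emotion
intensity dynamics within a section, or nonlinear sensor artifacts (an
optional quadratic term was considered and dropped — the linear mixture
already exercises the canceller).  Passing tests therefore show the pipeline
recovers *planted* effects of this simple form; they do not show that real
anger is detectable from real wrist PPG.

## Denoising (`ppg_denoise`)

The cleaner follows the combination adaptive + notch architecture used for
wearable PPG heart-rate tracking.  The exact internal topology of the cited
filter is not recoverable from the description this work is based on, so the
cascade here is a documented interpretation: one LMS-Newton canceller per
accelerometer axis (order M = 17, step mu = 9e-5, correlation-memory
alpha = 2e-4, inverse-correlation matrix initialized to delta = 400 times the
identity), followed by an IIR notch (Q = 8) at the dominant accelerometer
frequency of the frame when that peak is at least 4x the band median.  The
inverse-correlation matrix P tracks R^-1 of the exponentially weighted
reference correlation via the matrix-inversion lemma; weights take Newton
steps `w += mu e P x`.  Frames of 10 s advance by 2 s (8 s overlap); filter
state persists across frames within a session and resets between sessions,
so the cancellers converge over minutes of signal.

The cleaned signal is a *reference only*: raw 2-s hops pass downstream when
their Pearson correlation to the reference exceeds 0.6 strictly.  Gate
granularity is one reconstruction hop; the source description says "within
the window frame" without fixing granularity, and per-hop is the finest
choice consistent with the reconstruction scheme.  Accelerometer resampling
is linear interpolation (method unstated in the source; original sample
instants are preserved exactly, at the cost of ~2 % interpolation error on a
2 Hz tone).

## Windowing (`windows`)

Sections corroborate when the valence sign matches the retrospective word's
sign for more than half the section (neutral words: within +/-0.1 of full
scale for the majority).  The majority fraction (0.5) and neutral band
(0.1) are package choices — the principle is stated upstream but not the
thresholds.  Corroborated sections are cut into 70-s windows at 40-s stride
(30-s overlap); a window must lie entirely inside one section (windows never
mix labels) and, when gating is active, all of its 2-s hops must have passed
(`min_pass_fraction = 1.0`; the aggregation from 10-s gating to 70-s windows
is unstated upstream, and requiring every hop is the conservative reading).
Anger = 1 iff the section's word is in the anger vocabulary; all elicitation
methods pool identically.  Participants whose validated windows no longer
cover all five elicitation methods, or with a session lacking any anger
window, are excluded.

## Feature bank (`tsfeatures`)

The bank computes ~330 interpretable statistics per window across 15
operation families: distribution shape, first/second difference summaries,
block stationarity, autocorrelation (lags 1–40), Gaussian auto-mutual
information on the raw and first-differenced series (lags 1–20; the Gaussian
estimator is `-0.5 ln(1 - rho^2)` with the sample correlation plugged in),
three-letter equiprobable motifs on differences (word lengths 1–4), AR fits
of order 1–8 with Schwarz-criterion selection, an order-5
covariance-method AR fit, GARCH(1,2) by Gaussian quasi-maximum likelihood on
AR-prewhitened innovations (Nelder-Mead on the variance recursion;
non-convergence yields missing values), simple exponential smoothing with
the level constant trained on the first half of the window, a least-squares
fixed-order linear predictor trained on the first half and scored on the
second (a deliberate stand-in for subspace state-space identification,
keeping that family's train/predict residual semantics), FFT spectral
summaries, a 2-D time-delay embedding at the first AMI minimum (capped at
20), and wavelet log-variance scaling (db3) estimating the fractional-
Brownian-motion exponent.  A full several-thousand-operation library is out
of scope; the bank concentrates on the families that the screening stage
reports on, plus generic blocks.

Feature ids are `<tertiary>.<output>`; the tertiary token (e.g.
`MF_GARCH_ar_P1_Q2`) names the algorithm family, master operation, and
defining arguments, and is the unit of cross-session aggregation.  Columns
that evaluate non-finite for *any* window are dropped cohort-wide; the
retained matrix is max–min normalized to [0, 1] pooled across all
participants (zero-range columns dropped with a warning).  Pooled
normalization reproduces the upstream analysis exactly; it leaks test-fold
range information into training folds of the classifier, which is inherited
deliberately and noted here.

## Separability screening (`separability`)

Within each session, each feature is scored by the in-sample accuracy of the
best single-threshold rule (both directions; thresholds at midpoints between
adjacent sorted distinct values).  In-sample scoring is deliberate: the
quantity measured is linear separability within the session, not
generalization.  The null is k = 1000 label permutations per feature;
`p = (1 + #{null >= observed}) / (k + 1)`.  "0.01 FDR from the null
distribution" is operationalized as Benjamini-Hochberg at q = 0.01 across
the session's features (per-session, following "for every feature in each
session"); a feature must additionally beat the majority-class baseline
strictly.  Participants are categorized strong / moderate / weak by whether
both / one / neither session reaches 40 significant features.

Top-40 lists (by accuracy, ties broken by feature id) are pooled by tertiary
family; the tally counts *sessions*, not occurrences, since within-session
multiplicity would otherwise exceed the session count.  Stability uses
binary indicator vectors over the tertiary vocabulary: cosine similarity
pairwise, average-linkage hierarchical clustering on Euclidean distances
between the indicator vectors (the upstream analysis does not say whether
clustering used vectors or the similarity matrix; vectors are used here and
recorded in the result object), and groups are connected components of the
cosine > 0.25 graph.  The TBI vs non-TBI category distributions are compared
with the Freeman-Halton extension of Fisher's exact test, computed by full
enumeration of 2 x c tables with the observed margins; on the published
category counts [[13, 7, 2], [5, 4, 1]] it yields p = 0.858.

## Classification (`emoclass`)

The 2-D visual embedding is unsupervised UMAP (n_neighbours = 15,
min_dist = 0.1) with the fuzzy neighbour-graph edges exported.  For
classification, supervised UMAP maps features to a 10-D metric space
(target_weight 0.5 balancing data topology against labels), then an RBF SVM
with balanced class weights is tuned by randomized search (25 draws,
log-uniform over C in [0.1, 100] and gamma in [1e-4, 10]; draw count and
sampling law are package choices) with 5-fold CV.  Evaluation is
leave-one-session-out: the held-out participant-day never enters metric
fitting, SVM training, or hyperparameter search.  The comparator is the
constant all-anger predictor: accuracy = anger prevalence pi, F1 =
2 pi / (1 + pi) — the unique reading consistent with the published
per-participant score arithmetic.  Participant scores are the unweighted
mean of the participant's two sessions.

## Numerical and testing choices

* Determinism: everything is a pure function of configs and integer seeds;
  per-feature permutation streams derive from SHA-256 of the session id so
  p-values reproduce across processes.
* The permutation p of a discrete statistic ties heavily; calibration tests
  therefore check uniformity on randomized (smoothed) p-values from the
  returned null sample and super-uniformity (validity) of the reported p.
* Repeated-seed recovery studies (`experiments`) run scaled-down problem
  sizes chosen up front: a compact ~40-min protocol with the same section
  grammar (~30 windows/session), the feature bank minus the GARCH family,
  k = 200 permutations, 200 UMAP epochs, and motion_gain = 0 (denoise
  recovery is studied separately with seeded 240-s walking recordings at
  0 dB).  Package defaults are unchanged (full protocol, full bank,
  k = 1000, library-default epochs).
* Degenerate inputs: constant windows yield missing model-fit features;
  constant gate segments fail with "zero variance"; degenerate contingency
  margins return p = 1 with a warning; sessions with empty top-feature lists
  score cosine 0 against all others.

## Known limitations

* The generator's anger signature is global and stationary within a session;
  real anger is episodic with onset/decay dynamics, so the pipeline's high
  synthetic recovery scores are an upper bound by construction.
* The GARCH quasi-likelihood uses a bounded Nelder-Mead search; extreme
  parameter corners may return boundary estimates (handled by the validity
  filter when non-finite).
* The adaptive notch can sit near a pulse harmonic when gait and heart rate
  overlap; the correlation quality gate is the safeguard, not the notch.
* Supervised UMAP's transform of far-out-of-distribution points depends on
  neighbour structure; with too few overlapping training structures the
  metric space degrades — the same failure mode the original analysis
  reports for real day-to-day drift.
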