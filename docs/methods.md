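# Methods

## Overview

`thetadefeat` implements an event-locked analysis of two-region local field
potentials (LFP) recorded while a mouse performs a social interaction test:
band-limited power spectra around zone-entry events, the between-phase PSD
change, directed amplitude transfer entropy (ATE) from the basolateral
amygdala (BLA) to the ventral hippocampus (vHPC), and shuffle-controlled SVM
decoding of stress group. Because no public recordings exist for this
paradigm, the package ships a first-class synthetic-data module whose
generative structure matches the assumptions of every downstream stage, so
each stage can be verified against ground truth.

## Synthetic LFP model

Each session is one subject in one test phase (target cage empty, `NO_CD1`,
or aggressor present, `WITH_CD1`). Per region the signal is

    s(t) = A_region · g_phase · m(t) · theta(t) + b(t)

* `theta(t)` — Gaussian noise band-passed to the theta band
  (default 8 ± 4 Hz, i.e. the full 4–12 Hz band), unit RMS. A narrowband
  noise carrier rather than a sinusoid is essential: transfer entropy
  between amplitude envelopes is degenerate when envelopes are constant.
  The bandwidth matters for connectivity: the envelope of band-limited
  noise fluctuates on the time scale of the inverse bandwidth, and an
  overly narrow band produces envelopes so smooth that any lag estimator
  keys on the envelope derivative and biases the recovered delay early.
  With the full-band default the ATE lag is recovered to within one
  envelope sample.
* Directed coupling: the vHPC theta carrier is re-modulated with the
  envelope mixture `(1 − g)·e_vHPC(t) + g·e_BLA(t − τ)` with coupling gain
  `g` and delay `τ` (default 0.1 s). Coupling acts on amplitudes because
  the connectivity measure is amplitude-based.
* `b(t)` — 1/f^α background noise (α = 1), band-limited to the 0.5–250 Hz
  acquisition band, RMS `noise_scale` (default 1, against unit-RMS theta;
  this puts roughly 18% of the background power inside the theta band and
  makes theta the dominant band, as observed in such recordings).
* Events: zone entries drawn from a homogeneous process (default
  15 min⁻¹), thinned so every event keeps a full ±3 s window inside the
  recording and consecutive events are ≥ 6 s apart, keeping epochs
  disjoint. In the 3 s after each entry the theta amplitude is multiplied
  by `m(t) = post_entry_theta_factor` (per phase). A phase-level gain
  `g_phase = theta_gain_with_cd1` elevates theta throughout the With-CD1
  phase; this anticipatory elevation is what lets the With-minus-No PSD
  change be positive before entry and negative after it, matching the
  reported signs.
* Channels: 8 per region (configurable), each the shared region signal
  plus independent white noise (SD 0.5). Channels are averaged before
  analysis.

Default sessions are 90 s per phase at 2 kHz. Real sessions are 600 s; the
shorter default is a deliberate scale reduction that leaves every statistic
well-defined (≥ 6 events per session, ≥ 1800 envelope samples in the
post-entry stage) while keeping cohort-level Monte-Carlo studies cheap.

### Group presets

Only effect *directions* are reported for the spectra (the magnitudes are
figure-only), so preset magnitudes are free parameters chosen once:
susceptible stress raises BLA theta amplitude (1.0 → 1.4), lowers vHPC
theta (1.0 → 0.7), weakens BLA→vHPC coupling (0.6 → 0.25), and deepens the
post-entry theta drop (factor 0.85 → 0.55, chosen so the group ratio of
post-entry PSD-change magnitudes is ≈ 2.6, the reported contrast). The
ketamine preset moves each parameter strictly back toward control; saline
mirrors the susceptible preset.

### Behavior generator

Zone times and tail-suspension immobility are drawn per subject from
zero-truncated normals parameterized by the reported group means and
SEM-derived SDs (SD = SEM·√8). Naive truncation at zero inflates the mean
(≈ 6% for the stressed With-CD1 zone time), so the location parameter is
solved numerically so the *truncated* mean equals the reported mean; the
drawn SD is then fractionally below the nominal SD, which we accept. The
social interaction (SI) ratio is always derived as
time-with-CD1 / time-no-CD1, never drawn directly; subjects with SI ≥ 1 are
labelled resilient and excluded from susceptible-vs-control contrasts.

## Spectral analysis

Short-time Fourier PSD with a 1 s Hamming window on a 0.5 Hz grid
(0.5–90 Hz), hop 0.1 s, density scaling (units²/Hz). The 0.5 Hz grid is
reached by zero-padding the 1 s window to a 2 s FFT. Edge windows whose
support leaves the epoch are dropped, never padded (padding biases the
PSD). Band powers are means of the PSD over delta (0.5–4), theta (4–12),
beta (13–30), low gamma (30–60) and high gamma (60–90 Hz); bands are
closed-open `[lo, hi)` and the printed 12–13 Hz gap is kept verbatim.
Stage membership (pre-entry −3–0 s vs post-entry 0–3 s) is assigned by
window-center time, half-open. PSD values stay in linear units; the PSD
change `With CD1 − No CD1` is a difference of linear values, and dB
conversion (if any) belongs in plotting only.

## Amplitude transfer entropy

Theta envelopes are obtained by zero-phase band-pass (4–12 Hz), analytic
signal magnitude, edge trimming of half the effective filter length, and
decimation to 100 Hz. Transfer entropy is estimated by the plug-in
(histogram) method after equal-occupancy quantile discretization, defaults
k = l = 1 histories and 4 bins — robust at the few-thousand-sample scale of
concatenated 3 s post-entry stages and exactly checkable against a
brute-force enumeration of the joint histogram (the test suite holds them
to 1e−12). Lag convention: the source history ends at `x_{t+1−lag}` when
predicting `y_{t+1}`, so a pure copy process `y_{t+1} = x_t` gives exactly
1 bit at lag 1 and a generator delay of L envelope samples puts the ATE
peak at lag L. The lag sweep defaults to 0–0.5 s in 0.01 s steps; the
curve is summarized by its peak, peak lag and trapezoidal area (bits·s).
Epoch concatenation respects segment boundaries: no embedding vector
spans two epochs. The plug-in estimate of a conditional mutual information
is nonnegative by construction; no analytic bias correction is applied
(small positive bias at finite n is a known limitation, shared by the
surrogate null so comparisons are unaffected). Significance gating uses
circular-shift surrogates of the source envelope (shift ≥ the maximum
lag), which preserve marginals and autocorrelation while destroying the
directed dependence.

## Decoding

Samples are epochs by default (subject-level collapsing available); the
features are the five band powers per region, 10 when both regions are
fused. Each repetition draws a class-stratified subject-level 80/20 split
(all epochs of a subject on one side — subject leakage would otherwise
dominate at this n; stratification is needed because an unstratified
grouped draw leaves the held-out set dominated by one class and biases
accuracy systematically below chance). An RBF-kernel SVM (C = 1,
gamma = 'scale') is fit with standardization inside the pipeline, so
scaling parameters come from training folds only. The shuffle null
re-scores the identical split with the subject→label assignment permuted
within each side of the split: the association between features and labels
is destroyed, labels stay constant within a subject, and both partitions
keep their class balance, centring the null on the majority-class rate. A
circular offset of the label vector is available as an alternative scheme;
with labels contiguous in subject blocks it retains most of the true
alignment at small offsets and produces a much wider null, which is why it
is not the default. Metrics: accuracy, precision, F1 (positive class =
stressed) and ROC AUC from decision scores, reported as mean ± SEM in
percent over repetitions (default 1000 in the CLI; cohort-level studies in
the tests and acceptance script use 200, a scale reduction that leaves the
mean ± SEM estimates stable).

A caution documented by the negative-control test: with ~8 subjects per
class, the space of subject-label permutations is small enough that a null
permutation occasionally reproduces the true labeling, putting an atom at
perfect accuracy in the null distribution. Percentile-based comparisons
against the null need ≳ 12 subjects per class to be meaningful.

## Group statistics

Group summaries are mean ± SEM. Two-group contrasts use Welch's
unequal-variance t-test or a permutation test on the mean difference
(exact at small n); multiple-comparison control is plain Bonferroni
division. The factorial ANOVA machinery used in the original analysis is
deliberately not re-implemented — the package's claims are
simulation-based direction recoveries, not ANOVA-table reproduction.

## What the synthetic data does and does not show

The generator reproduces the statistical structure the analysis relies on:
theta-dominant spectra over 1/f background, envelope-level directed
coupling at a fixed lag, event-locked multiplicative theta changes, group
effect directions, and behavioral group separations at the reported means
and SEMs. It does not emulate nonstationary drift, movement or chewing
artifacts, volume conduction between regions, cross-frequency coupling, or
state-dependent (e.g. locomotion-gated) theta. Passing tests therefore
demonstrate that the estimators recover known structure of the right kind
at realistic sample sizes — not that real recordings satisfy the model.

## Numerical choices and degenerate inputs

* Filters: 4th-order Butterworth, forward–backward (zero phase); >40 dB
  one octave outside the band after the double pass.
* Constant (single-bin) series give a transfer entropy of 0 with a
  warning rather than an error.
* Quantile bins with duplicated edges collapse; the effective state count
  is used for degeneracy detection.
* Band-power ties in dominant-band selection resolve toward the lower
  band (first argmax).
* Events too close to the recording edge are skipped and counted, never
  zero-padded.
* All randomness flows from explicit integer seeds; the pipeline spawns
  per-stage substreams from one master seed, so any stage can be re-run
  without perturbing the others, and two runs from one config are
  byte-identical in `results.json`.

## Problem sizes used by the test suite and acceptance script

Cohort studies use 8 subjects per group (the study's n) with 90 s sessions;
direction-recovery checks use 10–20 replicate cohorts; estimator checks use
10,000-sample envelopes; decoder studies use 200 split repetitions; the
behavioral power analysis uses 200–500 replicate cohorts. These sizes are
the package's defaults for desk-scale verification and are configurable.
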