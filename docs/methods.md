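# Methods

`primeconflict` re-creates, end to end, a masked-prime/flanker conflict
study on synthetic data: a behavioral and EEG cohort generator, the
standard ERP preprocessing protocol, component quantification, the
behavioral statistics, and a data-driven machine-learning procedure that
asks which (electrode, time point) features of the single-subject ERP
predict whether a subject shows a small or a large positive compatibility
effect (PCE). This note records the models, the defaults and why, and what
the synthetic cohorts do and do not establish.

## Task model and behavioral generator

Each trial of the 2 (prime compatibility) x 2 (flanker congruency) x
2 (target direction) design runs fixation (100 ms), masked prime (30 ms),
mask (30 ms), target plus flankers (100 ms), a 2000 ms response window and
a 1000-1200 ms uniform response-stimulus interval; the prime-target onset
asynchrony is therefore fixed at 60 ms. All eight cells occur equally often
(384 trials -> 48 per cell), enforced exactly.

Reaction times are ex-Gaussian — normal(mu, sigma) plus exponential(tau) —
because empirical RT distributions are right-skewed and only condition
means constrain the fit. Condition effects shift mu additively:

* per-subject prime effect `pce_i ~ N(38, 15)` ms added on
  incompatible-prime trials (the cohort-mean PCE to emulate is 38 ms);
* per-subject flanker effect `~ N(14, 8)` ms added on incongruent trials
  (the source study reports the flanker effect only via efficiency scores;
  14 ms is a typical arrow-flanker RT cost at this presentation duration);
* an optional compatibility x congruency interaction term, 0 by default.

With mu = 323, sigma = 40, tau = 80 ms the generator reproduces grand hit-RT
means near 410 ms (compatible) and 448 ms (incompatible). Accuracy is
Bernoulli through a logistic (intercept 3.2; penalties 0.5 for incompatible
and 0.5 for incongruent), which keeps every cell near or above 90% — well
clear of the 75% exclusion bound, matching a task that healthy adults
perform close to ceiling. Error trials carry RTs from the same distribution
and leave the EEG components unchanged; all analyses use correct trials
only, so error modelling is deliberately minimal.

Reproducibility: subject `i` of master seed `m` draws from
`SeedSequence((m, i))`, so any subject's data are bit-identical regardless
of cohort size or iteration order.

## EEG generator

Evoked activity is a sum of Gaussian-envelope deflections (compact support
+-4 widths) with smooth scalp topographies `exp(-angle^2 / 2 sigma_s^2)`
around one or two center electrodes (sigma_s = 0.45 rad). The default set
emulates the protocol's components: prime-locked P1/N1 at P7/P8,
target-locked P1 (P7/P8), N1 (P9/P10), a fronto-central N2 at FCz whose
peak shifts 10 ms later for incongruent flankers (mirroring the
congruency-dependent quantification windows), and a parietal P3 at PO1/PO2.

Condition structure enters through additive amplitude deltas for
incompatible primes and incongruent flankers, and — the key manipulated
property — a PCE-linked scaling: subject i's compatibility modulation is
`delta + g * (pce_i - 38)` with `g` in uV/ms. Defaults give the N2 the
strongest coupling (g = -0.10), the target N1 an intermediate one (-0.08)
and the prime N1 a weak one (-0.03), so cohorts exhibit the qualitative
pattern that larger behavioral PCEs come with larger condition differences
in the conflict-sensitive components.

Background noise has a 1/f amplitude spectrum above a 1 Hz knee with a 5%
white floor, scaled to 10 uV RMS per channel, and is spatially correlated
through a squared-exponential kernel over inter-electrode angles
(length 0.6 rad), then mixed by its Cholesky factor. This is realistic
enough to exercise filtering, rejection, CSD and the statistics at low cost;
it contains no ocular or muscle artifacts (the protocol's ICA step is
therefore not implemented), no non-stationarity, and no trial-to-trial
latency jitter.

The montage ships as a packaged text file: 60 channels plus an Fpz
reference on idealized spherical 10-10-style coordinates (including the
lateral P11/P12, O9/O10 and the older PO1/PO2 names used by the protocol).
Positions are geometric, not digitized.

### The fast condition-average path

Most feature-discovery experiments need only per-subject condition-average
waveforms. `simulate_condition_averages` produces them directly: the
deterministic component sum per condition (congruency pooled) plus one
noise draw scaled by `1/sqrt(n_trials/2)` — the large-sample limit of
averaging epochs. It reuses the same per-subject substreams as the
behavioral generator, so PCE-derived group labels line up. Continuous-EEG
fidelity (filtering, epoching, rejection, CSD) is exercised separately by
the preprocessing tests and the end-to-end pipeline run.

## Preprocessing protocol

Fixed order, enforced by the containers (violations raise
`PipelineOrderError`): band-pass -> average reference -> resample ->
segment -> reject -> CSD -> baseline.

* Band-pass 0.5-20 Hz: order-5 Butterworth applied forward-backward
  (zero phase). The combined roll-off is ~60 dB/octave beyond the edges,
  satisfying the protocol's 48 dB/oct slope with margin (an order-4
  forward-backward design sits at ~48.2 dB, too close to the bound).
* Average reference: per-sample channel mean removed.
* 500 -> 256 Hz by polyphase rational resampling (up 128, down 250) with
  the built-in anti-alias filter; events re-timed to the nearest output
  sample.
* Target-locked epochs of -2000..+2000 ms; only correct trials; targets
  without full margin inside the recording are dropped and logged.
* Rejection (any channel, boundary samples inclusive, ms -> samples by
  half-up rounding): |x| > 100 uV; peak-to-peak > 200 uV within any 200 ms
  window; any 100 ms window with peak-to-peak < 0.5 uV (flatline). The
  implementation uses running min/max filters and is tested for exact
  agreement with a brute-force window scan.
* CSD: spherical-spline surface Laplacian (stiffness m = 4, ridge
  lambda = 1e-5, 50 Legendre terms — the common scalp-EEG defaults, all
  configurable). The transform is precomputed as one n x n matrix. Units
  are labelled uV/m^2 with head radius 1.0 by default; a scalp-realistic
  radius (e.g. 0.1 m) rescales the output by 1/r^2 and is exposed as
  configuration, since the conventional unit depends on that choice.
* Baseline -500..-200 ms before target onset (i.e. before the prime).

Manual inspection steps of the original protocol have no programmatic
counterpart and are replaced by the deterministic criteria above.

## ERP quantification

Per subject and condition cell, epochs are averaged pointwise; mean
amplitudes are taken over closed windows (endpoints inclusive, half-up
ms -> sample rounding at 256 Hz) and then averaged over the component's
electrodes: prime P1 55-70 ms, prime N1 95-110 ms, target P1 155-170 ms at
P7/P8; target N1 240-255 ms at P9/P10; N2 at FCz with 300-320 ms for
incongruent and 290-310 ms for congruent flankers (one component for the
statistics); P3 285-305 ms at PO1/PO2. All windows are stated relative to
target onset, including the prime-associated ones, following the protocol
as printed.

Electrode validation: per component, each electrode's window mean is
compared to the mean of all other electrodes with a paired t-test across
subjects (the procedure names the comparison but not the statistic; the
paired t is the natural choice), Bonferroni-corrected over electrodes, and
selected only when the difference lies in the component's polarity
direction — "larger" means more negative for N-components.

## Behavioral statistics

* Trial filter: correct responses with RT in the closed interval
  [100, 1000] ms (the bounds carry no endpoint language; inclusive chosen).
* Exclusion: mean accuracy <= 75% (inclusive, as stated).
* PCE: mean hit RT(incompatible) - mean hit RT(compatible) per subject.
* Efficiency: accuracy-in-percent / mean-hit-RT-in-ms per condition cell;
  the unit convention is pinned by the printed magnitudes (~0.21-0.25).
* Median split: PCE > median -> large group, ties to small; at n = 243
  with distinct values this forces sizes 122/121.
* Mixed 2 x 2 x 2 ANOVA via exact 1-df contrast algebra: each within
  effect is a contrast score per subject; with a between factor the grand
  (unweighted) contrast mean tests the within effect and the group
  difference in contrasts tests the interaction, both against the pooled
  residual with N - 2 df. For 2-level factors this is algebraically
  identical to the classical mixed ANOVA, every F is the square of the
  corresponding t, and the Greenhouse-Geisser epsilon is exactly 1 (still
  reported for API uniformity). Partial eta squared is F/(F + df_err).
* Chi-square on 2 x 2 tables without continuity correction; Pearson r with
  the t-based p; two-sample comparisons use Welch's correction when a
  Levene test flags unequal variances (the source reports fractional dfs).

## Feature discovery

Inputs are per-subject condition-average waveforms for one prime condition
(congruency pooled). Features are all (channel, sample) pairs in the
half-open window [0, 1.5) s at 256 Hz — 384 samples per channel, 23 040
features for 60 channels; each feature also carries its latency after prime
onset (target latency + 60 ms). The window start is configurable (the
reference feature tables contain a few pre-target latencies, which the
default window excludes).

Procedure, replicating the original protocol when `nested=False`:

1. z-score each feature over subjects (population SD; the convention is
   not stated in the protocol and is documented here); constant columns
   become zero and are flagged.
2. Filter: two-sided independent-samples t per feature between the small
   and large PCE groups; keep p < 0.01.
3. Wrapper: sequential floating forward selection. Forward steps add the
   feature maximizing stratified k-fold CV accuracy of an RBF-kernel SVM
   (C = 1, gamma = 1/(n_features * var), i.e. scikit-learn's "scale";
   hyperparameters unspecified in the protocol, exposed in config); ties
   break to the lowest feature index. After each forward step, a feature
   is removed whenever removal strictly improves the best recorded
   criterion at the smaller cardinality. The per-cardinality best subsets
   and scores are recorded; the reported ordering is the nested chain read
   off those subsets, truncated at the cardinality cap (default 20; the
   demo profile uses 10).
4. Evaluation: for each cardinality c, k = 10 stratified fold accuracies
   of the SVM on the first c features; CI = mean +- t(0.995, 9) * sd/sqrt(k).
   Feature 1 is significant when its CI lower bound exceeds chance (0.5);
   feature c > 1 adds significant predictability when its CI and the CI at
   c - 1 are disjoint (strict).

Two deliberate seeding rules: the wrapper criterion uses a fixed internal
substream derived from the caller's seed, and the evaluation re-divides
the sample afresh with the caller's seed itself. Sharing one partition
between the two would score the selection on its own objective and is
avoided.

### What the pipeline's significance means — and does not

The z-scoring, the filter and the wrapper all see the full sample,
including the subjects later used as CV test folds. The confidence-bound
machinery itself is well calibrated — with a fixed, pre-chosen feature and
null labels, the CI excludes chance in about 1-2% of runs, matching the
nominal one-sided 0.5-1% — but after whole-sample selection the first
feature's cross-validated accuracy is strongly inflated. On null cohorts
(no PCE-linked EEG signal) at demo scale (60 subjects, 16 channels) the
complete pipeline declares at least one significant feature in the large
majority of runs: the best of roughly sixty spuriously filtered features
carries a sample correlation near 0.45 with the labels, and its CV accuracy
(~0.72) sits above chance by more than the CI half-width. This is a
property of the replicated procedure, not of its implementation, and it is
measured, not hidden, by the acceptance audit. The `nested=True` mode
re-fits scaling, filter and wrapper inside every training fold and is the
leakage-free choice for any new data; the paper-faithful mode exists to
reproduce the original analysis.

As a positive control, an injected single-channel, single-latency
PCE-linked effect (1 uV condition delta, 0.12 uV/ms scaling, peak on the
sample grid) is recovered as the first selected feature within two
neighboring channels and two samples in >= 80% of replicates at the same
demo scale.

A classical-ERP baseline pushes the six components' mean amplitudes through
the same z-score/SVM/CV machinery, mirroring the comparison between
data-driven features and conventional ERP measures.

## Problem sizes

Defaults encode the emulated study (243 subjects, 384 trials, 60 channels,
500 Hz). Tests and the acceptance script run the documented demo profiles —
continuous-EEG pipeline at 12-20 subjects, 48-64 trials, 8 channels;
feature-discovery audits at 60 subjects, 16 channels with a cardinality cap
of 10; the null audit over 50 replicate seeds (20 in the acceptance script)
and recovery over 25 (15) replicates — sizes chosen so the Monte-Carlo
bands in the checks are informative while a full run stays cheap on one
CPU. Statistical conclusions at full scale follow the same code paths.

## Known limitations

* No ocular/muscle artifact model and no ICA; rejection is threshold-only.
* Component amplitudes are deterministic per subject given the latent PCE;
  there is no trial-to-trial amplitude or latency variability beyond noise.
* The spherical-head montage is geometric; no forward head model.
* The fast condition-average path bypasses preprocessing by construction;
  agreement between the two paths is established at small scale only.
* Passing tests demonstrate internal consistency and calibration on
  synthetic cohorts; they say nothing about effect sizes in real EEG.
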