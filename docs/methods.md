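# Methods

This note documents the models, conventions and design choices behind
`gazesync`: what the synthetic dyad generator does and does not emulate,
how each estimator and test is defined, and where a genuinely open
design question was settled.

## 1. The synthetic dyad generator

### Gaze behaviour

Each partner's gaze is a semi-Markov process over three states —
`partner`, `puppet`, `inattentive` — coded at 50 Hz, the resolution of
frame-by-frame video coding.  Dwell times are truncated-normal
(floor 0.2 s); the embedded state chain visits states with frequencies
proportional to `occupancy / mean_dwell`, so empirical occupancy
converges to the configured targets as the session grows.  The two
partners' processes are independent: the generator deliberately omits
behavioural contingency (no gaze-following, no partner-responsive
shifts), which is one of its main departures from real interaction.

Defaults describe a naturalistic infant–caregiver play session:

| parameter | infant | adult | why |
|---|---|---|---|
| occupancy partner/puppet/inattentive | .34/.31/.35 | .62/.31/.07 | observed descriptives for this paradigm |
| dwell mean partner/puppet/inattentive (s) | 4.2/3.8/4.3 | 5.5/2.75/0.65 | jointly matches occupancy **and** realistic sender onset counts (~19/12 infant, ~15/29 adult mutual/non-mutual per session) |
| dwell SD | mean/3 | mean/3 | coefficient of variation of naturalistic look durations |
| session length | 386.1 s | — | mean recorded play-session duration |

Mutual-gaze episode duration is an *emergent* dyadic overlap statistic
here (≈2.4 s mean under the defaults, vs ≈2.7 s reported for real
dyads); it is not directly set.  A "sender" gaze event is any frame at
which one partner transitions into `partner`; it is mutual iff the other
partner is already on `partner` at that frame.  Simultaneous shifts
produce one event per shifter.  Time convention: `onset_time =
frame_index / frame_rate` with 0-based frames; EEG sample index =
`round(onset_time × fs)`.

### EEG signal model

Per partner, 32 channels (Biosemi 10-20 labels) at 512 Hz, in µV:

- **Background**: eight 1/f pink-noise sources mixed into all channels
  with positive weights (smooth scalp fields project with the same sign
  into neighbouring electrodes, which is what keeps real channels
  mutually correlated) plus an independent per-channel sensor floor;
  total RMS 25 µV.  Infant EEG background is several-fold larger than
  its evoked responses — that is why ERPs require trial averaging, and
  the generator preserves this ratio.
- **Ongoing oscillators**: 4 Hz (8 µV) and 8 Hz (6 µV) cosines with
  Wiener phase drift (1 rad/√s), phase-coherent within the occipital
  cluster and, independently, within C3/C4, projecting at gain 0.25
  into all other channels (volume conduction).
- **ERP template**: Gaussian components P1 (+5 µV @ 120 ms, σ 30 ms),
  N290 (−6 µV @ 290 ms, σ 40 ms), P400 (+4 µV @ 450 ms, σ 60 ms) added
  to the occipital channels of the responding subject at each onset;
  adult latencies are 100 ms earlier (P1/N170/P300 analogues).  These
  are fixture conventions chosen inside the populations' component
  search windows, not empirical claims.
- **Phase reset**: oscillator phase is pulled toward a target angle
  with weight `reset_strength ∈ [0, 1]` by *circular interpolation of
  the phase over a 50-ms ramp* — amplitude is untouched, so a reset can
  never masquerade as a power artifact.
- **Responding roles**: by default the **sender only** carries ERP and
  reset at its own onsets (the study's empirical pattern); receiver
  responses, mutual-only scoping, common-driver coupling (a shared
  oscillator), directed coupling (lagged injection of one partner's
  central-channel signal into the other's) and biphasic frontal
  saccade-like transients are all switchable ground truths used by the
  mechanism-recovery tests.

Everything is deterministic under `seed` (gaze and EEG use separate
spawned streams, so changing the EEG model never changes behaviour).

### What the generator does not emulate

No behavioural contingency between partners; no inter-onset-interval
matching (only occupancy and dwell statistics are controlled); no
head-geometry forward model (spatial structure is a low-rank positive
mixing, not electrode-distance-dependent); no ocular dipoles (the
saccade transient is a stylised biphasic waveform); stationary
statistics throughout a session.  Passing tests on this fixture
demonstrate that the estimators and inference machinery behave
correctly under a *known* ground truth — they do not certify artifact
robustness on real recordings.

One consequence worth knowing: because a mutual onset requires the
receiver to be mid-look, the receiver's epochs genuinely contain that
subject's *own* earlier sender response at small negative lags, which
bleeds into the post-onset window.  At realistic background levels this
leakage stays sub-threshold; with an unrealistically clean background
it would masquerade as a receiver response.

## 2. Preprocessing

Chain per partner: zero-phase Butterworth band-pass 1–20 Hz (analyses
use wavelets up to 18 Hz; cleaning keeps the stated 20 Hz edge) →
correlation-based bad-channel interpolation → robust (per-sample
cross-channel median) average reference → high-power epoch rejection.

- **Interpolation before referencing.**  A channel is flagged when its
  Pearson correlation with the leave-one-out median of the other
  channels falls below 0.7, and replaced by the median of the good
  channels; more than 50 % flagged aborts.  This criterion is only
  informative while the shared scalp field is present: after per-sample
  median referencing the residuals are centred, and a centred channel
  necessarily anticorrelates with the central tendency of the others —
  every channel, good or bad, would be flagged.  Hence the order used
  here.  (The LOO median is computed in O(n·T) from the per-sample
  sorted values rather than by materialising n leave-one-out copies.)
- **Rejection rule.**  Non-overlapping 1-s epochs; per-channel epoch
  power = variance of the mean-removed epoch; per-channel mean/SD over
  all epochs of the recording; an epoch is rejected when > 70 % of
  channels exceed mean + 5 SD.  The 5-SD statistic is applied
  *per channel* (the pooled-over-channels alternative is ambiguous in
  the source description); the 70 %-of-channels vote is as stated.
  The two partners' masks are intersected so the dyad stays on one
  shared clock.
- **Count matching** between conditions truncates the larger condition
  to its first n trials / samples (the literal "1:n" reading),
  preserving order; it is idempotent.  Trials or looks overlapping
  rejected samples are dropped whole, with reasons logged.

## 3. Time–frequency decomposition

Complex Morlet wavelets, 2–18 Hz in 17 linear steps, cycles log-spaced
3→10, truncated at ±4σ_t.  Kernels are scaled so a unit-amplitude
sinusoid at the matched frequency yields |coefficient| ≈ 1
(amplitude-preserving convention); coefficient angles are the
instantaneous phases consumed by every synchrony statistic, making PLV
and ITC amplitude-invariant by construction.  An `edge_valid` mask
excludes the half-wavelet margin at each boundary.  Note that σ_t =
cycles/(2πf) is *not* strictly decreasing over the last few grid steps
(the cycle ratio per step, 7.8 %, eventually exceeds the frequency
ratio); temporal smearing falls steeply through Theta/Alpha and
flattens above ~13 Hz.  Band averages are unweighted means over grid
frequencies with **inclusive** edges — 6 Hz belongs to both Theta (3–6)
and Alpha (6–9), reproducing the stated band boundaries literally.

## 4. Synchrony estimators

- **PLV / ITC** are direct transcriptions of the mean-phasor formulas;
  unit tests pin them to brute-force evaluation at 1e-12.
- **VAR fitting** is least squares on lagged regressors, pooling
  disjoint segments or trials *without* letting lags cross segment
  boundaries (statsmodels' VAR cannot pool segments, hence the local
  implementation; it is cross-checked against statsmodels on single
  segments).  BIC(p) = ln det Σ̂ + p·d²·ln(T)/T with d = 2; order is
  selected on 1..max_order, per-segment orders averaged and rounded for
  segment collections; the conventional default order is 5.
- **PDC** is the standard column-normalised form
  |Ā_ij|/√(Σ_m |Ā_mj|²).  The source description of the denominator
  mixes bivariate and univariate model coefficients and cannot be
  evaluated as written; the standard form is used and no "as-printed"
  variant is offered.  Σ_i PDC²_{j→i} = 1 per source and frequency is
  an enforced identity.  Direction I→A means the infant channel is the
  source (column).
- **Event-locked PDC** slides a 1-s window (default step 250 ms) across
  the peri-event axis, fitting one VAR per window that pools all trials
  as segments.  The pipeline uses an algebraically equivalent fast
  path: cumulative lagged Gram matrices over the continuous recording
  turn each window-and-trial-set fit into a batched difference-and-
  solve, which makes the random-event surrogate refits cheap.  The fast
  path keeps the p samples of within-epoch history preceding each
  window (legitimate same-trial data); a unit test pins it to the
  reference windowed implementation.
- **Event-locked PLV** is across-trial phase-difference consistency at
  each (frequency, time) point, computed from continuous occipital
  cluster-mean phases sliced at onset times (the within-trial-windowed
  alternative is not offered; the across-trial reading matches the ITC
  construction).  Maps with fewer than 5 trials are flagged
  low-confidence, mirroring the ≥5-onsets participant inclusion rule.

## 5. Inference

- **Dyad-pairing surrogates**: each of n_perm (default 1000)
  permutations re-pairs every infant with a non-partner adult
  (derangement-sampled — "random pairing" with the real partner
  excluded), recomputes the group mean; pair metrics are memoised.
  P-values z-score the observed group mean against the null and read
  the Gaussian upper tail (one-sided: synchrony has a directional
  alternative), with a Bonferroni factor defaulting to the number of
  tests (12 for the non-event family).  The Gaussian read-out is the
  analysis convention reproduced here; on a mildly skewed null it runs
  slightly hot — the acceptance script measures the realised type-I
  rate on uncoupled dyads (`surrogate_rejection_rate_pct`), which lands
  about a percentage point above nominal.  The calibration statement in
  the test suite accounts for this.
- **Random-event surrogates**: onset times drawn uniformly from sample
  positions where a full epoch fits in unmasked data, event counts
  matched per participant; the analysis is re-evaluated per draw.
- **Cluster permutation**: pointwise statistic thresholded at the
  forming alpha (per-point null quantile for baseline tests; two-sided
  paired t across participants for contrasts), 4-connected clusters in
  the (frequency, time) grid scored by mass (sum of |statistic|);
  corrected p = fraction of permutations whose maximum cluster mass
  reaches the observed (with the +1 correction).  Families: inter-brain
  tests at α = 0.025, ITC tests at α = 0.05.  The paired variant's
  family-wise error rate is measured by the acceptance script
  (`cluster_fwer_pct`, ≈4–5 % at nominal 5 %).
- **2×2 RM-ANOVA**: for two-level within factors each effect's
  F(1, n−1) *equals* the squared paired t of its difference contrast;
  the implementation computes exactly that (cross-checked against
  pingouin).  Tukey–Kramer pairwise comparisons use the studentized
  range over the four cell means with the subject-by-cell residual MS
  on 3(n−1) df.  Degrees of freedom are reported as n−1.
- **JZS Bayes factor**: BF10 = ∫ nct(t | δ√n) Cauchy(δ; √2/2) dδ /
  t(t), by adaptive quadrature (cross-checked against pingouin);
  BF01 = 1/BF10.  Note the ceiling of BF01 under an exact null grows
  with n — moderate-evidence bands should be judged relative to the
  cohort size at hand.
- **Power**: r² → r → Cohen's d = 2r/√(1−r²); two-sided matched-pairs
  t power from the noncentral t with ncp = d√n.

## 6. ERPs

Baseline correction subtracts the −1000..−700 ms pre-onset mean.
Component amplitudes use the adaptive-mean approach: peak latency
located in a population-specific broad window (infants P1 100–300,
N290 200–400, P400 300–600 ms; adults 0–200, 100–300, 200–500 ms),
amplitude = mean over peak ± 10 ms ("20-ms window", inclusive),
peak-to-peak = change from the preceding component's adaptive mean
(P1 is referenced to the corrected baseline).  A flat input returns
zero amplitudes at window-centre latencies, flagged.

**Onset permutation test.**  Observed statistics are the adaptive means
around the maximum and the minimum of the grand ERP in 0–500 ms; each
permutation shuffles the time samples of every subject's ERP and
recomputes both; p-values via the z-score/Gaussian procedure (upper
tail for the max, lower for the min), the two statistics forming one
family at α/2 = 0.025.  ERPs are first block-averaged to 50 Hz — the
behavioural coding resolution, at which the ±10-ms adaptive window is
one sample.  This step matters: shuffling whitens the series, so at the
raw 512-Hz resolution the smooth 1–20 Hz background alone inflates the
observed peak statistic relative to the shuffled null and the test
would reject onset-unrelated activity essentially always.  At 20-ms
resolution adjacent samples are near-independent, the test is
calibrated on onset-unrelated data (verified on white noise in the unit
suite and on full receiver epochs in the acceptance suite), and real
deflections remain far outside the null.  `resample_hz` exposes the
choice; whole-epoch shuffling (not circular shifting) is the default
reading.

## 7. Pipeline, problem sizes and determinism

`CohortRunConfig` drives all three families with one seed; per-dyad and
per-stage sub-seeds derive from `SeedSequence([seed, k])` so every run
is byte-reproducible.  Inclusion bookkeeping lists every excluded dyad
with a reason; compared conditions are always count-matched per dyad.

Generator defaults are the study conditions (386.1-s sessions, 512 Hz,
32 channels, 55 dyads is the reference cohort size).  The bundled tests
and the acceptance script run scaled cohorts — typically 12–24 dyads of
240-s sessions with 200 permutations and a 250-ms event-locked PDC
step — chosen so the full chain (including the surrogate refits) stays
comfortable on a single core while leaving every qualitative contrast
far from its decision boundary.  The per-statistic ceilings that scale
with n (Bayes-factor ceilings, minimum attainable permutation p) are
interpreted at the scaled size.

## 8. Known limitations

- Eye-artifact removal (ICA) is out of scope; the pipeline assumes
  pre-cleaned or synthetic input.
- The behavioural generator cannot produce contingent interaction, so
  analyses of sender–receiver *timing* relationships beyond the onset
  definitions are untestable against it.
- The z-score/Gaussian read-out of permutation nulls (a reproduced
  convention) is mildly anticonservative on skewed nulls; empirical
  permutation p-values would be exact but would depart from the
  procedure being reproduced.
- Event-locked PDC pools trials into one stationary VAR per window;
  genuinely non-stationary within-window dynamics are averaged.
- Band edges are inclusive on both sides, so 6 Hz contributes to both
  Theta and Alpha averages; band statistics are therefore not
  independent across bands.
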