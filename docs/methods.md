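# Methods

`hrvtriage` implements an end-to-end risk-stratification pipeline for
critically ill emergency-department patients: short-term heart-rate
variability (HRV) extraction from a single-lead ECG, the modified early
warning score (MEWS) as the clinical comparator, a cluster-distance +
imbalanced-ensemble machine-learning (ML) risk score, and a paired
diagnostic-accuracy battery for comparing the two scores on the same
patients. This note records the models, the parameter choices that matter,
and what the synthetic generators do and do not emulate.

## ECG preprocessing

The pipeline assumes a single-lead ECG sampled at a nominal 125 Hz — the
export rate of defibrillator-monitor review software, sufficient for QRS
timing though not for high-frequency morphology.

**Band-pass filter.** 5–28 Hz, 4th-order Butterworth, applied
forward-backward (`sosfiltfilt`) so that the response is zero-phase and
beat positions are not shifted. The band suppresses baseline wander
(< 1 Hz) and mains interference (50/60 Hz) while preserving QRS energy.
Only the band edges are externally prescribed; the order and realization
are this package's choices, validated against the analytic frequency
response (≥ 20 dB attenuation at 0.5 Hz, ≤ 3 dB ripple at 15 Hz).

**QRS detection.** A threshold-plus-derivative scheme: the squared first
difference of the filtered signal, smoothed with a 120 ms moving average,
is compared against an adaptive threshold equal to 0.4 × the rolling 95th
percentile of that energy over 10 s blocks, with a 200 ms refractory
period. Detections are snapped to the local extremum of the signal within
±60 ms. The published method this follows is described only qualitatively;
the constants here are one faithful instantiation, chosen for testability
against generator ground truth (recall and precision ≥ 0.98 at 15 dB SNR
across 50 seeds).

**Beat classification.** Ectopic beats are flagged by robust outlier rules
on the quantities a human over-reader uses — QRS size, shape, and spacing:

* height: robust z-score vs the running median (MAD scale, floored at 10%
  of the median height so that homogeneous tracings are not over-flagged)
  above 3;
* width: half-height width above 1.5 × the median width, measured on the
  *unfiltered* signal (the band-pass largely equalizes template widths);
* prematurity: interval since the last sinus-labelled beat below 0.8 × the
  running median RR. Referencing the last *sinus* beat rather than the
  immediately preceding beat prevents the post-ectopic beat from being
  flagged as well.

These thresholds are package choices, not published values.
Atrial-fibrillation screening is out of automated scope; callers can mark
such records via the `af_flag` argument of `process_record`.

**NN extraction and QC.** NN intervals are formed only between consecutive
sinus-labelled beats (pairs bridging an ectopic or artifact are dropped).
A recording is eligible for HRV when at most 30% of its duration is
covered by artifact/ectopic spans; the burden is measured in *time*, not
beat count, and the flagged spans are reported for trimming. A 5-minute
minimum recording length applies.

## HRV parameters

Time-domain: aRR (mean NN), STD (SD of NN, n−1 denominator), avHR and sdHR
(mean/SD of the beat-wise instantaneous rate 60/NN), RMSSD, nn50 and pnn50
(successive differences beyond 50 ms). Intervals are reported in seconds
throughout; published tables that label RMSSD in "ms" with magnitudes near
0.04 are consistent with seconds, and this package labels units explicitly.

Geometric: NN histogram with fixed 1/128 s bins anchored at zero. The RR
triangular index is the total count divided by the modal bin count; TINN is
the base width of the least-squares triangular fit to the histogram,
found by exhaustive search over base endpoints on bin edges with the apex
fixed at the modal bin. Both are validated against independent loop-based
oracles. The bin width is configurable: published triangular-index values
near 2.5 imply a coarser histogram than the 1/128 s convention, but no
basis exists to reverse-engineer the original width, so the conventional
default stands.

Frequency domain: the Lomb–Scargle periodogram of the mean-subtracted NN
values at their actual beat times — the estimator of choice for unevenly
sampled tachograms, avoiding resampling. Grid 0.003–0.4 Hz in 1 mHz steps.
The raw periodogram is scaled by `2 · t_span / n` so that trapezoidal
integration over a band approximates that band's contribution to the NN
variance (a sinusoidal modulation of amplitude A integrates to ≈ A²/2;
verified to 15% in tests). Bands: VLF 0.003–0.04, LF 0.04–0.15, HF
0.15–0.40 Hz (the conventional short-term defaults; the VLF lower edge is
set at 0.003 Hz rather than 0). Normalized powers are 100·LF/(LF+HF) and
100·HF/(LF+HF), undefined (NaN) when LF+HF = 0.

## MEWS

Five components (respiratory rate, heart rate, systolic pressure,
temperature, AVPU) each binned to 0–3; total 0–14. The published bins are
integer-labelled, which leaves gaps for fractional inputs; inputs are
rounded to the bins' printed resolution first (HR/RR/SBP to integers,
temperature to one decimal, ties half-even as Python rounds), making the
bins exhaustive and non-overlapping — verified by exhaustive sweep. A
missing component raises rather than silently scoring zero. The screening
cutoff is total ≥ 3.

## ML risk score

Feature vector (fixed order): age; heart rate, respiratory rate, systolic
and diastolic pressure, SpO₂, temperature, GCS; then the 16 HRV
parameters. GCS is included because the source cohort tabulates it among
vital signs; a config switch can drop it. Features are z-scored with the
training rows' mean/SD (Euclidean distance on raw mixed units would be
meaningless); constant features get unit spread so they carry no distance.
Missing entries are imputed with training-cohort medians; a record with
more than 50% missing features is rejected.

**Base score.** Class centroids μ₊, μ₋ are the standardized means of event
and no-event rows. A patient's base score is `100 · d₋ / (d₊ + d₋)`
(Euclidean distances to the centroids): bounded, 0/100 at the centroids,
50 on the midplane, and symmetric under label swap (score → 100 − score).
The mapping from the two distances to a score is a design choice of this
package; a logistic transform of d₋ − d₊ would be a reasonable alternative
and the chosen form was preferred for its forced endpoints.

**Imbalanced ensemble.** Events are rare (≈ 4.6%), so the majority class
is shuffled (seeded) and partitioned into N disjoint groups covering it;
each group ∪ all minority rows forms one balanced training set for a
linear SVM (`SVC(kernel="linear", C=1)` — the linear kernel is the
published classifier choice; C is untuned). The ensemble's majority vote
adjusts the base score by ±δ, clamped to [0, 100]. Defaults: N =
floor(majority/minority); δ = 15 (one stratum width, so a vote can move a
mid-scale patient across one boundary but not two). Both are configurable;
neither value is published.

**Strata and cutoff.** Low ≤ 40 < intermediate ≤ 60 < high ≤ 100. The
screening cutoff is score ≥ 60. The published stratum boundary
("intermediate 41 to 60") and cutoff ("≥ 60") collide at exactly 60; both
are implemented as configured and not reconciled.

**Validation.** Leave-one-out: for each held-out patient the scaler,
centroids and ensemble are refit on the n−1 remaining rows. In the
acceptance battery the LOO runs use N = 5 partitions: each balanced set
then contains ≈ 176 majority + 43 minority rows at the study-scale
cohort's class balance, several times the minority count, and the 20-seed
battery completes in a few minutes of CPU. In-sample centroid scoring is
optimistically biased (each class mean is closer to its own members);
LOO removes this, which is why null calibration is checked on LOO or
out-of-sample scores only.

## Evaluation statistics

* AUROC by the tie-corrected Mann–Whitney rank formulation; the ordinal
  comparator score enters as its integer thresholds. Verified against
  exhaustive pairwise concordance for n ≤ 12.
* Paired AUROC difference: z-test with the DeLong placement-value
  covariance (Hanley–McNeil correlated approximation available), Wald 95%
  CI. Identical inputs give Δ = 0, p = 1.
* Threshold metrics with Wilson score CIs (Clopper–Pearson optional) and
  the log-method CI for LR+. PPV/NPV are reported missing when the
  relevant outcome class is absent.
* Paired sensitivity/specificity: McNemar chi-square (1 df, no continuity
  correction) on discordant pairs within the event (sensitivity) or
  non-event (specificity) stratum; the difference carries a Tango-type
  score CI obtained by numerically inverting the constrained-MLE score
  statistic.
* Paired predictive values: a cluster-robust generalized score test (GEE
  with identity link and working independence on the records where each
  test is positive — or negative, for NPV — with patient as the cluster),
  chi-square 1 df. This is an interpretation of the briefly-cited
  published approach; its type-I error calibrates to ≈ 5% in null
  simulation (1,000 replicates).
* `reconstruct_2x2` rebuilds integer confusion cells from (n, events,
  sensitivity%, specificity%) with half-away-from-zero rounding, enabling
  arithmetic checks of published tables. One published comparator cell
  (arrest-outcome PPV) is internally inconsistent with its own printed
  sensitivity/specificity by 0.1 at printed precision; the reconstruction
  reports the arithmetically consistent value.
* Strata event rates with exact binomial CIs.

## Synthetic data: what it does and does not emulate

**Tachogram** — NN(t) = mean + LF·sin + HF·sin + Gaussian jitter: the
simplest process with controllable spectral content. It does not model
respiratory-coupled RSA, circadian drift, or pathology-specific HRV
phenotypes. Defaults (0.8 s mean, 0.03 s amplitudes at 0.1/0.25 Hz,
5 ms jitter, 5 min) represent an unremarkable resting recording.
Ectopics are inserted as premature beats at 45% of the local cycle;
artifact is modelled as contiguous corrupted spans.

**ECG rendering** — a Mexican-hat QRS-like template at each beat time,
0.3 Hz baseline wander, white noise at a chosen SNR; ectopic beats are
rendered at twice the amplitude and width. No P/T waves, no electrode
artifacts, no morphology variability — so detector tests certify the
algorithmic logic, not performance on clinical tracings.

**Cohort** — class-conditional Gaussians for all 25 features with
means/SDs set to the published case-mix of a critically ill ED cohort
(n = 925, 4.6% arrest prevalence); GCS, reported only as median (IQR), is
approximated as N(14.6, 1.2) vs N(13.0, 3.0). Draws are intentionally
unclipped and, by default, uncorrelated between features (an
equicorrelation option exists): the generator targets its configured
moments exactly (verified to 3 SE), at the price of occasional
physiologically impossible values and of ignoring the strong correlations
among real HRV indices. Consequently the synthetic LOO AUROC (~0.85)
overstates what the same features achieve on real patients (published
cohort AUROC ≈ 0.78), and the acceptance battery asserts only that the
synthetic discrimination is material and that label shuffling destroys it.

## Problem sizes and numerical choices

The acceptance battery runs the study-scale cohort (n = 925) for 20 LOO
seeds with the 5-partition ensemble, 50 detection seeds at 15 dB SNR, 200
random tachograms against the brute-force HRV oracles, and 1,000-replicate
null simulations for the paired tests — sizes chosen so the full suite
completes in a few minutes on one CPU while keeping binomial noise on the
calibration checks within the asserted bands. Degenerate inputs are
handled explicitly: identical centroids score 50 with a warning; constant
tachograms yield zero power and undefined normalized units; empty strata
report missing rates; a vanished class in a LOO fold falls back to
centroid-only scoring.

## Known limitations

* The QRS detector and ectopic rules are tuned on the synthetic render,
  not on annotated clinical ECGs; constants would need revalidation before
  any clinical use.
* The published cohort's AUROCs are not reproducible without the original
  data; the package reproduces the published table arithmetic and the
  method's behaviour on synthetic cohorts instead.
* The imbalanced-ensemble fine-tuning is implemented as described at the
  mechanism level (partition, balance, vote, fixed increment); the
  original score-adjustment magnitude is unpublished.
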