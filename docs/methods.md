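# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `fallsense`. It is the package's own
account of its science; every empirical statement here is computed by the
test suite or the acceptance script, not asserted from elsewhere.

## 1. Problem and pipeline

The package classifies stroke survivors as high vs low fall risk from
inertial recordings of a ten-task clinical battery: balance with eyes
open/closed (30 s), Timed Up and Go (3 m), 10 Meter Walk Test, and
five-repetition Sit-to-Stand, each with and without a concurrent cognitive
load (counting backwards from 200 by 10). Eight sensors — feet, shanks,
thighs (bilateral), pelvis and thorax — record 3-axis segment angle (deg),
angular velocity (deg/s) and gravity-free linear acceleration (m/s²) at
60 Hz, in a subject frame with axis 1 anterior, axis 2 rightward
(medio-lateral), axis 3 downward.

Stages: low-pass filtering → test-specific event detection → a 92-feature
table (42 single-task motion + 42 dual-task motion + 8 clinical) → binary
classification under leave-one-subject-out (LOSO) cross-validation with
heuristic forward feature selection → optional sensor-configuration ×
test-battery search.

## 2. Filtering

All channels pass an order-4 Butterworth low-pass with a 5 Hz design cutoff,
applied forward-backward (zero phase) so that event timing downstream is not
skewed by group delay. The cutoff is interpreted per pass: the two-pass
magnitude at 5 Hz is 1/2 (−6 dB) while a single pass gives the textbook
1/√2. Zero-phase filtering pads with an even (reflective) extension of
3 × order samples, making outputs bit-stable across runs. Series shorter
than the padding raise an error rather than being silently truncated.
Whether the original analysis filtered angular velocity as well as
acceleration is not documented; we filter every channel, with the channel
list per task held in `features._TASK_CHANNELS` (only channels a task's
extractor reads are filtered).

## 3. Event detection

All detectors use relative (scale-free) thresholds, so detected event
*times* are invariant to positive rescaling of the signal and equivariant
to time shifts. Events are reported in seconds from trial start; sample
indices are 0-based; intervals are half-open.

**Gait events.** Candidate peaks of the resultant shank (or foot)
acceleration above `median + 3·MAD`, separated by at least 0.4 × a stride
prior (1.1 s default, or 120/cadence when a cadence prior is given). Heel
strikes are the candidates reaching ≥ 50 % of the tallest candidate; the
toe off for each heel strike is the highest minor peak in a physiological
window before it (0.1 s to max(0.6 s, 0.55 × local stride), the local
stride estimated from neighbouring heel-strike spacing so slow dual-task
gait with long swing stays covered) that reaches ≥ 10 % of the heel-strike
height (this floor keeps zero-phase filter ringing out of the toe-off
lists). Inputs with no usable peaks return empty event lists with a warning
flag, never an exception. Equal-height candidates resolve to the earliest.

**TUG phases.** Six boundaries: t1 = onset of the first thorax pitch
angular-velocity lobe (sit-to-stand start); t2/t4 = first foot transient
after the preceding transition ends (0.15 s lookback margin); t3/t5 =
onsets of the two thorax yaw lobes (turns); t6 = offset of the final pitch
lobe (seated). Lobes are peaks ≥ 50 % of the tallest on the rectified
channel that are at least 0.25 s wide at half height (width separates
movement lobes from noise spikes); onset/offset are the 10 %-of-peak
crossings, refined to sub-sample precision by linear interpolation between
the bracketing samples. Missing anchors produce a result with
`valid=False` and diagnostics naming the failed boundary.

**STS cycles.** The same lobe machinery on the (mean bilateral) thigh pitch
angular velocity; consecutive lobes pair into (rise, descent) cycles, giving
quadruples (start, sit→stand end, stand→sit start, end). An odd lobe count
sets a warning; a detected count differing from `expected_cycles` sets a
mismatch flag — never silently corrected.

With noise-free synthetic input, every temporal feature derived from these
events lands within one sample (1/60 s) of its annotation-derived value
(verified in the acceptance suite); at the generator's nominal noise ≥ 95 %
of gait events fall within ±50 ms of truth and TUG boundaries within
±100 ms over 100 seeded trials.

## 4. Feature pool

The 92-entry catalogue follows a fixed grammar: optional `Dual_` prefix,
optional `CE_` (closed eyes), a test tag and a descriptor. Units are
seconds for durations, steps/min for cadence, m/s² for accelerations,
deg/s for angular velocity.

Interpretation choices where the descriptor alone underdetermines the
computation:

* Balance "Linear Acc k" = standard deviation of the mean-removed filtered
  acceleration over the 30 s trial (axes 1–3; axis 4 is the resultant).
  Equal to the RMS after mean removal; chosen as the minimal sway-magnitude
  summary consistent with "medio-lateral trunk sway" being the flagship
  feature.
* `STS_Thorax Ang Vel` = mean over cycles of the peak resultant thorax
  angular velocity within the cycle; the `std` variant is the std over
  cycles. Same for the pelvis.
* `10MWT_Single Support` = mean single-support duration, computed as the
  contralateral swing (TO → next HS of the other foot).
* `10MWT_Step` = total heel-strike count; `TUG_Cadence toward Cone/Chair`
  is computed over the respective walk phase only, 60 · steps / duration.
* `TUG_Walk toward Cone/Chair` are durations in seconds (a speed variant,
  3 m / duration, is derivable but not a catalogue column).
* Gender is encoded M=0 / F=1; binary questionnaire items yes=1. Dual-task
  features are plain recomputations on dual trials, not dual-task-cost
  ratios.

Each motion entry also records which sensor placements it needs, as a tuple
of alternatives (e.g. step counts need shanks *or* feet; TUG phase timing
needs thorax + both feet; STS trunk/pelvis peaks need thighs + that
sensor). This map is data, editable without touching code, and drives the
configuration search. Clinical entries need no sensors and are available
under every configuration.

## 5. Classification and selection

Classifiers: linear-kernel SVM (C=1), L2 logistic regression (C=1), and a
random forest. Standardization (fit on training rows of each fold only) is
mandatory for SVM and logistic regression and optional for the forest.
The forest uses 100 trees for final reported models; during wrapper
selection, candidate sets are scored with a 25-tree forest and the winning
set is rescored at 100 trees — at n=21 subjects and ≤ 3 features this is
statistically ample, and it keeps the ~6,000 LOSO fits of a full wrapper
search tractable on one CPU. Candidate scoring prunes a LOSO loop as soon
as the candidate can no longer reach the incumbent accuracy; pruning is
exact because the incumbent is only replaced on a strict lexicographic
improvement (higher accuracy, then higher sensitivity, then lower catalogue
index; on a plateau the first step attaining the maximum wins).

Selection modes. *Pooled* scores a candidate set by its LOSO accuracy over
all subjects and reports one global feature set and trajectory. This is the
reporting style of single-trajectory feature-addition plots, and it is
optimistically biased: every subject's label participates in the selection.
*Nested* reruns the whole selection inside each of the n training folds
(via `ForwardSelectingClassifier`) and aggregates only hold-out
predictions, which is the honest generalisation estimate; its summary
feature list ranks features by how many folds chose them. Both modes are
first-class; pooled is the default because it reproduces the analysis style
the pipeline emulates, and the bias is documented here.

Metrics: faller = positive class; sensitivity TP/(TP+FN), specificity
TN/(TN+FP). On an 11/10 split, printed metrics of 0.91/0.82/1.00 are
consistent with exactly one confusion matrix (TP=9, FN=2, TN=10, FP=0),
which fixes the positive class; a metric whose class is absent is reported
as NaN, never 0. Reports print to two decimals; stored values keep full
precision.

Ablations: `no_motion` restricts candidates to the 8 clinical features,
`no_dual` drops the 42 `Dual_` columns.

## 6. The synthetic-data generator

The generator is a validation scaffold, not a biomechanical model: no
public description of the real signals exists, so each task is scripted
from deterministic motifs with exact ground truth, and all group structure
enters through explicit multipliers.

**Motifs.** Postural sway is white noise shaped by an order-2, 1.2 Hz
low-pass, rescaled to an exact target standard deviation per axis (thorax
base 0.08/0.06/0.04 m/s² anterior/ML/vertical; pelvis ×0.8, thighs ×0.5;
eyes closed ×1.35). Heel-strike and toe-off transients are symmetric
Gaussian bumps (σ = 25 ms, amplitudes 4.0 and 1.5 m/s²) — symmetric so
that zero-phase filtering preserves the peak time exactly. Transition
lobes (TUG pitch/yaw, STS thigh/trunk/pelvis) are Gaussian with
σ = duration/4.29, which places the 10 %-of-peak crossings exactly on the
scripted phase boundaries, so the onset detector has an unambiguous truth.
Sensor noise is additive white (std 0.02 m/s² and deg/s — the noise class
of modern wearable IMUs; configurable).

**Pace and timing.** Base non-faller values: stride time 1.15 s (CV 4 %
stride-to-stride), swing 40 % of the cycle, gait speed 1.0 m/s, TUG
sit-to-stand 1.6 s / turn 2.0 s / turn-and-sit 2.6 s with 3 m walks, STS
rise 1.2 s / stand 0.5 s / descent 1.3 s / sitting gap 0.8 s, five cycles.

**Heterogeneity** (all log-normal unless stated; values frozen at design
time from a distribution-level calibration study, before the pipeline was
built): latent mobility m ~ U(0.6, 1.0) scaling all difficulty as m^(−1/2);
per-subject sway factor σ=0.12 and pace factor σ=0.25 (stroke cohorts are
far more heterogeneous in timing than in sway magnitude); a per-subject
anthropometric stride-length factor σ=0.08 (without it, step counts would
be a deterministic function of group — an unrealistic give-away); a
per-axis-per-sensor sway idiosyncrasy σ=0.10; a per-trial "day form"
factor σ=0.12 shared by all channels of a trial; per-parameter jitter
σ=0.05; lobe amplitude jitter σ=0.08.

**Group effects** (`effect_profile`, all overridable): faller sway std
×1.5, faller transition times ×1.3, faller gait speed ×0.8 (stride time
also ×0.8^(−1/2), so cadence and stride length both degrade), dual-task
cost ×1.2 for fallers vs ×1.05 for non-fallers applied to durations and
sway on dual trials. Each faller additionally carries a *dual-task
unmasking* trait γ ~ U(0, 0.5): the sway multiplier is F^(1−γ) on
single-task trials and F^(1+γ) on dual-task trials (F the sway multiplier).
This reflects deficits that only surface under divided attention and is
what makes dual-task balance features, not their single-task twins, the
most discriminative — the qualitative finding the generator is required to
emulate. With all multipliers at 1 the trait cancels (F^x = 1) and faller
and non-faller trials are exchangeable by construction; the test suite
verifies bit-identical twin trials under the null and chance-level
classifiers on null cohorts.

**Clinical table.** Sampled from the printed group statistics: short FES-I
as a rounded truncated normal (fallers 13.1 ± 5.1, non-fallers 9.1 ± 3.0,
clipped to [7, 28]); binary items as Bernoulli with the printed group
proportions; age/height/weight normal per group; BMI computed from height
and weight. Clinical group differences are baked in regardless of the
motion multipliers — the null-calibration analyses therefore evaluate
motion features only.

**What the generator does not emulate.** Musculoskeletal realism, sensor
orientation/fusion error and drift, gravity leakage, magnetometer effects,
turning asymmetries, freezing or paretic-side-specific gait, and the actual
fall events (labels are group assignments). Passing tests therefore show
that the pipeline recovers what was scripted at realistic noise and
heterogeneity — not that it would reach any particular accuracy on real
stroke cohorts.

## 7. Null calibration and evaluator bias

Leave-one-out with near-balanced classes has a known pessimistic
pathology: with strong regularisation the prediction follows the
training-fold majority, which is biased *against* the held-out label, so
null accuracy lands below 0.5 (we measured ≈ 0.41–0.47 for strongly
regularised linear evaluators on exchangeable data). The null-calibration
tests therefore use a weakly regularised logistic evaluator (C=10) over ten
spread motion features, whose null mean we measured at ≈ 0.495 — close
enough to chance that the binomial band tests the generator's
exchangeability rather than the evaluator's own bias. The planted-effect
suite (20 seeded cohorts at default effect sizes) checks that the median
pooled LOSO accuracy of the tree-ensemble pipeline is ≥ 0.85 and that a
dual-task balance sway feature appears among the first three selections in
at least half the seeds.

## 8. Problem sizes used by the test and acceptance suites

Chosen as the package's own evaluation design: segmentation recovery uses
100 seeded trials per task family; parameter recovery uses a 4-subject
noise-free cohort plus the full 21-subject nominal cohort; the metric
oracle uses 1,000 random fixtures; null calibration uses 50 label
permutations of one null cohort (band ±0.030 around 0.5) and 12
independent null cohorts (band ±0.062); planted-effect recovery uses 20
seeded 21-subject cohorts. The acceptance script simulates a single
five-repetition STS trial and reports the detected cycle count.

## 9. Known limitations

* Pooled-mode accuracies are selection-biased upward; use nested mode for
  generalisation claims.
* The sensor-requirement map reflects which signals drive each computation
  here; other instrumentations may compute e.g. TUG phases from different
  sensors, and the map is deliberately editable data.
* The exhaustive configuration search is desk-scale (≤ ~25 configurations
  × 175 test subsets) but still hours of compute with the tree ensemble on
  one CPU; use the linear models or restrict `max_tests` for exploration.
* Event detectors assume one task execution per trial and the scripted
  motif polarity (e.g. impact transients dominate the shank resultant);
  real-data use will require revisiting thresholds, which are all exposed
  in `SegmentationParams`.
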