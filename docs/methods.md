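# Methods

## Data model

Behavioural observations are half-open events `[start_s, end_s)` in seconds
from the start of recording, coded against a calf ethogram and grouped into
four categories: resting (lying), active (standing, walking, posture
change, feeding, side-stepping), play (locomotor play only), and meta
(management, out-of-view).  Timestamps read from file are truncated to
whole seconds, the synchronisation accuracy of video-coded logs.  A point
event (zero duration) marks presence at its start second.  Head-only head
shakes involve no leg movement and are excluded from the locomotor-play
category by default (`include_head_only_play` restores them).

A *bout* is a maximal episode: events of one category separated by gaps of
at most `max_gap_s` (default 1 s) merge, so a play bout ends only when play
is discontinued for more than one second; brief within-bout pauses count
toward the bout's span.  Time budgets report, per window, the union
duration and bout count of lying, play, active-excluding-play and
active-including-play (the union of active and play events, so contiguous
active+play time is one bout).  A bout overlapping a window boundary counts
as a bout in every window it touches — whether a straddling bout should
count was genuinely open; any-overlap was chosen because one-zero logic
downstream uses the same convention.

The motion index is a non-negative value per interval on a regular grid at
one of the logger's export resolutions (1 s … 1 week).  Aggregation to a
coarser resolution **sums** constituent values: the MI is a total
accumulated over its interval, and summing preserves the relationship
between fine- and coarse-resolution thresholds.  Trailing partial
intervals are dropped (analysis uses complete intervals only).  Gaps in an
MI export are a hard error — calves with sensor malfunction are excluded,
not imputed.

The on-device MI formula is proprietary.  `surrogate_mi` is a documented
stand-in used only for simulation and sanity checks: per interval, the
scaled sum of absolute deviations of the acceleration magnitude
`sqrt(ax²+ay²+az²)` from the per-interval median magnitude (the gravity
baseline), rounded to whole integers.  It is orientation-invariant, zero
for a still sensor, and linear in deviation amplitude before rounding.
Nothing downstream depends on its exact form: the analysis consumes MI
values, not raw acceleration.

## Synthetic cohort generator

The generator emulates the behaviour structure of calves up to 48 h old:

| parameter | default | meaning |
|---|---|---|
| `n_calves` | 10 | cohort size |
| `duration_s` | 172 800 | 48 h per calf |
| `lying_fraction_target` | 0.80 | expected lying fraction |
| `mean_lying_bout_s` / `mean_active_bout_s` | 1800 / 450 | exponential posture bout means (rescaled to the lying target, cycle length preserved) |
| `play_bout_rate_per_h` | 9.0 | marginal play-bout rate per hour of **standing** |
| `bouts_per_session_mean` | 2.7 | bouts per play session (1 + Poisson) |
| `within_session_gap_s` | 40 | mean gap between bouts in a session |
| `play_bout_duration_median_s` / `sigma` | 6 / 0.5 | log-normal bout duration |
| `mi_rate_lying/active/play` | 0.005 / 0.5 / 60 | per-second Poisson MI rates |
| `transition_spike_mi` | 30 | MI added at each posture transition |
| `out_of_view_rate_per_h` | 0.1 | meta-event overlay |

Posture alternates lying/standing with exponential bouts.  Play occurs only
while standing (locomotor play requires being on the feet) and is
**clustered**: sessions arrive as a Poisson process within standing time at
rate `play_bout_rate_per_h / bouts_per_session_mean`, each a burst of
short bouts separated by > 1 s (so bouts remain distinct episodes under the
1 s merge rule).  Clustering, rather than a flat Poisson bout process, is
what lets a single parameter set land in the realistic prevalence window
at *both* resolutions — roughly 2–3% of 1 min intervals and 11–15% of
15 min intervals play-positive — and it is also why the optimal 15 min
threshold is far below 15× the 1 min threshold.  The two clustering
defaults (bout rate 9/h of standing, 40 s within-session gaps) were set by
matching those prevalence windows on the default cohort; the remaining
defaults come from first principles (e.g. 1800/450 s bout means give the
0.80 lying fraction directly).

Per-second MI is Poisson with a category-occupancy-weighted rate — simple,
non-negative and integer, matching how the logger reports MI; since the
analysis is threshold-based, only the ordering and overlap of the
category distributions matter.  The fixed transition spike reproduces the
mechanism by which cumulative MI correlates positively with the *number*
of lying bouts even though lying itself is near-motionless.

What the generator does **not** emulate: diurnal rhythm, social
synchrony between pen-mates, sensor noise while lying beyond a small
Poisson rate, and the heavy overlap between active and play MI
distributions seen in real data.  Synthetic separations are consequently
cleaner than field data: cross-validated balanced accuracies near 1 and
near-zero calibration error on synthetic cohorts demonstrate that the
*procedures* recover the generative truth, not that a field deployment
would achieve those numbers.  One visible artefact: simulated lying
*duration* correlates negatively with cumulative MI (lying time trades
exactly against active time in the simulator), whereas field data show no
duration correlation.

## Statistical procedures

**Normality gate.**  A²\* = A²(1 + 0.75/n + 2.25/n²) with mean and
variance estimated; normal iff A²\* < 0.752 (5% critical value, both
parameters estimated).  Only the 5% decision is needed, so no p-value
interpolation is done.  Pearson is selected when at least one of the two
variables passes; Spearman when neither does.  P-values are two-sided
throughout; Spearman uses average ranks for ties, an exact permutation
p-value for n ≤ 9 and the t-approximation otherwise.  Windows are
normalised to {0–12, 12–24, 24–36, 36–48, 0–48} h; a calf whose MI does
not cover a window is dropped from that window only, and windows with
fewer than 3 calves (or a constant variable) yield an explicitly undefined
cell rather than a number.

**Interval binarization.**  An interval is play-positive iff any play
event overlaps it; intervals touched by meta events are excluded from both
the label and MI streams before any tally (exclusion wins over play).
Resolutions are restricted to 1 min and 15 min unless explicitly
overridden.  An intermittent watch schedule (e.g. 1 h observed every 4 h)
can be applied, marking unobserved intervals excluded.

**Prediction rule at equality: positive iff MI ≥ cut point.**  The
boundary case had to be fixed one way; ≥ matches the convention in which
every cut point is phrased "greater than or equal to".

**Gini stump.**  Candidate thresholds are midpoints between consecutive
distinct sorted MI values; the chosen one maximises
ΔG = G(parent) − w_L·G(L) − w_R·G(R), G = 1 − p² − (1−p)², ties broken
toward the smaller threshold.  Classes are not reweighted: the Gini
criterion tolerates the heavy play/no-play imbalance.  Cross-validation
folds are class-stratified and deterministic given a seed (shuffle within
class, round-robin deal); a fold whose training complement is single-class
is merged into a neighbouring fold with a logged warning.

**One-zero calibration** searches whole integers only (the logger reports
MI in whole integers), defaults 1–200 at 1 min and 1–500 at 15 min.  The
visual and MI-equivalent scores share a denominator, so candidate
thresholds are compared on integer positive counts — exact, no float ties.
Ties break toward the larger threshold: false positives distort a one-zero
score more than false negatives, so the more specific threshold is
preferred.  Scores are reported at 3 decimals; comparisons use full
precision.  Validation on a held-out group passes iff the absolute score
difference is < 0.1 (configurable).

## Problem sizes and determinism

The default analyses use ten simulated calves × 48 h (≈ 29 000 one-minute
intervals cohort-wide) plus a ten-calf held-out cohort, which keeps every
stage under a few seconds while leaving hundreds of play bouts per cohort.
Monte-Carlo checks in the test suite use 500–1000 replicates.  Every
random draw flows from explicit seeds: per-calf streams derive from
`(seed, calf_index)`, so cohorts are reproducible and calves independent;
identical config + seed yields byte-identical report files.

## Known limitations

* The surrogate sensor model is not the proprietary on-device formula;
  absolute MI scales (and hence thresholds) are simulator-specific.
* Real-data correlation coefficients and field thresholds are not
  reproducible without the original recordings; the pipeline demonstrates
  sign, strength and mechanism on synthetic cohorts instead.
* Only locomotor play is modelled; social play (head-directed, requiring
  head/neck sensors) is out of scope.
* Deeper decision trees and predictive values (PPV/NPV) are deliberately
  not computed; prevalence varies per calf, making predictive values
  uninformative at this unit of analysis.
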