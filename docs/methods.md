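# Methods

This note documents the models, defaults and numerical choices behind
`mcmct-eval`, and what its synthetic data can and cannot establish.

## The hybrid confusion framework

Camera-based barn monitoring is a two-stage pipeline: detection (is a track
produced for a cow?) then identification (is the track labelled with her ear
tag identity?). Detection is validated daily against the automatic milking
system (AMS) visit log: every cow that visited the AMS at least once between
00:00 and 23:59 is known present via her RFID ear tag, so the day's AMS list
compared with the day's detected-ID list yields `TP-D`, `FN-D`, and — for
detected IDs not in the herd registry — `FP-D`. True negatives do not exist:
there is no population of "absent non-cows" the system could correctly
ignore. Identification is conditioned on detection, so identity-level false
positives and true negatives are structurally impossible; `TP-ID + FN-ID`
must equal `TP-D`, and the code asserts this.

The merged matrix (`TP = TP-ID`, `FN = FN-ID + FN-D`, `FP = FP-D`) drives
recall, precision and F1. Two consequences worth noting:

* `TP + FN` always equals the number of truly present evaluated cows, so
  TP% + FN% ≈ 100 while FP% sits outside that sum. `FP` is shared across the
  identification, activity and location tasks within one evaluation set,
  because ghosts are a detection-stage phenomenon.
* Published descriptions of such frameworks are not always internally
  consistent about FP (spurious output vs missed cow). This package commits
  to FP = detection-stage spurious output: it is the only reading under
  which precision penalises false alarms and the percentage structure above
  holds.

Activity and location are evaluated among detected cows **regardless of
identity correctness** by default — a system can label behaviour correctly
on a misattributed track. `classify_pairs(..., require_correct_id=True)`
restricts correctness to correctly identified cows instead; with that switch
the activity/location cells coincide with identification cells whenever
labels are otherwise perfect.

`compute_metrics` accepts fractional cells so that percentage rows from a
published table can be fed directly. Undefined ratios (zero denominators)
are returned as `None`, never silently as 0. Percent formatting rounds
half-up to two decimals; farm summaries round half-up to one decimal
(8.75 → 8.8), deliberately avoiding Python's default banker's rounding.

## Sample-size design

The number of gold-standard observations is planned with the population
proportion formula `n0 = z² p (1−p) / e²` with the conservative `p = 0.5`,
absolute margin `e`, and `z` the two-sided normal quantile at the stated
confidence — 1.959964 at 95%, not the rounded 1.96 (an override exists; both
give 60 for `N = 70`). With a finite herd `N`, `n = n0 / (1 + (n0 − 1)/N)`,
ceiled and capped at `N`. The function is non-decreasing in `N` and
converges to the unbounded-population value (385 at p=0.5, e=0.05, 95%).

## Synthetic herd generator

The generator emulates a freestall barn observed on a 5-minute grid
(288 ticks/day; any divisor of 1440 works) over a default 31-day window.
Per cow it draws a semi-Markov schedule: bout lengths are geometric with a
30-minute mean (minimum one tick), and each bout's activity is drawn from
time-budget weights modulated by time of day. Defaults (fractions of the
day): lying 0.50, standing 0.18, eating 0.17, walking 0.08, waiting 0.04,
drinking 0.03 — standard magnitudes for housed dairy cows. Lying weight is
doubled between 22:00 and 06:00 (cows lie in cubicles at night), eating
weight is tripled in the 07:00–09:00 fresh-feed window. Each activity maps
to compatible zones (eating↔feeding trough, drinking↔drinking trough,
lying↔cubicle, waiting↔AMS waiting area, walking↔alley, standing↔most
zones); only compatible pairs are ever emitted.

AMS visits: attendance per cow-day is Bernoulli (default probability 1 —
lactating cows milk at least daily), and attending cows make
`1 + Poisson(mean − 1)` visits (default mean 2.6/day) at uniform times.
Attendance probability 1 makes the daily evaluation denominator exactly the
herd size.

What the generator does **not** model: continuous spatial movement (the
Fréchet step runs on separately generated abstract tracks), social
behaviour, oestrus, illness, inter-cow correlation, or realistic AMS queue
dynamics. Passing tests therefore demonstrate correctness of the evaluation
machinery under a controlled error structure — not field performance of any
real system.

## System emulator

The error model mirrors the error taxonomy the evaluation is designed to
measure, with two channels:

* **Detection channel** (snapshots): each cow-day is suppressed entirely
  with probability `daily_miss` — daily detection is a cow-day property
  because the field protocol compares daily lists. Surviving cow-days are
  present per tick with probability `tick_detect`, reduced additively by
  `night_detect_drop` between 22:00 and 06:00. Ghosts (expected
  `ghost_rate × herd size` distinct per day, Poisson) occupy a random
  window of ticks (geometric dwell, mean 12 ticks) under IDs from a disjoint
  `GH…` namespace. Snapshots carry true cow IDs plus ghosts, so no tick ever
  contains a duplicate identity.
* **Identification channel** (records): per surviving cow-day the assigned
  identity is correct with probability `id_correct`; otherwise it is another
  (uniform) herd ID with probability `id_swap_share` or the `unidentified`
  marker. Drawing identity per cow-day reflects how trajectory-identity
  association fails: the association is made when the cow passes the RFID
  reader and then persists. Activity labels pass through a row-stochastic
  6×6 confusion matrix; a zone error accompanies an activity error with
  probability `location_cooccur` (field data show the two co-occur) and
  otherwise occurs at `location_base_rate`.

This separation is what makes the framework's recovery properties exact:
daily detection recall estimates `1 − daily_miss`, identification recall
among detected estimates `id_correct`, and hybrid identification recall
estimates `id_correct × (1 − daily_miss)`. Records carry a trailing
`source_id` bookkeeping column naming the true cow (or ghost) behind each
record; it is what allows gold-standard observation pairs to be rebuilt from
disk, playing the role of the human observer who knows which physical cow a
screen track covers.

### Trajectory-identity association

The discrete Fréchet distance between point sequences is computed by the
standard dynamic programme
`c(i,j) = max(d(p_i,q_j), min(c(i−1,j), c(i−1,j−1), c(i,j−1)))` with
Euclidean ground distance. The continuous Fréchet variant is not
implemented: on sampled tracks the discrete version is the natural choice
and upper-bounds the continuous one. Matching an observed track to the
calibration pool is threshold-gated nearest-neighbour; within a batch the
assignment is injective (two tracks cannot share an identity
simultaneously) and solved exactly as a minimum-total-cost partial matching
(Hungarian algorithm) where leaving a track unassigned costs exactly the
threshold. Exact distance ties in the single-track case break toward the
lexicographically smallest cow ID. The matching threshold is configurable
with no privileged default — it is a property of barn geometry and
calibration noise.

## Detection stability

Snapshot counts are averaged within each hour (12 five-minute ticks) and
divided by the day's AMS-visiting cow count. Proportions above 1 are kept
as-is on the linear scale — overdetection is real (ghosts, double tracks)
and informative; no logit transform is applied. A tick with no detections
counts as zero; in the long snapshot format an empty tick and a missing tick
are indistinguishable, so the grid is taken as complete by construction
(the emulator always emits the full grid). Days with a zero AMS count are
excluded with a warning.

The hour-fixed / day-random model `y_hd = μ + α_h + b_d + e_hd` is fitted on
the balanced layout only (every day × every hour exactly once; anything else
raises — no silent approximation). Balance admits the exact moment/REML
solution: hour estimated marginal means are per-hour averages, residual
variance is the hour×day interaction mean square with `(k−1)(n_days−1)`
degrees of freedom, and the day component is `max(0, (MS_day − MS_resid)/k)`
(truncated at zero, as REML requires). The test suite verifies this closed
form against direct numerical maximisation of the restricted likelihood to
1e−6. The SE of an hourly mean is `sqrt((σ²_day + σ²_resid)/n_days)`; the
day effect cancels in within-day hour contrasts, so pairwise comparisons use
`sqrt(2σ²_resid/n_days)`.

All `k(k−1)/2` hour pairs (276 for 24 hours) are tested with the Tukey
adjustment: `p = P(Q_{k,df} ≥ |diff| / sqrt(σ²_resid/n_days))` from the
studentized-range distribution, flagged at α = 0.01 by default. A
degenerate fit (residual variance zero up to floating-point noise, detected
at a 1e−12 relative threshold) yields p = 0 for unequal means with a
warning rather than a division error. Familywise error control under the
null is verified by simulation; the simulation uses a 6-hour × 5-day layout
because the property is dimension-free and the studentized-range SF is
numerically integrated per evaluation point, while the full 24-hour fit is
exercised on emulated data elsewhere.

## Pipeline and reproducibility

One YAML config describes the farm, grid, error model, evaluation options
and sample-size requests. Stage `s` draws from
`numpy.random.SeedSequence([master_seed, stage_code])`, so stages rerun
independently reproduce byte-identical artifacts (the suite asserts this at
file level). Every run writes `manifest.json` with the seed, a SHA-256 of
the config and the artifact list. All files are comma-separated UTF-8 with
headers; snapshots serialise each tick's ID set as a `;`-joined sorted list.

## Problem sizes

Desk-scale recomputations (farm summaries, sample sizes, metric
recomputation from percentage cells) are instantaneous. The parameter
recovery study runs at the largest-farm scale — 250 cows × 31 days ×
288 ticks ≈ 2.2 M truth events — in well under a minute; simulation-based
checks (variance-component recovery, familywise error) use 200 replicates.
Monte-Carlo assertions use 3 standard errors of the relevant binomial or
replicate distribution, with the effective sample size at the level the
randomness was drawn (cow-days for identity, not ticks).

## Known limitations

* The generator's time budgets and the error model's co-occurrence structure
  are stated assumptions, not fitted to field data.
* Field headline numbers (e.g. daily detection recall of 90–99%) depend on
  farm data that is not publicly deposited; the package reproduces the
  published *derived* quantities from published inputs and validates the
  method's internal consistency, not the field measurements themselves.
* Published minimum sample sizes for the activity (106) and location (140)
  tasks are not derivable from any stated population with the standard
  finite-population correction (a herd of 140 gives 103; 250 gives 152);
  the calculator exposes `population` explicitly and takes no position.
* No unbalanced mixed-model engine, no autocorrelation of within-day
  hourly proportions, no multi-observer agreement statistics.
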