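# mcmct-eval

Evaluation toolkit for **multi-camera multi-cow tracking (MCMCT)** systems —
networks of ceiling cameras that continuously detect, identify and localise
every cow in a freestall dairy barn.

It is written for animal scientists and precision-livestock engineers who
need to validate such a system on a commercial farm: how many cows does it
detect each day, how many does it identify correctly, how reliable are its
activity and zone labels, how stable is detection over the 24-hour day, and
how many gold-standard observations must be collected to say so.

## The evaluation framework

A cow must be **present and detected** before she can be **identified**.
This sequential dependency breaks the ordinary 2×2 confusion matrix:

* Detection stage: `TP-D` (present and detected), `FN-D` (present, missed),
  `FP-D` (a detected ID absent from the day's herd records — a "ghost").
  `TN-D` cannot occur: every animal in the camera field belongs to the herd.
* Identification stage, defined only among detected cows: `TP-ID` (assigned
  identity matches the ear tag), `FN-ID` (misidentified or unidentified).
  `FP-ID` and `TN-ID` are structurally impossible.

The two stages merge into a **hybrid confusion matrix**

    TP = TP-ID,    FN = FN-ID + FN-D,    FP = FP-D

from which the standard metrics follow:

    recall = TP / (TP + FN)
    precision = TP / (TP + FP)
    F1 = 2 · precision · recall / (precision + recall)

Activity and zone-location tasks reuse the same skeleton with label match as
the correctness criterion. Around this core the package provides:

* `farm_config` — validated farm descriptors; stocking density (m²/cow) and
  camera-to-cow ratios.
* `barn_sim` — a synthetic herd generator: six activities × six barn zones on
  a 5-minute grid (288 ticks/day), semi-Markov activity bouts, night-elevated
  lying, morning feeding window, at-least-daily AMS (automatic milking
  system) visits.
* `system_emulator` — emulates MCMCT outputs under a configurable error
  model (daily detection misses, ghosts, identity swaps, coupled
  activity/location errors, night detection drop), plus the calibration-phase
  association of observed trajectories to RFID-anchored reference tracks via
  the **discrete Fréchet distance** (dynamic programming, injective batch
  assignment).
* `hybrid_eval` — the hybrid confusion framework, daily detection evaluation
  against the AMS visit list, recall/precision/F1, and a finite-population
  sample-size calculator (`n0 = z²p(1−p)/e²`, corrected by
  `n = n0 / (1 + (n0−1)/N)`).
* `stability` — hourly detection proportions and a balanced hour-fixed /
  day-random variance-components model with Tukey-adjusted pairwise hour
  comparisons (studentized-range distribution).
* `pipeline` / `mcmct-eval` CLI — reproducible end-to-end orchestration with
  a manifest and seed-split random streams.

## Worked example

```python
from mcmct_eval import (HybridCounts, compute_metrics, sample_size,
                        SimConfig, ErrorModel, simulate_herd, emulate,
                        classify_pairs)
from mcmct_eval.farm_config import FarmConfig
from mcmct_eval.hybrid_eval import percent
from mcmct_eval.pipeline import daily_detection_evaluation, observation_pairs

# identification cells from a field evaluation, in percent units
m = compute_metrics(HybridCounts(tp=69.01, fn=30.94, fp=6.57))
print("recall", percent(m.recall), "precision", percent(m.precision),
      "f1", percent(m.f1))

# how many gold-standard observations does a 70-cow herd need?
print("n for herd of 70:", sample_size(0.5, 0.05, confidence=0.95, population=70))

# simulate a 70-cow barn for a week, emulate an imperfect system, evaluate it
farm = FarmConfig("DEMO", n_cows=70, barn_area=625, n_cubicles=66,
                  n_water_troughs=2, n_ams=1, n_cameras=3)
truth, visits = simulate_herd(farm, SimConfig(seed=7, n_days=7))
em = ErrorModel(daily_miss=0.07, ghost_rate=0.10, id_correct=0.75,
                id_swap_share=0.5, night_detect_drop=0.10)
records, snapshots = emulate(truth, visits, em, seed=7)

_, det = daily_detection_evaluation(visits, snapshots, truth["cow_id"].unique())
dm = compute_metrics(det)
print("detection recall", percent(dm.recall), "precision", percent(dm.precision))

pairs = observation_pairs(truth, records)
hyb = compute_metrics(classify_pairs(pairs, "identification"))
print("identification recall", percent(hyb.recall))
```

prints

```
recall 69.04 precision 91.31 f1 78.63
n for herd of 70: 60
detection recall 93.06 precision 89.76
identification recall 72.04
```

The first line recomputes recall/precision/F1 from percentage-unit confusion
cells. The sample size of 60 is the finite-population-corrected minimum for
estimating a proportion of 0.5 within ±5 points at 95% confidence in a herd
of 70. The emulated system was configured to miss each cow on 7% of days and
to identify 75% of detected cow-days correctly: the evaluation recovers a
daily detection recall near 93% and a hybrid identification recall near
0.75 × 0.93 ≈ 70% — the framework measures exactly the error rates that were
injected.

The same run is available from the shell:

```bash
mcmct-eval run --config examples/h1.yaml --seed 7 --outdir out/
cat out/report.txt
```

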