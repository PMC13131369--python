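"""Hybrid detection->identification confusion framework and metrics.

In a barn monitoring pipeline a cow must be present and detected before an
identity (and an activity / zone label) can be assigned.  The usual 2x2
confusion matrix therefore degenerates:

* detection stage: TP-D (present & detected), FN-D (present, missed), FP-D
  (output with no corresponding herd cow — a "ghost").  TN-D does not exist:
  every animal in the camera field belongs to the herd.
* identification stage, defined only among detected cows: TP-ID (identity
  matches the ear tag), FN-ID (misidentified or unidentified).  FP-ID and
  TN-ID are structurally impossible.

The merged ("hybrid") matrix has TP = TP-ID, FN = FN-ID + FN-D and
FP = FP-D, so TP + FN equals the number of truly present evaluated cows and
FP sits outside that sum.  Activity and zone tasks reuse the same skeleton
with label match as the correctness criterion.

Also implements the finite-population sample-size calculation used to plan
the number of on-farm gold-standard observations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Set, Union

import numpy as np
import pandas as pd
from scipy.stats import norm

from .farm_config import round_half_up

__all__ = [
    "DetectionCounts",
    "IdentificationCounts",
    "HybridCounts",
    "Metrics",
    "ObservationPair",
    "TASKS",
    "evaluate_detection_day",
    "pairs_to_frame",
    "stage_counts",
    "classify_pairs",
    "compute_metrics",
    "percent",
    "sample_size",
    "SampleSizeSpec",
]

TASKS = ("identification", "activity", "location")

Number = Union[int, float]


@dataclass(frozen=True)
class DetectionCounts:
    """Detection-stage cells.  tp_d + fn_d = truly present evaluated cows."""

    tp_d: Number
    fn_d: Number
    fp_d: Number

    def __post_init__(self):
        if min(self.tp_d, self.fn_d, self.fp_d) < 0:
            raise ValueError("detection counts must be >= 0")


@dataclass(frozen=True)
class IdentificationCounts:
    """Identification-stage cells, defined only among detected cows."""

    tp_id: Number
    fn_id: Number

    def __post_init__(self):
        if min(self.tp_id, self.fn_id) < 0:
            raise ValueError("identification counts must be >= 0")


@dataclass(frozen=True)
class HybridCounts:
    """Merged two-stage cells: tp = TP-ID, fn = FN-ID + FN-D, fp = FP-D."""

    tp: Number
    fn: Number
    fp: Number

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp) < 0:
            raise ValueError("hybrid counts must be >= 0")

    @classmethod
    def from_stages(cls, det: DetectionCounts, ident: IdentificationCounts) -> "HybridCounts":
        if not math.isclose(ident.tp_id + ident.fn_id, det.tp_d, rel_tol=0, abs_tol=1e-9):
            raise ValueError(
                "sequential-dependency violation: tp_id + fn_id must equal tp_d "
                f"({ident.tp_id} + {ident.fn_id} != {det.tp_d})"
            )
        return cls(tp=ident.tp_id, fn=ident.fn_id + det.fn_d, fp=det.fp_d)


@dataclass(frozen=True)
class Metrics:
    """Recall, precision and F1 as proportions in [0, 1].

    A field is ``None`` when its denominator is zero (flagged undefined,
    never silently coerced to 0).
    """

    recall: Optional[float]
    precision: Optional[float]
    f1: Optional[float]


def evaluate_detection_day(
    ams_cows: Set[str], detected: Set[str], day_registry: Set[str]
) -> DetectionCounts:
    """One day of detection evaluation.

    ``ams_cows`` — cows that visited the AMS at least once that day (the
    RFID-anchored gold standard of presence); must be a subset of the herd
    registry.  ``detected`` — the system's detected-ID list for the day.
    TP-D/FN-D are counted over AMS visitors; FP-D counts detected IDs absent
    from the day's herd registry.
    """
    ams_cows, detected, day_registry = set(ams_cows), set(detected), set(day_registry)
    if not ams_cows <= day_registry:
        raise ValueError("evaluate_detection_day: AMS cows must be a subset of the day registry")
    return DetectionCounts(
        tp_d=len(ams_cows & detected),
        fn_d=len(ams_cows - detected),
        fp_d=len(detected - day_registry),
    )


@dataclass(frozen=True)
class ObservationPair:
    """One gold-standard observation paired with the system's output.

    ``present=False`` rows represent system outputs with no corresponding
    cow (ghosts); for those the gold fields are meaningless and ``detected``
    is True by construction.
    """

    present: bool
    gold_id: Optional[str]
    gold_activity: Optional[str]
    gold_zone: Optional[str]
    detected: bool
    sys_id: Optional[str] = None
    sys_activity: Optional[str] = None
    sys_zone: Optional[str] = None


_PAIR_COLUMNS = [
    "present",
    "gold_id",
    "gold_activity",
    "gold_zone",
    "detected",
    "sys_id",
    "sys_activity",
    "sys_zone",
]


def pairs_to_frame(pairs: Iterable[ObservationPair]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in pairs], columns=_PAIR_COLUMNS)


def _as_pair_frame(pairs) -> pd.DataFrame:
    if isinstance(pairs, pd.DataFrame):
        missing = [c for c in _PAIR_COLUMNS if c not in pairs.columns]
        if missing:
            raise ValueError(f"observation-pair table missing columns {missing}")
        return pairs
    return pairs_to_frame(pairs)


def stage_counts(pairs) -> tuple[DetectionCounts, IdentificationCounts]:
    """Detection- and identification-stage cells of an observation-pair set."""
    df = _as_pair_frame(pairs)
    present = df["present"].astype(bool)
    detected = df["detected"].astype(bool)
    det = DetectionCounts(
        tp_d=int((present & detected).sum()),
        fn_d=int((present & ~detected).sum()),
        fp_d=int((~present).sum()),
    )
    scope = present & detected
    id_ok = scope & (df["sys_id"].astype(object) == df["gold_id"].astype(object))
    ident = IdentificationCounts(tp_id=int(id_ok.sum()), fn_id=int((scope & ~id_ok).sum()))
    return det, ident


def classify_pairs(pairs, task: str, require_correct_id: bool = False) -> HybridCounts:
    """Hybrid confusion cells for one evaluation task.

    task
        ``"identification"`` — correct means the assigned ID matches the ear
        tag; ``"activity"`` / ``"location"`` — correct means the label
        matches, evaluated among detected cows regardless of identity
        correctness unless ``require_correct_id`` is set.
    require_correct_id
        for activity/location, additionally require a correct identity for a
        pair to count as TP (misidentified cows then fall into FN).

    FP is the detection-stage spurious-output count for every task (shared
    across tasks within an evaluation set).
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    df = _as_pair_frame(pairs)
    present = df["present"].astype(bool)
    detected = df["detected"].astype(bool)
    scope = present & detected

    if task == "identification":
        ok = df["sys_id"].astype(object) == df["gold_id"].astype(object)
    else:
        col = "activity" if task == "activity" else "zone"
        ok = df[f"sys_{col}"].astype(object) == df[f"gold_{col}"].astype(object)
        if require_correct_id:
            ok = ok & (df["sys_id"].astype(object) == df["gold_id"].astype(object))

    tp = int((scope & ok).sum())
    fn = int(present.sum()) - tp  # detection misses + wrong labels
    fp = int((~present).sum())
    return HybridCounts(tp=tp, fn=fn, fp=fp)


def compute_metrics(counts) -> Metrics:
    """Recall, precision and F1 from (tp, fn, fp) cells.

    Accepts :class:`HybridCounts` or :class:`DetectionCounts` (or anything
    exposing tp/fn/fp, including fractional "counts" so percentage rows can
    be fed directly).  Undefined denominators yield ``None`` fields.
    """
    if isinstance(counts, DetectionCounts):
        tp, fn, fp = counts.tp_d, counts.fn_d, counts.fp_d
    else:
        tp, fn, fp = counts.tp, counts.fn, counts.fp
    recall = tp / (tp + fn) if tp + fn > 0 else None
    precision = tp / (tp + fp) if tp + fp > 0 else None
    if recall is None or precision is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return Metrics(recall=recall, precision=precision, f1=f1)


def percent(x: Optional[float]) -> Optional[float]:
    """Proportion -> percent, half-up rounded to 2 decimals (``None`` passes through)."""
    return None if x is None else round_half_up(100.0 * x, 2)


def sample_size(
    p: float,
    margin: float,
    confidence: float = 0.95,
    population: Optional[int] = None,
    z_value: Optional[float] = None,
) -> int:
    """Minimum sample size for estimating a proportion.

    n0 = z^2 p (1-p) / e^2, with z the two-sided normal quantile at the given
    confidence level (1.959964 at 95%; pass ``z_value`` to override, e.g. the
    rounded 1.96).  With a finite population N the correction
    n = n0 / (1 + (n0 - 1)/N) applies.  The result is the ceiling and never
    exceeds N.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    if not 0.0 < margin < 1.0:
        raise ValueError("margin must be in (0, 1)")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    z = float(z_value) if z_value is not None else float(norm.ppf(0.5 + confidence / 2.0))
    n0 = z * z * p * (1.0 - p) / (margin * margin)
    if population is None:
        return math.ceil(n0)
    population = int(population)
    if population < 1:
        raise ValueError("population must be >= 1")
    n = n0 / (1.0 + (n0 - 1.0) / population)
    return min(math.ceil(n), population)


@dataclass(frozen=True)
class SampleSizeSpec:
    """Declarative sample-size request (used by config files and the CLI)."""

    p: float
    margin: float
    confidence: float = 0.95
    population: Optional[int] = None

    @property
    def n(self) -> int:
        return sample_size(self.p, self.margin, self.confidence, self.population)
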