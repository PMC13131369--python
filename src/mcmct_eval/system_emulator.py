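"""Emulator of a multi-camera multi-cow tracking (MCMCT) system.

Takes gold-standard herd data from :mod:`mcmct_eval.barn_sim` and produces the
two outputs such a system emits, degraded by a configurable error model:

* **SystemRecords** — per-cow per-tick records (assigned identity, activity
  label, zone label).  Identity errors are drawn once per cow-day: the system
  either knows a cow on a given day (RFID-anchored association held) or
  mislabels/loses her for the day.  Activity labels pass through a
  row-stochastic confusion matrix; location errors co-occur with activity
  errors with a configurable probability, as observed in the field.
* **DetectionSnapshots** — per-tick sets of detected identities.  Detection is
  a cow-day property (a truly present cow drops out of a whole day's detected
  list with probability ``daily_miss``), additionally thinned per tick at
  night; spurious "ghost" detections carry identifiers from a disjoint
  namespace.

The detection channel carries true cow identities (plus ghosts) while
identity noise lives in the records channel: the field evaluation compares
the RFID-anchored AMS visit list with the daily detection list, which
isolates detection performance from identification performance.

The module also implements the trajectory-to-identity association step used
at calibration: each observed planar track is matched to a pool of reference
tracks by the discrete Fréchet distance, injectively within a batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .barn_sim import ACTIVITIES, ACTIVITY_ZONES, ZONES, is_night

__all__ = [
    "UNIDENTIFIED",
    "GHOST_PREFIX",
    "is_ghost_id",
    "ErrorModel",
    "discrete_frechet",
    "assign_identity",
    "assign_identities",
    "emulate",
    "random_walk_trajectory",
    "jitter_trajectory",
    "make_reference_pool",
]

#: Marker for a detected-but-unidentified output.
UNIDENTIFIED = "unidentified"
#: Ghost identities live in a namespace disjoint from herd IDs ("C...").
GHOST_PREFIX = "GH"


def is_ghost_id(assigned_id: str) -> bool:
    return str(assigned_id).startswith(GHOST_PREFIX)


# ---------------------------------------------------------------------------
# Discrete Fréchet distance and identity association
# ---------------------------------------------------------------------------

def discrete_frechet(p, q) -> float:
    """Discrete Fréchet distance between two point sequences.

    Dynamic programme over the coupling lattice with Euclidean ground
    distance:  c(i,j) = max(d(p_i, q_j), min(c(i-1,j), c(i-1,j-1), c(i,j-1))).
    Symmetric; zero iff the sequences are identical point-by-point.
    """
    p = np.atleast_2d(np.asarray(p, dtype=float))
    q = np.atleast_2d(np.asarray(q, dtype=float))
    if p.shape[0] == 0 or q.shape[0] == 0:
        raise ValueError("discrete_frechet: empty trajectory")
    if not (np.isfinite(p).all() and np.isfinite(q).all()):
        raise ValueError("discrete_frechet: non-finite coordinates")
    d = cdist(p, q)
    n, m = d.shape
    ca = np.empty((n, m))
    ca[0, 0] = d[0, 0]
    for j in range(1, m):
        ca[0, j] = max(ca[0, j - 1], d[0, j])
    for i in range(1, n):
        ca[i, 0] = max(ca[i - 1, 0], d[i, 0])
        row, prev = ca[i], ca[i - 1]
        di = d[i]
        for j in range(1, m):
            row[j] = max(di[j], min(prev[j], prev[j - 1], row[j - 1]))
    return float(ca[n - 1, m - 1])


def assign_identity(obs, pool: Mapping[str, np.ndarray], threshold: float) -> Optional[str]:
    """Match one observed trajectory against a reference pool.

    Returns the pool ID with minimal discrete Fréchet distance if that
    minimum is below ``threshold``, else ``None``.  Exact distance ties break
    toward the lexicographically smallest cow ID.
    """
    if not pool:
        raise ValueError("assign_identity: empty reference pool")
    if threshold <= 0:
        raise ValueError("assign_identity: threshold must be > 0")
    best_id, best_d = None, np.inf
    for cow_id in sorted(pool):
        dist = discrete_frechet(obs, pool[cow_id])
        if dist < best_d:
            best_id, best_d = cow_id, dist
    return best_id if best_d < threshold else None


def assign_identities(
    observations: Mapping, pool: Mapping[str, np.ndarray], threshold: float
) -> Dict:
    """Injective batch association of observed trajectories to references.

    Each observation is either matched to a distinct reference at discrete
    Fréchet distance < ``threshold`` or left unassigned; the solution
    minimises total distance with an unassigned sentinel costing exactly
    ``threshold`` per observation (solved exactly via the Hungarian method).
    Returns ``{observation key: cow_id or None}``.
    """
    if not pool:
        raise ValueError("assign_identities: empty reference pool")
    if threshold <= 0:
        raise ValueError("assign_identities: threshold must be > 0")
    keys = sorted(observations)
    refs = sorted(pool)
    if not keys:
        return {}
    dmat = np.array(
        [[discrete_frechet(observations[k], pool[r]) for r in refs] for k in keys]
    )
    n_obs, n_refs = dmat.shape
    # dummy column block = "unassigned" at cost threshold; inadmissible real
    # cells cost more than any full assignment to dummies, so they are never used
    big = float(threshold) * (n_obs + n_refs + 10.0) + 1.0
    cost = np.full((n_obs, n_refs + n_obs), float(threshold))
    cost[:, :n_refs] = np.where(dmat < threshold, dmat, big)
    rows, cols = linear_sum_assignment(cost)
    out: Dict = {}
    for r, c in zip(rows, cols):
        out[keys[r]] = refs[c] if c < n_refs else None
    return out


def random_walk_trajectory(
    rng: np.random.Generator,
    n_points: int = 40,
    step: float = 0.5,
    origin: Optional[Tuple[float, float]] = None,
) -> np.ndarray:
    """Planar Gaussian random-walk track (n_points x 2, metres)."""
    if origin is None:
        origin = (0.0, 0.0)
    steps = rng.normal(scale=step, size=(n_points - 1, 2))
    return np.vstack([np.asarray(origin, float), np.asarray(origin, float) + np.cumsum(steps, axis=0)])


def jitter_trajectory(traj, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian positional jitter — stands in for re-observation noise."""
    traj = np.asarray(traj, dtype=float)
    return traj + rng.normal(scale=sigma, size=traj.shape)


def make_reference_pool(
    rng: np.random.Generator,
    cow_ids,
    n_points: int = 40,
    step: float = 0.5,
    spread: float = 30.0,
) -> Dict[str, np.ndarray]:
    """Calibration-phase reference tracks: one random walk per cow, origins
    scattered over a ``spread`` x ``spread`` metre area."""
    pool = {}
    for cow_id in cow_ids:
        origin = tuple(rng.uniform(0.0, spread, size=2))
        pool[str(cow_id)] = random_walk_trajectory(rng, n_points=n_points, step=step, origin=origin)
    return pool


# ---------------------------------------------------------------------------
# Error model and emulation
# ---------------------------------------------------------------------------

def _identity_confusion() -> np.ndarray:
    return np.eye(len(ACTIVITIES))


def uniform_confusion(accuracy: float) -> np.ndarray:
    """Confusion matrix with ``accuracy`` on the diagonal, errors uniform."""
    k = len(ACTIVITIES)
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError("accuracy must be in [0, 1]")
    off = (1.0 - accuracy) / (k - 1)
    return np.full((k, k), off) + (accuracy - off) * np.eye(k)


@dataclass
class ErrorModel:
    """Error structure of the emulated monitoring system.

    daily_miss
        probability a truly present cow is absent from a whole day's
        detected list (detection operates at the cow-day level).
    ghost_rate
        expected number of distinct ghost detections per day, as a fraction
        of herd size.
    id_correct
        probability a detected cow-day carries the true identity.
    id_swap_share
        among identity errors, the fraction assigned another herd ID (the
        remainder are emitted as :data:`UNIDENTIFIED`).
    activity_confusion
        6x6 row-stochastic matrix over the activity vocabulary.
    location_cooccur / location_base_rate
        probability of a zone error given an activity error / given none.
    night_detect_drop
        additive reduction of the per-tick detection probability at night
        (22:00-06:00).
    tick_detect
        baseline per-tick detection probability for a non-suppressed cow-day.
    """

    daily_miss: float = 0.0
    ghost_rate: float = 0.0
    id_correct: float = 1.0
    id_swap_share: float = 0.5
    activity_confusion: np.ndarray = field(default_factory=_identity_confusion)
    location_cooccur: float = 0.0
    location_base_rate: float = 0.0
    night_detect_drop: float = 0.0
    tick_detect: float = 1.0
    ghost_mean_ticks: float = 12.0  # mean ghost dwell, in ticks

    def validate(self) -> None:
        for name in (
            "daily_miss",
            "ghost_rate",
            "id_correct",
            "id_swap_share",
            "location_cooccur",
            "location_base_rate",
            "night_detect_drop",
            "tick_detect",
        ):
            v = getattr(self, name)
            if name == "ghost_rate":
                if v < 0:
                    raise ValueError("ghost_rate must be >= 0")
                continue
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        conf = np.asarray(self.activity_confusion, dtype=float)
        k = len(ACTIVITIES)
        if conf.shape != (k, k):
            raise ValueError(f"activity_confusion must be {k}x{k}")
        if (conf < 0).any():
            raise ValueError("activity_confusion entries must be >= 0")
        if not np.allclose(conf.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("activity_confusion rows must sum to 1 within 1e-9")
        if self.ghost_mean_ticks < 1:
            raise ValueError("ghost_mean_ticks must be >= 1")


def _categorical_codes(series: pd.Series, categories) -> np.ndarray:
    cat = pd.Categorical(series, categories=categories)
    codes = np.asarray(cat.codes)
    if (codes < 0).any():
        raise ValueError("value outside the closed label vocabulary")
    return codes


def emulate(
    truth: pd.DataFrame,
    visits: pd.DataFrame,
    em: ErrorModel,
    seed,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Run the error model over gold-standard data.

    Returns ``(records, snapshots)``:

    * ``records`` — columns ``day, tick_minute, assigned_id, activity, zone,
      source_id`` (``source_id`` is bookkeeping: the true cow, or the ghost
      itself, behind each record; it is what makes gold-standard pairing
      possible downstream).
    * ``snapshots`` — long form, columns ``day, tick_minute, detected_id``;
      one row per detected identity per tick (set semantics guaranteed).
    """
    em.validate()
    rng = np.random.default_rng(seed)

    cow_index = pd.Index(np.sort(np.asarray(truth["cow_id"].unique(), dtype=object)))
    n_cows = len(cow_index)
    herd = cow_index.to_numpy(dtype=object)
    if len(visits):
        unknown = set(map(str, visits["cow_id"].unique())) - set(map(str, herd))
        if unknown:
            raise ValueError(f"emulate: AMS visits reference cows missing from truth: {sorted(unknown)[:5]}")

    days = np.sort(truth["day"].unique())
    n_days = len(days)
    day_index = pd.Index(days)

    t_cow = cow_index.get_indexer(truth["cow_id"])
    t_day = day_index.get_indexer(truth["day"])
    tick_minutes = truth["tick_minute"].to_numpy()
    act = _categorical_codes(truth["activity"], ACTIVITIES)
    zone = _categorical_codes(truth["zone"], ZONES)

    # --- cow-day draws: suppression and identity -------------------------
    miss = rng.random((n_cows, n_days)) < em.daily_miss
    correct = rng.random((n_cows, n_days)) < em.id_correct
    swap = rng.random((n_cows, n_days)) < em.id_swap_share
    if n_cows > 1:
        target = rng.integers(0, n_cows - 1, size=(n_cows, n_days))
        target = target + (target >= np.arange(n_cows)[:, None])
    else:
        target = np.zeros((n_cows, n_days), dtype=np.int64)
        swap = np.zeros_like(swap)  # nothing to swap to in a herd of one
    own = np.arange(n_cows)[:, None] * np.ones((1, n_days), dtype=np.int64)
    assigned_code = np.where(correct, own, np.where(swap, target, -1)).astype(np.int64)

    keep = ~miss[t_cow, t_day]

    # --- records channel --------------------------------------------------
    r_cow = t_cow[keep]
    r_day = t_day[keep]
    r_tick = tick_minutes[keep]
    r_act = act[keep]
    r_zone = zone[keep]
    a_code = assigned_code[r_cow, r_day]
    assigned = np.where(a_code >= 0, herd[np.clip(a_code, 0, None)], UNIDENTIFIED)

    conf = np.asarray(em.activity_confusion, dtype=float)
    if np.allclose(conf, np.eye(len(ACTIVITIES))):
        new_act = r_act
    else:
        cum = np.cumsum(conf, axis=1)
        u = rng.random(r_act.shape[0])
        new_act = (u[:, None] >= cum[r_act]).sum(axis=1).astype(np.int8)

    act_err = new_act != r_act
    u_zone = rng.random(r_act.shape[0])
    zone_err = np.where(act_err, u_zone < em.location_cooccur, u_zone < em.location_base_rate)
    wrong = rng.integers(0, len(ZONES) - 1, size=r_zone.shape[0])
    wrong = wrong + (wrong >= r_zone)
    new_zone = np.where(zone_err, wrong, r_zone).astype(np.int8)

    records = pd.DataFrame(
        {
            "day": days[r_day],
            "tick_minute": r_tick,
            "assigned_id": assigned.astype(object),
            "activity": pd.Categorical.from_codes(new_act, categories=ACTIVITIES),
            "zone": pd.Categorical.from_codes(new_zone, categories=ZONES),
            "source_id": herd[r_cow],
        }
    )

    # --- detection snapshots ----------------------------------------------
    night = is_night(tick_minutes[keep])
    p_tick = np.where(
        night,
        np.clip(em.tick_detect - em.night_detect_drop, 0.0, 1.0),
        em.tick_detect,
    )
    present = rng.random(keep.sum()) < p_tick
    snaps = pd.DataFrame(
        {
            "day": days[r_day[present]],
            "tick_minute": r_tick[present],
            "detected_id": herd[r_cow[present]],
        }
    )

    # --- ghosts -------------------------------------------------------------
    ticks_per_day = int(np.unique(tick_minutes).shape[0])
    tick = 1440 // ticks_per_day
    n_ghosts = rng.poisson(em.ghost_rate * n_cows, size=n_days)
    ghost_rec, ghost_snap = [], []
    for di, day in enumerate(days):
        for j in range(int(n_ghosts[di])):
            gid = f"{GHOST_PREFIX}{int(day):03d}N{j:03d}"
            start = int(rng.integers(0, ticks_per_day))
            length = int(rng.geometric(1.0 / em.ghost_mean_ticks))
            stop = min(start + length, ticks_per_day)
            g_ticks = (np.arange(start, stop) * tick).astype(tick_minutes.dtype)
            g_act = ACTIVITIES[int(rng.integers(0, len(ACTIVITIES)))]
            g_zone = ACTIVITY_ZONES[g_act][int(rng.integers(0, len(ACTIVITY_ZONES[g_act])))]
            ghost_rec.append(
                pd.DataFrame(
                    {
                        "day": int(day),
                        "tick_minute": g_ticks,
                        "assigned_id": gid,
                        "activity": g_act,
                        "zone": g_zone,
                        "source_id": gid,
                    }
                )
            )
            ghost_snap.append(
                pd.DataFrame({"day": int(day), "tick_minute": g_ticks, "detected_id": gid})
            )
    if ghost_rec:
        gr = pd.concat(ghost_rec, ignore_index=True)
        gr["activity"] = pd.Categorical(gr["activity"], categories=ACTIVITIES)
        gr["zone"] = pd.Categorical(gr["zone"], categories=ZONES)
        records = pd.concat([records, gr], ignore_index=True)
        snaps = pd.concat([snaps, pd.concat(ghost_snap, ignore_index=True)], ignore_index=True)

    records = records.sort_values(
        ["day", "tick_minute", "source_id"], kind="stable", ignore_index=True
    )
    snaps = snaps.sort_values(
        ["day", "tick_minute", "detected_id"], kind="stable", ignore_index=True
    )
    return records, snaps
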