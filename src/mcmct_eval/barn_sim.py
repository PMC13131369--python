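"""Gold-standard herd behaviour generator.

Generates, for every cow and every tick of a fixed sampling grid (default
5 minutes, i.e. 288 ticks/day), one truth event (activity label + barn zone)
plus the daily automatic-milking-system (AMS) visit log.  The generator is a
per-cow semi-Markov schedule: activity bouts with geometric tick lengths are
drawn with time-of-day-modulated weights (lying up-weighted at night, eating
up-weighted in the morning feeding window), and each bout is placed in a zone
compatible with its activity.

The generator guarantees the marginal properties the downstream evaluation
relies on — event-count conservation, closed label vocabularies, higher
night-time lying in expectation, at-least-daily AMS attendance — rather than
any behavioural micro-dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "ACTIVITIES",
    "ZONES",
    "ACTIVITY_ZONES",
    "NIGHT_START_MINUTE",
    "NIGHT_END_MINUTE",
    "BehaviorProfile",
    "SimConfig",
    "activity_zone_compatible",
    "is_night",
    "simulate_herd",
]

ACTIVITIES = ("eating", "drinking", "lying", "standing", "walking", "waiting")
ZONES = ("alley", "drinking_trough", "feeding_trough", "cubicle", "ams", "ams_waiting_area")

#: Activity -> admissible zones.  "Waiting" is by definition standing in the
#: AMS waiting area; standing itself can occur almost anywhere; walking is an
#: alley behaviour on the grid scale.
ACTIVITY_ZONES: Mapping[str, Tuple[str, ...]] = {
    "eating": ("feeding_trough",),
    "drinking": ("drinking_trough",),
    "lying": ("cubicle",),
    "waiting": ("ams_waiting_area",),
    "standing": ("alley", "cubicle", "ams", "ams_waiting_area", "feeding_trough"),
    "walking": ("alley",),
}

#: Night window (minutes since midnight, wrap-around): 22:00-06:00.
NIGHT_START_MINUTE = 22 * 60
NIGHT_END_MINUTE = 6 * 60


def is_night(minute_of_day) -> np.ndarray:
    """Vectorised night-window membership for minutes since midnight."""
    m = np.asarray(minute_of_day)
    return (m >= NIGHT_START_MINUTE) | (m < NIGHT_END_MINUTE)


def activity_zone_compatible(activity: str, zone: str) -> bool:
    """Whether an (activity, zone) pair is admissible.

    Raises :class:`ValueError` on a label outside the closed vocabularies.
    """
    if activity not in ACTIVITY_ZONES:
        raise ValueError(f"unknown activity label: {activity!r}")
    if zone not in ZONES:
        raise ValueError(f"unknown zone label: {zone!r}")
    return zone in ACTIVITY_ZONES[activity]


@dataclass
class BehaviorProfile:
    """Herd time-budget parameters.

    ``activity_weights`` are relative daily time-budget weights (lying ~50%
    of the day, eating ~17%, etc.); the night multiplier (>1) raises the
    lying weight between 22:00 and 06:00, the feeding multiplier raises the
    eating weight in the morning TMR feeding window (07:00-09:00 by default).
    AMS attendance is at-least-daily by default (``ams_visit_prob = 1``) with
    a mean of ``mean_ams_visits`` visits per cow-day.
    """

    activity_weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "eating": 0.17,
            "drinking": 0.03,
            "lying": 0.50,
            "standing": 0.18,
            "walking": 0.08,
            "waiting": 0.04,
        }
    )
    night_lying_multiplier: float = 2.0
    feeding_eating_multiplier: float = 3.0
    feeding_window: Tuple[int, int] = (7 * 60, 9 * 60)  # minutes since midnight
    mean_ams_visits: float = 2.6
    ams_visit_prob: float = 1.0
    mean_bout_minutes: float = 30.0
    standing_zone_weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "alley": 0.45,
            "cubicle": 0.20,
            "feeding_trough": 0.15,
            "ams_waiting_area": 0.15,
            "ams": 0.05,
        }
    )

    def validate(self) -> None:
        w = np.array([float(self.activity_weights.get(a, 0.0)) for a in ACTIVITIES])
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("activity weights must be non-negative and not all zero")
        if self.night_lying_multiplier <= 0 or self.feeding_eating_multiplier <= 0:
            raise ValueError("multipliers must be > 0")
        if not 0.0 <= self.ams_visit_prob <= 1.0:
            raise ValueError("ams_visit_prob must be in [0, 1]")
        if self.mean_ams_visits < 1.0:
            raise ValueError("mean_ams_visits must be >= 1 (visits are at least daily when attending)")
        if self.mean_bout_minutes <= 0:
            raise ValueError("mean_bout_minutes must be > 0")


@dataclass
class SimConfig:
    """Simulation grid: seed, number of days (default 31) and tick (default 5 min)."""

    seed: int = 0
    n_days: int = 31
    tick: int = 5
    profile: BehaviorProfile = field(default_factory=BehaviorProfile)

    def validate(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.tick < 1 or 1440 % self.tick != 0:
            raise ValueError(f"tick must divide 1440 minutes, got {self.tick}")
        self.profile.validate()


def _weight_table(profile: BehaviorProfile) -> np.ndarray:
    """Rows: 0 = baseline, 1 = feeding window, 2 = night; columns: ACTIVITIES."""
    base = np.array([float(profile.activity_weights.get(a, 0.0)) for a in ACTIVITIES])
    table = np.tile(base, (3, 1))
    table[1, ACTIVITIES.index("eating")] *= profile.feeding_eating_multiplier
    table[2, ACTIVITIES.index("lying")] *= profile.night_lying_multiplier
    return table


def simulate_herd(
    cfg, sim: SimConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the herd of ``cfg.n_cows`` cows over the grid of ``sim``.

    Returns ``(truth, visits)``:

    * ``truth`` — one row per (cow, day, tick): columns ``day`` (1-based),
      ``tick_minute`` (minutes since midnight on the grid), ``cow_id``,
      ``activity``, ``zone``; sorted by (day, tick_minute, cow_id).
    * ``visits`` — AMS visit log: columns ``day``, ``visit_minute`` (0-1439),
      ``cow_id``.

    Fully reproducible for a fixed ``sim.seed`` (or an explicitly supplied
    generator, which then takes precedence).
    """
    sim.validate()
    n_cows = int(cfg.n_cows)
    if n_cows < 1:
        raise ValueError("empty herd")
    if rng is None:
        rng = np.random.default_rng(sim.seed)
    profile = sim.profile

    ticks_per_day = 1440 // sim.tick
    n_ticks = sim.n_days * ticks_per_day
    minute_of_day = (np.arange(n_ticks) % ticks_per_day) * sim.tick

    # time-of-day category per tick: 0 base / 1 feeding window / 2 night
    category = np.zeros(n_ticks, dtype=np.int8)
    fw0, fw1 = profile.feeding_window
    category[(minute_of_day >= fw0) & (minute_of_day < fw1)] = 1
    category[is_night(minute_of_day)] = 2

    weights = _weight_table(profile)
    cum_probs = np.cumsum(weights / weights.sum(axis=1, keepdims=True), axis=1)

    mean_bout_ticks = max(profile.mean_bout_minutes / sim.tick, 1.0)
    p_geom = 1.0 / mean_bout_ticks

    # primary (non-standing) zone index per activity
    primary_zone = np.array(
        [ZONES.index(ACTIVITY_ZONES[a][0]) for a in ACTIVITIES], dtype=np.int8
    )
    standing_idx = ACTIVITIES.index("standing")
    stand_zones = ACTIVITY_ZONES["standing"]
    stand_zone_ids = np.array([ZONES.index(z) for z in stand_zones], dtype=np.int8)
    sw = np.array([float(profile.standing_zone_weights.get(z, 0.0)) for z in stand_zones])
    if (sw < 0).any() or sw.sum() <= 0:
        raise ValueError("standing zone weights must be non-negative and not all zero")
    stand_cum = np.cumsum(sw / sw.sum())

    act_codes = np.empty((n_cows, n_ticks), dtype=np.int8)
    zone_codes = np.empty((n_cows, n_ticks), dtype=np.int8)
    approx_bouts = int(n_ticks * p_geom * 1.3) + 32
    for ci in range(n_cows):
        lengths = rng.geometric(p_geom, size=approx_bouts)
        while lengths.sum() < n_ticks:
            lengths = np.concatenate([lengths, rng.geometric(p_geom, size=64)])
        ends = np.cumsum(lengths)
        n_bouts = int(np.searchsorted(ends, n_ticks)) + 1
        lengths = lengths[:n_bouts]
        starts = np.concatenate(([0], ends[: n_bouts - 1]))

        u = rng.random(n_bouts)
        bout_act = (u[:, None] >= cum_probs[category[starts]]).sum(axis=1).astype(np.int8)
        bout_zone = primary_zone[bout_act]
        standing = bout_act == standing_idx
        if standing.any():
            uz = rng.random(int(standing.sum()))
            bout_zone = bout_zone.copy()
            bout_zone[standing] = stand_zone_ids[(uz[:, None] >= stand_cum).sum(axis=1)]

        act_codes[ci] = np.repeat(bout_act, lengths)[:n_ticks]
        zone_codes[ci] = np.repeat(bout_zone, lengths)[:n_ticks]

    cow_ids = np.array([f"C{i:03d}" for i in range(1, n_cows + 1)])
    day = (np.arange(n_ticks) // ticks_per_day + 1).astype(np.int32)

    truth = pd.DataFrame(
        {
            "day": np.tile(day, n_cows),
            "tick_minute": np.tile(minute_of_day.astype(np.int32), n_cows),
            "cow_id": pd.Categorical.from_codes(
                np.repeat(np.arange(n_cows), n_ticks), categories=cow_ids
            ),
            "activity": pd.Categorical.from_codes(act_codes.ravel(), categories=ACTIVITIES),
            "zone": pd.Categorical.from_codes(zone_codes.ravel(), categories=ZONES),
        }
    )
    truth = truth.sort_values(["day", "tick_minute", "cow_id"], kind="stable", ignore_index=True)

    # AMS visits: attendance Bernoulli(ams_visit_prob) per cow-day; attending
    # cows make 1 + Poisson(mean - 1) visits at uniform times of day.
    attend = rng.random((n_cows, sim.n_days)) < profile.ams_visit_prob
    n_visits = np.zeros((n_cows, sim.n_days), dtype=np.int64)
    n_visits[attend] = 1 + rng.poisson(profile.mean_ams_visits - 1.0, size=int(attend.sum()))
    cow_rep = np.repeat(np.arange(n_cows), n_visits.sum(axis=1))
    day_rep = np.concatenate(
        [np.repeat(np.arange(1, sim.n_days + 1), n_visits[ci]) for ci in range(n_cows)]
    ) if n_visits.sum() else np.empty(0, dtype=np.int64)
    minutes = rng.integers(0, 1440, size=int(n_visits.sum()))
    visits = pd.DataFrame(
        {
            "day": day_rep.astype(np.int32),
            "visit_minute": minutes.astype(np.int32),
            "cow_id": pd.Categorical.from_codes(cow_rep, categories=cow_ids),
        }
    ).sort_values(["day", "visit_minute", "cow_id"], kind="stable", ignore_index=True)

    return truth, visits
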