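"""Hourly detection-stability analysis.

The monitoring system's simultaneous-detection counts (sampled every 5
minutes, 288 per day) are averaged within each hour and divided by the
number of cows that visited the AMS that day, giving hourly detection
proportions (values above 1 are legal: overdetection).  Stability over the
24-h day is assessed with a variance-components model on the balanced
hour x day layout:

    y_{h,d} = mu + alpha_h + b_d + e_{h,d},  b_d ~ N(0, s2_day),
    e_{h,d} ~ N(0, s2_resid)

with hour fixed and day random.  Because the layout is balanced (every day
contributes every hour exactly once), the REML solution has a closed
moment-based form: hour estimated marginal means are per-hour averages
across days, the residual variance is the hour x day interaction mean
square, and the day component is (MS_day - MS_resid) / k truncated at zero.
Pairwise hour contrasts are Tukey-adjusted through the studentized-range
distribution with k groups and (k-1)(n_days-1) denominator degrees of
freedom; the day effect cancels in within-day contrasts, so the contrast
standard error uses the residual component only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import studentized_range

__all__ = [
    "StabilityFit",
    "hourly_proportions",
    "fit_hour_day_model",
    "tukey_pairwise",
]


def hourly_proportions(
    snaps: pd.DataFrame,
    ams_daily_counts: Mapping[int, int],
    tick: int = 5,
    farm_id: Optional[str] = None,
) -> pd.DataFrame:
    """Hourly mean detected counts and detection proportions.

    ``snaps`` is the long-form snapshot table (day, tick_minute,
    detected_id); a tick with no detections simply has no rows and counts as
    zero.  ``ams_daily_counts`` maps day -> number of distinct cows that
    visited the AMS that day (the proportion denominator).  Days with a zero
    or missing AMS count are excluded with a warning.  Returns one row per
    (day, hour): columns ``day, hour, mean_count, proportion`` (plus
    ``farm_id`` if given), 24 x n_days rows.
    """
    if 60 % tick != 0:
        raise ValueError("tick must divide 60 minutes")
    ticks_per_hour = 60 // tick

    days = np.sort(snaps["day"].unique())
    counts = (
        snaps.groupby(["day", "tick_minute"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    full = pd.MultiIndex.from_product(
        [days, np.arange(0, 1440, tick)], names=["day", "tick_minute"]
    )
    counts = counts.set_index(["day", "tick_minute"]).reindex(full, fill_value=0).reset_index()
    counts["hour"] = counts["tick_minute"] // 60

    hourly = (
        counts.groupby(["day", "hour"], observed=True)["count"]
        .agg(mean_count="mean", n_ticks="size")
        .reset_index()
    )
    short = hourly["n_ticks"] != ticks_per_hour
    if short.any():
        raise ValueError("incomplete snapshot grid: some hours are missing ticks")
    hourly = hourly.drop(columns="n_ticks")

    denom = hourly["day"].map(lambda d: ams_daily_counts.get(int(d), 0))
    bad = denom <= 0
    if bad.any():
        warnings.warn(
            f"excluding {sorted(hourly.loc[bad, 'day'].unique().tolist())} day(s) "
            "with zero AMS-visiting cows",
            stacklevel=2,
        )
        hourly = hourly.loc[~bad].reset_index(drop=True)
        denom = denom.loc[~bad].reset_index(drop=True)
    hourly["proportion"] = hourly["mean_count"] / denom.astype(float)
    if farm_id is not None:
        hourly.insert(0, "farm_id", farm_id)
    return hourly


@dataclass(frozen=True)
class StabilityFit:
    """Closed-form fit of the balanced hour-fixed / day-random model."""

    hours: np.ndarray  # (k,) hour labels, sorted
    emm: np.ndarray  # (k,) estimated marginal means
    se_emm: float  # common SE of an hourly mean
    sigma2_day: float  # day variance component (>= 0)
    sigma2_resid: float  # residual variance component
    df_resid: int  # (k-1)(n_days-1)
    n_days: int
    grand_mean: float
    f_hour: float  # F statistic for the hour fixed effect
    p_hour: float

    @property
    def k(self) -> int:
        return len(self.hours)

    @property
    def contrast_se(self) -> float:
        """SE of a pairwise hour contrast (day effect cancels within days)."""
        return float(np.sqrt(2.0 * self.sigma2_resid / self.n_days))


def fit_hour_day_model(rows: pd.DataFrame) -> StabilityFit:
    """Fit the variance-components model on a balanced (day x hour) table.

    ``rows`` must contain columns ``day``, ``hour`` and ``proportion`` with
    exactly one observation per (day, hour) cell and every day contributing
    every hour; anything else raises (no silent approximation of unbalanced
    layouts).
    """
    required = {"day", "hour", "proportion"}
    if not required <= set(rows.columns):
        raise ValueError(f"rows must have columns {sorted(required)}")
    pivot = rows.pivot_table(
        index="day", columns="hour", values="proportion", aggfunc="count", fill_value=0
    )
    if not (pivot.to_numpy() == 1).all():
        raise ValueError("unbalanced layout: every (day, hour) cell must hold exactly one row")
    y = rows.pivot(index="day", columns="hour", values="proportion").sort_index(axis=1)
    n_days, k = y.shape
    if n_days < 2 or k < 2:
        raise ValueError("need at least 2 days and 2 hours")
    ymat = y.to_numpy(dtype=float)

    grand = float(ymat.mean())
    hour_means = ymat.mean(axis=0)
    day_means = ymat.mean(axis=1)

    ms_day = k * float(((day_means - grand) ** 2).sum()) / (n_days - 1)
    ms_hour = n_days * float(((hour_means - grand) ** 2).sum()) / (k - 1)
    resid = ymat - day_means[:, None] - hour_means[None, :] + grand
    df_resid = (k - 1) * (n_days - 1)
    ms_resid = float((resid**2).sum()) / df_resid

    sigma2_resid = ms_resid
    sigma2_day = max(0.0, (ms_day - ms_resid) / k)
    se_emm = float(np.sqrt((sigma2_day + sigma2_resid) / n_days))

    if ms_resid > 0:
        f_hour = ms_hour / ms_resid
        p_hour = float(f_dist.sf(f_hour, k - 1, df_resid))
    else:  # degenerate: no residual noise
        f_hour = np.inf if ms_hour > 0 else 0.0
        p_hour = 0.0 if ms_hour > 0 else 1.0

    return StabilityFit(
        hours=y.columns.to_numpy(),
        emm=hour_means,
        se_emm=se_emm,
        sigma2_day=float(sigma2_day),
        sigma2_resid=float(sigma2_resid),
        df_resid=int(df_resid),
        n_days=int(n_days),
        grand_mean=grand,
        f_hour=float(f_hour),
        p_hour=p_hour,
    )


def tukey_pairwise(fit: StabilityFit, alpha: float = 0.01) -> pd.DataFrame:
    """All pairwise hour comparisons with Tukey (studentized-range) adjustment.

    Returns a table with one row per unordered hour pair — k*(k-1)/2 rows
    (276 for 24 hours) — with columns ``hour_a, hour_b, difference``
    (EMM_b - EMM_a), ``adjusted_p`` and ``significant`` at ``alpha``.  With a
    degenerate fit (zero residual variance) unequal means get adjusted_p = 0,
    flagged by a warning.
    """
    if fit.k < 2:
        raise ValueError("tukey_pairwise: need at least 2 hours")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    ia, ib = np.triu_indices(fit.k, k=1)
    diff = fit.emm[ib] - fit.emm[ia]
    se_mean = np.sqrt(fit.sigma2_resid / fit.n_days)
    # degenerate when the residual component is zero up to floating-point
    # noise relative to the spread of the means
    tiny = 1e-12 * (np.abs(diff).max() + 1.0)
    if se_mean <= tiny:
        warnings.warn(
            "degenerate fit: zero residual variance; unequal means get p = 0",
            stacklevel=2,
        )
        p_adj = np.where(np.abs(diff) <= tiny, 1.0, 0.0)
    else:
        q = np.abs(diff) / se_mean
        p_adj = studentized_range.sf(q, fit.k, fit.df_resid)
        p_adj = np.clip(np.nan_to_num(p_adj, nan=0.0), 0.0, 1.0)
    return pd.DataFrame(
        {
            "hour_a": fit.hours[ia],
            "hour_b": fit.hours[ib],
            "difference": diff,
            "adjusted_p": p_adj,
            "significant": p_adj < alpha,
        }
    )
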