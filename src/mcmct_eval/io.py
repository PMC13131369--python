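"""Delimited-text readers and writers.

All files are comma-separated UTF-8 with a mandatory header row; days are
1-based integers and tick/visit minutes are minutes since midnight (no
locale-dependent formatting).  Snapshot files aggregate the detected-ID set
of each tick into one row with a ``;``-separated ID list.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

__all__ = [
    "write_truth_events",
    "read_truth_events",
    "write_ams_visits",
    "read_ams_visits",
    "write_system_records",
    "read_system_records",
    "write_snapshots",
    "read_snapshots",
    "write_observation_pairs",
    "read_observation_pairs",
    "write_table",
    "read_table",
    "write_key_values",
    "read_key_values",
]

_ID_SEP = ";"


def _write_csv(df: pd.DataFrame, path, columns) -> None:
    df.to_csv(path, index=False, columns=list(columns))


def write_truth_events(df: pd.DataFrame, path) -> None:
    _write_csv(df, path, ["day", "tick_minute", "cow_id", "activity", "zone"])


def read_truth_events(path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        dtype={"day": int, "tick_minute": int, "cow_id": str, "activity": str, "zone": str},
    )


def write_ams_visits(df: pd.DataFrame, path) -> None:
    _write_csv(df, path, ["day", "visit_minute", "cow_id"])


def read_ams_visits(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"day": int, "visit_minute": int, "cow_id": str})


def write_system_records(df: pd.DataFrame, path) -> None:
    cols = ["day", "tick_minute", "assigned_id", "activity", "zone"]
    if "source_id" in df.columns:
        cols.append("source_id")
    _write_csv(df, path, cols)


def read_system_records(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str).astype({"day": int, "tick_minute": int})


def write_snapshots(df: pd.DataFrame, path) -> None:
    """Long-form (day, tick_minute, detected_id) -> one row per tick with a
    ``;``-joined, sorted ID list."""
    grouped = (
        df.groupby(["day", "tick_minute"], observed=True)["detected_id"]
        .apply(lambda ids: _ID_SEP.join(sorted(map(str, ids))))
        .rename("detected_ids")
        .reset_index()
    )
    grouped.to_csv(path, index=False)


def read_snapshots(path) -> pd.DataFrame:
    """Inverse of :func:`write_snapshots`: back to long form."""
    wide = pd.read_csv(path, dtype={"day": int, "tick_minute": int, "detected_ids": str})
    wide["detected_ids"] = wide["detected_ids"].fillna("")
    wide = wide.assign(detected_id=wide["detected_ids"].str.split(_ID_SEP)).explode("detected_id")
    wide = wide[wide["detected_id"].astype(str).str.len() > 0]
    return (
        wide[["day", "tick_minute", "detected_id"]]
        .sort_values(["day", "tick_minute", "detected_id"], kind="stable", ignore_index=True)
    )


def write_observation_pairs(df: pd.DataFrame, path) -> None:
    _write_csv(
        df,
        path,
        [
            "present",
            "gold_id",
            "gold_activity",
            "gold_zone",
            "detected",
            "sys_id",
            "sys_activity",
            "sys_zone",
        ],
    )


def read_observation_pairs(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    for col in ("present", "detected"):
        df[col] = df[col].map({"True": True, "False": False}).astype(bool)
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_key_values(values: Mapping, path) -> None:
    """Machine-readable key=value report, one entry per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for key in values:
            fh.write(f"{key}={values[key]}\n")


def read_key_values(path) -> dict:
    out = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            out[key] = value
    return out
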