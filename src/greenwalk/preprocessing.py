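"""Wear-time, day-window and GPS-quality filtering, and stream merging.

The funnel mirrors the field workflow: answered prompts are successively
reduced by requiring a GPS fix near the prompt, fix accuracy strictly
below 20 m, a position inside the study boundary, a street-network point
within 30 m (the kept location is snapped to it), and a complete diary.
The first and last monitoring days are excluded, and days with less than
8 h of device wear are invalid; participants with fewer than 7 valid days
are flagged (dropping them is a configuration choice, not automatic).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from greenwalk.scales_and_coding import (
    ALL_ITEM_COLUMNS,
    add_si_dummies,
    code_si_intensity,
    score_table,
)
from greenwalk.synthetic_world import World, nearest_street_point


@dataclass(frozen=True)
class PreprocessConfig:
    max_accuracy: float = 20.0        # keep iff accuracy < this (strict)
    max_snap_distance: float = 30.0   # keep iff street point <= this
    min_wear_hours: float = 8.0
    min_valid_days: int = 7
    drop_flagged_participants: bool = False
    gps_match_window_s: float = 60.0
    n_days: int = 9


@dataclass
class FunnelReport:
    """Ordered stage counts; non-increasing along the funnel."""

    stages: list[tuple[str, int]] = field(default_factory=list)

    def add(self, name: str, count: int) -> None:
        if self.stages and count > self.stages[-1][1]:
            raise ValueError(
                f"funnel count increased at stage {name!r}: "
                f"{self.stages[-1][1]} -> {count}")
        self.stages.append((name, int(count)))

    def as_dict(self) -> dict[str, int]:
        return dict(self.stages)

    @property
    def final_count(self) -> int:
        return self.stages[-1][1] if self.stages else 0


def drop_boundary_days(records: pd.DataFrame, n_days: int = 9,
                       ts_col: str = "timestamp",
                       start_dates: dict | None = None) -> pd.DataFrame:
    """Remove records on the first and last monitoring day (per participant).

    ``start_dates`` maps participant id to the first day of the
    monitoring period; without it the participant's first record date
    stands in.  With the standard 9-day period, 7 analysis days remain.
    """
    if len(records) == 0:
        return records.copy()
    dates = pd.DatetimeIndex(records[ts_col]).normalize()
    if start_dates is None and dates.nunique() < 3:
        raise ValueError("need at least 3 distinct days to drop the "
                         "first and last one")
    if start_dates is not None:
        first = pd.DatetimeIndex(
            [start_dates[int(p)] for p in records["pid"]]).normalize()
    else:
        first = pd.DatetimeIndex(records.assign(_date=dates)
                                 .groupby("pid")["_date"].transform("min"))
    day_idx = (dates - first).days
    keep = (day_idx >= 1) & (day_idx <= n_days - 2)
    return records.loc[np.asarray(keep)].copy()


def wear_time_filter(stream: pd.DataFrame,
                     cfg: PreprocessConfig = PreprocessConfig()) -> pd.DataFrame:
    """Per (participant, day) wear validity flags.

    A day is valid iff at least ``min_wear_hours`` of worn minutes; a
    participant is flagged when fewer than ``min_valid_days`` days are
    valid.  Returns columns (pid, date, worn_minutes, valid, flagged).
    """
    s = stream.assign(date=pd.DatetimeIndex(stream["timestamp"]).normalize())
    per_day = (s.groupby(["pid", "date"], as_index=False)["worn"]
               .sum().rename(columns={"worn": "worn_minutes"}))
    per_day["valid"] = per_day["worn_minutes"] >= cfg.min_wear_hours * 60
    valid_days = per_day.groupby("pid")["valid"].transform("sum")
    per_day["flagged"] = valid_days < cfg.min_valid_days
    return per_day


def gps_quality_filter(points: pd.DataFrame, boundary, streets,
                       cfg: PreprocessConfig = PreprocessConfig()
                       ) -> tuple[pd.DataFrame, FunnelReport]:
    """Accuracy / boundary / street-snap filtering of prompt locations.

    Keeps a location iff accuracy < 20 m, it lies inside the boundary, and
    the nearest street point is at most 30 m away; kept locations are
    replaced by the street point.  Returns the surviving rows (with
    snapped x, y) and the stage counts.
    """
    funnel = FunnelReport()
    funnel.add("locations", len(points))
    df = points.loc[points["accuracy"] < cfg.max_accuracy].copy()
    funnel.add("accuracy", len(df))
    x0, y0, x1, y1 = boundary
    inside = (df["x"].between(x0, x1)) & (df["y"].between(y0, y1))
    df = df.loc[inside].copy()
    funnel.add("within_boundary", len(df))
    snapped = []
    for _, row in df.iterrows():
        (sx, sy), d = nearest_street_point(streets, (row["x"], row["y"]))
        snapped.append((sx, sy, d))
    if snapped:
        arr = np.array(snapped)
        df["x"], df["y"], df["snap_distance"] = arr[:, 0], arr[:, 1], arr[:, 2]
        df = df.loc[df["snap_distance"] <= cfg.max_snap_distance].copy()
    funnel.add("street_snap", len(df))
    return df, funnel


def merge_streams(prompts: pd.DataFrame, ediary: pd.DataFrame,
                  sensor: pd.DataFrame, gps: pd.DataFrame, world: World,
                  cfg: PreprocessConfig = PreprocessConfig()
                  ) -> tuple[pd.DataFrame, FunnelReport]:
    """Build the analysis-ready observation table with a funnel report.

    One row per answered, quality-passing prompt with a complete diary;
    affect scores and social-interaction intensity are attached, the
    location is snapped to the street network, and rows with any missing
    component are dropped and counted.  Greenness is attached downstream
    by the exposure computation.
    """
    answered = prompts.loc[prompts["status"] == "answered"].copy()
    if answered.duplicated(["pid", "timestamp"]).any():
        raise ValueError("duplicate (participant, timestamp) prompt keys")
    funnel = FunnelReport()
    funnel.add("answered_prompts", len(answered))

    starts = (sensor.assign(_d=pd.DatetimeIndex(sensor["timestamp"]).normalize())
              .groupby("pid")["_d"].min().to_dict())
    starts = {int(k): v for k, v in starts.items()}
    answered = drop_boundary_days(answered, n_days=cfg.n_days,
                                  start_dates=starts)
    funnel.add("analysis_days", len(answered))

    validity = wear_time_filter(sensor, cfg)
    if cfg.drop_flagged_participants:
        validity = validity.loc[~validity["flagged"]]
    valid_days = {(int(p), pd.Timestamp(d))
                  for p, d in validity.loc[validity["valid"],
                                           ["pid", "date"]].itertuples(index=False)}
    dates = pd.DatetimeIndex(answered["timestamp"]).normalize()
    keep = [(int(p), pd.Timestamp(d)) in valid_days
            for p, d in zip(answered["pid"], dates)]
    answered = answered.loc[np.asarray(keep, bool)]
    funnel.add("wear_time", len(answered))

    # nearest recorded fix within the match window
    matched = _match_fixes(answered, gps, cfg.gps_match_window_s)
    funnel.add("with_gps", len(matched))

    snapped, gps_funnel = gps_quality_filter(
        matched, world.boundary, world.streets, cfg)
    for name, count in gps_funnel.stages[1:]:
        funnel.add(name, count)

    # complete diaries only
    diary = ediary.copy()
    complete = diary[ALL_ITEM_COLUMNS].notna().all(axis=1)
    diary = diary.loc[complete]
    obs = snapped.merge(diary, on=["pid", "timestamp"], how="inner",
                        validate="one_to_one")
    funnel.add("complete_diary", len(obs))

    obs = score_table(obs)
    obs = add_si_dummies(obs)
    keep_cols = ["pid", "timestamp", "x", "y", "accuracy", "snap_distance",
                 "valence", "calmness", "energetic_arousal",
                 "si_intensity", "D1", "D2", "D3", "sex", "age"]
    obs = obs[[c for c in keep_cols if c in obs.columns]].reset_index(drop=True)
    return obs, funnel


def _match_fixes(prompts: pd.DataFrame, gps: pd.DataFrame,
                 window_s: float) -> pd.DataFrame:
    """Attach the nearest-in-time recorded fix to each prompt."""
    rows = []
    for pid, grp in prompts.groupby("pid"):
        fixes = gps.loc[gps["pid"] == pid].sort_values("timestamp")
        if len(fixes) == 0:
            continue
        ft = pd.DatetimeIndex(fixes["timestamp"]).asi8
        pt = pd.DatetimeIndex(grp["timestamp"]).asi8
        pos = np.searchsorted(ft, pt)
        for k, (idx_right, t) in enumerate(zip(pos, pt)):
            best, best_dt = None, None
            for j in (idx_right - 1, idx_right):
                if 0 <= j < len(ft):
                    dt = abs(ft[j] - t) / 1e9
                    if best_dt is None or dt < best_dt:
                        best, best_dt = j, dt
            if best is not None and best_dt <= window_s:
                row = grp.iloc[k].to_dict()
                fix = fixes.iloc[best]
                row.update({"x": fix["x"], "y": fix["y"],
                            "accuracy": fix["accuracy"]})
                rows.append(row)
    if not rows:
        cols = [c for c in prompts.columns if c not in ("x", "y")]
        return pd.DataFrame(columns=cols + ["x", "y", "accuracy"])
    return pd.DataFrame(rows)
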