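"""Walking-triggered prompt logic: detection, lifecycle, and compliance.

A prompt candidate fires at minute t when all of the following hold: the
movement acceleration has exceeded the threshold (default 0.1 g) for the
required number of consecutive minutes ending at t; the current position
lies more than the displacement radius (default 100 m) from the central
position, taken as the centroid of fixes during the preceding stationary
interval; local time falls within the day window (06:00–22:00); the device
is worn; and at least the cooldown (default 60 min) has passed since the
last fired prompt.  The central position resets to the prompt location
after each firing.  The cooldown is an explicit modelling assumption: it
reproduces the observed prompt economy (a handful of prompts per day)
which continuous walking detection alone would not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import time

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class TriggerConfig:
    accel_threshold: float = 0.1        # g
    sustain_minutes: int = 1
    displacement_radius: float = 100.0  # m
    day_window: tuple[time, time] = (time(6, 0), time(22, 0))
    reminders: int = 5
    sound_duration: float = 10.0        # s
    display_duration: float = 50.0      # s
    max_delay: float = 20.0             # s
    cooldown_minutes: int = 60

    def __post_init__(self) -> None:
        for name in ("accel_threshold", "sustain_minutes",
                     "displacement_radius", "reminders", "sound_duration",
                     "display_duration", "max_delay", "cooldown_minutes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.day_window[0] >= self.day_window[1]:
            raise ValueError("day window start must precede its end")


@dataclass
class BehaviorModel:
    """Participant answering behaviour for the prompt lifecycle."""

    compliance: float = 0.655
    reject_share: float = 0.5   # of non-answered prompts (rest are missed)

    def __post_init__(self) -> None:
        if not 0 <= self.compliance <= 1 or not 0 <= self.reject_share <= 1:
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class PromptEvent:
    participant_id: int
    trigger_time: pd.Timestamp
    x: float
    y: float
    status: str = "pending"             # answered / rejected / missed
    answer_time: pd.Timestamp | None = None
    reminders_used: int = 0

    def __post_init__(self) -> None:
        if self.answer_time is not None and self.answer_time < self.trigger_time:
            raise ValueError("answer time cannot precede the trigger")


def detect_trigger_points(stream: pd.DataFrame, track: pd.DataFrame,
                          cfg: TriggerConfig = TriggerConfig()) -> pd.DataFrame:
    """Candidate trigger timestamps and locations for one participant.

    ``stream`` needs minute-level columns (timestamp, movement_accel,
    worn); ``track`` needs (timestamp, x, y).  Returns a DataFrame with
    columns (pid, timestamp, x, y), possibly empty.
    """
    if len(stream) == 0 or len(track) == 0:
        return pd.DataFrame(columns=["pid", "timestamp", "x", "y"])
    ts = pd.DatetimeIndex(stream["timestamp"])
    if not ts.is_monotonic_increasing or ts.has_duplicates:
        raise ValueError("sensor timestamps must be strictly increasing")
    tts = pd.DatetimeIndex(track["timestamp"])
    if not tts.is_monotonic_increasing:
        raise ValueError("track timestamps must be ordered")

    accel = stream["movement_accel"].to_numpy()
    worn = stream["worn"].to_numpy().astype(bool) \
        if "worn" in stream else np.ones(len(stream), bool)
    above = accel > cfg.accel_threshold
    # latest fix at or before each minute
    fix_idx = np.searchsorted(tts.asi8, ts.asi8, side="right") - 1
    tx = track["x"].to_numpy()
    ty = track["y"].to_numpy()

    w0, w1 = cfg.day_window
    in_window = np.array([(w0 <= t.time() < w1) for t in ts])

    pid = int(stream["pid"].iloc[0]) if "pid" in stream else -1
    candidates = []
    run = 0
    stationary_xs: list[float] = []
    stationary_ys: list[float] = []
    central: tuple[float, float] | None = None
    last_fire: int | None = None
    for t in range(len(stream)):
        has_fix = fix_idx[t] >= 0
        if above[t]:
            run += 1
        else:
            run = 0
            if has_fix and worn[t]:
                stationary_xs.append(tx[fix_idx[t]])
                stationary_ys.append(ty[fix_idx[t]])
            continue
        if run < cfg.sustain_minutes or not worn[t] or not in_window[t]:
            continue
        if last_fire is not None and (t - last_fire) < cfg.cooldown_minutes:
            continue
        if not has_fix:
            continue
        px, py = tx[fix_idx[t]], ty[fix_idx[t]]
        if stationary_xs:
            central = (float(np.mean(stationary_xs)),
                       float(np.mean(stationary_ys)))
        if central is None:
            continue
        if np.hypot(px - central[0], py - central[1]) <= cfg.displacement_radius:
            continue
        candidates.append((pid, ts[t], px, py))
        last_fire = t
        central = (px, py)           # reset after each fired prompt
        stationary_xs, stationary_ys = [], []
    return pd.DataFrame(candidates, columns=["pid", "timestamp", "x", "y"])


def run_prompt_lifecycle(candidates: pd.DataFrame, behavior: BehaviorModel,
                         cfg: TriggerConfig, seed) -> pd.DataFrame:
    """Resolve each candidate into answered / rejected / missed.

    Answered prompts get a latency drawn within the maximum active window
    (max delay plus the reminder cycles) and the number of reminder cycles
    that elapsed before the answer.
    """
    if len(candidates) == 0:
        return pd.DataFrame(columns=["pid", "timestamp", "x", "y", "status",
                                     "answer_time", "reminders_used"])
    ts = pd.DatetimeIndex(candidates["timestamp"])
    if "pid" in candidates:
        for _, grp in candidates.groupby("pid"):
            if not pd.DatetimeIndex(grp["timestamp"]).is_monotonic_increasing:
                raise ValueError("candidates must be time-ordered")
    elif not ts.is_monotonic_increasing:
        raise ValueError("candidates must be time-ordered")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    n = len(candidates)
    answered = rng.random(n) < behavior.compliance
    rejected = ~answered & (rng.random(n) < behavior.reject_share)
    cycle = cfg.sound_duration + cfg.display_duration
    reminders_used = rng.integers(0, cfg.reminders + 1, n)
    latency = reminders_used * cycle + rng.uniform(0, cfg.max_delay, n)
    out = candidates.copy()
    out["status"] = np.where(answered, "answered",
                             np.where(rejected, "rejected", "missed"))
    out["answer_time"] = pd.NaT
    out.loc[answered, "answer_time"] = (
        ts[answered] + pd.to_timedelta(latency[answered], unit="s"))
    out["reminders_used"] = np.where(answered, reminders_used, cfg.reminders)
    return out


def compliance_report(events: pd.DataFrame,
                      n_participants: int | None = None) -> dict:
    """Issued/answered counts, compliance percentage, prompts per subject.

    The compliance percentage is rounded to one decimal; with zero issued
    prompts it is reported as None.  The per-participant mean divides the
    answered count by the participant count.
    """
    if events is None or len(events) == 0:
        return {"issued": 0, "answered": 0, "compliance_pct": None,
                "mean_prompts_per_participant": None}
    issued = int(len(events))
    answered = int((events["status"] == "answered").sum())
    if n_participants is None:
        n_participants = int(events["pid"].nunique())
    return {
        "issued": issued,
        "answered": answered,
        "compliance_pct": round(100.0 * answered / issued, 1),
        "mean_prompts_per_participant":
            round(answered / n_participants, 1) if n_participants else None,
    }
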