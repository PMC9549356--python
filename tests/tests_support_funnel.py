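"""Support for the funnel acceptance check: event streams with injected
per-stage failure modes plus an independent, pure-python recount."""

import numpy as np
import pandas as pd

from greenwalk.scales_and_coding import ALL_ITEM_COLUMNS


def build_event_streams(world, n=300, seed=0):
    """Prompt/diary/sensor/GPS streams with known per-prompt conditions.

    Injected failure rates: 30% unanswered, day drawn over all 9 days
    (first/last fail the analysis-day rule), 15% missing GPS fix, 25%
    accuracy >= 20 m, 10% of fixes displaced outside the boundary, 10%
    placed > 30 m from a street, 8% incomplete diaries.
    """
    rng = np.random.default_rng(seed)
    base = pd.Timestamp("2020-09-07")
    x1 = world.boundary[2]

    day = rng.integers(0, 9, n)
    answered = rng.random(n) < 0.7
    has_fix = rng.random(n) < 0.85
    accuracy = np.where(rng.random(n) < 0.25,
                        rng.uniform(20, 40, n), rng.uniform(3, 19, n))
    outside = rng.random(n) < 0.10
    off_street = rng.random(n) < 0.10
    complete = rng.random(n) < 0.92

    ts = [base + pd.Timedelta(days=int(d), hours=9, minutes=2 * k)
          for k, d in enumerate(day)]
    # on-street location 5 m from the edge y=100; failure variants move it
    fx = np.full(n, 150.0)
    fy = np.full(n, 105.0)
    fy[off_street] = 160.0          # 40 m from the nearest street
    fx[outside] = x1 + 50.0         # beyond the boundary

    prompts = pd.DataFrame({
        "pid": 0, "timestamp": ts, "x": fx, "y": fy,
        "status": np.where(answered, "answered", "missed")})
    gps = pd.DataFrame({
        "pid": 0,
        "timestamp": [t for t, h in zip(ts, has_fix) if h],
        "x": fx[has_fix], "y": fy[has_fix],
        "accuracy": accuracy[has_fix]}).sort_values("timestamp")
    items = {c: rng.integers(2, 6, n).astype(float) for c in ALL_ITEM_COLUMNS}
    items[ALL_ITEM_COLUMNS[-1]] = np.where(
        complete, items[ALL_ITEM_COLUMNS[-1]], np.nan)
    ediary = pd.DataFrame({"pid": 0, "timestamp": ts,
                           "si_intensity": rng.integers(1, 5, n),
                           "sex": "female", "age": 44.0, **items})
    minutes = pd.date_range(base, periods=9 * 1440, freq="min")
    sensor = pd.DataFrame({"pid": 0, "timestamp": minutes,
                           "worn": True, "movement_accel": 0.0, "steps": 0})

    log = [{"answered": bool(answered[k]),
            "analysis_day": 1 <= int(day[k]) <= 7,
            "has_fix": bool(has_fix[k]),
            "accurate": float(accuracy[k]) < 20.0,
            "inside": not bool(outside[k]),
            "near_street": not bool(off_street[k]),
            "complete": bool(complete[k])} for k in range(n)]
    return (prompts, ediary, sensor, gps), log


def recount(log):
    """Cumulative stage counts recomputed directly from the event log."""
    stage_conditions = {
        "answered_prompts": ["answered"],
        "analysis_days": ["answered", "analysis_day"],
        "wear_time": ["answered", "analysis_day"],   # fully worn streams
        "with_gps": ["answered", "analysis_day", "has_fix"],
        "accuracy": ["answered", "analysis_day", "has_fix", "accurate"],
        "within_boundary": ["answered", "analysis_day", "has_fix",
                            "accurate", "inside"],
        "street_snap": ["answered", "analysis_day", "has_fix", "accurate",
                        "inside", "near_street"],
        "complete_diary": ["answered", "analysis_day", "has_fix",
                           "accurate", "inside", "near_street", "complete"],
    }
    return {name: sum(all(e[c] for c in need) for e in log)
            for name, need in stage_conditions.items()}
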