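"""End-to-end orchestration: world → cohort → triggers → exposure → models.

A run is reproducible from (config, seed): the global seed is expanded
into independent per-stage substreams so stages can be rerun in
isolation.  ``mode='realism'`` executes the full sensor-level pipeline
(minute streams, trigger detection, funnel filtering, viewsheds, integer
diary items); ``mode='recovery'`` takes the fast path that draws the
analysis table directly from the truth with continuous responses.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from greenwalk import preprocessing, trigger_engine
from greenwalk.cohort_simulator import (
    EDiaryRecord,
    TruthConfig,
    draw_si,
    generate_response,
    simulate_cohort,
    simulate_days,
    simulate_observations,
)
from greenwalk.greenness_exposure import (
    ExposureConfig,
    build_surface_model,
    compute_green_exposure,
)
from greenwalk.mlm_analysis import (
    OUTCOMES,
    center_predictors,
    report_table,
    step_up,
    table_to_markdown,
)
from greenwalk.preprocessing import PreprocessConfig
from greenwalk.scales_and_coding import calibrate_item_noise, code_si_intensity
from greenwalk.synthetic_world import World, WorldConfig, generate_world, write_world
from greenwalk.trigger_engine import BehaviorModel, TriggerConfig


@dataclass
class RunConfig:
    mode: str = "realism"                  # or "recovery"
    n_participants: int = 46
    n_days: int = 9
    seed: int = 17
    outcomes: tuple[str, ...] = OUTCOMES
    world: WorldConfig = field(default_factory=WorldConfig)
    truth: TruthConfig = field(default_factory=TruthConfig)
    trigger: TriggerConfig = field(default_factory=TriggerConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    exposure: ExposureConfig = field(default_factory=ExposureConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for name, sub_cls in (("world", WorldConfig), ("truth", TruthConfig),
                              ("trigger", TriggerConfig),
                              ("preprocess", PreprocessConfig),
                              ("exposure", ExposureConfig)):
            if name in doc:
                kwargs[name] = sub_cls(**doc.pop(name))
        kwargs.update(doc)
        if "outcomes" in kwargs:
            kwargs["outcomes"] = tuple(kwargs["outcomes"])
        return cls(**kwargs)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute all stages in order; returns the run manifest.

    Stage outputs (CSV/JSON/Markdown) are written under ``out_dir``; any
    stage failure aborts with the stage name while earlier outputs are
    preserved on disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root_ss = np.random.SeedSequence(config.seed)
    stage_seeds = root_ss.spawn(8)
    manifest: dict = {"seed": config.seed, "mode": config.mode, "stages": []}

    def record(stage: str, t0: float, **counts) -> None:
        manifest["stages"].append({"stage": stage,
                                   "seconds": round(time.time() - t0, 3),
                                   **counts})

    if config.mode == "recovery":
        t0 = time.time()
        obs = simulate_observations(
            config.truth, config.n_participants,
            np.random.default_rng(stage_seeds[0]))
        obs.to_csv(out / "observations.csv", index=False)
        record("simulate", t0, n_obs=len(obs))
        _analyze(obs, config, out, manifest)
        _write_manifest(manifest, out)
        return manifest

    # ---- realism mode ----
    t0 = time.time()
    world = generate_world(config.world, int(stage_seeds[0].generate_state(1)[0] % 2**31))
    write_world(world, out / "world")
    record("world", t0, n_buildings=len(world.buildings.footprints))

    truth = _calibrated_truth(config.truth.with_integer_items(True))

    t0 = time.time()
    cohort = simulate_cohort(config.n_participants, truth, stage_seeds[1])
    sensors, tracks, devices = [], [], []
    day_rngs = np.random.default_rng(stage_seeds[2]).spawn(len(cohort))
    for p, rng in zip(cohort, day_rngs):
        sensor, gps, info = simulate_days(p, world, truth, rng,
                                          n_days=config.n_days)
        sensors.append(sensor)
        tracks.append(gps)
        devices.append(info["device_track"])
    sensor_df = pd.concat(sensors, ignore_index=True)
    gps_df = pd.concat(tracks, ignore_index=True)
    device_df = pd.concat(devices, ignore_index=True)
    sensor_df.to_csv(out / "sensor_minutes.csv", index=False)
    gps_df.to_csv(out / "gps_fixes.csv", index=False)
    record("simulate", t0, n_sensor_rows=len(sensor_df),
           n_gps_rows=len(gps_df))

    t0 = time.time()
    cands = []
    for p in cohort:
        cands.append(trigger_engine.detect_trigger_points(
            sensor_df.loc[sensor_df["pid"] == p.id],
            device_df.loc[device_df["pid"] == p.id], config.trigger))
    candidates = pd.concat(cands, ignore_index=True)
    behavior = BehaviorModel(truth.compliance, truth.reject_share)
    prompts = trigger_engine.run_prompt_lifecycle(
        candidates, behavior, config.trigger, stage_seeds[3])
    prompts.to_csv(out / "prompts.csv", index=False)
    report = trigger_engine.compliance_report(prompts, len(cohort))
    (out / "compliance.json").write_text(json.dumps(report, indent=2))
    record("trigger", t0, **{k: v for k, v in report.items()
                             if isinstance(v, (int, float))})

    t0 = time.time()
    surface = build_surface_model(world.dem, world.buildings,
                                  config.exposure.target_res)
    answered = prompts.loc[prompts["status"] == "answered"]
    # affect responses depend on the true surroundings at the prompt
    true_pos = _device_positions(device_df, answered)
    exposure_true = compute_green_exposure(world, true_pos, config.exposure,
                                           surface)
    ediary = _generate_diaries(cohort, answered, exposure_true, truth,
                               stage_seeds[4])
    ediary.to_csv(out / "ediary_raw.csv", index=False)
    record("diaries", t0, n_answered=len(ediary))

    t0 = time.time()
    obs, funnel = preprocessing.merge_streams(
        prompts, ediary, sensor_df, gps_df, world, config.preprocess)
    (out / "funnel.json").write_text(json.dumps(funnel.as_dict(), indent=2))
    record("preprocess", t0, **funnel.as_dict())

    t0 = time.time()
    # measured exposure at the snapped (noisy) locations
    exposure = compute_green_exposure(world, obs[["x", "y"]], config.exposure,
                                      surface)
    obs["green_pct"] = exposure["green_pct"].to_numpy()
    for c in exposure.columns:
        if c.startswith("area_"):
            obs[c] = exposure[c].to_numpy()
    obs.to_csv(out / "observations.csv", index=False)
    exposure.to_csv(out / "exposure.csv", index=False)
    record("exposure", t0, n_points=len(obs))

    _analyze(obs, config, out, manifest)
    _write_manifest(manifest, out)
    return manifest


def _calibrated_truth(truth: TruthConfig) -> TruthConfig:
    """Fill per-dimension item-noise variances from the alpha targets."""
    dims = {}
    for name, dim in truth.dimensions.items():
        if dim.item_noise is None:
            w = calibrate_item_noise(
                truth.pooled_latent_variance(name), dim.alpha_target,
                latent_mean=dim.mean, integer_items=truth.integer_items)
            dims[name] = dataclasses.replace(dim, item_noise=w)
        else:
            dims[name] = dim
    return dataclasses.replace(truth, dimensions=dims)


def _device_positions(device_df: pd.DataFrame,
                      prompts: pd.DataFrame) -> pd.DataFrame:
    """True device position at each prompt time."""
    rows = []
    for pid, grp in prompts.groupby("pid"):
        track = device_df.loc[device_df["pid"] == pid]
        tt = pd.DatetimeIndex(track["timestamp"]).asi8
        pt = pd.DatetimeIndex(grp["timestamp"]).asi8
        idx = np.clip(np.searchsorted(tt, pt, side="right") - 1, 0, len(tt) - 1)
        for k, i in enumerate(idx):
            rows.append({"pid": pid, "timestamp": grp["timestamp"].iloc[k],
                         "x": track["x"].iloc[i], "y": track["y"].iloc[i]})
    return pd.DataFrame(rows)


def _generate_diaries(cohort, answered: pd.DataFrame,
                      exposure_true: pd.DataFrame, truth: TruthConfig,
                      seed) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    by_id = {p.id: p for p in cohort}
    exp = exposure_true.set_index(["pid", "timestamp"])
    green_run = exposure_true["green_pct"]
    gm, gs = float(green_run.mean()), float(green_run.std())
    si_draws = draw_si(len(answered), truth, rng)
    rows = []
    for (si, (_, prompt)) in zip(si_draws, answered.iterrows()):
        p = by_id[int(prompt["pid"])]
        green = float(exp.loc[(prompt["pid"], prompt["timestamp"]),
                              "green_pct"])
        rec: EDiaryRecord = generate_response(
            p, int(si), green, truth, rng, timestamp=prompt["timestamp"],
            green_mean=gm, green_sd=gs if gs > 0 else None)
        row = {"pid": p.id, "timestamp": prompt["timestamp"],
               "sex": p.sex, "age": p.age,
               "si_intensity": code_si_intensity(rec.answers)}
        row.update(rec.items)
        if rng.random() < truth.incomplete_diary_prob:
            drop = rng.choice(list(rec.items))
            row[drop] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def _analyze(obs: pd.DataFrame, config: RunConfig, out: Path,
             manifest: dict) -> None:
    t0 = time.time()
    logs = {}
    df = center_predictors(obs) if len(obs) else obs
    for outcome in config.outcomes:
        if len(df) < 10 or df["pid"].nunique() < 2:
            logs[outcome] = [{"step": "skipped",
                              "reason": "too few observations"}]
            continue
        try:
            fit, log = step_up(df, outcome)
        except ValueError as exc:   # e.g. degenerate/collinear tiny designs
            logs[outcome] = [{"step": "failed", "reason": str(exc)}]
            continue
        logs[outcome] = log
        table = report_table(fit)
        table.to_csv(out / f"model_{outcome}.csv", index=False)
        (out / f"model_{outcome}.md").write_text(table_to_markdown(table))
    (out / "comparison_log.json").write_text(
        json.dumps(logs, indent=2, default=str))
    manifest["stages"].append({"stage": "analyze",
                               "seconds": round(time.time() - t0, 3),
                               "n_obs": len(df),
                               "outcomes": list(config.outcomes)})


def _write_manifest(manifest: dict, out: Path) -> None:
    manifest["n_stages"] = len(manifest["stages"])
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
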