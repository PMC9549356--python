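# Run configuration (YAML)

`greenwalk run --config run.yaml --out runs/r1` accepts a YAML document
whose top-level keys mirror `greenwalk.pipeline.RunConfig`; every block is
optional and defaults to the study conditions.

```yaml
mode: realism            # realism | recovery
n_participants: 46
n_days: 9
seed: 17
outcomes: [valence, calmness, energetic_arousal]

world:                   # synthetic_world.WorldConfig
  width: 1000            # m
  height: 1000
  street_spacing: 100    # m between grid streets
  landcover_cell: 10     # m, one class per cell
  dem_cell: 25           # m
  dem_relief: 10         # m of smooth relief
  building_height: 8     # m, uniform
  building_density: 0.5  # share of built-up cells carrying a building
  class_mix:             # proportions, must sum to 1
    forest: 0.20
    low_vegetation: 0.135
    water: 0.005
    built_up: 0.40
    bare_soil: 0.06
    agriculture: 0.20

trigger:                 # trigger_engine.TriggerConfig
  accel_threshold: 0.1   # g
  sustain_minutes: 1
  displacement_radius: 100   # m from the central position
  cooldown_minutes: 60
  reminders: 5
  sound_duration: 10     # s
  display_duration: 50   # s
  max_delay: 20          # s

preprocess:              # preprocessing.PreprocessConfig
  max_accuracy: 20       # m, strict (<)
  max_snap_distance: 30  # m, inclusive (<=)
  min_wear_hours: 8
  min_valid_days: 7
  drop_flagged_participants: false
  gps_match_window_s: 60

exposure:                # greenness_exposure.ExposureConfig
  target_res: 0.5        # m, surface-model resolution
  max_dist: 100          # m sight bound
  observer_height: 1.7   # m
  max_hole_cells: 25     # gap-fill threshold
```

The truth block (cohort and affect-model ground truth) is constructed in
code via `cohort_simulator.TruthConfig`; the seed is expanded into
per-stage substreams recorded in `manifest.json`, and re-running with the
same config and seed reproduces every output byte-identically.
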