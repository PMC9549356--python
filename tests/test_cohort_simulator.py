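import dataclasses

import numpy as np
import pandas as pd
import pytest

from greenwalk.cohort_simulator import (
    DimensionTruth,
    Participant,
    TruthConfig,
    assign_social_context,
    draw_si,
    generate_response,
    simulate_cohort,
    simulate_days,
    simulate_observations,
)
from greenwalk.scales_and_coding import ITEM_COLUMNS
from greenwalk.trigger_engine import TriggerConfig, detect_trigger_points


def zero_noise_truth(**dim_overrides):
    base = TruthConfig.default()
    dims = {}
    for name, dim in base.dimensions.items():
        dims[name] = dataclasses.replace(
            dim, tau00=0.0, sigma2=0.0, item_noise=0.0, **dim_overrides)
    return dataclasses.replace(base, dimensions=dims)


class TestSimulateCohort:
    def test_zero_tau_gives_zero_intercepts(self):
        cohort = simulate_cohort(10, zero_noise_truth(), seed=1)
        assert all(u == 0.0 for p in cohort
                   for u in p.random_intercepts.values())

    def test_generator_moments_at_large_n(self, truth):
        cohort = simulate_cohort(5000, truth, seed=2)
        ages = np.array([p.age for p in cohort])
        female = np.mean([p.sex == "female" for p in cohort])
        assert ages.mean() == pytest.approx(41, abs=0.7)
        assert ages.min() >= 18
        assert female == pytest.approx(0.52, abs=0.02)

    def test_same_seed_identical(self, truth):
        c1 = simulate_cohort(20, truth, seed=9)
        c2 = simulate_cohort(20, truth, seed=9)
        assert [(p.age, p.sex, p.random_intercepts) for p in c1] == \
               [(p.age, p.sex, p.random_intercepts) for p in c2]

    def test_rejects_empty_cohort(self, truth):
        with pytest.raises(ValueError):
            simulate_cohort(0, truth, seed=1)


class TestGenerateResponse:
    def make_participant(self):
        return Participant(id=0, age=41.0, sex="female", education="higher",
                           random_intercepts={d: 0.0 for d in ITEM_COLUMNS})

    def test_deterministic_limit_all_items_equal_mean(self):
        """No betas, no variances: every item equals the grand mean
        (calmness stored reverse-keyed)."""
        truth = zero_noise_truth(
            sex_effect=0.0, age_effect=0.0,
            std_betas={"D1": 0, "D2": 0, "D3": 0, "green": 0})
        p = self.make_participant()
        p = dataclasses.replace(p, sex="female", age=truth.mean_age)
        rec = generate_response(p, 1, 34.0, truth, seed=0)
        for dim, cols in ITEM_COLUMNS.items():
            mean = truth.dimensions[dim].mean
            expected = 7.0 - mean if dim == "calmness" else mean
            for c in cols:
                assert rec.items[c] == pytest.approx(expected)

    def test_si_contrast_is_exactly_the_d3_effect(self):
        truth = zero_noise_truth()
        p = dataclasses.replace(self.make_participant(), age=truth.mean_age)
        r1 = generate_response(p, 1, 34.0, truth, seed=0)
        r4 = generate_response(p, 4, 34.0, truth, seed=0)
        b, _ = truth.raw_effects("calmness")
        keyed1 = 7.0 - r1.items["calm_relaxed_tense"]
        keyed4 = 7.0 - r4.items["calm_relaxed_tense"]
        assert keyed4 - keyed1 == pytest.approx(b[2])

    def test_latent_variance_matches_components(self, truth):
        """Empirical variance of repeated draws at fixed covariates equals
        tau00 + sigma2 (fresh intercept per draw) within 5%."""
        dim = truth.dimensions["calmness"]
        rng = np.random.default_rng(5)
        n = 10_000
        vals = np.empty(n)
        for i in range(n):
            p = Participant(
                id=i, age=41.0, sex="female", education="higher",
                random_intercepts={
                    "calmness": rng.normal(0, np.sqrt(dim.tau00)),
                    "valence": 0.0, "energetic_arousal": 0.0})
            rec = generate_response(p, 2, 34.0, truth, rng)
            keyed = 7.0 - np.mean([rec.items[c]
                                   for c in ITEM_COLUMNS["calmness"]])
            vals[i] = keyed
        target = dim.tau00 + dim.sigma2
        assert vals.var() == pytest.approx(target, rel=0.05)

    def test_rejects_bad_inputs(self, truth):
        p = self.make_participant()
        with pytest.raises(ValueError):
            generate_response(p, 5, 34.0, truth, seed=0)
        with pytest.raises(ValueError):
            generate_response(p, 2, 101.0, truth, seed=0)


class TestSocialContext:
    def test_degenerate_distribution(self, truth):
        t = dataclasses.replace(truth, si_probs=(1.0, 0.0, 0.0, 0.0))
        assert assign_social_context("bout", t, seed=0) == 1

    def test_default_median_is_three(self, truth, rng):
        draws = draw_si(10_000, truth, rng)
        assert np.median(draws) == 3

    def test_seeded_reproducibility(self, truth):
        assert assign_social_context("bout", truth, seed=7) == \
            assign_social_context("bout", truth, seed=7)


class TestSimulateDays:
    def test_zero_bouts_never_walks_and_never_triggers(self, small_world, truth):
        t = dataclasses.replace(truth, bouts_per_day=0.0)
        p = simulate_cohort(1, t, seed=3)[0]
        sensor, gps, info = simulate_days(p, small_world, t, seed=3, n_days=3)
        assert (sensor["movement_accel"] <= 0.1).all()
        cands = detect_trigger_points(sensor, info["device_track"],
                                      TriggerConfig())
        assert len(cands) == 0

    def test_bout_moves_monotonically_along_path(self, small_world, truth):
        p = simulate_cohort(1, truth, seed=4)[0]
        _, _, info = simulate_days(p, small_world, truth, seed=4, n_days=9)
        assert info["bouts"], "expected at least one walking bout"
        bout = max(info["bouts"], key=lambda b: b["minutes"])
        track = info["device_track"]
        sl = track.iloc[2 * bout["start"]:
                        2 * bout["start"] + bout["minutes"]]  # outbound leg
        home = info["home"]
        d = np.hypot(sl["x"] - home[0], sl["y"] - home[1]).to_numpy()
        # device track is noiseless: outbound displacement never decreases
        # (path may bend back on the grid, so allow small dips)
        assert d[-1] > d[0]
        assert (np.diff(d) > -60).all()

    def test_walking_minutes_exceed_threshold_and_step_calibration(
            self, small_world, truth):
        p = simulate_cohort(1, truth, seed=8)[0]
        sensor, _, info = simulate_days(p, small_world, truth, seed=8)
        walking = np.zeros(len(sensor), dtype=bool)
        for b in info["bouts"]:
            walking[b["start"]:b["start"] + b["minutes"]] = True
        walking &= sensor["worn"].to_numpy()
        assert (sensor.loc[walking, "movement_accel"] > 0.1).all()
        assert (sensor.loc[~sensor["worn"], "steps"] == 0).all()
        # 3-minute step totals from long bouts center near 193
        totals = []
        for b in info["bouts"]:
            if b["minutes"] >= 3:
                s = sensor["steps"].to_numpy()[b["start"]:b["start"] + 3]
                totals.append(s.sum())
        assert 100 < np.mean(totals) < 290

    def test_same_seed_identical_streams(self, small_world, truth):
        p = simulate_cohort(1, truth, seed=5)[0]
        s1, g1, _ = simulate_days(p, small_world, truth, seed=6, n_days=2)
        s2, g2, _ = simulate_days(p, small_world, truth, seed=6, n_days=2)
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(g1, g2)

    def test_speed_validation(self, small_world, truth):
        t = dataclasses.replace(truth, walk_speed_kmh=(0.0, 12.0))
        p = simulate_cohort(1, truth, seed=5)[0]
        with pytest.raises(ValueError):
            simulate_days(p, small_world, t, seed=1)


class TestSimulateObservations:
    def test_shapes_and_ranges(self, truth):
        obs = simulate_observations(truth, 46, seed=11)
        assert obs["pid"].nunique() <= 46
        assert obs["si_intensity"].isin([1, 2, 3, 4]).all()
        assert obs["green_pct"].between(0, 100).all()
        per = obs.groupby("pid").size()
        assert per.between(1, 48).all()

    def test_green_distribution_matches_study_conditions(self, truth):
        obs = simulate_observations(truth, 2000, seed=12)
        g = obs["green_pct"]
        assert g.mean() == pytest.approx(34, abs=1.5)
        assert g.std() == pytest.approx(32, abs=1.5)

    def test_deterministic_under_seed(self, truth):
        a = simulate_observations(truth, 10, seed=3)
        b = simulate_observations(truth, 10, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestTruthCalibration:
    def test_null_model_decomposition(self):
        t = TruthConfig.null_model(icc=0.56, total_var=1.21)
        d = t.dimensions["energetic_arousal"]
        assert d.tau00 / (d.tau00 + d.sigma2) == pytest.approx(0.56)
        assert d.tau00 + d.sigma2 == pytest.approx(1.21)

    def test_raw_effects_scale_with_std_targets(self, truth):
        """Raw coefficient over expected outcome SD and predictor SD
        reproduces the configured standardized effect."""
        b, sd_y = truth.raw_effects("calmness")
        C = truth.dummy_covariance()
        sd_x = np.sqrt(np.r_[np.diag(C), 1.0])
        np.testing.assert_allclose(
            b * sd_x / sd_y,
            [truth.dimensions["calmness"].std_betas[k]
             for k in ("D1", "D2", "D3", "green")], rtol=1e-8)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            TruthConfig(compliance=1.2)
        with pytest.raises(ValueError):
            TruthConfig(si_probs=(0.5, 0.5, 0.5, -0.5))
        with pytest.raises(ValueError):
            DimensionTruth(mean=5, sex_effect=0, age_effect=0,
                           std_betas={}, tau00=-1, sigma2=0.4)
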