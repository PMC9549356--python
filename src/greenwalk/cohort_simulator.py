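"""Simulation of participants, movement, sensor/GPS streams, and diaries.

Ground truth for the affect model is a two-level linear model per dimension

    Y_ti = gamma00 + gamma01*Sex + gamma02*Age + b1*D1 + b2*D2 + b3*D3
           + bg*Green_z + u_0i + r_ti,

with person random intercepts u_0i ~ N(0, tau00) and residuals
r_ti ~ N(0, sigma2).  The level-1 truth is parameterized by STANDARDIZED
coefficients (effect per predictor SD, in outcome-SD units): the raw
generating coefficients are derived by a deterministic fixed-point
calibration so that the expected standardized coefficient recovered by the
analysis pipeline equals the configured value.  The calibration accounts
for the fact that with clustered observations the realized sample SD of the
outcome underestimates the population SD (between-person variance shrinks
by roughly the expected share of squared cluster sizes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from greenwalk.scales_and_coding import (
    DIMENSIONS,
    ITEM_COLUMNS,
    SocialContextAnswers,
    si_to_answers,
)
from greenwalk.synthetic_world import World, nearest_street_point

SI_LEVELS = (1, 2, 3, 4)


@dataclass(frozen=True)
class DimensionTruth:
    """Generating parameters for one affect dimension."""

    mean: float                       # grand mean on the 1-6 scale
    sex_effect: float                 # raw shift for female (0/1 coded)
    age_effect: float                 # raw shift per year of age
    std_betas: dict[str, float]       # D1, D2, D3, green (standardized)
    tau00: float                      # between-person intercept variance
    sigma2: float                     # within-person residual variance
    alpha_target: float = 0.85        # Cronbach's alpha target for the items
    item_noise: float | None = None   # per-item noise variance (calibrated)

    def __post_init__(self) -> None:
        if self.tau00 < 0 or self.sigma2 < 0:
            raise ValueError("variance components must be >= 0")


def _default_dimensions() -> dict[str, DimensionTruth]:
    return {
        "valence": DimensionTruth(
            mean=5.2, sex_effect=-0.34, age_effect=0.01,
            std_betas={"D1": -0.05, "D2": 0.07, "D3": 0.10, "green": 0.02},
            tau00=0.27, sigma2=0.41, alpha_target=0.85),
        "calmness": DimensionTruth(
            mean=4.8, sex_effect=-0.07, age_effect=0.01,
            std_betas={"D1": 0.06, "D2": 0.07, "D3": 0.16, "green": 0.09},
            tau00=0.40, sigma2=0.40, alpha_target=0.86),
        "energetic_arousal": DimensionTruth(
            mean=4.6, sex_effect=-0.20, age_effect=0.02,
            std_betas={"D1": 0.07, "D2": 0.13, "D3": 0.08, "green": 0.08},
            tau00=0.52, sigma2=0.43, alpha_target=0.81),
    }


@dataclass(frozen=True)
class TruthConfig:
    """Study conditions: cohort, behaviour, and affect-model ground truth.

    Defaults encode the study conditions the simulation emulates: 46
    participants (52% female, age 41 ± 13 truncated at 18), about 8.5
    analyzed entries per participant with strong overdispersion, prompt
    compliance 65.5%, a four-level social-interaction distribution with
    median 3, and a viewshed green percentage with mean 34 and SD 32
    spanning 0–100.
    """

    dimensions: dict[str, DimensionTruth] = field(
        default_factory=_default_dimensions)
    mean_age: float = 41.0
    sd_age: float = 13.0
    min_age: float = 18.0
    p_female: float = 0.52
    p_higher_education: float = 0.81
    si_probs: tuple[float, ...] = (0.25, 0.20, 0.30, 0.25)
    green_mean: float = 34.0
    green_sd: float = 32.0
    compliance: float = 0.655
    reject_share: float = 0.5          # rejected share of non-answered prompts
    incomplete_diary_prob: float = 0.05
    # analyzed entries per participant: truncated negative binomial
    obs_mean: float = 8.5
    obs_dispersion: float = 0.71
    obs_min: int = 1
    obs_max: int = 48
    # movement behaviour
    bouts_per_day: float = 6.0
    bout_minutes: tuple[int, int] = (5, 20)
    walk_speed_kmh: tuple[float, float] = (3.0, 6.0)
    steps_180s_mean: float = 193.0
    steps_180s_sd: float = 95.0
    # GPS recording
    gps_accuracy_shape: float = 3.0
    gps_accuracy_scale: float = 5.0
    gps_outage_blocks_per_day: float = 6.0
    gps_outage_minutes: tuple[int, int] = (30, 90)
    # response discretization (off for parameter-recovery runs)
    integer_items: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.compliance <= 1:
            raise ValueError("compliance must be in [0, 1]")
        if not math.isclose(sum(self.si_probs), 1.0, abs_tol=1e-9):
            raise ValueError("si_probs must sum to 1")
        if any(p < 0 for p in self.si_probs):
            raise ValueError("si_probs must be non-negative")
        object.__setattr__(self, "_cache", {})

    # -- derived quantities -------------------------------------------------

    def beta_params(self) -> tuple[float, float]:
        """Beta-distribution parameters matching the green mean/SD on 0-100."""
        m = self.green_mean / 100.0
        v = (self.green_sd / 100.0) ** 2
        s = m * (1 - m) / v - 1.0
        if s <= 0:
            raise ValueError("green_sd too large for a Beta distribution")
        return m * s, (1 - m) * s

    def cluster_size_moments(self) -> tuple[float, float]:
        """(E[n], E[n^2]) of the truncated negative-binomial entry count."""
        r = self.obs_dispersion
        p = r / (r + self.obs_mean)
        k = np.arange(0, 4000)
        pmf = stats.nbinom.pmf(k, r, p)
        v = np.clip(k, self.obs_min, self.obs_max)
        return float(np.sum(pmf * v)), float(np.sum(pmf * v**2))

    def age_loc(self) -> float:
        """Location parameter such that the mean AFTER truncation at
        ``min_age`` equals ``mean_age``."""
        key = ("age_loc",)
        if key in self._cache:
            return self._cache[key]
        loc = self.mean_age
        for _ in range(60):
            a = (self.min_age - loc) / self.sd_age
            shift = self.sd_age * stats.norm.pdf(a) / stats.norm.sf(a)
            loc_new = self.mean_age - shift
            if abs(loc_new - loc) < 1e-12:
                loc = loc_new
                break
            loc = loc_new
        self._cache[key] = loc
        return loc

    def age_variance(self) -> float:
        loc = self.age_loc()
        a = (self.min_age - loc) / self.sd_age
        return float(stats.truncnorm.var(a, np.inf, loc=loc,
                                         scale=self.sd_age))

    def dummy_covariance(self) -> np.ndarray:
        q = np.asarray(self.si_probs[1:])
        return np.diag(q) - np.outer(q, q)

    def raw_effects(self, dimension: str,
                    n_participants: int = 46) -> tuple[np.ndarray, float]:
        """Raw level-1 coefficients (D1, D2, D3, green_z) and expected
        realized outcome SD for one dimension.

        Solves the fixed point b_j = std_beta_j * sd_Y / sd_xj where sd_Y
        depends on the b_j through the fixed-effect variance.  Between-
        person variance components (random intercept, sex, age effects)
        enter sd_Y shrunk by (1 - c) with c = E[sum n_i^2] / E[N^2], the
        expected loss of between-cluster variance in a clustered sample SD.
        """
        key = ("raw_effects", dimension, n_participants)
        if key in self._cache:
            return self._cache[key]
        dim = self.dimensions[dimension]
        C = self.dummy_covariance()
        sd_x = np.sqrt(np.r_[np.diag(C), 1.0])
        targets = np.array([dim.std_betas.get(k, 0.0)
                            for k in ("D1", "D2", "D3", "green")])
        en, en2 = self.cluster_size_moments()
        m = n_participants
        c = (m * en2) / (m**2 * en**2 + m * (en2 - en**2))
        var_between_fixed = (dim.sex_effect**2 * self.p_female * (1 - self.p_female)
                             + dim.age_effect**2 * self.age_variance())
        sigma_full = np.zeros((4, 4))
        sigma_full[:3, :3] = C
        sigma_full[3, 3] = 1.0
        sd_y = math.sqrt(dim.tau00 + dim.sigma2 + var_between_fixed)
        for _ in range(100):
            b = targets * sd_y / sd_x
            vf_within = float(b @ sigma_full @ b)
            sd_new = math.sqrt(
                vf_within
                + (1 - c) * (var_between_fixed + dim.tau00)
                + dim.sigma2)
            if abs(sd_new - sd_y) < 1e-13:
                sd_y = sd_new
                break
            sd_y = sd_new
        result = (targets * sd_y / sd_x, sd_y)
        self._cache[key] = result
        return result

    def pooled_latent_variance(self, dimension: str) -> float:
        """Approximate pooled variance of the latent dimension score."""
        dim = self.dimensions[dimension]
        b, _ = self.raw_effects(dimension)
        sigma_full = np.zeros((4, 4))
        sigma_full[:3, :3] = self.dummy_covariance()
        sigma_full[3, 3] = 1.0
        vb = (dim.sex_effect**2 * self.p_female * (1 - self.p_female)
              + dim.age_effect**2 * self.age_variance())
        return float(b @ sigma_full @ b) + vb + dim.tau00 + dim.sigma2

    # -- variants -----------------------------------------------------------

    @classmethod
    def default(cls) -> "TruthConfig":
        return cls()

    @classmethod
    def null_model(cls, icc: float = 0.56, total_var: float = 1.21,
                   mean: float = 4.6) -> "TruthConfig":
        """Intercept-only truth with a fixed variance decomposition.

        Used for ICC-recovery experiments: no fixed effects at level 1 or
        2, tau00 = icc * total_var, sigma2 = (1 - icc) * total_var.
        """
        dim = DimensionTruth(
            mean=mean, sex_effect=0.0, age_effect=0.0,
            std_betas={"D1": 0.0, "D2": 0.0, "D3": 0.0, "green": 0.0},
            tau00=icc * total_var, sigma2=(1 - icc) * total_var)
        return cls(dimensions={d: dim for d in DIMENSIONS})

    def with_integer_items(self, flag: bool = True) -> "TruthConfig":
        return replace(self, integer_items=flag)


@dataclass
class Participant:
    id: int
    age: float
    sex: str                      # "female" / "male"
    education: str                # "higher" / "other"
    random_intercepts: dict[str, float]

    def __post_init__(self) -> None:
        if self.age < 18:
            raise ValueError("participants must be at least 18")


@dataclass
class EDiaryRecord:
    """One answered prompt: six raw item responses plus context answers.

    The two calmness items are stored with the calm pole on the LOW end
    (raw 1 = relaxed), as printed on the questionnaire; scoring
    reverse-keys them.
    """

    participant_id: int
    timestamp: pd.Timestamp | None
    items: dict[str, float]
    answers: SocialContextAnswers


def simulate_cohort(n: int, truth: TruthConfig, seed) -> list[Participant]:
    """Draw a cohort: ages ~ N(41, 13^2) truncated at 18, 52% female,
    education 81% higher, random intercepts ~ N(0, tau00) per dimension."""
    if n < 1:
        raise ValueError("need at least one participant")
    rng = np.random.default_rng(seed)
    loc = truth.age_loc()
    a = (truth.min_age - loc) / truth.sd_age
    ages = stats.truncnorm.rvs(a, np.inf, loc=loc,
                               scale=truth.sd_age, size=n, random_state=rng)
    female = rng.random(n) < truth.p_female
    higher = rng.random(n) < truth.p_higher_education
    out = []
    for i in range(n):
        u = {d: (rng.normal(0.0, math.sqrt(truth.dimensions[d].tau00))
                 if truth.dimensions[d].tau00 > 0 else 0.0)
             for d in truth.dimensions}
        out.append(Participant(
            id=i, age=float(ages[i]),
            sex="female" if female[i] else "male",
            education="higher" if higher[i] else "other",
            random_intercepts=u))
    return out


def assign_social_context(bout, truth: TruthConfig, seed) -> int:
    """Social-interaction intensity for one prompt moment (1..4)."""
    if bout is None:
        raise ValueError("bout must exist")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    return int(rng.choice(SI_LEVELS, p=truth.si_probs))


def draw_si(n: int, truth: TruthConfig, rng: np.random.Generator) -> np.ndarray:
    return rng.choice(SI_LEVELS, size=n, p=truth.si_probs)


def generate_response(participant: Participant, si_intensity: int,
                      green_pct: float, truth: TruthConfig, seed,
                      timestamp=None,
                      green_mean: float | None = None,
                      green_sd: float | None = None) -> EDiaryRecord:
    """Draw one diary record from the two-level truth.

    The latent dimension score is the linear predictor plus the person's
    random intercept and a fresh residual; each of the two items adds
    independent item noise, is clipped to [1, 6], and (in realism mode)
    rounded to the integer scale.  Greenness enters standardized; by
    default the population mean/SD stand in for the run-level values.
    """
    if si_intensity not in SI_LEVELS:
        raise ValueError(f"si_intensity must be 1..4, got {si_intensity}")
    if not 0 <= green_pct <= 100:
        raise ValueError("green_pct must be in [0, 100]")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    gm = truth.green_mean if green_mean is None else green_mean
    gs = truth.green_sd if green_sd is None else green_sd
    green_z = (green_pct - gm) / gs if gs > 0 else 0.0
    dummies = np.array([si_intensity == 2, si_intensity == 3,
                        si_intensity == 4], dtype=float)
    sex_ind = 1.0 if participant.sex == "female" else 0.0
    items: dict[str, float] = {}
    for dname, dim in truth.dimensions.items():
        b, _ = truth.raw_effects(dname)
        latent = (dim.mean
                  + dim.sex_effect * (sex_ind - truth.p_female)
                  + dim.age_effect * (participant.age - truth.mean_age)
                  + float(dummies @ b[:3]) + b[3] * green_z
                  + participant.random_intercepts.get(dname, 0.0)
                  + (rng.normal(0.0, math.sqrt(dim.sigma2))
                     if dim.sigma2 > 0 else 0.0))
        noise_sd = math.sqrt(dim.item_noise) if dim.item_noise else 0.0
        for col in ITEM_COLUMNS[dname]:
            val = latent + (rng.normal(0.0, noise_sd) if noise_sd else 0.0)
            if dname == "calmness":
                val = 7.0 - val  # store with the calm pole on the low end
            if truth.integer_items:
                # realism: clip to the printed scale and round to integers
                val = float(np.clip(np.rint(val), 1, 6))
            items[col] = float(val)
    return EDiaryRecord(participant.id, timestamp, items,
                        si_to_answers(si_intensity))


# ---------------------------------------------------------------------------
# fast path: analysis-ready observations straight from the truth
# ---------------------------------------------------------------------------

def simulate_observations(truth: TruthConfig, n_participants: int,
                          seed) -> pd.DataFrame:
    """Analysis-ready observation table drawn directly from the truth.

    This is the parameter-recovery path: entry counts per participant come
    from the truncated negative binomial, social-interaction intensity and
    green percentage are drawn i.i.d. within persons, and the continuous
    dimension scores follow the two-level model exactly (no item split, no
    clipping or rounding), so refitting the model measures estimator
    behaviour rather than discretization artifacts.  Greenness enters the
    generating model person-mean-centered and scaled by its realized
    sample SD, matching the analysis parameterization.
    """
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    r = truth.obs_dispersion
    p = r / (r + truth.obs_mean)
    n_obs = np.clip(rng.negative_binomial(r, p, n_participants),
                    truth.obs_min, truth.obs_max)
    pid = np.repeat(np.arange(n_participants), n_obs)
    n = pid.size

    loc = truth.age_loc()
    a = (truth.min_age - loc) / truth.sd_age
    ages = stats.truncnorm.rvs(a, np.inf, loc=loc,
                               scale=truth.sd_age, size=n_participants,
                               random_state=rng)
    female = (rng.random(n_participants) < truth.p_female).astype(float)

    si = draw_si(n, truth, rng)
    ba, bb = truth.beta_params()
    green = 100.0 * rng.beta(ba, bb, n)
    gseries = pd.Series(green)
    gc = gseries - gseries.groupby(pid).transform("mean")
    sd_gc = gc.std()
    green_z = (gc / sd_gc).to_numpy() if sd_gc > 0 else np.zeros(n)
    dummies = np.stack([(si == k).astype(float) for k in (2, 3, 4)], axis=1)

    df = pd.DataFrame({
        "pid": pid,
        "sex": np.where(female[pid] == 1.0, "female", "male"),
        "age": ages[pid],
        "si_intensity": si,
        "green_pct": green,
    })
    sex_c = female[pid] - female.mean()
    age_c = ages[pid] - ages.mean()
    for dname, dim in truth.dimensions.items():
        b, _ = truth.raw_effects(dname, n_participants)
        u = (rng.normal(0.0, math.sqrt(dim.tau00), n_participants)
             if dim.tau00 > 0 else np.zeros(n_participants))
        resid = (rng.normal(0.0, math.sqrt(dim.sigma2), n)
                 if dim.sigma2 > 0 else np.zeros(n))
        df[dname] = (dim.mean + dim.sex_effect * sex_c
                     + dim.age_effect * age_c
                     + dummies @ b[:3] + b[3] * green_z
                     + u[pid] + resid)
    return df


# ---------------------------------------------------------------------------
# realism path: minute-level streams over the study period
# ---------------------------------------------------------------------------

def simulate_days(participant: Participant, world: World, truth: TruthConfig,
                  seed, n_days: int = 9,
                  start_date: str = "2020-09-07") -> tuple[pd.DataFrame,
                                                           pd.DataFrame, dict]:
    """Minute-level sensor stream and GPS track over the monitoring period.

    Walking bouts are out-and-back trips along the street network at 3–6
    km/h starting from a home node; during walking minutes movement
    acceleration exceeds 0.1 g and the step rate is calibrated so that 180
    s of walking accumulates ~N(193, 95^2) steps (truncated at 0).  The
    returned GPS track has a fix every 30 s with a per-fix accuracy value
    and half-normal radial error scaled by it, and carries realistic
    outage blocks; ``info['device_track']`` holds the device-internal
    (noise-free, gap-free) positions that drive the trigger, emulating the
    fused location the handset itself uses.
    """
    lo, hi = truth.walk_speed_kmh
    if not (0 < lo <= hi <= 10):
        raise ValueError("walking speed must lie in (0, 10] km/h")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    t0 = pd.Timestamp(start_date)
    total_min = n_days * 1440
    minutes = t0 + pd.to_timedelta(np.arange(total_min), unit="m")

    worn = np.ones(total_min, dtype=bool)
    moff = (minutes.hour < 6) | ((minutes.hour == 6) & (minutes.minute < 30))
    worn[moff | (minutes.hour >= 23)] = False
    for day in range(n_days):
        for _ in range(rng.poisson(1.0)):
            s = day * 1440 + int(rng.integers(7 * 60, 22 * 60))
            worn[s:s + int(rng.integers(20, 61))] = False

    adj = world.streets.adjacency()
    nodes = world.streets.nodes
    home_idx = int(rng.integers(len(nodes)))
    home = nodes[home_idx]

    # positions at 30 s resolution (2 per minute)
    pos = np.tile(home, (2 * total_min, 1)).astype(float)
    walking = np.zeros(total_min, dtype=bool)
    bouts = []
    for day in range(n_days):
        n_b = rng.poisson(truth.bouts_per_day)
        starts = np.sort(rng.integers(6 * 60, 21 * 60 + 30, n_b))
        prev_end = -10
        for s in starts:
            dur = int(rng.integers(truth.bout_minutes[0],
                                   truth.bout_minutes[1] + 1))
            start = day * 1440 + int(s)
            if start <= prev_end + 5:
                continue
            prev_end = start + dur
            speed = rng.uniform(lo, hi) * 1000.0 / 60.0  # m per minute
            out_len = speed * dur / 2.0
            path = _street_path(home_idx, out_len, adj, nodes, rng)
            t_half = np.arange(2 * dur) * 0.5
            dist = speed * t_half
            half = speed * dur / 2.0
            dist = np.where(dist <= half, dist, 2 * half - dist)  # out & back
            pts = _along_path(path, np.clip(dist, 0, None))
            sl = slice(2 * start, 2 * (start + dur))
            pos[sl] = pts[: 2 * dur]
            walking[start:start + dur] = True
            bouts.append({"start": start, "minutes": dur,
                          "speed_m_min": speed, "path": path})

    walking &= worn

    accel = np.zeros(total_min)
    steps = np.zeros(total_min, dtype=int)
    idle = worn & ~walking
    accel[idle] = rng.uniform(0.0, 0.08, idle.sum())
    accel[walking] = rng.uniform(0.15, 0.45, walking.sum())
    # per-bout step rate: 3-minute totals ~ N(193, 95^2) truncated at 0
    rate_mean = truth.steps_180s_mean / 3.0
    rate_sd = truth.steps_180s_sd / 3.0 / math.sqrt(3.0)
    for b in bouts:
        rate = rng.normal(rate_mean, rate_sd * math.sqrt(3.0))
        per_min = rate + rng.normal(0.0, 5.0, b["minutes"])
        sl = slice(b["start"], b["start"] + b["minutes"])
        steps[sl] = np.clip(np.rint(per_min), 0, None).astype(int)
    steps[~worn] = 0
    accel[~worn] = 0.0

    sensor = pd.DataFrame({
        "pid": participant.id, "timestamp": minutes,
        "movement_accel": accel, "steps": steps, "worn": worn})

    fix_times = t0 + pd.to_timedelta(np.arange(2 * total_min) * 30, unit="s")
    fix_worn = np.repeat(worn, 2)
    outage = np.zeros(total_min, dtype=bool)
    for day in range(n_days):
        for _ in range(rng.poisson(truth.gps_outage_blocks_per_day)):
            s = day * 1440 + int(rng.integers(0, 1440))
            outage[s:s + int(rng.integers(*truth.gps_outage_minutes))] = True
    recorded = fix_worn & ~np.repeat(outage, 2)
    acc = rng.gamma(truth.gps_accuracy_shape, truth.gps_accuracy_scale,
                    recorded.sum())
    theta = rng.uniform(0, 2 * np.pi, recorded.sum())
    radius = np.abs(rng.normal(0.0, acc / 2.0))
    gps = pd.DataFrame({
        "pid": participant.id,
        "timestamp": fix_times[recorded],
        "x": pos[recorded, 0] + radius * np.cos(theta),
        "y": pos[recorded, 1] + radius * np.sin(theta),
        "accuracy": acc,
    })
    device_track = pd.DataFrame({
        "pid": participant.id, "timestamp": fix_times,
        "x": pos[:, 0], "y": pos[:, 1]})
    info = {"bouts": bouts, "device_track": device_track, "home": home}
    return sensor, gps, info


def _street_path(start_idx: int, length: float, adj, nodes,
                 rng: np.random.Generator) -> np.ndarray:
    """Random non-backtracking walk along street edges, >= length meters."""
    path = [start_idx]
    total = 0.0
    prev = -1
    while total < length:
        nbrs = [k for k in adj[path[-1]] if k != prev] or adj[path[-1]]
        nxt = int(rng.choice(nbrs))
        total += float(np.hypot(*(nodes[nxt] - nodes[path[-1]])))
        prev = path[-1]
        path.append(nxt)
    return nodes[np.array(path)]


def _along_path(path: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Points at given arc-length distances along a polyline (clamped)."""
    seg = np.diff(path, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.r_[0.0, np.cumsum(seg_len)]
    d = np.clip(dist, 0.0, cum[-1])
    idx = np.clip(np.searchsorted(cum, d, side="right") - 1, 0, len(seg) - 1)
    frac = np.where(seg_len[idx] > 0, (d - cum[idx]) / seg_len[idx], 0.0)
    return path[idx] + frac[:, None] * seg[idx]


def relocate_to_street(world: World, x: float, y: float) -> tuple[float, float, float]:
    """Nearest street point and distance (convenience wrapper)."""
    (sx, sy), d = nearest_street_point(world.streets, (x, y))
    return sx, sy, d
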