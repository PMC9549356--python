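# Methods

This note documents the generative model, the exposure computation, the
estimation procedures, and the numerical and design choices behind them.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Study conditions emulated by the generator

The synthetic cohort and behaviour defaults are the conditions of the
emulated design: 46 participants, 52% female, age normally distributed
with SD 13 and truncated at 18 (the location parameter is solved so the
**post-truncation** mean is 41); nine monitoring days of which seven are
analyzed; a prompt economy of roughly 4–6 fired prompts per participant-day
with 65.5% compliance; about 8.5 analyzed entries per participant with
strong overdispersion (truncated negative binomial, dispersion 0.71,
clipped to 1–48); a four-level social-interaction distribution
(0.25, 0.20, 0.30, 0.25) whose median is 3; and a viewshed green
percentage with mean 34 and SD 32 spanning the full 0–100 range (Beta
distribution in the fast path, actual viewsheds in the sensor-level path).

## The affect truth and its calibration

Each affect dimension follows the two-level model

    Y_ti = mean + γ_sex·Sex_i + γ_age·Age_i + b1·D1 + b2·D2 + b3·D3
           + bg·Green_z + u_0i + r_ti,

u_0i ~ N(0, τ00), r_ti ~ N(0, σ²). The level-1 truth is specified in
**standardized** units (effect per predictor SD, in outcome-SD units),
because standardized coefficients are the scale on which such effects are
compared across studies. The raw generating coefficients are derived by a
deterministic fixed-point calibration, b_j = β_j · sd_Y / sd_xj, where
sd_Y solves

    sd_Y² = b'Σb + (1 − c)(τ00 + var of level-2 fixed effects) + σ²,

Σ being the joint covariance of the dummies and the standardized green
predictor. The factor (1 − c), with c = E[Σn_i²]/E[N²] computed from the
entry-count distribution, accounts for the loss of between-person variance
in a clustered **sample** SD: the analysis standardizes with realized
sample SDs, so the calibration must target the realized, not the
population, outcome SD. With this calibration the replicate mean of each
recovered standardized coefficient matches its configured value to well
within Monte-Carlo error at study size (verified by the recovery suite).

Greenness enters generation person-mean-centered and scaled by its
realized sample SD — the same parameterization the analysis uses — so the
within-person slope is recovered without attenuation. Dummies are left
raw in generation and analysis to preserve the reference-category
interpretation.

Default variance components, standardized targets, and level-2 raw
effects per dimension (valence / calmness / energetic arousal): grand
means 5.2 / 4.8 / 4.6; τ00 0.27 / 0.40 / 0.52; σ² 0.41 / 0.40 / 0.43;
β(D1, D2, D3, Green) = (−0.05, 0.07, 0.10, 0.02) / (0.06, 0.07, 0.16,
0.09) / (0.07, 0.13, 0.08, 0.08); sex −0.34 / −0.07 / −0.20; age 0.01 /
0.01 / 0.02 per year.

### Items, reliability, and discretization

Responses are generated at the latent dimension level and split into two
parallel items (item = latent + noise); the item-level model is a design
choice, since only dimension scores enter the analysis. The calmness
items are stored with the calm pole on the **low** end, mirroring the
printed anchor order (1 = relaxed), and reverse-keyed (7 − raw) at
scoring so that a higher processed score always means calmer.

Two response modes exist:

* **recovery mode** (default): continuous responses, no clipping or
  rounding. The model is then exactly linear-Gaussian and recovery
  experiments measure estimator behaviour, not discretization bias.
  Scores may fall slightly outside [1, 6].
* **realism mode** (`integer_items=True`, used by the sensor-level
  pipeline): items are clipped to [1, 6] and rounded to integers. The
  per-item noise variance is then calibrated by bisection on a large
  simulated sample so that pooled Cronbach's alpha of the discretized
  items hits the targets 0.85 (valence), 0.86 (calmness), 0.81
  (energetic arousal). For two parallel continuous items the closed form
  is alpha = 2v/(2v + w), hence w = 2v(1 − alpha)/alpha; clipping and
  rounding break the closed form, which is why the bisection simulates
  the full transformation. In any single 46-person run the realized
  pooled alpha scatters around the target with an SD of roughly 0.02
  (the realized spread of 46 random intercepts interacts with the scale
  ceiling), so the calibration property is asserted on a larger
  simulated cohort where the Monte-Carlo error is small.

## Movement, sensors, and triggers

Walking bouts are out-and-back trips from a home street node along a
random non-backtracking street path at 3–6 km/h, about six per day, 5–20
minutes each. During walking minutes movement acceleration is drawn above
the 0.1 g trigger threshold (0.15–0.45 g), otherwise below 0.08 g; step
rates are calibrated so that 180 s of walking accumulates ~N(193, 95²)
steps (truncated at zero). Device non-wear covers nights plus random
daytime blocks; steps and acceleration are zero when not worn.

The recorded GPS track has a fix every 30 s with per-fix accuracy drawn
from Gamma(3, 5) (mean 15 m, ~27% above the 20 m analysis threshold),
half-normal radial error scaled by accuracy/2, and realistic multi-minute
outage blocks. The **trigger**, however, consumes the device-internal
fused position (noise- and gap-free), emulating a handset that still
knows roughly where it is when the exported GPS is unusable; this is what
lets prompts fire whose locations later fail the GPS quality filter, as
observed in such studies.

Trigger logic: a candidate fires at minute t iff acceleration exceeded
the threshold for the sustained window ending at t, the current position
is more than 100 m from the central position (the centroid of fixes over
the preceding stationary interval), local time is inside 06:00–22:00, the
device is worn, and at least the cooldown (default 60 min) has passed
since the last firing; the central position then resets to the prompt
location. The cooldown and the centroid operationalization of "central
position" are explicit assumptions: continuous walking detection alone
would fire far more often than the handful of prompts per day such
designs report. Non-answered prompts split 50/50 into rejected and
missed; compliance is an independent Bernoulli per prompt (only the
aggregate rate is specified by the design).

## Preprocessing funnel

Answered prompts are successively filtered: analysis days (first and last
monitoring day dropped, anchored on the sensor stream's first day);
wear-time (a day is valid iff ≥ 8 h worn; participants with fewer than 7
valid days are flagged, and dropping them is a config switch, not
automatic); a recorded fix within 60 s of the prompt; accuracy strictly
below 20 m ("fewer than 20 m" read as exclusive); inside the study
boundary; nearest street point at most 30 m away (inclusive), with the
kept location snapped to that street point; and a complete six-item
diary. Stage counts are recorded in a funnel report whose counts are
non-increasing by construction and whose final count equals the
observation-table row count.

## Viewshed greenness

The surface model is the terrain bilinearly resampled to the target
resolution (default 0.5 m; the test and pipeline configurations use 2 m,
which changes only occlusion precision since land-cover class is
inherited from 10 m pixels either way) plus a uniform 8 m on building
footprints. A cell within the 100 m sight bound is visible iff the 3-D
segment from the observer's eye (ground + 1.7 m; observer height is a
config key) to the **cell's surface top** clears every interior profile
sample, taken by bilinear interpolation at quarter-cell steps with a 1e-6
m clearance tolerance; samples within half a step of the target are
skipped so a cell never occludes itself. Building roofs are therefore
both occluders and reachable targets — adding a building can flip its own
roof cells visible but never reveals anything beyond it. The production
test is fully vectorized per cell; an independent scalar ray-marcher at
10× sampling density serves as the oracle (≥ 99.5% per-cell agreement on
random building scenes). Quarter-cell (rather than coarser) sampling was
chosen because grazing rays along roof edges are the dominant
disagreement source.

Enclosed false regions of at most 25 fine cells (default) that do not
touch the disc boundary are filled, compensating for speckle holes from
discrete elevation sampling. Green percentage is the share of visible
fine cells whose center falls in a forest, low-vegetation, or water
land-cover pixel; water is merged into greenness (blue space is a
fraction of a percent of the land cover and has comparable associations
with affect), and per-class visible areas are reported so the
decomposition always sums exactly to the visible area.

## Estimation

Models are fit with statsmodels MixedLM. REML is used for all reported
fits; likelihood-ratio comparisons between mean structures refit by ML,
while the random-slope check compares REML fits with identical mean
structure (χ² with 2 df for the added slope variance and covariance — a
conservative approximation to the boundary mixture). The BFGS optimizer
is run with a tight gradient tolerance (1e-10) so that on balanced data
the variance components agree with the closed-form ANOVA estimators to
1e-6; a Powell restart covers the rare non-convergent case, which is
flagged on the fit rather than raised. Negative variance estimates are
truncated at zero with the convergence flag set.

Standardized coefficients use post-hoc scaling (estimate × SD(x)/SD(y),
realized sample SDs), which for fixed slopes in a linear model is
identical to refitting on z-scored data (cross-checked in the tests).
p-values use the normal approximation; CIs are Wald. No multiple-testing
correction is applied. ICC is reported as τ00/(τ00 + σ²); marginal and
conditional R² use the fixed-vs-total variance decomposition
(var(Xβ̂)/(var(Xβ̂)+τ00+σ²) and (var(Xβ̂)+τ00)/(·)).

The step-up sequence retains main effects regardless of significance
(matching how such final models are conventionally reported) and prunes
only the random-slope and interaction blocks when they fail to improve
fit at α = 0.05; every comparison is logged.

## Problem sizes

Recovery experiments use 200 replicates at 46 × ~8.5 observations — enough
for the Monte-Carlo standard error of a replicate-mean standardized
coefficient to be ~0.003. The recovered mean ICC from intercept-only fits
at 46 clusters sits about 0.02 below the generating ratio, the expected
small-sample bias of a ratio of variance-component estimates; the ICC
recovery check allows for it explicitly. The sensor-level pipeline
defaults to the full study size but completes in minutes at 2 m viewshed
resolution; oracle comparisons use 200×200-cell scenes with a 30 m sight
bound to keep the brute-force marcher affordable.

## What the synthetic data do not show

The generator validates the pipeline's statistics, not the science of
real cities: land cover is a stationary random field, not real urban
form; GPS error is radially symmetric; compliance is independent of
context (no mood- or place-dependent missingness); social context is
drawn independently of location and greenness, so the simulated
interaction truth is exactly zero unless injected; and affect responses
ignore weather, noise, and time-of-day dynamics. Passing recovery means
the estimation chain is unbiased under the stated model — not that the
model captures everything that shapes affect during real walks.
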