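# Methods

This note records the models, conventions, and design choices behind
`wardsense`, and what the synthetic cohort does and does not emulate.

## The monitored protocol being emulated

The package targets a remote-monitoring design for sub-acute rehabilitation:
patients in a skilled nursing facility wear a smartwatch from 09:00 to 18:00
daily over a course of up to 21 days, spend about one scheduled hour per day
in the facility's therapy area, and receive physical-therapy (PT) and
occupational-therapy (OT) assessment batteries at admission and weekly.
Discharge outcome is binary: most patients return to the community (~95%),
a few are readmitted to hospital (~5%). The population is overwhelmingly
sedentary — walking on the order of 0.2% of wear time — so the analytics are
built around movement *energy* rather than steps.

## Synthetic cohort generator

### Latent mobility

Each patient carries a latent mobility scale
`μ_i(t) = clip(μ_i0 + s_i·t_weeks, 0.3, 2.5)` with baseline
`μ_i0 ~ N(1.05, 0.12)` (hospital-group mean shifted down by 0.15) and
per-week drift `s_i` (+0.04 community, −0.02 hospital by default). The same
latent scale multiplies the per-activity movement-intensity baselines *and*
drives the weekly assessment scores, so sensor features and clinical
outcomes share one longitudinal signal — exactly the structure the mixed
models are meant to estimate. The hospital group additionally has its
resident-room MAD scaled by 0.8, reflecting lower in-room activity.

### Day schedules

Days are built on a 10-s slot grid (3,240 slots per 9-h wear day), so
ground-truth intervals tile the wear window exactly and all truth-bypass
time budgets are exact by construction. Per day: one therapy block of
60 min (jittered ±8%, placed uniformly), ~4 Poisson bathroom visits of
30 s–5 min, resident-room time filled with stationary bouts (mean ~10 min)
drawn as laying 0.25 / sitting 0.40 / standing 0.35, therapy time as
alternating 2–8-min sitting/standing efforts, and 4–8 slots (40–80 s) of
walking in 1–3-slot bouts. The realized walking fraction is ~0.18% of wear
time and the sedentary fraction ~99.8%, matching the monitored regime.
Whole days go missing independently with probability `p_missing_day`
(default 0.10), emulating watch refusal; within-day non-wear exists only in
raw mode via the windowing rules.

### Movement-intensity calibration

Per-activity MAD baselines are laying 0.005, sitting 0.012, standing 0.022,
walking 0.080 m/s², with lognormal window-to-window jitter (σ = 0.15 in log
space). With the activity mix above and κ = 1000, the cohort median overall
energy intensity lands in the mid-teens, inside the [13, 26] envelope of
typical weekly EI summaries for this population. The activity mix was chosen
once for this calibration; the baselines, mix and jitter are all
configurable.

### Raw-signal mode

Raw mode synthesizes 25 Hz triaxial samples: gravity on the z-axis plus a
zero-mean fluctuation whose realized MAD is rescaled to the window's target
(so regime MADs concentrate tightly around baseline × mobility × jitter),
clipped to the ±2 g hardware range. Standing windows carry a 0.3–0.8 Hz
postural-sway oscillation (60% of the fluctuation) and walking windows a
1.5–2.1 Hz gait oscillation (70%), giving the spectral features genuine
class information, as wrist signals have in practice. Beacon pings are
emitted once per second per beacon under a log-distance path-loss model
(−45 dBm at 1 m, exponent 2.0): the beacon co-located with the truth
location sits at 2 m (≈ −51 dBm), all others at 12 m (≈ −66.6 dBm), plus
Gaussian shadowing noise (σ = 4 dBm by default).

### Assessments

Functional levels (transfers, gait on level surfaces, bed mobility, lower
body dressing, toileting, hygiene) are integers 1–6 with **higher = more
independent**, generated as `round(base + 5·(μ_i(t) − 1) + noise)` clipped
to [1, 6]. Gait distance (feet) and activity tolerance (minutes) are
continuous and nonnegative, with week-over-week gains proportional to the
latent slope (≈ +56 ft/week and +4 min/week for community defaults), so
community medians rise from ~40 ft at admission to ~150 ft by week 2. All
assessment noise scales with `score_noise_sd`, so a zero-noise, zero-slope
configuration reproduces identical scores at every session.

### What the generator does *not* emulate

Real accelerometer artefacts (orientation changes, autocorrelated tremor,
device calibration drift), radio-layer beacon physics (multipath, body
shadowing beyond Gaussian noise), staggered enrollment, early discharge,
informative missingness (missing days are independent of health state), and
ordinal measurement structure beyond rounding a latent Gaussian. Passing
tests therefore demonstrate that the *pipeline computes its statistics
correctly under its assumptions*, not that those statistics would behave
identically on real cohorts.

## Signal conventions

- Magnitude is computed on raw axes, gravity included; MAD's translation
  invariance makes high-pass filtering unnecessary for energy metrics.
- Windows are non-overlapping, left-aligned, half-open `[kT, (k+1)T)` with
  T = 10 s. A trailing partial window is kept when it holds ≥ 50% of a full
  window's expected samples; a window is *worn* when ≥ 80% are present.
  Unworn windows carry no MAD, features, or energy (excluded, never zeroed).
- Moments are population (biased) estimators; kurtosis is the raw
  standardized fourth moment (3 for a Gaussian). The spectrum is a plain
  boxcar periodogram of the mean-subtracted window; peak frequency/power are
  its argmax/max, with a constant window reported as (0 Hz, 0 power).
- Displacement uses the gated constant-acceleration proxy ½·MAD·T²
  (threshold 0.02 m/s²). It is a relative movement index; treat absolute
  meters with caution.

## Labeling and dwell conventions

- Localization granularity is the 10-s analysis window; the window's
  location is the beacon with the highest **median** RSSI (robust to ping
  dropouts), `unknown` below a −90 dBm floor, ties to the lexicographically
  smallest beacon id.
- Activity ties (equal class probabilities) break by the fixed order
  laying < sitting < standing < walking.
- The dwell rule is strict: an occurrence requires a maximal same-location
  run of duration > 40 s, evaluated on the windowed location sequence
  (a 40.0-s run does not count).
- The reference classifier is a shallow seeded random forest (60 trees,
  depth 8) over MAD + the seven window features. Its contract is the
  accuracy floor (≥ 0.90 balanced accuracy on default regimes, measured
  ≈ 0.99), not the model family, which is swappable.

## Cohort and modelling conventions

- A valid day has ≥ 4 h wear (inclusive). Inclusion needs ≥ 3 valid days
  and ≥ 3 PT/OT sessions, pooled across disciplines, a session being one
  (patient, day, discipline) battery.
- Assessment-to-sensor merging minimizes |gap| over valid days only, with a
  hard maximum gap of 3 days and ties to the earlier sensor day; dropped
  assessments are logged so emitted + dropped = input.
- Weekly descriptives bin day 0 as admission and days 7(k−1)+1…7k as week
  k, with linear-interpolation quartiles; the mixed models instead use
  continuous weeks (t = day/7). These are deliberately separate conventions.
- Energy intensities of zero-time categories are missing, not zero, and
  complete-case rows are dropped per outcome × model (counted) so absent
  categories cannot bias the fits.
- The mixed models are Gaussian with identity link even for the ordinal 1–6
  levels — a single linear slope per term is the quantity of interest — with
  a random intercept per patient only (random slopes are a config option,
  off by default), REML estimation, and Wald z p-values without
  multiple-testing correction. Outcomes and EI covariates are z-scored over
  the analysis rows (the scaling record allows exact back-transformation);
  time stays in raw weeks so its coefficient reads per week.
- Estimation falls back from bfgs to powell if the optimizer fails;
  non-convergence is flagged, never silent, and boundary fits report
  σ_b² = 0.

## Validation strategy and problem sizes

The test suite validates each statistic against an independent brute-force
oracle (direct-sum MAD and moments, an independently coded periodogram,
run-length scans for occurrences, sorted order statistics for quartiles) on
hundreds to thousands of random instances at 1e-9 relative tolerance;
conservation laws (category times tile wear time; overall EI × wear time
decomposes identically over activities and over rooms) on simulated days;
the verbatim boundary rules on hand-built fixtures; and truth-bypass
pipeline exactness on a protocol-scale cohort of 110 patients × 21 days in
window mode. The mixed-model stack is validated by a 200-replicate recovery
experiment at 110 patients × 4 visits (effects: time 0.28, EI 0.22,
interaction 0; σ_b = 0.5, σ_ε = 0.7): bias within Monte-Carlo error, 95%
Wald CI coverage ≈ 0.94–0.97, type-I error of the null interaction ≈ 0.04.
These sizes keep the whole suite at about a minute and a half on one CPU
while exercising the pipeline at the full protocol scale.

## Known limitations

- The displacement proxy is a heuristic index, not validated kinematics.
- Gaussian mixed models on ordinal 1–6 outcomes trade ordinal correctness
  for a single interpretable slope; a cumulative-link model would be the
  statistically stricter choice.
- The localizer is nearest-beacon only; no trilateration or fingerprinting.
- Simulated effect sizes and noise levels are plausible but not fitted to
  any real dataset; coefficient magnitudes from simulated cohorts should
  not be read as clinical estimates.
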