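# Methods

This note documents the models, conventions and design choices behind
`cubsign`, in the order the pipeline runs them.

## 1. Synthetic bear-years (`cubsign.simulate`)

**What it emulates.** One simulated bear-year is: den residency (metre-scale
jitter within 50 m of the den) for `den_residency_days`, then a
heading-autocorrelated correlated random walk (CRW). Each movement day's
total path length is Gamma-distributed with mean `mean_daily_displacement`
(km/day) and coefficient of variation `displacement_cv`, split evenly over
the day's steps; step headings perform a wrapped-normal random walk whose
turning SD is set so that E[cos(turn)] equals `directional_persistence`
(ρ = 1 is straight-line travel, ρ = 0 is uniform headings). The simulator
works directly in planar km with the den at the origin — the analysis is
scale-dependent, not place-dependent, and projection is an ingestion
concern.

The movement model is deliberately **not** the CTCRW used for
standardization, so the interpolation stage is never validated against its
own generating process. An exact CTCRW simulator
(`ctcrw.simulate_ctcrw_track`) exists separately for parameter-recovery
studies.

**Observation model.** Fix times walk forward with i.i.d. uniform intervals
from `fix_interval_range` (defaults: 15 min–6 h for GPS-era grizzly
collars; 1–24 h for the mixed polar fleet, which also has 10% whole-day
dropouts and 50% Argos fixes). Whole days vanish with `gap_probability`.
Each fix gets isotropic Gaussian noise with a per-axis SD equal to its
source's assigned accuracy: GPS 30 m; Argos classes 0/1/2/3/A/B/Z =
6800/2500/1000/400/4100/7600/4700 m, class drawn uniformly from
{0,1,2,3,A} by default. **Convention:** "accuracy" is applied as the
per-axis SD, so the 2-D RMS error of a fix is accuracy × √2. The accuracy
tables this mimics do not define an RMS; the same convention is used in the
CTCRW measurement model, so simulator and filter are consistent.

**Class contrast and heterogeneity.** Females with cubs travel less per day
than females without, and polar bears travel several-fold more than grizzly
bears at matched status. No quantitative movement model for either class is
published, so the default profiles are plausible calibrations, not
canonical values:

| profile | class | mean daily displacement | day CV | persistence ρ | residency |
|---|---|---|---|---|---|
| grizzly | cub-present | 1.8 km/d | 0.5 | 0.35 | 4 d |
| grizzly | cub-absent | 3.1 km/d | 0.7 | 0.60 | 3 d |
| polar | cub-present | 12 km/d | 0.55 | 0.90 | 4 d |
| polar | cub-absent (non-denning) | 16 km/d | 0.5 | 0.75 | 0 d |

Real cohorts overlap heavily in every single metric, and that overlap —
not the class means — is what makes the classification problem
interesting. The generator therefore adds structured heterogeneity:

* between-individual lognormal scatter on mean daily displacement
  (`individual_cv`, default 0.3) and truncated-normal scatter on
  persistence (`individual_persistence_sd`, default 0.15);
* between-ecosystem scale: per-population multipliers on daily displacement
  (grizzly default 0.65 for GYE, 1.6 for NCDE), so the class contrast lives
  *within* populations while marginal distributions overlap;
* cub-present females draw departure dates from a distribution shifted ~10
  days later in spring, consistent with later emergence of maternal females.

With these defaults, the per-metric standardized class difference
(Cohen's d) at 30 days is ≈ 0.6–1.3 — overlapping boxplots, not separated
ones — while the joint contrast still supports ~0.85–0.90 leave-two-out
accuracy at n = 30, and a sample-size learning curve that rises from
n = 10 to n = 30 and then saturates. Non-denning polar females (the
cub-absent class) get `den_residency_days = 0` and a pseudo-departure date
drawn with replacement from the empirical departure-date distribution.

**What it does not emulate:** habitat, sea-ice drift, elevation, home-range
fidelity, multi-year individual effects, temperature-sensor departure
dating. A passing pipeline on synthetic cohorts demonstrates the machinery
is correct and well-calibrated under the stated movement model; it cannot
certify accuracy on real telemetry.

## 2. Preprocessing (`cubsign.preprocess`)

Filters are applied in order, all with **strict** inequalities (a fix at
exactly 125 m / PDOP 10 / 25 km h⁻¹ survives): GPS horizontal error
> 125 m; GPS PDOP > 10 only for populations configured with that rule (GYE
by default); then a forward-iterative speed screen — a fix implying > 25
km/h from the previously *retained* fix is dropped and its neighbours
re-linked, so one bad fix cannot shadow a good one. Filtering is
idempotent and never mutates its input.

Den departure is the first fix farther than the species threshold (0.25 km
grizzly, 3 km polar land dens) from the den such that none of the next 10
records returns within the threshold. If fewer than 10 records remain after
a candidate, the rule is applied to those that do (the series ends away
from the den). Sea-ice dens, whose departure is dated from temperature
sensors, must arrive with `departure_time` supplied; the same mechanism
carries non-denners' pseudo-departures. The artifact filters first and
detects departure on filtered fixes.

Bear-years are clipped to [departure, departure + 60 d]. A day *k* "has
data" if at least one retained fix falls in
[departure + 24k h, departure + 24(k+1) h). Eligibility for a period P
requires data on ≥ 75% of days 0..P−1, with the **full** P-day
denominator. Grizzly cub-present series are additionally truncated at the
last observation confirming cubs, and are ineligible for any period
extending past that truncation — beyond it the label itself, not just the
coverage, is unverified. This reproduces the characteristic shrink of
usable sample sizes as the period lengthens.

## 3. CTCRW standardization (`cubsign.ctcrw`)

The model is the integrated Ornstein–Uhlenbeck-velocity process per axis,

  dv = −β v dt + σ dW,  dx = v dt,

with one (β, σ) pair shared by x and y, no drift, and no behavioural
switching. β (1/h) sets the velocity decorrelation time 1/β; σ (km/√h)
sets the stochastic scale. Measurement error is fixed (not estimated) at
the assigned per-axis SDs above. The exact discrete-time transition over a
gap Δ is

  F = [[1, (1−e^{−βΔ})/β], [0, e^{−βΔ}]],

with the standard integrated-OU process covariance; for βΔ < 10⁻⁴ the
position variance uses its series form σ²Δ³/3 · (1 − 3βΔ/4) to avoid
catastrophic cancellation.

`CTCRW.loglike` is the exact Gaussian log-likelihood by forward Kalman
filtering (x and y share the covariance recursion, so one pass filters
both). `fit()` maximizes over (log β, log σ) with L-BFGS-B from a 3 × 3
multi-start grid around a moment-based guess (β₀ = 0.1/h; σ₀ from the
median empirical speed via the stationary velocity variance σ²/2β); ties
break to the highest log-likelihood, then the smallest β. The initial
state is the first fix with zero velocity and a diffuse covariance
(10⁴ km², 10² (km/h)²). Duplicate timestamps are legal (Δ = 0 steps);
fewer than 4 fixes is an error and fewer than 8 flags a low-information
fit. One CTCRW is fitted per bear-year.

Predicted locations are the RTS-smoothed state means on the exact grid
departure + k·interval (interval 6 or 24 h) — the posterior mode of a
Gaussian, i.e. the maximum-likelihood location. The smoother will
extrapolate past the last fix but warns beyond a configurable horizon
(24 h). Filter and smoother are validated against brute-force
joint-Gaussian conditioning to ~10⁻¹⁰ relative error.

## 4. Movement metrics (`cubsign.features`)

Daily net displacement (DND) for 24-h tracks is the distance between
consecutive daily locations. For 6-h tracks the daily value is the
**sum** of the four within-day step lengths — a path length, kept so the
daily scale is comparable across intervals; a zig-zag day scores its full
path length even with zero net motion, and this convention is documented
rather than hidden. Threshold-day counts use strict inequalities. Maximum
net-squared displacement (km²) is evaluated at standardized grid positions
only. (Displays elsewhere that label NSD in "gigameters" are treated as an
axis-scaling artifact; this package uses km² throughout.) R̄ is the mean
resultant length of the *absolute headings* of nonzero steps within the
period — 1 for straight travel, near 0 for fully dispersed headings; it is
rotation-invariant and lives in [0, 1].

Feature vectors are nested: the model for period P stacks the six metrics
for every analysis period ≤ P, after a one-hot (sub)population encoding
and the departure date as Julian day (day-of-year of the bear's local
calendar year; for non-denners this is the pseudo-sampled date).
Standardization is Z-scoring with the **sample** SD (ddof = 1);
zero-variance columns are flagged and passed through as exactly 0. The
default reference is the training fold only; a `global` option reproduces
the simpler pre-CV standardization.

## 5. Classification (`cubsign.classify`)

C-classification SVMs with per-class penalty `cost × w_c`; the default
class weights are inverse frequencies, w_c = n_total / (2 n_c), so the
larger class cannot dominate. The tuning grid is kernels {linear, radial,
polynomial, sigmoid} × cost {0.01, 0.1, 1, 3, 4, 5, 10, 50}, with γ =
1/n_features, degree 3, coef0 0; grid points are scored by stratified
10-fold inner CV (leave-one-out when a class has < 10 samples), ties
breaking to smaller cost, then kernel order linear < radial < polynomial <
sigmoid. A single-point grid is returned without inner CV.

Leave-two-out CV withholds every (cub-present, cub-absent) pair —
n_present × n_absent iterations, two predictions each. Within each
iteration the training fold is standardized and (by default) re-tuned, so
no statistic of the withheld pair ever touches training; a constant-in-
training canary feature demonstrably cannot move fold standardization.
`tune_mode="once"` instead tunes a single configuration on the full
standardized data first — the procedure that matches a single reported
kernel/cost per dataset, and the experiments module's default. The two
modes trade leakage for fidelity: tune-once is slightly optimistic
(selection sees all samples), which matters near chance level — the null-
calibration check therefore uses per-fold tuning — while per-fold tuning
occasionally underfits trivially separable folds because the smaller-cost
tie-break picks C = 0.01 when every config ties at inner accuracy 1.

## 6. Experiments (`cubsign.experiments`)

`run_full_data` mirrors the all-available-data design: one LTOCV per
period on the bears eligible at that period (rows marked not-estimable
below 2 + 2). `run_sample_size` holds the period at 30 days and draws
balanced subsets of 10–50 bears (100 iterations by default; the validation
suite uses 20 to stay within desk-scale runtimes) and reports median
sensitivity/specificity/accuracy. `run_period_length` holds n at 15 + 15
(the Methods/Table value; the Results prose's 13 + 13 is reachable via
`n_per_class`) and draws a fresh subset per period per iteration.
Subsets are drawn without replacement, seeded by (experiment seed, cell
index, iteration index), so partial re-runs reproduce. `run_early_departure`
trains one tuned SVM per period on the full training cohort and predicts a
disjoint holdout — the synthetic analogue of testing January-departing
females against models trained with non-denners as the cub-absent class.

## Problem sizes and numerical choices

Synthetic validation cohorts simulate 36 post-departure days (26 for
holdout bears), 15–27 bears per class, standardized at 24 h — sizes chosen
so the full suite runs in minutes on one CPU while every stage operates in
its realistic regime. CTCRW parameter recovery uses 50 replicates of 200
fixes at 2-h spacing. Degenerate inputs are handled explicitly: zero
movement and zero CV collapse the Gamma draw to constants; ρ = 0/1 bypass
the wrapped-normal turn; empty fix tables and single-class training raise
typed errors.

## Known limitations

* The CTCRW has a single behavioural state; haul-out/resting phases and
  Argos error ellipses are out of scope.
* Measurement SDs are assigned, not estimated; misassigned Argos
  accuracies propagate directly into the smoother.
* The leave-two-out accuracy of an exhaustive CV is an average of highly
  correlated predictions (each bear is re-tested against every
  opposite-class partner with nearly identical training sets), so its
  sampling variance across cohorts is several times the nominal binomial
  variance — near-chance accuracies should be interpreted against
  bear-level, not prediction-level, noise.
* Synthetic calibrations are plausible, not estimated from telemetry;
  elevation/habitat covariates and litter-size effects are out of scope.
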