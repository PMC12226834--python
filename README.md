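# cubsign

Infer whether a denning female bear left her winter den **with or without
cubs-of-the-year**, using nothing but her satellite-collar locations after
den departure.

For grizzly bears (*Ursus arctos*) and polar bears (*U. maritimus*), den
visits are unsafe and aerial observations often happen weeks after
emergence, so early-spring reproductive status — a vital rate that reacts
first to environmental change — is hard to obtain. Females with young cubs,
however, move measurably less and differently than females without them in
the weeks after departure. `cubsign` turns that signal into a classifier:

1. **Quality-filter** collar fixes (GPS horizontal error > 125 m, PDOP > 10
   where that rule applies, implied travel speed > 25 km/h).
2. **Detect den departure** — first fix > 250 m (grizzly) or > 3 km (polar,
   land dens) from the den with no return within the next 10 records.
3. **Standardize** the irregular, heteroscedastic fix series with a
   continuous-time correlated random walk (CTCRW): along each axis the
   velocity is an Ornstein–Uhlenbeck process, dv = −βv dt + σ dW, dx = v dt,
   observed through Gaussian location error (GPS 30 m; Argos classes
   0/1/2/3/A/B/Z = 6800/2500/1000/400/4100/7600/4700 m). The exact
   likelihood comes from Kalman filtering; maximum-likelihood locations at
   24-h (or 6-h) intervals come from the RTS smoother.
4. **Compute six movement metrics** over nested post-departure periods
   (5–60 days): cumulative daily net displacement; days with daily
   displacement < 1, > 2, > 5 km (grizzly; 5/10/25 km for polar bears);
   maximum net-squared displacement; mean resultant length R̄ of step
   headings. Features also include (sub)population and departure Julian day,
   all Z-scored.
5. **Classify** with class-weighted, grid-tuned kernel SVMs, validated by
   exhaustive **leave-two-out cross-validation** (every cub-present ×
   cub-absent pair withheld in turn), reporting sensitivity, specificity and
   accuracy.

A built-in synthetic bear-cohort generator (a heading-autocorrelated random
walk with den residency, individual heterogeneity, irregular sampling, data
gaps and per-class Argos/GPS noise) makes the whole pipeline testable
without field data.

## Worked example

```python
import cubsign as cs
from cubsign.preprocess import preprocess_cohort

# 15 + 15 synthetic grizzly bear-years; filter, detect departure, clip
bears = preprocess_cohort(cs.generate_cohort(15, 15, cs.GRIZZLY_PROFILE, seed=1))

# CTCRW-standardize to daily locations, build 30-day nested features
tracks = cs.standardize_cohort(bears, interval=24.0, horizon_days=30)
elig   = cs.eligible_subset(bears, 30)           # 75%-of-days coverage rule
X, y   = cs.build_feature_matrix(elig, tracks, 30)

report = cs.leave_two_out_cv(X, y, seed=0, tune_mode="once")
print(report.summary())
```

```
Leave-two-out cross-validation
------------------------------
n cub-present         15
n cub-absent          15
iterations           225
sensitivity         0.99
specificity         0.79
accuracy            0.89
tuned kernel/cost  radial/3
```

Each of the 225 iterations withholds one cub-present and one cub-absent
bear-year, standardizes and trains on the remaining 28, and predicts the
withheld pair; sensitivity/specificity are the fraction of cub-present /
cub-absent predictions that were correct. Under the default generator the
classes overlap in every single metric (as real cohorts do), so accuracy in
the 0.8–0.9 range at n = 30 is the expected regime, rising from roughly
0.75 at n = 10 and saturating near n = 30.

The same pipeline is scriptable from the shell:

```bash
cubsign simulate --species grizzly --n-present 15 --n-absent 15 --seed 1 --outdir run/sim
cubsign preprocess --fixes run/sim/fixes.csv --manifest run/sim/manifest.csv --outdir run/pre
cubsign cv --fixes run/pre/fixes.csv --manifest run/pre/manifest.csv --period 30 --outdir run/cv
cubsign experiment samplesize --fixes run/pre/fixes.csv --manifest run/pre/manifest.csv --outdir run/ss
```

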