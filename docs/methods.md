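# Methods and design rationale

This note records the modeling choices behind `phenosense`: what the
synthetic cohort generator assumes, which conventions the feature
extractors fix, and why the evaluation protocol looks the way it does.

## Synthetic cohort model

Each participant carries a single latent trait `z ~ N(0, 1)` that stands
in for chronic stress load. It propagates two ways.

**Outcomes.** PSS and MCS load on the same latent with independent
noise. With loading `b = sqrt(1 − σ²)` and noise scale `σ = 0.25`:

```
PSS* = b·z + σ·ε          →  PSS = round(clip(17.1 + 6.5·PSS*, 0, 40))
MCS* = −d·z + σ_mcs·ε′    →  MCS = round(clip(40.4 + 9.5·MCS*, 5, 75), 1)
```

where `d = |r| / b` is chosen so that corr(PSS, MCS) hits the target
`r = −0.71` in expectation before rounding. The loadings are asymmetric
(PSS takes `+b`, MCS takes `−d`) because solving the symmetric problem
for two different noise scales has no closed form; this version does,
and `CohortConfig.validate` rejects (noise, target) pairs for which
`d² + σ_mcs² > 1` would make the target unreachable. Rounding and
clipping to instrument ranges attenuate the sample correlation only
slightly (≈ −0.75 observed at n = 200).

**Behavior.** Each effect family scales a behavioral rate through a
log-normal multiplier `m = exp(0.35·effect·z + 0.05·η)`: electrodermal
peak rates (4/min awake, 1/min asleep at baseline), nap counts, mobility
radius, screen-on time, and bedtime jitter. With all effect sizes at 0,
behavior is independent of the outcomes — the null configuration used by
the recovery tests.

Skin conductance is a baseline plus sparse SCR events convolved with a
biexponential kernel (the kernel degenerates to a unit impulse below
1-minute sampling, where its shape is unresolvable). Streams, phone
logs, diary, and sleep episodes are all derived from one
`numpy.random.SeedSequence` tree, so every byte of a dataset is a
function of the seed.

**Exact persistence.** Datasets round-trip through CSV exactly:
floats are written with `%.17g`, read back with
`float_precision="round_trip"` (pandas' default parser is 1 ULP off on
some 17-digit decimals), and empty bed/wake strings are restored after
`read_csv` turns them into NaN.

## Sensor conventions

- **Filtering:** zero-phase-intent FIR low-pass, 0.4 Hz cutoff, order
  32. The design requires `sample_rate > 2 × cutoff`; lower rates raise
  rather than silently aliasing.
- **Validity:** inclusive physiological ranges (SC 0.01–30 µS, ST
  20–42 °C) AND-ed with any device validity mask.
- **Peaks:** one event per maximal run of first-difference slope
  strictly above 0.02 µS/s; the event time is the run onset. A slope of
  exactly 0.02 is not an event. Detection is offset-invariant by
  construction (it sees only differences).
- **Epochs:** 30-s epochs aligned to absolute midnight, not to the
  first sample. Each inter-sample trapezoid is assigned to the epoch
  containing its left sample, so epoch AUCs sum exactly to the
  whole-series integral. An epoch is valid when at least 50 % of its
  expected samples are present and in range — 15 of 30 at 1 Hz counts
  as valid.
- **Windows:** day 9:00–18:00, night 18:00–24:00, late night 0:00–3:00,
  plus the diary-defined sleep window; 17 base features × 4 windows ×
  3 aggregates = 204 columns.

## Sleep

SRI is `−100 + 200·P[state(t) = state(t + 24 h)]` over minute pairs
where both states are observed; a perfectly repeating schedule scores
100, a 24-hour-alternating one −100, and a memoryless random schedule 0
in expectation. Bedtimes are averaged on a circular axis referenced to
18:00, so a 23:30/00:30 pair averages to midnight rather than noon.
`vector_from_episodes` rasterizes unknown minutes as wake: diary-backed
days are treated as observed, and the missing code is reserved for
truly absent days.

## Evaluation protocol

Outer loop: leave-one-cohort-out, so no fold ever trains on a
participant from its test cohort (cohort = recruitment wave). Within
each training fold, entirely: median imputation and standardization are
fit on training data only; a Welch-t prefilter keeps the 100 smallest
p-values (undefined p-values rank last — which is what structurally
excludes any feature that is constant on the training side); sequential
forward selection adds up to 5 features, scoring each candidate set by
inner 10-fold stratified CV jointly over the SVM (C, γ) grid; ties break
toward the lower prefilter rank, and the shortest best prefix wins. The
L1-logistic alternative ("lasso", liblinear) skips the prefilter and
SFS — its selection is the set of nonzero coefficients. Accuracy is
pooled over out-of-fold predictions with an adjusted-Wald (Agresti–
Coull) 95 % interval, which stays inside [0, 1] at the edges where the
plain Wald interval fails.

The inner grid search dominates runtime, so the hot path calls
scikit-learn's low-level `_libsvm` binding directly (verified to give
bit-identical predictions to `SVC`), with `SVC` as fallback. This is a
constant-factor speedup only; the protocol is unchanged.

## Group statistics

Per-feature two-sample tests route by a Shapiro–Wilk screen (α = 0.05,
both groups normal → Welch t, otherwise Mann–Whitney); features constant
in both groups are skipped. p-values are adjusted with
Benjamini–Hochberg over the tested features only.

## Problem sizes

Defaults model a realistic study (30 days at 8 Hz SC), but tests and
examples deliberately run smaller instances — 2–4 days at 0.5–1 Hz,
cohorts of 6–100 — chosen so the full test suite completes in minutes
on one CPU while still exercising every code path at realistic feature
dimensionality (the 204/237/441-column blocks are invariant to the
duration). The parameter-recovery experiment uses n = 100 over 5
cohorts, 4 days at 1 Hz, with an `sc_peak_rate` effect of 1.5: large
enough that cohort-level cross-validation has ~20 test participants per
fold, small enough to run in about a minute.

## Limitations

The generator is a calibration and validation instrument, not a
physiological simulator: SCR shapes, mobility, and diary behavior are
simplified, missingness is artifact-style rather than behavioral, and
the latent structure is one-dimensional. Conclusions about real cohorts
require real data; what the synthetic path certifies is that the
pipeline recovers known structure and reports chance when none exists.
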