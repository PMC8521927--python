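# Methods

This note documents the models behind `somnoseason`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions a user should know before trusting or
extending the results.

## 1. Sleep/wake inference from trunk acceleration

A tri-axial trunk trace (default 31.25 Hz, units of g) is split into
non-overlapping 1-min epochs aligned to the trace start (not to wall-clock
minutes). Per epoch:

* **Gravity / posture.** A moving-average low-pass with a 5 s window
  estimates the gravity vector per sample; tilt is the angle between that
  vector and the device's longitudinal axis (z by convention, configurable).
  A centered moving average was chosen because it is phase-free and cheap;
  the window is configurable (`FeatureConfig.gravity_window_s`). Epochs whose
  gravity estimate has essentially zero norm (a dead sensor) raise a
  degenerate-input error naming the epoch rather than producing NaN tilt.
* **Activity.** Local variances of the high-pass residual (sample minus the
  gravity estimate) per axis, plus their sum (`local_variance_norm`). The
  residual of a pure sinusoid of amplitude *a* well above the low-pass
  corner has variance a²/2, which the tests use as an oracle.

The classifier is an RBF-kernel SVM (scikit-learn `SVC`, C = 1, gamma
"scale", class-balanced weights) on standardized features, with variances
entered as log10 — they span several decades between quiet sleep and
daytime activity, and the log makes the two regimes comparable in scale.
The kernel and hyperparameters are this package's defaults, documented
stand-ins rather than a replication of any particular published classifier.
Post-hoc median smoothing of labels exists but is OFF by default. Metrics
treat sleep as the positive class.

## 2. Sleep scoring

Scoring operates on per-minute labels anchored to the recording-start-day
midnight; all clock-like quantities are elapsed minutes in [0, 2880].

Rest-interval detection (the database has no event marker): candidate
epochs are recumbent (tilt > 60°) **or** quiescent (total local variance
below the recording's 0.25 quantile); candidate runs separated by gaps of at
most 20 min are merged; the longest merged block of at least 180 min that
intersects the 18:00–12:00 overnight window is the rest interval. Without
features the fall-back candidacy is the sleep labels themselves. All four
thresholds are configurable (`ScoringConfig`); their defaults reproduce
"gets into bed to sleep" semantics from posture and quiescence.

Scoring conventions, fixed and tested against an independent brute-force
oracle:

* sleep onset = start of the first run of ≥10 consecutive sleep minutes at
  or after in-bed time (searched strictly before get-up); records with no
  such run are unscorable and excluded from statistics, with a logged count;
* the WASO/WEP window is half-open [onset, get-up) — the get-up minute
  itself is excluded;
* a wake episode is any maximal wake run of length ≥1 (no minimum episode
  length);
* TST + SL + WASO = TIB holds as an exact integer identity and
  SE = 100·TST/TIB exactly.

## 3. Meteorological exposures

Daily tables carry mean Ta [°C], humidity [%], pressure [hPa] and local
sunrise/sunset clock times per (date, location). A recording spanning two
consecutive days gets the arithmetic 2-day mean of Ta/humidity/pressure, the
sunset of day 1 (the evening before sleep) and the sunrise of day 2 (the
morning of awakening). Sunrise/sunset enter regressions as minutes from
their own day's midnight — the constant 1440 offset of day-2 clock times is
absorbed by intercepts — while in-bed/get-up times use the 0–2880 elapsed
scale. Single-day (not 2-day-averaged) sun times are used because the night
actually slept is bracketed by exactly one sunset and one sunrise; the
pairing is configurable in the reader conventions.

## 4. Seasonality statistics

"Seasonal model" means ordinary least squares with identity link and
Gaussian error — the responses are continuous and reported as mean ± SEM, so
nothing beyond the Gaussian case is needed. Terms: month (12 levels,
reference July — the comparison anchor), age decade (8 levels, reference
60s, the largest cell), gender (reference male), and an age×gender
interaction screened by an F-test at p < 0.01; when not significant the
model is refit without it, when significant monthly contrasts are also
computed within gender strata. Records with unknown gender are excluded
from model fitting. The month-vs-July contrasts are Bonferroni-adjusted
within a family of 11 contrasts per sleep parameter (not pooled across
parameters). The study-wide significance threshold is 0.01.

The annual sinusoid is fitted to the 12 monthly means by linear least
squares on (1, cos 2πm/12, sin 2πm/12); amplitude and peak phase follow
algebraically, so the fit equals direct nonlinear least squares exactly on
noiseless input. At least three observed months are required.

## 5. Adaptive LASSO with bootstrap model averaging

For response *y*, candidates {ta, humidity, pressure, sunset, sunrise} are
standardized internally; gender and age-decade dummies plus the intercept
are always included and never penalized. Adaptive weights are 1/|β̂|, γ = 1,
with β̂ from the unpenalized OLS of the full design — the standard adaptive
LASSO initializer (configurable). Profiling out the unpenalized block
(Frisch–Waugh) reduces the problem to a weighted LASSO path on the
residualized candidates; every distinct support along the path is refit by
OLS and scored by SBC = n·ln(RSS/n) + k·ln(n) with k counting all estimated
coefficients; the SBC-minimal support is then pruned to a fixpoint by
dropping any candidate with refit p ≥ 0.01. This pruning reproduces the
guarantee that every selected coefficient is individually significant
without emulating any particular solver's entry/exit rules. Reported
coefficients are on the original covariate scale.

Bootstrap averaging draws B record-level resamples (with replacement,
resample size n), runs the selector on each, scores candidates by selection
frequency, keeps those at or above the cutoff (default 70%), and reports the
ensemble mean ± SD of the final model refit to every resample. Averaging
only over the resamples that selected a term is available as a switch
(`average_all_resamples=False`); the default averages over all resamples
because the final model is a fixed, post-selection object. Degenerate
resamples are skipped and logged; more than 10% skipped is a hard error.
B defaults to 5,000; analyses in the test suite and the acceptance script
use B = 300, where the binomial error of a frequency estimate
(√(f(1−f)/B) ≈ 2.6 points at f = 0.5) is already far from the 65–80%
decision band.

Ridge-based selection (no path; candidates significant at p < 0.01 in the
unpenalized full refit) and elastic-net-based selection (path with
l1_ratio = 0.5, same SBC + pruning) run inside the same bootstrap wrapper
for robustness comparisons.

## 6. The synthetic-data generator

The generator defines the study conditions; everything downstream is
validated against it.

**Meteorology.** Annual cosines (period 365.25 d) for Ta, humidity,
pressure, sunrise and sunset around Tokyo-like levels: Ta from 5 °C (winter)
to 28 °C (peak near day 216), humidity 55–75% with a +8% rainy-season bump
(days 152–196), pressure 1008–1020 hPa peaking in winter, sunrise between
4:30 and 7:00, sunset between 16:30 and 19:00. Day-to-day Gaussian noise
(Ta 3.5 °C, humidity 8%, pressure 4 hPa, sun times 10 min) represents both
weather variability and the cross-station dispersion of a nationwide cohort;
it is also what keeps five same-period cosines jointly identifiable as
regressors — with no non-seasonal variation they would span only a
two-dimensional seasonal subspace and no selection method could separate
them. The sunrise phase is not set astronomically: it is solved analytically
(including noise attenuation) so that the Pearson correlation between daily
Ta and sunrise elapsed minutes over a year equals a configurable target,
0.70 by default — the collinearity level the variable selection must cope
with — and it is placed on the far side of the Ta peak from the sunset peak
so sunrise and sunset remain well-conditioned as separate regressors.
Consequently the simulated sunrise cycle reproduces the *range* and the
*collinearity* of the real one, not its calendar phase; analyses that need
real solar phase should supply their own meteorology table.

**Cohort records.** A 12×8 month × age-decade count table (the published
cohort's counts by default, rescalable per month) fixes the sample
structure; gender is drawn at the published female fraction with an optional
"unknown" fraction that downstream statistics exclude. Each sleep parameter
follows a structural model: intercept + month offset + age offset + gender
offset + Σ coefficient × covariate + Gaussian noise. Because
TST + SL + WASO = TIB binds the parameters, exactly one of TST, SE or
get-up is drawn from its model (the `tib_driver`) and the accounting is
completed deterministically; minutes are rounded to integers with the
identity enforced exactly, and SE recomputed from the integers. WEP is drawn
and clipped to [1 if WASO > 0 else 0, min(WASO, TST−10)] so a label sequence
realizing the record always exists; `synthesize_labels` constructs one (wake
prefix of length SL, a 10-min onset run, WASO split into exactly WEP maximal
wake runs at random admissible positions) and scoring it returns the
record's parameters exactly — the round-trip the tests rely on.

For coefficient-recovery cohorts the response operating point is placed at
least ~3 residual SDs from its physical boundary (WASO mean 150 min at
sd 40, SE mean 88% at sd 5, SL mean 60 at sd 10 when used as a response):
near a boundary the enforced truncation (WASO ≥ 0, SE ≤ 100) would bend the
structural model and attenuate the very coefficient being recovered.
Within-month meteorological variance is not published anywhere we know of;
the noise SDs above are assumptions and are recorded as such.

**Acceleration traces.** A script is an ordered, contiguous schedule of
(state, start, duration, posture angle, activity variance) entries. Samples
are the gravity unit vector pitched about the x axis by the posture angle,
plus white activity noise of the scripted per-axis variance, plus sensor
noise; 60 × 31.25 = 1875 samples per minute. Ground-truth labels and the
true rest interval (first to last sleep entry) come with the trace. The
standard fixture suite is 3 randomized days × 2 sensor-noise levels (0.005
and 0.02 g): daytime upright activity, a 6.5–8 h recumbent night with 2–5
brief wake bouts of intermediate activity, and a morning after. Scripted
states change on whole-minute boundaries, so every epoch has a pure label;
real transitions are gradual, which is one reason real-data accuracy would
be lower than the fixture suite's ~99%.

**What passing tests do and do not show.** The generator produces exactly
the structure the estimators assume: linear effects, Gaussian noise,
Gaussian-ish activity, posture as a clean scalar rotation. Passing the
recovery suites therefore demonstrates correctness of the implementation
under its stated model, and calibrated realism of magnitudes — not
robustness to model misspecification, device artifacts, circadian drift
within the night, or regional climate gradients (deliberately not modelled).

## 7. Problem sizes and numerical conventions

* Monthly-mean recovery runs 5,000 records/month (60,000 records) through
  label synthesis and re-scoring; with residual sd 100 min the monthly SEM
  is ≈1.4 min, comfortably inside the ±3 min (0.05 h) check.
* Coefficient recovery uses single cohorts of n = 10,000 and B = 300
  bootstrap replicates per response. With residual sd 100 min and
  sd(Ta) ≈ 8.5 °C the sampling SE of the recovered Ta→TST coefficient is
  ≈0.12 min/°C; recovered values scatter around the generating −1.58
  accordingly.
* The classifier gate trains on four fixture recordings and evaluates two
  held-out ones (one per noise level), ~2,880 evaluated minutes.
* All randomness flows from one master seed through named substreams
  (`meteo:<location>`, `cohort`, `accel`, `labels`,
  `bootstrap:<response>:<selector>`), so stages can be regenerated
  independently and whole runs are byte-identical given a seed.
* Ties and degenerate inputs: variance floors at 1e-12 g² before logs;
  lasso-path supports are deduplicated before SBC scoring; perfectly
  collinear candidates raise rather than silently dropping a column; months
  with no records are reported missing, not zero; single-record months have
  undefined SEM.

## 8. Known limitations

* The sunrise/sunset model trades calendar phase for collinearity realism
  (see §6); do not interpret the synthetic sunrise dates literally.
* Each subject appears once; no longitudinal or mixed-effects structure.
* No sleep staging, nap scoring beyond the primary interval, light exposure,
  or behavioral thermoregulation; a U-shaped Ta response is not modelled
  (effects are linear in the generator and in the regressions).
* SAS-style selection internals are not replicated; the SBC + significance
  pruning combination is this package's documented approximation.
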