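# somnoseason

Seasonality of habitual sleep, measured objectively from trunk acceleration,
and its attribution to meteorological drivers.

Large ambulatory-monitoring databases (e.g. 24-h Holter recordings) carry
tri-axial trunk acceleration alongside the ECG. From that signal one can
infer minute-by-minute sleep/wake states, score the standard actigraphic
sleep parameters, and — because recordings accumulate across all months of
the year — ask how sleep varies with season and which meteorological
variables (ambient temperature *Ta*, humidity, barometric pressure, sunrise
and sunset times) drive that variation. `somnoseason` implements this whole
pipeline for epidemiologists and sleep researchers, together with a
calibrated synthetic-data generator so every stage is testable without
access to any restricted clinical database.

## What the package computes

**Sleep/wake inference.** Each 1-min epoch of a tri-axial trace (31.25 Hz)
is summarized by the upper-body tilt angle θ = arccos(g·ẑ/|g|) of a
low-pass gravity estimate g and by the local variances of the high-pass
residual per axis. An RBF support-vector machine maps these features to
`sleep`/`wake` labels; agreement with reference labels is reported as
accuracy / sensitivity / specificity / F1 (sleep = positive class).

**Sleep scoring.** From the label sequence and the detected nocturnal rest
interval [in-bed, get-up):

* sleep onset = start of the first ≥10 consecutive sleep minutes after
  in-bed time;
* SL = onset − in-bed; WASO = wake minutes in [onset, get-up);
  WEP = number of maximal wake runs there;
* TST = TIB − SL − WASO with TIB = get-up − in-bed; SE = 100·TST/TIB.

In-bed/get-up are elapsed minutes from 0:00 of the recording start day
(range 0–2880 over the two recording days).

**Seasonality.** Monthly mean ± SEM tables; a Gaussian-identity linear model
of each parameter on categorical month, age decade and gender (age×gender
interaction screened at p < 0.01); Bonferroni-adjusted contrasts of every
month against July; and a cosinor fit
mesor + A·cos(2π(m − φ)/12) to the monthly means.

**Meteorological attribution.** For each sleep parameter *y* and candidate
set {Ta, humidity, pressure, sunset, sunrise} (gender and age always
adjusted, unpenalized), adaptive LASSO (weights 1/|β̂ OLS|) selects a model
along the L1 path by the Schwarz Bayesian Criterion, pruned to terms
significant at p < 0.01. Selection is repeated on B bootstrap resamples;
candidates selected in ≥70% of resamples form the final model, whose
coefficients are ensemble averages of the final-model refit over resamples.
Ridge- and elastic-net-based selection provide robustness comparisons, and
the cutoff can be swept (65–80%) to check stability.

## Worked example

Classify and score one synthetic recording, then recover a known
temperature effect from a synthetic cohort:

```python
import numpy as np, pandas as pd
from somnoseason import synthetic, selection, sleepwake, scoring

# train on three fixture recordings, evaluate and score a held-out one
scripts = synthetic.fixture_suite(seed=0, n_scripts=2, noise_levels=(0.005, 0.02))
feats, labels = [], []
for s in scripts[:-1]:
    trace, truth, _ = synthetic.gen_acceleration_trace(s)
    feats.append(sleepwake.extract_epoch_features(trace))
    labels.append(truth.labels)
model = sleepwake.train_classifier(pd.concat(feats, ignore_index=True), np.concatenate(labels))

trace, truth, _ = synthetic.gen_acceleration_trace(scripts[-1])
f = sleepwake.extract_epoch_features(trace)
pred = sleepwake.classify(model, f, scripts[-1].start_datetime)
print(sleepwake.evaluate_classifier(pred, truth))
record = scoring.score_sleep(pred, scoring.detect_rest_interval(pred, f))
print(record.as_dict())

# cohort with a known Ta -> TST effect of -1.58 min/degC
meteo = synthetic.default_meteorology(year=2014, seed=0)
cfg = synthetic.effect_recovery_config("tst", {"ta": -1.58}, noise_sd=100.0,
                                       n_total=10_000, seed=0)
cohort = synthetic.gen_cohort_records(cfg, meteo)
avg = selection.bootstrap_model_average(selection.DesignSpec(response="tst"),
                                        cohort, B=300, cutoff=70.0, seed=0)
print(avg.table.round(3).to_string(index=False), "\nfinal model:", avg.selected)
```

prints

```
ClassifierMetrics(accuracy=99.58333333333333, sensitivity=98.62700228832952,
                  specificity=100.0, f1=99.30875576036867)
{'in_bed': 1350, 'get_up': 1803, 'sl': 0, 'waso': 22, 'wep': 3, 'tst': 431,
 'se': 95.14348785871965}
candidate  frequency  ensemble_coef  ensemble_se
       ta    100.000         -1.577        0.108
 humidity      2.000            NaN          NaN
 pressure      0.333            NaN          NaN
   sunset      0.000            NaN          NaN
  sunrise      1.333            NaN          NaN
final model: ['ta']
```

The held-out recording is labelled with 99.6% per-minute accuracy; the
scored record went to bed at 22:30 (elapsed minute 1350) and got up at
06:03 on day 2 (minute 1803) with TST 431 min and SE 95.1%. In the cohort,
ambient temperature is selected in 100% of bootstrap resamples, none of the
null covariates reach the 70% cutoff, and the ensemble-averaged coefficient
−1.577 ± 0.108 min/°C recovers the generating effect of −1.58.

## Command line

```bash
somnoseason all --config config.yaml       # simulate -> train -> classify ->
                                           # score -> season -> select (+ manifest)
somnoseason simulate --out-dir fixtures    # materialize the standard fixture suite
somnoseason select --records cohort.csv --response tst --seed 1 --out-dir out
```

Settings layer as config-file < flags; `manifest.json` records inputs,
outputs, seeds, versions and wall time.

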