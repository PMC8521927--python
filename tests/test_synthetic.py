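import datetime as dt

import numpy as np
import pandas as pd
import pytest

from somnoseason import calibration, scoring, synthetic
from somnoseason._rng import substream
from somnoseason.sleepwake import SLEEP, WAKE

from conftest import make_script


# ---------------------------------------------------------------------------
# meteorology
# ---------------------------------------------------------------------------

def _year_dates():
    return pd.date_range("2014-01-01", periods=365, freq="D")


def test_noiseless_meteorology_spans_tokyo_like_ranges():
    cfg = synthetic.MeteoModelConfig(noise_sd_ta=0.0, noise_sd_humidity=0.0,
                                     noise_sd_pressure=0.0, noise_sd_sun=0.0)
    met = synthetic.gen_meteorology(cfg, _year_dates(), seed=0)
    monthly_ta = met.set_index(pd.to_datetime(met["date"]))["ta_mean"].resample("ME").mean()
    assert monthly_ta.min() < 8.0
    assert monthly_ta.max() > 26.0
    rise = np.array([t.hour * 60 + t.minute for t in met["sunrise"]])
    assert abs(rise.min() - 270) <= 15
    assert abs(rise.max() - 420) <= 15
    assert (met["humidity"].between(0, 100)).all()
    assert (met["pressure"].between(900, 1100)).all()


def test_meteorology_deterministic_given_seed():
    cfg = synthetic.MeteoModelConfig()
    a = synthetic.gen_meteorology(cfg, _year_dates(), seed=11)
    b = synthetic.gen_meteorology(cfg, _year_dates(), seed=11)
    pd.testing.assert_frame_equal(a, b)
    c = synthetic.gen_meteorology(cfg, _year_dates(), seed=12)
    assert not np.allclose(a["ta_mean"], c["ta_mean"])


def test_ta_sunrise_correlation_hits_configured_target():
    for target in (0.70, 0.40):
        cfg = synthetic.MeteoModelConfig(target_ta_sunrise_corr=target)
        met = synthetic.gen_meteorology(cfg, _year_dates(), seed=5)
        rise = np.array([t.hour * 60 + t.minute for t in met["sunrise"]])
        r = np.corrcoef(met["ta_mean"], rise)[0, 1]
        assert abs(r - target) < 0.05


def test_empty_date_range_is_an_error():
    with pytest.raises(ValueError, match="at least one day"):
        synthetic.gen_meteorology(synthetic.MeteoModelConfig(), [], seed=0)


# ---------------------------------------------------------------------------
# cohort records
# ---------------------------------------------------------------------------

def test_published_month_age_counts_are_reproduced(meteo_year):
    cfg = synthetic.CohortConfig(
        month_age_counts=calibration.COHORT_MONTH_AGE_COUNTS,
        models=synthetic.default_parameter_models(),
        seed=3,
    )
    cohort = synthetic.gen_cohort_records(cfg, meteo_year)
    assert len(cohort) == 68603
    assert (cohort["month"] == 7).sum() == 5533
    assert (cohort["age_group"] == "70s").sum() == 21710
    table = cohort.groupby(["month", "age_group"]).size().unstack()[calibration.AGE_GROUPS]
    pd.testing.assert_frame_equal(
        table, calibration.COHORT_MONTH_AGE_COUNTS, check_names=False, check_dtype=False
    )


def test_zero_noise_parameters_equal_structural_values(meteo_year):
    models = {
        "in_bed": synthetic.ParameterModel(intercept=1340.0),
        "sl": synthetic.ParameterModel(intercept=12.0),
        "waso": synthetic.ParameterModel(intercept=40.0),
        "tst": synthetic.ParameterModel(intercept=420.0, gender_offset=-10.0),
        "wep": synthetic.ParameterModel(intercept=4.0),
    }
    counts = pd.DataFrame(np.full((12, 8), 3), index=calibration.MONTHS,
                          columns=calibration.AGE_GROUPS)
    cfg = synthetic.CohortConfig(month_age_counts=counts, models=models, seed=9)
    cohort = synthetic.gen_cohort_records(cfg, meteo_year)
    assert (cohort["in_bed"] == 1340).all()
    assert (cohort["sl"] == 12).all()
    assert (cohort["waso"] == 40).all()
    female = cohort["gender"] == "female"
    assert (cohort.loc[~female, "tst"] == 420).all()
    assert (cohort.loc[female, "tst"] == 410).all()
    assert (cohort["wep"] == 4).all()


def test_accounting_identity_holds_exactly(small_cohort):
    tib = small_cohort["get_up"] - small_cohort["in_bed"]
    assert ((small_cohort["tst"] + small_cohort["sl"] + small_cohort["waso"]) == tib).all()
    np.testing.assert_allclose(small_cohort["se"], 100.0 * small_cohort["tst"] / tib)
    assert ((small_cohort["wep"] == 0) == (small_cohort["waso"] == 0)).all()
    assert (small_cohort["wep"] <= small_cohort["waso"]).all()


def test_injected_ta_coefficient_recovered_by_ols(meteo_year):
    beta = -2.0
    cfg = synthetic.effect_recovery_config("tst", {"ta": beta}, noise_sd=60.0,
                                           n_total=4000, seed=21)
    cohort = synthetic.gen_cohort_records(cfg, meteo_year)
    X = np.column_stack([np.ones(len(cohort)), cohort["ta"]])
    y = cohort["tst"].to_numpy(float)
    est, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ est
    se = np.sqrt(resid.var(ddof=2) / ((cohort["ta"] - cohort["ta"].mean()) ** 2).sum())
    assert abs(est[1] - beta) < 2 * se


def test_monthly_means_converge_to_calibration_targets(meteo_year):
    # standard-error scaling: the deviation from the configured monthly means
    # shrinks ~1/sqrt(n) between two cohort sizes
    devs = {}
    for n in (100, 1600):
        cfg = synthetic.monthly_calibrated_config(n_per_month=n, seed=13)
        cohort = synthetic.gen_cohort_records(cfg, meteo_year)
        means = cohort.groupby("month")["tst"].mean()
        target = calibration.MONTHLY_PARAMETER_MEANS["tst"]
        devs[n] = float(np.sqrt(((means - target) ** 2).mean()))
    assert devs[1600] < devs[100]
    assert devs[1600] < 3 * 100.0 / np.sqrt(1600)  # ~3 SEM


def test_cohort_deterministic_and_missing_meteo_raises(meteo_year):
    cfg = synthetic.monthly_calibrated_config(n_per_month=20, seed=4)
    a = synthetic.gen_cohort_records(cfg, meteo_year)
    b = synthetic.gen_cohort_records(cfg, meteo_year)
    pd.testing.assert_frame_equal(a, b)
    with pytest.raises(LookupError):
        synthetic.gen_cohort_records(cfg, meteo_year.iloc[:100])


# ---------------------------------------------------------------------------
# label synthesis
# ---------------------------------------------------------------------------

def test_synthesized_labels_score_back_to_the_record(small_cohort):
    rng = substream(17, "labels")
    for _, row in small_cohort.sample(300, random_state=1).iterrows():
        seq, rest = synthetic.synthesize_labels(row, rng)
        rec = scoring.score_sleep(seq, rest)
        assert (rec.sl, rec.waso, rec.wep, rec.tst) == \
            (row["sl"], row["waso"], row["wep"], row["tst"])


# ---------------------------------------------------------------------------
# acceleration traces
# ---------------------------------------------------------------------------

def test_identity_posture_gives_unit_gravity_samples():
    script = synthetic.AccelScript(
        entries=[synthetic.ScriptEntry("wake", 0, 2, 0.0, 0.0)], noise_sd=0.0
    )
    trace, truth, rest = synthetic.gen_acceleration_trace(script)
    np.testing.assert_array_equal(trace.samples, np.tile([0.0, 0.0, 1.0], (2 * 1875, 1)))
    assert rest is None


def test_24h_trace_sample_count():
    script = make_script(noise_sd=0.0)
    trace, _, _ = synthetic.gen_acceleration_trace(script)
    assert len(trace.samples) == 24 * 60 * 1875 == 2_700_000


def test_scripted_wake_bouts_appear_in_ground_truth():
    script = make_script(in_bed_min=720, sleep_len=420, bouts=((100, 5), (250, 5)))
    _, truth, rest = synthetic.gen_acceleration_trace(script)
    inside = truth.labels[720:1140]
    assert (inside == WAKE).sum() == 10
    offset = truth.start_day_offset()
    assert rest.in_bed == offset + 720
    assert rest.get_up == offset + 1140


def test_overlapping_schedule_rejected():
    entries = [
        synthetic.ScriptEntry("wake", 0, 10, 0.0, 0.0),
        synthetic.ScriptEntry("sleep", 5, 10, 80.0, 0.0),
    ]
    with pytest.raises(ValueError, match="overlap"):
        synthetic.AccelScript(entries=entries)
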