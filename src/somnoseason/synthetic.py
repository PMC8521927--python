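"""Synthetic data with known ground truth for every pipeline stage.

Three generators, all driven by named substreams of one master seed:

* ``gen_meteorology`` — daily meteorological tables for a temperate,
  Tokyo-like location: annual cosines for temperature, humidity, pressure
  and sunrise/sunset, a rainy-season humidity bump, and day-to-day noise.
  The phase of the sunrise cycle is placed analytically so that the Pearson
  correlation between daily mean temperature and sunrise elapsed minutes over
  a full year matches a configurable target (0.70 by default, the
  collinearity level the downstream variable selection has to cope with).
* ``gen_cohort_records`` — scored sleep records for a cohort with a known
  structural model per sleep parameter (intercept + month/age/gender offsets
  + meteorological coefficients + Gaussian noise), with the accounting
  identity TST + SL + WASO = TIB enforced exactly.
* ``gen_acceleration_trace`` — tri-axial trunk acceleration for a scripted
  day (posture = gravity rotated by a pitch angle, activity = white noise of
  scripted variance) together with per-minute ground-truth labels.
"""

from __future__ import annotations

import calendar
import datetime as dt
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import calibration
from ._rng import substream
from .meteo import exposure_table
from .scoring import RestInterval
from .sleepwake import SLEEP, WAKE, AccelTrace, SleepWakeSequence

PERIOD_DAYS = 365.25
COVARIATES = ["ta", "humidity", "pressure", "sunset", "sunrise"]


# ---------------------------------------------------------------------------
# meteorology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeteoModelConfig:
    """Annual-cycle model of a temperate-zone (Tokyo-like) climate.

    Winter/summer levels set the cosine midline and amplitude; peak days are
    day-of-year positions of each cycle's maximum. ``sunrise_peak_day=None``
    places the sunrise phase analytically to hit ``target_ta_sunrise_corr``.
    """

    ta_winter_low: float = 5.0        # degC, coldest monthly level
    ta_summer_high: float = 28.0      # degC, hottest monthly level
    ta_peak_day: float = 216.0        # early August
    humidity_low: float = 55.0        # %
    humidity_high: float = 75.0       # %
    humidity_peak_day: float = 200.0
    rainy_season: tuple[int, int] = (152, 196)  # day-of-year window (Jun 1 - Jul 15)
    rainy_season_bump: float = 8.0    # % humidity added inside the window
    pressure_low: float = 1008.0      # hPa, summer level
    pressure_high: float = 1020.0     # hPa, winter level
    pressure_peak_day: float = 15.0
    sunrise_earliest: dt.time = dt.time(4, 30)
    sunrise_latest: dt.time = dt.time(7, 0)
    sunrise_peak_day: float | None = None
    sunset_earliest: dt.time = dt.time(16, 30)
    sunset_latest: dt.time = dt.time(19, 0)
    sunset_peak_day: float = 180.0
    target_ta_sunrise_corr: float = calibration.TA_SUNRISE_CORRELATION
    # day-to-day weather variability; also stands in for the cross-regional
    # dispersion of a nationwide cohort sampled from many stations. Without
    # it the five covariates would be pure same-period cosines spanning a
    # two-dimensional seasonal subspace and jointly unidentifiable.
    noise_sd_ta: float = 3.5          # degC
    noise_sd_humidity: float = 8.0    # %
    noise_sd_pressure: float = 4.0    # hPa
    noise_sd_sun: float = 10.0        # minutes, sunrise and sunset

    def __post_init__(self) -> None:
        if not self.ta_winter_low < self.ta_summer_high:
            raise ValueError("ta_winter_low must be below ta_summer_high")
        if not -1.0 < self.target_ta_sunrise_corr < 1.0:
            raise ValueError("target_ta_sunrise_corr must be in (-1, 1)")


def _annual(doy: np.ndarray, low: float, high: float, peak_day: float) -> np.ndarray:
    mid, amp = (low + high) / 2.0, (high - low) / 2.0
    return mid + amp * np.cos(2 * np.pi * (doy - peak_day) / PERIOD_DAYS)


def _attenuation(amplitude: float, noise_sd: float) -> float:
    # correlation shrinkage of a cosine observed with additive white noise
    signal_var = amplitude**2 / 2.0
    return math.sqrt(signal_var / (signal_var + noise_sd**2))


def resolved_sunrise_peak_day(config: MeteoModelConfig) -> float:
    """Sunrise peak day, solved for the Ta-sunrise correlation target."""
    if config.sunrise_peak_day is not None:
        return config.sunrise_peak_day
    ta_amp = (config.ta_summer_high - config.ta_winter_low) / 2.0
    sun_amp = (_t2m(config.sunrise_latest) - _t2m(config.sunrise_earliest)) / 2.0
    att = _attenuation(ta_amp, config.noise_sd_ta) * _attenuation(sun_amp, config.noise_sd_sun)
    cos_dphi = np.clip(config.target_ta_sunrise_corr / att, -1.0, 1.0)
    delta_days = math.acos(cos_dphi) * PERIOD_DAYS / (2 * np.pi)
    # place the sunrise peak on the far side of the Ta peak from the sunset
    # peak: the Ta-sunrise correlation is unchanged (cosine is even in the
    # phase difference) but sunrise and sunset stay well-conditioned as
    # separate regressors instead of nearly coinciding
    return config.ta_peak_day + delta_days


def _t2m(t: dt.time) -> float:
    return t.hour * 60 + t.minute


def _m2t(minutes: np.ndarray) -> list[dt.time]:
    m = np.clip(np.round(minutes).astype(int), 0, 1439)
    return [dt.time(int(v) // 60, int(v) % 60) for v in m]


def gen_meteorology(
    config: MeteoModelConfig,
    dates,
    locations=("TOKYO",),
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a daily meteorology table (one row per date and location)."""
    dates = pd.DatetimeIndex(pd.to_datetime(list(dates)))
    if len(dates) == 0:
        raise ValueError("date range must contain at least one day")
    doy = np.asarray(dates.dayofyear, dtype=float)

    sunrise_peak = resolved_sunrise_peak_day(config)
    frames = []
    for loc in locations:
        rng = substream(seed, f"meteo:{loc}")
        ta = _annual(doy, config.ta_winter_low, config.ta_summer_high, config.ta_peak_day)
        ta = ta + rng.normal(0.0, config.noise_sd_ta, len(doy))
        hum = _annual(doy, config.humidity_low, config.humidity_high, config.humidity_peak_day)
        lo, hi = config.rainy_season
        hum = hum + np.where((doy >= lo) & (doy <= hi), config.rainy_season_bump, 0.0)
        hum = np.clip(hum + rng.normal(0.0, config.noise_sd_humidity, len(doy)), 0.0, 100.0)
        pres = _annual(doy, config.pressure_low, config.pressure_high, config.pressure_peak_day)
        pres = pres + rng.normal(0.0, config.noise_sd_pressure, len(doy))
        rise = _annual(doy, _t2m(config.sunrise_earliest), _t2m(config.sunrise_latest), sunrise_peak)
        rise = rise + rng.normal(0.0, config.noise_sd_sun, len(doy))
        sett = _annual(doy, _t2m(config.sunset_earliest), _t2m(config.sunset_latest), config.sunset_peak_day)
        sett = sett + rng.normal(0.0, config.noise_sd_sun, len(doy))
        frames.append(
            pd.DataFrame(
                {
                    "date": [d.date() for d in dates],
                    "location": loc,
                    "ta_mean": ta,
                    "humidity": hum,
                    "pressure": pres,
                    "sunrise": _m2t(rise),
                    "sunset": _m2t(sett),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def default_meteorology(year: int = 2014, config: MeteoModelConfig | None = None,
                        seed: int = 0, location: str = "TOKYO") -> pd.DataFrame:
    """One calendar year (plus the first day of the next, so that recordings
    starting on Dec 31 have a second day) at the default calibration."""
    cfg = config or MeteoModelConfig()
    dates = pd.date_range(f"{year}-01-01", f"{year + 1}-01-01", freq="D")
    return gen_meteorology(cfg, dates, locations=(location,), seed=seed)


# ---------------------------------------------------------------------------
# cohort records
# ---------------------------------------------------------------------------

@dataclass
class ParameterModel:
    """Structural model of one sleep parameter.

    value = intercept + month_offset + age_offset (+ gender_offset if female)
            + sum(coef * covariate) + N(0, noise_sd)
    """

    intercept: float = 0.0
    month_offsets: np.ndarray | None = None   # length 12, indexed by month-1
    age_offsets: np.ndarray | None = None     # length 8, by age-decade index
    gender_offset: float = 0.0                # added for female
    coef: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.0

    def structural(self, month: np.ndarray, age_idx: np.ndarray,
                   female: np.ndarray, cov: pd.DataFrame) -> np.ndarray:
        out = np.full(len(month), float(self.intercept))
        if self.month_offsets is not None:
            out += np.asarray(self.month_offsets, dtype=float)[month - 1]
        if self.age_offsets is not None:
            out += np.asarray(self.age_offsets, dtype=float)[age_idx]
        out += self.gender_offset * female
        for name, beta in self.coef.items():
            out += beta * cov[name].to_numpy(dtype=float)
        return out

    def draw(self, rng: np.random.Generator, month, age_idx, female, cov) -> np.ndarray:
        mu = self.structural(month, age_idx, female, cov)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.noise_sd == 0:
            return mu
        return mu + rng.normal(0.0, self.noise_sd, len(mu))


@dataclass
class CohortConfig:
    """Cohort composition plus the per-parameter structural models.

    ``tib_driver`` names the parameter drawn directly from its model while
    the rest of the in-bed accounting is derived: with driver ``tst`` the
    get-up time is in_bed + SL + WASO + TST; with ``se`` the time in bed is
    back-solved from SE and the wake totals; with ``get_up`` TST is the
    remainder. Only one of the three can be structurally linear in the
    covariates at a time because the identity TST + SL + WASO = TIB binds
    them together.
    """

    month_age_counts: pd.DataFrame
    models: dict[str, ParameterModel]
    tib_driver: str = "tst"
    female_fraction: float = calibration.FEMALE_FRACTION
    unknown_gender_fraction: float = 0.0
    year: int = 2014
    location: str = "TOKYO"
    seed: int = 0

    def __post_init__(self) -> None:
        counts = np.asarray(self.month_age_counts)
        if counts.shape != (12, 8):
            raise ValueError(f"month_age_counts must be 12x8, got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("month_age_counts must be non-negative")
        if self.tib_driver not in ("tst", "se", "get_up"):
            raise ValueError(f"unknown tib_driver {self.tib_driver!r}")


# plausible central values used when a parameter has no calibrated model
_DEFAULT_LEVELS = {
    "in_bed": (1339.0, 60.0),
    "sl": (15.0, 10.0),
    "waso": (42.0, 25.0),
    "tst": (419.0, 100.0),
    "wep": (4.7, 2.0),
    "se": (91.0, 5.0),
    "get_up": (1806.0, 60.0),
}

# rough annual means of the default meteorology, used only to keep response
# levels realistic when meteorological coefficients are injected
_COVARIATE_MEANS = {"ta": 16.5, "humidity": 66.0, "pressure": 1014.0,
                    "sunset": 1065.0, "sunrise": 345.0}


def default_parameter_models(noise: bool = True) -> dict[str, ParameterModel]:
    models = {}
    for name in ("in_bed", "sl", "waso", "tst", "wep"):
        mean, sd = _DEFAULT_LEVELS[name]
        models[name] = ParameterModel(intercept=mean, noise_sd=sd if noise else 0.0)
    return models


def monthly_calibrated_config(n_per_month: int | None = None, *, seed: int = 0,
                              noise: bool = True) -> CohortConfig:
    """Cohort calibrated to the published monthly sleep-parameter means.

    ``n_per_month=None`` reproduces the published month x age sample counts;
    an integer redistributes that month's age mix to the requested total.
    """
    counts = calibration.COHORT_MONTH_AGE_COUNTS.copy()
    if n_per_month is not None:
        scaled = counts.div(counts.sum(axis=1), axis=0) * n_per_month
        counts = scaled.round().astype(int)
        # fix rounding so each month totals exactly n_per_month
        for m in counts.index:
            counts.loc[m, counts.columns[-1]] += n_per_month - counts.loc[m].sum()
    means = calibration.MONTHLY_PARAMETER_MEANS
    sds = {"tst": 100.0, "sl": 10.0, "waso": 25.0, "wep": 2.0, "in_bed": 60.0}
    models = {
        name: ParameterModel(
            month_offsets=means[name].to_numpy(dtype=float),
            noise_sd=sds[name] if noise else 0.0,
        )
        for name in ("tst", "sl", "waso", "wep", "in_bed")
    }
    return CohortConfig(month_age_counts=counts, models=models, tib_driver="tst", seed=seed)


# response operating points for coefficient-recovery cohorts: chosen so the
# physical truncation boundaries (WASO >= 0, SE <= 100, TST > 0) sit several
# residual SDs away and the structural model stays linear where it is probed
_RECOVERY_LEVELS = {"tst": 419.0, "se": 88.0, "waso": 150.0, "sl": 60.0,
                    "wep": 4.7, "get_up": 1806.0, "in_bed": 1339.0}


def effect_recovery_config(response: str, coef: dict[str, float], *, noise_sd: float,
                           n_total: int = 10_000, seed: int = 0) -> CohortConfig:
    """Cohort with a single known meteorological effect on one parameter.

    Months are sampled uniformly (maximal seasonal spread of the covariates);
    all other parameters keep their default, effect-free models.
    """
    per_cell = n_total // 96
    counts = np.full((12, 8), per_cell, dtype=int)
    counts[-1, -1] += n_total - counts.sum()
    counts_df = pd.DataFrame(counts, index=calibration.MONTHS, columns=calibration.AGE_GROUPS)

    models = default_parameter_models()
    base_mean = _RECOVERY_LEVELS[response]
    intercept = base_mean - sum(b * _COVARIATE_MEANS[c] for c, b in coef.items())
    models[response] = ParameterModel(intercept=intercept, coef=dict(coef), noise_sd=noise_sd)
    driver = response if response in ("tst", "se", "get_up") else "tst"
    return CohortConfig(month_age_counts=counts_df, models=models, tib_driver=driver, seed=seed)


def gen_cohort_records(config: CohortConfig, meteo: pd.DataFrame) -> pd.DataFrame:
    """Generate one scored sleep record per subject.

    Output columns: subject_id, month, start_date, location, age, age_group,
    gender, the five meteorological covariates, and the seven sleep
    parameters (integer minutes; SE recomputed from the integers so the
    accounting identity is exact).
    """
    rng = substream(config.seed, "cohort")
    counts = np.asarray(config.month_age_counts, dtype=int)

    month = np.repeat(np.repeat(np.arange(1, 13), 8), counts.ravel())
    age_idx = np.repeat(np.tile(np.arange(8), 12), counts.ravel())
    n = len(month)
    if n == 0:
        raise ValueError("empty cohort: all month/age counts are zero")

    ndays = np.array([calendar.monthrange(config.year, m)[1] for m in range(1, 13)])
    day = rng.integers(1, ndays[month - 1] + 1)
    start_date = pd.to_datetime(
        {"year": config.year, "month": month, "day": day}
    )

    cov = exposure_table(meteo, pd.Series(start_date), location=config.location)

    u = rng.random(n)
    gender = np.where(u < config.unknown_gender_fraction, "unknown",
                      np.where(rng.random(n) < config.female_fraction, "female", "male"))
    female = (gender == "female").astype(float)
    age = age_idx * 10 + 10 + rng.integers(0, 10, n)

    models = dict(default_parameter_models())
    models.update(config.models)

    def draw(name: str) -> np.ndarray:
        return models[name].draw(rng, month, age_idx, female, cov)

    in_bed = np.round(np.clip(draw("in_bed"), 600, 2200)).astype(int)
    sl = np.maximum(np.round(draw("sl")), 0).astype(int)
    waso = np.maximum(np.round(draw("waso")), 0).astype(int)

    if config.tib_driver == "tst":
        tst = np.maximum(np.round(draw("tst")), 30).astype(int)
        get_up = in_bed + sl + waso + tst
    elif config.tib_driver == "se":
        se_draw = np.clip(draw("se"), 5.0, 99.5)
        waso = np.where(sl + waso == 0, 1, waso)  # SE<100 needs some wake
        tib = np.round((sl + waso) / (1.0 - se_draw / 100.0)).astype(int)
        tib = np.maximum(tib, sl + waso + 30)
        get_up = in_bed + tib
        tst = tib - sl - waso
    else:  # get_up driver
        get_up = np.round(draw("get_up")).astype(int)
        get_up = np.maximum(get_up, in_bed + sl + waso + 30)
        tst = get_up - in_bed - sl - waso

    # keep everything inside the 2-day elapsed scale
    over = get_up > 2880
    if over.any():
        shift = get_up - 2880
        in_bed = np.where(over, in_bed - shift, in_bed)
        get_up = np.where(over, 2880, get_up)

    tib = get_up - in_bed
    se = 100.0 * tst / tib

    wep_raw = np.round(draw("wep")).astype(int)
    wep = np.clip(wep_raw, np.where(waso > 0, 1, 0), np.minimum(waso, tst - 10))
    wep = np.maximum(wep, 0)

    return pd.DataFrame(
        {
            "subject_id": [f"S{i:06d}" for i in range(n)],
            "month": month,
            "start_date": start_date,
            "location": config.location,
            "age": age,
            "age_group": np.array(calibration.AGE_GROUPS)[age_idx],
            "gender": gender,
            "ta": cov["ta"].to_numpy(),
            "humidity": cov["humidity"].to_numpy(),
            "pressure": cov["pressure"].to_numpy(),
            "sunset": cov["sunset"].to_numpy(),
            "sunrise": cov["sunrise"].to_numpy(),
            "in_bed": in_bed,
            "get_up": get_up,
            "sl": sl,
            "waso": waso,
            "wep": wep,
            "tst": tst,
            "se": se,
        }
    )


def synthesize_labels(record, rng: np.random.Generator) -> tuple[SleepWakeSequence, RestInterval]:
    """Build a per-minute label sequence that scores back to the record.

    The sequence spans the full 0-2880 elapsed range (wake outside the rest
    interval); WASO minutes are split into exactly WEP maximal wake runs at
    random positions after the 10-min onset run.
    """
    in_bed, get_up = int(record["in_bed"]), int(record["get_up"])
    sl, waso, wep, tst = (int(record[k]) for k in ("sl", "waso", "wep", "tst"))
    labels = np.full(2880, WAKE, dtype=np.int8)
    seg = np.full(get_up - in_bed - sl, SLEEP, dtype=np.int8)
    if waso > 0:
        # run lengths: composition of waso into wep positive parts
        if wep > 1:
            cuts = np.sort(rng.choice(waso - 1, size=wep - 1, replace=False)) + 1
            run_lengths = np.diff(np.concatenate(([0], cuts, [waso])))
        else:
            run_lengths = np.array([waso])
        # sleep gaps: onset run of 10, then >=1 between runs, free ends
        extra = (tst - 10) - (wep - 1)
        if extra < 0:
            raise ValueError("record cannot host its wake episodes (TST too small)")
        bonus = rng.multinomial(extra, np.full(wep + 1, 1.0 / (wep + 1)))
        gaps = np.concatenate(([10 + bonus[0]], bonus[1:-1] + 1, [bonus[-1]]))
        pos = 0
        for g, r in zip(gaps[:-1], run_lengths):
            pos += int(g)
            seg[pos : pos + int(r)] = WAKE
            pos += int(r)
    labels[in_bed : in_bed + sl] = WAKE
    labels[in_bed + sl : get_up] = seg
    start = record["start_date"]
    start = start.to_pydatetime() if hasattr(start, "to_pydatetime") else dt.datetime(2014, 1, 1)
    start = dt.datetime(start.year, start.month, start.day)
    return SleepWakeSequence(start, labels), RestInterval(in_bed, get_up)


# ---------------------------------------------------------------------------
# acceleration traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScriptEntry:
    state: str            # 'sleep' or 'wake'
    start_min: int
    duration_min: int
    posture_deg: float    # pitch of the longitudinal axis away from vertical
    activity_var: float   # per-axis variance of body-movement noise, g^2


@dataclass
class AccelScript:
    """Scripted day used to generate a ground-truth acceleration trace."""

    entries: list[ScriptEntry]
    sampling_rate: float = 31.25
    noise_sd: float = 0.01  # sensor noise, g
    seed: int = 0
    start_datetime: dt.datetime = dt.datetime(2014, 1, 15, 11, 0)

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        pos = 0
        for e in sorted(self.entries, key=lambda e: e.start_min):
            if e.start_min < pos:
                raise ValueError(f"overlapping schedule entries at minute {e.start_min}")
            if e.start_min > pos:
                raise ValueError(f"schedule gap before minute {e.start_min}")
            if e.state not in ("sleep", "wake"):
                raise ValueError(f"unknown state {e.state!r}")
            pos = e.start_min + e.duration_min

    @property
    def total_minutes(self) -> int:
        return max(e.start_min + e.duration_min for e in self.entries)


def gen_acceleration_trace(
    script: AccelScript,
) -> tuple[AccelTrace, SleepWakeSequence, RestInterval | None]:
    """Trace + ground-truth labels + true rest interval for a script.

    Samples are the gravity unit vector pitched by the posture angle (about
    the x axis, rotating z toward y) plus white body-movement noise of the
    scripted variance plus sensor noise.
    """
    rng = substream(script.seed, "accel")
    n_per_min = int(round(60 * script.sampling_rate))
    entries = sorted(script.entries, key=lambda e: e.start_min)

    chunks = []
    labels = np.empty(script.total_minutes, dtype=np.int8)
    for e in entries:
        theta = math.radians(e.posture_deg)
        gravity = np.array([0.0, math.sin(theta), math.cos(theta)], dtype=np.float64)
        n = e.duration_min * n_per_min
        sd = math.sqrt(e.activity_var + script.noise_sd**2)
        block = np.tile(gravity, (n, 1))
        if sd > 0:
            block = block + rng.normal(0.0, sd, (n, 3))
        chunks.append(block.astype(np.float32))
        labels[e.start_min : e.start_min + e.duration_min] = SLEEP if e.state == "sleep" else WAKE

    trace = AccelTrace(
        start_datetime=script.start_datetime,
        sampling_rate=script.sampling_rate,
        samples=np.concatenate(chunks, axis=0),
    )
    truth = SleepWakeSequence(script.start_datetime, labels)

    sleep_entries = [e for e in entries if e.state == "sleep"]
    rest = None
    if sleep_entries:
        offset = truth.start_day_offset()
        rest = RestInterval(
            in_bed=offset + sleep_entries[0].start_min,
            get_up=offset + sleep_entries[-1].start_min + sleep_entries[-1].duration_min,
        )
    return trace, truth, rest


def fixture_script(seed: int, noise_sd: float = 0.01, duration_min: int = 24 * 60) -> AccelScript:
    """One randomized 24-h day: active daytime, a nocturnal sleep block with
    a few brief wake bouts, and a morning after."""
    rng = substream(seed, "script")
    in_bed = int(rng.integers(11 * 60 + 30, 12 * 60 + 31))       # 22:30-23:30 wall clock
    sleep_len = int(rng.integers(390, 481))
    day_angle = float(rng.uniform(0, 30))
    day_var = 10 ** float(rng.uniform(-2.3, -1.3))
    sleep_angle = float(rng.uniform(70, 90))
    sleep_var = 10 ** float(rng.uniform(-5.0, -4.0))

    entries = [ScriptEntry("wake", 0, in_bed, day_angle, day_var)]
    n_bouts = int(rng.integers(2, 6))
    bout_starts = np.sort(rng.choice(np.arange(15, sleep_len - 15), n_bouts, replace=False))
    pos = in_bed
    for b in bout_starts:
        b_abs = in_bed + int(b)
        if b_abs <= pos + 1:
            continue
        entries.append(ScriptEntry("sleep", pos, b_abs - pos, sleep_angle, sleep_var))
        bout_len = int(rng.integers(2, 9))
        bout_var = 10 ** float(rng.uniform(-3.4, -2.5))
        entries.append(ScriptEntry("wake", b_abs, bout_len, float(rng.uniform(60, 85)), bout_var))
        pos = b_abs + bout_len
    end_sleep = in_bed + sleep_len
    if end_sleep > pos:
        entries.append(ScriptEntry("sleep", pos, end_sleep - pos, sleep_angle, sleep_var))
        pos = end_sleep
    if duration_min > pos:
        entries.append(ScriptEntry("wake", pos, duration_min - pos, day_angle, day_var))
    return AccelScript(entries=entries, noise_sd=noise_sd, seed=seed)


def fixture_suite(seed: int = 0, n_scripts: int = 3,
                  noise_levels: tuple[float, ...] = (0.005, 0.02)) -> list[AccelScript]:
    """The standard suite: ``n_scripts`` randomized days x each noise level."""
    return [
        fixture_script(seed=seed * 1000 + i, noise_sd=nl)
        for nl in noise_levels
        for i in range(n_scripts)
    ]
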