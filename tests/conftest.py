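import datetime as dt

import pytest

from somnoseason import synthetic


@pytest.fixture(scope="session")
def meteo_year():
    """One simulated year of default Tokyo-like meteorology."""
    return synthetic.default_meteorology(year=2014, seed=7)


@pytest.fixture(scope="session")
def small_cohort(meteo_year):
    """Calibrated cohort, 60 records/month, for structural checks."""
    cfg = synthetic.monthly_calibrated_config(n_per_month=60, seed=7)
    return synthetic.gen_cohort_records(cfg, meteo_year)


def make_script(in_bed_min=720, sleep_len=450, bouts=((120, 5), (300, 4)),
                day_angle=20.0, sleep_angle=80.0, bout_angle=80.0,
                day_var=0.01, sleep_var=1e-5, bout_var=1e-3,
                noise_sd=0.0, seed=0, total=1440):
    """Hand-built contiguous script: day wake, night sleep with wake bouts."""
    entries = [synthetic.ScriptEntry("wake", 0, in_bed_min, day_angle, day_var)]
    pos = in_bed_min
    for offset, blen in bouts:
        b = in_bed_min + offset
        entries.append(synthetic.ScriptEntry("sleep", pos, b - pos, sleep_angle, sleep_var))
        entries.append(synthetic.ScriptEntry("wake", b, blen, bout_angle, bout_var))
        pos = b + blen
    end = in_bed_min + sleep_len
    entries.append(synthetic.ScriptEntry("sleep", pos, end - pos, sleep_angle, sleep_var))
    if total > end:
        entries.append(synthetic.ScriptEntry("wake", end, total - end, day_angle, day_var))
    return synthetic.AccelScript(entries=entries, noise_sd=noise_sd, seed=seed,
                                 start_datetime=dt.datetime(2014, 1, 15, 11, 0))


@pytest.fixture(scope="session")
def noisefree_recordings():
    """Three noise-free scripted days sharing posture/variance levels."""
    scripts = [
        make_script(in_bed_min=715, sleep_len=460, bouts=((90, 4), (250, 6)), seed=1),
        make_script(in_bed_min=740, sleep_len=430, bouts=((60, 3), (200, 5), (350, 4)), seed=2),
        make_script(in_bed_min=725, sleep_len=445, bouts=((150, 5),), seed=3),
    ]
    return [synthetic.gen_acceleration_trace(s) + (s,) for s in scripts]


def brute_force_score(labels, in_bed, get_up, min_run=10):
    """Independent minute-count oracle. Returns dict or None if unscorable.

    ``labels`` indexed by elapsed minute (sequence starting at midnight);
    1 = sleep, 0 = wake.
    """
    onset = None
    for i in range(in_bed, get_up - min_run + 1):
        if all(labels[i : i + min_run]):
            onset = i
            break
    if onset is None:
        return None
    window = list(labels[onset:get_up])
    waso = sum(1 for v in window if v == 0)
    wep, prev = 0, 1
    for v in window:
        if v == 0 and prev == 1:
            wep += 1
        prev = v
    sl = onset - in_bed
    tib = get_up - in_bed
    tst = tib - sl - waso
    return {"sl": sl, "waso": waso, "wep": wep, "tst": tst, "se": 100.0 * tst / tib}
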