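"""Rest-interval detection and sleep-parameter scoring.

Scoring conventions (all on per-minute label sequences):

* time in bed (TIB) = get-up − in-bed, minutes;
* sleep onset = start of the first run of >=10 consecutive sleep minutes at
  or after in-bed time;
* SL (sleep latency) = onset − in-bed;
* WASO = wake minutes in the half-open window [onset, get-up);
* WEP = number of maximal wake runs in that window (any length >= 1);
* TST = TIB − SL − WASO  (equivalently, sleep minutes in [onset, get-up));
* SE = 100 * TST / TIB.

In-bed and get-up times are elapsed minutes counted from 0:00 of the
recording start day, so they range over [0, 2880] for a two-day recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .sleepwake import SLEEP, WAKE, SleepWakeSequence

SLEEP_PARAMETERS = ["in_bed", "get_up", "sl", "waso", "wep", "tst", "se"]


class NoRestIntervalError(ValueError):
    """No candidate rest period of the minimum duration was found."""


class OnsetNotFoundError(ValueError):
    """No run of >=10 consecutive sleep minutes inside the rest interval."""


@dataclass(frozen=True)
class RestInterval:
    """Primary nocturnal rest interval in elapsed minutes (0–2880)."""

    in_bed: int
    get_up: int

    def __post_init__(self) -> None:
        if not (0 <= self.in_bed < self.get_up <= 2880):
            raise ValueError(
                f"need 0 <= in_bed < get_up <= 2880, got ({self.in_bed}, {self.get_up})"
            )

    @property
    def tib(self) -> int:
        return self.get_up - self.in_bed


@dataclass
class SleepRecord:
    """Scored sleep parameters for one subject-recording."""

    in_bed: int
    get_up: int
    sl: int
    waso: int
    wep: int
    tst: int
    se: float
    demographics: dict[str, Any] = field(default_factory=dict)

    def as_dict(self) -> dict[str, Any]:
        out = dict(self.demographics)
        out.update(
            in_bed=self.in_bed, get_up=self.get_up, sl=self.sl,
            waso=self.waso, wep=self.wep, tst=self.tst, se=self.se,
        )
        return out


@dataclass(frozen=True)
class ScoringConfig:
    """Rest-interval detection settings.

    Candidate epochs are recumbent (tilt above ``recumbent_tilt_deg``) or
    quiescent (local variance below the ``quiescence_quantile`` of the
    recording); candidate runs separated by gaps up to ``merge_gap_min`` are
    merged, and the longest merged block of at least ``min_duration_min`` that
    intersects the overnight window is taken as the rest interval.
    """

    recumbent_tilt_deg: float = 60.0
    quiescence_quantile: float = 0.25
    merge_gap_min: int = 20
    min_duration_min: int = 180
    overnight_start: int = 18 * 60          # 18:00 on day 1, elapsed minutes
    overnight_end: int = 24 * 60 + 12 * 60  # 12:00 on day 2
    min_onset_run: int = 10


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, end) index pairs of True runs."""
    if mask.size == 0:
        return []
    padded = np.diff(np.concatenate(([0], mask.astype(np.int8), [0])))
    starts = np.where(padded == 1)[0]
    ends = np.where(padded == -1)[0]
    return list(zip(starts.tolist(), ends.tolist()))


def detect_rest_interval(
    sequence: SleepWakeSequence,
    features: pd.DataFrame | None = None,
    config: ScoringConfig | None = None,
) -> RestInterval:
    """Locate the primary nocturnal rest interval.

    With epoch features available, candidacy is posture/quiescence based;
    without them it falls back to the sleep labels themselves.
    """
    cfg = config or ScoringConfig()
    n = len(sequence)
    if features is not None:
        feats = features.iloc[:n]
        recumbent = feats["tilt_mean"].to_numpy() > cfg.recumbent_tilt_deg
        thresh = np.quantile(feats["local_variance_norm"].to_numpy(), cfg.quiescence_quantile)
        quiet = feats["local_variance_norm"].to_numpy() <= thresh
        candidate = recumbent | quiet
    else:
        candidate = sequence.labels == SLEEP

    runs = _runs(candidate)
    if not runs:
        raise NoRestIntervalError("no candidate rest epochs in the recording")

    # merge runs across gaps <= merge_gap_min
    merged: list[list[int]] = [list(runs[0])]
    for s, e in runs[1:]:
        if s - merged[-1][1] <= cfg.merge_gap_min:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    offset = sequence.start_day_offset()
    blocks = [
        (s, e) for s, e in merged
        if (e - s) >= cfg.min_duration_min
        and (s + offset) < cfg.overnight_end and (e + offset) > cfg.overnight_start
    ]
    if not blocks:
        raise NoRestIntervalError(
            f"no rest block of >= {cfg.min_duration_min} min in the overnight window"
        )
    s, e = max(blocks, key=lambda b: b[1] - b[0])
    return RestInterval(in_bed=int(s + offset), get_up=int(min(e + offset, 2880)))


def find_sleep_onset(
    sequence: SleepWakeSequence,
    in_bed: int,
    min_run: int = 10,
    until: int | None = None,
) -> int:
    """Start (elapsed minutes) of the first >=min_run sleep run after in-bed.

    ``until`` bounds the search (exclusive, elapsed minutes), typically the
    get-up time.
    """
    offset = sequence.start_day_offset()
    i0 = in_bed - offset
    i1 = len(sequence) if until is None else min(len(sequence), until - offset)
    if not (0 <= i0 < len(sequence)):
        raise ValueError(f"in_bed {in_bed} outside the labelled span")
    labels = sequence.labels[i0:i1]
    run = 0
    for i, lab in enumerate(labels):
        run = run + 1 if lab == SLEEP else 0
        if run == min_run:
            return in_bed + i - min_run + 1
    raise OnsetNotFoundError(
        f"no {min_run}-min sleep run between minutes {in_bed} and {until}"
    )


def score_sleep(
    sequence: SleepWakeSequence,
    interval: RestInterval,
    demographics: dict[str, Any] | None = None,
    config: ScoringConfig | None = None,
) -> SleepRecord:
    """Score the seven sleep parameters over the given rest interval."""
    cfg = config or ScoringConfig()
    onset = find_sleep_onset(sequence, interval.in_bed, cfg.min_onset_run, until=interval.get_up)
    offset = sequence.start_day_offset()
    window = sequence.labels[onset - offset : interval.get_up - offset]
    wake = window == WAKE
    sl = onset - interval.in_bed
    waso = int(wake.sum())
    wep = len(_runs(wake))
    tib = interval.tib
    tst = tib - sl - waso
    se = 100.0 * tst / tib
    return SleepRecord(
        in_bed=interval.in_bed, get_up=interval.get_up,
        sl=int(sl), waso=waso, wep=wep, tst=int(tst), se=se,
        demographics=dict(demographics or {}),
    )


def records_to_frame(records: list[SleepRecord]) -> pd.DataFrame:
    """SleepRecords -> tidy table (one row per subject-recording)."""
    return pd.DataFrame([r.as_dict() for r in records])


def elapsed_to_clock(minutes: float) -> str:
    """Elapsed minutes from day-1 midnight -> hh:mm on a 24-h clock."""
    m = int(round(minutes)) % 1440
    return f"{m // 60:02d}:{m % 60:02d}"


def write_records_csv(records: pd.DataFrame, path) -> None:
    """Write a sleep-record table with added human-readable clock columns."""
    out = records.copy()
    for col in ("in_bed", "get_up"):
        if col in out.columns:
            out[f"{col}_clock"] = out[col].map(elapsed_to_clock)
    out.to_csv(path, index=False)
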