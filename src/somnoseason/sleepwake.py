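"""Per-minute sleep/wake inference from tri-axial trunk acceleration.

The classifier follows the standard actigraphy recipe: each 1-min epoch is
summarized by the upper-body tilt angle (from a low-pass gravity estimate)
and the local variances of the high-pass residual, and an RBF support-vector
machine maps the feature vector to a ``sleep``/``wake`` label.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

WAKE, SLEEP = 0, 1
LABEL_NAMES = {WAKE: "wake", SLEEP: "sleep"}

FEATURE_COLUMNS = [
    "tilt_mean",
    "tilt_sd",
    "local_variance_x",
    "local_variance_y",
    "local_variance_z",
    "local_variance_norm",
]

_VAR_FLOOR = 1e-12  # variance floor before log-transform, g^2


class DegenerateEpochError(ValueError):
    """An epoch carries no gravity signal (all-zero acceleration)."""


@dataclass
class AccelTrace:
    """Tri-axial trunk acceleration for one subject-recording.

    ``samples`` is an (n, 3) array in units of g; axis order (x, y, z) with z
    the device's longitudinal axis by convention.
    """

    start_datetime: dt.datetime
    sampling_rate: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.samples = np.asarray(self.samples, dtype=np.float32).reshape(-1, 3)

    @property
    def duration_minutes(self) -> float:
        return len(self.samples) / self.sampling_rate / 60.0


@dataclass
class SleepWakeSequence:
    """Per-minute sleep/wake labels anchored to a clock time (1=sleep)."""

    start_datetime: dt.datetime
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)

    def __len__(self) -> int:
        return len(self.labels)

    def label_names(self) -> list[str]:
        return [LABEL_NAMES[v] for v in self.labels]

    @classmethod
    def from_names(cls, start_datetime: dt.datetime, names) -> "SleepWakeSequence":
        inv = {"wake": WAKE, "sleep": SLEEP, "W": WAKE, "S": SLEEP}
        return cls(start_datetime, np.array([inv[str(n)] for n in names], dtype=np.int8))

    def start_day_offset(self) -> int:
        """Minutes from midnight of the start day to the first label."""
        t = self.start_datetime
        return t.hour * 60 + t.minute

    def to_frame(self) -> pd.DataFrame:
        times = [self.start_datetime + dt.timedelta(minutes=int(i)) for i in range(len(self))]
        return pd.DataFrame({"datetime": times, "label": self.label_names()})


@dataclass(frozen=True)
class FeatureConfig:
    """Epoch feature settings.

    gravity_window_s: moving-average window of the low-pass gravity estimate.
    longitudinal_axis: index of the device axis pointing head-to-foot.
    """

    gravity_window_s: float = 5.0
    longitudinal_axis: int = 2
    epoch_seconds: float = 60.0


def extract_epoch_features(trace: AccelTrace, config: FeatureConfig | None = None) -> pd.DataFrame:
    """One feature row per whole minute of the trace.

    Tilt is the angle between the low-pass (gravity) vector and the
    longitudinal axis; local variances are computed on the high-pass residual
    within the epoch. ``local_variance_norm`` is the total residual variance
    (sum over the three axes). A trailing partial minute is dropped.
    """
    cfg = config or FeatureConfig()
    n_per_epoch = int(round(cfg.epoch_seconds * trace.sampling_rate))
    n_epochs = len(trace.samples) // n_per_epoch
    if n_epochs < 1:
        raise ValueError("trace shorter than one epoch")
    x = np.asarray(trace.samples[: n_epochs * n_per_epoch], dtype=np.float64)

    win = max(1, int(round(cfg.gravity_window_s * trace.sampling_rate)))
    gravity = uniform_filter1d(x, size=win, axis=0, mode="nearest")
    gnorm = np.linalg.norm(gravity, axis=1)

    gnorm_ep = gnorm.reshape(n_epochs, n_per_epoch)
    dead = np.where(gnorm_ep.max(axis=1) < 1e-6)[0]
    if dead.size:
        raise DegenerateEpochError(
            f"no gravity signal (all-zero acceleration) in epoch(s) {dead[:5].tolist()}"
        )

    cosang = gravity[:, cfg.longitudinal_axis] / np.maximum(gnorm, 1e-12)
    tilt = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))).reshape(n_epochs, n_per_epoch)

    resid = (x - gravity).reshape(n_epochs, n_per_epoch, 3)
    local_var = resid.var(axis=1)

    return pd.DataFrame(
        {
            "epoch_index": np.arange(n_epochs),
            "tilt_mean": tilt.mean(axis=1),
            "tilt_sd": tilt.std(axis=1),
            "local_variance_x": local_var[:, 0],
            "local_variance_y": local_var[:, 1],
            "local_variance_z": local_var[:, 2],
            "local_variance_norm": local_var.sum(axis=1),
        }
    )


@dataclass(frozen=True)
class SVMConfig:
    C: float = 1.0
    gamma: str | float = "scale"
    class_weight: str | None = "balanced"
    smoothing_window: int = 0  # odd median-filter width over labels; 0 = off


@dataclass
class SleepWakeClassifier:
    """Trained sleep/wake model (standardization statistics live inside)."""

    pipeline: Pipeline
    feature_columns: list[str] = field(default_factory=lambda: list(FEATURE_COLUMNS))
    config: SVMConfig = field(default_factory=SVMConfig)

    def save(self, path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "SleepWakeClassifier":
        model = joblib.load(path)
        if not isinstance(model, cls):
            raise TypeError(f"{path} does not contain a SleepWakeClassifier")
        return model


def _design_matrix(features: pd.DataFrame, columns: list[str]) -> np.ndarray:
    missing = [c for c in columns if c not in features.columns]
    if missing:
        raise ValueError(f"feature schema mismatch, missing columns: {missing}")
    mat = features[columns].to_numpy(dtype=np.float64)
    # variances span decades; classify on their logarithms
    var_idx = [i for i, c in enumerate(columns) if c.startswith("local_variance")]
    mat[:, var_idx] = np.log10(np.maximum(mat[:, var_idx], 0.0) + _VAR_FLOOR)
    return mat


def train_classifier(
    features: pd.DataFrame,
    labels: SleepWakeSequence | np.ndarray,
    config: SVMConfig | None = None,
) -> SleepWakeClassifier:
    """Fit the SVM on aligned epoch features and reference labels."""
    cfg = config or SVMConfig()
    y = labels.labels if isinstance(labels, SleepWakeSequence) else np.asarray(labels, dtype=np.int8)
    if len(features) != len(y):
        raise ValueError(f"features ({len(features)}) and labels ({len(y)}) misaligned")
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class; need both sleep and wake")
    X = _design_matrix(features, list(FEATURE_COLUMNS))
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", SVC(C=cfg.C, gamma=cfg.gamma, kernel="rbf", class_weight=cfg.class_weight)),
        ]
    )
    pipe.fit(X, y)
    return SleepWakeClassifier(pipeline=pipe, config=cfg)


def classify(
    model: SleepWakeClassifier,
    features: pd.DataFrame,
    start_datetime: dt.datetime | None = None,
) -> SleepWakeSequence:
    """Predict one label per epoch; no smoothing unless enabled in config."""
    start = start_datetime or dt.datetime(2000, 1, 1)
    if len(features) == 0:
        return SleepWakeSequence(start, np.empty(0, dtype=np.int8))
    X = _design_matrix(features, model.feature_columns)
    y = model.pipeline.predict(X).astype(np.int8)
    w = model.config.smoothing_window
    if w and w > 1:
        from scipy.ndimage import median_filter

        y = median_filter(y, size=w, mode="nearest").astype(np.int8)
    return SleepWakeSequence(start, y)


@dataclass(frozen=True)
class ClassifierMetrics:
    """Agreement with a reference labeling, in percent (sleep = positive)."""

    accuracy: float
    sensitivity: float
    specificity: float
    f1: float


def evaluate_classifier(
    predicted: SleepWakeSequence | np.ndarray,
    reference: SleepWakeSequence | np.ndarray,
) -> ClassifierMetrics:
    yp = predicted.labels if isinstance(predicted, SleepWakeSequence) else np.asarray(predicted)
    yr = reference.labels if isinstance(reference, SleepWakeSequence) else np.asarray(reference)
    if len(yp) != len(yr):
        raise ValueError(f"length mismatch: predicted {len(yp)} vs reference {len(yr)}")
    if len(yp) == 0:
        raise ValueError("empty sequences")
    tp = int(np.sum((yp == SLEEP) & (yr == SLEEP)))
    tn = int(np.sum((yp == WAKE) & (yr == WAKE)))
    fp = int(np.sum((yp == SLEEP) & (yr == WAKE)))
    fn = int(np.sum((yp == WAKE) & (yr == SLEEP)))
    pos, neg = tp + fn, tn + fp
    acc = 100.0 * (tp + tn) / len(yp)
    sens = 100.0 * tp / pos if pos else float("nan")
    spec = 100.0 * tn / neg if neg else float("nan")
    f1 = 100.0 * 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else float("nan")
    return ClassifierMetrics(accuracy=acc, sensitivity=sens, specificity=spec, f1=f1)
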