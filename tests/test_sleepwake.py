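import datetime as dt

import numpy as np
import pandas as pd
import pytest

from somnoseason import sleepwake, synthetic
from somnoseason.sleepwake import (
    SLEEP,
    WAKE,
    AccelTrace,
    DegenerateEpochError,
    SleepWakeSequence,
    classify,
    evaluate_classifier,
    extract_epoch_features,
    train_classifier,
)

START = dt.datetime(2014, 1, 15, 11, 0)


def _trace(samples, fs=31.25):
    return AccelTrace(start_datetime=START, sampling_rate=fs, samples=samples)


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

def test_constant_upright_trace_has_zero_tilt_and_variance():
    n = 2 * 1875
    feats = extract_epoch_features(_trace(np.tile([0.0, 0.0, 1.0], (n, 1))))
    assert len(feats) == 2
    np.testing.assert_allclose(feats["tilt_mean"], 0.0, atol=1e-9)
    np.testing.assert_allclose(feats["local_variance_norm"], 0.0, atol=1e-15)


def test_gravity_along_x_gives_90_degree_tilt():
    n = 1875
    feats = extract_epoch_features(_trace(np.tile([1.0, 0.0, 0.0], (n, 1))))
    np.testing.assert_allclose(feats["tilt_mean"], 90.0, atol=1e-9)


def test_sinusoidal_component_appears_as_local_variance():
    fs = 31.25
    t = np.arange(int(60 * fs)) / fs
    z = 1.0 + 0.1 * np.sin(2 * np.pi * 2.0 * t)
    samples = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
    feats = extract_epoch_features(_trace(samples, fs))
    # a 2 Hz sine of amplitude 0.1 survives the 5 s low-pass: variance a^2/2
    assert feats.loc[0, "local_variance_z"] == pytest.approx(0.005, rel=0.05)


def test_added_white_noise_raises_each_local_variance_by_its_variance():
    rng = np.random.default_rng(0)
    base = np.tile([0.0, 0.3, 0.9], (10 * 1875, 1))
    v = 4e-4
    noisy = base + rng.normal(0.0, np.sqrt(v), base.shape)
    f0 = extract_epoch_features(_trace(base))
    f1 = extract_epoch_features(_trace(noisy))
    for axis in ("x", "y", "z"):
        delta = (f1[f"local_variance_{axis}"] - f0[f"local_variance_{axis}"]).mean()
        assert delta == pytest.approx(v, rel=0.10)


def test_all_zero_samples_raise_degenerate_epoch_error():
    with pytest.raises(DegenerateEpochError, match="epoch"):
        extract_epoch_features(_trace(np.zeros((1875, 3))))


def test_trailing_partial_minute_dropped():
    feats = extract_epoch_features(_trace(np.tile([0.0, 0.0, 1.0], (1875 + 900, 1))))
    assert len(feats) == 1


# ---------------------------------------------------------------------------
# training and classification
# ---------------------------------------------------------------------------

def _cluster_features(n_each=80, seed=0):
    rng = np.random.default_rng(seed)
    sleep = pd.DataFrame(
        {
            "tilt_mean": rng.normal(80, 2, n_each),
            "tilt_sd": rng.normal(0.5, 0.1, n_each),
            "local_variance_x": 10 ** rng.normal(-4.5, 0.2, n_each),
            "local_variance_y": 10 ** rng.normal(-4.5, 0.2, n_each),
            "local_variance_z": 10 ** rng.normal(-4.5, 0.2, n_each),
        }
    )
    wake = pd.DataFrame(
        {
            "tilt_mean": rng.normal(15, 3, n_each),
            "tilt_sd": rng.normal(2.0, 0.3, n_each),
            "local_variance_x": 10 ** rng.normal(-2.0, 0.2, n_each),
            "local_variance_y": 10 ** rng.normal(-2.0, 0.2, n_each),
            "local_variance_z": 10 ** rng.normal(-2.0, 0.2, n_each),
        }
    )
    feats = pd.concat([sleep, wake], ignore_index=True)
    feats["local_variance_norm"] = feats[
        ["local_variance_x", "local_variance_y", "local_variance_z"]
    ].sum(axis=1)
    labels = np.array([SLEEP] * n_each + [WAKE] * n_each, dtype=np.int8)
    return feats, labels


def test_separable_clusters_train_to_perfect_accuracy():
    feats, labels = _cluster_features()
    model = train_classifier(feats, labels)
    pred = classify(model, feats)
    assert evaluate_classifier(pred.labels, labels).accuracy == 100.0


def test_training_rejects_single_class_labels():
    feats, labels = _cluster_features()
    with pytest.raises(ValueError, match="single class"):
        train_classifier(feats, np.full(len(feats), SLEEP, dtype=np.int8))


def test_retraining_is_deterministic():
    feats, labels = _cluster_features()
    probe, _ = _cluster_features(seed=5)
    p1 = classify(train_classifier(feats, labels), probe)
    p2 = classify(train_classifier(feats, labels), probe)
    np.testing.assert_array_equal(p1.labels, p2.labels)


def test_classify_empty_features_returns_empty_sequence():
    feats, labels = _cluster_features()
    model = train_classifier(feats, labels)
    assert len(classify(model, feats.iloc[:0])) == 0


def test_classify_rejects_schema_mismatch():
    feats, labels = _cluster_features()
    model = train_classifier(feats, labels)
    with pytest.raises(ValueError, match="schema"):
        classify(model, feats.drop(columns=["tilt_mean"]))


def test_noisefree_fixture_classified_exactly(noisefree_recordings):
    (tr0, truth0, _, s0), (tr1, truth1, _, s1), (tr2, truth2, _, s2) = noisefree_recordings
    train_feats = pd.concat(
        [extract_epoch_features(tr0), extract_epoch_features(tr1)], ignore_index=True
    )
    train_labels = np.concatenate([truth0.labels, truth1.labels])
    model = train_classifier(train_feats, train_labels)
    pred = classify(model, extract_epoch_features(tr2), s2.start_datetime)
    np.testing.assert_array_equal(pred.labels, truth2.labels)


def test_model_roundtrip_through_file(tmp_path):
    feats, labels = _cluster_features()
    model = train_classifier(feats, labels)
    model.save(tmp_path / "clf.joblib")
    loaded = sleepwake.SleepWakeClassifier.load(tmp_path / "clf.joblib")
    np.testing.assert_array_equal(classify(loaded, feats).labels, classify(model, feats).labels)


# ---------------------------------------------------------------------------
# evaluation metrics
# ---------------------------------------------------------------------------

def test_identical_sequences_score_100_percent():
    y = np.array([SLEEP, WAKE, SLEEP, SLEEP], dtype=np.int8)
    m = evaluate_classifier(y, y)
    assert (m.accuracy, m.sensitivity, m.specificity, m.f1) == (100.0, 100.0, 100.0, 100.0)


def test_all_sleep_prediction_against_80_percent_sleep_reference():
    ref = np.array([SLEEP] * 80 + [WAKE] * 20, dtype=np.int8)
    pred = np.full(100, SLEEP, dtype=np.int8)
    m = evaluate_classifier(pred, ref)
    assert m.accuracy == 80.0
    assert m.sensitivity == 100.0
    assert m.specificity == 0.0


def test_label_swap_complements_accuracy():
    rng = np.random.default_rng(3)
    ref = (rng.random(500) < 0.7).astype(np.int8)
    pred = (rng.random(500) < 0.8).astype(np.int8)
    acc = evaluate_classifier(pred, ref).accuracy
    acc_swapped = evaluate_classifier(1 - pred, ref).accuracy
    assert acc + acc_swapped == pytest.approx(100.0)


def test_accuracy_decomposes_into_class_weighted_sensitivity_specificity():
    rng = np.random.default_rng(4)
    ref = (rng.random(400) < 0.6).astype(np.int8)
    pred = (rng.random(400) < 0.65).astype(np.int8)
    m = evaluate_classifier(pred, ref)
    p, n = int(ref.sum()), int((1 - ref).sum())
    assert m.accuracy == pytest.approx((m.sensitivity * p + m.specificity * n) / (p + n))


def test_length_mismatch_rejected():
    with pytest.raises(ValueError, match="mismatch"):
        evaluate_classifier(np.array([1, 0]), np.array([1]))
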