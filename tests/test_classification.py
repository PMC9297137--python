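"""AUC computation, min-max scaling, splitting, learners and the benchmark."""

import numpy as np
import pandas as pd
import pytest

from foodtract.classification import (
    SplitConfig,
    compute_auc,
    minmax_fit_apply,
    model_feature_sets,
    run_benchmark,
    split_data,
    train_ensemble,
    train_learner,
)
from foodtract.features import (
    NUTRITION_FEATURES,
    SENTIMENT_FEATURES,
    SES_FEATURES,
    TRACT_FEATURES,
)


def brute_force_auc(scores, labels):
    """O(n^2) pair counting with half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def test_auc_worked_examples():
    assert compute_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0
    assert compute_auc([0.5] * 6, [1, 1, 0, 0, 0, 1]) == 0.5
    with pytest.raises(ValueError):
        compute_auc([0.1, 0.2], [1, 1])


def test_auc_equals_pairwise_oracle(rng):
    for _ in range(300):
        n = int(rng.integers(4, 51))
        labels = rng.random(n) < 0.4
        if labels.all() or not labels.any():
            continue
        scores = np.round(rng.random(n), 2)  # coarse grid forces ties
        assert compute_auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )


def test_auc_invariant_to_monotone_transform(rng):
    scores = rng.normal(size=80)
    labels = rng.random(80) < 0.3
    base = compute_auc(scores, labels)
    assert compute_auc(np.exp(scores), labels) == pytest.approx(base)
    assert compute_auc(3 * scores + 7, labels) == pytest.approx(base)


def test_minmax_worked_examples():
    train = pd.DataFrame({"a": [2.0, 4.0, 6.0], "b": [5.0, 5.0, 5.0]})
    test = pd.DataFrame({"a": [8.0], "b": [9.0]})
    train_s, test_s, params = minmax_fit_apply(train, test)
    assert list(train_s["a"]) == [0.0, 0.5, 1.0]
    assert list(train_s["b"]) == [0.0, 0.0, 0.0]  # constant column convention
    assert test_s["a"].iloc[0] == pytest.approx(1.5)  # outside [0,1], not clipped
    assert test_s["b"].iloc[0] == 0.0
    assert params.loc["a", "min"] == 2.0 and params.loc["a", "max"] == 6.0


def test_minmax_rejects_unknown_test_column():
    train = pd.DataFrame({"a": [1.0, 2.0]})
    test = pd.DataFrame({"a": [1.0], "z": [1.0]})
    with pytest.raises(ValueError, match="z"):
        minmax_fit_apply(train, test)


def test_scaling_uses_train_statistics_only():
    """Leakage guard: the scaler must never see test rows."""
    train = pd.DataFrame({"a": [0.0, 10.0]})
    test = pd.DataFrame({"a": [100.0]})
    _, test_s, params = minmax_fit_apply(train, test)
    assert params.loc["a", "max"] == 10.0  # not 100: test row ignored
    assert test_s["a"].iloc[0] == pytest.approx(10.0)


def _label_table(n=200, pos_rate=0.1, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.random(n) < pos_rate
    table = pd.DataFrame({"is_food_desert": y})
    for c in SES_FEATURES:
        table[c] = rng.normal(size=n)
    for c in TRACT_FEATURES:
        table[c] = rng.normal(size=n)
    table["tract_id"] = [f"T{i}" for i in range(n)]
    return table


def test_split_is_stratified_and_deterministic():
    table = _label_table(n=100, pos_rate=0.1, seed=3)
    # force exactly 10 positives
    table["is_food_desert"] = np.arange(100) < 10
    cfg = SplitConfig(seed=11)
    train_idx, test_idx, folds = split_data(table, cfg)
    y = table["is_food_desert"].to_numpy()
    assert len(train_idx) == 70 and len(test_idx) == 30
    assert y[train_idx].sum() == 7 and y[test_idx].sum() == 3
    again = split_data(table, cfg)
    assert np.array_equal(train_idx, again[0]) and np.array_equal(folds, again[2])
    assert sorted(np.concatenate([train_idx, test_idx])) == list(range(100))
    assert set(folds) == set(range(5))


def test_split_requires_both_classes():
    table = _label_table(n=60)
    table["is_food_desert"] = False
    with pytest.raises(ValueError):
        split_data(table, SplitConfig())


def _separable(n=120, seed=0):
    rng = np.random.default_rng(seed)
    y = (np.arange(n) % 4 == 0).astype(int)
    X = rng.normal(size=(n, 3))
    X[:, 0] = y * 5.0 + rng.normal(scale=0.1, size=n)
    return X, y


def test_logistic_separable_training_auc():
    X, y = _separable()
    folds = np.arange(len(y)) % 5
    scorer = train_learner("logistic_regression", X, y, folds, seed=0)
    assert compute_auc(scorer.predict(X), y) == 1.0


def test_learners_score_noise_near_chance():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(300, 5))
    y = (rng.random(300) < 0.3).astype(int)
    folds = np.arange(300) % 5
    X_test = rng.normal(size=(200, 5))
    y_test = (rng.random(200) < 0.3).astype(int)
    for method in ("gradient_boosting", "logistic_regression"):
        scorer = train_learner(method, X, y, folds, seed=1)
        auc = compute_auc(scorer.predict(X_test), y_test)
        assert 0.35 <= auc <= 0.65


def test_hyperparameter_selection_deterministic():
    X, y = _separable(n=150, seed=2)
    folds = np.arange(150) % 5
    a = train_learner("gradient_boosting", X, y, folds, seed=7)
    b = train_learner("gradient_boosting", X, y, folds, seed=7)
    assert a.params == b.params
    assert np.array_equal(a.predict(X), b.predict(X))


def test_ensemble_tracks_a_strong_base_learner():
    X, y = _separable(n=200, seed=4)
    folds = np.arange(200) % 5
    ensemble = train_ensemble(X, y, folds, seed=0)
    X_test, y_test = _separable(n=100, seed=9)
    assert compute_auc(ensemble.predict(X_test), y_test) >= 0.95


def test_model_feature_sets_follow_the_benchmark_design():
    sig = ("mean_cholesterol", "pct_fastfood_pos")
    sets = model_feature_sets(sig)
    assert sets[1] == tuple(SES_FEATURES)
    assert sets[2] == tuple(SES_FEATURES) + tuple(NUTRITION_FEATURES)
    assert sets[3] == tuple(SES_FEATURES) + tuple(SENTIMENT_FEATURES)
    assert set(sets[4]) == set(SES_FEATURES) | set(TRACT_FEATURES)
    assert sets[5] == tuple(SES_FEATURES) + sig
    assert len(sets[2]) == 12 + 22 and len(sets[3]) == 12 + 6


def test_benchmark_shape_and_baseline_delta():
    table = _label_table(n=220, pos_rate=0.15, seed=6)
    out = run_benchmark(
        table,
        SplitConfig(seed=1),
        significant=("mean_cholesterol",),
        methods=("logistic_regression",),
        models=(1, 3, 5),
    )
    assert len(out) == 3
    assert set(out.columns) >= {"method", "model_id", "auc", "delta_vs_baseline"}
    base = out.loc[out.model_id == 1, "auc"].iloc[0]
    assert out.loc[out.model_id == 3, "delta_vs_baseline"].iloc[0] == pytest.approx(
        out.loc[out.model_id == 3, "auc"].iloc[0] - base
    )
    assert ((out["auc"] >= 0) & (out["auc"] <= 1)).all()


def test_benchmark_reproducible_under_fixed_seed():
    table = _label_table(n=150, pos_rate=0.2, seed=8)
    kwargs = dict(
        cfg=SplitConfig(seed=3), methods=("logistic_regression",), models=(1, 3)
    )
    a = run_benchmark(table, **kwargs)
    b = run_benchmark(table, **kwargs)
    pd.testing.assert_frame_equal(a, b)
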