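"""Feature selection, staged tuning, training and prediction."""

import numpy as np
import pandas as pd
import pytest

from soluprot.modeling import (
    TrainedModel,
    correlation_prune,
    cv_auc,
    lasso_select,
    train,
    tune_hyperparameters,
)

rng_global = np.random.default_rng(0)


def _noise_frame(n, names, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.normal(size=(n, len(names))), columns=names)


def test_correlation_prune_removes_lesser_importance_duplicate():
    m = _noise_frame(100, ["a"], seed=1)
    m["b"] = m["a"]  # perfect copy
    kept = correlation_prune(m, {"a": 0.9, "b": 0.1}, r_max=0.75)
    assert kept == ["a"]
    kept = correlation_prune(m, {"a": 0.1, "b": 0.9}, r_max=0.75)
    assert kept == ["b"]


def test_correlation_prune_keeps_uncorrelated():
    m = _noise_frame(200, list("abcde"), seed=2)
    imp = {c: 0.2 for c in m.columns}
    assert correlation_prune(m, imp) == list("abcde")


def test_correlation_prune_triplet_keeps_highest():
    m = _noise_frame(50, ["a"], seed=3)
    m["b"], m["c"] = m["a"], m["a"]
    kept = correlation_prune(m, {"a": 0.1, "b": 0.5, "c": 0.2})
    assert kept == ["b"]


@pytest.mark.parametrize("seed", range(4))
def test_correlation_prune_brute_force_invariant(seed):
    """No surviving pair has |r| above the cap, on random <=15-feature
    matrices with injected correlated blocks."""
    rng = np.random.default_rng(seed)
    n_feat = int(rng.integers(5, 16))
    base = rng.normal(size=(80, n_feat))
    # correlate some columns to force pruning work
    for j in range(1, n_feat, 3):
        base[:, j] = base[:, j - 1] + 0.1 * rng.normal(size=80)
    m = pd.DataFrame(base, columns=[f"f{j}" for j in range(n_feat)])
    imp = {c: float(rng.random()) for c in m.columns}
    kept = correlation_prune(m, imp, r_max=0.75)
    corr = m[kept].corr().to_numpy()
    off_diag = np.abs(corr[~np.eye(len(kept), dtype=bool)])
    assert (off_diag <= 0.75 + 1e-12).all()


def _planted_frame(n=150, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.normal(size=(n, 6)), columns=[f"f{i}" for i in range(6)]
    )
    y = (X["f0"] + 0.3 * rng.normal(size=n) > 0).astype(int).to_numpy()
    return X, y


def test_lasso_select_alpha_zero_keeps_all():
    X, y = _planted_frame()
    selected, best_alpha, audit = lasso_select(X, y, alpha_grid=[0.0], folds=3)
    assert selected == list(X.columns)
    assert best_alpha == 0.0


def test_lasso_select_recovers_planted_support():
    X, y = _planted_frame(n=200, seed=1)
    selected, best_alpha, audit = lasso_select(
        X, y, alpha_grid=[0.2, 0.05, 0.0], folds=3, seed=0
    )
    assert "f0" in selected
    assert len(selected) < 6  # pure-noise features dropped at the chosen alpha
    # determinism
    again = lasso_select(X, y, alpha_grid=[0.2, 0.05, 0.0], folds=3, seed=0)
    assert (again[0], again[1]) == (selected, best_alpha)


def test_lasso_select_single_class_rejected():
    X, _ = _planted_frame()
    with pytest.raises(ValueError):
        lasso_select(X, np.zeros(len(X)), alpha_grid=[0.01])


def _xor_frame(n=240, seed=4):
    rng = np.random.default_rng(seed)
    a = rng.integers(0, 2, n)
    b = rng.integers(0, 2, n)
    X = pd.DataFrame(
        {"a": a + 0.05 * rng.normal(size=n), "b": b + 0.05 * rng.normal(size=n)}
    )
    return X, (a ^ b).astype(int)


def test_tune_single_point_grid():
    X, y = _planted_frame()
    best, audit = tune_hyperparameters(
        X, y, stages=[{"max_depth": [2]}], folds=3
    )
    assert best == {"max_depth": 2}
    assert len(audit) == 1


def test_tune_prefers_dominant_configuration():
    # XOR labels need interaction depth; stumps cannot express them
    X, y = _xor_frame()
    best, audit = tune_hyperparameters(
        X, y, stages=[{"max_depth": [1, 3]}], folds=3, seed=0
    )
    assert best["max_depth"] == 3


def test_tune_stages_carry_winners_forward():
    X, y = _planted_frame()
    stages = [{"max_depth": [2, 3]}, {"min_samples_leaf": [1, 4]}]
    best, audit = tune_hyperparameters(X, y, stages=stages, folds=3)
    assert audit[1]["carried_forward"]["max_depth"] == best["max_depth"]
    for row in audit[1]["results"]:
        assert "max_depth" not in row["params"]  # stage 2 varies only its own grid


def test_tune_empty_stage_rejected():
    X, y = _planted_frame()
    with pytest.raises(ValueError):
        tune_hyperparameters(X, y, stages=[])


def test_train_separable_feature_gives_auc_one():
    X, y = _planted_frame(n=100, seed=2)
    y = (X["f0"] > 0).astype(int).to_numpy()  # perfectly determined
    model = train(X, y, seed=0)
    from sklearn.metrics import roc_auc_score

    assert roc_auc_score(y, model.predict(X)) == 1.0
    assert model.predict(X).min() >= 0.0 and model.predict(X).max() <= 1.0


def test_predict_refuses_missing_features():
    X, y = _planted_frame()
    model = train(X, y, seed=0, selected_features=["f0", "f1"])
    with pytest.raises(ValueError):
        model.predict(X[["f0"]])
    # superset matrices are fine; columns sliced by name
    scores_full = model.predict(X)
    scores_sub = model.predict(X[["f1", "f0"]])
    assert np.array_equal(scores_full, scores_sub)


def test_training_is_seed_deterministic():
    X, y = _planted_frame(n=120, seed=5)
    s1 = train(X, y, seed=9).predict(X)
    s2 = train(X, y, seed=9).predict(X)
    assert np.array_equal(s1, s2)


def test_feature_importances_normalized_and_ranked():
    X, y = _planted_frame(n=200, seed=6)
    model = train(X, y, seed=0)
    imp = model.feature_importances()
    assert sum(imp.values()) == pytest.approx(1.0)
    assert next(iter(imp)) == "f0"  # the planted informative feature ranks first
    single = train(X[["f0"]], y, seed=0, selected_features=["f0"])
    assert single.feature_importances() == {"f0": 1.0}


def test_model_save_load_round_trip(tmp_path):
    X, y = _planted_frame(n=100, seed=7)
    model = train(X, y, seed=3, params={"n_estimators": 50})
    path = tmp_path / "model.sol"
    model.save(path)
    loaded = TrainedModel.load(path)
    assert loaded.selected_features == model.selected_features
    assert loaded.hyperparameters == {"n_estimators": 50}
    assert np.array_equal(loaded.predict(X), model.predict(X))


def test_cv_auc_shuffled_labels_near_half():
    rng = np.random.default_rng(8)
    X = _noise_frame(200, [f"f{i}" for i in range(5)], seed=8)
    y = rng.integers(0, 2, 200)
    mean, _ = cv_auc(X, y, folds=4, seed=0)
    assert 0.3 < mean < 0.7
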