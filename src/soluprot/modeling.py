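"""Feature selection, staged hyperparameter tuning and gradient boosting.

The model is a gradient-boosting classifier over standardized sequence
features. Feature selection has two steps: correlation pruning (of any pair
with Pearson |r| above a cap, the feature with the lesser importance in a
default-parameter booster is dropped) and LASSO screening (the L1 penalty
alpha is chosen to maximize mean cross-validated AUC of a default booster on
the surviving nonzero-coefficient features). Hyperparameters are then tuned
by an iterative staged grid search: each stage optimizes one or two
parameters by grid search while earlier winners stay fixed and untouched
parameters keep library defaults.

Everything is deterministic under a fixed seed: cross-validation folds are
stratified, seeded, and shared across the alpha grid and all tuning stages.
"""

from __future__ import annotations

import io
import itertools
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import Lasso
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .features import (
    Standardizer,
    apply_standardizer,
    fit_standardizer,
)

R_MAX_DEFAULT = 0.75

# alpha varied from 0.08 down to 0 with step 6.25e-4
DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(0.08, -1e-12, -6.25e-4), 10))

# Staged tuning plan: ordered (parameter-grid) stages, one or two parameters
# each. Grids are deliberately compact defaults; pass a custom spec for
# larger searches.
DEFAULT_STAGES: tuple[dict, ...] = (
    {"n_estimators": [100, 200], "learning_rate": [0.1, 0.05]},
    {"max_depth": [2, 3, 5], "min_samples_split": [2, 10]},
    {"min_samples_leaf": [1, 5]},
    {"subsample": [1.0, 0.8]},
    {"max_features": [None, "sqrt"]},
    {"n_estimators": [100, 200, 300], "learning_rate": [0.05, 0.025]},
    {"min_impurity_decrease": [0.0, 1e-4]},
)


def default_booster(seed: int = 42, **params) -> GradientBoostingClassifier:
    """A gradient-boosting classifier at library defaults (plus overrides)."""
    return GradientBoostingClassifier(random_state=seed, **params)


def _cv_folds(labels: np.ndarray, folds: int, seed: int):
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(labels)), labels))


def cv_auc(
    matrix: pd.DataFrame,
    labels: np.ndarray,
    params: Optional[dict] = None,
    folds: int = 5,
    seed: int = 42,
    fold_indices=None,
) -> tuple[float, float]:
    """Mean and std of validation AUC over stratified CV folds."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels contain a single class")
    fold_indices = fold_indices or _cv_folds(labels, folds, seed)
    X = matrix.to_numpy()
    aucs = []
    for train_idx, val_idx in fold_indices:
        clf = default_booster(seed, **(params or {}))
        clf.fit(X[train_idx], labels[train_idx])
        scores = clf.predict_proba(X[val_idx])[:, 1]
        aucs.append(roc_auc_score(labels[val_idx], scores))
    return float(np.mean(aucs)), float(np.std(aucs))


# ---------------------------------------------------------------------------
# feature selection

def correlation_prune(
    matrix: pd.DataFrame,
    importances: dict[str, float],
    r_max: float = R_MAX_DEFAULT,
) -> list[str]:
    """Drop the lesser-importance member of every feature pair with |r| > r_max.

    Pairs are processed in descending |r| (ties broken lexicographically by
    name pair); a pair is skipped if either member was already removed.
    Equal importances are broken by removing the lexicographically later
    name. The survivors provably contain no pair with |r| > r_max.
    """
    names = list(matrix.columns)
    if set(names) - set(importances):
        raise ValueError("importances missing for some features")
    with np.errstate(invalid="ignore", divide="ignore"):
        # constant columns yield NaN correlations; treat as uncorrelated
        corr = np.nan_to_num(np.corrcoef(matrix.to_numpy(), rowvar=False))
    pairs = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            r = abs(corr[i, j])
            if r > r_max:
                pairs.append((r, names[i], names[j]))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    removed: set[str] = set()
    for _, a, b in pairs:
        if a in removed or b in removed:
            continue
        ia, ib = importances[a], importances[b]
        if ia < ib or (ia == ib and a > b):
            removed.add(a)
        else:
            removed.add(b)
    return [n for n in names if n not in removed]


def lasso_select(
    matrix: pd.DataFrame,
    labels: np.ndarray,
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    folds: int = 5,
    seed: int = 42,
) -> tuple[list[str], float, pd.DataFrame]:
    """LASSO screening with alpha chosen by cross-validated booster AUC.

    For each alpha (descending) the features with nonzero LASSO coefficient
    form a candidate set; the winning alpha maximizes mean CV AUC of a
    default booster restricted to that set, ties resolved toward the larger
    alpha (fewer features). alpha = 0 means no penalty: all features.

    The matrix is standardized internally before the LASSO fits (idempotent
    if already standardized). Returns (selected names, best alpha, audit
    table of alpha / set size / mean+std AUC).
    """
    labels = np.asarray(labels, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels contain a single class")
    std = fit_standardizer(matrix)
    Z = apply_standardizer(std, matrix)
    names = list(matrix.columns)
    folds_idx = _cv_folds(labels.astype(int), folds, seed)

    alphas = sorted(set(float(a) for a in alpha_grid), reverse=True)
    cache: dict[frozenset, tuple[float, float]] = {}
    audit_rows = []
    best: Optional[tuple[float, float, list[str]]] = None  # (auc, alpha, names)
    for alpha in alphas:
        if alpha == 0.0:
            selected = list(names)
        else:
            lasso = Lasso(alpha=alpha, max_iter=10000, tol=1e-4)
            lasso.fit(Z.to_numpy(), labels)
            selected = [n for n, c in zip(names, lasso.coef_) if c != 0.0]
        key = frozenset(selected)
        if not selected:
            audit_rows.append((alpha, 0, np.nan, np.nan))
            continue
        if key not in cache:
            cache[key] = cv_auc(
                Z[selected], labels.astype(int), folds=folds, seed=seed,
                fold_indices=folds_idx,
            )
        mean_auc, std_auc = cache[key]
        audit_rows.append((alpha, len(selected), mean_auc, std_auc))
        if best is None or mean_auc > best[0]:  # descending alphas: ties keep larger
            best = (mean_auc, alpha, selected)
    if best is None:
        raise ValueError("no alpha produced a nonempty feature set")
    audit = pd.DataFrame(
        audit_rows, columns=["alpha", "n_features", "cv_auc_mean", "cv_auc_std"]
    )
    return best[2], best[1], audit


# ---------------------------------------------------------------------------
# staged hyperparameter tuning

def tune_hyperparameters(
    matrix: pd.DataFrame,
    labels: np.ndarray,
    stages: Sequence[dict] = DEFAULT_STAGES,
    folds: int = 5,
    seed: int = 42,
) -> tuple[dict, list[dict]]:
    """Iterative staged grid search maximizing mean CV AUC.

    Returns (best params, audit trail). Each audit entry records the stage's
    grid, every point's mean/std AUC, and the parameters carried forward.
    """
    if not stages or any(not st for st in stages):
        raise ValueError("stage specification is empty")
    labels = np.asarray(labels).astype(int)
    folds_idx = _cv_folds(labels, folds, seed)
    best_params: dict = {}
    audit: list[dict] = []
    for stage_no, grid in enumerate(stages, start=1):
        param_names = sorted(grid)
        points = list(itertools.product(*(grid[p] for p in param_names)))
        stage_rows = []
        stage_best: Optional[tuple[float, dict]] = None
        for values in points:
            candidate = dict(best_params)
            candidate.update(dict(zip(param_names, values)))
            mean_auc, std_auc = cv_auc(
                matrix, labels, params=candidate, folds=folds, seed=seed,
                fold_indices=folds_idx,
            )
            stage_rows.append(
                {"params": dict(zip(param_names, values)),
                 "cv_auc_mean": mean_auc, "cv_auc_std": std_auc}
            )
            if stage_best is None or mean_auc > stage_best[0]:
                stage_best = (mean_auc, dict(zip(param_names, values)))
        best_params.update(stage_best[1])
        audit.append(
            {"stage": stage_no, "grid": {p: list(grid[p]) for p in param_names},
             "results": stage_rows, "carried_forward": dict(best_params)}
        )
    return best_params, audit


# ---------------------------------------------------------------------------
# trained model

@dataclass
class TrainedModel:
    """A fitted booster plus everything needed to score new feature matrices."""

    booster: GradientBoostingClassifier
    selected_features: tuple[str, ...]
    standardizer: Standardizer
    hyperparameters: dict
    seed: int
    cv_auc_mean: float = float("nan")
    cv_auc_std: float = float("nan")

    def predict(self, matrix: pd.DataFrame) -> np.ndarray:
        """Probability of soluble expression for each row, in [0, 1].

        The matrix may carry any superset of the selected features; columns
        are sliced by name, never by position.
        """
        missing = [f for f in self.selected_features if f not in matrix.columns]
        if missing:
            raise ValueError(f"matrix missing selected features: {missing[:5]}")
        sub = matrix[list(self.selected_features)]
        Z = apply_standardizer(self.standardizer, sub)
        return self.booster.predict_proba(Z.to_numpy())[:, 1]

    def feature_importances(self) -> dict[str, float]:
        """Importances normalized to sum 1, sorted descending."""
        imp = np.asarray(self.booster.feature_importances_, dtype=float)
        total = imp.sum()
        if total > 0:
            imp = imp / total
        pairs = sorted(
            zip(self.selected_features, imp), key=lambda t: (-t[1], t[0])
        )
        return dict(pairs)

    # -- serialization: zip archive of JSON manifest + joblib booster -------

    def save(self, path) -> None:
        manifest = {
            "format": "soluprot-model",
            "version": 1,
            "selected_features": list(self.selected_features),
            "standardizer": {
                "names": list(self.standardizer.names),
                "means": self.standardizer.means.tolist(),
                "scales": self.standardizer.scales.tolist(),
            },
            "hyperparameters": {
                k: v for k, v in self.hyperparameters.items()
            },
            "seed": self.seed,
            "cv_auc_mean": self.cv_auc_mean,
            "cv_auc_std": self.cv_auc_std,
        }
        buf = io.BytesIO()
        joblib.dump(self.booster, buf)
        with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
            zf.writestr("manifest.json", json.dumps(manifest, indent=2))
            zf.writestr("booster.joblib", buf.getvalue())

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with zipfile.ZipFile(path) as zf:
            manifest = json.loads(zf.read("manifest.json"))
            booster = joblib.load(io.BytesIO(zf.read("booster.joblib")))
        std = Standardizer(
            tuple(manifest["standardizer"]["names"]),
            np.asarray(manifest["standardizer"]["means"]),
            np.asarray(manifest["standardizer"]["scales"]),
        )
        return cls(
            booster=booster,
            selected_features=tuple(manifest["selected_features"]),
            standardizer=std,
            hyperparameters=manifest["hyperparameters"],
            seed=manifest["seed"],
            cv_auc_mean=manifest["cv_auc_mean"],
            cv_auc_std=manifest["cv_auc_std"],
        )


def train(
    matrix: pd.DataFrame,
    labels: np.ndarray,
    params: Optional[dict] = None,
    seed: int = 42,
    selected_features: Optional[Sequence[str]] = None,
    folds: int = 0,
) -> TrainedModel:
    """Fit the final booster on the full training matrix.

    The standardizer is fitted on the same training matrix (restricted to the
    selected features) and stored with the model. With ``folds`` > 0 the CV
    AUC of the chosen parameters is recorded in the model metadata.
    """
    labels = np.asarray(labels).astype(int)
    selected = list(selected_features) if selected_features else list(matrix.columns)
    missing = [f for f in selected if f not in matrix.columns]
    if missing:
        raise ValueError(f"selected features absent from matrix: {missing[:5]}")
    sub = matrix[selected]
    std = fit_standardizer(sub)
    Z = apply_standardizer(std, sub)
    params = dict(params or {})
    booster = default_booster(seed, **params)
    booster.fit(Z.to_numpy(), labels)
    cv_mean = cv_std = float("nan")
    if folds:
        cv_mean, cv_std = cv_auc(Z, labels, params=params, folds=folds, seed=seed)
    return TrainedModel(
        booster=booster,
        selected_features=tuple(selected),
        standardizer=std,
        hyperparameters=params,
        seed=seed,
        cv_auc_mean=cv_mean,
        cv_auc_std=cv_std,
    )


@dataclass
class SelectionAudit:
    """Audit trail of the feature-selection and tuning pipeline."""

    importances_full: dict = field(default_factory=dict)
    kept_after_corr: list = field(default_factory=list)
    lasso_audit: Optional[pd.DataFrame] = None
    best_alpha: float = float("nan")
    selected: list = field(default_factory=list)
    tuning_audit: list = field(default_factory=list)
    best_params: dict = field(default_factory=dict)


def fit_pipeline(
    matrix: pd.DataFrame,
    labels: np.ndarray,
    seed: int = 42,
    excluded_features: Sequence[str] = (),
    r_max: float = R_MAX_DEFAULT,
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    folds: int = 5,
    stages: Optional[Sequence[dict]] = None,
) -> tuple[TrainedModel, SelectionAudit]:
    """Full training pipeline: prune, LASSO-select, optionally tune, train.

    ``excluded_features`` (e.g. sentinel-filled plugin features) are removed
    before any selection. ``stages=None`` skips hyperparameter tuning and
    trains at library defaults.
    """
    labels = np.asarray(labels).astype(int)
    audit = SelectionAudit()
    work = matrix.drop(columns=[c for c in excluded_features if c in matrix.columns])

    std = fit_standardizer(work)
    Z = apply_standardizer(std, work)

    base = default_booster(seed)
    base.fit(Z.to_numpy(), labels)
    audit.importances_full = dict(zip(work.columns, base.feature_importances_))

    kept = correlation_prune(Z, audit.importances_full, r_max=r_max)
    audit.kept_after_corr = kept

    selected, best_alpha, lasso_audit = lasso_select(
        Z[kept], labels, alpha_grid=alpha_grid, folds=folds, seed=seed
    )
    audit.lasso_audit = lasso_audit
    audit.best_alpha = best_alpha
    audit.selected = selected

    params: dict = {}
    if stages:
        params, tuning_audit = tune_hyperparameters(
            Z[selected], labels, stages=stages, folds=folds, seed=seed
        )
        audit.tuning_audit = tuning_audit
    audit.best_params = params

    model = train(
        work, labels, params=params, seed=seed, selected_features=selected
    )
    return model, audit
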