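"""Five-model food-desert classification benchmark.

Five feature sets are compared: (1) the 12 SES covariates alone (the
baseline), (2) SES + the tweet-derived nutrition features, (3) SES + the
six sentiment percentages, (4) SES + both, (5) SES + the association
screen's significant features.  Each set is fed to four learner families —
adaptive boosting (boosted stumps), gradient boosting (shallow trees on
logistic loss), logistic regression, and a stacked ensemble of the three —
and scored by test-set AUC after a label-stratified 70:30 split.  Min-max
scaling and median imputation are fit on training rows only; 5-fold CV on
the training rows selects hyperparameters from small fixed grids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import AdaBoostClassifier, GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.tree import DecisionTreeClassifier

from .features import NUTRITION_FEATURES, SENTIMENT_FEATURES, SES_FEATURES

logger = logging.getLogger(__name__)

METHODS: tuple[str, ...] = (
    "adaptive_boosting",
    "gradient_boosting",
    "logistic_regression",
    "ensemble",
)

BASE_METHODS: tuple[str, ...] = METHODS[:3]

#: Small fixed hyperparameter grids searched by 5-fold CV AUC.
HYPER_GRIDS: dict[str, tuple[dict, ...]] = {
    "adaptive_boosting": tuple(
        {"n_estimators": n} for n in (50, 100, 200)
    ),
    "gradient_boosting": tuple(
        {"max_depth": d, "n_estimators": n} for d in (1, 2, 3) for n in (100, 200)
    ),
    "logistic_regression": tuple({"C": c} for c in (0.1, 1.0, 10.0)),
}


def model_feature_sets(
    significant: Sequence[str] = (),
) -> dict[int, tuple[str, ...]]:
    """The five benchmark feature sets (model id -> column names)."""
    ses = tuple(SES_FEATURES)
    return {
        1: ses,
        2: ses + tuple(NUTRITION_FEATURES),
        3: ses + tuple(SENTIMENT_FEATURES),
        4: ses + tuple(NUTRITION_FEATURES) + tuple(SENTIMENT_FEATURES),
        5: ses + tuple(f for f in significant if f not in ses),
    }


@dataclass(frozen=True)
class SplitConfig:
    train_fraction: float = 0.70
    n_folds: int = 5
    seed: int = 0


@dataclass(frozen=True)
class EvalResult:
    method: str
    model_id: int
    auc: float
    seed: int


def compute_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the Mann-Whitney probability of correct ranking.

    Equals the fraction of (positive, negative) pairs the scores rank
    correctly, with half credit for ties; computed from midranks.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def minmax_fit_apply(
    train: pd.DataFrame, test: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Min-max scale both matrices using training-set minima/maxima only.

    A constant training column maps to all zeros; test values outside the
    training range are not clipped, so they may fall outside [0, 1].
    """
    missing = [c for c in test.columns if c not in train.columns]
    if missing:
        raise ValueError(f"test columns absent from train: {missing}")
    lo = train.min(axis=0)
    hi = train.max(axis=0)
    span = hi - lo
    constant = span.index[span == 0.0]
    safe_span = span.replace(0.0, 1.0)
    train_s = (train - lo) / safe_span
    test_s = (test[train.columns] - lo) / safe_span
    train_s[constant] = 0.0
    test_s[constant] = 0.0
    params = pd.DataFrame({"min": lo, "max": hi})
    return train_s, test_s, params


def split_data(
    table: pd.DataFrame, cfg: SplitConfig, label_col: str = "is_food_desert"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Label-stratified 70:30 split plus stratified folds over the training rows.

    Returns (train row positions, test row positions, fold id per training
    row); fully determined by ``cfg.seed``.
    """
    y = table[label_col].astype(int).to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present to split")
    if counts.min() < 10:
        raise ValueError("need >= 10 rows per class to split")
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx,
        train_size=cfg.train_fraction,
        stratify=y,
        random_state=cfg.seed,
        shuffle=True,
    )
    folds = make_folds(y[train_idx], cfg.n_folds, cfg.seed)
    return train_idx, test_idx, folds


def make_folds(y_train: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Stratified fold assignment; refolds with a new seed if a fold ends
    up single-class (logged)."""
    for attempt in range(10):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + attempt)
        folds = np.empty(len(y_train), dtype=int)
        ok = True
        for f, (_, val) in enumerate(skf.split(np.zeros(len(y_train)), y_train)):
            folds[val] = f
            if len(np.unique(y_train[val])) < 2 or len(np.unique(y_train[~np.isin(np.arange(len(y_train)), val)])) < 2:
                ok = False
        if ok:
            if attempt:
                logger.info("make_folds: refolded %d time(s) to avoid a single-class fold", attempt)
            return folds
    raise ValueError("could not build folds with both classes in every fold")


def _make_estimator(method: str, params: Mapping, seed: int):
    if method == "adaptive_boosting":
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1),
            random_state=seed,
            **params,
        )
    if method == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed, **params)
    if method == "logistic_regression":
        return LogisticRegression(max_iter=2000, **params)
    raise ValueError(f"unknown method {method!r}")


@dataclass
class FittedScorer:
    """A trained learner exposing a probability-like score in [0, 1]."""

    method: str
    params: Mapping
    model: object
    cv_auc: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(X)[:, 1]


def _cv_scores(
    method: str, params: Mapping, X: np.ndarray, y: np.ndarray, folds: np.ndarray, seed: int
) -> np.ndarray:
    """Out-of-fold scores for one hyperparameter setting."""
    oof = np.empty(len(y))
    for f in np.unique(folds):
        fit_mask = folds != f
        est = _make_estimator(method, params, seed)
        est.fit(X[fit_mask], y[fit_mask])
        oof[~fit_mask] = est.predict_proba(X[~fit_mask])[:, 1]
    return oof


def _select_params(
    method: str, X: np.ndarray, y: np.ndarray, folds: np.ndarray, seed: int,
    grid: Sequence[Mapping] | None = None,
) -> tuple[Mapping, float, np.ndarray]:
    """Pick the grid point with the best mean cross-validated AUC.

    Ties break toward the earlier grid entry, so selection is
    deterministic given the seed.
    """
    grid = HYPER_GRIDS[method] if grid is None else grid
    best: tuple[Mapping, float, np.ndarray] | None = None
    for params in grid:
        oof = _cv_scores(method, params, X, y, folds, seed)
        aucs = [
            compute_auc(oof[folds == f], y[folds == f]) for f in np.unique(folds)
        ]
        mean_auc = float(np.mean(aucs))
        if best is None or mean_auc > best[1]:
            best = (params, mean_auc, oof)
    assert best is not None
    return best


def train_learner(
    method: str,
    X: np.ndarray,
    y: np.ndarray,
    folds: np.ndarray,
    seed: int = 0,
    grid: Sequence[Mapping] | None = None,
) -> FittedScorer:
    """CV-select hyperparameters, then refit on the full training set."""
    params, cv_auc, _ = _select_params(method, X, y, folds, seed, grid)
    est = _make_estimator(method, params, seed)
    est.fit(X, y)
    return FittedScorer(method=method, params=params, model=est, cv_auc=cv_auc)


@dataclass
class StackedScorer:
    """Stacked ensemble: logistic meta-learner over three base scorers."""

    base: dict[str, FittedScorer]
    meta: LogisticRegression

    method: str = "ensemble"

    def predict(self, X: np.ndarray) -> np.ndarray:
        meta_X = np.column_stack([self.base[m].predict(X) for m in BASE_METHODS])
        return self.meta.predict_proba(meta_X)[:, 1]


def train_ensemble(
    X: np.ndarray,
    y: np.ndarray,
    folds: np.ndarray,
    seed: int = 0,
    grids: Mapping[str, Sequence[Mapping]] | None = None,
) -> StackedScorer:
    """Stack the three base methods under a logistic meta-learner.

    Each base method's hyperparameters are CV-selected; its out-of-fold
    scores on the training rows become the meta-features, avoiding leakage
    of the training labels into the meta-fit.  At prediction time the base
    models refit on all training rows feed the meta-learner.
    """
    base: dict[str, FittedScorer] = {}
    oof_cols = []
    for method in BASE_METHODS:
        grid = None if grids is None else grids.get(method)
        params, cv_auc, oof = _select_params(method, X, y, folds, seed, grid)
        est = _make_estimator(method, params, seed)
        est.fit(X, y)
        base[method] = FittedScorer(method=method, params=params, model=est, cv_auc=cv_auc)
        oof_cols.append(oof)
    meta_X = np.column_stack(oof_cols)
    meta = LogisticRegression(max_iter=2000)
    meta.fit(meta_X, y)
    return StackedScorer(base=base, meta=meta)


def _prepare_matrix(
    table: pd.DataFrame,
    columns: Sequence[str],
    train_idx: np.ndarray,
    test_idx: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Median-impute (training medians) then min-max scale (training stats)."""
    train = table.iloc[train_idx][list(columns)].astype(float)
    test = table.iloc[test_idx][list(columns)].astype(float)
    medians = train.median(axis=0).fillna(0.0)
    n_imputed = int(train.isna().sum().sum() + test.isna().sum().sum())
    if n_imputed:
        logger.info("imputed %d missing cells with training medians", n_imputed)
    train = train.fillna(medians)
    test = test.fillna(medians)
    train_s, test_s, _ = minmax_fit_apply(train, test)
    return train_s.to_numpy(), test_s.to_numpy()


def run_benchmark(
    table: pd.DataFrame,
    cfg: SplitConfig,
    significant: Sequence[str] = (),
    methods: Sequence[str] = METHODS,
    models: Sequence[int] = (1, 2, 3, 4, 5),
    label_col: str = "is_food_desert",
    grids: Mapping[str, Sequence[Mapping]] | None = None,
) -> pd.DataFrame:
    """Run the method x model benchmark and report held-out test AUCs.

    Returns one row per (method, model): columns method, model_id, auc,
    delta_vs_baseline (versus that method's model-1 AUC, NaN when model 1
    is not among ``models``).  Reproducible bit-for-bit given ``cfg.seed``.
    """
    feature_sets = model_feature_sets(significant)
    train_idx, test_idx, folds = split_data(table, cfg, label_col)
    y_train = table.iloc[train_idx][label_col].astype(int).to_numpy()
    y_test = table.iloc[test_idx][label_col].astype(int).to_numpy()

    rows = []
    for model_id in models:
        columns = feature_sets[model_id]
        X_train, X_test = _prepare_matrix(table, columns, train_idx, test_idx)
        for method in methods:
            if method == "ensemble":
                scorer = train_ensemble(X_train, y_train, folds, seed=cfg.seed, grids=grids)
            else:
                grid = None if grids is None else grids.get(method)
                scorer = train_learner(method, X_train, y_train, folds, seed=cfg.seed, grid=grid)
            auc = compute_auc(scorer.predict(X_test), y_test)
            rows.append(
                {"method": method, "model_id": model_id, "auc": auc, "seed": cfg.seed}
            )
    out = pd.DataFrame(rows)
    baseline = out[out["model_id"] == 1].set_index("method")["auc"]
    out["delta_vs_baseline"] = [
        row["auc"] - baseline.get(row["method"], np.nan) for _, row in out.iterrows()
    ]
    return out
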