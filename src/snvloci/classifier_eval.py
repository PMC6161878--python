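"""Training and evaluation of the pathogenicity classifier.

The classification task: given the loci feature vector of an SNV (structure
and/or sequence block, optionally wild-type-difference features), predict
Benign vs Pathogenic. The reference model is a random forest; six further
algorithm families (naive Bayes, SVM, logistic regression, MLP, k-NN and a
shallow rule-tree standing in for a decision table) are exposed behind the
same interface for the comparison protocol.

Evaluation follows a fixed protocol: hyperparameters are chosen by weighted
F-score on a held-out validation split of the training data, missing values
are imputed with training statistics, and the final decision threshold is
the one maximizing weighted F along the ROC curve.

Weighted F-score: per-class F1 values averaged with weights proportional to
class support — the measure of choice under the strong class imbalance of
clinical variant sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .dataset_assembly import (
    ALL_PRIOR_FEATURES,
    LABEL_COLUMN,
    MUTATION_FEATURES,
    SEQUENCE_FEATURES,
    STR_NONEIGH_FEATURES,
    STRUCTURE_FEATURES,
    ImputationModel,
    apply_imputer,
    fit_imputer,
    split_train_validation,
)

__all__ = [
    "FEATURE_SETS", "Hyperparameters", "ModelBundle", "EvalMetrics",
    "FeatureRanking", "weighted_f", "weighted_f_from_confusion",
    "train_model", "select_hyperparameters", "predict_scores", "roc_scan",
    "rank_features", "default_grid", "run_protocol",
]

POSITIVE = "Pathogenic"
NEGATIVE = "Benign"

#: Named feature subsets used throughout the comparison protocol.
FEATURE_SETS: Dict[str, List[str]] = {
    "sequence": list(SEQUENCE_FEATURES),
    "structure": list(STRUCTURE_FEATURES),
    "str_noneigh": list(STR_NONEIGH_FEATURES),
    "seq+str": list(ALL_PRIOR_FEATURES),
    "all+mutation": list(ALL_PRIOR_FEATURES) + list(MUTATION_FEATURES),
}


@dataclass(frozen=True)
class Hyperparameters:
    """One grid point: algorithm family plus family-specific settings."""

    family: str = "random_forest"
    params: tuple = ()  # sorted (name, value) pairs, hashable
    seed: int = 0

    @staticmethod
    def make(family: str, seed: int = 0, **params) -> "Hyperparameters":
        return Hyperparameters(family=family, params=tuple(sorted(params.items())), seed=seed)

    @property
    def settings(self) -> Dict:
        return dict(self.params)


def default_grid(family: str = "random_forest", seed: int = 0) -> List[Hyperparameters]:
    """Small library-default grids per algorithm family."""
    H = Hyperparameters.make
    grids = {
        "random_forest": [
            H("random_forest", seed, n_estimators=n, max_depth=d)
            for n in (100, 200, 500) for d in (None, 10)
        ],
        "naive_bayes": [H("naive_bayes", seed)],
        "svm": [H("svm", seed, C=c) for c in (0.1, 1.0, 10.0)],
        "logistic": [H("logistic", seed, C=c) for c in (0.1, 1.0, 10.0)],
        "mlp": [H("mlp", seed, hidden=h) for h in (16, 64)],
        "knn": [H("knn", seed, k=k) for k in (1, 5, 15, 31)],
        "decision_table": [H("decision_table", seed, max_depth=d) for d in (4, 8)],
    }
    if family == "all":
        return [hp for fam in grids.values() for hp in fam]
    return grids[family]


def _build_estimator(hp: Hyperparameters):
    p = hp.settings
    if hp.family == "random_forest":
        return RandomForestClassifier(
            n_estimators=p.get("n_estimators", 200),
            max_depth=p.get("max_depth"),
            max_features="sqrt",
            random_state=hp.seed,
            n_jobs=1,
        )
    if hp.family == "naive_bayes":
        return GaussianNB()
    if hp.family == "svm":
        return make_pipeline(
            StandardScaler(),
            SVC(C=p.get("C", 1.0), probability=True, random_state=hp.seed),
        )
    if hp.family == "logistic":
        return make_pipeline(
            StandardScaler(),
            LogisticRegression(C=p.get("C", 1.0), max_iter=2000),
        )
    if hp.family == "mlp":
        return make_pipeline(
            StandardScaler(),
            MLPClassifier(
                hidden_layer_sizes=(p.get("hidden", 32),),
                max_iter=800,
                random_state=hp.seed,
            ),
        )
    if hp.family == "knn":
        return make_pipeline(
            StandardScaler(), KNeighborsClassifier(n_neighbors=p.get("k", 5))
        )
    if hp.family == "decision_table":
        # shallow rule tree: the closest sklearn analog of a decision table
        return DecisionTreeClassifier(max_depth=p.get("max_depth", 6), random_state=hp.seed)
    raise ValueError(f"unknown algorithm family {hp.family!r}")


def weighted_f_from_confusion(confusion: Dict[str, Dict[str, int]]) -> float:
    """Weighted F from a nested {true_class: {predicted_class: count}} table.

    Per-class F1 = 2PR/(P+R) with F1 = 0 when precision+recall = 0; the
    average weights each class by its true support.
    """
    classes = sorted(set(confusion) | {c for row in confusion.values() for c in row})
    total = sum(sum(row.values()) for row in confusion.values())
    if total == 0:
        raise ValueError("empty confusion table")
    score = 0.0
    for cls in classes:
        support = sum(confusion.get(cls, {}).values())
        if support == 0:
            continue
        tp = confusion.get(cls, {}).get(cls, 0)
        predicted = sum(confusion.get(t, {}).get(cls, 0) for t in classes)
        precision = tp / predicted if predicted else 0.0
        recall = tp / support
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        score += (support / total) * f1
    return score


def weighted_f(y_true: Sequence, y_pred: Sequence) -> float:
    """Support-weighted mean of per-class F1 scores."""
    if len(y_true) == 0:
        raise ValueError("empty input")
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    confusion: Dict[str, Dict[str, int]] = {}
    for t, p in zip(y_true, y_pred):
        confusion.setdefault(str(t), {}).setdefault(str(p), 0)
        confusion[str(t)][str(p)] += 1
    return weighted_f_from_confusion(confusion)


@dataclass
class ModelBundle:
    """A fitted model plus everything needed to apply it consistently."""

    model: object
    feature_columns: List[str]
    hyperparameters: Hyperparameters
    imputer: Optional[ImputationModel] = None
    classes: Tuple[str, ...] = (NEGATIVE, POSITIVE)
    metadata: Dict = field(default_factory=dict)

    def save(self, path) -> None:
        joblib.dump({"format_version": 1, "bundle": self}, path)

    @staticmethod
    def load(path) -> "ModelBundle":
        payload = joblib.load(path)
        if payload.get("format_version") != 1:
            raise ValueError("unsupported model bundle version")
        return payload["bundle"]


def _design_matrix(table: pd.DataFrame, columns: Sequence[str]) -> np.ndarray:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise ValueError(f"feature table lacks columns: {missing}")
    X = table[list(columns)].to_numpy(dtype=float)
    return X


def train_model(
    train: pd.DataFrame,
    hp: Optional[Hyperparameters] = None,
    feature_columns: Optional[Sequence[str]] = None,
    impute: bool = True,
) -> ModelBundle:
    """Fit one model on an assembled (and, unless disabled, imputed) table.

    Deterministic for a fixed seed in ``hp``. Raises on single-class input.
    """
    hp = hp or Hyperparameters.make("random_forest", n_estimators=200, max_depth=None)
    if feature_columns is None:
        feature_columns = [c for c in FEATURE_SETS["seq+str"] if c in train.columns]
    labels = train[LABEL_COLUMN]
    if labels.nunique() < 2:
        raise ValueError("training table has a single class")
    imputer = None
    if impute:
        imputer = fit_imputer(train, columns=list(feature_columns))
        train = apply_imputer(imputer, train)
    X = _design_matrix(train, feature_columns)
    est = _build_estimator(hp)
    est.fit(X, labels.to_numpy())
    return ModelBundle(
        model=est,
        feature_columns=list(feature_columns),
        hyperparameters=hp,
        imputer=imputer,
        classes=tuple(est.classes_) if hasattr(est, "classes_") else tuple(est[-1].classes_),
        metadata={"n_train": len(train)},
    )


def predict_scores(bundle: ModelBundle, table: pd.DataFrame) -> np.ndarray:
    """Pathogenicity score in [0, 1] per row (probability of Pathogenic)."""
    if table.empty:
        return np.array([])
    extra = []  # schema check: exact feature availability
    missing = [c for c in bundle.feature_columns if c not in table.columns]
    if missing:
        raise ValueError(f"schema mismatch; missing columns: {missing}, extra: {extra}")
    if bundle.imputer is not None:
        table = apply_imputer(bundle.imputer, table)
    X = _design_matrix(table, bundle.feature_columns)
    proba = bundle.model.predict_proba(X)
    classes = list(bundle.classes)
    return proba[:, classes.index(POSITIVE)]


def select_hyperparameters(
    train: pd.DataFrame,
    validation: pd.DataFrame,
    grid: Sequence[Hyperparameters],
    feature_columns: Optional[Sequence[str]] = None,
) -> Hyperparameters:
    """Grid point maximizing validation weighted F (ties: first declared)."""
    if not grid:
        raise ValueError("empty hyperparameter grid")
    best_hp, best_score = None, -np.inf
    for hp in grid:
        bundle = train_model(train, hp, feature_columns=feature_columns)
        scores = predict_scores(bundle, validation)
        preds = np.where(scores >= 0.5, POSITIVE, NEGATIVE)
        f = weighted_f(validation[LABEL_COLUMN].tolist(), preds.tolist())
        if f > best_score:
            best_hp, best_score = hp, f
    return best_hp


@dataclass
class EvalMetrics:
    """Confusion-derived rates at a fixed decision threshold."""

    threshold: float
    weighted_F: float
    TPR: float
    FNR: float
    TNR: float
    FPR: float
    tp: int
    fn: int
    tn: int
    fp: int

    def as_dict(self) -> Dict[str, float]:
        return {
            "threshold": self.threshold, "weighted_F": self.weighted_F,
            "TPR": self.TPR, "FNR": self.FNR, "TNR": self.TNR,
            "FPR": self.FPR, "tp": self.tp, "fn": self.fn,
            "tn": self.tn, "fp": self.fp,
        }


def _metrics_at(scores: np.ndarray, y: np.ndarray, threshold: float) -> EvalMetrics:
    pred_pos = scores >= threshold
    pos = y == POSITIVE
    tp = int(np.sum(pred_pos & pos))
    fn = int(np.sum(~pred_pos & pos))
    fp = int(np.sum(pred_pos & ~pos))
    tn = int(np.sum(~pred_pos & ~pos))
    preds = np.where(pred_pos, POSITIVE, NEGATIVE)
    return EvalMetrics(
        threshold=threshold,
        weighted_F=weighted_f(y.tolist(), preds.tolist()),
        TPR=tp / (tp + fn) if tp + fn else 0.0,
        FNR=fn / (tp + fn) if tp + fn else 0.0,
        TNR=tn / (tn + fp) if tn + fp else 0.0,
        FPR=fp / (tn + fp) if tn + fp else 0.0,
        tp=tp, fn=fn, tn=tn, fp=fp,
    )


def roc_scan(
    scores: Sequence[float],
    labels: Sequence[str],
) -> Tuple[float, EvalMetrics, pd.DataFrame]:
    """Scan ROC thresholds for the one maximizing weighted F.

    Candidate thresholds are midpoints between adjacent distinct sorted
    scores plus one below the minimum and one above the maximum; ties
    resolve to the lowest threshold. Also returns the ROC curve points
    (FPR, TPR, threshold).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if len(set(y)) < 2:
        raise ValueError("both classes required for a ROC scan")
    uniq = np.unique(scores)
    candidates = [uniq[0] - 1.0]
    candidates += [0.5 * (a + b) for a, b in zip(uniq[:-1], uniq[1:])]
    candidates += [uniq[-1] + 1.0]
    best = None
    for t in candidates:  # ascending: first maximum is the lowest threshold
        m = _metrics_at(scores, y, t)
        if best is None or m.weighted_F > best.weighted_F:
            best = m
    fpr, tpr, thr = roc_curve(y, scores, pos_label=POSITIVE)
    roc_points = pd.DataFrame({"FPR": fpr, "TPR": tpr, "threshold": thr})
    return best.threshold, best, roc_points


@dataclass
class FeatureRanking:
    """Features ordered by cross-validated ensemble importance."""

    names: List[str]
    importances: List[float]

    def rank_of(self, name: str) -> int:
        return self.names.index(name) + 1

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "feature": self.names,
            "importance": self.importances,
            "rank": np.arange(1, len(self.names) + 1),
        })


def rank_features(
    train: pd.DataFrame,
    feature_columns: Optional[Sequence[str]] = None,
    folds: int = 5,
    seed: int = 0,
    n_estimators: int = 200,
) -> FeatureRanking:
    """Random-forest impurity importances averaged over stratified CV folds,
    sorted descending."""
    if feature_columns is None:
        feature_columns = [c for c in FEATURE_SETS["all+mutation"] if c in train.columns]
    imputer = fit_imputer(train, columns=list(feature_columns))
    table = apply_imputer(imputer, train)
    X = _design_matrix(table, feature_columns)
    y = table[LABEL_COLUMN].to_numpy()
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    importances = np.zeros(len(feature_columns))
    for fold, (train_idx, _) in enumerate(skf.split(X, y)):
        rf = RandomForestClassifier(
            n_estimators=n_estimators, max_features="sqrt",
            random_state=seed + fold, n_jobs=1,
        )
        rf.fit(X[train_idx], y[train_idx])
        importances += rf.feature_importances_
    importances /= folds
    order = np.argsort(-importances)
    return FeatureRanking(
        names=[feature_columns[i] for i in order],
        importances=[float(importances[i]) for i in order],
    )


def run_protocol(
    train_table: pd.DataFrame,
    test_tables: Dict[str, pd.DataFrame],
    feature_set: str = "seq+str",
    family: str = "random_forest",
    seed: int = 0,
    validation_fraction: float = 0.2,
    grid: Optional[Sequence[Hyperparameters]] = None,
    tune_threshold_on: str = "validation",
) -> Dict[str, EvalMetrics]:
    """End-to-end evaluation protocol for one feature set.

    Splits the training table 80/20 (stratified), selects hyperparameters
    and the decision threshold by weighted F on the 20% validation split
    (or on each test set itself with ``tune_threshold_on='self'``), refits
    on the full training table, and reports threshold metrics per test set.
    """
    columns = [c for c in FEATURE_SETS[feature_set] if c in train_table.columns]
    sub_train, validation = split_train_validation(
        train_table, fraction=validation_fraction, seed=seed
    )
    grid = grid if grid is not None else default_grid(family, seed=seed)
    hp = select_hyperparameters(sub_train, validation, grid, feature_columns=columns)
    bundle = train_model(train_table, hp, feature_columns=columns)
    val_scores = predict_scores(bundle, validation)
    results: Dict[str, EvalMetrics] = {}
    if tune_threshold_on == "validation":
        threshold, _, _ = roc_scan(val_scores, validation[LABEL_COLUMN].tolist())
    for name, test in test_tables.items():
        scores = predict_scores(bundle, test)
        y = np.asarray(test[LABEL_COLUMN])
        if tune_threshold_on == "self":
            threshold, metrics, _ = roc_scan(scores, y.tolist())
        else:
            metrics = _metrics_at(scores, y, threshold)
        results[name] = metrics
    return results
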