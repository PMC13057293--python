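"""Classifier benchmarking under segment-level stratified k-fold CV.

Provides the two neural specs (a 4-block deep net and a 3-block shallow net),
a registry of classical baselines in their named variants, the confusion-
matrix metric suite, and a sweep driver that mirrors the band-wise /
combined / Top-k table layout.

Note the deliberate caveat: folds are stratified at the *epoch* level, so
epochs from one subject can appear in both train and test folds. A grouped
(subject-wise) mode is available to expose the difference.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, GroupKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from eegscreen._nn import MLPNet
from eegscreen.features import FeatureMatrix

METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "auc",
                "sensitivity", "specificity")


class StratificationError(ValueError):
    """A CV fold ended up with a single class in its training split."""


@dataclass
class ModelSpec:
    """Hyperparameters for one classifier.

    ``kind`` is ``"dnn"``, ``"snn"`` or ``"classical:<name>"`` where name is a
    key of :data:`CLASSICAL_MODELS`.
    """

    kind: str
    hidden_sizes: tuple[int, ...] | None = None
    dropout: float = 0.5
    batch_size: int = 16
    optimizer: str = "nadam"
    learning_rate: float = 1e-3
    max_epochs: int = 30
    early_stopping: dict = field(
        default_factory=lambda: {"monitor": "val_loss", "patience": 5,
                                 "val_fraction": 0.1}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.hidden_sizes is None:
            if self.kind == "dnn":
                self.hidden_sizes = (256, 128, 64, 32)
            elif self.kind == "snn":
                self.hidden_sizes = (128, 64, 32)
        if self.kind == "dnn" and len(self.hidden_sizes) != 4:
            raise ValueError("dnn requires exactly 4 hidden blocks")
        if self.kind == "snn" and len(self.hidden_sizes) != 3:
            raise ValueError("snn requires exactly 3 hidden blocks")

    def fingerprint(self) -> str:
        payload = asdict(self)
        payload["hidden_sizes"] = list(self.hidden_sizes or ())
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


def _scaled(est):
    return make_pipeline(StandardScaler(), est)


def _classical_factory(name: str, seed: int, input_dim: int):
    # MATLAB-style preset variants: tree depths via leaf caps, SVM kernel
    # scales fine/medium/coarse, kNN k values as printed.
    p = max(input_dim, 1)
    table = {
        "fine_tree": lambda: DecisionTreeClassifier(
            max_leaf_nodes=100, random_state=seed),
        "medium_tree": lambda: DecisionTreeClassifier(
            max_leaf_nodes=20, random_state=seed),
        "coarse_tree": lambda: DecisionTreeClassifier(
            max_leaf_nodes=4, random_state=seed),
        "lda": lambda: LinearDiscriminantAnalysis(),
        "qda": lambda: QuadraticDiscriminantAnalysis(reg_param=1e-3),
        "logistic_regression": lambda: _scaled(
            LogisticRegression(max_iter=2000, random_state=seed)),
        "gaussian_nb": lambda: GaussianNB(),
        "linear_svm": lambda: _scaled(SVC(
            kernel="linear", probability=False, random_state=seed)),
        "quadratic_svm": lambda: _scaled(SVC(
            kernel="poly", degree=2, random_state=seed)),
        "cubic_svm": lambda: _scaled(SVC(
            kernel="poly", degree=3, random_state=seed)),
        "fine_gaussian_svm": lambda: _scaled(SVC(
            kernel="rbf", gamma=16.0 / p, random_state=seed)),
        "medium_gaussian_svm": lambda: _scaled(SVC(
            kernel="rbf", gamma=1.0 / p, random_state=seed)),
        "coarse_gaussian_svm": lambda: _scaled(SVC(
            kernel="rbf", gamma=1.0 / (16.0 * p), random_state=seed)),
        "fine_knn": lambda: _scaled(KNeighborsClassifier(n_neighbors=3)),
        "medium_knn": lambda: _scaled(KNeighborsClassifier(n_neighbors=10)),
        "coarse_knn": lambda: _scaled(KNeighborsClassifier(n_neighbors=100)),
        "cosine_knn": lambda: _scaled(KNeighborsClassifier(
            n_neighbors=10, metric="cosine")),
        "cubic_knn": lambda: _scaled(KNeighborsClassifier(
            n_neighbors=10, p=3)),
        "weighted_knn": lambda: _scaled(KNeighborsClassifier(
            n_neighbors=20, weights="distance")),
        "ensemble_boosted_trees": lambda: AdaBoostClassifier(
            DecisionTreeClassifier(max_leaf_nodes=20, random_state=seed),
            n_estimators=30, random_state=seed),
        "ensemble_bagged_trees": lambda: RandomForestClassifier(
            n_estimators=100, random_state=seed),
        "ensemble_subspace_discriminant": lambda: BaggingClassifier(
            LinearDiscriminantAnalysis(), n_estimators=30,
            max_features=0.5, bootstrap=False, random_state=seed),
        "ensemble_rusboost": lambda: AdaBoostClassifier(
            DecisionTreeClassifier(max_leaf_nodes=20, random_state=seed,
                                   class_weight="balanced"),
            n_estimators=30, random_state=seed),
    }
    if name not in table:
        raise ValueError(f"unknown classical model {name!r}")
    return table[name]()


CLASSICAL_MODELS = (
    "fine_tree", "medium_tree", "coarse_tree", "lda", "qda",
    "logistic_regression", "gaussian_nb", "linear_svm", "quadratic_svm",
    "cubic_svm", "fine_gaussian_svm", "medium_gaussian_svm",
    "coarse_gaussian_svm", "fine_knn", "medium_knn", "coarse_knn",
    "cosine_knn", "cubic_knn", "weighted_knn", "ensemble_boosted_trees",
    "ensemble_bagged_trees", "ensemble_subspace_discriminant",
    "ensemble_rusboost",
)


def build_model(spec: ModelSpec, input_dim: int):
    """Instantiate the classifier described by ``spec`` for ``input_dim`` inputs."""
    if input_dim < 1:
        raise ValueError("input_dim must be >= 1")
    if spec.kind in ("dnn", "snn"):
        return MLPNet(
            input_dim=input_dim,
            hidden_sizes=spec.hidden_sizes,
            dropout=spec.dropout,
            learning_rate=spec.learning_rate,
            batch_size=spec.batch_size,
            max_epochs=spec.max_epochs,
            patience=spec.early_stopping.get("patience", 5),
            seed=spec.seed,
        )
    if spec.kind.startswith("classical:"):
        return _classical_factory(spec.kind.split(":", 1)[1], spec.seed, input_dim)
    raise ValueError(f"unknown model kind {spec.kind!r}")


def _rank_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUC with midranks for ties."""
    pos = y_true == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        return float("nan")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def compute_metrics(
    confusion: Mapping[str, int],
    y_true: np.ndarray | None = None,
    scores: np.ndarray | None = None,
) -> dict:
    """Metric suite from confusion counts (positive class = dyslexic = 1).

    Precision/recall/F1 are class-weighted, so weighted recall equals
    accuracy. Metrics with a zero denominator are reported as ``None`` with a
    corresponding entry in ``undefined``. ``auc`` is computed from per-sample
    class-1 scores when given.
    """
    tp, tn = confusion["TP"], confusion["TN"]
    fp, fn = confusion["FP"], confusion["FN"]
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("empty confusion matrix")
    undefined: list[str] = []
    pos_support, neg_support = tp + fn, tn + fp

    sensitivity = tp / pos_support if pos_support else None
    specificity = tn / neg_support if neg_support else None
    if sensitivity is None:
        undefined.append("sensitivity")
    if specificity is None:
        undefined.append("specificity")

    prec_pos = tp / (tp + fp) if (tp + fp) else 0.0
    prec_neg = tn / (tn + fn) if (tn + fn) else 0.0
    rec_pos = sensitivity if sensitivity is not None else 0.0
    rec_neg = specificity if specificity is not None else 0.0

    def weighted(a, b):
        return (pos_support * a + neg_support * b) / total

    def f1(p, r):
        return 2 * p * r / (p + r) if (p + r) else 0.0

    out = {
        "accuracy": (tp + tn) / total,
        "precision": weighted(prec_pos, prec_neg),
        "recall": weighted(rec_pos, rec_neg),
        "f1": weighted(f1(prec_pos, rec_pos), f1(prec_neg, rec_neg)),
        "sensitivity": sensitivity,
        "specificity": specificity,
        "auc": None,
        "undefined": undefined,
    }
    if scores is not None and y_true is not None:
        out["auc"] = _rank_auc(np.asarray(y_true), np.asarray(scores))
    return out


@dataclass
class EvalReport:
    """Per-fold metrics plus average/maximum aggregates for one model."""

    model_kind: str
    n_folds: int
    per_fold: list[dict]
    confusions: list[dict]
    aggregate: dict
    fingerprint: str


def _predict_scores(model, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(model, "predict_proba"):
        try:
            proba = model.predict_proba(X)
            return proba.argmax(axis=1), proba[:, 1]
        except Exception:
            pass
    if hasattr(model, "decision_function"):
        scores = model.decision_function(X)
        return (scores > 0).astype(int), scores
    pred = model.predict(X)
    return pred, pred.astype(float)


def _fit_fold(spec: ModelSpec, fold_seed: int, X_tr, y_tr):
    fold_spec = ModelSpec(**{**asdict(spec), "seed": fold_seed,
                             "hidden_sizes": spec.hidden_sizes})
    model = build_model(fold_spec, X_tr.shape[1])
    if isinstance(model, MLPNet):
        val_fraction = spec.early_stopping.get("val_fraction", 0.1)
        if val_fraction and len(np.unique(y_tr)) > 1:
            X_fit, X_val, y_fit, y_val = train_test_split(
                X_tr, y_tr, test_size=val_fraction, stratify=y_tr,
                random_state=fold_seed,
            )
            model.fit(X_fit, y_fit, X_val, y_val)
        else:
            model.fit(X_tr, y_tr)
    else:
        model.fit(X_tr, y_tr)
    return model


def run_cv(
    X: FeatureMatrix,
    spec: ModelSpec,
    n_folds: int = 10,
    seed: int = 0,
    grouped: bool = False,
) -> EvalReport:
    """Stratified k-fold cross-validation at the epoch level.

    With ``grouped=True`` folds are split by subject instead (exposing the
    subject-leakage gap the segment-level protocol carries).
    """
    values, labels = X.values, X.labels
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError("binary labels required")
    if counts.min() < n_folds:
        raise ValueError("each class needs at least n_folds samples")

    if grouped:
        groups = np.asarray(X.subject_ids)
        splitter = GroupKFold(n_splits=n_folds)
        splits = splitter.split(values, labels, groups)
    else:
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True,
                                   random_state=seed)
        splits = splitter.split(values, labels)

    per_fold, confusions = [], []
    for fold, (tr, te) in enumerate(splits):
        if len(np.unique(labels[tr])) < 2:
            raise StratificationError(f"fold {fold} has a single class in train")
        model = _fit_fold(spec, seed + fold, values[tr], labels[tr])
        pred, scores = _predict_scores(model, values[te])
        y_te = labels[te]
        conf = {
            "TP": int(np.sum((pred == 1) & (y_te == 1))),
            "TN": int(np.sum((pred == 0) & (y_te == 0))),
            "FP": int(np.sum((pred == 1) & (y_te == 0))),
            "FN": int(np.sum((pred == 0) & (y_te == 1))),
        }
        per_fold.append(compute_metrics(conf, y_true=y_te, scores=scores))
        confusions.append(conf)

    aggregate = {"average": {}, "maximum": {}}
    for m in METRIC_NAMES:
        vals = [f[m] for f in per_fold if f[m] is not None]
        aggregate["average"][m] = float(np.mean(vals)) if vals else None
        aggregate["maximum"][m] = float(np.max(vals)) if vals else None
    return EvalReport(
        model_kind=spec.kind,
        n_folds=n_folds,
        per_fold=per_fold,
        confusions=confusions,
        aggregate=aggregate,
        fingerprint=spec.fingerprint(),
    )


def benchmark_suite(
    feature_settings: Mapping[str, FeatureMatrix],
    specs: Iterable[ModelSpec],
    n_folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Run every (feature setting x model) cell and return a tidy table."""
    rows = []
    for setting, fm in feature_settings.items():
        for spec in specs:
            report = run_cv(fm, spec, n_folds=n_folds, seed=seed)
            row = {
                "feature_set": setting,
                "model": spec.kind,
                "n_features": fm.n_features,
            }
            for m in METRIC_NAMES:
                row[f"avg_{m}"] = report.aggregate["average"][m]
                row[f"max_{m}"] = report.aggregate["maximum"][m]
            rows.append(row)
    return pd.DataFrame(rows)
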