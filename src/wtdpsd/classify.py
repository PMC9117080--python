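"""Classifier bank and evaluation metrics.

Five classifiers are trained on the reduced features: k-nearest
neighbours, RBF support-vector machine, linear discriminant analysis, a
decision tree, and the small 1-D CNN.  Evaluation produces a 3x3
confusion matrix (rows = true class, columns = predicted; classes
HC=1, AD=2, MCI=3), per-class sensitivity and precision, overall
accuracy — all on the percent scale — and one-vs-rest ROC curves with
trapezoid AUC per class plus the macro average.

The experiment driver runs stratified k-fold cross-validation with
identical folds for every classifier; standardization and PCA are fit on
each training fold only, so no test-sample statistics leak into the
projection.  An optional resubstitution mode trains and evaluates on the
full set instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import confusion_matrix, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .cnn import SmallCNN
from .errors import ConfigurationError, ShapeError
from .reduce import fit_pca, transform

CLASSIFIER_KINDS = ("KNN", "SVM", "LDA", "DT", "CNN")

#: Fixed class coding used throughout: HC=1, AD=2, MCI=3.
CLASS_LABELS = (1, 2, 3)
CLASS_NAMES = ("HC", "AD", "MCI")

DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "KNN": {"n_neighbors": 5},
    "SVM": {"kernel": "rbf", "C": 1.0, "gamma": "scale"},
    "LDA": {},
    "DT": {"criterion": "gini", "min_samples_leaf": 1},
    "CNN": {
        "n_filters": 8,
        "kernel": 3,
        "hidden": 600,
        "lr": 1e-3,
        "epochs": 200,
        "batch_size": 32,
    },
}


@dataclass
class ClassifierConfig:
    kind: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ConfigurationError(
                f"unknown classifier kind {self.kind!r}; expected one of "
                f"{CLASSIFIER_KINDS}"
            )

    def resolved_hyperparameters(self) -> dict:
        return DEFAULT_HYPERPARAMETERS[self.kind] | self.hyperparameters


@dataclass
class FittedModel:
    """A trained classifier together with its score-extraction rule."""

    kind: str
    estimator: object
    classes: np.ndarray  # label values in estimator order

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if self.kind == "CNN":
            return self.classes[self.estimator.predict(X)]
        return self.estimator.predict(X)

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Per-class ranking scores, columns ordered by ``self.classes``.

        Probabilities for KNN (vote fractions), DT (leaf frequencies) and
        CNN (softmax); signed distance to boundary for SVM and LDA.
        """
        X = np.asarray(X, dtype=np.float64)
        if self.kind in ("KNN", "DT"):
            return self.estimator.predict_proba(X)
        if self.kind == "CNN":
            return self.estimator.predict_proba(X)
        return self.estimator.decision_function(X)


@dataclass
class EvaluationReport:
    """All evaluation metrics for one classifier on one test set."""

    confusion: np.ndarray  # (3, 3) int, rows true, cols predicted
    sensitivity: np.ndarray  # (3,) percent
    precision: np.ndarray  # (3,) percent
    accuracy: float  # percent
    auc: np.ndarray  # (3,) one-vs-rest
    macro_auc: float
    roc_curves: dict[int, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "class_labels": list(CLASS_LABELS),
            "class_names": list(CLASS_NAMES),
            "sensitivity_pct": self.sensitivity.tolist(),
            "precision_pct": self.precision.tolist(),
            "accuracy_pct": self.accuracy,
            "auc": self.auc.tolist(),
            "macro_auc": self.macro_auc,
            "flags": self.flags,
        }

    def confusion_text(self) -> str:
        """Labeled plain-text confusion matrix."""
        lines = ["true\\pred  " + "  ".join(f"{n:>5s}" for n in CLASS_NAMES)]
        for i, name in enumerate(CLASS_NAMES):
            lines.append(
                f"{name:>9s}  " + "  ".join(f"{int(v):5d}" for v in self.confusion[i])
            )
        return "\n".join(lines)


def _validate_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if not np.all(np.isin(y, CLASS_LABELS)):
        bad = sorted(set(np.unique(y)) - set(CLASS_LABELS))
        raise ValueError(f"labels outside {CLASS_LABELS}: {bad}")
    return y.astype(np.int64)


def train(config: ClassifierConfig, X: np.ndarray, y: np.ndarray) -> FittedModel:
    """Train one classifier; deterministic for a fixed config seed."""
    X = np.asarray(X, dtype=np.float64)
    y = _validate_labels(y)
    if not np.all(np.isfinite(X)):
        raise ValueError("training matrix contains non-finite entries")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")

    hp = config.resolved_hyperparameters()
    if config.kind == "KNN":
        est = KNeighborsClassifier(**hp).fit(X, y)
        classes = est.classes_
    elif config.kind == "SVM":
        est = SVC(decision_function_shape="ovr", random_state=config.seed, **hp).fit(X, y)
        classes = est.classes_
    elif config.kind == "LDA":
        est = LinearDiscriminantAnalysis(**hp).fit(X, y)
        classes = est.classes_
    elif config.kind == "DT":
        est = DecisionTreeClassifier(random_state=config.seed, **hp).fit(X, y)
        classes = est.classes_
    else:  # CNN
        classes = np.unique(y)
        est = SmallCNN(n_classes=len(classes), seed=config.seed, **hp)
        index = np.searchsorted(classes, y)
        est.fit(X, index)
    return FittedModel(kind=config.kind, estimator=est, classes=np.asarray(classes))


def evaluate_confusion(confusion: np.ndarray) -> dict:
    """Sensitivity, precision and accuracy (percent) from a confusion matrix.

    Rows are true classes, columns predictions.  A zero column sum yields
    precision 0 with a flag rather than a division error.
    """
    C = np.asarray(confusion, dtype=np.float64)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ShapeError(f"confusion matrix must be square, got {C.shape}")
    total = C.sum()
    row = C.sum(axis=1)
    col = C.sum(axis=0)
    diag = np.diag(C)
    flags = []
    sensitivity = np.where(row > 0, 100.0 * diag / np.maximum(row, 1), 0.0)
    precision = np.where(col > 0, 100.0 * diag / np.maximum(col, 1), 0.0)
    for c in np.flatnonzero(col == 0):
        flags.append(f"empty_predicted_class:{c}")
    accuracy = 100.0 * diag.sum() / total
    return {
        "sensitivity": sensitivity,
        "precision": precision,
        "accuracy": float(accuracy),
        "flags": flags,
    }


def roc_one_vs_rest(
    scores: np.ndarray, y_test: np.ndarray
) -> tuple[dict[int, tuple[np.ndarray, np.ndarray]], np.ndarray, float, list[str]]:
    """One-vs-rest ROC curves and trapezoid AUC per class.

    ``scores`` has one column per class in CLASS_LABELS order.  Constant
    score columns degenerate to the chance diagonal (AUC 0.5, flagged).
    Returns (curves, auc_per_class, macro_auc, flags).
    """
    y_test = _validate_labels(y_test)
    scores = np.asarray(scores, dtype=np.float64)
    if scores.shape != (len(y_test), len(CLASS_LABELS)):
        raise ShapeError(
            f"scores shape {scores.shape} != ({len(y_test)}, {len(CLASS_LABELS)})"
        )
    curves: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    aucs = np.zeros(len(CLASS_LABELS))
    flags: list[str] = []
    for i, label in enumerate(CLASS_LABELS):
        col = scores[:, i]
        if np.ptp(col) == 0:
            flags.append(f"degenerate_roc:{CLASS_NAMES[i]}")
            fpr, tpr = np.array([0.0, 1.0]), np.array([0.0, 1.0])
        else:
            fpr, tpr, _ = roc_curve(y_test == label, col)
        curves[label] = (fpr, tpr)
        aucs[i] = np.trapezoid(tpr, fpr)
    return curves, aucs, float(aucs.mean()), flags


def evaluate(model: FittedModel, X_test: np.ndarray, y_test: np.ndarray) -> EvaluationReport:
    """Full evaluation of a fitted model on a held-out set."""
    X_test = np.asarray(X_test, dtype=np.float64)
    y_test = _validate_labels(y_test)
    if len(y_test) == 0:
        raise ValueError("empty test set")
    pred = model.predict(X_test)
    scores = _scores_in_class_order(model, X_test)
    return _report_from_predictions(y_test, pred, scores)


def _scores_in_class_order(model: FittedModel, X: np.ndarray) -> np.ndarray:
    """Score matrix with one column per CLASS_LABELS entry (absent -> -inf)."""
    raw = model.scores(X)
    out = np.full((X.shape[0], len(CLASS_LABELS)), -np.inf)
    for j, label in enumerate(model.classes):
        out[:, CLASS_LABELS.index(label)] = raw[:, j]
    return out


def _report_from_predictions(
    y_test: np.ndarray, pred: np.ndarray, scores: np.ndarray
) -> EvaluationReport:
    C = confusion_matrix(y_test, pred, labels=list(CLASS_LABELS))
    metrics = evaluate_confusion(C)
    finite = np.where(np.isfinite(scores), scores, np.nanmin(scores[np.isfinite(scores)]) - 1.0)
    curves, aucs, macro, roc_flags = roc_one_vs_rest(finite, y_test)
    return EvaluationReport(
        confusion=C,
        sensitivity=metrics["sensitivity"],
        precision=metrics["precision"],
        accuracy=metrics["accuracy"],
        auc=aucs,
        macro_auc=macro,
        roc_curves=curves,
        flags=metrics["flags"] + roc_flags,
    )


@dataclass
class ExperimentConfig:
    """Settings of the cross-validated five-classifier comparison."""

    classifiers: Sequence[str] = CLASSIFIER_KINDS
    n_folds: int = 5
    n_components: int = 7
    standardize: bool = True
    seed: int = 0
    paper_mode: bool = False  # resubstitution: fit and evaluate on the full set
    hyperparameters: dict[str, dict] = field(default_factory=dict)


def run_experiment(
    features: np.ndarray,
    labels: np.ndarray,
    config: Optional[ExperimentConfig] = None,
) -> tuple[dict[str, EvaluationReport], pd.DataFrame]:
    """Cross-validated comparison of the classifier bank.

    ``features`` is the raw n x 49 descriptor matrix; standardization and
    PCA are refit inside each training fold and applied frozen to its test
    fold.  Folds are identical across classifiers.  Confusion matrices and
    scores are pooled over folds before metrics are computed.

    Returns per-classifier reports and a summary table (accuracy, AUC).
    """
    if config is None:
        config = ExperimentConfig()
    X = np.asarray(features, dtype=np.float64)
    y = _validate_labels(labels)

    if config.paper_mode:
        warnings.warn(
            "resubstitution mode: training and evaluating on the same samples "
            "overstates generalization accuracy",
            stacklevel=2,
        )
        splits = [(np.arange(len(y)), np.arange(len(y)))]
    else:
        skf = StratifiedKFold(
            n_splits=config.n_folds, shuffle=True, random_state=config.seed
        )
        splits = list(skf.split(X, y))

    pooled_pred = {kind: np.zeros(len(y), dtype=np.int64) for kind in config.classifiers}
    pooled_scores = {
        kind: np.zeros((len(y), len(CLASS_LABELS))) for kind in config.classifiers
    }

    for fold_idx, (tr, te) in enumerate(splits):
        model_pca = fit_pca(
            X[tr], n_components=config.n_components, standardize=config.standardize
        )
        Z_tr = transform(X[tr], model_pca)
        Z_te = transform(X[te], model_pca)
        for kind in config.classifiers:
            cconf = ClassifierConfig(
                kind=kind,
                hyperparameters=config.hyperparameters.get(kind, {}),
                seed=config.seed + fold_idx,
            )
            fitted = train(cconf, Z_tr, y[tr])
            pooled_pred[kind][te] = fitted.predict(Z_te)
            pooled_scores[kind][te] = _scores_in_class_order(fitted, Z_te)

    reports: dict[str, EvaluationReport] = {}
    rows = []
    for kind in config.classifiers:
        scores = pooled_scores[kind]
        finite_min = (
            np.min(scores[np.isfinite(scores)]) - 1.0 if np.isfinite(scores).any() else 0.0
        )
        scores = np.where(np.isfinite(scores), scores, finite_min)
        report = _report_from_predictions(y, pooled_pred[kind], scores)
        reports[kind] = report
        rows.append(
            {
                "classifier": kind,
                "accuracy_pct": report.accuracy,
                "macro_auc": report.macro_auc,
                **{
                    f"auc_{name}": report.auc[i]
                    for i, name in enumerate(CLASS_NAMES)
                },
            }
        )
    return reports, pd.DataFrame(rows)
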