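"""Downstream transferability protocol: fit seven shallow classifiers on frozen
features and report accuracy plus class-wise precision / recall / specificity /
F1 from the confusion matrix.

Metric conventions: all values are percentages; a metric whose denominator is
zero (e.g. precision of a never-predicted class) is reported as ``None``.
In the binary setting the specificity of one class equals the recall of the
other, which is asserted as a structural invariant in the tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

__all__ = [
    "CLASSIFIER_NAMES",
    "build_protocol",
    "confusion_matrix_counts",
    "confusion_metrics",
    "EvalReport",
    "evaluate_predictions",
    "fit_and_evaluate",
    "reports_to_rows",
]

CLASSIFIER_NAMES: Tuple[str, ...] = (
    "LR",
    "kNN",
    "NaiveBayes",
    "RF",
    "LinearSVM",
    "RBFSVM",
    "ANN",
)


def build_protocol(seed: int = 0) -> Dict[str, object]:
    """The seven-classifier family: LR, kNN (k=9), Gaussian NB, RF (10 trees),
    linear SVM, RBF SVM, and a two-hidden-layer MLP."""
    return {
        "LR": LogisticRegression(max_iter=2000),
        "kNN": KNeighborsClassifier(n_neighbors=9),
        "NaiveBayes": GaussianNB(),
        "RF": RandomForestClassifier(n_estimators=10, random_state=seed),
        "LinearSVM": SVC(kernel="linear", C=1.0),
        "RBFSVM": SVC(kernel="rbf", C=1.0, gamma="scale"),
        "ANN": MLPClassifier(
            hidden_layer_sizes=(100, 100), max_iter=500, random_state=seed
        ),
    }


def confusion_matrix_counts(
    y_true: np.ndarray, y_pred: np.ndarray, n_classes: int
) -> np.ndarray:
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        cm[int(t), int(p)] += 1
    return cm


def _ratio(num: float, den: float) -> Optional[float]:
    if den == 0:
        return None
    return 100.0 * num / den


def confusion_metrics(cm: np.ndarray, positive_class: int) -> Dict[str, Optional[float]]:
    """Per-class metrics (in %) from a rows-true / columns-predicted count matrix.

    Zero-denominator ratios come back as ``None`` (undefined, not zero).
    """
    cm = np.asarray(cm)
    if cm.size == 0:
        raise ValueError("empty confusion matrix")
    if (cm < 0).any():
        raise ValueError("confusion matrix counts must be nonnegative")
    k = positive_class
    tp = cm[k, k]
    fp = cm[:, k].sum() - tp
    fn = cm[k, :].sum() - tp
    tn = cm.sum() - tp - fp - fn
    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    specificity = _ratio(tn, tn + fp)
    if precision is None or recall is None or (precision + recall) == 0:
        f1 = None
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return {
        "precision": precision,
        "recall": recall,
        "specificity": specificity,
        "f1": f1,
    }


@dataclass
class EvalReport:
    accuracy: float  # percent
    per_class: Dict[int, Dict[str, Optional[float]]]
    confusion: np.ndarray
    n_eval: int = 0

    def __post_init__(self) -> None:
        self.confusion = np.asarray(self.confusion)
        self.n_eval = int(self.confusion.sum())


def evaluate_predictions(y_true: np.ndarray, y_pred: np.ndarray,
                         n_classes: int | None = None) -> EvalReport:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if n_classes is None:
        n_classes = int(max(y_true.max(), y_pred.max())) + 1
    cm = confusion_matrix_counts(y_true, y_pred, n_classes)
    acc = 100.0 * np.trace(cm) / cm.sum()
    per_class = {c: confusion_metrics(cm, c) for c in range(n_classes)}
    return EvalReport(accuracy=float(acc), per_class=per_class, confusion=cm)


def _standardize(train: np.ndarray, test: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    mean = train.mean(axis=0)
    std = train.std(axis=0)
    zero_var = std == 0
    if zero_var.all():
        warnings.warn("all feature columns have zero variance; standardization skipped")
    std = np.where(zero_var, 1.0, std)
    return (train - mean) / std, (test - mean) / std


def fit_and_evaluate(
    features: np.ndarray,
    labels: np.ndarray,
    protocol: Dict[str, object] | None = None,
    split_seed: int = 0,
    test_fraction: float = 0.2,
) -> Dict[str, EvalReport]:
    """Stratified single split, z-score standardization fit on the training
    portion, then each protocol classifier fitted and scored on the same split."""
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if features.shape[0] < 20:
        raise ValueError("need at least 20 samples for the evaluation protocol")
    if protocol is None:
        protocol = build_protocol(seed=split_seed)
    x_tr, x_te, y_tr, y_te = train_test_split(
        features, labels,
        test_size=test_fraction, random_state=split_seed, stratify=labels,
    )
    if np.unique(y_tr).size < 2 or np.unique(y_te).size < 2:
        raise ValueError("both classes must be present in train and test splits")
    x_tr, x_te = _standardize(x_tr, x_te)
    n_classes = int(labels.max()) + 1
    reports = {}
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=UserWarning)
        warnings.filterwarnings("ignore", message=".*convergence.*")
        warnings.filterwarnings("ignore", module="sklearn")
        for name, clf in protocol.items():
            clf.fit(x_tr, y_tr)
            reports[name] = evaluate_predictions(y_te, clf.predict(x_te), n_classes)
    return reports


def reports_to_rows(reports: Dict[str, EvalReport],
                    class_names: Sequence[str] | None = None) -> List[dict]:
    """Flatten reports into one row per classifier for CSV export."""
    rows = []
    for name, rep in reports.items():
        row = {"classifier": name, "accuracy": round(rep.accuracy, 2)}
        for c, metrics in rep.per_class.items():
            cname = class_names[c] if class_names else f"class{c}"
            for metric, value in metrics.items():
                row[f"{cname}_{metric}"] = (
                    None if value is None else round(value, 2)
                )
        rows.append(row)
    return rows
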