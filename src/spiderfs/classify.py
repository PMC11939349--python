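"""Class-weighted SVM, a uniform classifier registry, and the
two-phase evaluation harness.

The weighted SVM counters class imbalance by giving the minority (+1)
class a larger slack penalty C+ than the majority's C-, so margin
violations on rare samples cost more.  Penalties follow the balanced
inverse-frequency rule C_class = C * n / (2 * n_class), under which
C+/C- equals the imbalance ratio and both reduce to C when the classes
are balanced.  The quadratic program itself (soft-margin primal, its
kernelized dual with per-class box constraints 0 <= a_i <= C_i) is
delegated to the libsvm solver behind scikit-learn's SVC.

Phase I evaluates classifiers on the mRMR-filtered feature set alone;
Phase II on the feature subset chosen by the full hybrid wrapper.  Both
phases consume the identical train/test partition so the comparison
isolates the wrapper's contribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .bpsoa import FitnessConfig, bpsoa_select
from .core import ExpressionDataset, SplitSpec, split_train_test
from .metrics import MetricPanel, ConfusionCounts, classification_metrics, confusion_counts, roc_points
from .mrmr import discretize, fast_mrmr_select
from .psoa import PsoaParams

CLASSIFIER_NAMES = ("svm", "wsvm", "dt", "xgb", "ada", "rf", "knn")


class ClassifierError(ValueError):
    pass


@dataclass(frozen=True)
class ClassWeights:
    """Per-class slack penalties for the weighted SVM."""

    c_plus: float
    c_minus: float
    base_c: float

    def as_dict(self) -> dict[int, float]:
        # scikit-learn's class_weight multiplies C per class
        return {1: self.c_plus / self.base_c, -1: self.c_minus / self.base_c}


def class_weights(labels: np.ndarray, base_c: float = 1.0) -> ClassWeights:
    """Balanced inverse-frequency penalties C_class = C*n/(2*n_class)."""
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == -1))
    if n_pos == 0 or n_neg == 0:
        raise ClassifierError("both classes must be present")
    n = n_pos + n_neg
    return ClassWeights(
        c_plus=base_c * n / (2 * n_pos),
        c_minus=base_c * n / (2 * n_neg),
        base_c=base_c,
    )


class _XgbWrapper:
    """Adapts xgboost to the package's {+1,-1} label coding."""

    def __init__(self, **hyper):
        self.model = XGBClassifier(
            eval_metric="logloss", random_state=hyper.pop("random_state", 0), **hyper
        )

    def fit(self, X, y):
        self.model.fit(X, (np.asarray(y) == 1).astype(int))
        return self

    def predict(self, X):
        return np.where(self.model.predict(X) == 1, 1, -1)

    def decision_scores(self, X):
        return self.model.predict_proba(X)[:, 1]


def _decision_scores(model, X) -> np.ndarray:
    if hasattr(model, "decision_scores"):
        return model.decision_scores(X)
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X))
    proba = model.predict_proba(X)
    pos_col = list(model.classes_).index(1)
    return proba[:, pos_col]


def train_classifier(
    name: str,
    train: ExpressionDataset,
    selected: np.ndarray,
    hyper: dict | None = None,
):
    """Fit a named classifier on the selected feature columns.

    ``wsvm`` applies the per-class penalties from :func:`class_weights`
    on top of an RBF-kernel SVC; all other names use the established
    library defaults (recorded in the benchmark report for
    reproducibility).
    """
    hyper = dict(hyper or {})
    selected = np.asarray(selected)
    if selected.size == 0:
        raise ClassifierError("selected feature set is empty")
    X = train.matrix[:, selected]
    y = train.labels
    seed = hyper.pop("random_state", 0)
    if name == "svm":
        model = SVC(kernel=hyper.pop("kernel", "rbf"), random_state=seed, **hyper)
    elif name == "wsvm":
        cw = class_weights(y, base_c=hyper.pop("base_c", 1.0))
        model = SVC(
            kernel=hyper.pop("kernel", "rbf"),
            class_weight=cw.as_dict(),
            random_state=seed,
            **hyper,
        )
    elif name == "dt":
        model = DecisionTreeClassifier(random_state=seed, **hyper)
    elif name == "xgb":
        model = _XgbWrapper(random_state=seed, **hyper)
    elif name == "ada":
        model = AdaBoostClassifier(random_state=seed, **hyper)
    elif name == "rf":
        model = RandomForestClassifier(random_state=seed, **hyper)
    elif name == "knn":
        model = KNeighborsClassifier(n_neighbors=hyper.pop("n_neighbors", 5), **hyper)
    else:
        raise ClassifierError(
            f"unknown classifier {name!r}; valid names: {', '.join(CLASSIFIER_NAMES)}"
        )
    model.fit(X, y)
    return _FittedModel(name=name, model=model, selected=selected)


@dataclass(frozen=True)
class _FittedModel:
    name: str
    model: object
    selected: np.ndarray


@dataclass(frozen=True)
class EvaluationReport:
    """Held-out metrics for one classifier."""

    classifier: str
    counts: ConfusionCounts
    panel: MetricPanel
    roc: np.ndarray
    n_features: int

    def as_dict(self) -> dict:
        return {
            "classifier": self.classifier,
            "counts": {
                "tp": self.counts.tp,
                "fp": self.counts.fp,
                "tn": self.counts.tn,
                "fn": self.counts.fn,
            },
            "metrics": self.panel.as_dict(),
            "n_features": self.n_features,
            "roc": [[float(a), float(b)] for a, b in self.roc],
        }


def evaluate_classifier(fitted: _FittedModel, test: ExpressionDataset) -> EvaluationReport:
    """Score a fitted model on held-out data (same feature subset)."""
    if fitted.selected.max() >= test.n_features:
        raise ClassifierError("selected features out of range for test data")
    X = test.matrix[:, fitted.selected]
    pred = np.asarray(fitted.model.predict(X))
    counts = confusion_counts(test.labels, pred)
    scores = _decision_scores(fitted.model, X)
    roc = roc_points(test.labels, scores)
    return EvaluationReport(
        classifier=fitted.name,
        counts=counts,
        panel=classification_metrics(counts),
        roc=roc,
        n_features=int(fitted.selected.size),
    )


def run_phase_experiment(
    ds: ExpressionDataset,
    phase: str,
    classifiers: list[str],
    split: SplitSpec | None = None,
    m_top: int = 100,
    params: PsoaParams | None = None,
    cfg: FitnessConfig | None = None,
) -> dict[str, EvaluationReport]:
    """Run the filter-only or filter+wrapper protocol end to end.

    ``phase`` is ``filter-only`` (fast mRMR top-M features straight
    into each classifier) or ``filter+wrapper`` (full hybrid
    selection).  Feature selection sees only the training split; the
    split itself depends only on the seed, so both phases consume the
    identical partition.
    """
    if phase not in ("filter-only", "filter+wrapper"):
        raise ClassifierError(f"unknown phase {phase!r}")
    split = split or SplitSpec()
    params = params or PsoaParams(seed=split.seed)
    cfg = cfg or FitnessConfig(seed=split.seed)
    m_top = min(m_top, ds.n_features)
    train, test = split_train_test(ds, split)
    # selection must never see test samples
    assert set(train.sample_ids).isdisjoint(test.sample_ids)
    if phase == "filter-only":
        dm = discretize(train.matrix)
        ranking = fast_mrmr_select(dm, train.labels, k=m_top)
        selected = np.sort(ranking.order)
    else:
        result = bpsoa_select(train, m_top=m_top, params=params, cfg=cfg)
        selected = result.selected_indices
    reports: dict[str, EvaluationReport] = {}
    for name in classifiers:
        fitted = train_classifier(name, train, selected, {"random_state": split.seed})
        try:
            reports[name] = evaluate_classifier(fitted, test)
        except Exception as exc:
            raise ClassifierError(f"[phase {phase}] {name}: {exc}") from exc
    return reports
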