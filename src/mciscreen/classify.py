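"""Classifiers, repeated leave-one-out evaluation, and decision fusion.

Four classifier families are used, with fixed hyperparameters: a decision
tree, a random forest with 150 trees, an RBF-kernel SVM, and XGBoost with
gamma 0, learning rate 0.3 and 120 estimators.  Evaluation is leave-one-out
cross-validation (one fold per participant), repeated with re-seeded
classifiers and averaged, and reports accuracy, precision, recall and F1
with MCI as the positive class.

Decision-level fusion across language tasks uses accuracy-weighted voting:
each task's per-class scores are weighted by that task's share of the
summed task accuracies, summed across tasks, and the argmax class wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import precision_recall_fscore_support
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "ClassifierSpec",
    "make_estimator",
    "EvaluationResult",
    "loocv_scores",
    "loocv_evaluate",
    "fuse_features",
    "compute_task_weights",
    "weighted_vote",
    "encode_labels",
    "POSITIVE_CLASS",
]

# Platt-scaled SVM probabilities are part of the decision-fusion contract;
# sklearn 1.9 deprecates the flag but keeps the behaviour.
warnings.filterwarnings(
    "ignore",
    message="The `probability` parameter was deprecated",
    category=FutureWarning,
)

POSITIVE_CLASS = "MCI"
NEGATIVE_CLASS = "HC"
CLASSIFIER_KINDS = ("DT", "RF", "SVM", "XGB")

MODALITY_ORDER = ("eeg", "speech", "digital")


@dataclass(frozen=True)
class ClassifierSpec:
    """One of the four classifier families with its fixed hyperparameters.

    Defaults: RF n_estimators=150; SVM kernel RBF; XGB gamma=0, eta=0.3,
    n_estimators=120.  ``seed`` controls any internal randomness.
    """

    kind: str = "SVM"
    seed: int = 0
    rf_n_estimators: int = 150
    svm_kernel: str = "rbf"
    xgb_gamma: float = 0.0
    xgb_eta: float = 0.3
    xgb_n_estimators: int = 120

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"kind must be one of {CLASSIFIER_KINDS}, got {self.kind!r}")

    def reseed(self, seed: int) -> "ClassifierSpec":
        return ClassifierSpec(
            kind=self.kind,
            seed=int(seed),
            rf_n_estimators=self.rf_n_estimators,
            svm_kernel=self.svm_kernel,
            xgb_gamma=self.xgb_gamma,
            xgb_eta=self.xgb_eta,
            xgb_n_estimators=self.xgb_n_estimators,
        )


def make_estimator(spec: ClassifierSpec, probability: bool = True):
    """Instantiate the scikit-learn / XGBoost estimator for a spec.

    The SVM is wrapped with training-fold standardization (RBF kernels are
    scale-sensitive); with ``probability=True`` it emits Platt-scaled
    probabilities, otherwise decision values only (faster).
    """
    if spec.kind == "DT":
        return DecisionTreeClassifier(random_state=spec.seed)
    if spec.kind == "RF":
        return RandomForestClassifier(
            n_estimators=spec.rf_n_estimators, random_state=spec.seed
        )
    if spec.kind == "SVM":
        svc = SVC(
            kernel=spec.svm_kernel, probability=probability, random_state=spec.seed
        )
        return Pipeline([("scale", StandardScaler()), ("svm", svc)])
    if spec.kind == "XGB":
        from xgboost import XGBClassifier

        return XGBClassifier(
            gamma=spec.xgb_gamma,
            learning_rate=spec.xgb_eta,
            n_estimators=spec.xgb_n_estimators,
            random_state=spec.seed,
            eval_metric="logloss",
            verbosity=0,
        )
    raise ValueError(spec.kind)  # pragma: no cover


def encode_labels(y) -> np.ndarray:
    """Map group labels to {0, 1} with MCI = 1 (the positive class)."""
    y = np.asarray(y)
    if y.dtype.kind in "iub":
        return y.astype(int)
    if y.dtype.kind == "f":
        return y.astype(int)
    known = {POSITIVE_CLASS, NEGATIVE_CLASS}
    bad = set(np.unique(y)) - known
    if bad:
        raise ValueError(f"unknown labels {sorted(bad)}; expected {sorted(known)}")
    return (y == POSITIVE_CLASS).astype(int)


# ---------------------------------------------------------------------------
# Leave-one-out evaluation


def loocv_scores(
    X, y, spec: ClassifierSpec, probability: bool = True
) -> pd.DataFrame:
    """Leave-one-out class scores: one row per sample, columns HC/MCI/label.

    Each sample is predicted by a model trained on all other samples.
    Scores are class probabilities for classifiers that provide them and
    Platt-scaled probabilities for the SVM; they sum to 1 per row.
    """
    X = np.asarray(X, dtype=float)
    yb = encode_labels(y)
    n = len(yb)
    if n < 4:
        raise ValueError(f"need n >= 4 samples for LOOCV, got {n}")
    if len(np.unique(yb)) < 2:
        raise ValueError("need both classes present")
    index = y.index if isinstance(y, pd.Series) else pd.RangeIndex(n)

    proba = np.zeros((n, 2))
    labels = np.zeros(n, dtype=int)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        if len(np.unique(yb[mask])) < 2:
            mask[i] = True
            raise ValueError("a training fold lost a class; need >= 2 per class")
        est = make_estimator(spec, probability=probability)
        est.fit(X[mask], yb[mask])
        xi = X[i : i + 1]
        if probability:
            p = est.predict_proba(xi)[0]
            classes = list(est.classes_) if hasattr(est, "classes_") else [0, 1]
            proba[i, 0] = p[classes.index(0)]
            proba[i, 1] = p[classes.index(1)]
            labels[i] = int(proba[i, 1] >= proba[i, 0])
        else:
            labels[i] = int(est.predict(xi)[0])
            proba[i, labels[i]] = 1.0
        mask[i] = True
    return pd.DataFrame(
        {"HC": proba[:, 0], "MCI": proba[:, 1], "label": labels}, index=index
    )


def _metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    acc = float((y_true == y_pred).mean())
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, pos_label=1, average="binary", zero_division=0.0
    )
    return {"accuracy": acc, "precision": float(prec), "recall": float(rec), "f1": float(f1)}


@dataclass
class EvaluationResult:
    """Repeated-LOOCV metrics: per-repeat values and their means."""

    classifier: str
    repeats: int
    per_repeat: pd.DataFrame = field(repr=False)  # rows = repeats, 4 metric columns
    scores: pd.DataFrame | None = field(default=None, repr=False)  # last repeat's LOOCV scores

    @property
    def accuracy(self) -> float:
        return float(self.per_repeat["accuracy"].mean())

    @property
    def precision(self) -> float:
        return float(self.per_repeat["precision"].mean())

    @property
    def recall(self) -> float:
        return float(self.per_repeat["recall"].mean())

    @property
    def f1(self) -> float:
        return float(self.per_repeat["f1"].mean())

    def summary(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


def loocv_evaluate(
    X, y, spec: ClassifierSpec, repeats: int = 1, probability: bool = False
) -> EvaluationResult:
    """Repeated leave-one-out evaluation.

    LOOCV has no fold randomness, so repetition re-draws the classifier
    seed (repeat r uses ``spec.seed + r``); stochastic learners (RF, XGB,
    SVM Platt scaling) vary across repeats, a deterministic tree does not.
    Metrics are computed per repeat and averaged.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    yb = encode_labels(y)
    rows = []
    scores = None
    for r in range(repeats):
        scores = loocv_scores(X, y, spec.reseed(spec.seed + r), probability=probability)
        rows.append(_metrics(yb, scores["label"].to_numpy()))
    return EvaluationResult(
        classifier=spec.kind,
        repeats=repeats,
        per_repeat=pd.DataFrame(rows),
        scores=scores,
    )


# ---------------------------------------------------------------------------
# Fusion


def fuse_features(
    tables: dict[str, pd.DataFrame],
    subsets: dict[str, list[str]] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Column-wise fusion of per-modality feature tables.

    ``tables`` maps modality -> DataFrame (rows = participants); columns
    are restricted to ``subsets[modality]`` when given, then concatenated
    in the fixed order EEG, speech, digital.  Participants missing any
    included modality are excluded and returned in the second element.
    """
    order = [m for m in MODALITY_ORDER if m in tables] + [
        m for m in tables if m not in MODALITY_ORDER
    ]
    parts = []
    common: set | None = None
    for m in order:
        t = tables[m]
        if subsets is not None and m in subsets:
            missing = [c for c in subsets[m] if c not in t.columns]
            if missing:
                raise KeyError(f"modality {m!r}: unknown features {missing}")
            t = t[list(subsets[m])]
        if t.shape[1] == 0:
            continue
        parts.append(t)
        common = set(t.index) if common is None else common & set(t.index)
    if not parts:
        raise ValueError("no features to fuse")
    all_ids = set().union(*(set(t.index) for t in parts))
    excluded = sorted(all_ids - (common or set()))
    keep = [i for i in parts[0].index if i in (common or set())]
    fused = pd.concat([t.loc[keep] for t in parts], axis=1)
    return fused, excluded


def compute_task_weights(accuracies: dict[str, float]) -> dict[str, float]:
    """Decision weights w_t = Acc_t / sum_t Acc_t (nonnegative, sum to 1)."""
    if any(a < 0 for a in accuracies.values()):
        raise ValueError("accuracies must be nonnegative")
    total = sum(accuracies.values())
    if total <= 0:
        raise ValueError("all task accuracies are zero; weights undefined")
    return {t: a / total for t, a in accuracies.items()}


def weighted_vote(
    decisions: dict[str, pd.DataFrame],
    weights: dict[str, float],
    tie_label: str = NEGATIVE_CLASS,
) -> tuple[pd.Series, list[str]]:
    """Accuracy-weighted decision fusion across tasks.

    ``decisions`` maps task -> DataFrame with columns "MCI" and "HC"
    (per-participant class scores).  The fused score of class c is
    sum_t w_t * score_t(c); the larger class wins, exact ties go to the
    screening-conservative ``tie_label`` (HC).  Participants without a
    decision in every task are excluded and listed in the second element.
    The vote is invariant to rescaling all weights by a positive constant.
    """
    if set(decisions) != set(weights):
        raise ValueError("decisions and weights must cover the same tasks")
    if any(w < 0 for w in weights.values()):
        raise ValueError("weights must be nonnegative")
    if sum(weights.values()) <= 0:
        raise ValueError("weights must not all be zero")

    common: set | None = None
    union: set = set()
    for t, df in decisions.items():
        union |= set(df.index)
        common = set(df.index) if common is None else common & set(df.index)
    excluded = sorted(union - (common or set()))
    first = next(iter(decisions.values()))
    ids = [i for i in first.index if i in (common or set())]

    total = pd.DataFrame(0.0, index=ids, columns=[POSITIVE_CLASS, NEGATIVE_CLASS])
    for t, df in decisions.items():
        total[POSITIVE_CLASS] += weights[t] * df.loc[ids, POSITIVE_CLASS]
        total[NEGATIVE_CLASS] += weights[t] * df.loc[ids, NEGATIVE_CLASS]
    labels = pd.Series(
        np.where(total[POSITIVE_CLASS] > total[NEGATIVE_CLASS], POSITIVE_CLASS, NEGATIVE_CLASS),
        index=ids,
        name="label",
    )
    ties = total[POSITIVE_CLASS] == total[NEGATIVE_CLASS]
    labels[ties] = tie_label
    return labels, excluded
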