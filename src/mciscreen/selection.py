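"""Frequency-band combination selection and RFECV feature-subset selection.

Band selection searches all 31 non-empty subsets of the five classical
EEG bands for the one whose band-restricted features maximize repeated
leave-one-out classification accuracy; feature selection then applies
recursive feature elimination with cross-validated scoring (RFECV) within
each modality to keep the best-performing subset.

Two leakage policies are offered.  ``global`` mode selects bands/features
once on the full cohort and then reports LOOCV on the same data, which
mirrors how selection protocols are commonly reported; ``nested`` mode
re-runs selection inside each training fold and gives unbiased estimates.
The evaluation report always states which mode ran.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.feature_selection import RFECV
from sklearn.model_selection import StratifiedKFold

from .classify import ClassifierSpec, encode_labels, loocv_evaluate, make_estimator
from .eeg import BAND_ORDER

__all__ = [
    "BandCombination",
    "BandSelectionResult",
    "FeatureSubset",
    "enumerate_band_combinations",
    "band_of_feature",
    "select_bands",
    "rfecv_select",
]

BandCombination = tuple[str, ...]

TIE_BREAK = "fewest bands, then lowest-frequency-first lexicographic"

#: Estimators exposing the importance/coefficient signal RFECV needs.
RFECV_USABLE = ("DT", "RF", "XGB")


def enumerate_band_combinations(
    bands: tuple[str, ...] = BAND_ORDER,
) -> list[BandCombination]:
    """All 31 non-empty band subsets, ordered by size then band order."""
    combos: list[BandCombination] = []
    for k in range(1, len(bands) + 1):
        combos.extend(combinations(bands, k))
    return combos


def band_of_feature(feature_id: str) -> str:
    """The band a feature belongs to: the suffix after the last dot."""
    band = feature_id.rsplit(".", 1)[-1]
    if band not in BAND_ORDER:
        raise ValueError(f"feature {feature_id!r} has no recognizable band suffix")
    return band


@dataclass
class BandSelectionResult:
    """Per-combination accuracies and the argmax combination."""

    accuracies: dict[BandCombination, float]
    chosen: BandCombination
    classifier: str
    repeats: int
    tie_break: str = TIE_BREAK

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"bands": "+".join(c), "n_bands": len(c), "mean_cv_accuracy": a}
            for c, a in self.accuracies.items()
        ]
        return pd.DataFrame(rows)


def select_bands(
    eeg_features: pd.DataFrame,
    y,
    clf: ClassifierSpec | None = None,
    repeats: int = 50,
    candidates: list[BandCombination] | None = None,
) -> BandSelectionResult:
    """Choose the band combination maximizing repeated-LOOCV accuracy.

    ``eeg_features`` columns must carry their band as a ``.<band>`` suffix
    (the extractor's naming).  Each candidate combination is scored by
    repeated leave-one-out accuracy on its columns only; since LOOCV has
    no fold randomness, repeats re-seed the classifier.  Ties are broken
    toward fewer bands, then lower frequencies, and the rule is recorded
    in the result.
    """
    clf = clf or ClassifierSpec("SVM")
    yb = encode_labels(y)
    if len(np.unique(yb)) < 2:
        raise ValueError("need both classes to select bands")
    by_band: dict[str, list[str]] = {b: [] for b in BAND_ORDER}
    for c in eeg_features.columns:
        by_band[band_of_feature(c)].append(c)
    present = [b for b in BAND_ORDER if by_band[b]]
    if candidates is None:
        candidates = enumerate_band_combinations(tuple(present))

    accuracies: dict[BandCombination, float] = {}
    for combo in candidates:
        cols = [c for b in combo for c in by_band[b]]
        if not cols:
            raise ValueError(f"no features for combination {combo}")
        res = loocv_evaluate(eeg_features[cols], y, clf, repeats=repeats)
        accuracies[combo] = res.accuracy

    def sort_key(combo: BandCombination):
        return (-accuracies[combo], len(combo), [BAND_ORDER.index(b) for b in combo])

    chosen = min(accuracies, key=sort_key)
    return BandSelectionResult(
        accuracies=accuracies, chosen=chosen, classifier=clf.kind, repeats=repeats
    )


@dataclass
class FeatureSubset:
    """RFECV outcome: retained features plus the elimination audit trail."""

    features: list[str]
    ranking: dict[str, int] = field(repr=False)
    cv_scores: list[float] = field(repr=False)  # mean CV score vs. #features (1..p)
    estimator: str = "RF"

    def __len__(self) -> int:
        return len(self.features)


def rfecv_select(
    X: pd.DataFrame,
    y,
    estimator: ClassifierSpec | None = None,
    cv: int = 5,
    scoring: str = "accuracy",
    step: int = 1,
    min_features: int = 1,
) -> FeatureSubset:
    """Recursive feature elimination with cross-validated scoring.

    Features are eliminated ``step`` at a time by estimator importance;
    the subset size maximizing mean stratified ``cv``-fold score is kept.
    The estimator must expose ``feature_importances_`` or ``coef_`` (DT,
    RF, XGB); the RBF SVM does not and is rejected with a pointer to the
    usable kinds.
    """
    estimator = estimator or ClassifierSpec("RF")
    if estimator.kind not in RFECV_USABLE:
        raise ValueError(
            f"estimator {estimator.kind!r} exposes no feature-importance signal; "
            f"use one of {RFECV_USABLE}"
        )
    if X.shape[1] == 0:
        raise ValueError("no features to select from")
    yb = encode_labels(y)
    n_min_class = int(np.bincount(yb).min())
    if cv > n_min_class:
        raise ValueError(
            f"cv={cv} folds need at least {cv} samples per class; "
            f"smallest class has {n_min_class}"
        )
    if X.shape[1] == 1:
        return FeatureSubset(
            features=list(X.columns),
            ranking={X.columns[0]: 1},
            cv_scores=[float("nan")],
            estimator=estimator.kind,
        )
    splitter = StratifiedKFold(n_splits=cv, shuffle=True, random_state=estimator.seed)
    selector = RFECV(
        make_estimator(estimator, probability=False),
        step=step,
        cv=splitter,
        scoring=scoring,
        min_features_to_select=min_features,
    )
    selector.fit(X.to_numpy(dtype=float), yb)
    features = [c for c, keep in zip(X.columns, selector.support_) if keep]
    ranking = dict(zip(X.columns, (int(r) for r in selector.ranking_)))
    scores = [float(s) for s in selector.cv_results_["mean_test_score"]]
    return FeatureSubset(
        features=features, ranking=ranking, cv_scores=scores, estimator=estimator.kind
    )
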