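"""Classification benchmark: %total vs %parent as feature sets.

Each sample becomes one observation whose features are the node-level
proportions of one quantification, and a random forest (500 trees) is
scored by balanced accuracy under repeated stratified 5-fold
cross-validation (20 repetitions), fold-averaged within each repetition.
Comparing the per-repetition distributions across feature sets shows
whether parent-relative proportions carry predictive signal that
sample-relative proportions miss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold

from ._random import rng_for
from .io import SampleMetadata
from .proportions import ProportionMatrix

FEATURE_SETS = ("pct_total", "pct_parent_hclust", "pct_parent_hopach")


@dataclass
class ClassificationResult:
    """Cross-validated balanced accuracies for one feature set."""

    feature_set: str
    balanced_accuracy_per_repetition: np.ndarray  # (repetitions,)
    rank: int | None = None

    @property
    def mean(self) -> float:
        return float(np.mean(self.balanced_accuracy_per_repetition))

    @property
    def sd(self) -> float:
        return float(np.std(self.balanced_accuracy_per_repetition, ddof=1))


def balanced_accuracy(confusion: np.ndarray) -> float:
    """(sensitivity + specificity) / 2 from a 2x2 confusion table.

    Rows are true classes, columns predicted classes.
    """
    confusion = np.asarray(confusion, dtype=float)
    if confusion.shape != (2, 2):
        raise ValueError("confusion must be 2x2")
    row_sums = confusion.sum(axis=1)
    if (row_sums == 0).any():
        raise ValueError("both true classes must have at least one sample")
    return float((confusion[0, 0] / row_sums[0] + confusion[1, 1] / row_sums[1]) / 2)


def features_from_proportions(
    props: ProportionMatrix, meta: SampleMetadata, kind: str
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Samples x nodes feature matrix plus 0/1 labels for one quantification.

    The root row is dropped (constant by construction).  %parent entries
    can be missing (zero-count parents); imputation is left to the
    cross-validation loop so that only training-fold information is used.
    """
    ref, _ = meta.require_two_levels()
    mat = {"total": props.pct_total, "parent": props.pct_parent}[kind]
    mat = mat.drop(index=props.tree.root)
    samples = list(mat.columns)
    X = mat.to_numpy(dtype=float).T  # samples x nodes
    y = np.array([0 if meta.condition_of(s) == ref else 1 for s in samples])
    return X, y, list(mat.index)


def _make_forest(n_trees: int, n_features: int, seed: int) -> LGBMClassifier:
    """Random forest (bagging + per-tree sqrt-feature subsampling).

    LightGBM's rf boosting mode is used as the forest engine: identical
    model class to the classical random forest (bootstrap-aggregated,
    feature-subsampled decision trees) with far lower per-tree overhead on
    the small sample sizes typical of patient-level cytometry cohorts.
    """
    return LGBMClassifier(
        boosting_type="rf",
        n_estimators=n_trees,
        subsample=0.632,           # bootstrap-sized bagging fraction
        subsample_freq=1,
        # sqrt-feature sampling per split, the classical forest convention
        colsample_bynode=max(1.0 / n_features, n_features ** -0.5),
        min_child_samples=1,       # cohorts are tiny; let trees grow
        min_data_in_bin=1,
        n_jobs=1,
        random_state=int(seed) % (2**31 - 1),
        verbose=-1,
    )


def crossval_balanced_accuracy(
    features: np.ndarray,
    labels: np.ndarray,
    feature_set: str = "pct_total",
    folds: int = 5,
    repetitions: int = 20,
    n_trees: int = 500,
    seed: int = 0,
) -> ClassificationResult:
    """Repeated stratified k-fold CV of a random forest, balanced accuracy.

    Per repetition, fold assignment is re-randomized (seeded); the
    repetition's score is the mean balanced accuracy over its held-out
    folds.  Missing feature values are imputed with the training fold's
    per-feature median (falling back to 0 if a feature is entirely missing
    in the training fold).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("labels must be binary")
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples; use at most {counts.min()} folds")
    rng = rng_for(seed, "cv")
    rep_scores = np.empty(repetitions)
    import warnings

    warnings.filterwarnings("ignore", message="X does not have valid feature names")
    for rep in range(repetitions):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rep_seed)
        fold_scores = []
        for fold_i, (tr, te) in enumerate(skf.split(X, y)):
            Xtr, Xte = X[tr].copy(), X[te].copy()
            med = np.nanmedian(Xtr, axis=0)
            med = np.where(np.isfinite(med), med, 0.0)
            for mat in (Xtr, Xte):
                nan_r, nan_c = np.where(~np.isfinite(mat))
                mat[nan_r, nan_c] = med[nan_c]
            clf = _make_forest(n_trees, Xtr.shape[1], rep_seed + fold_i)
            clf.fit(Xtr, y[tr])
            fold_scores.append(balanced_accuracy_score(y[te], clf.predict(Xte)))
        rep_scores[rep] = float(np.mean(fold_scores))
    return ClassificationResult(
        feature_set=feature_set, balanced_accuracy_per_repetition=rep_scores)


def rank_feature_sets(results: list[ClassificationResult]) -> list[ClassificationResult]:
    """Rank 1 = best: highest mean, ties by lowest sd, then feature-set order."""
    if len(results) < 2:
        raise ValueError("need at least two feature sets to rank")

    def enum_pos(r):
        return FEATURE_SETS.index(r.feature_set) if r.feature_set in FEATURE_SETS else len(FEATURE_SETS)

    ordered = sorted(results, key=lambda r: (-r.mean, r.sd, enum_pos(r)))
    for i, r in enumerate(ordered, start=1):
        r.rank = i
    return ordered


def results_table(results: list[ClassificationResult]) -> pd.DataFrame:
    """Long-format per-repetition table plus summary columns."""
    rows = []
    for r in results:
        for rep, ba in enumerate(r.balanced_accuracy_per_repetition):
            rows.append({
                "feature_set": r.feature_set,
                "repetition": rep,
                "balanced_accuracy": ba,
                "mean": r.mean,
                "sd": r.sd,
                "rank": r.rank,
            })
    return pd.DataFrame(rows)
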