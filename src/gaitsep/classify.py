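"""Linear soft-margin SVM evaluation with ten-fold cross-validation.

The classifier is a linear-kernel soft-margin SVM with penalty parameter
c = 1 by default. Accuracy-vs-number-of-PCs curves evaluate every prefix of
a PC ranking with a fold assignment shared across prefix sizes, so curves
for the two rankings are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .pca import CovariancePCA, PCRanking, rank_by_variance


@dataclass
class CVResult:
    """One cross-validated evaluation at a fixed number of PCs."""

    n_components: int
    mode: str
    fold_accuracies: np.ndarray
    mean_accuracy: float
    seed: int | None
    c: float


@dataclass
class AccuracyCurve:
    """Mean CV accuracy for every prefix size k = 1..K of a ranking."""

    mode: str
    mean_accuracy: np.ndarray
    fold_accuracies: np.ndarray  # (K, n_folds)
    cumulative_variance: np.ndarray
    min_abs_key: np.ndarray
    seed: int | None
    c: float
    extras: dict = field(default_factory=dict)

    @property
    def argmax_k(self) -> int:
        """Smallest k attaining the maximum mean accuracy (1-based)."""
        return int(np.argmax(self.mean_accuracy)) + 1

    @property
    def max_accuracy(self) -> float:
        return float(self.mean_accuracy.max())


def make_folds(
    n: int, n_folds: int = 10, seed: int | None = None, labels=None
) -> np.ndarray:
    """Random partition into folds of size floor(n/folds) or ceil(n/folds).

    Returns a fold id (0..n_folds-1) per subject; deterministic under seed.
    With ``labels`` the partition is stratified by class.
    """
    if not 2 <= n_folds <= n:
        raise ValueError(f"need 2 <= n_folds <= n, got folds={n_folds}, n={n}")
    rng = np.random.default_rng(seed)
    fold_ids = np.empty(n, dtype=int)

    def assign(indices: np.ndarray, start_fold: int) -> None:
        perm = rng.permutation(indices)
        for i, idx in enumerate(perm):
            fold_ids[idx] = (start_fold + i) % n_folds

    if labels is None:
        assign(np.arange(n), 0)
    else:
        labels = np.asarray(labels)
        start = 0
        for lab in np.unique(labels):
            idx = np.nonzero(labels == lab)[0]
            assign(idx, start)
            start += idx.size
    return fold_ids


def crossval_accuracy(
    X,
    y,
    fold_ids: np.ndarray | None = None,
    n_folds: int = 10,
    c: float = 1.0,
    seed: int | None = None,
    n_repeats: int = 1,
    mode: str = "",
) -> CVResult:
    """Mean of per-fold accuracies of a linear soft-margin SVM.

    With ``n_repeats`` > 1 the whole k-fold procedure is repeated with
    re-randomized folds (seeded ``seed + r``) and the mean of means is
    reported; per-fold accuracies are then those of all repetitions.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y)
    if np.unique(y).size != 2:
        raise ValueError("exactly two classes required")
    accs = []
    for r in range(n_repeats):
        if fold_ids is not None and r == 0:
            ids = np.asarray(fold_ids)
        else:
            s = None if seed is None else seed + r
            ids = make_folds(len(y), n_folds, seed=s)
        for f in np.unique(ids):
            train, test = ids != f, ids == f
            if np.unique(y[train]).size < 2:
                raise ValueError(f"training split for fold {f} has one class")
            clf = SVC(kernel="linear", C=c)
            clf.fit(X[train], y[train])
            accs.append(float(np.mean(clf.predict(X[test]) == y[test])))
    accs = np.array(accs)
    return CVResult(
        n_components=X.shape[1],
        mode=mode,
        fold_accuracies=accs,
        mean_accuracy=float(accs.mean()),
        seed=seed,
        c=c,
    )


def accuracy_curve(
    pca: CovariancePCA,
    ranking: PCRanking,
    y,
    n_folds: int = 10,
    c: float = 1.0,
    seed: int | None = None,
    max_k: int | None = None,
) -> AccuracyCurve:
    """CV accuracy at every prefix size of the ranking, shared folds across k."""
    y = np.asarray(y)
    K = len(ranking.order) if max_k is None else min(max_k, len(ranking.order))
    fold_ids = make_folds(len(y), n_folds, seed=seed)
    scores = pca.scores_[:, ranking.order]
    fold_acc = np.empty((K, n_folds))
    for k in range(1, K + 1):
        res = crossval_accuracy(scores[:, :k], y, fold_ids=fold_ids, c=c, seed=seed)
        fold_acc[k - 1] = res.fold_accuracies
    return AccuracyCurve(
        mode=ranking.mode,
        mean_accuracy=fold_acc.mean(axis=1),
        fold_accuracies=fold_acc,
        cumulative_variance=ranking.cumulative_variance[:K].copy(),
        min_abs_key=ranking.key_values[:K].copy(),
        seed=seed,
        c=c,
    )


def accuracy_curve_leakage_free(
    X,
    y,
    mode: str = "effect_size",
    n_folds: int = 10,
    c: float = 1.0,
    seed: int | None = None,
    max_k: int | None = None,
    correction: bool = True,
) -> AccuracyCurve:
    """Fold-internal variant: standardization, PCA and ranking are refitted on
    each training split and test subjects are projected through them.

    Methodologically safer than ranking on the full sample before CV (no
    information from test subjects enters the feature construction); the
    curve is indexed by prefix size of the *within-fold* ranking, capped at
    the smallest training-split rank.
    """
    from .effect_size import rank_by_effect_size  # local import: cycle-free

    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    fold_ids = make_folds(len(y), n_folds, seed=seed)
    folds = np.unique(fold_ids)
    per_fold = []
    for f in folds:
        train, test = fold_ids != f, fold_ids == f
        pca = CovariancePCA().fit(X[train])
        ranking = (
            rank_by_effect_size(pca, y[train], correction=correction)
            if mode == "effect_size"
            else rank_by_variance(pca)
        )
        per_fold.append((pca, ranking, train, test))
    K = min(len(r.order) for _, r, _, _ in per_fold)
    if max_k is not None:
        K = min(K, max_k)
    fold_acc = np.empty((K, len(folds)))
    for i, (pca, ranking, train, test) in enumerate(per_fold):
        train_scores = pca.scores_[:, ranking.order]
        test_scores = pca.transform(X[test])[:, ranking.order]
        for k in range(1, K + 1):
            clf = SVC(kernel="linear", C=c)
            clf.fit(train_scores[:, :k], y[train])
            fold_acc[k - 1, i] = float(
                np.mean(clf.predict(test_scores[:, :k]) == y[test])
            )
    return AccuracyCurve(
        mode=f"{mode}_fold_internal",
        mean_accuracy=fold_acc.mean(axis=1),
        fold_accuracies=fold_acc,
        cumulative_variance=np.full(K, np.nan),
        min_abs_key=np.full(K, np.nan),
        seed=seed,
        c=c,
    )


def select_optimal(
    curve: AccuracyCurve,
    ranking: PCRanking | None = None,
    g_threshold: float | None = None,
) -> dict:
    """Optimal prefix size under both selection rules.

    ``argmax``: smallest k maximizing mean accuracy. ``g_threshold`` (when a
    threshold and an effect-size ranking are given): largest prefix whose
    every PC has |g| strictly above the threshold.
    """
    if curve.mean_accuracy.size == 0:
        raise ValueError("empty curve")
    out = {
        "argmax": {
            "k": curve.argmax_k,
            "accuracy": curve.max_accuracy,
        }
    }
    if g_threshold is not None:
        if ranking is None or not ranking.mode.startswith("effect"):
            raise ValueError("g-threshold rule requires an effect-size ranking")
        k = int(np.sum(ranking.key_values > g_threshold))
        k = min(max(k, 1), len(curve.mean_accuracy))
        out["g_threshold"] = {
            "k": k,
            "accuracy": float(curve.mean_accuracy[k - 1]),
            "threshold": g_threshold,
        }
    return out
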