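"""Clinical decision-support layer: classifiers, CV evaluation, search.

Six classifier families are supported — linear and RBF support vector
machines, k-nearest neighbours, random forests, AdaBoost over decision
stumps, and a Parzen (kernel-density Bayes) classifier implemented here
from first principles.  Evaluation pools out-of-fold scores from
(stratified) k-fold or leave-one-out cross-validation, computes the
AUC by the Mann-Whitney statistic, and reports sensitivity/specificity
at the pooled-score Youden cut-off.  Feature selection is an exhaustive
search over every non-empty subset of the candidate oscillometry
parameters.

The search is run outside the cross-validation loop (the winning
subset is chosen on the same folds it is evaluated on), which carries
an optimistic bias on small samples; see the methods note.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import ClassBalanceError, CombinatorialLimitError
from .roc import CutoffResult, RocCurve, optimal_cutoff, roc_auc

CLASSIFIER_NAMES = ("svm_linear", "svm_rbf", "knn", "random_forest",
                    "adaboost_tree", "parzen")

MAX_CANDIDATES = 20


@dataclass(frozen=True)
class ClassifierSpec:
    """A named classifier family with optional hyperparameter overrides."""

    name: str
    hyperparameters: Dict = field(default_factory=dict)
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_NAMES:
            raise ValueError(f"unknown classifier {self.name!r}")


@dataclass(frozen=True)
class CvSpec:
    """Cross-validation scheme.  LOOCV is the k = n limit of k-fold."""

    scheme: str = "kfold"  # "kfold" | "loocv"
    k: int = 10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in ("kfold", "loocv"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.scheme == "kfold" and self.k < 2:
            raise ValueError("kfold requires k >= 2")


@dataclass(frozen=True)
class EvaluationResult:
    auc: float
    se: float  # %
    sp: float  # %
    cutoff: CutoffResult
    curve: RocCurve
    oof_scores: np.ndarray
    labels: np.ndarray
    features: Tuple[str, ...]
    classifier: str
    n_folds: int


@dataclass(frozen=True)
class SearchResult:
    best: EvaluationResult
    n_subsets: int
    all_aucs: Dict[Tuple[str, ...], float]


class ParzenClassifier:
    """Kernel-density Bayes classifier with a product Gaussian kernel.

    Class-conditional densities are estimated per class by averaging
    product Gaussian kernels centred on the training points; the score
    of a test point is the posterior probability of the positive class
    (kernel density times the class prior, normalized).  The default
    per-feature bandwidth follows Silverman's rule on the pooled
    training sample,

        h_j = sigma_j * (4 / ((d + 2) n)) ** (1 / (d + 4)).
    """

    def __init__(self, bandwidth: Optional[float] = None):
        self.bandwidth = bandwidth

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ParzenClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ClassBalanceError("both classes required in training data")
        n, d = X.shape
        if self.bandwidth is not None:
            self.h_ = np.full(d, float(self.bandwidth))
        else:
            sigma = X.std(axis=0, ddof=1)
            sigma[sigma == 0] = 1.0
            self.h_ = sigma * (4.0 / ((d + 2.0) * n)) ** (1.0 / (d + 4.0))
        self.X_by_class_ = {c: X[y == c] for c in self.classes_}
        self.prior_ = {c: float(np.mean(y == c)) for c in self.classes_}
        return self

    def _density(self, Xc: np.ndarray, X: np.ndarray) -> np.ndarray:
        # mean over training kernels of the product Gaussian
        diff = (X[:, None, :] - Xc[None, :, :]) / self.h_[None, None, :]
        log_k = -0.5 * np.sum(diff * diff, axis=2)
        norm = np.prod(self.h_) * (2.0 * np.pi) ** (X.shape[1] / 2.0)
        return np.exp(log_k).mean(axis=1) / norm

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        dens = np.column_stack([
            self.prior_[c] * self._density(self.X_by_class_[c], X)
            for c in self.classes_
        ])
        total = dens.sum(axis=1, keepdims=True)
        # equidistant-from-everything points get the prior
        flat = total[:, 0] == 0
        out = np.where(total > 0, dens / np.where(total == 0, 1.0, total), 0.0)
        if np.any(flat):
            out[flat] = [self.prior_[c] for c in self.classes_]
        return out


def build_classifier(spec: ClassifierSpec, seed: int = 0, n_features: int = 1):
    """Instantiate the sklearn (or Parzen) estimator behind a spec."""
    hp = dict(spec.hyperparameters)
    if spec.name == "svm_linear":
        return SVC(kernel="linear", C=hp.pop("C", 1.0), **hp)
    if spec.name == "svm_rbf":
        return SVC(kernel="rbf", C=hp.pop("C", 1.0),
                   gamma=hp.pop("gamma", "scale"), **hp)
    if spec.name == "knn":
        return KNeighborsClassifier(n_neighbors=hp.pop("n_neighbors", 5), **hp)
    if spec.name == "random_forest":
        return RandomForestClassifier(n_estimators=hp.pop("n_estimators", 500),
                                      random_state=seed, **hp)
    if spec.name == "adaboost_tree":
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=hp.pop("max_depth", 1)),
            n_estimators=hp.pop("n_estimators", 100), random_state=seed, **hp)
    return ParzenClassifier(bandwidth=hp.pop("bandwidth", None))


def _score_estimator(est, X: np.ndarray) -> np.ndarray:
    if isinstance(est, ParzenClassifier):
        return est.predict_proba(X)[:, -1]
    if hasattr(est, "decision_function"):
        return np.asarray(est.decision_function(X), dtype=float)
    return np.asarray(est.predict_proba(X)[:, 1], dtype=float)


def _folds(cv: CvSpec, y: np.ndarray) -> List[Tuple[np.ndarray, np.ndarray]]:
    n = y.size
    if cv.scheme == "loocv":
        idx = np.arange(n)
        return [(np.delete(idx, i), np.array([i])) for i in range(n)]
    from sklearn.model_selection import KFold, StratifiedKFold

    if cv.stratified:
        counts = np.bincount(y)
        if np.any(counts[counts > 0] < cv.k):
            raise ValueError("stratified k-fold requires >= k samples per class")
        splitter = StratifiedKFold(n_splits=cv.k, shuffle=True, random_state=cv.seed)
    else:
        shuffle = cv.k < n
        splitter = KFold(n_splits=cv.k, shuffle=shuffle,
                         random_state=cv.seed if shuffle else None)
    return list(splitter.split(np.zeros((n, 1)), y))


def cross_validate(spec: ClassifierSpec, table: pd.DataFrame,
                   features: Sequence[str], labels: Sequence[int],
                   cv: Optional[CvSpec] = None) -> EvaluationResult:
    """Pooled out-of-fold evaluation of one classifier/feature subset.

    Standardization parameters (mean/sd) are fit on the training folds
    only.  Folds whose training part lacks a class are skipped with a
    warning (cannot happen under stratification or LOOCV with >= 2 per
    class).
    """
    cv = cv or CvSpec()
    features = tuple(features)
    X = table.loc[:, list(features)].to_numpy(dtype=float)
    y = np.asarray(labels).astype(int)
    if np.unique(y).size < 2:
        raise ClassBalanceError("both classes must be present")

    oof = np.full(y.size, np.nan)
    n_used = 0
    for train, test in _folds(cv, y):
        y_tr = y[train]
        if np.unique(y_tr).size < 2:
            warnings.warn("skipping fold with a single training class")
            continue
        X_tr, X_te = X[train], X[test]
        if spec.standardize:
            mu = X_tr.mean(axis=0)
            sd = X_tr.std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            X_tr = (X_tr - mu) / sd
            X_te = (X_te - mu) / sd
        est = build_classifier(spec, seed=cv.seed, n_features=X.shape[1])
        est.fit(X_tr, y_tr)
        oof[test] = _score_estimator(est, X_te)
        n_used += 1

    mask = ~np.isnan(oof)
    curve = roc_auc(oof[mask], y[mask])
    cut = optimal_cutoff(curve)
    return EvaluationResult(auc=curve.auc, se=cut.se, sp=cut.sp, cutoff=cut,
                            curve=curve, oof_scores=oof[mask], labels=y[mask],
                            features=features, classifier=spec.name,
                            n_folds=n_used)


def exhaustive_search(spec: ClassifierSpec, table: pd.DataFrame,
                      candidate_features: Sequence[str],
                      labels: Sequence[int],
                      cv: Optional[CvSpec] = None) -> SearchResult:
    """Evaluate every non-empty feature subset; return the AUC argmax.

    Ties are broken toward the smaller subset, then toward the
    lexicographically first subset in the candidate ordering.
    """
    candidates = list(candidate_features)
    if len(candidates) > MAX_CANDIDATES:
        raise CombinatorialLimitError(
            f"{len(candidates)} candidates exceed the {MAX_CANDIDATES}-feature limit"
        )
    order = {f: i for i, f in enumerate(candidates)}
    best: Optional[EvaluationResult] = None
    best_key: Optional[tuple] = None
    all_aucs: Dict[Tuple[str, ...], float] = {}
    n_subsets = 0
    for size in range(1, len(candidates) + 1):
        for subset in itertools.combinations(candidates, size):
            n_subsets += 1
            res = cross_validate(spec, table, subset, labels, cv)
            all_aucs[subset] = res.auc
            key = (-res.auc, len(subset), tuple(order[f] for f in subset))
            if best_key is None or key < best_key:
                best, best_key = res, key
    assert best is not None
    return SearchResult(best=best, n_subsets=n_subsets, all_aucs=all_aucs)
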