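"""SVM-RFE classifiers over molecular feature sets, with permutation nulls.

Candidate molecule sets (structurally dominant nodes, differential proteins,
differential genes, or their union) are evaluated as classifiers: an
RBF-kernel support vector machine is tuned by cross-validated grid search,
features are pruned by recursive feature elimination, and the surviving
signature is scored on independent cohorts (accuracy, sensitivity,
specificity, AUC) and against a null of random gene sets of the same size.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import LeaveOneOut, StratifiedKFold, cross_val_score
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class FeatureSet:
    """A named, ordered candidate molecule list (SDN / DEP / DEG / CF)."""

    name: str
    genes: list[str]

    @staticmethod
    def union(name: str, *sets: "FeatureSet") -> "FeatureSet":
        """Comprehensive features: ordered union of the source sets."""
        seen, merged = set(), []
        for fs in sets:
            for g in fs.genes:
                if g not in seen:
                    seen.add(g)
                    merged.append(g)
        return FeatureSet(name=name, genes=merged)


def rank_top_features(table, k: int, name: str = "features") -> FeatureSet:
    """Top-k molecules by each source's native significance ordering.

    Differential-gene tables rank by ascending p (then descending \\|t\\|),
    protein fold tables by descending \\|log2 fold\\|, SDN rankings by
    descending composite score.  Ties break lexicographically by symbol.
    Asks beyond the available rows truncate with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    from .factor import SDNRanking

    if isinstance(table, SDNRanking):
        df = table.table
        order = df.sort_values(["sdn_score", "node"], ascending=[False, True],
                               kind="mergesort").index
    elif "p" in table.columns:
        df = table[table["selected"]] if "selected" in table else table
        aux = pd.DataFrame({"p": df["p"], "abs_t": -df["t"].abs(), "sym": df.index})
        order = aux.sort_values(["p", "abs_t", "sym"], kind="mergesort").index
    elif "fold" in table.columns:
        df = table[table["selected"]] if "selected" in table else table
        aux = pd.DataFrame({"mag": -np.abs(np.log2(df["fold"])), "sym": df.index})
        order = aux.sort_values(["mag", "sym"], kind="mergesort").index
    else:
        raise TypeError("unrecognized ranking table")
    if k > len(order):
        warnings.warn(f"requested top {k} but only {len(order)} available; truncating")
        k = len(order)
    return FeatureSet(name=name, genes=list(order[:k]))


def _rbf_sq_dists(X: np.ndarray) -> np.ndarray:
    """Pairwise squared Euclidean distances, (n, n)."""
    sq = np.sum(X**2, axis=1)
    d = sq[:, None] + sq[None, :] - 2.0 * X @ X.T
    return np.clip(d, 0.0, None)


class SVMRFEClassifier(BaseEstimator, ClassifierMixin):
    """RBF-kernel SVM with recursive feature elimination.

    Fitting proceeds in three stages: (1) the regularization parameter C and
    kernel width gamma are tuned by cross-validated grid search on the full
    feature set (leave-one-out by default); (2) features are eliminated one
    at a time, ranking by the change in the SVM dual objective when a
    feature is removed from the kernel (the kernel-space generalization of
    the weight-magnitude rule); the cross-validated accuracy of every
    intermediate subset is recorded; (3) the signature is the subset with
    the best cross-validated accuracy, ties resolved toward fewer features,
    and the final machine is refit on it.

    Parameters
    ----------
    C_grid, gamma_grid : sequences
        Hyperparameter candidates.  ``gamma_grid=None`` uses 5 log-spaced
        values between 1/(50 d) and 1/d for d input features.
    tuning_cv : "loo" or int
        Scheme for the hyperparameter search.
    rfe_cv : int
        Fold count for the per-subset accuracy path.
    criterion : {"kernel", "linear"}
        RFE ranking rule: kernel dual-objective change, or squared weight
        of a linear SVM fit alongside.
    random_state : int
        Seeds the stratified folds.

    Attributes
    ----------
    C_, gamma_ : tuned hyperparameters
    signature_ : list of surviving feature names
    support_ : boolean mask over input features
    cv_path_ : DataFrame (n_features rows): subset size, cv accuracy
    best_cv_accuracy_ : float
    estimator_ : the refit SVC
    """

    def __init__(
        self,
        C_grid: Sequence[float] = (0.1, 1.0, 10.0, 100.0),
        gamma_grid: Sequence[float] | None = None,
        tuning_cv: str | int = "loo",
        rfe_cv: int = 5,
        criterion: str = "kernel",
        class_weight: str | None = None,
        random_state: int = 0,
    ):
        self.C_grid = C_grid
        self.gamma_grid = gamma_grid
        self.tuning_cv = tuning_cv
        self.rfe_cv = rfe_cv
        self.criterion = criterion
        self.class_weight = class_weight
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _cv(self, scheme, y):
        if scheme == "loo":
            return LeaveOneOut()
        n_splits = int(scheme)
        _, counts = np.unique(y, return_counts=True)
        n_splits = min(n_splits, counts.min())
        return StratifiedKFold(n_splits=n_splits, shuffle=True,
                               random_state=self.random_state)

    def _tune(self, X, y) -> tuple[float, float]:
        d = X.shape[1]
        gammas = (self.gamma_grid if self.gamma_grid is not None
                  else np.geomspace(1.0 / (50.0 * d), 1.0 / d, 5))
        cv = self._cv(self.tuning_cv, y)
        best = (-np.inf, None, None)
        for c in self.C_grid:
            for g in gammas:
                svc = SVC(kernel="rbf", C=c, gamma=g, class_weight=self.class_weight)
                acc = cross_val_score(svc, X, y, cv=cv, scoring="accuracy").mean()
                if acc > best[0]:
                    best = (acc, c, g)
        return float(best[1]), float(best[2])

    def _rank_criterion(self, X: np.ndarray, y01: np.ndarray) -> np.ndarray:
        """Per-feature importance; smaller = first to eliminate."""
        if self.criterion == "linear":
            lin = SVC(kernel="linear", C=self.C_, class_weight=self.class_weight)
            lin.fit(X, y01)
            return np.ravel(lin.coef_) ** 2
        svc = SVC(kernel="rbf", C=self.C_, gamma=self.gamma_,
                  class_weight=self.class_weight)
        svc.fit(X, y01)
        sv = X[svc.support_]
        alpha_y = svc.dual_coef_.ravel()  # alpha_i * y_i
        d_all = _rbf_sq_dists(sv)
        k_full = np.exp(-self.gamma_ * d_all)
        outer = np.outer(alpha_y, alpha_y)
        w_full = float(np.sum(outer * k_full))
        scores = np.empty(X.shape[1])
        for f in range(X.shape[1]):
            df = (sv[:, f][:, None] - sv[:, f][None, :]) ** 2
            k_minus = k_full * np.exp(self.gamma_ * df)
            scores[f] = abs(w_full - float(np.sum(outer * k_minus)))
        return scores

    # -- sklearn surface ---------------------------------------------------

    def fit(self, X, y, feature_names: Sequence[str] | None = None):
        if isinstance(X, pd.DataFrame):
            feature_names = list(X.columns)
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training labels contain a single class")
        counts = [np.sum(y == c) for c in self.classes_]
        if min(counts) < 3:
            raise ValueError("need at least 3 samples per class")
        names = list(feature_names) if feature_names is not None else [
            f"f{i}" for i in range(X.shape[1])
        ]
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.train_mean_ = X.mean(axis=0)
        y01 = (y == self.classes_[1]).astype(int)

        self.C_, self.gamma_ = self._tune(X, y01)

        cv = self._cv(self.rfe_cv, y01)
        active = list(range(X.shape[1]))
        path = []  # (size, accuracy, frozenset of active indices)
        elim_order: list[int] = []
        while active:
            sub = X[:, active]
            svc = SVC(kernel="rbf", C=self.C_, gamma=self.gamma_,
                      class_weight=self.class_weight)
            acc = cross_val_score(svc, sub, y01, cv=cv, scoring="accuracy").mean()
            path.append((len(active), float(acc), tuple(active)))
            if len(active) == 1:
                elim_order.append(active.pop())
                break
            crit = self._rank_criterion(sub, y01)
            worst = int(np.argmin(crit))  # first index on ties (deterministic)
            elim_order.append(active.pop(worst))

        best_acc = max(a for _, a, _ in path)
        best_size, best_subset = min(
            (size, subset) for size, a, subset in path if a == best_acc
        )
        self.cv_path_ = pd.DataFrame(
            [(s, a) for s, a, _ in path], columns=["n_features", "cv_accuracy"]
        )
        self.best_cv_accuracy_ = best_acc
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[list(best_subset)] = True
        self.ranking_ = np.empty(X.shape[1], dtype=int)
        # rank 1 = eliminated last (most important)
        for rank, idx in enumerate(reversed(elim_order), start=1):
            self.ranking_[idx] = rank
        self.signature_ = [names[i] for i in sorted(best_subset)]

        self.estimator_ = SVC(
            kernel="rbf", C=self.C_, gamma=self.gamma_,
            class_weight=self.class_weight,
        )
        self.estimator_.fit(X[:, self.support_], y01)
        self.n_features_in_ = X.shape[1]
        return self

    def _subset(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X.reindex(columns=self.feature_names_in_).to_numpy(dtype=float)
            # genes absent from a cohort arrive as NaN; impute at training mean
            nan_cols = np.isnan(X).any(axis=0)
            if nan_cols.any():
                missing = list(self.feature_names_in_[nan_cols])
                logger.warning("imputing %d absent feature(s) at training mean: %s",
                               len(missing), missing[:5])
                X = np.where(np.isnan(X), self.train_mean_, X)
        X = np.asarray(X, dtype=float)
        return X[:, self.support_]

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "estimator_")
        return self.estimator_.decision_function(self._subset(X))

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "estimator_")
        return self.classes_[self.estimator_.predict(self._subset(X))]


# -- evaluation ------------------------------------------------------------


def binary_metrics(y_true, y_pred, decision, positive) -> dict[str, float]:
    """Accuracy, sensitivity, specificity and AUC for one cohort."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    pos, neg = (y_true == positive), (y_true != positive)
    tp = float(np.sum(pos & (y_pred == positive)))
    tn = float(np.sum(neg & (y_pred != positive)))
    out = {
        "accuracy": float(np.mean(y_true == y_pred)),
        "sensitivity": tp / pos.sum() if pos.sum() else float("nan"),
        "specificity": tn / neg.sum() if neg.sum() else float("nan"),
    }
    if pos.sum() and neg.sum():
        out["auc"] = float(roc_auc_score(pos.astype(int), decision))
    else:
        out["auc"] = float("nan")
    return out


@dataclass
class ClassifierReport:
    """Per-cohort and pooled (meta) metrics for one feature-set classifier."""

    feature_set: str
    signature: list[str]
    train_cv_accuracy: float
    cohorts: dict[str, dict[str, float]]
    meta: dict[str, float]
    permutation_p: float | None = None
    permutation_null: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        d = {
            "feature_set": self.feature_set,
            "signature": self.signature,
            "train_cv_accuracy": self.train_cv_accuracy,
            "cohorts": self.cohorts,
            "meta": self.meta,
        }
        if self.permutation_p is not None:
            d["permutation_p"] = self.permutation_p
        return d


def feature_matrix(m: ExpressionMatrix, genes: Sequence[str]) -> pd.DataFrame:
    """Samples x genes block for a feature set (genes may be absent -> NaN)."""
    return m.values.reindex(list(genes)).T


def evaluate(
    clf: SVMRFEClassifier,
    cohorts: dict[str, ExpressionMatrix],
    feature_set_name: str = "features",
    meta: str = "pooled",
) -> ClassifierReport:
    """Score a fitted classifier on independent cohorts.

    The positive class is the lexicographically later label.  Meta metrics
    pool predictions across cohorts (``meta="pooled"``) or average the
    per-cohort metrics (``meta="mean"``).
    """
    positive = clf.classes_[1]
    per_cohort, pooled_true, pooled_pred, pooled_dec = {}, [], [], []
    for name, cohort in cohorts.items():
        X = feature_matrix(cohort, clf.feature_names_in_)
        y = cohort.labels.to_numpy()
        pred = clf.predict(X)
        dec = clf.decision_function(X)
        per_cohort[name] = binary_metrics(y, pred, dec, positive)
        pooled_true.append(y)
        pooled_pred.append(pred)
        pooled_dec.append(dec)
    if meta == "pooled":
        meta_metrics = binary_metrics(
            np.concatenate(pooled_true), np.concatenate(pooled_pred),
            np.concatenate(pooled_dec), positive,
        )
    elif meta == "mean":
        keys = ["accuracy", "sensitivity", "specificity", "auc"]
        meta_metrics = {k: float(np.nanmean([m[k] for m in per_cohort.values()]))
                        for k in keys}
    else:
        raise ValueError(f"unknown meta scheme {meta!r}")
    return ClassifierReport(
        feature_set=feature_set_name,
        signature=list(clf.signature_),
        train_cv_accuracy=float(clf.best_cv_accuracy_),
        cohorts=per_cohort,
        meta=meta_metrics,
    )


def permutation_test(
    evaluate_gene_set: Callable[[Sequence[str]], float],
    observed: float,
    universe: Sequence[str],
    set_size: int,
    B: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Random-gene-set null for a classifier metric.

    Draws ``B`` gene sets of ``set_size`` without replacement from the
    universe, runs each through the supplied train/evaluate path, and
    returns the null metric distribution with the add-one p-value
    p = (r + 1)/(B + 1), r = #{null >= observed}.
    """
    universe = list(universe)
    if set_size > len(universe):
        raise ValueError(f"set_size {set_size} exceeds universe {len(universe)}")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    null = np.empty(B)
    for b in range(B):
        genes = rng.choice(universe, size=set_size, replace=False)
        null[b] = evaluate_gene_set(list(genes))
    r = int(np.sum(null >= observed))
    return null, (r + 1) / (B + 1)


def train_svm_rfe(
    train: ExpressionMatrix,
    features: FeatureSet,
    tuning_cv: str | int = "loo",
    rfe_cv: int = 5,
    random_state: int = 0,
    **kwargs,
) -> SVMRFEClassifier:
    """Fit an SVM-RFE classifier for one feature set on a training cohort."""
    genes = [g for g in features.genes if g in set(train.genes)]
    if not genes:
        raise ValueError(f"no feature of set {features.name!r} is in the matrix")
    X = feature_matrix(train, genes)
    clf = SVMRFEClassifier(tuning_cv=tuning_cv, rfe_cv=rfe_cv,
                           random_state=random_state, **kwargs)
    clf.fit(X, train.labels.to_numpy())
    return clf
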