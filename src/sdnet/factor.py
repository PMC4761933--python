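"""Orthogonal factor-model fusion of topological indexes into an SDN score.

The seven per-node topology measures are standardized, reduced to a small
number m of common factors extracted from their correlation matrix, rotated
(varimax by default), and scored per node.  A variance-weighted composite of
the factor scores ranks nodes; the top-ranked nodes are the structurally
dominant nodes (SDNs).

The model is the classical orthogonal factor decomposition

    X = A F + eps,

with X the standardized index vector (p = 7), F the m common factors,
A the p x m loading matrix and eps uncorrelated specific factors, so that
corr(X) ~= A A' + Psi with Psi diagonal (uniquenesses).  Factors are
extracted as principal components of the correlation matrix, so the
per-factor "contribution" (explained-variance proportion) of factor j is
the column sum of squared loadings divided by p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .topology import MEASURES, TopologyProfile


def standardize_indexes(X: np.ndarray, feature_names: list[str] | None = None) -> np.ndarray:
    """Columnwise z-scoring with population (1/n) scaling.

    Raises if a column is constant, naming the degenerate measure.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    n, p = X.shape
    if n < p + 1:
        raise ValueError(f"need more observations ({n}) than variables ({p})")
    sd = X.std(axis=0, ddof=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = feature_names or [f"column {i}" for i in range(p)]
        raise ValueError(
            "constant column(s), cannot standardize: "
            + ", ".join(names[i] for i in bad)
        )
    return (X - X.mean(axis=0)) / sd


def varimax(loadings: np.ndarray, tol: float = 1e-8, max_iter: int = 1000) -> np.ndarray:
    """Varimax rotation: the orthogonal rotation maximizing loading-variance.

    Standard pairwise/SVD iteration on the raw (Kaiser-unnormalized)
    loadings.  Returns the rotated loading matrix.
    """
    L = np.asarray(loadings, dtype=float)
    p, m = L.shape
    if m < 2:
        return L.copy()
    R = np.eye(m)
    d_old = 0.0
    for _ in range(max_iter):
        Lr = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (Lr ** 3 - Lr @ np.diag(np.sum(Lr ** 2, axis=0)) / p)
        )
        R = u @ vt
        d = np.sum(s)
        if d_old != 0 and d / d_old < 1 + tol:
            break
        d_old = d
    return L @ R


class TopologyFactorModel(BaseEstimator, TransformerMixin):
    """Orthogonal factor model over standardized topology indexes.

    Parameters
    ----------
    n_factors : int or "auto"
        Number of common factors m.  "auto" selects the smallest m whose
        cumulative explained-variance proportion reaches ``min_cumulative``.
    min_cumulative : float
        Target cumulative contribution for "auto" selection (default 0.95).
    rotation : {"varimax", None}
        Orthogonal rotation applied to the extracted loadings.
    score_method : {"regression", "bartlett"}
        Factor-score estimator.  Regression (Thomson) scores are
        F = Z R^+ A; Bartlett scores weight by inverse uniquenesses.
    composite : {"weighted", "norm"}
        How factor scores combine into one SDN score per node: a
        variance-contribution-weighted sum, or the Euclidean norm of the
        score vector.

    Attributes
    ----------
    loadings_ : ndarray (p, m)       rotated loading matrix A
    uniquenesses_ : ndarray (p,)     specific variances (1 - communality)
    contributions_ : ndarray (m,)    per-factor explained-variance proportions
    cumulative_contribution_ : float sum of contributions
    n_factors_ : int                 selected m
    mean_, scale_ : ndarray (p,)     standardization parameters
    """

    def __init__(
        self,
        n_factors: int | str = "auto",
        min_cumulative: float = 0.95,
        rotation: str | None = "varimax",
        score_method: str = "regression",
        composite: str = "weighted",
    ):
        self.n_factors = n_factors
        self.min_cumulative = min_cumulative
        self.rotation = rotation
        self.score_method = score_method
        self.composite = composite

    def fit(self, X, y=None, feature_names: list[str] | None = None):
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        if self.n_factors != "auto" and not 1 <= int(self.n_factors) <= p:
            raise ValueError(f"n_factors must be in 1..{p} or 'auto'")
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=0)
        Z = standardize_indexes(X, feature_names)
        R = (Z.T @ Z) / n
        eigvals, eigvecs = np.linalg.eigh(R)
        order = np.argsort(eigvals)[::-1]
        eigvals, eigvecs = eigvals[order], eigvecs[:, order]
        if eigvals[-1] < -1e-8:
            raise ValueError("correlation matrix is not positive semi-definite")
        eigvals = np.clip(eigvals, 0.0, None)

        explained = eigvals / p
        if self.n_factors == "auto":
            m = int(np.searchsorted(np.cumsum(explained), self.min_cumulative) + 1)
            m = min(m, p)
        else:
            m = int(self.n_factors)

        loadings = eigvecs[:, :m] * np.sqrt(eigvals[:m])
        if self.rotation == "varimax":
            loadings = varimax(loadings)
        elif self.rotation is not None:
            raise ValueError(f"unknown rotation {self.rotation!r}")

        # Sign convention: each factor oriented so the first variable's
        # loading (the degree column for topology profiles) is non-negative;
        # a zero first loading falls back to the largest-magnitude loading.
        for j in range(m):
            ref = loadings[0, j]
            if ref == 0:
                ref = loadings[np.argmax(np.abs(loadings[:, j])), j]
            if ref < 0:
                loadings[:, j] *= -1

        contributions = np.sum(loadings ** 2, axis=0) / p
        order = np.argsort(contributions)[::-1]
        loadings, contributions = loadings[:, order], contributions[order]

        communality = np.sum(loadings ** 2, axis=1)
        self.n_factors_ = m
        self.loadings_ = loadings
        self.contributions_ = contributions
        self.cumulative_contribution_ = float(np.sum(contributions))
        self.uniquenesses_ = 1.0 - communality
        self.correlation_ = R
        self.n_features_in_ = p
        self.feature_names_in_ = np.asarray(feature_names if feature_names else
                                            [f"x{i}" for i in range(p)])
        return self

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_

    def transform(self, X) -> np.ndarray:
        """Per-observation factor scores, shape (n, m)."""
        check_is_fitted(self, "loadings_")
        Z = self._standardize(X)
        if self.score_method == "regression":
            return Z @ np.linalg.pinv(self.correlation_) @ self.loadings_
        if self.score_method == "bartlett":
            u_inv = np.diag(1.0 / np.clip(self.uniquenesses_, 1e-8, None))
            a = self.loadings_
            return Z @ u_inv @ a @ np.linalg.pinv(a.T @ u_inv @ a)
        raise ValueError(f"unknown score_method {self.score_method!r}")

    def composite_score(self, X) -> np.ndarray:
        """Collapse factor scores into one SDN score per observation."""
        scores = self.transform(X)
        if self.composite == "weighted":
            w = self.contributions_ / self.cumulative_contribution_
            return scores @ w
        if self.composite == "norm":
            return np.linalg.norm(scores, axis=1)
        raise ValueError(f"unknown composite {self.composite!r}")


@dataclass
class SDNRanking:
    """Full node ranking by composite SDN score with a flagged top-k set."""

    table: pd.DataFrame  # node-indexed: F1..Fm, sdn_score, rank, is_top_k

    @property
    def top(self) -> list[str]:
        return list(self.table.index[self.table["is_top_k"]])


def fit_factor_model(
    profile: TopologyProfile,
    n_factors: int | str = "auto",
    min_cumulative: float = 0.95,
    rotation: str | None = "varimax",
    score_method: str = "regression",
    composite: str = "weighted",
) -> TopologyFactorModel:
    """Fit the orthogonal factor model to a topology profile."""
    model = TopologyFactorModel(
        n_factors=n_factors,
        min_cumulative=min_cumulative,
        rotation=rotation,
        score_method=score_method,
        composite=composite,
    )
    model.fit(profile.X, feature_names=list(MEASURES))
    return model


def sdn_rank(model: TopologyFactorModel, profile: TopologyProfile, top_k: int = 50) -> SDNRanking:
    """Rank nodes by composite SDN score, descending.

    Ties are broken lexicographically by symbol.  ``rank`` is a 1-based dense
    rank (tied scores share a rank); ``is_top_k`` flags the first ``top_k``
    rows of the sorted order.
    """
    if top_k <= 0:
        raise ValueError("top_k must be positive")
    if top_k > len(profile.nodes):
        raise ValueError(f"top_k={top_k} exceeds node count {len(profile.nodes)}")
    scores = model.transform(profile.X)
    sdn = model.composite_score(profile.X)
    df = pd.DataFrame(
        scores,
        index=pd.Index(profile.nodes, name="node"),
        columns=[f"F{j + 1}" for j in range(model.n_factors_)],
    )
    df["sdn_score"] = sdn
    df = df.sort_values(["sdn_score", "node"], ascending=[False, True],
                        kind="mergesort")
    df["rank"] = df["sdn_score"].rank(method="dense", ascending=False).astype(int)
    df["is_top_k"] = np.arange(len(df)) < top_k
    return SDNRanking(table=df)
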