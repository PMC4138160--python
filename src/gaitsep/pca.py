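"""Covariance PCA of the standardized feature table.

The decomposition follows the classical recipe for discrete gait variables:
standardize each column to zero mean and unit sample SD (divisor n-1), then
eigendecompose the sample covariance of the standardized matrix — i.e. the
correlation matrix of the raw table. PC scores are the standardized matrix
times the eigenvector matrix, so with n subjects and 72 variables there are
min(72, n-1) components (483 subjects give 72, 56 give 55, 51 give 50).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .variables import VARIABLE_NAMES


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        cols = [c for c in X.columns if c in VARIABLE_NAMES] or list(X.columns)
        return X[cols].to_numpy(float), list(cols)
    X = np.asarray(X, dtype=float)
    return X, [f"x{j}" for j in range(X.shape[1])]


class CovariancePCA(TransformerMixin, BaseEstimator):
    """Standardize-then-eigendecompose PCA with a deterministic sign rule.

    Parameters
    ----------
    n_components : int or None
        Number of components to retain; ``None`` keeps the numerical rank
        (eigenvalues above ``tol`` times the largest).
    tol : float
        Relative eigenvalue cutoff defining the numerical rank.

    Attributes
    ----------
    mean_, scale_ : (p,) per-column standardization parameters (sample SD).
    components_ : (k, p) eigenvectors of the correlation matrix, row-wise,
        each flipped so its largest-|loading| entry is positive.
    eigenvalues_ : (k,) descending, non-negative.
    explained_variance_ratio_ : (k,) eigenvalue / total variance.
    scores_ : (n, k) training-set PC scores.
    """

    def __init__(self, n_components: int | None = None, tol: float = 1e-10):
        self.n_components = n_components
        self.tol = tol

    def fit(self, X, y=None):
        M, cols = _as_matrix(X)
        n, p = M.shape
        if n < 2:
            raise ValueError("PCA requires at least 2 samples")
        self.feature_names_in_ = np.asarray(cols, dtype=object)
        self.mean_ = M.mean(axis=0)
        self.scale_ = M.std(axis=0, ddof=1)
        zero = np.nonzero(self.scale_ == 0)[0]
        if zero.size:
            raise ValueError(
                f"zero-variance column(s): {[cols[j] for j in zero]}"
            )
        Z = (M - self.mean_) / self.scale_
        cov = Z.T @ Z / (n - 1)
        eigvals, eigvecs = np.linalg.eigh(cov)
        order = np.argsort(eigvals)[::-1]
        eigvals = np.clip(eigvals[order], 0.0, None)
        eigvecs = eigvecs[:, order]
        total = eigvals.sum()
        k = self.n_components
        if k is None:
            k = int(np.sum(eigvals > self.tol * eigvals[0])) if eigvals[0] > 0 else 1
        k = min(k, p, n - 1) if n - 1 < p else min(k, p)
        eigvals, eigvecs = eigvals[:k], eigvecs[:, :k]
        # deterministic sign: largest-|loading| entry of each eigenvector > 0
        flip = np.sign(eigvecs[np.argmax(np.abs(eigvecs), axis=0), np.arange(k)])
        flip[flip == 0] = 1.0
        eigvecs = eigvecs * flip
        self.components_ = eigvecs.T
        self.eigenvalues_ = eigvals
        self.explained_variance_ratio_ = eigvals / total if total > 0 else eigvals
        self.n_components_ = k
        self.scores_ = Z @ eigvecs
        self.n_samples_ = n
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "components_")
        M, _ = _as_matrix(X)
        return (M - self.mean_) / self.scale_ @ self.components_.T

    def inverse_transform(self, scores) -> np.ndarray:
        check_is_fitted(self, "components_")
        Z = np.asarray(scores, dtype=float) @ self.components_
        return Z * self.scale_ + self.mean_


@dataclass
class PCRanking:
    """An ordering of PCs with its sort key.

    ``order`` holds 0-based PC indices (position in the eigenvalue-descending
    decomposition); ``key_values`` is the non-increasing sort key along the
    order; ``signed_g`` is populated for effect-size rankings.
    """

    mode: str
    order: np.ndarray
    key_values: np.ndarray
    cumulative_variance: np.ndarray
    signed_g: np.ndarray | None = None

    def __post_init__(self) -> None:
        k = len(self.order)
        if sorted(self.order) != list(range(k)):
            raise ValueError("order must be a permutation of 0..k-1")
        if np.any(np.diff(self.key_values) > 1e-12):
            raise ValueError("sort key must be non-increasing along the order")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "rank": np.arange(1, len(self.order) + 1),
                "pc_index": self.order + 1,  # 1-based, as PCs are usually named
                "key_value": self.key_values,
                "cumulative_variance": self.cumulative_variance,
            }
        )
        if self.signed_g is not None:
            df["signed_g"] = self.signed_g[self.order]
        return df


def standardize(X) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standardize columns to mean 0, sample SD 1; returns (Z, mean, scale)."""
    M, cols = _as_matrix(X)
    mean = M.mean(axis=0)
    scale = M.std(axis=0, ddof=1)
    zero = np.nonzero(scale == 0)[0]
    if zero.size:
        raise ValueError(f"zero-variance column(s): {[cols[j] for j in zero]}")
    return (M - mean) / scale, mean, scale


def decompose(X, n_components: int | None = None) -> CovariancePCA:
    """Fit a :class:`CovariancePCA` on a feature table or matrix."""
    return CovariancePCA(n_components=n_components).fit(X)


def rank_by_variance(pca: CovariancePCA) -> PCRanking:
    """PCs in non-increasing eigenvalue order (stable: identity permutation)."""
    check_is_fitted(pca, "components_")
    evr = pca.explained_variance_ratio_
    order = np.arange(pca.n_components_)
    return PCRanking(
        mode="variance",
        order=order,
        key_values=evr.copy(),
        cumulative_variance=np.cumsum(evr),
    )
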