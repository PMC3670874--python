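"""PCA comparator: eigen-decomposition of the sample covariance.

Used as the alternative dimensionality-reduction front end so hybrid models
(PCA + classifier) can be compared against F-score ranking.  Rows are
mean-centered, the ddof=1 sample covariance is eigen-decomposed, eigenpairs
are sorted by descending eigenvalue and the top-d eigenvectors form the
projection Y = U (x − mean).  Eigenvector signs are fixed by making each
vector's largest-magnitude entry positive, for run-to-run reproducibility.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = ["PCAProjector", "pca_fit", "pca_apply"]


class PCAProjector(BaseEstimator, TransformerMixin):
    """Project onto the top ``n_components`` principal axes.

    Attributes
    ----------
    mean_ : ndarray (n_features,)
        Training mean subtracted before projection.
    components_ : ndarray (n_components, n_features)
        Rows are unit-norm eigenvectors of the sample covariance, descending
        eigenvalue order.
    explained_variance_ : ndarray (n_components,)
        The corresponding eigenvalues.
    eigenvalues_ : ndarray (n_features,)
        Full descending spectrum (trace equals total variance).
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = check_array(X, dtype=float, ensure_min_samples=2)
        d = self.n_components
        if not 1 <= d <= X.shape[1]:
            raise ValueError(f"n_components={d} out of range 1..{X.shape[1]}")
        self.mean_ = X.mean(axis=0)
        cov = np.cov(X, rowvar=False, ddof=1)
        cov = np.atleast_2d(cov)
        evals, evecs = np.linalg.eigh(cov)  # ascending
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        # sign convention: largest-|entry| of each eigenvector positive
        flip = np.sign(evecs[np.argmax(np.abs(evecs), axis=0), np.arange(evecs.shape[1])])
        flip[flip == 0] = 1.0
        evecs = evecs * flip
        self.eigenvalues_ = evals
        self.components_ = evecs[:, :d].T
        self.explained_variance_ = evals[:d]
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        X = check_array(X, dtype=float, ensure_min_samples=0)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, projector was fit on {self.n_features_in_}"
            )
        return (X - self.mean_) @ self.components_.T


def pca_fit(rows, d: int) -> PCAProjector:
    """Fit the top-``d`` principal-axis projection on training rows."""
    return PCAProjector(n_components=d).fit(np.asarray(rows, dtype=float))


def pca_apply(transform: PCAProjector, rows) -> np.ndarray:
    """Project rows with a fitted :class:`PCAProjector` (d columns out)."""
    return transform.transform(np.asarray(rows, dtype=float))
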