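"""F-score feature ranking.

The F-score of a feature measures the separation of its class-conditional
means relative to the within-class spread::

    F = [ (x̄⁺ − x̄)² + (x̄⁻ − x̄)² ] /
        [ s²₊ + s²₋ ]

where x̄⁺, x̄⁻, x̄ are the positive-class, negative-class and pooled means and
s²₊, s²₋ are the class sample variances (1/(n−1) normalization).  It is the
univariate filter statistic popularized for SVM feature selection; not the
harmonic-mean F1 metric.  Larger is more discriminative.  Conventions: a
feature constant within both classes scores 0 when the class means agree
(0/0) and +inf when they differ (perfectly separating constant feature).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = ["fscore", "fscore_columns", "FScoreSelector", "FScoreRanking", "rank_features"]


def _validate_labels(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    bad = set(np.unique(labels)) - {1, -1}
    if bad:
        raise ValueError(f"labels must be +1/-1, got extraneous {sorted(bad)}")
    pos = labels == 1
    neg = labels == -1
    if pos.sum() < 2 or neg.sum() < 2:
        raise ValueError("each class needs at least 2 members for the F-score")
    return pos, neg


def fscore_columns(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """F-score of every column of ``X`` against ±1 ``labels``."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    pos, neg = _validate_labels(labels)
    xp, xn = X[pos], X[neg]
    mp = xp.mean(axis=0)
    mn = xn.mean(axis=0)
    m = X.mean(axis=0)
    num = (mp - m) ** 2 + (mn - m) ** 2
    den = xp.var(axis=0, ddof=1) + xn.var(axis=0, ddof=1)
    out = np.empty(X.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.where(num > 0, np.inf, 0.0))
    return out


def fscore(values, labels) -> float:
    """F-score of a single feature column."""
    return float(fscore_columns(np.asarray(values, dtype=float).reshape(-1, 1), labels)[0])


class FScoreSelector(BaseEstimator, TransformerMixin):
    """Rank features by F-score; transform keeps the top ``k``.

    Parameters
    ----------
    k : int or None
        Number of top-ranked features kept by :meth:`transform`; ``None``
        keeps all (pure reordering is left to the caller via ``ranking_``).

    Attributes
    ----------
    scores_ : ndarray of shape (n_features,)
        Per-feature F-scores.
    ranking_ : ndarray of shape (n_features,)
        Column indices sorted by descending score, ties broken by original
        column index (stable).
    """

    def __init__(self, k: int | None = None):
        self.k = k

    def fit(self, X, y):
        X = check_array(X, dtype=float)
        self.scores_ = fscore_columns(X, y)
        self.ranking_ = np.argsort(-self.scores_, kind="stable")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "ranking_")
        X = check_array(X, dtype=float)
        k = self.n_features_in_ if self.k is None else self.k
        if not 1 <= k <= self.n_features_in_:
            raise ValueError(f"k={k} out of range 1..{self.n_features_in_}")
        return X[:, self.ranking_[:k]]


@dataclass
class FScoreRanking:
    """Scores and the descending-score feature ordering of a feature table."""

    feature_names: list[str]
    scores: np.ndarray  # aligned with feature_names
    order: np.ndarray  # permutation: indices into feature_names, best first
    n_pos: int
    n_neg: int

    @property
    def ordered_names(self) -> list[str]:
        return [self.feature_names[i] for i in self.order]

    def to_dict(self) -> dict:
        return {
            "scores": {n: float(s) for n, s in zip(self.feature_names, self.scores)},
            "order": self.ordered_names,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
        }


def rank_features(table: pd.DataFrame) -> FScoreRanking:
    """Rank all feature columns of a feature table by descending F-score."""
    names = [c for c in table.columns if c not in ("subject_id", "label")]
    labels = table["label"].to_numpy()
    try:
        sel = FScoreSelector().fit(table[names].to_numpy(dtype=float), labels)
    except ValueError as exc:
        raise ValueError(f"ranking failed on columns {names}: {exc}") from exc
    return FScoreRanking(
        feature_names=names,
        scores=sel.scores_,
        order=sel.ranking_,
        n_pos=int((labels == 1).sum()),
        n_neg=int((labels == -1).sum()),
    )
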