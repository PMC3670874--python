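"""Joint optimization of feature-subset size S and hidden-node count K.

The search wraps feature ranking around the ELM: features are sorted by
descending F-score (or replaced by principal components, in which case the
retained dimension d plays the role of S), then for every S = 1…D the top-S
features are fed to ELMs with K = S…S+k_span hidden nodes — a D×(k_span+1)
grid.  Each cell is scored by balanced training accuracy (BA_train) under
subject-wise cross-validation (SWCV): one subject per class held out per
fold, so no subject contributes to both training and evaluation, with a
stratified 10-fold CV inside each fold's training subjects.  Per cell,

    TR_sen = mean over outer folds of the inner-CV sensitivity,
    TR_spe = likewise for specificity,
    BA_train = (TR_sen + TR_spe) / 2  (percent).

The selected (S*, K*) is the cell of highest BA_train, with a configurable
parsimony tolerance: among all cells within ``parsimony`` percentage points
of the maximum, the smallest S then smallest K wins (tolerance 0 reproduces
the strict arg-max).  Final ELMs are retrained per outer fold on the fold's
full training subjects at (S*, K*) and evaluated on the held-out subject
pair, giving TE_sen, TE_spe and BA_test.

Ranking and [−1, 1] normalization are fit inside each outer fold, on that
fold's training subjects only, so held-out subjects can never leak into
feature selection, scaling or training.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.special import expit
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .elm import ELMClassifier
from .features import SymmetricMinMaxScaler
from .fscore import fscore_columns
from .pca import PCAProjector

__all__ = [
    "CVPlan",
    "make_swcv_folds",
    "balanced_accuracy",
    "paired_ttest",
    "FScoreELMSearch",
    "grid_search",
]


@dataclass(frozen=True)
class CVPlan:
    """Subject-wise folds: each fold holds out one subject per class."""

    folds: tuple  # ((train_subjects, (test_pos, test_neg)), ...)
    inner_folds: int = 10
    seed: int | None = None


def make_swcv_folds(pos_subjects, neg_subjects, inner_folds: int = 10, seed=None) -> CVPlan:
    """Pair the f-th positive with the f-th negative subject (sorted IDs).

    Every subject appears in exactly one test fold; fold count equals the
    per-class subject count, which must match between classes and be >= 2.
    """
    pos = sorted(str(s) for s in pos_subjects)
    neg = sorted(str(s) for s in neg_subjects)
    for name, ids in (("positive", pos), ("negative", neg)):
        if len(set(ids)) != len(ids):
            dupes = sorted({s for s in ids if ids.count(s) > 1})
            raise ValueError(f"duplicate {name}-class subject ids: {dupes}")
        if len(ids) < 2:
            raise ValueError(f"need >= 2 {name}-class subjects for SWCV")
    if set(pos) & set(neg):
        raise ValueError(f"subjects in both classes: {sorted(set(pos) & set(neg))}")
    if len(pos) != len(neg):
        raise ValueError(
            f"SWCV pairs one subject per class per fold; got {len(pos)} vs {len(neg)}"
        )
    folds = []
    for p, n in zip(pos, neg):
        train = tuple(s for s in pos + neg if s not in (p, n))
        folds.append((train, (p, n)))
    return CVPlan(folds=tuple(folds), inner_folds=inner_folds, seed=seed)


def balanced_accuracy(sensitivities, specificities) -> tuple[float, float, float]:
    """(mean sensitivity, mean specificity, their average), same units in/out."""
    sen = np.asarray(sensitivities, dtype=float)
    spe = np.asarray(specificities, dtype=float)
    if sen.size == 0 or sen.size != spe.size:
        raise ValueError("need equal-length, non-empty sensitivity/specificity lists")
    return float(sen.mean()), float(spe.mean()), float((sen.mean() + spe.mean()) / 2)


def paired_ttest(a, b) -> tuple[float, float]:
    """Paired t-test on per-fold accuracies of two models (two-sided).

    Zero variance of the differences is degenerate for the t statistic: it
    returns p = NaN with a warning (t = 0 for identical vectors, ±inf for a
    constant nonzero shift).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("paired t-test needs two equal-length vectors, n >= 2")
    d = a - b
    if np.ptp(d) == 0:
        warnings.warn(
            "zero variance of paired differences; p-value undefined", UserWarning
        )
        t = 0.0 if d[0] == 0 else float(np.copysign(np.inf, d[0]))
        return t, float("nan")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def _class_rates(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    """Percent correct among +1 rows (sensitivity) and −1 rows (specificity)."""
    pos = y_true == 1
    neg = ~pos
    sen = 100.0 * np.mean(y_pred[pos] == 1) if pos.any() else np.nan
    spe = 100.0 * np.mean(y_pred[neg] == -1) if neg.any() else np.nan
    return sen, spe


@dataclass
class _FoldTransform:
    scaler: SymmetricMinMaxScaler
    order: np.ndarray | None  # feature permutation (fscore route)
    projector: PCAProjector | None  # pca route
    model: ELMClassifier | None = None
    selected_names: list[str] = field(default_factory=list)

    def transform(self, X: np.ndarray, s: int) -> np.ndarray:
        Xn = self.scaler.transform(X)
        if self.projector is not None:
            return self.projector.transform(Xn)[:, :s]
        return Xn[:, self.order[:s]]


class FScoreELMSearch(BaseEstimator):
    """Grid search over (feature-subset size S, hidden-node count K).

    Parameters
    ----------
    selector : {"fscore", "pca"}
        Feature front end: descending F-score ranking, or projection onto
        principal components (d = S retained components).
    k_span : int
        Inner K loop runs K = S … S + k_span (k_span + 1 candidates).
    inner_folds : int
        Stratified CV folds inside each outer fold's training subjects.
    parsimony : float
        BA_train tolerance (percentage points) within which smaller (S, K)
        is preferred; 0 gives the strict arg-max.
    global_ranking : bool
        Rank features once on the full table instead of per outer fold.
        Leaks held-out subjects into the ranking; off by default, available
        for comparison.
    random_state : int or None
        Master seed; fans out to inner-CV shuffles and all ELM draws.

    Attributes (after ``fit``)
    --------------------------
    ba_train_grid_, tr_sen_grid_, tr_spe_grid_ : ndarray (D, k_span+1), percent
    s_values_, k_offsets_ : the grid axes (K at cell (i, j) is S_i + j)
    s_opt_, k_opt_ : selected S* (NFS) and K* (NHN)
    ba_train_, ba_test_, te_sen_, te_spe_ : summary accuracies, percent
    fold_ba_train_, fold_ba_test_ : per outer fold, for paired t-tests
    fold_te_sen_, fold_te_spe_ : per-fold test rates (per-subject accuracies)
    selected_features_ : top-S* feature names per outer fold (fscore route)
    models_ : the per-fold final ELMs
    train_seconds_, test_seconds_ : wall-clock diagnostics (never asserted)
    """

    def __init__(
        self,
        selector: str = "fscore",
        k_span: int = 20,
        inner_folds: int = 10,
        parsimony: float = 0.5,
        rcond: float = 1e-10,
        global_ranking: bool = False,
        random_state: int | None = None,
    ):
        self.selector = selector
        self.k_span = k_span
        self.inner_folds = inner_folds
        self.parsimony = parsimony
        self.rcond = rcond
        self.global_ranking = global_ranking
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _seed(self, *key: int) -> np.random.SeedSequence:
        master = 0 if self.random_state is None else int(self.random_state)
        return np.random.SeedSequence(entropy=master, spawn_key=tuple(key))

    def _cell_weights(self, fold: int, s: int, k_max: int):
        rng = np.random.default_rng(self._seed(1, fold, s))
        w = rng.uniform(-1.0, 1.0, size=(s, k_max))
        b = rng.uniform(-1.0, 1.0, size=k_max)
        return w, b

    @staticmethod
    def _solve(G: np.ndarray, c: np.ndarray, H: np.ndarray, y: np.ndarray) -> np.ndarray:
        # normal equations + Cholesky; sigmoid H is a.s. full column rank
        # whenever K <= N, with an SVD fallback guarding rank deficiency
        if G.shape[0] <= H.shape[0]:
            try:
                return linalg.cho_solve(linalg.cho_factor(G, lower=True), c)
            except np.linalg.LinAlgError:
                pass
        return linalg.lstsq(H, y, lapack_driver="gelsd")[0]

    # -- fit ---------------------------------------------------------------

    def fit(self, X, y=None, subject_id=None):
        """Run the full search.

        ``X`` may be a feature table (DataFrame with ``subject_id`` and
        ``label`` columns) or a raw N×D array with ``y`` (±1) and
        ``subject_id`` given separately.  Features must be unnormalized;
        scaling is fit per outer fold.
        """
        if isinstance(X, pd.DataFrame) and "label" in X.columns:
            names = [c for c in X.columns if c not in ("subject_id", "label")]
            y = X["label"].to_numpy(dtype=float)
            subject_id = X["subject_id"].astype(str).to_numpy()
            X = X[names].to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            names = [f"f{i}" for i in range(X.shape[1])]
            if y is None or subject_id is None:
                raise ValueError("array input needs explicit y and subject_id")
            y = np.asarray(y, dtype=float).ravel()
            subject_id = np.asarray([str(s) for s in subject_id])
        if self.selector not in ("fscore", "pca"):
            raise ValueError(f"unknown selector {self.selector!r}")
        if self.k_span < 0:
            raise ValueError("k_span must be >= 0")
        if X.shape[1] < 1:
            raise ValueError("empty feature set")
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite feature values")

        t_train0 = time.perf_counter()
        self.feature_names_ = names
        D = X.shape[1]
        n_k = self.k_span + 1
        plan = make_swcv_folds(
            np.unique(subject_id[y == 1]),
            np.unique(subject_id[y == -1]),
            inner_folds=self.inner_folds,
            seed=self.random_state,
        )
        self.cv_plan_ = plan
        n_folds = len(plan.folds)

        global_order = None
        if self.global_ranking and self.selector == "fscore":
            scores = fscore_columns(X, y)
            global_order = np.argsort(-scores, kind="stable")

        sen_grid = np.zeros((n_folds, D, n_k))
        spe_grid = np.zeros((n_folds, D, n_k))
        transforms: list[_FoldTransform] = []
        fold_features: list[np.ndarray] = []  # ordered/projected training X
        fold_targets: list[np.ndarray] = []
        for f, (train_subjects, _test_pair) in enumerate(plan.folds):
            tr_mask = np.isin(subject_id, train_subjects)
            Xtr_raw, ytr = X[tr_mask], y[tr_mask]
            scaler = SymmetricMinMaxScaler().fit(Xtr_raw)
            Xtr = scaler.transform(Xtr_raw)
            if self.selector == "pca":
                projector = PCAProjector(n_components=D).fit(Xtr)
                Ftr = projector.transform(Xtr)
                tf = _FoldTransform(scaler, None, projector)
            else:
                order = (
                    global_order
                    if global_order is not None
                    else np.argsort(-fscore_columns(Xtr, ytr), kind="stable")
                )
                Ftr = Xtr[:, order]
                tf = _FoldTransform(scaler, order, None)
            transforms.append(tf)
            fold_features.append(Ftr)
            fold_targets.append(ytr)

            n_splits = min(self.inner_folds, int((ytr == 1).sum()), int((ytr == -1).sum()))
            if n_splits < 2:
                raise ValueError(
                    f"fold {f}: too few responses per class for inner CV"
                )
            skf = StratifiedKFold(
                n_splits=n_splits,
                shuffle=True,
                random_state=int(self._seed(2, f).generate_state(1)[0] % (2**31)),
            )
            splits = list(skf.split(Ftr, ytr))
            for s in range(1, D + 1):
                k_max = s + self.k_span
                w, b = self._cell_weights(f, s, k_max)
                H_all = expit(Ftr[:, :s] @ w + b)
                acc_sen = np.zeros(n_k)
                acc_spe = np.zeros(n_k)
                for itr, iva in splits:
                    Htr, Hva = H_all[itr], H_all[iva]
                    ytr_i, yva = ytr[itr], ytr[iva]
                    G = Htr.T @ Htr
                    c = Htr.T @ ytr_i
                    pos_va = yva == 1
                    neg_va = ~pos_va
                    for j in range(n_k):
                        k = s + j
                        beta = self._solve(G[:k, :k], c[:k], Htr[:, :k], ytr_i)
                        pred = np.where(Hva[:, :k] @ beta >= 0, 1.0, -1.0)
                        acc_sen[j] += np.mean(pred[pos_va] == 1.0)
                        acc_spe[j] += np.mean(pred[neg_va] == -1.0)
                sen_grid[f, s - 1] = 100.0 * acc_sen / len(splits)
                spe_grid[f, s - 1] = 100.0 * acc_spe / len(splits)

        self.fold_tr_sen_grid_ = sen_grid
        self.fold_tr_spe_grid_ = spe_grid
        self.tr_sen_grid_ = sen_grid.mean(axis=0)
        self.tr_spe_grid_ = spe_grid.mean(axis=0)
        self.ba_train_grid_ = (self.tr_sen_grid_ + self.tr_spe_grid_) / 2.0
        self.s_values_ = np.arange(1, D + 1)
        self.k_offsets_ = np.arange(n_k)

        # parsimony selection: smallest S, then smallest K, within tolerance
        best = float(self.ba_train_grid_.max())
        s_idx, k_idx = next(
            (i, j)
            for i in range(D)
            for j in range(n_k)
            if self.ba_train_grid_[i, j] >= best - self.parsimony
        )
        self.s_opt_ = int(s_idx + 1)
        self.k_opt_ = int(self.s_opt_ + k_idx)
        self.ba_train_ = float(self.ba_train_grid_[s_idx, k_idx])
        self.tr_sen_ = float(self.tr_sen_grid_[s_idx, k_idx])
        self.tr_spe_ = float(self.tr_spe_grid_[s_idx, k_idx])
        self.fold_ba_train_ = (sen_grid[:, s_idx, k_idx] + spe_grid[:, s_idx, k_idx]) / 2.0

        # final models: retrain per outer fold at (S*, K*), then Step-8 testing
        for f, tf in enumerate(transforms):
            model = ELMClassifier(
                n_hidden=self.k_opt_,
                rcond=self.rcond,
                random_state=np.random.default_rng(self._seed(3, f)),
            ).fit(fold_features[f][:, : self.s_opt_], fold_targets[f])
            tf.model = model
            if tf.order is not None:
                tf.selected_names = [names[i] for i in tf.order[: self.s_opt_]]
        self.train_seconds_ = time.perf_counter() - t_train0

        t_test0 = time.perf_counter()
        fold_sen = np.empty(n_folds)
        fold_spe = np.empty(n_folds)
        subject_accuracy = {}
        for f, (train_subjects, test_pair) in enumerate(plan.folds):
            te_mask = np.isin(subject_id, test_pair)
            Fte = transforms[f].transform(X[te_mask], self.s_opt_)
            pred = transforms[f].model.predict(Fte)
            sen, spe = _class_rates(y[te_mask], pred)
            fold_sen[f], fold_spe[f] = sen, spe
            subject_accuracy[test_pair[0]] = sen
            subject_accuracy[test_pair[1]] = spe
        self.test_seconds_ = time.perf_counter() - t_test0

        self.fold_te_sen_ = fold_sen
        self.fold_te_spe_ = fold_spe
        self.te_sen_, self.te_spe_, self.ba_test_ = balanced_accuracy(fold_sen, fold_spe)
        self.fold_ba_test_ = (fold_sen + fold_spe) / 2.0
        self.subject_accuracy_ = subject_accuracy
        self.transforms_ = transforms
        self.models_ = [tf.model for tf in transforms]
        self.selected_features_ = [tf.selected_names for tf in transforms]
        return self

    # -- reporting ---------------------------------------------------------

    @property
    def grid_(self) -> pd.DataFrame:
        """Long-format grid: one row per (S, K) cell."""
        check_is_fitted(self, "ba_train_grid_")
        rows = []
        for i, s in enumerate(self.s_values_):
            for j in self.k_offsets_:
                rows.append(
                    (s, s + j, self.tr_sen_grid_[i, j], self.tr_spe_grid_[i, j], self.ba_train_grid_[i, j])
                )
        return pd.DataFrame(rows, columns=["S", "K", "TR_sen", "TR_spe", "BA_train"])

    def result_dict(self) -> dict:
        """Seed-deterministic summary (no wall-clock timings)."""
        check_is_fitted(self, "ba_train_grid_")
        return {
            "selector": self.selector,
            "k_span": int(self.k_span),
            "inner_folds": int(self.inner_folds),
            "parsimony": float(self.parsimony),
            "NFS": self.s_opt_,
            "NHN": self.k_opt_,
            "BA_train": self.ba_train_,
            "TR_sen": self.tr_sen_,
            "TR_spe": self.tr_spe_,
            "BA_test": self.ba_test_,
            "TE_sen": self.te_sen_,
            "TE_spe": self.te_spe_,
            "fold_ba_train": [float(v) for v in self.fold_ba_train_],
            "fold_ba_test": [float(v) for v in self.fold_ba_test_],
            "fold_te_sen": [float(v) for v in self.fold_te_sen_],
            "fold_te_spe": [float(v) for v in self.fold_te_spe_],
            "subject_accuracy": {k: float(v) for k, v in self.subject_accuracy_.items()},
            "selected_features": self.selected_features_,
            "ba_train_grid": [[float(v) for v in row] for row in self.ba_train_grid_],
        }


def grid_search(
    table: pd.DataFrame,
    selector: str = "fscore",
    k_span: int = 20,
    inner_folds: int = 10,
    parsimony: float = 0.5,
    seed: int | None = None,
    global_ranking: bool = False,
) -> FScoreELMSearch:
    """Run the (S, K) search on a feature table; returns the fitted search."""
    return FScoreELMSearch(
        selector=selector,
        k_span=k_span,
        inner_folds=inner_folds,
        parsimony=parsimony,
        global_ranking=global_ranking,
        random_state=seed,
    ).fit(table)
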