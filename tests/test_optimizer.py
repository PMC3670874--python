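import json

import numpy as np
import pytest

from conftest import make_feature_table
from fscore_elm import (
    FScoreELMSearch,
    balanced_accuracy,
    grid_search,
    make_swcv_folds,
    paired_ttest,
)


class TestSwcvFolds:
    def test_each_fold_holds_out_one_subject_per_class(self):
        pos = [f"G{i:02d}" for i in range(14)]
        neg = [f"I{i:02d}" for i in range(14)]
        plan = make_swcv_folds(pos, neg)
        assert len(plan.folds) == 14
        tested = [s for _, pair in plan.folds for s in pair]
        assert sorted(tested) == sorted(pos + neg)  # each subject exactly once
        for train, pair in plan.folds:
            assert len(pair) == 2
            assert not set(train) & set(pair)
            assert len(train) == 26

    def test_two_subjects_per_class_gives_two_folds(self):
        assert len(make_swcv_folds(["a", "b"], ["c", "d"]).folds) == 2

    def test_duplicate_subject_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            make_swcv_folds(["a", "a", "b"], ["c", "d", "e"])

    def test_too_few_or_unbalanced_subjects_rejected(self):
        with pytest.raises(ValueError):
            make_swcv_folds(["a"], ["b"])
        with pytest.raises(ValueError):
            make_swcv_folds(["a", "b", "c"], ["d", "e"])

    def test_subject_in_both_classes_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            make_swcv_folds(["a", "b"], ["b", "c"])


class TestBalancedAccuracy:
    def test_simple_average(self):
        assert balanced_accuracy([100, 100], [90, 90])[2] == pytest.approx(95.0)

    def test_hand_mean(self):
        sen, spe, ba = balanced_accuracy([80, 100], [60, 100])
        assert (sen, spe, ba) == (90.0, 80.0, 85.0)

    def test_single_fold(self):
        assert balanced_accuracy([100], [100]) == (100.0, 100.0, 100.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            balanced_accuracy([], [])


class TestPairedTTest:
    def test_identical_vectors(self):
        with pytest.warns(UserWarning, match="zero variance"):
            t, p = paired_ttest([90.0, 92.0, 94.0], [90.0, 92.0, 94.0])
        assert t == 0.0 and np.isnan(p)

    def test_constant_shift(self):
        with pytest.warns(UserWarning, match="zero variance"):
            t, p = paired_ttest([90.0, 92.0, 94.0], [85.0, 87.0, 89.0])
        assert t == np.inf and np.isnan(p)

    def test_matches_scipy_on_regular_data(self):
        from scipy import stats

        rng = np.random.default_rng(0)
        a = rng.normal(90, 3, 14)
        b = rng.normal(88, 3, 14)
        t, p = paired_ttest(a, b)
        ref = stats.ttest_rel(a, b)
        assert t == pytest.approx(ref.statistic) and p == pytest.approx(ref.pvalue)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_ttest([1.0], [1.0, 2.0])


@pytest.fixture(scope="module")
def small_search():
    table = make_feature_table(n_subjects=4, per_subject=10, n_noise=4, seed=5)
    return grid_search(table, k_span=4, inner_folds=4, seed=5), table


class TestGridSearch:
    def test_grid_geometry(self, small_search):
        search, _ = small_search
        D = 7  # 3 informative + 4 noise columns
        assert search.ba_train_grid_.shape == (D, 5)
        grid = search.grid_
        assert len(grid) == D * 5
        ks = grid.loc[grid.S == 3, "K"].tolist()
        assert ks == list(range(3, 8))  # K = S ... S + k_span

    def test_selection_respects_parsimony_rule(self, small_search):
        search, _ = small_search
        best = search.ba_train_grid_.max()
        assert search.ba_train_ >= best - search.parsimony
        # no cell with smaller S (or equal S, smaller K) is within tolerance
        for i in range(search.s_opt_ - 1):
            assert np.all(search.ba_train_grid_[i] < best - search.parsimony)

    def test_informative_structure_recovered(self, small_search):
        search, _ = small_search
        assert search.ba_test_ > 90.0
        assert all("inf" in search.selected_features_[0][i] for i in range(min(search.s_opt_, 3)))

    def test_deterministic_for_fixed_seed(self, small_search):
        search, table = small_search
        again = grid_search(table, k_span=4, inner_folds=4, seed=5)
        np.testing.assert_array_equal(search.ba_train_grid_, again.ba_train_grid_)
        assert (search.s_opt_, search.k_opt_) == (again.s_opt_, again.k_opt_)
        np.testing.assert_array_equal(search.fold_ba_test_, again.fold_ba_test_)

    def test_result_dict_is_json_serializable(self, small_search):
        search, _ = small_search
        blob = json.dumps(search.result_dict())
        assert '"NFS"' in blob and '"ba_train_grid"' in blob

    def test_balanced_test_accuracy_identity(self, small_search):
        search, _ = small_search
        assert search.ba_test_ == pytest.approx((search.te_sen_ + search.te_spe_) / 2)
        np.testing.assert_allclose(
            search.fold_ba_test_, (search.fold_te_sen_ + search.fold_te_spe_) / 2
        )

    def test_pca_selector_route(self):
        table = make_feature_table(n_subjects=3, per_subject=10, n_noise=3, seed=8)
        search = grid_search(table, selector="pca", k_span=3, inner_folds=3, seed=8)
        assert search.ba_train_grid_.shape == (6, 4)
        assert 1 <= search.s_opt_ <= 6
        assert search.ba_test_ > 80.0  # informative structure survives projection

    def test_invalid_arguments(self):
        table = make_feature_table(n_subjects=3, per_subject=6, n_noise=2, seed=1)
        with pytest.raises(ValueError):
            grid_search(table, selector="anova")
        with pytest.raises(ValueError):
            grid_search(table, k_span=-1)
        with pytest.raises(ValueError):
            FScoreELMSearch().fit(np.zeros((4, 2)))  # array input without metadata


class TestLeakage:
    def test_held_out_rows_cannot_influence_their_fold(self):
        clean = make_feature_table(n_subjects=3, per_subject=12, n_noise=4, seed=21)
        plan_pair = ("G01", "I01")  # fold 0 test subjects (sorted-ID pairing)
        poisoned = clean.copy()
        rows = poisoned.subject_id.isin(plan_pair)
        feat_cols = [c for c in poisoned.columns if c not in ("subject_id", "label")]
        poisoned.loc[rows, feat_cols] = 1e6

        a = grid_search(clean, k_span=3, inner_folds=3, seed=21)
        b = grid_search(poisoned, k_span=3, inner_folds=3, seed=21)
        assert a.cv_plan_.folds[0][1] == plan_pair
        # fold 0 never sees its held-out subjects during ranking, scaling or
        # training, so its whole training-side grid is bit-identical
        np.testing.assert_array_equal(a.fold_tr_sen_grid_[0], b.fold_tr_sen_grid_[0])
        np.testing.assert_array_equal(a.fold_tr_spe_grid_[0], b.fold_tr_spe_grid_[0])
        np.testing.assert_array_equal(a.transforms_[0].scaler.data_min_, b.transforms_[0].scaler.data_min_)
        np.testing.assert_array_equal(a.transforms_[0].scaler.data_max_, b.transforms_[0].scaler.data_max_)
        np.testing.assert_array_equal(a.transforms_[0].order, b.transforms_[0].order)
        if (a.s_opt_, a.k_opt_) == (b.s_opt_, b.k_opt_):
            np.testing.assert_array_equal(
                a.transforms_[0].model.output_weights_, b.transforms_[0].model.output_weights_
            )
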