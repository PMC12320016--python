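"""Feature tables, partition schemes, leakage-free preprocessing and the SVM."""

import numpy as np
import pytest

from statefeats.classify import (
    ClassifierConfig,
    FeatureTable,
    apply_preprocessor,
    assemble_feature_table,
    balanced_accuracy,
    build_folds,
    fit_preprocessor,
    permutation_null,
    run_classification,
    select_classes,
)


def _toy_table(n_subjects=4, n_per_state=6, n_feats=3, n_units=2, seed=0, separation=0.0):
    """Synthetic-feature table (no signal generation) for fold/preproc tests."""
    rng = np.random.default_rng(seed)
    states = ["EC", "EO", "BSL", "VS"]
    rows, ys, subs, orders = [], [], [], []
    for s in range(n_subjects):
        k = 0
        for st_i, state in enumerate(states):
            for _ in range(n_per_state):
                rows.append(rng.standard_normal(n_feats * n_units) + separation * st_i)
                ys.append(state)
                subs.append(f"sub-{s:02d}")
                orders.append(k)
                k += 1
    meta = [(f"f{i}", f"u{j}") for i in range(n_feats) for j in range(n_units)]
    return FeatureTable(np.asarray(rows), np.asarray(ys), np.asarray(subs),
                        np.asarray(orders), meta)


class TestAssembly:
    def test_timefeats_table_shape(self, small_cohort):
        from statefeats.classify import assemble_feature_table

        table = assemble_feature_table(small_cohort, "TimeFeats")
        # 3 subjects x 32 epochs, 41 features x 2 units
        assert table.X.shape == (96, 82)
        assert len(table.column_meta) == 82
        assert table.feature_names[:1] == ["DN_HistogramMode_5"]

    def test_freqbands_and_fullfft_column_counts(self, small_cohort, small_freqbands_table):
        assert small_freqbands_table.X.shape[1] == 12  # 6 features x 2 units
        table = assemble_feature_table(small_cohort, "fullFFT")
        assert table.X.shape[1] == 200  # 100 x 2 units

    def test_column_order_is_feature_major(self, small_freqbands_table):
        meta = small_freqbands_table.column_meta
        assert meta[0][0] == meta[1][0]  # same feature, successive units
        assert meta[0][1] != meta[1][1]

    def test_mismatched_units_rejected(self, small_cohort):
        import copy

        broken = copy.deepcopy(small_cohort)
        broken[1].unit_names = ["other-1", "other-2"]
        with pytest.raises(ValueError, match="share"):
            assemble_feature_table(broken, "FreqBands")


class TestFolds:
    def test_within_folds_test_contiguous_chunks_per_state(self):
        table = _toy_table(n_subjects=2, n_per_state=10)
        plan = build_folds(table, "within", n_folds=5)
        assert plan.n_folds == 10  # 2 subjects x 5 folds
        for train, test in plan.folds:
            subj = np.unique(table.subject[np.concatenate([train, test])])
            assert len(np.unique(table.subject[test])) == 1
            # each state's contribution is a contiguous run of epoch_order
            for state in np.unique(table.y[test]):
                rows = test[table.y[test] == state]
                orders = np.sort(table.epoch_order[rows])
                assert np.all(np.diff(orders) == 1)
            # 10 epochs per state, 5 folds -> 2 contiguous epochs per state
            assert all((table.y[test] == s).sum() == 2 for s in np.unique(table.y[test]))

    def test_between_leave_one_subject_out(self):
        table = _toy_table(n_subjects=5)
        plan = build_folds(table, "between", n_folds=10)
        assert plan.n_folds == 5
        for train, test in plan.folds:
            test_subjects = set(table.subject[test])
            assert len(test_subjects) == 1
            assert test_subjects.isdisjoint(set(table.subject[train]))

    def test_between_grouped_kfold_never_splits_subjects(self):
        table = _toy_table(n_subjects=6)
        plan = build_folds(table, "between", n_folds=3, seed=1)
        assert plan.n_folds == 3
        seen = set()
        for train, test in plan.folds:
            test_subjects = set(table.subject[test])
            assert test_subjects.isdisjoint(set(table.subject[train]))
            seen |= test_subjects
        assert seen == set(np.unique(table.subject))

    def test_across_every_subject_in_both_sides_each_fold(self):
        table = _toy_table(n_subjects=3, n_per_state=10)
        plan = build_folds(table, "across", n_folds=10)
        assert plan.n_folds == 10
        all_subjects = set(np.unique(table.subject))
        for train, test in plan.folds:
            assert set(table.subject[train]) == all_subjects
            assert set(table.subject[test]) == all_subjects
            frac = test.size / table.X.shape[0]
            assert frac == pytest.approx(0.1, abs=0.05)

    def test_across_single_split_85_15(self):
        table = _toy_table(n_subjects=3, n_per_state=20)
        plan = build_folds(table, "across", holdout_fraction=0.15)
        assert plan.n_folds == 1
        train, test = plan.folds[0]
        assert test.size / table.X.shape[0] == pytest.approx(0.15, abs=0.02)

    def test_schemes_require_two_subjects(self):
        table = _toy_table(n_subjects=1)
        for scheme in ("between", "across"):
            with pytest.raises(ValueError, match="2 subjects"):
                build_folds(table, scheme)


class TestPreprocessor:
    def test_constant_column_centered_to_zero(self):
        X = np.column_stack([np.full(20, 5.0), np.random.default_rng(0).standard_normal(20)])
        params = fit_preprocessor(X)
        out = apply_preprocessor(params, X)
        # PCA of [0-column, varying column] keeps 1 component; reconstruct pre-PCA
        from statefeats.classify import _impute_scale_tanh

        pre = _impute_scale_tanh(X, params)
        np.testing.assert_allclose(pre[:, 0], 0.0)

    def test_tanh_bounds_all_values(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((50, 4)) * 100
        params = fit_preprocessor(X)
        from statefeats.classify import _impute_scale_tanh

        pre = _impute_scale_tanh(X, params)
        assert np.all(pre > -1) and np.all(pre < 1)

    def test_rank_one_matrix_keeps_single_component(self):
        u = np.random.default_rng(2).standard_normal(30)
        X = np.outer(u, [1.0, 2.0, -1.0])
        params = fit_preprocessor(X)
        assert params.pca.n_components_ == 1

    def test_isotropic_gaussian_needs_nine_of_ten_components(self):
        X = np.random.default_rng(3).standard_normal((10_000, 10))
        params = fit_preprocessor(X)
        # equal eigenvalues: smallest k with k/10 >= 0.9
        assert params.pca.n_components_ == 9

    def test_nan_imputed_with_train_column_mean(self):
        X = np.array([[1.0, np.nan], [3.0, 2.0], [5.0, 4.0], [7.0, 6.0]])
        params = fit_preprocessor(X)
        assert params.col_means[1] == pytest.approx(4.0)

    def test_all_nan_column_dropped_with_warning(self):
        X = np.random.default_rng(4).standard_normal((10, 3))
        X[:, 1] = np.nan
        with pytest.warns(RuntimeWarning, match="all-NaN"):
            params = fit_preprocessor(X)
        assert list(params.kept_cols) == [0, 2]

    def test_transform_is_frozen_and_repeatable(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((40, 6))
        params = fit_preprocessor(X)
        np.testing.assert_array_equal(
            apply_preprocessor(params, X), apply_preprocessor(params, X)
        )

    def test_no_leakage_from_test_rows(self):
        """Perturbing any test row never changes fitted parameters."""
        table = _toy_table(n_subjects=3, n_per_state=8, separation=0.5)
        plan = build_folds(table, "across", n_folds=4)
        train, test = plan.folds[0]
        params_a = fit_preprocessor(table.X[train])
        table.X[test] += 1e6  # corrupt the test rows in place
        params_b = fit_preprocessor(table.X[train])
        np.testing.assert_array_equal(params_a.medians, params_b.medians)
        np.testing.assert_array_equal(params_a.col_means, params_b.col_means)
        np.testing.assert_array_equal(params_a.pca.components_, params_b.pca.components_)

    def test_per_feature_mode_keeps_every_feature_block(self):
        table = _toy_table(n_subjects=3, n_per_state=6, n_feats=5, n_units=3)
        params = fit_preprocessor(
            table.X, pca_mode="per_feature", feature_blocks=table.feature_blocks()
        )
        assert len(params.per_feature_pcas) == 5
        out = apply_preprocessor(params, table.X)
        assert out.shape[0] == table.X.shape[0]

    def test_identical_unit_columns_reduce_to_one_component(self):
        rng = np.random.default_rng(6)
        col = rng.standard_normal(40)
        X = np.column_stack([col, col, rng.standard_normal(40)])
        meta = [("f0", "u0"), ("f0", "u1"), ("f1", "u0")]
        table = FeatureTable(X, np.array(["EC"] * 40), np.array(["s"] * 40),
                             np.arange(40), meta)
        params = fit_preprocessor(X, pca_mode="per_feature",
                                  feature_blocks=table.feature_blocks())
        blocks = dict(zip(["f0", "f1"], [p.n_components_ for _, p in params.per_feature_pcas]))
        assert blocks["f0"] == 1


class TestBalancedAccuracy:
    def test_perfect_and_constant_predictors(self):
        y = np.array(["A", "A", "B", "B"])
        assert balanced_accuracy(y, y) == 1.0
        assert balanced_accuracy(y, np.array(["A"] * 4)) == 0.5

    def test_hand_computed_per_class_recall(self):
        y_true = np.array(["A", "A", "A", "B"])
        y_pred = np.array(["A", "A", "B", "B"])
        assert balanced_accuracy(y_true, y_pred) == pytest.approx(5 / 6)

    def test_empty_or_mismatched_inputs_rejected(self):
        with pytest.raises(ValueError):
            balanced_accuracy(np.array([]), np.array([]))
        with pytest.raises(ValueError):
            balanced_accuracy(np.array(["A"]), np.array(["A", "B"]))


class TestRunClassification:
    def test_separable_blobs_reach_perfect_accuracy(self):
        rng = np.random.default_rng(7)
        rows, ys, subs, orders = [], [], [], []
        for s in range(4):
            k = 0
            for state, shift in (("EC", 0.0), ("EO", 10.0)):
                for _ in range(10):
                    rows.append(rng.standard_normal(3) * 0.1 + shift)
                    ys.append(state)
                    subs.append(f"s{s}")
                    orders.append(k)
                    k += 1
        meta = [(f"f{i}", "u0") for i in range(3)]
        table = FeatureTable(np.asarray(rows), np.asarray(ys), np.asarray(subs),
                             np.asarray(orders), meta)
        plan = build_folds(table, "across", n_folds=4)
        res = run_classification(table, plan, ClassifierConfig(), seed=0)
        assert res.pooled_accuracy == 1.0

    def test_fixed_seed_reproduces_results_bit_identically(self, small_freqbands_table):
        plan = build_folds(small_freqbands_table, "across", n_folds=4, seed=3)
        r1 = run_classification(small_freqbands_table, plan, seed=3)
        r2 = run_classification(small_freqbands_table, plan, seed=3)
        assert r1.fold_accuracies == r2.fold_accuracies
        assert r1.pooled_accuracy == r2.pooled_accuracy

    def test_select_classes_restricts_labels(self, small_freqbands_table):
        sub = select_classes(small_freqbands_table, ("EC", "EO"))
        assert set(sub.y) == {"EC", "EO"}
        assert sub.X.shape[0] == small_freqbands_table.X.shape[0] // 2


class TestPermutationNull:
    def test_four_class_null_centers_on_chance(self):
        rng = np.random.default_rng(8)
        y = np.repeat(["EC", "EO", "BSL", "VS"], 25)
        y_pred = rng.permutation(y)
        null = permutation_null(y, y_pred, n_permutations=500, seed=0)
        se = null.std(ddof=1) / np.sqrt(len(null))
        assert abs(null.mean() - 0.25) < 2 * se + 1e-3
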