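"""Dichotomization, split plans, preprocessing, permutation tests."""

import numpy as np
import pandas as pd
import pytest

from neurofuse import tabular
from neurofuse.tabular import (FeatureDef, FeatureSchema, Preprocessor,
                               SplitPlan, StratificationError, dichotomize,
                               make_split_plan, permutation_test,
                               phantom_schema)


class TestDichotomize:
    @pytest.mark.parametrize("value,expected", [(8, 0), (8.0, 0), (9, 1),
                                                (2, 0), (40, 1)])
    def test_los_strict_threshold(self, value, expected):
        assert dichotomize([value], "los")[0] == expected

    @pytest.mark.parametrize("value,expected", [(2, 0), (3, 1), (0, 0), (6, 1)])
    def test_mrs_strict_threshold(self, value, expected):
        assert dichotomize([value], "mrs")[0] == expected

    def test_absent_stays_absent(self):
        out = dichotomize([5.0, np.nan, 12.0], "los")
        assert np.isnan(out[1]) and out[0] == 0 and out[2] == 1

    def test_cohort_positive_fraction_reproduces_published_rate(self):
        # 282 of 1491 above 8 days -> 18.91%
        values = np.concatenate([np.full(282, 9.0), np.full(1209, 5.0)])
        labels = dichotomize(values, "los")
        assert round(100 * labels.mean(), 2) == 18.91

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            dichotomize([-1.0], "los")
        with pytest.raises(ValueError):
            dichotomize([7.0], "mrs")


class TestSplitPlan:
    def test_balanced_cohort_gives_exact_test_stratification(self):
        labels = np.array([0] * 50 + [1] * 50)
        plan = make_split_plan(labels, seed=0)
        test_labels = labels[plan.test_indices]
        assert len(plan.test_indices) == 20
        assert test_labels.sum() == 10

    def test_same_seed_identical_plan_json(self):
        labels = np.array([0] * 60 + [1] * 40)
        a = make_split_plan(labels, seed=3).to_json()
        b = make_split_plan(labels, seed=3).to_json()
        assert a == b

    def test_fold_arithmetic_and_class_balance(self):
        # 100 subjects, 20% prevalence: 80 remain, 16 validation per fold
        labels = np.array([0] * 80 + [1] * 20)
        plan = make_split_plan(labels, seed=1)
        cohort_prop = labels.mean()
        for fold in plan.folds:
            assert len(fold["val"]) == 16
            assert len(fold["train"]) == 64
            for part in ("train", "val"):
                got = labels[fold[part]].sum()
                want = cohort_prop * len(fold[part])
                assert abs(got - want) <= 1

    def test_test_set_disjoint_from_every_fold(self):
        labels = np.array([0, 1] * 30)
        plan = make_split_plan(labels, seed=2)
        test = set(plan.test_indices)
        for fold in plan.folds:
            assert not test & set(fold["train"])
            assert not test & set(fold["val"])
            assert not set(fold["train"]) & set(fold["val"])

    def test_json_round_trip_lossless(self):
        labels = np.array([0, 1] * 20)
        plan = make_split_plan(labels, seed=5)
        again = SplitPlan.from_json(plan.to_json())
        assert again == plan
        assert again.plan_hash == plan.plan_hash

    def test_tiny_class_rejected(self):
        with pytest.raises(StratificationError):
            make_split_plan(np.array([0] * 50 + [1, 1]), seed=0)


class TestPreprocessor:
    schema = FeatureSchema(
        clinical_features=[FeatureDef("x", "continuous"),
                           FeatureDef("flag", "binary"),
                           FeatureDef("med", "categorical", ["a", "b"])],
        idf_features=[FeatureDef("lesion_volume_cm3", "continuous")])

    def test_mean_imputation_from_train_only(self):
        train = pd.DataFrame({"x": [1.0, 2.0, np.nan], "flag": [0, 1, 0],
                              "med": ["a", "a", "b"],
                              "lesion_volume_cm3": [1.0, 2.0, 3.0]})
        test = pd.DataFrame({"x": [np.nan], "flag": [np.nan], "med": ["a"],
                             "lesion_volume_cm3": [np.nan]})
        pre = Preprocessor(self.schema).fit(train)
        assert pre.stats_["x"][0] == pytest.approx(1.5)
        out = pre.transform(test)
        # imputed to train mean then standardized -> exactly 0
        assert out[0, pre.column_names.index("x")] == pytest.approx(0.0)

    def test_training_columns_standardized(self):
        rng = np.random.default_rng(0)
        train = pd.DataFrame({"x": rng.normal(10, 3, 50),
                              "flag": rng.integers(0, 2, 50),
                              "med": ["a"] * 50,
                              "lesion_volume_cm3": rng.uniform(0, 5, 50)})
        pre = Preprocessor(self.schema).fit(train)
        out = pre.transform(train)
        col = out[:, pre.column_names.index("x")]
        assert col.mean() == pytest.approx(0.0, abs=1e-9)
        assert col.std() == pytest.approx(1.0, abs=1e-9)

    def test_absent_category_encodes_all_zero(self):
        train = pd.DataFrame({"x": [1.0, 2.0], "flag": [0, 1],
                              "med": ["a", "b"],
                              "lesion_volume_cm3": [1.0, 2.0]})
        pre = Preprocessor(self.schema).fit(train)
        test = pd.DataFrame({"x": [1.0], "flag": [0], "med": [np.nan],
                             "lesion_volume_cm3": [1.0]})
        out = pre.transform(test)
        block = [i for i, n in enumerate(pre.column_names)
                 if n.startswith("med=")]
        assert np.all(out[0, block] == 0.0)

    def test_unseen_category_encodes_all_zero_with_warning(self):
        train = pd.DataFrame({"x": [1.0, 2.0], "flag": [0, 1],
                              "med": ["a", "b"],
                              "lesion_volume_cm3": [1.0, 2.0]})
        pre = Preprocessor(self.schema).fit(train)
        test = pd.DataFrame({"x": [1.0], "flag": [0], "med": ["zzz"],
                             "lesion_volume_cm3": [1.0]})
        with pytest.warns(UserWarning, match="unseen"):
            out = pre.transform(test)
        block = [i for i, n in enumerate(pre.column_names)
                 if n.startswith("med=")]
        assert np.all(out[0, block] == 0.0)

    def test_zero_variance_guard(self):
        train = pd.DataFrame({"x": [2.0, 2.0, 2.0], "flag": [0, 1, 0],
                              "med": ["a", "a", "a"],
                              "lesion_volume_cm3": [1.0, 1.0, 1.0]})
        with pytest.warns(UserWarning, match="zero-variance"):
            pre = Preprocessor(self.schema).fit(train)
        out = pre.transform(train)
        assert np.isfinite(out).all()

    def test_missing_binary_assumed_false(self):
        train = pd.DataFrame({"x": [1.0, 2.0], "flag": [1, np.nan],
                              "med": ["a", "b"],
                              "lesion_volume_cm3": [1.0, 2.0]})
        pre = Preprocessor(self.schema).fit(train)
        out = pre.transform(train)
        assert out[1, pre.column_names.index("flag")] == 0.0

    def test_encoded_width_constant_across_folds(self, small_cohort):
        schema = phantom_schema()
        t = small_cohort.table
        widths = set()
        for lo in (0, 10, 20):
            pre = Preprocessor(schema).fit(t.iloc[lo:lo + 15])
            widths.add(pre.transform(t).shape[1])
        assert widths == {schema.clinical_width + schema.idf_width}

    def test_transform_before_fit_rejected(self):
        with pytest.raises(RuntimeError):
            Preprocessor(self.schema).transform(pd.DataFrame())


class TestPermutationTest:
    def test_identical_groups_give_p_one(self):
        a = np.array([1.0, 2.0, 3.0])
        assert permutation_test(a, a.copy(), n_perm=200, seed=0) == 1.0

    def test_fully_separated_groups_give_smallest_p(self):
        a = np.zeros(30)
        b = np.full(30, 10.0)
        p = permutation_test(a, b, n_perm=500, seed=0)
        assert p == pytest.approx(1 / 501, abs=1e-12)

    def test_categorical_statistic(self):
        a = np.array(["x"] * 20 + ["y"] * 5)
        b = np.array(["x"] * 5 + ["y"] * 20)
        assert permutation_test(a, b, kind="categorical", n_perm=300,
                                seed=0) < 0.05

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            permutation_test([1.0], [2.0], n_perm=0)
        with pytest.raises(ValueError):
            permutation_test([], [1.0])
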