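"""Split counts, kernel formulas and classifier behaviour on toy data."""

import math

import numpy as np
import pandas as pd
import pytest

from pcnradiomics.errors import InvalidArgumentError, StratificationError
from pcnradiomics.modeling import (SubtypeClassifier, cv_select,
                                   default_ann_grid, default_rf_grid,
                                   default_svm_grid, kernel_eval,
                                   stratified_split, train_ann, train_rf,
                                   train_svm)


def _blobs(rng, centers, n_per, sd=0.5):
    X, y = [], []
    for i, c in enumerate(centers):
        X.append(rng.normal(0, sd, size=(n_per, len(c))) + np.asarray(c))
        y += [f"class{i}"] * n_per
    return np.vstack(X), np.array(y)


class TestStratifiedSplit:
    def test_cohort_sizes_reproduce_printed_counts(self):
        labels = np.repeat(["SCA", "MCN", "IPMN"], [76, 40, 48])
        plan = stratified_split(labels, 0.7, seed=0)
        assert plan.per_class["SCA"] == (53, 23)
        assert plan.per_class["MCN"] == (28, 12)
        assert plan.per_class["IPMN"] == (34, 14)
        assert len(plan.train_idx) == 115 and len(plan.val_idx) == 49

    def test_ratio_one_empties_validation(self):
        labels = np.repeat(["a", "b", "c"], 5)
        plan = stratified_split(labels, 1.0, seed=0)
        assert len(plan.val_idx) == 0

    def test_seed_determinism_and_sensitivity(self):
        labels = np.repeat(["a", "b", "c"], 10)
        p1 = stratified_split(labels, 0.7, seed=4)
        p2 = stratified_split(labels, 0.7, seed=4)
        p3 = stratified_split(labels, 0.7, seed=5)
        np.testing.assert_array_equal(p1.train_idx, p2.train_idx)
        assert not np.array_equal(p1.train_idx, p3.train_idx)
        assert p1.per_class == p3.per_class

    def test_singleton_class_rejected(self):
        with pytest.raises(StratificationError):
            stratified_split(["a", "a", "b"], 0.7, seed=0)

    def test_split_partitions_every_case(self):
        labels = np.repeat(["a", "b", "c"], [7, 9, 11])
        plan = stratified_split(labels, 0.7, seed=1)
        merged = np.sort(np.concatenate([plan.train_idx, plan.val_idx]))
        np.testing.assert_array_equal(merged, np.arange(27))


class TestKernels:
    def test_gaussian_self_similarity_is_one(self):
        x = np.array([1.0, -2.0, 3.0])
        assert kernel_eval("gaussian", {"sigma": 0.7}, x, x) == pytest.approx(1.0)

    def test_anova_rbf_degree_one_self_value_is_dimension(self):
        x = np.arange(5.0)
        assert kernel_eval("anova_rbf", {"sigma": 1.0, "degree": 1}, x, x) \
            == pytest.approx(5.0)

    def test_each_kernel_matches_formula_oracle(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=4), rng.normal(size=4)
        sigma, degree = 0.37, 2
        d2 = sum((a - b) ** 2 for a, b in zip(x, y))
        oracle = {
            "linear": sum(a * b for a, b in zip(x, y)),
            "gaussian": math.exp(-sigma * d2),
            "laplacian": math.exp(-sigma * math.sqrt(d2)),
            "anova_rbf": sum(math.exp(-sigma * (a - b) ** 2)
                             for a, b in zip(x, y)) ** degree,
        }
        for kind, expected in oracle.items():
            got = kernel_eval(kind, {"sigma": sigma, "degree": degree}, x, y)
            assert got == pytest.approx(expected, abs=1e-12), kind

    def test_nonfinite_input_rejected(self):
        with pytest.raises(InvalidArgumentError):
            kernel_eval("gaussian", {}, [np.nan, 1.0], [0.0, 1.0])


class TestSvm:
    def test_linearly_separable_two_class(self):
        rng = np.random.default_rng(5)
        X, y = _blobs(rng, [(-3, -3), (3, 3)], 20, sd=0.3)
        clf = train_svm(X, y, kernel="linear", C=10)
        assert (clf.predict(X) == y).all()

    def test_three_well_separated_blobs_gaussian(self):
        rng = np.random.default_rng(6)
        X, y = _blobs(rng, [(0, 0), (10, 0), (0, 10)], 15, sd=1.0)
        clf = train_svm(X, y, kernel="gaussian", C=2)
        assert (clf.predict(X) == y).all()

    def test_standardization_statistics_come_from_training(self):
        rng = np.random.default_rng(7)
        X, y = _blobs(rng, [(-2, 0), (2, 0)], 15)
        clf = train_svm(X, y, kernel="linear", C=1)
        np.testing.assert_allclose(clf.mean_, X.mean(axis=0))
        np.testing.assert_allclose(clf.sd_, X.std(axis=0))


class TestRf:
    def test_single_informative_feature_drives_oob_to_zero(self):
        rng = np.random.default_rng(8)
        y = np.repeat(["a", "b"], 40)
        X = np.column_stack([(y == "a") + 0.1 * rng.normal(size=80),
                             rng.normal(size=80)])
        clf = train_rf(X, y, n_trees=300, mtry=1, seed=0)
        assert clf.extra["oob_trajectory"][-1] < 0.05

    def test_pure_noise_oob_near_majority_error(self):
        rng = np.random.default_rng(9)
        y = np.repeat(["a", "b", "c"], [30, 20, 10])
        X = rng.normal(size=(60, 5))
        clf = train_rf(X, y, n_trees=400, mtry=2, seed=0)
        majority_error = 1 - 30 / 60
        assert clf.extra["oob_error"] == pytest.approx(majority_error, abs=0.12)

    def test_trajectory_reported_per_tree_and_stabilizes(self):
        rng = np.random.default_rng(10)
        X, y = _blobs(rng, [(0, 0), (4, 4)], 40, sd=0.8)
        clf = train_rf(X, y, n_trees=500, mtry=1, seed=0)
        traj = clf.extra["oob_trajectory"]
        assert len(traj) == 500
        # smoothed error late in the run no worse than early
        assert np.mean(traj[-100:]) <= np.mean(traj[:100]) + 1e-9

    def test_mtry_exceeding_features_rejected(self):
        with pytest.raises(InvalidArgumentError):
            train_rf(np.zeros((10, 2)), np.repeat(["a", "b"], 5), mtry=3)


class TestAnn:
    def test_xor_is_learnable_with_two_hidden_units(self):
        X = np.array([[0.0, 0], [0, 1], [1, 0], [1, 1]])
        y = np.array(["a", "b", "b", "a"])
        clf = train_ann(X, y, hidden_units=2, weight_decay=0.0, seed=1,
                        restarts=5, maxiter=800)
        assert (clf.predict(X) == y).all()

    def test_huge_decay_collapses_predictions_to_priors(self):
        rng = np.random.default_rng(11)
        X, y = _blobs(rng, [(-2, 0), (2, 0), (0, 2)], 20)
        clf = train_ann(X, y, hidden_units=10, weight_decay=1e3, seed=0,
                        restarts=2)
        proba = clf.extra["predict_proba"](X)
        assert float(np.ptp(proba)) < 0.05

    def test_weight_norm_nonincreasing_in_decay(self):
        rng = np.random.default_rng(12)
        X, y = _blobs(rng, [(-2, 0), (2, 0)], 20)
        norms = [train_ann(X, y, hidden_units=5, weight_decay=d, seed=3,
                           restarts=3).extra["weight_norm"]
                 for d in (0.0, 0.1, 1.0)]
        assert norms[0] >= norms[1] >= norms[2]

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidArgumentError):
            train_ann(np.zeros((4, 2)), np.array(["a", "a", "b", "b"]),
                      hidden_units=0)


class TestCvSelect:
    def test_single_point_grid_returned(self):
        rng = np.random.default_rng(13)
        X, y = _blobs(rng, [(-2, 0), (2, 0), (0, 3)], 12)
        spec, table = cv_select("svm", [{"kernel": "linear", "C": 3}], X, y,
                                seed=0)
        assert spec == {"kernel": "linear", "C": 3}
        assert len(table) == 1

    def test_cv_table_bookkeeping(self):
        rng = np.random.default_rng(14)
        X, y = _blobs(rng, [(-2, 0), (2, 0), (0, 3)], 12)
        grid = [{"kernel": "linear", "C": c} for c in (1, 5)]
        _, table = cv_select("svm", grid, X, y, folds=4, seed=0)
        assert len(table) == len(grid)
        folds = table[[c for c in table.columns if c.startswith("fold")]]
        np.testing.assert_allclose(folds.mean(axis=1), table["mean"],
                                   atol=1e-12)

    def test_radial_structure_prefers_gaussian_kernel(self):
        """Classes on concentric rings: the gaussian kernel should win the
        grid over the linear one in >= 18/20 seeds."""
        wins = 0
        grid = [{"kernel": "linear", "C": 2}, {"kernel": "gaussian", "C": 2}]
        for s in range(20):
            rng = np.random.default_rng(200 + s)
            theta = rng.uniform(0, 2 * np.pi, 60)
            radius = np.repeat([1.0, 4.0], 30) + 0.3 * rng.normal(size=60)
            X = np.column_stack([radius * np.cos(theta),
                                 radius * np.sin(theta)])
            y = np.repeat(["inner", "outer"], 30)
            spec, _ = cv_select("svm", grid, X, y, seed=s)
            wins += spec["kernel"] == "gaussian"
        assert wins >= 18

    def test_rf_selection_by_oob_error(self):
        rng = np.random.default_rng(15)
        X, y = _blobs(rng, [(-2, 0), (2, 0)], 25)
        spec, table = cv_select("rf", default_rf_grid((100,), (1, 2)), X, y,
                                seed=0)
        assert set(table.columns) >= {"n_trees", "mtry", "oob_error"}
        assert spec in [{"n_trees": 100, "mtry": 1}, {"n_trees": 100, "mtry": 2}]

    def test_missing_class_in_fold_rejected(self):
        X = np.zeros((8, 2))
        y = np.array(["a"] * 6 + ["b"] * 2)
        with pytest.raises(StratificationError):
            cv_select("svm", [{"kernel": "linear", "C": 1}], X, y, folds=4)


class TestGrids:
    def test_grid_shapes_match_search_spaces(self):
        assert len(default_svm_grid()) == 4 * 10
        assert len(default_ann_grid()) == 6 * 6
        assert {g["weight_decay"] for g in default_ann_grid()} \
            == {2.0, 1.0, 0.5, 0.25, 0.125, 0.0625}
        assert {g["hidden_units"] for g in default_ann_grid()} \
            == set(range(10, 16))


class TestFacade:
    def test_fit_evaluate_and_summary(self):
        rng = np.random.default_rng(16)
        X, y = _blobs(rng, [(-3, 0), (3, 0), (0, 4)], 16, sd=0.6)
        df = pd.DataFrame(X, columns=["u", "v"])
        model = SubtypeClassifier(df, y, kind="svm",
                                  grid=[{"kernel": "linear", "C": 2}], seed=0)
        res = model.fit()
        cm, rep = res.evaluate(df, y)
        assert rep.overall_accuracy > 0.9
        text = res.summary()
        assert "SVM" in text and "overall accuracy" in text

    def test_from_dataframe_constructor(self):
        rng = np.random.default_rng(17)
        X, y = _blobs(rng, [(-3, 0), (3, 0)], 10)
        df = pd.DataFrame(X, columns=["u", "v"])
        df["label"] = y
        model = SubtypeClassifier.from_dataframe(df, kind="rf",
                                                 grid=[{"n_trees": 50,
                                                        "mtry": 1}], seed=0)
        res = model.fit()
        assert set(res.predict(df)) <= set(y)
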