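"""ICC robustness, correlation pruning, univariate tests and Boruta."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import gammaln

from pcnradiomics.boruta import boruta_select
from pcnradiomics.errors import (DegenerateTableError, InvalidArgumentError,
                                 InvalidLabelsError)
from pcnradiomics.screening import (ScreeningConfig, categorical_test,
                                    correlation_prune, icc_2_1, icc_screen,
                                    kruskal_wallis, screen_pipeline)


def _tables(arrays, names=None):
    names = names or [f"f{i}" for i in range(arrays[0].shape[1])]
    idx = [f"p{i}" for i in range(arrays[0].shape[0])]
    return [pd.DataFrame(a, index=idx, columns=names) for a in arrays]


class TestIcc:
    def test_identical_columns_give_icc_one(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=(50, 1))
        res = icc_screen(_tables([col, col, col]))
        assert res["f0"].estimate == pytest.approx(1.0)
        assert res["f0"].kept

    def test_independent_noise_rejected(self):
        rng = np.random.default_rng(1)
        res = icc_screen(_tables([rng.normal(size=(200, 1)) for _ in range(3)]))
        assert abs(res["f0"].estimate) < 0.15
        assert not res["f0"].kept

    def test_matches_anova_oracle_on_worked_example(self):
        """Six patients x three raters against pingouin's ICC2 estimate."""
        pingouin = pytest.importorskip("pingouin")
        data = np.array([[9.0, 2.0, 5.0], [6.0, 1.0, 3.0], [8.0, 4.0, 6.0],
                         [7.0, 1.0, 2.0], [10.0, 5.0, 6.0], [6.0, 2.0, 4.0]])
        long = pd.DataFrame({
            "targets": np.repeat(np.arange(6), 3),
            "raters": np.tile(np.arange(3), 6),
            "score": data.ravel(),
        })
        icc_table = pingouin.intraclass_corr(long, targets="targets",
                                             raters="raters", ratings="score")
        # two-way random effects, absolute agreement, single rater
        row = icc_table["Type"].isin(["ICC2", "ICC(A,1)"])
        expected = float(icc_table.loc[row, "ICC"].iloc[0])
        assert icc_2_1(data) == pytest.approx(expected, abs=1e-10)

    def test_mismatched_tables_rejected(self):
        a, b, c = _tables([np.zeros((4, 2))] * 3)
        with pytest.raises(InvalidArgumentError):
            icc_screen([a, b.iloc[:3], c])


class TestCorrelationPrune:
    def test_perfectly_correlated_pair_keeps_one(self):
        x = np.arange(20.0)
        table = pd.DataFrame({"a": x, "b": 2 * x + 1})
        assert len(correlation_prune(table)) == 1

    def test_orthogonal_features_all_survive(self):
        rng = np.random.default_rng(2)
        q, _ = np.linalg.qr(rng.normal(size=(40, 5)))
        table = pd.DataFrame(q, columns=list("abcde"))
        assert sorted(correlation_prune(table)) == list("abcde")

    def test_planted_collinear_block_collapses_to_one(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=100)
        cols = {f"block{i}": base + 0.05 * rng.normal(size=100) for i in range(3)}
        for i in range(7):
            cols[f"noise{i}"] = rng.normal(size=100)
        table = pd.DataFrame(cols)
        survivors = correlation_prune(table, 0.75)
        assert sum(s.startswith("block") for s in survivors) == 1
        # exhaustive pairwise verification of the survivor property
        corr = table[survivors].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        assert corr.max() <= 0.75

    def test_constant_feature_treated_as_uncorrelated(self):
        rng = np.random.default_rng(4)
        table = pd.DataFrame({"a": rng.normal(size=30),
                              "const": np.ones(30)})
        assert sorted(correlation_prune(table)) == ["a", "const"]


class TestKruskalWallis:
    def test_hand_ranked_example(self):
        """Groups (1,2,3 | 4,5,6 | 7,8,9): rank sums 6/15/24 give H = 7.2."""
        h, p = kruskal_wallis([1, 2, 3, 4, 5, 6, 7, 8, 9],
                              ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert h == pytest.approx(7.2)
        assert p == pytest.approx(float(stats.chi2.sf(7.2, 2)))

    def test_identical_values_give_h_zero(self):
        h, p = kruskal_wallis([5.0] * 9, ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert (h, p) == (0.0, 1.0)

    def test_large_shift_detected(self):
        rng = np.random.default_rng(5)
        vals = np.concatenate([rng.normal(0, 1, 20), rng.normal(0, 1, 20),
                               rng.normal(10, 1, 20)])
        groups = np.repeat(["a", "b", "c"], 20)
        _, p = kruskal_wallis(vals, groups)
        assert p < 0.001

    def test_type_i_error_near_alpha(self):
        """Null simulation: rejection rate at alpha=0.05 within binomial CI."""
        rng = np.random.default_rng(6)
        groups = np.repeat(["a", "b", "c"], 20)
        rejections = sum(
            kruskal_wallis(rng.normal(size=60), groups)[1] < 0.05
            for _ in range(1000))
        # 3-sigma binomial band around 0.05 for 1000 trials
        assert 0.029 <= rejections / 1000 <= 0.071


class TestCategoricalTest:
    def test_balanced_2x2_gives_zero_statistic(self):
        name, stat, p = categorical_test([[10, 10], [10, 10]])
        assert name == "chi-square"
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_fisher_2x2_equals_hypergeometric_tail_oracle(self):
        """p equals the exhaustive sum over tables with fixed margins whose
        probability does not exceed the observed table's."""
        table = np.array([[5, 1], [1, 8]])  # expected min < 5, n < 40
        name, _, p = categorical_test(table)
        assert name == "fisher"

        r0, c0, n = table[0].sum(), table[:, 0].sum(), table.sum()

        def log_prob(a):
            t = np.array([[a, r0 - a], [c0 - a, n - r0 - c0 + a]])
            if (t < 0).any():
                return None
            return float(gammaln(r0 + 1) + gammaln(n - r0 + 1)
                         + gammaln(c0 + 1) + gammaln(n - c0 + 1)
                         - gammaln(n + 1) - gammaln(t + 1).sum())

        obs = log_prob(table[0, 0])
        total = sum(np.exp(lp) for a in range(0, min(r0, c0) + 1)
                    if (lp := log_prob(a)) is not None and lp <= obs + 1e-9)
        assert p == pytest.approx(total, abs=1e-9)

    def test_tiny_expected_count_selects_fisher_branch(self):
        # one rare row in a 3x2 table: min expected < 1
        name, _, p = categorical_test([[1, 0], [20, 15], [18, 22]], seed=0)
        assert name == "fisher-mc"
        assert 0.0 < p <= 1.0

    def test_corrected_chi_square_branch_for_2x2(self):
        # n >= 40 with one expected count in [1, 5)
        table = [[4, 26], [5, 45]]
        name, _, _ = categorical_test(table)
        exp = np.outer(np.sum(table, 1), np.sum(table, 0)) / np.sum(table)
        assert exp.min() < 5 and np.sum(table) >= 40
        assert name == "corrected-chi-square"

    def test_degenerate_table_rejected(self):
        with pytest.raises(DegenerateTableError):
            categorical_test([[0, 0], [3, 4]])


class TestBoruta:
    def test_perfect_feature_confirmed_at_first_opportunity(self):
        rng = np.random.default_rng(7)
        y = np.repeat(["A", "B", "C"], 20)
        X = pd.DataFrame({
            "oracle": (y == "A").astype(float) + 2 * (y == "B"),
            "noise1": rng.normal(size=60),
            "noise2": rng.normal(size=60),
        })
        res = boruta_select(X, y=y, seed=0)
        assert res.status["oracle"] == "confirmed"
        # earliest iteration where binom.sf(it-1, it, .5) < alpha/m
        alpha_bonf = 0.01 / 3
        earliest = next(it for it in itertools.count(1)
                        if stats.binom.sf(it - 1, it, 0.5) < alpha_bonf)
        assert res.hits["oracle"] >= earliest

    def test_all_noise_rarely_confirms(self):
        """Null design: no feature confirmed in >= 9 of 10 seeded runs."""
        y = np.repeat(["A", "B", "C"], 20)
        clean = 0
        for s in range(10):
            rng = np.random.default_rng(100 + s)
            X = rng.normal(size=(60, 20))
            res = boruta_select(X, y=y, seed=s, max_iter=30, n_estimators=60)
            clean += len(res.confirmed) == 0
        assert clean >= 9

    def test_single_class_labels_rejected(self):
        with pytest.raises(InvalidLabelsError):
            boruta_select(np.zeros((10, 3)), y=np.repeat("A", 10))


class TestScreenPipeline:
    @staticmethod
    def _make_inputs(rng, informative=True, n_per_class=20):
        n = 3 * n_per_class
        labels = np.repeat(["SCA", "MCN", "IPMN"], n_per_class)
        shift = {"SCA": 0.0, "MCN": 1.5, "IPMN": 3.0}
        cols = {}
        for i in range(6):
            base = rng.normal(size=n)
            if informative and i < 2:
                base = base + np.array([shift[l] for l in labels])
            cols[f"f{i}"] = base
        idx = [f"p{i}" for i in range(n)]
        base_t = pd.DataFrame(cols, index=idx)
        tables = [base_t,
                  base_t + rng.normal(0, 0.05, size=base_t.shape),
                  base_t + rng.normal(0, 0.05, size=base_t.shape)]
        clinical = pd.DataFrame({
            "age": rng.normal(55, 10, n) + (informative * 1.0)
                   * np.array([shift[l] for l in labels]) * 4,
            "ca199": np.exp(rng.normal(2.5, 1.0, n)),
            "sex": rng.choice(["M", "F"], n),
        }, index=idx)
        return tables, clinical, labels

    def test_survivors_are_nested_and_planted_features_selected(self):
        rng = np.random.default_rng(8)
        tables, clinical, labels = self._make_inputs(rng)
        report = screen_pipeline(tables, clinical, labels,
                                 ScreeningConfig(seed=1))
        assert set(report.decorrelated) <= set(report.robust)
        assert set(report.significant) <= set(report.decorrelated)
        assert set(report.boruta.confirmed if report.boruta else []) \
            <= set(report.significant) | set(report.clinical_significant)
        assert {"f0", "f1"} <= set(report.significant)
        assert "age" in report.clinical_significant
        assert {"f0", "f1"} <= set(report.selected)

    def test_null_inputs_yield_empty_selection(self):
        rng = np.random.default_rng(9)
        tables, clinical, labels = self._make_inputs(rng, informative=False)
        report = screen_pipeline(tables, clinical, labels,
                                 ScreeningConfig(seed=1))
        assert len(report.selected) <= 1
        if report.boruta is None:
            assert any("Boruta skipped" in n for n in report.notes)
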