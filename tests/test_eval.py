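"""Evaluation statistics against independent oracles: exhaustive pair-count
AUC, closed-form kappa and chi-square, hypergeometric Fisher enumeration,
analytic binomial bootstrap, and cross-product odds ratios."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import cohen_kappa_score

from statinscope.evaluation import (
    EvalReport,
    binary_metrics,
    bootstrap_ci,
    cohens_kappa,
    contingency_test,
    cv_tune,
    logistic_or,
    split_train_test,
    weighted_multiclass_metrics,
)


def auc_pair_counting(y, s):
    """Exhaustive all-pairs AUC oracle: P(positive ranked above negative),
    ties credited 1/2."""
    y = np.asarray(y)
    s = np.asarray(s, dtype=float)
    pos = s[y == 1]
    neg = s[y == 0]
    wins = sum(float(p > q) + 0.5 * float(p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


class TestSplit:
    @pytest.mark.parametrize("n, n_train, n_test", [(1742, 1393, 349), (1000, 800, 200)])
    def test_split_sizes(self, n, n_train, n_test):
        ids = [f"p{i}" for i in range(n)]
        labels = [i % 2 for i in range(n)]
        plan = split_train_test(ids, labels, seed=0)
        assert len(plan.train_ids) == n_train
        assert len(plan.test_ids) == n_test
        assert set(plan.train_ids) | set(plan.test_ids) == set(ids)
        assert not set(plan.train_ids) & set(plan.test_ids)

    def test_stratification_within_one_unit(self):
        labels = [0] * 37 + [1] * 63
        ids = list(range(100))
        plan = split_train_test(ids, labels, seed=5)
        test_pos = sum(labels[i] for i in plan.test_ids)
        assert abs(test_pos - 0.2 * 63) <= 1

    def test_balanced_small_split(self):
        ids = list(range(10))
        labels = [0, 1] * 5
        plan = split_train_test(ids, labels, seed=1)
        assert sum(labels[i] for i in plan.test_ids) == 1

    def test_too_few_ids(self):
        with pytest.raises(ValueError, match="at least 5"):
            split_train_test([1, 2, 3], [0, 1, 0], seed=0)

    def test_deterministic(self):
        ids = list(range(50))
        labels = [i % 2 for i in ids]
        assert split_train_test(ids, labels, 3) == split_train_test(ids, labels, 3)


class _ThresholdModel:
    """Toy tunable model: scores by presence of a keyword; the 'good' grid
    point uses the separating keyword."""

    def __init__(self, keyword):
        self.keyword = keyword

    def fit(self, X, y):
        return self

    def score_texts(self, X):
        return np.array([float(self.keyword in x) for x in X])


class TestCvTune:
    def test_single_point_grid(self):
        X = [f"doc pos{i % 2}" for i in range(30)]
        y = np.array([i % 2 for i in range(30)])
        best, info = cv_tune(X, y, ["pos1"], _ThresholdModel, k=10, seed=0)
        assert best == "pos1"
        assert len(info["fold_aucs"][0]) == 10

    def test_separating_grid_point_wins(self):
        X = [("alpha " if i % 2 else "beta ") + f"doc{i}" for i in range(40)]
        y = np.array([i % 2 for i in range(40)])
        best, info = cv_tune(X, y, ["gamma", "alpha"], _ThresholdModel, k=5, seed=0)
        assert best == "alpha"
        assert info["best_index"] == 1

    def test_tie_prefers_first_grid_point(self):
        X = ["x"] * 12
        y = np.array([0, 1] * 6)
        best, _ = cv_tune(X, y, ["a", "b"], _ThresholdModel, k=3, seed=0)
        assert best == "a"

    def test_same_seed_same_folds(self):
        X = list("ab" * 10)
        y = np.array([0, 1] * 10)
        _, i1 = cv_tune(X, y, ["a"], _ThresholdModel, k=5, seed=2)
        _, i2 = cv_tune(X, y, ["a"], _ThresholdModel, k=5, seed=2)
        assert i1["fold_aucs"] == i2["fold_aucs"]

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            cv_tune(["a", "b"], [0, 1], ["a"], _ThresholdModel, k=10, seed=0)


class TestBinaryMetrics:
    def test_perfect_separation(self):
        row = binary_metrics([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])
        assert (row.precision, row.recall, row.f1, row.auc) == (1, 1, 1, 1)

    def test_total_ties_auc_half(self):
        assert binary_metrics([1, 0], [0.5, 0.5]).auc == 0.5

    def test_one_class_auc_nan(self):
        assert np.isnan(binary_metrics([1, 1], [0.4, 0.9]).auc)

    @pytest.mark.parametrize("seed", range(10))
    def test_auc_matches_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 41))
        y = rng.integers(0, 2, size=n)
        if len(set(y.tolist())) < 2:
            y[0], y[1] = 0, 1
        s = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)  # force ties
        assert binary_metrics(y, s).auc == pytest.approx(auc_pair_counting(y, s))

    @pytest.mark.parametrize("seed", range(8))
    def test_f1_between_min_and_mean_of_precision_recall(self, seed):
        rng = np.random.default_rng(100 + seed)
        y = rng.integers(0, 2, size=60)
        s = rng.random(60)
        row = binary_metrics(y, s)
        if row.precision + row.recall > 0:
            assert min(row.precision, row.recall) - 1e-12 <= row.f1
            assert row.f1 <= (row.precision + row.recall) / 2 + 1e-12


class TestWeightedMulticlass:
    def test_perfect_predictions_all_ones(self):
        truth = ["a"] * 5 + ["b"] * 3 + ["c"] * 2
        proba = np.zeros((10, 3))
        for i, t in enumerate(truth):
            proba[i, "abc".index(t)] = 1.0
        rep = weighted_multiclass_metrics(truth, proba, list("abc"))
        assert rep.weighted.precision == rep.weighted.recall == 1.0
        assert rep.weighted.f1 == rep.weighted.auc == 1.0

    def test_known_confusion_matches_hand_computation(self):
        # 3-class toy: truth a,a,a,b,b,c; predictions a,a,b,b,b,a
        truth = list("aaabbc")
        proba = np.array([
            [0.8, 0.1, 0.1],
            [0.7, 0.2, 0.1],
            [0.2, 0.7, 0.1],
            [0.1, 0.8, 0.1],
            [0.3, 0.6, 0.1],
            [0.9, 0.05, 0.05],
        ])
        rep = weighted_multiclass_metrics(truth, proba, list("abc"))
        # per-class precision by hand: a: 2/3, b: 2/3, c: 0
        assert rep.per_class["a"].precision == pytest.approx(2 / 3)
        assert rep.per_class["b"].precision == pytest.approx(2 / 3)
        assert rep.per_class["c"].precision == 0.0
        # recall by hand: a: 2/3, b: 1, c: 0
        hand_weighted_recall = (3 * (2 / 3) + 2 * 1.0 + 1 * 0.0) / 6
        assert rep.weighted.recall == pytest.approx(hand_weighted_recall)
        hand_weighted_precision = (3 * (2 / 3) + 2 * (2 / 3) + 1 * 0.0) / 6
        assert rep.weighted.precision == pytest.approx(hand_weighted_precision)

    def test_weights_sum_to_one(self):
        truth = list("aabb")
        proba = np.array([[0.6, 0.4], [0.7, 0.3], [0.2, 0.8], [0.1, 0.9]])
        rep = weighted_multiclass_metrics(truth, proba, list("ab"))
        supports = [r.n for r in rep.per_class.values()]
        assert sum(supports) == rep.n

    def test_single_category_rejected(self):
        with pytest.raises(ValueError, match="two categories"):
            weighted_multiclass_metrics(["a", "a"], np.ones((2, 1)), ["a"])


class TestBootstrap:
    @staticmethod
    def proportion(y, s):
        return float(np.mean(y))

    def test_perfectly_separated_auc_ci_degenerate(self):
        y = [1] * 20 + [0] * 20
        s = [0.9] * 20 + [0.1] * 20
        lo, hi = bootstrap_ci(lambda a, b: binary_metrics(a, b).auc, y, s,
                              B=200, seed=0)
        assert (lo, hi) == (1.0, 1.0)

    def test_proportion_ci_matches_analytic_binomial(self):
        rng = np.random.default_rng(42)
        n = 500
        y = (rng.random(n) < 0.3).astype(int)
        s = np.zeros(n)
        lo, hi = bootstrap_ci(self.proportion, y, s, B=2000, seed=1)
        phat = y.mean()
        a_lo = stats.binom.ppf(0.025, n, phat) / n
        a_hi = stats.binom.ppf(0.975, n, phat) / n
        assert abs(lo - a_lo) <= 0.02
        assert abs(hi - a_hi) <= 0.02

    def test_ci_width_shrinks_with_n(self):
        rng = np.random.default_rng(3)
        widths = []
        for n in (100, 400, 1600):
            y = (rng.random(n) < 0.3).astype(int)
            lo, hi = bootstrap_ci(self.proportion, y, np.zeros(n), B=500, seed=4)
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_same_seed_identical(self):
        y = [0, 1] * 25
        s = np.linspace(0, 1, 50)
        f = lambda a, b: binary_metrics(a, b).auc
        assert bootstrap_ci(f, y, s, B=200, seed=9) == bootstrap_ci(f, y, s, B=200, seed=9)

    def test_undefined_metric_errors(self):
        y = [1] * 10  # AUC undefined on every resample

        def metric(a, b):
            return binary_metrics(a, b).auc

        with pytest.raises(ValueError, match="undefined"):
            bootstrap_ci(metric, y, np.zeros(10), B=100, seed=0)

    def test_small_b_rejected(self):
        with pytest.raises(ValueError, match="B"):
            bootstrap_ci(self.proportion, [0, 1], [0, 1], B=10, seed=0)


class TestKappa:
    def test_identical_vectors(self):
        assert cohens_kappa(list("aabbc"), list("aabbc")) == 1.0

    def test_single_shared_label_perfect(self):
        assert cohens_kappa(["x"] * 5, ["x"] * 5) == 1.0

    def test_balanced_zero_agreement(self):
        assert cohens_kappa([0, 1], [1, 0]) == pytest.approx(-1.0)

    def test_matches_direct_formula_on_random_table(self):
        rng = np.random.default_rng(17)
        a = rng.choice(list("xyz"), size=60)
        b = rng.choice(list("xyz"), size=60)
        # direct evaluation from the 3x3 contingency table
        labels = sorted(set(a) | set(b))
        t = np.zeros((3, 3))
        for x, y in zip(a, b):
            t[labels.index(x), labels.index(y)] += 1
        p_o = np.trace(t) / 60
        p_e = float((t.sum(1) / 60) @ (t.sum(0) / 60))
        expected = (p_o - p_e) / (1 - p_e)
        assert cohens_kappa(a, b) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 3, size=80)
        b = np.where(rng.random(80) < 0.7, a, rng.integers(0, 3, size=80))
        assert cohens_kappa(a, b) == pytest.approx(cohen_kappa_score(a, b))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cohens_kappa([1, 2], [1])


class TestContingency:
    def test_gender_by_prescription_significant(self):
        # female/male by prescription present/absent in the source cohort
        res = contingency_test([[12179, 22055], [10054, 12242]])
        assert res.method == "chi2"
        assert res.p_value < 0.001

    def test_identical_row_proportions_null(self):
        res = contingency_test([[10, 20], [20, 40]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_chi2_matches_hand_computation(self):
        t = np.array([[20, 30], [40, 10]], dtype=float)
        exp = np.outer(t.sum(1), t.sum(0)) / t.sum()
        hand = float(((t - exp) ** 2 / exp).sum())
        res = contingency_test(t)
        assert res.statistic == pytest.approx(hand)

    def test_fisher_selected_and_matches_enumeration(self):
        table = [[2, 8], [9, 2]]  # expected counts < 5
        res = contingency_test(table)
        assert res.method == "fisher"
        # two-sided Fisher p by exhaustive hypergeometric enumeration
        a, b = table[0]
        c, d = table[1]
        n, r1, c1 = a + b + c + d, a + b, a + c
        p_obs = stats.hypergeom.pmf(a, n, r1, c1)
        p_total = sum(
            p for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1)
            if (p := stats.hypergeom.pmf(k, n, r1, c1)) <= p_obs * (1 + 1e-9)
        )
        assert res.p_value == pytest.approx(p_total)

    def test_non_2x2_small_expected_flagged(self):
        with pytest.warns(UserWarning, match="expected count"):
            res = contingency_test([[1, 2, 3], [2, 1, 4]])
        assert res.method == "chi2_small_expected"

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            contingency_test([[0, 0], [0, 0]])


class TestLogisticOr:
    def test_unadjusted_or_equals_cross_product(self):
        # outcome x covariate 2x2: a=40 (y=1,x=1), b=60, c=20, d=80
        y = np.array([1] * 40 + [1] * 60 + [0] * 20 + [0] * 80)
        x = np.array([1] * 40 + [0] * 60 + [1] * 20 + [0] * 80)
        out = logistic_or(y, pd.DataFrame({"x": x}))
        cross = (40 * 80) / (60 * 20)
        assert out.loc["x", "or_unadjusted"] == pytest.approx(cross, rel=1e-4)
        assert out.loc["x", "or_adjusted"] == pytest.approx(cross, rel=1e-4)

    def test_null_covariates_ci_covers_one(self):
        """With outcome independent of covariates, 95% CIs should cover OR=1
        in at least 90% of replicates."""
        rng = np.random.default_rng(11)
        covered = 0
        reps = 100
        for _ in range(reps):
            n = 2000
            y = rng.integers(0, 2, size=n)
            X = pd.DataFrame({"x1": rng.integers(0, 2, size=n)})
            out = logistic_or(y, X)
            covered += int(
                ((out["or_adjusted_lo"] <= 1) & (1 <= out["or_adjusted_hi"])).all()
            )
        assert covered / reps >= 0.90

    def test_constant_covariate_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, size=200)
        X = pd.DataFrame({"x": rng.integers(0, 2, size=200), "const1": np.ones(200)})
        with pytest.warns(UserWarning, match="constant covariate"):
            out = logistic_or(y, X)
        assert list(out.index) == ["x"]

    def test_perfect_separation_names_covariate(self):
        y = np.array([0] * 50 + [1] * 50)
        X = pd.DataFrame({"sep": y.astype(float)})
        with pytest.raises(ValueError, match="sep"):
            logistic_or(y, X)

    def test_nonbinary_outcome_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            logistic_or([0, 1, 2], pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
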