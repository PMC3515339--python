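import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from evosig.errors import UndefinedMetricError, ValidationError
from evosig.evaluation import (
    ConcordanceMatrix,
    binomial_sign_test,
    cluster_methods,
    operating_point,
    partial_auc,
    roc_auc,
    spearman_concordance,
)


def brute_force_auc(scores, labels):
    """Pair-counting oracle: concordant + half ties over P*N."""
    scores = np.asarray(scores)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


score_label_case = st.integers(0, 10_000).map(
    lambda seed: (
        np.random.default_rng(seed).choice([0.1, 0.25, 0.5, 0.7, 0.9], size=(n := int(np.random.default_rng(seed).integers(4, 60)))),
        np.r_[1, 0, np.random.default_rng(seed + 1).integers(0, 2, n - 2)],
    )
)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_chance(self):
        assert roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_interleaved_example(self):
        assert roc_auc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc([0.1, 0.2], [1, 1])

    @given(score_label_case)
    @settings(max_examples=80, deadline=None)
    def test_matches_pair_counting(self, case):
        scores, labels = case
        assert roc_auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )

    @given(score_label_case)
    @settings(max_examples=40, deadline=None)
    def test_negation_symmetry(self, case):
        scores, labels = case
        assert roc_auc(scores, labels) + roc_auc(-scores, labels) == pytest.approx(1.0)

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(5, 80))
            scores = rng.choice(np.linspace(0, 1, 7), size=n)
            labels = np.r_[1, 0, rng.integers(0, 2, n - 2)]
            assert roc_auc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )


class TestPartialAuc:
    def test_perfect_classifier(self):
        assert partial_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], 0.1) == pytest.approx(1.0)

    def test_uninformative_chance_level(self):
        # all ties: ROC is the diagonal; area to 0.1 is 0.005, ratio 0.05
        assert partial_auc([0.3] * 10, [1, 0] * 5, 0.1) == pytest.approx(0.05)

    def test_full_range_equals_auc(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = int(rng.integers(5, 60))
            scores = rng.choice(np.linspace(0, 1, 9), size=n)
            labels = np.r_[1, 0, rng.integers(0, 2, n - 2)]
            assert partial_auc(scores, labels, 1.0) == pytest.approx(
                roc_auc(scores, labels), abs=1e-9
            )

    def test_matches_fine_grid_integration(self):
        from sklearn.metrics import roc_curve as sk_roc

        rng = np.random.default_rng(7)
        for _ in range(10):
            n = int(rng.integers(10, 80))
            scores = rng.normal(size=n)
            labels = np.r_[1, 0, rng.integers(0, 2, n - 2)]
            fpr, tpr, _ = sk_roc(labels, scores, drop_intermediate=False)
            grid = np.linspace(0, 0.1, 20001)
            ref = np.trapezoid(np.interp(grid, fpr, tpr), grid) / 0.1
            assert partial_auc(scores, labels, 0.1) == pytest.approx(ref, abs=1e-3)


class TestOperatingPoint:
    def test_perfect_classifier(self):
        op = operating_point([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], 0.98)
        assert op.specificity == 1.0
        assert op.precision == 1.0

    def test_all_ties_full_sensitivity(self):
        op = operating_point([0.5] * 8, [1, 1, 0, 0, 0, 0, 0, 0], 1.0)
        assert op.specificity == 0.0
        assert op.precision == pytest.approx(0.25)  # prevalence

    def test_matches_exhaustive_threshold_scan(self):
        scores = np.array([0.9, 0.7, 0.7, 0.5, 0.3, 0.1])
        labels = np.array([1, 0, 1, 1, 0, 0])
        for target in (0.5, 0.66, 0.9, 1.0):
            op = operating_point(scores, labels, target)
            # oracle: scan all unique thresholds high to low
            best = None
            for thr in np.unique(scores)[::-1]:
                pred = scores >= thr
                tp = int((pred & (labels == 1)).sum())
                if tp / 3 >= target:
                    fp = int((pred & (labels == 0)).sum())
                    best = (thr, 1 - fp / 3, tp / (tp + fp))
                    break
            assert (op.threshold, op.specificity, op.precision) == pytest.approx(best)


class TestSignTest:
    def test_clean_sweep(self):
        res = binomial_sign_test(np.arange(10) + 1.0, np.arange(10))
        assert res.n_wins == 10
        assert res.p_value == pytest.approx(2.0 ** -10, rel=1e-12)

    def test_seven_of_ten(self):
        a = np.array([1.0] * 7 + [0.0] * 3)
        b = np.array([0.0] * 7 + [1.0] * 3)
        res = binomial_sign_test(a, b)
        assert res.p_value == pytest.approx(176.0 / 1024.0, rel=1e-12)

    def test_ties_excluded(self):
        a = np.r_[np.ones(5), np.zeros(5), np.full(400, 0.5)]
        b = np.r_[np.zeros(5), np.ones(5), np.full(400, 0.5)]
        res = binomial_sign_test(a, b)
        assert res.n_ties == 400
        assert res.n_informative == 10
        assert res.p_value == pytest.approx(float(stats.binom.sf(4, 10, 0.5)), rel=1e-12)

    def test_all_ties_undefined(self):
        res = binomial_sign_test([1.0, 2.0], [1.0, 2.0])
        assert res.p_value is None

    @given(st.integers(1, 40), st.integers(0, 40))
    @settings(max_examples=60, deadline=None)
    def test_matches_exact_binomial_tail(self, n, wins_raw):
        wins = min(wins_raw, n)
        a = np.r_[np.ones(wins), np.zeros(n - wins)]
        b = np.r_[np.zeros(wins), np.ones(n - wins)]
        res = binomial_sign_test(a, b)
        from math import comb

        tail = sum(comb(n, k) for k in range(wins, n + 1)) / 2.0 ** n
        assert res.p_value == pytest.approx(tail, abs=1e-12)


class FakeFam:
    def __init__(self, scores):
        self.scores = scores
        self.family_id = "f"


def fake_family(**arrays):
    from evosig.alignment import ScoreVector

    return FakeFam({k: ScoreVector(k, np.asarray(v, float)) for k, v in arrays.items()})


class TestConcordance:
    def test_self_correlation_one(self):
        fam = fake_family(a=[1.0, 2.0, 3.0, 2.5])
        c = spearman_concordance([fam], ["a", "a"])
        np.testing.assert_allclose(c.mean, 1.0)

    def test_negation_minus_one(self):
        fam = fake_family(a=[1.0, 2.0, 3.0, 2.5], b=[-1.0, -2.0, -3.0, -2.5])
        c = spearman_concordance([fam], ["a", "b"])
        assert c.mean[0, 1] == pytest.approx(-1.0)

    def test_hand_rank_example(self):
        fam = fake_family(a=[1.0, 2.0, 3.0, 4.0], b=[1.0, 3.0, 2.0, 4.0])
        c = spearman_concordance([fam], ["a", "b"])
        assert c.mean[0, 1] == pytest.approx(0.8)

    def test_too_few_shared_positions_skipped(self):
        fam = fake_family(a=[1.0, 2.0, np.nan, np.nan], b=[1.0, np.nan, 2.0, 3.0])
        c = spearman_concordance([fam], ["a", "b"])
        assert np.isnan(c.mean[0, 1])
        assert c.n_families[0, 1] == 0

    def test_averaged_over_families(self):
        f1 = fake_family(a=[1.0, 2.0, 3.0], b=[1.0, 2.0, 3.0])
        f2 = fake_family(a=[1.0, 2.0, 3.0], b=[3.0, 2.0, 1.0])
        c = spearman_concordance([f1, f2], ["a", "b"])
        assert c.mean[0, 1] == pytest.approx(0.0)
        assert c.sd[0, 1] == pytest.approx(1.0)


class TestClusterMethods:
    def _matrix(self, methods, mean):
        K = len(methods)
        return ConcordanceMatrix(
            methods=methods,
            mean=np.asarray(mean, float),
            sd=np.zeros((K, K)),
            n_families=np.ones((K, K), dtype=int),
        )

    def test_correlated_pair_merges_first(self):
        c = self._matrix(
            ["a", "b", "c"],
            [[1.0, 0.95, 0.1], [0.95, 1.0, 0.1], [0.1, 0.1, 1.0]],
        )
        dendro = cluster_methods(c)
        first = dendro.linkage_matrix[0]
        assert {int(first[0]), int(first[1])} == {0, 1}  # a and b

    def test_uncorrelated_methods_equal_heights(self):
        c = self._matrix(["a", "b", "c"], np.eye(3))
        dendro = cluster_methods(c)
        np.testing.assert_allclose(dendro.linkage_matrix[:, 2], 1.0)

    def test_average_linkage_hand_trace(self):
        # 4 methods; a-b very close (0.1), c-d close (0.2),
        # cross distances 0.8/0.9/1.0/0.7 -> average linkage merges
        # {a,b} then {c,d}, then joins at mean cross distance 0.85
        d = np.array(
            [
                [0.0, 0.1, 0.8, 0.9],
                [0.1, 0.0, 1.0, 0.7],
                [0.8, 1.0, 0.0, 0.2],
                [0.9, 0.7, 0.2, 0.0],
            ]
        )
        c = self._matrix(list("abcd"), 1.0 - d)
        dendro = cluster_methods(c)
        Z = dendro.linkage_matrix
        assert Z[0, 2] == pytest.approx(0.1)
        assert Z[1, 2] == pytest.approx(0.2)
        assert Z[2, 2] == pytest.approx((0.8 + 0.9 + 1.0 + 0.7) / 4)

    def test_newick_contains_all_methods(self):
        c = self._matrix(["beta", "alpha", "gamma"], np.eye(3))
        nwk = cluster_methods(c).to_newick()
        for m in ("alpha", "beta", "gamma"):
            assert m in nwk
        assert nwk.endswith(";")
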