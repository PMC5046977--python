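import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import epitoc as e


class TestAgeAdjustedAssociation:
    def test_noiseless_coefficient(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 40)
        age = rng.uniform(20, 80, 40)
        rep = e.age_adjusted_association(2 * x, x, age)
        assert rep.coefficient == pytest.approx(2.0, abs=1e-10)
        assert rep.p_two_sided < 1e-12

    def test_five_point_closed_form(self):
        # hand-computed two-covariate OLS via normal equations
        y = np.array([1.0, 2.0, 2.5, 4.0, 5.5])
        x = np.array([0.0, 1.0, 1.5, 3.0, 4.0])
        age = np.array([30.0, 40.0, 50.0, 60.0, 70.0])
        X = np.column_stack([np.ones(5), x, age])
        coef = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ coef
        s2 = resid @ resid / 2
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        rep = e.age_adjusted_association(y, x, age)
        assert rep.coefficient == pytest.approx(coef[1], rel=1e-10)
        assert rep.t == pytest.approx(coef[1] / se, rel=1e-8)
        assert rep.n == 5

    def test_null_x_p_uniform(self):
        """With y depending only on age, the x p-value is U(0,1) (KS check)."""
        rng = np.random.default_rng(123)
        ps = []
        for _ in range(200):
            age = rng.uniform(20, 80, 30)
            y = 0.01 * age + rng.normal(0, 1, 30)
            x = rng.normal(0, 1, 30)
            ps.append(e.age_adjusted_association(y, x, age).p_two_sided)
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_one_sided_sign_convention(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 30)
        age = rng.uniform(20, 80, 30)
        y = -x + rng.normal(0, 0.1, 30)
        rep = e.age_adjusted_association(y, x, age, hypothesized_sign=1)
        assert rep.p_one_sided > 0.5
        rep2 = e.age_adjusted_association(y, x, age, hypothesized_sign=-1)
        assert rep2.p_one_sided == pytest.approx(rep2.p_two_sided / 2)

    def test_collinear_x_age_error(self):
        age = np.linspace(20, 80, 20)
        with pytest.raises(e.InputError, match="collinear"):
            e.age_adjusted_association(np.random.default_rng(0).normal(size=20),
                                       2 * age + 1, age)

    def test_adding_age_multiple_preserves_x_inference(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 50)
        age = rng.uniform(20, 80, 50)
        y = 0.5 * x + rng.normal(0, 1, 50)
        a = e.age_adjusted_association(y, x, age)
        b = e.age_adjusted_association(y + 0.03 * age, x, age)
        assert b.coefficient == pytest.approx(a.coefficient, rel=1e-8)
        assert b.p_two_sided == pytest.approx(a.p_two_sided, rel=1e-6)


class TestOneTailedWilcoxon:
    def test_exact_unpaired_enumeration(self):
        # {4,5,6} vs {1,2,3}: most extreme of C(6,3)=20 orderings
        res = e.one_tailed_wilcoxon([4, 5, 6], [1, 2, 3], alternative="greater")
        assert res.p_value == pytest.approx(0.05)
        assert res.method == "exact"
        # same data phrased as "b greater"
        res2 = e.one_tailed_wilcoxon([1, 2, 3], [4, 5, 6], alternative="less")
        assert res2.p_value == pytest.approx(0.05)

    def test_identical_groups_not_significant(self):
        res = e.one_tailed_wilcoxon([1.0, 2, 3, 4], [1.0, 2, 3, 4], alternative="greater")
        assert res.p_value >= 0.5

    def test_paired_sign_flip_enumeration(self):
        res = e.one_tailed_wilcoxon(
            [2, 4, 7, 11, 16], [1, 2, 3, 4, 5], paired=True, alternative="greater"
        )
        assert res.p_value == pytest.approx(1 / 32)
        assert res.method == "exact"

    def test_exact_close_to_normal_at_n20(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            pooled = rng.permutation(np.arange(20, dtype=float))
            a, b = pooled[:10], pooled[10:]
            exact = e.one_tailed_wilcoxon(a, b, alternative="greater")
            assert exact.method == "exact"
            # push past the exact threshold by duplicating a value (tie)
            approx = e.one_tailed_wilcoxon(np.append(a, a[0]), b, alternative="greater")
            assert approx.method == "normal"
        # direct check of the two paths on one instance
        a = np.arange(10, dtype=float)
        b = np.arange(10, dtype=float) + 0.5
        p_exact = e.one_tailed_wilcoxon(a, b, alternative="greater").p_value
        p_norm = sps.mannwhitneyu(a, b, alternative="greater", method="asymptotic").pvalue
        assert abs(p_exact - p_norm) < 0.02

    def test_age_adjustment_residualizes(self):
        rng = np.random.default_rng(1)
        age_a = rng.uniform(60, 80, 30)
        age_b = rng.uniform(20, 40, 30)
        slope = 0.01
        a = slope * age_a + rng.normal(0, 0.01, 30)
        b = slope * age_b + rng.normal(0, 0.01, 30)
        raw = e.one_tailed_wilcoxon(a, b, alternative="greater")
        adj = e.one_tailed_wilcoxon(a, b, alternative="greater", age=(age_a, age_b))
        assert raw.p_value < 0.01            # trivial age-driven difference
        assert adj.p_value > 0.05            # removed by residualization
        assert adj.p_value_unadjusted == pytest.approx(raw.p_value)

    def test_unmatched_pair_ids_error(self):
        with pytest.raises(e.InputError, match="p3"):
            e.one_tailed_wilcoxon(
                [1, 2], [3, 4], paired=True,
                pair_ids=(["p1", "p2"], ["p1", "p3"]),
            )

    def test_pair_ids_reorder(self):
        res = e.one_tailed_wilcoxon(
            [5, 1], [0, 4], paired=True, alternative="greater",
            pair_ids=(["p1", "p2"], ["p2", "p1"]),
        )
        # after reordering, differences are (5-4, 1-0) = (1, 1): both positive
        assert res.statistic == 3.0


def _auc_brute(pos, neg):
    wins = 0.0
    for p in pos:
        for n in neg:
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        rep = e.roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert rep.auc == 1.0
        assert rep.ci_low <= rep.auc <= rep.ci_high

    def test_tie_counted_half(self):
        rep = e.roc_auc([0.9, 0.5, 0.5, 0.1], [1, 1, 0, 0])
        assert rep.auc == pytest.approx(0.875)

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            m, n = rng.integers(3, 100, 2)
            scores = np.round(rng.normal(0, 1, m + n), 1)  # induce ties
            labels = np.concatenate([np.ones(m), np.zeros(n)])
            rep = e.roc_auc(scores, labels)
            assert rep.auc == pytest.approx(
                _auc_brute(scores[:m], scores[m:]), abs=1e-12
            )

    def test_null_auc_near_half(self):
        """Random scores vs random labels: AUC concentrates at 1/2 (sd of a
        null AUC at n=200 is ~0.04, so essentially all replicates fall in
        0.5 +/- 0.1 and the mean is much tighter)."""
        rng = np.random.default_rng(0)
        aucs = np.array([
            e.roc_auc(rng.normal(size=200), rng.integers(0, 2, 200)).auc
            for _ in range(20)
        ])
        assert (np.abs(aucs - 0.5) < 0.1).sum() >= 18
        assert abs(aucs.mean() - 0.5) < 0.03

    def test_bootstrap_ci_deterministic_and_sane(self):
        rng = np.random.default_rng(4)
        scores = np.concatenate([rng.normal(1, 1, 40), rng.normal(0, 1, 40)])
        labels = np.concatenate([np.ones(40), np.zeros(40)])
        r1 = e.roc_auc(scores, labels, ci_method="bootstrap", seed=7)
        r2 = e.roc_auc(scores, labels, ci_method="bootstrap", seed=7)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)
        assert r1.ci_low <= r1.auc <= r1.ci_high
        d = e.roc_auc(scores, labels)
        assert abs(d.ci_low - r1.ci_low) < 0.1

    def test_one_class_errors(self):
        with pytest.raises(e.InputError):
            e.roc_auc([1.0, 2.0], [1, 1])


class TestAgeMatchPairs:
    def _pheno(self, ages, groups, ids=None):
        ids = ids or [f"s{i}" for i in range(len(ages))]
        return e.SampleSheet(
            pd.DataFrame({"age": ages, "group": groups},
                         index=pd.Index(ids, name="sample_id"))
        )

    def test_two_by_two(self):
        ph = self._pheno([50, 60, 51, 59], ["A", "A", "B", "B"],
                         ids=["a1", "a2", "b1", "b2"])
        pairs = e.age_match_pairs(ph, "A", "B", tolerance=2)
        assert sorted(pairs) == [("a1", "b1"), ("a2", "b2")]

    def test_zero_tolerance_no_exact_ties(self):
        ph = self._pheno([50, 51], ["A", "B"])
        assert e.age_match_pairs(ph, "A", "B", tolerance=0) == []

    def test_tie_break_by_sample_id(self):
        ph = self._pheno([50, 49, 51], ["A", "B", "B"], ids=["a1", "b1", "b2"])
        pairs = e.age_match_pairs(ph, "A", "B", tolerance=5)
        assert pairs == [("a1", "b1")]

    def test_deterministic_and_within_tolerance(self):
        rng = np.random.default_rng(0)
        ages = rng.uniform(20, 80, 40)
        groups = ["A"] * 20 + ["B"] * 20
        ph = self._pheno(ages, groups)
        p1 = e.age_match_pairs(ph, "A", "B", tolerance=3)
        p2 = e.age_match_pairs(ph, "A", "B", tolerance=3)
        assert p1 == p2
        for ia, ib in p1:
            assert abs(ph.age.loc[ia] - ph.age.loc[ib]) <= 3


class TestCompareSignificanceCounts:
    def test_no_discordant_types(self):
        assert e.compare_significance_counts([True, False], [True, False]) == 1.0

    def test_six_a_only(self):
        p = e.compare_significance_counts([True] * 6 + [False] * 9, [False] * 15)
        assert p == pytest.approx(0.015625)

    def test_matches_binomial_tail_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = rng.random(15) < 0.4
            b = rng.random(15) < 0.3
            n_a = int(np.sum(a & ~b))
            n_d = n_a + int(np.sum(~a & b))
            expect = 1.0 if n_d == 0 else sum(
                sps.binom.pmf(k, n_d, 0.5) for k in range(n_a, n_d + 1)
            )
            assert e.compare_significance_counts(a, b) == pytest.approx(expect)
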