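import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tmescore import (
    GeneSetCollection,
    chisq_contingency,
    compare_groups,
    correlate,
    distance_correlation,
    ora,
    score_response_association,
)

from ._oracles import distance_correlation_brute


class TestCompareGroups:
    def test_exact_wilcoxon_separated_triples(self):
        res = compare_groups([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3,
                             force_method="wilcoxon")
        assert res.method == "wilcoxon"
        assert res.p == pytest.approx(0.1, abs=1e-12)  # 2 / C(6,3)

    def test_identical_groups_kruskal_null(self):
        res = compare_groups([5.0] * 9, ["a", "b", "c"] * 3, force_method="kruskal_wallis")
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_routing_normal_vs_skewed(self):
        # quantile-constructed samples: exactly normal / grossly skewed shapes
        probs = (np.arange(20) + 0.5) / 20
        normal_shape = stats.norm.ppf(probs)
        skewed_shape = stats.expon.ppf(probs) ** 3
        labels = np.array(["a"] * 20 + ["b"] * 20)
        normal = np.concatenate([normal_shape, normal_shape + 0.3])
        assert compare_groups(normal, labels).method == "t"
        skewed = np.concatenate([skewed_shape, skewed_shape * 1.1])
        assert compare_groups(skewed, labels).method == "wilcoxon"
        three = np.array(["a"] * 20 + ["b"] * 20 + ["c"] * 20)
        normal3 = np.concatenate([normal_shape, normal_shape + 0.3, normal_shape - 0.3])
        assert compare_groups(normal3, three).method == "anova"
        skewed3 = np.concatenate([skewed_shape, skewed_shape * 1.1, skewed_shape * 0.9])
        assert compare_groups(skewed3, three).method == "kruskal_wallis"

    def test_small_group_named_in_error(self):
        with pytest.raises(ValueError, match="'b'"):
            compare_groups([1.0, 2.0, 3.0, 4.0], ["a", "a", "a", "b"])

    def test_t_type_one_error_nominal(self):
        """t-test on same-distribution groups rejects at ~ 5%."""
        rng = np.random.default_rng(123)
        x = rng.normal(size=(500, 30))
        p = stats.ttest_ind(x[:, :15], x[:, 15:], axis=1).pvalue
        rate = float(np.mean(p < 0.05))
        assert 0.03 <= rate <= 0.07


class TestChisq:
    def test_diagonal_table(self):
        chi2, df, p = chisq_contingency([[10, 0], [0, 10]])
        assert chi2 == pytest.approx(20.0, abs=1e-10)
        assert df == 1

    def test_independent_table_null(self):
        rows = np.array([2.0, 3.0])
        cols = np.array([5.0, 7.0, 11.0])
        chi2, df, _ = chisq_contingency(np.outer(rows, cols))
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert df == 2

    def test_small_expected_count_warns(self):
        with pytest.warns(UserWarning, match="expected count"):
            chisq_contingency([[2, 1], [1, 3]])

    def test_transpose_invariance(self):
        tab = [[12, 7, 9], [4, 16, 8]]
        a = chisq_contingency(tab)
        b = chisq_contingency(np.transpose(tab))
        assert a[0] == pytest.approx(b[0], abs=1e-10)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chisq_contingency([[0, 0], [3, 4]])


class TestCorrelate:
    def test_perfect_linear(self, rng):
        x = rng.normal(size=20)
        r, p = correlate(x, 2 * x + 1)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert p < 1e-10

    def test_quadratic_seen_by_distance_not_pearson(self):
        x = np.array([-4.0, -3.0, -2.0, -1.0, 1.0, 2.0, 3.0, 4.0])
        y = x**2
        r, _ = correlate(x, y, method="pearson")
        assert r == pytest.approx(0.0, abs=1e-12)
        dcor, none = correlate(x, y, method="distance")
        assert none is None
        assert dcor > 0.3
        assert dcor == pytest.approx(distance_correlation_brute(x.tolist(), y.tolist()),
                                     abs=1e-10)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(5):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            assert distance_correlation(x, y) == pytest.approx(
                distance_correlation_brute(x.tolist(), y.tolist()), abs=1e-10
            )

    def test_independent_pairs_near_zero(self):
        """Small-sample bias of the plug-in estimator, but clearly below dependence.

        The double-centered plug-in coefficient has a positive O(n^-1/2)
        bias under independence (~0.24 at n=50 by simulation); its square
        stays below 0.15 and both sit far under the value seen for even a
        moderately dependent pair.
        """
        rng = np.random.default_rng(9)
        vals = np.array(
            [distance_correlation(rng.normal(size=50), rng.normal(size=50))
             for _ in range(100)]
        )
        assert np.mean(vals) < 0.30
        assert np.mean(vals**2) < 0.15
        x = rng.normal(size=50)
        assert distance_correlation(x, x + rng.normal(size=50)) > 0.5

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            correlate(np.ones(5), np.arange(5.0))


class TestOra:
    def test_full_overlap_exact_p(self):
        universe = [f"g{i}" for i in range(10)]
        sets = GeneSetCollection({"s": universe[:5]})
        out = ora(universe[:5], sets, universe)
        assert out.loc["s", "overlap"] == 5
        assert out.loc["s", "p"] == pytest.approx(1 / 252, abs=1e-12)

    def test_no_hits_gives_unit_p(self):
        universe = [f"g{i}" for i in range(8)]
        sets = GeneSetCollection({"a": universe[:3], "b": universe[3:6]})
        out = ora([], sets, universe)
        assert (out["p"] == 1.0).all()

    def test_overlap_at_expectation_not_enriched(self):
        universe = [f"g{i}" for i in range(100)]
        sets = GeneSetCollection({"s": universe[:20]})
        # 10 hits drawn proportionally: 2 in-set (expectation = 10*20/100)
        hits = universe[:2] + universe[20:28]
        out = ora(hits, sets, universe)
        assert out.loc["s", "p"] >= 0.5

    def test_stray_hit_listed(self):
        with pytest.raises(ValueError, match="gX"):
            ora(["gX"], GeneSetCollection({"s": ["g1"]}), ["g1", "g2"])

    def test_matches_hypergeometric_monte_carlo(self):
        """Tail p within Monte-Carlo error of 1e6 hypergeometric draws."""
        rng = np.random.default_rng(42)
        big_n, m, n_draw = 60, 18, 12
        universe = [f"g{i}" for i in range(big_n)]
        sets = GeneSetCollection({"s": universe[:m]})
        hits = universe[:6] + universe[m : m + n_draw - 6]
        out = ora(hits, sets, universe)
        draws = rng.hypergeometric(m, big_n - m, n_draw, size=1_000_000)
        mc_p = np.mean(draws >= 6)
        sd = np.sqrt(mc_p * (1 - mc_p) / 1_000_000)
        assert abs(out.loc["s", "p"] - mc_p) < 3 * sd


class TestScoreResponse:
    @staticmethod
    def _scored(rng, n=100, slope=2.0):
        score = rng.normal(size=n)
        p = 1.0 / (1.0 + np.exp(-slope * score))
        response = np.where(rng.random(n) < p, "CR/PR", "SD/PD")
        return (
            pd.DataFrame(
                {
                    "tme_score": score,
                    "score_group": np.where(score > np.median(score), "high", "low"),
                },
                index=[f"s{i}" for i in range(n)],
            ),
            response,
        )

    def test_responders_score_higher(self):
        detected = []
        for seed in range(10):
            scored, response = self._scored(np.random.default_rng(seed))
            rep = score_response_association(scored, response)
            detected.append(rep["wilcoxon_p"] < 0.05)
        assert np.median(detected) == 1.0

    def test_single_category_rejected(self, rng):
        scored, _ = self._scored(rng)
        with pytest.raises(ValueError):
            score_response_association(scored, np.array(["CR/PR"] * len(scored)))

    def test_report_is_complete(self, rng):
        scored, response = self._scored(rng)
        rep = score_response_association(scored, response)
        assert {"wilcoxon_p", "chi_square", "chi_square_p", "contingency"} <= set(rep)
        assert rep["contingency"].to_numpy().sum() == len(scored)
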