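import numpy as np
import pandas as pd
import pytest

from tmescore import (
    cox_univariate,
    dichotomize_score,
    filter_prognostic,
    median_cutpoint,
    pc1_signature,
    tme_score,
)
from tmescore.scoring import (
    DegenerateCovariateError,
    DegenerateScoreError,
    NoEventsError,
)


def _surv(rng, n, beta=0.0, x=None):
    if x is None:
        x = rng.standard_normal(n)
    t = rng.exponential(1.0 / np.exp(beta * x)) + 1e-9
    e = np.ones(n, dtype=int)
    return x, t, e


class TestCoxUnivariate:
    def test_constant_covariate_rejected(self, rng):
        _, t, e = _surv(rng, 20)
        with pytest.raises(DegenerateCovariateError):
            cox_univariate(np.ones(20), t, e)

    def test_no_events_rejected(self, rng):
        x, t, _ = _surv(rng, 20)
        with pytest.raises(NoEventsError):
            cox_univariate(x, t, np.zeros(20, dtype=int))

    def test_negating_covariate_negates_beta(self, rng):
        x, t, e = _surv(rng, 60, beta=0.5)
        a = cox_univariate(x, t, e)
        b = cox_univariate(-x, t, e)
        assert a.beta == pytest.approx(-b.beta, abs=1e-10)
        assert a.se == pytest.approx(b.se, abs=1e-10)
        assert a.p == pytest.approx(b.p, abs=1e-10)

    def test_agrees_with_statsmodels(self, rng):
        """Independent Breslow fit (statsmodels PHReg) matches to 1e-6."""
        from tmescore.survival import cox_multivariate

        x, t, e = _surv(rng, 150, beta=0.7)
        e[rng.random(150) < 0.2] = 0
        mine = cox_univariate(x, t, e)
        ref = cox_multivariate(pd.DataFrame({"x": x}), t, e)
        assert mine.beta == pytest.approx(ref["beta"].iloc[0], abs=1e-6)
        assert mine.se == pytest.approx(ref["se"].iloc[0], abs=1e-6)
        lo, hi = mine.ci95
        assert lo < mine.hr < hi

    def test_true_hr_unbiased_and_ci_calibrated(self):
        """Two-group HR=2 survival: near-unbiased beta, ~95% Wald CI coverage."""
        betas, covered = [], 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            grp = np.repeat([0.0, 1.0], 150)
            t = rng.exponential(1.0 / np.where(grp == 1, 2.0, 1.0))
            fit = cox_univariate(grp, t + 1e-9, np.ones(300, dtype=int))
            betas.append(fit.beta)
            lo, hi = fit.ci95
            covered += lo <= 2.0 <= hi
        assert abs(np.mean(betas) - np.log(2)) < 3 * np.std(betas) / np.sqrt(40)
        assert covered >= 34  # expect ~38 of 40


class TestFilterPrognostic:
    def test_empty_input_empty_output(self, small_cohort):
        kept, fits = filter_prognostic([], small_cohort.expression, small_cohort.clinical)
        assert kept == [] and fits == {}

    def test_keeps_only_small_p(self, small_cohort):
        expr, clin = small_cohort.expression, small_cohort.clinical
        genes = list(expr.index[:30])
        kept, fits = filter_prognostic(genes, expr, clin, p_max=0.05)
        assert set(kept) <= set(genes)
        for g in genes:
            assert (fits[g].p < 0.05) == (g in kept)

    def test_invalid_threshold(self, small_cohort):
        with pytest.raises(ValueError):
            filter_prognostic(["G00001"], small_cohort.expression,
                              small_cohort.clinical, p_max=1.5)


class TestPc1Signature:
    def test_two_correlated_genes_closed_form(self):
        """Two perfectly correlated genes: PC1 is their shared z-profile * sqrt(2)."""
        rng = np.random.default_rng(5)
        base = rng.standard_normal(20)
        expr = pd.DataFrame(
            {f"s{i}": [base[i], 3 * base[i] + 7] for i in range(20)},
            index=["gA", "gB"],
        )
        pc1 = pc1_signature(expr, ["gA", "gB"])
        z = (base - base.mean()) / base.std(ddof=1)
        np.testing.assert_allclose(pc1.to_numpy(), np.sqrt(2) * z, atol=1e-8)
        # positive orientation: correlates positively with the mean z-score
        assert np.corrcoef(pc1, z)[0, 1] > 0

    def test_duplicated_gene_row(self):
        rng = np.random.default_rng(6)
        base = rng.standard_normal(10)
        expr = pd.DataFrame([base, base], index=["g1", "g2"],
                            columns=[f"s{i}" for i in range(10)])
        pc1 = pc1_signature(expr, ["g1", "g2"])
        z = (base - base.mean()) / base.std(ddof=1)
        np.testing.assert_allclose(pc1.to_numpy(), np.sqrt(2) * z, atol=1e-8)

    def test_scale_invariance(self, small_cohort):
        expr = small_cohort.expression
        genes = list(expr.index[:5])
        before = pc1_signature(expr, genes)
        scaled = expr.copy()
        scaled.loc[genes[0]] *= 10.0
        after = pc1_signature(scaled, genes)
        np.testing.assert_allclose(before.to_numpy(), after.to_numpy(), atol=1e-8)

    def test_too_few_genes(self, small_cohort):
        with pytest.raises(ValueError, match=">= 2 genes"):
            pc1_signature(small_cohort.expression, ["G00001"])

    def test_zero_variance_gene_dropped(self, small_cohort):
        expr = small_cohort.expression.copy()
        expr.loc["G00001"] = 5.0
        with pytest.warns(UserWarning, match="zero-variance"):
            pc1 = pc1_signature(expr, ["G00001", "G00002", "G00003"])
        assert np.isfinite(pc1).all()


class TestTmeScore:
    def test_formula_fixture(self):
        pc1 = {
            "A": pd.Series([1.0, 2.0], index=["s1", "s2"]),
            "B": pd.Series([0.5, 0.5], index=["s1", "s2"]),
        }
        hr = {"A": 1.8, "B": 0.6}
        out = tme_score(pc1, hr)
        np.testing.assert_allclose(out.to_numpy(), [0.5, 1.5])

    def test_single_protective_cluster_negates(self):
        pc1 = {"only": pd.Series([1.0, -2.0, 0.5])}
        out = tme_score(pc1, {"only": 0.5})
        np.testing.assert_allclose(out.to_numpy(), [-1.0, 2.0, -0.5])

    def test_flip_and_pc1_sign_linearity(self):
        pc1 = {
            "A": pd.Series([1.0, 2.0]),
            "B": pd.Series([0.5, -0.5]),
        }
        hr = {"A": 2.0, "B": 0.5}
        base = tme_score(pc1, hr)
        flipped = tme_score(pc1, hr, flip_sign=True)
        np.testing.assert_allclose(flipped.to_numpy(), -base.to_numpy())
        neg = tme_score({k: -v for k, v in pc1.items()}, hr)
        np.testing.assert_allclose(neg.to_numpy(), -base.to_numpy())

    def test_cluster_order_invariance(self):
        pc1 = {"A": pd.Series([1.0]), "B": pd.Series([2.0]), "C": pd.Series([4.0])}
        hr = {"A": 2.0, "B": 0.5, "C": 3.0}
        a = tme_score(pc1, hr)
        b = tme_score(dict(reversed(list(pc1.items()))), hr)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy())

    def test_unit_hr_warns(self):
        pc1 = {"A": pd.Series([1.0, 2.0])}
        with pytest.warns(UserWarning, match="HR exactly 1"):
            out = tme_score(pc1, {"A": 1.0})
        np.testing.assert_allclose(out.to_numpy(), [-1.0, -2.0])

    def test_missing_direction_rejected(self):
        with pytest.raises(ValueError, match="without an HR"):
            tme_score({"A": pd.Series([1.0])}, {})


class TestDichotomize:
    def test_cut_separates_survival_regimes(self):
        """Events concentrated in low scores put the cut between the regimes."""
        score = np.array([1.0, 2.0, 3.0, 4.0] * 5)
        t = np.where(score <= 2, 1.0, 100.0) + np.arange(20) * 0.01
        e = (score <= 2).astype(int)
        cut, labels = dichotomize_score(score, t, e, min_group_frac=0.2)
        assert 2.0 <= cut < 3.0
        assert set(labels[score <= 2]) == {"low"}
        assert set(labels[score >= 3]) == {"high"}

    def test_degenerate_scores_rejected(self, rng):
        t = rng.exponential(1, 10) + 0.01
        with pytest.raises(DegenerateScoreError):
            dichotomize_score(np.ones(10), t, np.ones(10, dtype=int))
        with pytest.raises(DegenerateScoreError):
            median_cutpoint(np.full(8, 3.3))

    def test_monotone_transform_same_partition(self, rng):
        score = rng.standard_normal(40)
        t = rng.exponential(1, 40) + 0.01
        e = (rng.random(40) < 0.7).astype(int)
        _, lab1 = dichotomize_score(score, t, e)
        _, lab2 = dichotomize_score(np.exp(score), t, e)
        np.testing.assert_array_equal(lab1, lab2)

    def test_median_cutpoint_balances(self, rng):
        s = rng.standard_normal(50)
        cut, labels = median_cutpoint(s)
        assert abs((labels == "high").sum() - 25) <= 1
        assert set(labels[s <= cut]) == {"low"}
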