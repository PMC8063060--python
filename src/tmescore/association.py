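"""Group-comparison, contingency, correlation and over-representation tests.

Two- and multi-group comparisons are routed by per-group Shapiro-Wilk
normality at alpha 0.05: all groups normal -> t-test / one-way ANOVA,
otherwise Wilcoxon rank-sum / Kruskal-Wallis.  Over-representation is
the one-sided hypergeometric tail with BH correction across sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import bh_adjust
from .enrichment import GeneSetCollection

__all__ = [
    "GroupComparison",
    "compare_groups",
    "chisq_contingency",
    "correlate",
    "distance_correlation",
    "ora",
    "score_response_association",
]

_NORMALITY_ALPHA = 0.05


@dataclass
class GroupComparison:
    method: str  # t | wilcoxon | anova | kruskal_wallis
    statistic: float
    p: float
    group_summaries: pd.DataFrame = field(default_factory=pd.DataFrame)


def _split_groups(values, labels):
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    levels = pd.unique(lab)
    groups = [v[lab == g] for g in levels]
    return levels, groups


def compare_groups(values, labels, force_method: str | None = None) -> GroupComparison:
    """Two- or multi-group location comparison with normality routing.

    ``force_method`` (one of t, wilcoxon, anova, kruskal_wallis)
    bypasses the Shapiro-Wilk routing.  The Wilcoxon rank-sum p is exact
    for combined n <= 20 without ties, and normal-approximated with tie
    correction otherwise.
    """
    levels, groups = _split_groups(values, labels)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    min_n = 3 if force_method is None else 2
    for g, arr in zip(levels, groups):
        if arr.size < min_n:
            raise ValueError(f"group {g!r} has n={arr.size} < {min_n}")

    if force_method is None:
        normal = all(
            stats.shapiro(arr).pvalue > _NORMALITY_ALPHA if np.ptp(arr) > 0 else False
            for arr in groups
        )
        if len(levels) == 2:
            method = "t" if normal else "wilcoxon"
        else:
            method = "anova" if normal else "kruskal_wallis"
    else:
        method = force_method

    if method == "t":
        if len(groups) != 2:
            raise ValueError("t-test needs exactly 2 groups")
        res = stats.ttest_ind(groups[0], groups[1])
        stat, p = float(res.statistic), float(res.pvalue)
    elif method == "wilcoxon":
        if len(groups) != 2:
            raise ValueError("wilcoxon needs exactly 2 groups")
        combined = np.concatenate(groups)
        no_ties = np.unique(combined).size == combined.size
        how = "exact" if (combined.size <= 20 and no_ties) else "asymptotic"
        res = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided", method=how)
        stat, p = float(res.statistic), float(res.pvalue)
    elif method == "anova":
        res = stats.f_oneway(*groups)
        stat, p = float(res.statistic), float(res.pvalue)
    elif method == "kruskal_wallis":
        if np.ptp(np.concatenate(groups)) == 0:  # identical values: no evidence
            stat, p = 0.0, 1.0
        else:
            res = stats.kruskal(*groups)
            stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown method {force_method!r}")

    summaries = pd.DataFrame(
        {
            "group": levels,
            "n": [g.size for g in groups],
            "mean": [g.mean() for g in groups],
            "median": [float(np.median(g)) for g in groups],
        }
    )
    return GroupComparison(method=method, statistic=stat, p=p, group_summaries=summaries)


def chisq_contingency(table) -> tuple[float, int, float]:
    """Pearson chi-square of independence without continuity correction."""
    tab = np.asarray(table, dtype=float)
    if (tab < 0).any():
        raise ValueError("counts must be non-negative")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("every row and column margin must be positive")
    chi2, p, dof, expected = stats.chi2_contingency(tab, correction=False)
    if (expected < 5).any():
        warnings.warn("expected count < 5 in some cell; chi-square approximation is rough",
                      stacklevel=2)
    return float(chi2), int(dof), float(p)


def distance_correlation(x, y) -> float:
    """Sample distance correlation (double-centered distance covariance)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    a = np.abs(x[:, None] - x[None, :])
    b = np.abs(y[:, None] - y[None, :])
    A = a - a.mean(axis=0) - a.mean(axis=1)[:, None] + a.mean()
    B = b - b.mean(axis=0) - b.mean(axis=1)[:, None] + b.mean()
    dcov2 = (A * B).mean()
    dvarx = (A * A).mean()
    dvary = (B * B).mean()
    if dvarx <= 0 or dvary <= 0:
        return 0.0
    return float(np.sqrt(max(dcov2, 0.0) / np.sqrt(dvarx * dvary)))


def correlate(x, y, method: str = "pearson"):
    """Pearson r (with t-based two-sided p) or distance correlation.

    Returns ``(r, p)`` for pearson and ``(dcor, None)`` for distance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    if method == "pearson":
        if x.size < 3:
            raise ValueError("pearson needs n >= 3")
        r, p = stats.pearsonr(x, y)
        return float(r), float(p)
    if method == "distance":
        if x.size < 4:
            raise ValueError("distance correlation needs n >= 4")
        return distance_correlation(x, y), None
    raise ValueError(f"unknown method {method!r}")


def ora(hits: list[str], sets: GeneSetCollection, universe: list[str]) -> pd.DataFrame:
    """Hypergeometric over-representation of ``hits`` in each gene set.

    Sets are intersected with the universe; the p-value is the one-sided
    upper tail P(X >= overlap), BH-adjusted across the tested sets.
    """
    uni = list(dict.fromkeys(universe))
    uni_set = set(uni)
    stray = [h for h in hits if h not in uni_set]
    if stray:
        raise ValueError(f"hits not in universe: {stray[:10]}")
    hit_set = set(hits)
    rows = []
    for name, genes in sets.items():
        in_uni = [g for g in genes if g in uni_set]
        if not in_uni:
            warnings.warn(f"set {name!r} has no overlap with the universe; dropped",
                          stacklevel=2)
            continue
        k = len(hit_set & set(in_uni))
        m, big_n, n_draw = len(in_uni), len(uni), len(hit_set)
        expected = n_draw * m / big_n
        p = float(stats.hypergeom.sf(k - 1, big_n, m, n_draw))
        rows.append((name, k, expected, p))
    out = pd.DataFrame(rows, columns=["set", "overlap", "expected", "p"]).set_index("set")
    if len(out):
        out["adj_p"] = bh_adjust(out["p"].to_numpy())
    else:
        out["adj_p"] = []
    return out


def score_response_association(scored: pd.DataFrame, response) -> dict:
    """Associate the TME score with immunotherapy response.

    ``scored`` needs ``tme_score`` and ``score_group`` columns; the
    report holds the rank-sum comparison of scores between responders
    (CR/PR) and non-responders (SD/PD) and the chi-square of score
    group x response, with group summaries.
    """
    resp = pd.Series(np.asarray(response), index=scored.index).dropna()
    resp = resp[resp != ""]
    levels = pd.unique(resp)
    if len(levels) < 2:
        raise ValueError("need >= 2 response categories")
    counts = resp.value_counts()
    if (counts < 2).any():
        raise ValueError(f"response categories with n < 2: {counts[counts < 2].index.tolist()}")
    sub = scored.loc[resp.index]
    comp = compare_groups(sub["tme_score"].to_numpy(), resp.to_numpy(), force_method="wilcoxon")
    tab = pd.crosstab(sub["score_group"], resp)
    chi2, dof, chi_p = chisq_contingency(tab.to_numpy())
    return {
        "wilcoxon_statistic": comp.statistic,
        "wilcoxon_p": comp.p,
        "chi_square": chi2,
        "chi_square_df": dof,
        "chi_square_p": chi_p,
        "group_summaries": comp.group_summaries,
        "contingency": tab,
    }
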