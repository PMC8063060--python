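"""Two-group differential expression with empirical-Bayes variance moderation.

The per-gene model is an ordinary two-group comparison on log-scale
expression; gene-wise residual variances are shrunk toward a common
prior by the scaled-inverse-chi-square empirical-Bayes scheme:

    s_tilde_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

with the prior degrees of freedom ``d0`` and prior variance ``s0^2``
estimated by matching the first two moments of ``log s_g^2`` to an
F-distribution (the trigamma moment-matching used by the limma family).
The moderated t statistic has ``d0 + d_g`` degrees of freedom, which is
what buys power at tiny group sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = ["DEResult", "moderated_de", "bh_adjust", "filter_degs"]


@dataclass
class DEResult:
    """Per-gene moderated two-group test results.

    ``table`` columns: logFC (group1 - group2), t, p_value, adj_p,
    mean_expr, flagged (constant genes whose variance came entirely from
    the prior).  ``d0``/``s0_sq`` are the fitted prior df and variance
    (``d0`` may be ``inf`` when variances are effectively common).
    """

    table: pd.DataFrame
    d0: float
    s0_sq: float
    group1: str
    group2: str


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton, as in the limma family)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _fit_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-match log residual variances to a scaled inverse chi-square prior.

    Returns (d0, s0_sq); d0 = inf when the moment equation has no
    positive solution (observed spread no larger than sampling noise).
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.median(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_bar = e.mean()
    n = e.size
    rhs = ((e - e_bar) ** 2).sum() / (n - 1) - special.polygamma(1, df / 2.0)
    if rhs <= 0:
        d0 = np.inf
        s0_sq = float(np.exp(e_bar))
    else:
        d0 = 2.0 * _trigamma_inverse(rhs)
        s0_sq = float(np.exp(e_bar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderated_de(
    expr: pd.DataFrame,
    groups: pd.Series | np.ndarray,
    prior_df: float | None = None,
) -> DEResult:
    """Moderated two-group differential expression over all genes.

    Parameters
    ----------
    expr
        Genes x samples log-scale expression.
    groups
        Binary labels per sample (aligned with ``expr`` columns); the
        lexicographically smaller label is "group1" and logFC =
        mean(group1) - mean(group2), so with cluster labels 1/2 the
        fold change reads cluster1 - cluster2.
    prior_df
        Override the estimated prior degrees of freedom: 0 disables
        moderation (ordinary pooled t), ``inf`` forces a fully common
        variance, ``None`` (default) estimates it from the data.
    """
    groups = np.asarray(groups)
    if groups.shape[0] != expr.shape[1]:
        raise ValueError("groups must have one label per sample")
    levels = np.sort(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(levels)}")
    m1 = groups == levels[0]
    m2 = groups == levels[1]
    n1, n2 = int(m1.sum()), int(m2.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError(f"each group needs >= 2 samples (got {n1} and {n2})")

    x = expr.to_numpy(dtype=float)
    x1, x2 = x[:, m1], x[:, m2]
    mean1, mean2 = x1.mean(axis=1), x2.mean(axis=1)
    logfc = mean1 - mean2
    df_resid = n1 + n2 - 2
    ss = ((x1 - mean1[:, None]) ** 2).sum(axis=1) + ((x2 - mean2[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_resid
    flagged = s2 == 0

    if prior_df is None:
        d0, s0_sq = _fit_prior(s2, df_resid)
    else:
        d0 = float(prior_df)
        _, s0_sq = _fit_prior(s2, df_resid)
        if d0 == 0:
            s0_sq = 0.0

    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_tilde = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / np.where(se > 0, se, 1.0), 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    p = np.where(se > 0, p, 1.0)

    table = pd.DataFrame(
        {
            "logFC": logfc,
            "t": t,
            "p_value": p,
            "adj_p": bh_adjust(p),
            "mean_expr": x.mean(axis=1),
            "flagged": flagged,
        },
        index=expr.index,
    )
    return DEResult(table=table, d0=d0, s0_sq=s0_sq, group1=str(levels[0]), group2=str(levels[1]))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def filter_degs(res: DEResult, adj_p_max: float = 0.01, min_abs_lfc: float = 1.0) -> list[str]:
    """Genes with adj_p strictly below and |logFC| strictly above the cutoffs."""
    if adj_p_max <= 0 or min_abs_lfc < 0:
        raise ValueError("thresholds must be positive")
    t = res.table
    keep = (t["adj_p"] < adj_p_max) & (t["logFC"].abs() > min_abs_lfc)
    return t.index[keep].tolist()
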