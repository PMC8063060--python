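"""Prognostic gene filtering, PC1 gene-cluster signatures, and the TME score.

The TME score condenses the immune-related differential-expression
signal into one prognostic number per sample: differentially expressed
genes are screened by univariate Cox regression, grouped into gene
clusters, each cluster is summarised by the first principal component
of its z-scored expression, and the per-sample score is

    score = sum(PC1 of clusters with HR > 1) - sum(PC1 of clusters with HR < 1)

i.e. risk-associated cluster signatures count positively and protective
ones negatively.  An orientation flag can flip the global sign so that
a high score marks good prognosis (the convention used by the pipeline
driver).  Patients are then dichotomized at the maximally selected
log-rank cutpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .survival import two_group_logrank_z

__all__ = [
    "CoxFit",
    "ScoredCohort",
    "DegenerateCovariateError",
    "NoEventsError",
    "DegenerateScoreError",
    "cox_univariate",
    "filter_prognostic",
    "pc1_signature",
    "tme_score",
    "dichotomize_score",
    "median_cutpoint",
]


class DegenerateCovariateError(ValueError):
    """Constant covariate carries no hazard information."""


class NoEventsError(ValueError):
    """No observed events: the partial likelihood is flat."""


class DegenerateScoreError(ValueError):
    """All scores identical: no cutpoint exists."""


@dataclass
class CoxFit:
    """One univariate Cox proportional-hazards fit (Breslow ties)."""

    beta: float
    se: float
    p: float
    converged: bool = True
    monotone: bool = False  # perfect separation: beta capped

    @property
    def hr(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci95(self) -> tuple[float, float]:
        zq = stats.norm.ppf(0.975)
        return float(np.exp(self.beta - zq * self.se)), float(np.exp(self.beta + zq * self.se))


_BETA_CAP = 15.0


def _cox_prep(os_time, os_event):
    """Sort once; reused across the per-gene fits of a screen."""
    t = np.asarray(os_time, dtype=float)
    e = np.asarray(os_event, dtype=int)
    if (t <= 0).any():
        raise ValueError("survival times must be positive")
    if e.sum() == 0:
        raise NoEventsError("no events observed")
    order = np.argsort(t, kind="stable")[::-1]  # descending time
    t_s, e_s = t[order], e[order]
    # position of the last tied element (largest index) for each time:
    # the risk set of time u is positions 0..risk_end(u) in descending order
    event_pos = np.flatnonzero(e_s == 1)
    # group events by distinct time (Breslow): risk set per distinct event time
    uniq, counts = np.unique(t_s[event_pos], return_counts=True)
    risk_end = np.searchsorted(-t_s, -uniq, side="right")  # descending search
    return order, t_s, e_s, event_pos, uniq, counts, risk_end


def _cox_newton(x_sorted, event_pos, d_counts, risk_end, tol=1e-8, max_iter=60):
    """Scalar Newton on the Breslow partial likelihood; returns (beta, se, flags)."""
    sum_x_events = x_sorted[event_pos].sum()
    beta = 0.0
    monotone = False
    converged = False
    for _ in range(max_iter):
        eta = beta * x_sorted
        w = np.exp(eta - eta.max())  # c-ratios are scale invariant
        c0 = np.cumsum(w)[risk_end - 1]
        c1 = np.cumsum(w * x_sorted)[risk_end - 1]
        c2 = np.cumsum(w * x_sorted**2)[risk_end - 1]
        mean = c1 / c0
        grad = sum_x_events - (d_counts * mean).sum()
        info = (d_counts * (c2 / c0 - mean**2)).sum()
        if info <= 0:
            break
        step = grad / info
        step = np.clip(step, -2.0, 2.0)
        beta += step
        if abs(beta) > _BETA_CAP:
            beta = np.sign(beta) * _BETA_CAP
            monotone = True
            break
        if abs(grad) < tol:
            converged = True
            break
    eta = beta * x_sorted
    w = np.exp(eta - eta.max())
    c0 = np.cumsum(w)[risk_end - 1]
    c1 = np.cumsum(w * x_sorted)[risk_end - 1]
    c2 = np.cumsum(w * x_sorted**2)[risk_end - 1]
    info = (d_counts * (c2 / c0 - (c1 / c0) ** 2)).sum()
    se = 1.0 / np.sqrt(info) if info > 0 else np.inf
    return beta, se, converged, monotone


def cox_univariate(x, os_time, os_event) -> CoxFit:
    """Single-covariate Cox fit by Newton iteration (Breslow ties, Wald p)."""
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateCovariateError("constant covariate")
    order, t_s, e_s, event_pos, uniq, counts, risk_end = _cox_prep(os_time, os_event)
    x_sorted = x[order]
    # center for numerical stability; beta is translation invariant
    x_sorted = x_sorted - x_sorted.mean()
    beta, se, converged, monotone = _cox_newton(x_sorted, event_pos, counts, risk_end)
    if monotone:
        warnings.warn("monotone partial likelihood: beta capped", stacklevel=2)
    z = beta / se if np.isfinite(se) and se > 0 else 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return CoxFit(beta=float(beta), se=float(se), p=float(p), converged=converged, monotone=monotone)


def filter_prognostic(
    degs: list[str],
    expr: pd.DataFrame,
    clinical: pd.DataFrame,
    p_max: float = 0.05,
) -> tuple[list[str], dict[str, CoxFit]]:
    """Keep genes whose univariate Cox Wald p is strictly below ``p_max``.

    ``clinical`` must carry ``os_time`` and ``os_event`` indexed by
    sample id, aligned with the columns of ``expr``.
    """
    if not (0 < p_max < 1):
        raise ValueError("p_max must lie in (0, 1)")
    if not degs:
        return [], {}
    clin = clinical.loc[expr.columns]
    prep = _cox_prep(clin["os_time"].to_numpy(), clin["os_event"].to_numpy())
    order, _, _, event_pos, _, counts, risk_end = prep
    kept: list[str] = []
    fits: dict[str, CoxFit] = {}
    for gene in degs:
        x = expr.loc[gene].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise DegenerateCovariateError(f"gene {gene!r} has constant expression")
        xs = x[order]
        xs = xs - xs.mean()
        beta, se, converged, monotone = _cox_newton(xs, event_pos, counts, risk_end)
        z = beta / se if np.isfinite(se) and se > 0 else 0.0
        fit = CoxFit(
            beta=float(beta),
            se=float(se),
            p=float(2.0 * stats.norm.sf(abs(z))),
            converged=converged,
            monotone=monotone,
        )
        fits[gene] = fit
        if fit.p < p_max:
            kept.append(gene)
    return kept, fits


def pc1_signature(expr: pd.DataFrame, genes: list[str]) -> pd.Series:
    """First-principal-component signature score of a gene list.

    Genes are z-scored across samples; PC1 is the leading right singular
    vector projection of the samples, sign-oriented so that it
    correlates non-negatively with the mean z-score of the signature
    genes (PCA leaves the sign arbitrary).
    """
    present = [g for g in genes if g in expr.index]
    if len(present) < 2:
        raise ValueError(f"signature needs >= 2 genes present in the matrix, got {len(present)}")
    if expr.shape[1] < 3:
        raise ValueError("PC1 signature needs >= 3 samples")
    sub = expr.loc[present].to_numpy(dtype=float)
    sd = sub.std(axis=1, ddof=1)
    if (sd == 0).any():
        dropped = [present[i] for i in np.flatnonzero(sd == 0)]
        warnings.warn(f"dropping zero-variance gene(s): {dropped}", stacklevel=2)
        keep = sd > 0
        sub, sd = sub[keep], sd[keep]
        present = [g for g, k in zip(present, keep) if k]
        if len(present) < 2:
            # single informative gene: its z-profile is the signature
            z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
            return pd.Series(z[0], index=expr.columns, name="pc1")
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
    # samples are the observations: PC1 scores from the SVD of z.T
    u, s, vt = np.linalg.svd(z.T, full_matrices=False)
    pc1 = u[:, 0] * s[0]
    mean_z = z.mean(axis=0)
    if np.dot(pc1, mean_z) < 0:
        pc1 = -pc1
    return pd.Series(pc1, index=expr.columns, name="pc1")


def tme_score(
    pc1_by_cluster: dict[str, pd.Series],
    hr_by_cluster: dict[str, float],
    flip_sign: bool = False,
) -> pd.Series:
    """Signed sum of gene-cluster PC1 signatures by prognostic direction.

    Clusters with HR > 1 (risk) enter with ``+``, clusters with HR < 1
    (protective) with ``-``.  ``flip_sign=True`` negates the total —
    the pipeline default, so that a high score reads as good prognosis.
    """
    if not pc1_by_cluster:
        raise ValueError("need at least one gene cluster")
    missing = set(pc1_by_cluster) - set(hr_by_cluster)
    if missing:
        raise ValueError(f"clusters without an HR direction: {sorted(missing)}")
    total = None
    for name, pc1 in pc1_by_cluster.items():
        hr = hr_by_cluster[name]
        if hr <= 0:
            raise ValueError(f"cluster {name!r} has non-positive HR")
        if hr == 1.0:
            warnings.warn(
                f"cluster {name!r} has HR exactly 1; treated as protective", stacklevel=2
            )
            sign = -1.0
        else:
            sign = 1.0 if hr > 1.0 else -1.0
        term = sign * pc1
        total = term if total is None else total + term
    if flip_sign:
        total = -total
    total.name = "tme_score"
    return total


def median_cutpoint(score: pd.Series | np.ndarray) -> tuple[float, np.ndarray]:
    """Split at the median score (low: score <= median value).

    Insensitive to survival, hence immune to the cut-selection
    inflation that the maximally selected statistic suffers when the
    score was itself built on the same cohort's survival; this is the
    pipeline's default dichotomization.
    """
    s = np.asarray(score, dtype=float)
    if np.unique(s).size < 2:
        raise DegenerateScoreError("all scores identical")
    cut = float(np.quantile(s, 0.5, method="lower"))
    if (s > cut).sum() == 0:  # heavy ties at the top: cut below the median value
        cut = float(np.max(s[s < np.max(s)]))
    labels = np.where(s > cut, "high", "low")
    return cut, labels


def dichotomize_score(
    score: pd.Series | np.ndarray,
    os_time,
    os_event,
    min_group_frac: float = 0.1,
) -> tuple[float, np.ndarray]:
    """Split at the maximally selected log-rank cutpoint.

    Every distinct score value is a candidate cut (low group: score <=
    cut) provided it leaves at least ``min_group_frac`` of the samples
    on each side; the cut with the largest |standardized log-rank
    statistic| wins, ties resolved toward the lower cut.  Returns the
    cutpoint and per-sample "high"/"low" labels.
    """
    s = np.asarray(score, dtype=float)
    if not (0 < min_group_frac <= 0.5):
        raise ValueError("min_group_frac must lie in (0, 0.5]")
    uniq = np.unique(s)
    if uniq.size < 2:
        raise DegenerateScoreError("all scores identical")
    t = np.asarray(os_time, dtype=float)
    e = np.asarray(os_event, dtype=int)
    n = s.size
    min_n = int(np.ceil(min_group_frac * n))
    best_z, best_cut = -np.inf, None
    for cut in uniq[:-1]:
        low = s <= cut
        n_low = int(low.sum())
        if n_low < min_n or n - n_low < min_n:
            continue
        z = abs(two_group_logrank_z(low, t, e))
        if z > best_z + 1e-12:
            best_z, best_cut = z, float(cut)
    if best_cut is None:
        # fall back to the most balanced admissible split (median-like)
        best_cut = float(np.quantile(s, 0.5, method="lower"))
    labels = np.where(s > best_cut, "high", "low")
    return best_cut, labels
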