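"""Kaplan-Meier curves, log-rank tests, and multivariate Cox models."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

__all__ = [
    "KMCurve",
    "km_estimate",
    "logrank_test",
    "two_group_logrank_z",
    "cox_multivariate",
    "CollinearityError",
]


class CollinearityError(ValueError):
    """Design matrix is rank deficient."""


@dataclass
class KMCurve:
    """Product-limit survival estimate.

    ``times`` are the sorted distinct observed times, ``survival`` the
    step values S(t) immediately after each time, ``at_risk`` the
    numbers at risk just before each time, and ``censor_times`` the
    times carrying at least one censoring (for tick marks).
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    censor_times: np.ndarray

    def median(self) -> float:
        below = self.survival <= 0.5
        return float(self.times[below][0]) if below.any() else np.inf

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival, "at_risk": self.at_risk}
        )


def _check_surv(os_time, os_event):
    t = np.asarray(os_time, dtype=float)
    e = np.asarray(os_event)
    if t.size == 0:
        raise ValueError("empty survival input")
    if (t <= 0).any():
        raise ValueError("survival times must be positive")
    if not np.isin(e, [0, 1]).all():
        raise ValueError("events must be 0/1")
    return t, e.astype(int)


def km_estimate(os_time, os_event) -> KMCurve:
    """Kaplan-Meier product-limit estimator (deaths before censorings at ties)."""
    t, e = _check_surv(os_time, os_event)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    times = np.sort(np.unique(t))
    surv = kmf.survival_function_at_times(times).to_numpy()
    # numbers at risk just before each distinct time
    at_risk = np.array([(t >= u).sum() for u in times])
    censor_times = np.sort(np.unique(t[e == 0]))
    return KMCurve(times=times, survival=surv, at_risk=at_risk, censor_times=censor_times)


def logrank_test(groups, os_time, os_event) -> tuple[float, int, float]:
    """Multi-group log-rank test; returns (chi_square, df, p)."""
    t, e = _check_surv(os_time, os_event)
    g = np.asarray(groups)
    levels = pd.unique(g)
    if len(levels) < 2:
        raise ValueError("log-rank needs >= 2 groups")
    if e.sum() == 0:
        raise ValueError("log-rank needs at least one event")
    res = multivariate_logrank_test(t, g, e)
    df = len(levels) - 1
    return float(res.test_statistic), df, float(res.p_value)


def two_group_logrank_z(in_low: np.ndarray, os_time: np.ndarray, os_event: np.ndarray) -> float:
    """Standardized log-rank statistic (O - E)/sqrt(V) for the ``in_low`` group.

    Vectorised over the pooled distinct event times; used by the
    maximally selected cutpoint scan where thousands of candidate splits
    are evaluated.
    """
    t = np.asarray(os_time, dtype=float)
    e = np.asarray(os_event, dtype=int)
    low = np.asarray(in_low, dtype=bool)
    ev_times = np.unique(t[e == 1])
    # at-risk and death counts at each event time, overall and in group
    n_at = (t[None, :] >= ev_times[:, None]).sum(axis=1).astype(float)
    d_at = ((t[None, :] == ev_times[:, None]) & (e[None, :] == 1)).sum(axis=1).astype(float)
    n1_at = ((t[None, :] >= ev_times[:, None]) & low[None, :]).sum(axis=1).astype(float)
    d1_at = (
        ((t[None, :] == ev_times[:, None]) & (e[None, :] == 1) & low[None, :])
        .sum(axis=1)
        .astype(float)
    )
    exp1 = d_at * n1_at / n_at
    with np.errstate(invalid="ignore", divide="ignore"):
        var1 = np.where(
            n_at > 1,
            d_at * (n1_at / n_at) * (1 - n1_at / n_at) * (n_at - d_at) / (n_at - 1),
            0.0,
        )
    v = var1.sum()
    if v <= 0:
        return 0.0
    return float((d1_at.sum() - exp1.sum()) / np.sqrt(v))


def cox_multivariate(covariates: pd.DataFrame, os_time, os_event) -> pd.DataFrame:
    """Joint Cox proportional-hazards fit (Breslow ties) for all covariates.

    Returns a table with one row per covariate: beta, HR, se, Wald p,
    and the 95% CI bounds — the contract behind forest plots where
    HR < 1 marks a protective factor.
    """
    import statsmodels.api as sm

    t, e = _check_surv(os_time, os_event)
    if e.sum() == 0:
        raise ValueError("Cox model needs at least one event")
    X = covariates.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name a minimal set of offending columns for the error message
        bad = []
        kept: list[int] = []
        for j in range(X.shape[1]):
            if np.linalg.matrix_rank(X[:, kept + [j]]) == len(kept):
                bad.append(covariates.columns[j])
            else:
                kept.append(j)
        raise CollinearityError(f"rank-deficient design; dependent columns: {bad}")
    model = sm.PHReg(t, X, status=e, ties="breslow")
    fit = model.fit()
    beta = fit.params
    se = fit.bse
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    zq = stats.norm.ppf(0.975)
    return pd.DataFrame(
        {
            "beta": beta,
            "HR": np.exp(beta),
            "se": se,
            "p": p,
            "lo95": np.exp(beta - zq * se),
            "hi95": np.exp(beta + zq * se),
        },
        index=covariates.columns,
    )
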