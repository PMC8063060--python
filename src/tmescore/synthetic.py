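"""Synthetic immune-infiltration cohorts with known ground truth.

The generator emulates the statistical skeleton of a bulk-transcriptome
immuno-oncology cohort: two latent immune phenotypes ("hot" = high
infiltration, "cold" = low), a block of immune-signature genes whose
log2 expression is shifted upward in hot samples, exponential overall
survival whose hazard is multiplied for cold samples, independent
uniform censoring calibrated to a target censoring fraction, and
immunotherapy response labels drawn from a logistic model of the latent
phenotype.  Every draw derives from one integer seed, so cohorts are
bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .enrichment import GeneSetCollection

__all__ = ["CohortParams", "SyntheticCohort", "generate_cohort", "generate_null_cohort"]


@dataclass(frozen=True)
class CohortParams:
    """Cohort design; defaults mirror a desk-scale two-phenotype study.

    The signature layout (28 sets) follows the 28 immune-cell-type
    convention of bulk TME deconvolution panels; effect_size is the
    log2 shift added to signature genes of hot samples; baseline_hazard
    is in events per month (hot-group median survival ~ 35 months);
    hazard_ratio_cold_vs_hot multiplies the cold group's hazard.
    """

    n_samples: int = 120
    n_genes: int = 1200
    n_signatures: int = 28
    genes_per_signature: int = 10
    hot_fraction: float = 0.5
    effect_size: float = 3.0
    noise_sd: float = 1.0
    baseline_hazard: float = 0.02
    hazard_ratio_cold_vs_hot: float = 2.0
    censor_rate: float = 0.3
    response_logit_slope: float = 2.0
    response_fraction: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_samples", "n_genes", "n_signatures", "genes_per_signature"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0 < self.hot_fraction < 1):
            raise ValueError("hot_fraction must lie in (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.hazard_ratio_cold_vs_hot <= 0:
            raise ValueError("hazard_ratio_cold_vs_hot must be positive")
        if not (0 <= self.censor_rate < 1):
            raise ValueError("censor_rate must lie in [0, 1)")
        if not (0 <= self.response_fraction <= 1):
            raise ValueError("response_fraction must lie in [0, 1]")
        if self.genes_per_signature * self.n_signatures > self.n_genes:
            raise ValueError("genes_per_signature * n_signatures must be <= n_genes")


@dataclass
class SyntheticCohort:
    expression: pd.DataFrame  # genes x samples, log2 scale
    signatures: GeneSetCollection
    clinical: pd.DataFrame  # indexed by sample id
    truth: pd.Series  # "hot"/"cold" per sample
    params: CohortParams = field(default=None)


def _uniform_censor_max(lam: float, target: float) -> float:
    """Upper bound c of U(0, c) censoring giving P(censored) = target.

    With T ~ Exp(lam) and C ~ U(0, c), P(C < T) = (1 - exp(-lam c))/(lam c),
    which decreases from 1 (c -> 0) to 0 (c -> inf); solved by bisection.
    """

    def frac(c):
        return (1.0 - np.exp(-lam * c)) / (lam * c) - target

    lo, hi = 1e-9 / lam, 1.0 / lam
    while frac(hi) > 0:
        hi *= 2.0
    return brentq(frac, lo, hi)


def generate_cohort(params: CohortParams) -> SyntheticCohort:
    """Draw one cohort; deterministic given ``params.seed``."""
    params.validate()
    streams = np.random.SeedSequence(params.seed).spawn(6)
    rng_pheno, rng_gene, rng_expr, rng_surv, rng_cens, rng_resp = (
        np.random.default_rng(s) for s in streams
    )

    n, g = params.n_samples, params.n_genes
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    gene_ids = [f"G{i + 1:05d}" for i in range(g)]

    n_hot = int(np.clip(round(params.hot_fraction * n), 1, n - 1))
    hot_mask = np.zeros(n, dtype=bool)
    hot_mask[rng_pheno.permutation(n)[:n_hot]] = True
    truth = pd.Series(np.where(hot_mask, "hot", "cold"), index=sample_ids, name="phenotype")

    # per-gene baseline on log2 scale, then iid noise per cell
    baseline = rng_gene.normal(loc=6.0, scale=2.0, size=g)
    expr = baseline[:, None] + rng_expr.normal(scale=params.noise_sd, size=(g, n))

    gps = params.genes_per_signature
    sig_sets: dict[str, list[str]] = {}
    for s in range(params.n_signatures):
        members = gene_ids[s * gps : (s + 1) * gps]
        sig_sets[f"sig{s + 1:02d}"] = members
    sig_gene_rows = np.arange(params.n_signatures * gps)
    expr[np.ix_(sig_gene_rows, np.flatnonzero(hot_mask))] += params.effect_size
    expression = pd.DataFrame(expr, index=gene_ids, columns=sample_ids)
    signatures = GeneSetCollection(sig_sets, source="synthetic immune signatures")

    lam = np.where(hot_mask, params.baseline_hazard,
                   params.baseline_hazard * params.hazard_ratio_cold_vs_hot)
    t_event = rng_surv.exponential(1.0 / lam)
    if params.censor_rate > 0:
        c_hot = _uniform_censor_max(params.baseline_hazard, params.censor_rate)
        c_cold = _uniform_censor_max(
            params.baseline_hazard * params.hazard_ratio_cold_vs_hot, params.censor_rate
        )
        c_max = np.where(hot_mask, c_hot, c_cold)
        t_cens = rng_cens.uniform(0.0, c_max)
        os_time = np.minimum(t_event, t_cens)
        os_event = (t_event <= t_cens).astype(int)
    else:
        os_time = t_event
        os_event = np.ones(n, dtype=int)
    os_time = np.maximum(os_time, 1e-8)

    # response: logistic in the centred latent phenotype (+1 hot / -1 cold)
    z = np.where(hot_mask, 1.0, -1.0)
    p_resp = 1.0 / (1.0 + np.exp(-params.response_logit_slope * z))
    responder = rng_resp.random(n) < p_resp
    response = np.where(responder, "CR/PR", "SD/PD").astype(object)
    if params.response_fraction < 1:
        n_with = int(round(params.response_fraction * n))
        labeled = np.zeros(n, dtype=bool)
        labeled[rng_resp.permutation(n)[:n_with]] = True
        response[~labeled] = None
    age = np.round(rng_resp.normal(55.0, 10.0, size=n), 1)

    clinical = pd.DataFrame(
        {
            "os_time": os_time,
            "os_event": os_event,
            "response": response,
            "age": age,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return SyntheticCohort(
        expression=expression,
        signatures=signatures,
        clinical=clinical,
        truth=truth,
        params=params,
    )


def generate_null_cohort(params: CohortParams) -> SyntheticCohort:
    """Same generator with no expression shift and no survival effect."""
    null = dataclasses.replace(params, effect_size=0.0, hazard_ratio_cold_vs_hot=1.0)
    return generate_cohort(null)
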