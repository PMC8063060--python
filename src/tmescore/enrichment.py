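"""Single-sample gene-set enrichment (ssGSEA) and ESTIMATE-style scores.

ssGSEA summarises, per sample, how concentrated a gene set is at the top
of that sample's expression ranking.  Genes are walked in order of
decreasing expression; the running sum gains ``w_g / sum(w in-set)`` at
in-set genes (``w_g = rank_g ** alpha`` with ranks ascending in
expression, so the highest-expressed gene carries the largest weight)
and loses ``1 / (N - m)`` at out-of-set genes.  The enrichment score is
the sum of the running-sum values over all N positions — the integrated
(rather than maximum-deviation) statistic.

The ESTIMATE-style score is the sum of the immune and stromal set
scores, a proxy for non-tumor content of the sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneSetCollection",
    "EnrichmentMatrix",
    "DegenerateComplementError",
    "GeneOverlapError",
    "DegenerateRangeError",
    "ssgsea_scores",
    "minmax_normalize",
    "estimate_scores",
]


class GeneOverlapError(ValueError):
    """A gene set overlaps the expression matrix in fewer genes than required."""


class DegenerateComplementError(ValueError):
    """A gene set covers every gene of the matrix: the out-of-set penalty is undefined."""


class DegenerateRangeError(ValueError):
    """Min-max normalization of a constant matrix."""


@dataclass
class GeneSetCollection:
    """Named, ordered, duplicate-free gene lists.

    Parameters
    ----------
    sets
        Mapping from set name to gene list.  Within-set duplicates are
        removed preserving first occurrence.
    source
        Free-text provenance (e.g. the GMT path the sets came from).
    """

    sets: dict[str, list[str]] = field(default_factory=dict)
    source: str = ""

    def __post_init__(self) -> None:
        clean: dict[str, list[str]] = {}
        for name, genes in self.sets.items():
            if name in clean:
                raise ValueError(f"duplicate gene-set name: {name!r}")
            deduped = list(dict.fromkeys(genes))
            if not deduped:
                raise ValueError(f"gene set {name!r} is empty")
            clean[name] = deduped
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()

    def subset(self, names: Sequence[str]) -> "GeneSetCollection":
        return GeneSetCollection({n: self.sets[n] for n in names}, source=self.source)


@dataclass
class EnrichmentMatrix:
    """Gene-set x sample enrichment scores plus the scoring metadata."""

    scores: pd.DataFrame  # sets x samples
    normalized: bool = False
    alpha: float = 0.25

    @property
    def set_names(self) -> pd.Index:
        return self.scores.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.scores.columns


def _validate_expression(expr: pd.DataFrame) -> None:
    if expr.shape[0] < 2 or expr.shape[1] < 2:
        raise ValueError("expression matrix needs >= 2 genes and >= 2 samples")
    if expr.index.duplicated().any():
        dupes = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dupes[:5]}")
    if not np.isfinite(expr.to_numpy(dtype=float)).all():
        raise ValueError("expression matrix contains non-finite values")


def _sample_order_and_weights(col: pd.Series, alpha: float):
    """Walk order (decreasing expression, ties by gene id) and rank weights.

    Weights are average expression ranks (ascending: top gene ~ N) raised
    to ``alpha``; the walk order breaks expression ties lexicographically
    by gene id so the score is deterministic.
    """
    ranks = col.rank(method="average", ascending=True).to_numpy()
    order = np.lexsort((col.index.to_numpy(), -col.to_numpy()))
    weights = np.abs(ranks[order]) ** alpha
    return order, weights


def ssgsea_scores(
    expr: pd.DataFrame,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    min_overlap: int = 2,
) -> EnrichmentMatrix:
    """Score every gene set in every sample with the ssGSEA running sum.

    Parameters
    ----------
    expr
        Genes x samples expression matrix on log scale.
    sets
        Gene sets to score.
    alpha
        Rank-weight exponent; 0 makes the score purely rank-order based.
    min_overlap
        Minimum number of set genes that must be present in ``expr``.

    Returns
    -------
    EnrichmentMatrix
        Unnormalized scores (sets x samples).
    """
    _validate_expression(expr)
    if alpha < 0:
        raise ValueError("alpha must be non-negative")

    gene_index = expr.index
    n_genes = len(gene_index)
    memberships: dict[str, np.ndarray] = {}
    for name, genes in sets.items():
        mask = gene_index.isin(genes)
        overlap = int(mask.sum())
        if overlap < min_overlap:
            missing = sorted(set(genes) - set(gene_index))
            raise GeneOverlapError(
                f"gene set {name!r} overlaps the matrix in {overlap} genes "
                f"(< min_overlap={min_overlap}); missing: {missing}"
            )
        if overlap == n_genes:
            raise DegenerateComplementError(
                f"gene set {name!r} covers all {n_genes} genes: empty complement"
            )
        memberships[name] = mask

    out = np.empty((len(memberships), expr.shape[1]))
    for j, sample in enumerate(expr.columns):
        order, weights = _sample_order_and_weights(expr[sample], alpha)
        for i, (name, mask) in enumerate(memberships.items()):
            in_set = mask[order]
            m = int(in_set.sum())
            step = np.where(in_set, weights / weights[in_set].sum(), -1.0 / (n_genes - m))
            out[i, j] = np.cumsum(step).sum()

    scores = pd.DataFrame(out, index=list(memberships), columns=expr.columns)
    return EnrichmentMatrix(scores=scores, normalized=False, alpha=alpha)


def minmax_normalize(scores: EnrichmentMatrix) -> EnrichmentMatrix:
    """Rescale a whole enrichment matrix to [0, 1] by its global range."""
    if scores.normalized:
        # idempotent by construction, but keep the contract honest
        lo, hi = scores.scores.min().min(), scores.scores.max().max()
        if np.isclose(lo, 0.0) and np.isclose(hi, 1.0):
            return EnrichmentMatrix(scores.scores.copy(), normalized=True, alpha=scores.alpha)
    vals = scores.scores.to_numpy(dtype=float)
    lo, hi = vals.min(), vals.max()
    if np.isclose(hi, lo):
        raise DegenerateRangeError("constant enrichment matrix cannot be min-max normalized")
    rescaled = (scores.scores - lo) / (hi - lo)
    return EnrichmentMatrix(rescaled, normalized=True, alpha=scores.alpha)


def estimate_scores(
    expr: pd.DataFrame,
    immune_set: Sequence[str],
    stromal_set: Sequence[str],
    alpha: float = 0.25,
) -> pd.DataFrame:
    """Per-sample immune, stromal and combined (ESTIMATE-style) scores.

    The combined score is simply ``immune + stromal``; the tumor-purity
    transformation of the original ESTIMATE method is out of scope.
    """
    coll = GeneSetCollection({"immune": list(immune_set), "stromal": list(stromal_set)})
    em = ssgsea_scores(expr, coll, alpha=alpha)
    immune = em.scores.loc["immune"]
    stromal = em.scores.loc["stromal"]
    return pd.DataFrame(
        {
            "immune_score": immune,
            "stromal_score": stromal,
            "estimate_score": immune + stromal,
        }
    )
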