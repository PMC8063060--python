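"""End-to-end driver: enrichment -> clusters -> DEGs -> TME score -> survival.

Stage order and artifacts (one file each, written to ``outdir``):

1. ``enrichment.tsv``      ssGSEA scores of the immune signatures
2. ``tme_clusters.tsv``    per-sample TME cluster (consensus PAM on samples)
3. ``diffexp.tsv``         moderated DE between TME clusters 1 and 2
4. ``prognostic.tsv``      univariate-Cox screen of the DEGs
5. ``gene_clusters.tsv``   consensus gene clusters of the prognostic DEGs
6. ``pc1.tsv``             per-sample PC1 signature of each gene cluster
7. ``scored.tsv``          TME score, cutpoint group, survival fields
8. ``survival.tsv``        KM curves, log-rank, multivariate Cox
9. ``association.json``    score/response association report

plus ``manifest.json`` (config, seed, package versions, stage checksums).
Any stage failure aborts with the stage name; artifacts already written
stay on disk.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import score_response_association
from .clustering import ConsensusParams, consensus_cluster
from .diffexp import filter_degs, moderated_de
from .enrichment import GeneSetCollection, minmax_normalize, ssgsea_scores
from .scoring import (
    cox_univariate,
    dichotomize_score,
    filter_prognostic,
    median_cutpoint,
    pc1_signature,
    tme_score,
)
from .survival import cox_multivariate, km_estimate, logrank_test

logger = logging.getLogger("tmescore")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

STAGES = [
    "enrichment",
    "tme_clusters",
    "diffexp",
    "prognostic",
    "gene_clusters",
    "pc1",
    "scored",
    "survival",
    "association",
]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; everything has a working default."""

    outdir: str = "tmescore_out"
    # enrichment
    alpha: float = 0.25
    normalize_enrichment: bool = True
    min_overlap: int = 2
    # consensus clustering
    k_range: tuple[int, int] = (2, 5)
    n_resamples: int = 100
    item_fraction: float = 0.8
    tme_k: int = 2  # clusters used downstream; optimal k is recorded separately
    # differential expression
    de_adj_p_max: float = 0.01
    de_min_abs_lfc: float = 1.0
    # prognostic screen / dichotomization
    cox_p_max: float = 0.05
    cut_method: str = "median"  # or "maxstat" (maximally selected log-rank)
    min_group_frac: float = 0.1
    # score orientation: high score = good prognosis
    flip_score_sign: bool = True
    covariates: tuple[str, ...] = ("age",)
    seed: int = 0
    log_level: str = "INFO"


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    expression: pd.DataFrame,
    clinical: pd.DataFrame,
    signatures: GeneSetCollection,
    config: PipelineConfig | None = None,
) -> dict:
    """Run every stage on in-memory inputs and write all artifacts.

    Returns a dict with the per-stage in-memory results plus the
    manifest.  Samples present in the expression matrix but absent from
    the clinical table (or vice versa) are dropped with a logged count.
    """
    cfg = config or PipelineConfig()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=cfg.log_level)

    shared = expression.columns.intersection(clinical.index)
    dropped = (len(expression.columns) - len(shared)) + (len(clinical.index) - len(shared))
    if dropped:
        logger.warning("dropping %d sample(s) not shared by expression and clinical", dropped)
    expression = expression[shared]
    clinical = clinical.loc[shared]

    results: dict = {}
    stage = "enrichment"
    try:
        em = ssgsea_scores(expression, signatures, alpha=cfg.alpha, min_overlap=cfg.min_overlap)
        if cfg.normalize_enrichment:
            em = minmax_normalize(em)
        em.scores.rename_axis("set").to_csv(outdir / "enrichment.tsv", sep="\t",
                                            float_format="%.10g")
        results["enrichment"] = em

        stage = "tme_clusters"
        params = ConsensusParams(
            k_range=cfg.k_range,
            n_resamples=cfg.n_resamples,
            item_fraction=cfg.item_fraction,
            distance="euclidean",
            seed=cfg.seed,
        )
        cons = consensus_cluster(em.scores.T.to_numpy(), params)
        labels_k = cons.labels[cfg.tme_k]
        # orient: cluster 1 = higher mean immune enrichment
        mean_by_cluster = {
            c: em.scores.T.to_numpy()[labels_k == c].mean() for c in np.unique(labels_k)
        }
        order = sorted(mean_by_cluster, key=mean_by_cluster.get, reverse=True)
        remap = {old: new + 1 for new, old in enumerate(order)}
        tme_cluster = pd.Series(
            [remap[c] for c in labels_k], index=em.scores.columns, name="tme_cluster"
        )
        pd.DataFrame(
            {"tme_cluster": tme_cluster, "optimal_k": cons.optimal_k}
        ).rename_axis("sample_id").to_csv(outdir / "tme_clusters.tsv", sep="\t")
        results["tme_clusters"] = {"labels": tme_cluster, "consensus": cons}

        stage = "diffexp"
        two = tme_cluster[tme_cluster.isin([1, 2])]
        de = moderated_de(expression[two.index], two.to_numpy())
        degs = filter_degs(de, adj_p_max=cfg.de_adj_p_max, min_abs_lfc=cfg.de_min_abs_lfc)
        de.table.rename_axis("gene").to_csv(outdir / "diffexp.tsv", sep="\t",
                                            float_format="%.10g")
        results["diffexp"] = {"result": de, "degs": degs}
        logger.info("%d DEGs pass adj_p < %g and |logFC| > %g",
                    len(degs), cfg.de_adj_p_max, cfg.de_min_abs_lfc)

        stage = "prognostic"
        kept, fits = filter_prognostic(degs, expression, clinical, p_max=cfg.cox_p_max)
        prog = pd.DataFrame(
            {
                "gene": degs,
                "beta": [fits[g].beta for g in degs],
                "HR": [fits[g].hr for g in degs],
                "p": [fits[g].p for g in degs],
                "kept": [g in set(kept) for g in degs],
            }
        ).set_index("gene")
        prog.to_csv(outdir / "prognostic.tsv", sep="\t", float_format="%.10g")
        results["prognostic"] = {"kept": kept, "fits": fits}
        if len(kept) < 4:
            raise ValueError(
                f"only {len(kept)} prognostic DEGs; need >= 4 for gene clustering"
            )

        stage = "gene_clusters"
        gparams = ConsensusParams(
            k_range=cfg.k_range,
            n_resamples=cfg.n_resamples,
            item_fraction=cfg.item_fraction,
            distance="one_minus_pearson",
            seed=cfg.seed + 1,
        )
        gexpr = expression.loc[kept]
        gz = gexpr.sub(gexpr.mean(axis=1), axis=0).div(gexpr.std(axis=1, ddof=1), axis=0)
        gcons = consensus_cluster(gz.to_numpy(), gparams)
        glabels = gcons.labels[2]
        # orient: gene cluster 1 = higher mean correlation with immune enrichment
        mean_enrich = em.scores.mean(axis=0).to_numpy()
        cors = np.array([np.corrcoef(gz.iloc[i].to_numpy(), mean_enrich)[0, 1]
                         for i in range(len(kept))])
        gmeans = {c: cors[glabels == c].mean() for c in np.unique(glabels)}
        gorder = sorted(gmeans, key=gmeans.get, reverse=True)
        gremap = {old: new + 1 for new, old in enumerate(gorder)}
        gene_cluster = pd.Series([f"gc{gremap[c]}" for c in glabels], index=kept,
                                 name="gene_cluster")
        gene_cluster.rename_axis("gene").to_frame().to_csv(outdir / "gene_clusters.tsv", sep="\t")
        results["gene_clusters"] = {"labels": gene_cluster, "consensus": gcons}

        stage = "pc1"
        pc1_by_cluster: dict[str, pd.Series] = {}
        for cname in sorted(gene_cluster.unique()):
            members = gene_cluster.index[gene_cluster == cname].tolist()
            if len(members) < 2:
                logger.warning("gene cluster %s has < 2 genes; skipped", cname)
                continue
            pc1_by_cluster[cname] = pc1_signature(expression, members)
        if not pc1_by_cluster:
            raise ValueError("no gene cluster large enough for a PC1 signature")
        pc1_frame = pd.DataFrame(pc1_by_cluster)
        pc1_frame.rename_axis("sample_id").to_csv(outdir / "pc1.tsv", sep="\t",
                                                  float_format="%.10g")
        results["pc1"] = pc1_frame

        stage = "scored"
        hr_by_cluster = {
            cname: cox_univariate(
                pc1.to_numpy(), clinical["os_time"].to_numpy(), clinical["os_event"].to_numpy()
            ).hr
            for cname, pc1 in pc1_by_cluster.items()
        }
        score = tme_score(pc1_by_cluster, hr_by_cluster, flip_sign=cfg.flip_score_sign)
        if cfg.cut_method == "median":
            cut, group = median_cutpoint(score)
        elif cfg.cut_method == "maxstat":
            cut, group = dichotomize_score(
                score,
                clinical["os_time"].to_numpy(),
                clinical["os_event"].to_numpy(),
                min_group_frac=cfg.min_group_frac,
            )
        else:
            raise ValueError(f"unknown cut_method {cfg.cut_method!r}")
        scored = pd.DataFrame(
            {
                **{c: pc1_frame[c] for c in pc1_frame.columns},
                "tme_score": score,
                "score_group": group,
                "os_time": clinical["os_time"],
                "os_event": clinical["os_event"],
            }
        )
        scored.rename_axis("sample_id").to_csv(outdir / "scored.tsv", sep="\t",
                                               float_format="%.10g")
        results["scored"] = {
            "table": scored,
            "cutpoint": cut,
            "hr_by_cluster": hr_by_cluster,
        }

        stage = "survival"
        chi2, df, logrank_p = logrank_test(
            group, clinical["os_time"].to_numpy(), clinical["os_event"].to_numpy()
        )
        km_rows = []
        for gname in ("high", "low"):
            mask = group == gname
            if mask.sum() == 0:
                continue
            curve = km_estimate(clinical["os_time"].to_numpy()[mask],
                                clinical["os_event"].to_numpy()[mask])
            frame = curve.to_frame()
            frame.insert(0, "group", gname)
            km_rows.append(frame)
        km_table = pd.concat(km_rows, ignore_index=True)
        covs = pd.DataFrame({"tme_score": score})
        for c in cfg.covariates:
            if c in clinical.columns and pd.api.types.is_numeric_dtype(clinical[c]):
                covs[c] = clinical[c]
        cox_table = cox_multivariate(
            covs, clinical["os_time"].to_numpy(), clinical["os_event"].to_numpy()
        )
        with open(outdir / "survival.tsv", "w", encoding="utf-8") as fh:
            fh.write(f"# log-rank chi_square={chi2:.10g} df={df} p={logrank_p:.10g}\n")
            km_table.to_csv(fh, sep="\t", index=False, float_format="%.10g")
            fh.write("# multivariate Cox\n")
            cox_table.rename_axis("term").to_csv(fh, sep="\t", float_format="%.10g")
        results["survival"] = {
            "logrank": (chi2, df, logrank_p),
            "km": km_table,
            "cox": cox_table,
        }

        stage = "association"
        report: dict = {"logrank_p": logrank_p}
        if "response" in clinical.columns and clinical["response"].notna().sum() >= 4:
            try:
                assoc = score_response_association(scored, clinical["response"])
                report.update(
                    {
                        "wilcoxon_p": assoc["wilcoxon_p"],
                        "chi_square": assoc["chi_square"],
                        "chi_square_p": assoc["chi_square_p"],
                        "contingency": assoc["contingency"].to_dict(),
                    }
                )
                results["association"] = assoc
            except ValueError as err:
                report["response_association_skipped"] = str(err)
        with open(outdir / "association.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, default=str)
        results.setdefault("association", report)
    except PipelineError:
        raise
    except Exception as err:  # noqa: BLE001 - stage context is the contract
        raise PipelineError(stage, err) from err

    manifest = {
        "config": dataclasses.asdict(cfg),
        "seed": cfg.seed,
        "versions": {
            "tmescore": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "python": sys.version.split()[0],
        },
        "checksums": {
            name: _checksum(outdir / fname)
            for name, fname in [
                ("enrichment", "enrichment.tsv"),
                ("tme_clusters", "tme_clusters.tsv"),
                ("diffexp", "diffexp.tsv"),
                ("prognostic", "prognostic.tsv"),
                ("gene_clusters", "gene_clusters.tsv"),
                ("pc1", "pc1.tsv"),
                ("scored", "scored.tsv"),
                ("survival", "survival.tsv"),
                ("association", "association.json"),
            ]
        },
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    results["manifest"] = manifest
    return results
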