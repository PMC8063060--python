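# Methods

`tmescore` classifies bulk tumor transcriptomes by immune infiltration and
condenses the result into a single prognostic score per sample. This note
describes the statistical machinery, the choices that were genuinely open,
and what the synthetic benchmark does and does not establish.

## Pipeline overview

1. **Single-sample enrichment (ssGSEA).** For each sample, genes are walked
   in order of decreasing expression (expression ties broken
   lexicographically by gene id, so scores are deterministic). The running
   sum gains `w_g / Σ_set w` at in-set genes and loses `1/(N − m)` at
   out-of-set genes, where `w_g = rank_g^α` with average expression ranks
   ascending — the highest-expressed gene carries the largest weight, the
   published ssGSEA convention. The score is the *sum* of the running-sum
   values over all N positions (the integrated statistic, not the maximum
   deviation). α defaults to 0.25, the published ssGSEA exponent. Scores
   may be min–max normalized to [0, 1] over the whole matrix; the
   normalization is a global affine map, so it is order-preserving and
   idempotent. An ESTIMATE-style summary is the sum of the immune-set and
   stromal-set scores; the tumor-purity transform of the original ESTIMATE
   method is out of scope.

2. **Consensus clustering (PAM).** Samples (or genes) are repeatedly
   subsampled (default 100 resamples at 80% item fraction), each subsample
   is clustered with Partitioning Around Medoids (greedy BUILD, then
   steepest-descent SWAP; all ties break toward the lowest index), and the
   consensus matrix records how often each pair co-clusters among the
   resamples where both were drawn. Final labels come from average-linkage
   hierarchical clustering of `1 − consensus`. PAM is a single-swap local
   search: swap-stable solutions that are not globally optimal exist even
   for five items, and the R reference implementation returns the same
   ones, so global optimality is not a contract of this stage.

   **Choosing k.** The per-k area under the consensus CDF and its relative
   increase (delta area) are computed and reported as diagnostics, but they
   do not drive selection: on cleanly clustered data the CDF area keeps
   growing past the true k (each extra cluster moves pair mass off 1), so a
   delta-area cutoff systematically over-selects. Selection instead uses
   the proportion of ambiguous clustering (PAC): a k is eligible when at
   most 10% of off-diagonal consensus entries fall strictly between 0.1
   and 0.9, the largest eligible k wins, and the floor is the smallest k in
   the range (normally 2). On two-/three-blob benchmarks this recovers the
   planted k exactly and falls back to the floor for structureless data.
   Sample clusters use Euclidean distance on the enrichment matrix; gene
   clusters use `1 − Pearson` on standardized expression (scale-free
   similarity is the natural choice for genes). Cluster "1" is oriented to
   be the immune-high cluster (higher mean enrichment for sample clusters,
   higher correlation with mean enrichment for gene clusters).

3. **Differential expression.** A per-gene two-group comparison on
   log-scale expression with empirical-Bayes variance moderation: residual
   variances are shrunk toward a scaled-inverse-chi-square prior whose
   parameters `(d0, s0²)` come from trigamma moment matching of the log
   residual variances; the moderated t has `d0 + d_g` degrees of freedom.
   When the moment equation has no positive solution the prior df is
   infinite (fully common variance). `d0 = 0` recovers the ordinary pooled
   t exactly. The fold change is `cluster1 − cluster2` (lexicographically
   smaller label first; recorded in the result metadata). DEGs require
   adjusted p < 0.01 **and** |logFC| > 1, both strict. BH adjustment is the
   standard step-up. No expression-level prefilter is applied.

4. **Prognostic screen and TME score.** Each DEG is screened by univariate
   Cox regression (Breslow ties, scalar Newton iteration to gradient
   < 1e-8, Wald p; betas capped at ±15 with a warning under monotone
   likelihood). The screen is hand-vectorised because it runs over
   thousands of genes; it agrees with statsmodels' PHReg to ~1e-8 and is
   cross-checked against it in the tests. Genes with p < 0.05 survive.
   Surviving genes are consensus-clustered into gene clusters; each
   cluster's signature is the first principal component of its z-scored
   expression, sign-oriented to correlate positively with the cluster's
   mean z-score (the PCA sign is otherwise arbitrary). Each cluster gets a
   hazard direction from a univariate Cox fit of its PC1, and

       score = Σ PC1 (clusters with HR > 1) − Σ PC1 (clusters with HR < 1).

   A cluster with HR exactly 1 is assigned to the protective side with a
   warning. The pipeline applies a global sign flip by default so that a
   high score reads as good prognosis; the raw orientation is available by
   configuration, and the flip is recorded in the manifest.

5. **Dichotomization.** Two methods are provided. The default is the
   median split. The maximally selected log-rank cutpoint (evaluate the
   standardized two-group log-rank statistic at every distinct score value
   leaving at least 10% of samples on each side; largest |statistic| wins,
   ties to the lower cut) is available as `cut_method="maxstat"` and as the
   standalone `dichotomize_score`. The default is deliberate: the score is
   built on the same cohort whose survival it is then cut against (the Cox
   screen biases retained genes' noise toward survival alignment, and PC1
   averaging amplifies that into a substantial within-phenotype
   score–survival correlation), and a maximally selected statistic on top
   of an already survival-fitted score compounds the overfitting — in
   simulation it reliably places the cut inside a phenotype rather than
   between phenotypes. The median split is immune to this because it never
   looks at survival. Candidate cuts are rank-based, so any monotone
   transform of the score yields the same maxstat partition.

6. **Survival and association statistics.** Kaplan–Meier curves process
   deaths before censorings at tied times; the multi-group log-rank test
   and multivariate Cox model (Breslow ties, Wald p, 95% CIs) summarize the
   group contrast. Group comparisons route on per-group Shapiro–Wilk
   normality at α = 0.05 (t / one-way ANOVA when all groups pass, Wilcoxon
   rank-sum / Kruskal–Wallis otherwise); the rank-sum p is exact for
   combined n ≤ 20 without ties and tie-corrected asymptotic otherwise.
   The chi-square contingency test is Pearson's without continuity
   correction, with a warning when any expected count is below 5.
   Correlation is Pearson (t-based p) or the plug-in distance correlation
   (double-centered distance covariance). Over-representation of a hit
   list in user-supplied gene sets is the one-sided hypergeometric tail
   with BH correction across sets; annotation databases are not bundled.

## Synthetic cohorts

The generator plants the structure the pipeline is designed to find: two
latent phenotypes ("hot"/"cold", default 50/50), gene-wise baselines
`N(6, 2²)` on the log2 scale with iid `N(0, noise_sd²)` noise, and a block
of signature genes (28 sets × 10 genes by default, emulating the
28-immune-cell-type panels used in bulk TME profiling) shifted upward by
`effect_size` (default 3 log2 units) in hot samples. Overall survival is
exponential with 0.02 events/month for hot samples (median ≈ 35 months)
and the hazard multiplied by 2 for cold samples; censoring is independent
uniform with its upper bound calibrated per group so the expected censored
fraction equals `censor_rate` (default 0.3). Response labels (CR/PR vs
SD/PD) follow a logistic model of the centred latent phenotype with slope
2, optionally for only a subset of samples. All draws derive from one
integer seed through independent sub-streams, so cohorts are
bit-reproducible.

Default sizes (n = 120 samples, 1200 genes) are desk-scale: large enough
for every stage to be exercised and for the planted effects to be
recoverable, small enough that the full pipeline runs in seconds. One
structural requirement worth knowing: ssGSEA is rank-based within each
sample, so signature genes must be a minority of the transcriptome — if
nearly all genes shift together, within-sample ranks barely move and the
phenotypes become invisible to enrichment. The defaults keep signature
genes at ~23% of the matrix.

What the generator does **not** emulate: gene–gene correlation beyond the
phenotype block, library-size or batch effects, heterogeneous per-gene
effect sizes, non-exponential hazards, informative censoring, mutation or
copy-number structure. Passing tests therefore demonstrate that the
machinery is correct and calibrated under the model's assumptions, not
that the score generalizes to any particular real cohort.

## Numerical notes

- ssGSEA requires each set to overlap the matrix in ≥ 2 genes (default)
  and to leave a non-empty complement.
- Min–max normalization refuses constant matrices.
- Cox fits center the covariate and normalize risk-set weights by their
  maximum before exponentiation, so large betas do not overflow.
- PC1 signatures drop zero-variance genes with a warning; a signature
  reduced to one informative gene degenerates to that gene's z-profile.
- Consensus items never drawn in any resample are flagged and their
  consensus rows left at zero with a warning.
- The null prognostic screen keeps ≈ 5% of genes (its nominal level), the
  moderated t holds its ~5% type-I error at 3 + 3 samples, and the
  plug-in distance correlation carries a positive small-sample bias
  (~0.24 under independence at n = 50); tests assert these measured
  values, not idealized ones.

## Known limitations

- PAM local optimality only (see above); consensus clustering inherits it.
- The prognostic screen / PC1 / cutpoint chain double-dips the cohort.
  The package mitigates the worst compounding (cutpoint choice) by
  defaulting to the median split, but the score's association with
  survival in the same cohort it was trained on remains optimistically
  biased — as in the study designs this pipeline mirrors. Validating the
  score on an independent cohort is the user's responsibility.
- The Wilcoxon exact path requires no ties; with ties it switches to the
  tie-corrected normal approximation regardless of sample size.
- TIDE/SubMap-style response predictors are not implemented; only the
  association statistics around externally supplied response labels are.
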