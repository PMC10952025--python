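# Methods

This package re-implements, as a tested and seeded pipeline, a
colorectal-cancer analysis pattern that is common in tumor-immunology
bioinformatics: prioritize one immune checkpoint gene out of a candidate
panel by survival and clinical association, stratify the cohort by that
checkpoint's expression, and work outward from the stratification —
differential expression, pathway enrichment, immune-infiltration
filtering — until a competing-endogenous-RNA (ceRNA) network yields a
short ranked list of key genes.  Because the real inputs of such studies
(TCGA/GEO cohorts, TIMER infiltration estimates, DIANA-LncBase and miRWalk
prediction services) are large external resources, the package ships a
synthetic-cohort generator that emulates their statistical structure with
planted, recorded ground truth; every stage is validated by recovering
what was planted.

## Survival screening

For each candidate checkpoint (default panel: PDCD1, CTLA4, PDL1, LAG3,
HAVCR2, TIGIT, ICOS, TNFRSF4, TNFRSF9, CD73, CD47, BTLA, SIRPA, VTCN1),
samples are dichotomized two ways:

* **median split** — expression strictly above the median is "high";
  samples at the median go to "low".  The tie rule is a convention; it is
  deterministic and recorded.
* **maximally selected cutpoint** — every observed expression value whose
  `>`-split keeps both group fractions inside `[q_low, q_high]`
  (default 0.1–0.9) is a candidate; the threshold maximizing the log-rank
  chi-square is kept.

Group survival is compared with the log-rank test: at each distinct event
time the observed events in the high group are compared with their
hypergeometric expectation, tied events handled by the simultaneous-event
convention, and the squared standardized sum is referred to chi-square
with 1 df.  Kaplan–Meier curves use the product-limit estimator; censored
times enter only through the at-risk counts.

The maximized statistic is selection-biased, so the naive p-value at the
optimum is reported with an explicit `selection_inflated` flag, and a
permutation p-value — expression shuffled against survival, the whole
scan repeated, `p = (b + 1) / (n_perm + 1)` — is available
(`n_perm = 1000` by default in the function; the orchestrator leaves it
off for speed and flags the naive value).  The calibration suite
demonstrates both facts: under the null the naive p rejects at ~40%
nominal 5%, while the permutation p is calibrated.

Prognostic direction is "favorable" when the high-expression group has the
longer Kaplan–Meier median survival, falling back to the sign of the
observed-minus-expected event count when a median is undefined.  Because
the median-split and optimal-threshold screens can disagree, the
orchestrator reports both plus a concordance column rather than choosing.

## Clinical association

Expression of each checkpoint is compared across the levels of each
categorical clinical feature: Welch's t-test for two levels, Welch's
heteroscedastic one-way ANOVA otherwise (Satterthwaite-type denominator
df).  All location tests are two-sided.  Missing labels are dropped and
counted; levels with fewer than two observations are discarded.  Since it
is ambiguous whether such association p-values should be adjusted across
the checkpoint-by-feature family, the orchestrator reports both the raw
and the BH-adjusted columns.

## Differential expression

Expression is log2-scale throughout, so the difference of group means is a
log2 fold change.  Genes are partitioned by biotype: `protein_coding`
defines the mRNA list; `non_coding`, `lincRNA`, `antisense`,
`sense_intronic`, `sense_overlapping`, `processed_transcript` and
`3prime_overlapping_ncRNA` define the lncRNA list; anything else
(pseudogenes, ...) is excluded from both.  Microarray-style probe matrices
are collapsed to genes by averaging probes.

Per-gene two-group models give `logFC` and a pooled residual variance with
`n − 2` df.  Variances are shrunk empirically Bayes-style: the prior
(d0, s0²) is estimated by closed-form moment matching on the log residual
variances (solving trigamma equations; the scaled-F model of the moderated-t
framework), the posterior variance is
`(d0·s0² + df·s²) / (d0 + df)`, and the moderated t is referred to a t
distribution with `d0 + df` degrees of freedom (normal when d0 is
infinite).  This closed form is deterministic and reproduces R limma's
`eBayes` to near machine precision on shared fixtures; limma serves as a
cross-check oracle in the tests, never as the implementation.

Calling thresholds are strict: `adj_p < 0.05` (Benjamini–Hochberg) and
`|logFC| > 2` (4-fold).  The same thresholds apply to mRNAs and lncRNAs.
No expression pre-filtering is applied.

## Enrichment

Three complementary routes over one GMT collection:

* **ORA** — hypergeometric upper tail of the DE-list/set overlap within
  the expression universe.  The default keep rule is `p < 0.5` and overlap
  strictly `> 2`.  The permissive `0.5` default reproduces a published
  workflow's printed rule verbatim; it is almost certainly a typo for
  `0.05`, so both are plain config keys (`ora_p_cut`) and the BH column is
  reported alongside.
* **GSEA** — genes ranked by signed logFC (absolute ranking available by
  flag); running sum with hit increments `|score|^w` (w = 1 by default)
  normalized to total 1 and miss decrements `1/(N − Nh)`; ES is the signed
  maximal deviation.  The null permutes gene labels (`(b+1)/(n_perm+1)`,
  never zero); NES divides ES by the mean same-sign permuted |ES|.
  Gene-label permutation is used because the ranked list is a single
  precomputed logFC vector, leaving no phenotype labels to permute.
* **GSVA-style scores** — per sample, genes become within-sample mid-ranks;
  per set, the rank-weighted in-set ECDF is compared with the uniform
  out-of-set ECDF and the signed maximal deviation is the score.  This is
  the deterministic rank/max-deviation variant of gene-set variation
  analysis, without kernel density smoothing — an intentional
  approximation; it retains the key invariance (any strictly increasing
  within-sample transform leaves scores unchanged).  The score matrix is
  then pushed through the same moderated-t machinery with the score-scale
  threshold `|Δ| > 0.263` (1.2-fold) and `adj_p < 0.05`.

## Immune filtering and the ceRNA network

Only differentially expressed genes are tested against infiltration:
Spearman correlation (mid-ranks; exact permutation p for n ≤ 10,
t-approximation otherwise) against the named cell-type abundance, keeping
genes with `|rho| > 0.4` strictly.  The test p-value is reported but plays
no part in the keep rule, by design.  The CD4+ and CD8+ branches are fully
independent from this point on.

Per branch, all (immune-related DE lncRNA) × (immune-related DE mRNA)
Pearson correlations are computed; BH runs over the full tested grid
(not per-lncRNA), and pairs with `r > 0.7` (positive only, strict) and
`adj_p < 0.05` survive.  lncRNA–miRNA predictions need score `> 0.9`
(strict); miRNA–mRNA predictions must appear in at least `min_sources` of
the six databases (miRWalk, Targetscan, Microt4, PITA, RNA22, miRanda).
"More than five of six" is ambiguous — literally 6/6, conventionally ≥ 5;
the default is `min_sources = 5` with the literal reading one config key
away.

A triad (L, m, M) enters the network iff the (L, M) co-expression pair,
the (L, m) prediction and the (m, M) consensus all pass.  The network is
the union of triad edges; the lncRNA–mRNA co-expression edge is exported
as its own edge type and counts toward degree like the others, because
node importance is plain unweighted degree (distinct neighbors).  An audit
routine re-verifies every emitted triad against the three thresholds
independently.  mRNAs ranked top-k (default 10) by degree — within the
full network, not within the mRNA class — in *both* branch networks are
the key genes, ordered by the worse of their two ranks; they are validated
by Pearson correlation with the checkpoint in independent cohorts.

## The synthetic generator

`SimConfig` defaults are the study conditions; the main ones:

| parameter | default | meaning |
|---|---|---|
| `n_samples` | 300 | cohort size |
| `n_mrna` / `n_lncrna` / `n_mirna` | 800 / 200 / 150 | feature counts |
| `hazard_ratio` | 2.5 | low- vs high-checkpoint OS hazard (PFS: 1.8) |
| `baseline_hazard` | 0.02 /month | favorable-group event rate |
| `censor_rate` | 0.012 /month | independent exponential censoring |
| `de_effect` | 3.0 | planted log2 shift of DE genes |
| `planted_rho` / `shared_rho` | 0.6 / 0.7 | module-gene correlation with its factor |
| `factor_corr` | 0.3 | CD4–CD8 latent factor correlation |
| `validation_rho` | 0.5 | key-gene/checkpoint correlation in validation cohorts |

Construction: checkpoint expression is Gaussian; the cohort splits at the
planted checkpoint's (default ICOS) realized median.  Survival is
exponential conditional on the half — the simplest model with an exactly
controllable hazard ratio — with independent exponential censoring.
Two correlated standard-normal latent factors stand for CD4+ and CD8+
infiltration; reported abundances are exponential (monotone) transforms,
which preserves every Spearman-based statistic downstream.  Branch module
genes load on one factor, shared "key" genes on the normalized sum of
both, with loadings solved in closed form so the marginal correlation with
the factor equals the planted value; all DE genes additionally get the
`de_effect` mean shift between the halves.  Planted ceRNA lncRNAs are
noisy averages of their partner mRNA groups, which puts the intended
lncRNA–mRNA correlations near 0.97–0.84 while same-module non-partner
pairs stay near 0.5–0.6 — clearly on opposite sides of the 0.7 rule.
Planted up-genes draw their baseline means from the low end of the
expression range (immune genes are near-silent in the immune-cold half),
so the +3 shift genuinely moves them to the top of the within-sample rank
distribution; this is what makes the planted module recoverable by the
rank-based per-sample scores, not only by logFC.

Prediction databases are tabular by design (the pipeline consumes
predictions tabularly): planted triads get lncRNA–miRNA scores in
(0.92, 0.99) and 6/6 source flags; decoys near-miss exactly one
threshold (score in (0.85, 0.90]; 3–4 source flags; or a module-like decoy
lncRNA whose correlation with its nominal partner sits near 0.53, passing
the DE and immune filters but failing co-expression); background records
sit below all thresholds.  miRNA identifiers are synthetic (`mir-s####`);
no sequence-level simulation.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: count-level noise (no negative-binomial
library-size model; values are Gaussian on the log scale), correlation
between infiltration abundance and the checkpoint group (real cohorts show
higher infiltration in checkpoint-high tumors; modelling it would entangle
the DE and immune-filter truths, so abundance is independent of the split
here), batch structure, and realistic gene–gene correlation beyond the
planted modules.  Recovery results on this generator certify the
*machinery* (thresholds applied exactly, assembly correct, calibrated
tests), not performance on real cohorts.

## Numerical choices and degenerate inputs

* Ranks use mid-ranks everywhere; median-split ties go to "low".
* Degree-rank ties break lexicographically by node id — deterministic
  exports.
* Two groups both constant and equal: t = 0, p = 1; constant but unequal:
  a degenerate-data error (no infinite statistics).
* BH is the only multiple-testing method; adjusted values are clipped to
  `[p, 1]` with step-up monotonicity enforced.
* Gene sets are intersected with the expression universe; sets reduced
  below 2 genes are skipped and logged.
* Empirical-Bayes shrinkage requires ≥ 10 genes; an all-zero-variance
  matrix is a degenerate-data error.  A matrix with no lncRNAs skips the
  lncRNA DE stage and yields an empty network; the run still completes.
* All writers emit TSV with `.` decimals, `NA` for missing and floats at
  6 significant digits; reruns with identical seed and config are
  byte-identical (the run log is the only timestamped artifact).

## Known limitations

* The GSVA-style score is the rank/max-deviation variant, not the
  kernel-smoothed published algorithm; scores are comparable within a run,
  not with other GSVA implementations.
* GSEA uses gene-label permutation; phenotype permutation (the stronger
  null when sample labels exist) is out of scope.
* No Cox modelling, competing risks or interval censoring; the screening
  is purely rank-based.
* Identifier conversion is a plain two-column mapping file; no annotation
  snapshot ships with the package.
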