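# Methods

## Overview

`wntsig` chains five statistical stages: correlation-threshold signature
derivation, complete-linkage sample stratification, survival modelling,
empirical-Bayes differential expression, and rank-based pathway
enrichment, plus a separate univariate scan for an ordinally scored IHC
cohort. This note records the models, the defaults and why, the numerical
choices, and what the synthetic-data generators do and do not emulate.

## Signature derivation

For anchor set A (probes of LEF1 and TCF4 pooled, or of AXIN2) and a
WNT-target panel probe g, we compute Pearson correlations r(g, a) over
samples for every anchor probe a, and the mean r̄(g) across anchor probes.
The probe enters the positive arm when r̄ ≥ τ and the negative arm when
r̄ ≤ −τ, with τ = 0.4 by default. Membership is decided per probe; a gene
is in the signature when any of its probes passes, so gene and probe counts
are reported separately.

Design choices that were genuinely open:

- *Pooling.* "Mean correlation over the anchors" is read as the mean over
  all anchor **probes** pooled (for a two-gene anchor set the probes of
  both genes form one pool). `mean_over="genes"` first averages within each
  anchor gene, then across genes, for users who prefer gene-level weights.
- *No p-value gate.* Entry is governed by |r̄| alone; at small n the
  threshold rule therefore admits occasional null correlates, which is a
  property of the rule, not a bug (see the generator notes below).
- Anchor probes are never variance-filtered; all resolved probes are used.

The two-sided p reported by `pearson_r` comes from the t-distribution with
n − 2 df, and the 95 % CI from the Fisher z-transform.

## Clustering

Samples are clustered on the signature-probe dimensions with Euclidean
distance and complete linkage, and the dendrogram is cut to exactly k = 2
groups. Rows are used unscaled by default (`row_scale="zscore"` is
available). Samples are sorted lexicographically before agglomeration so
ties break identically regardless of input order, and labels are oriented
by expression: cluster 1 is the group with the higher mean over the
positive-arm probes (the signature-high, poor-prognosis group). This makes
the labelling a pure function of the data. Fewer than 3 signature probes
present is an error (configurable minimum).

## Survival machinery

Implemented from first principles:

- **Kaplan–Meier**: product-limit S(t) = Π_{t_i ≤ t} (1 − d_i/n_i) over
  event times; censoring only thins the risk set.
- **Log-rank (Mantel–Cox)**: per event time, a hypergeometric
  observed-minus-expected contribution with the full g × g covariance;
  χ² on g − 1 df via the reduced system. Zero events overall returns
  χ² = 0, p = 1 by convention.
- **Cox PH**: Newton–Raphson on the partial likelihood with Efron tie
  handling by default (Breslow available); Efron is the modern default of
  the field's survival software and both coincide when no event times are
  tied. Convergence at max|score| < 1e−8 or |Δ log-lik| < 1e−10 within 50
  iterations, with step-halving. Covariates are centred internally; the
  linear predictor is shifted by its maximum before exponentiation (the
  shift cancels exactly in the partial likelihood). Monotone likelihoods
  are detected two ways — a scaled coefficient exceeding 50 per covariate
  SD during iteration, or settling above 10 per SD at "convergence" — and
  raise an error instead of returning a silent huge β. CIs and p-values
  are Wald (symmetric on the log-HR scale), matching how hazard ratios are
  conventionally reported for this design. Time is in months end-to-end.

The cluster contrast is reported as HR for **cluster 2 vs cluster 1**, so
a protective HR < 1 means the signature-low cluster does better.

## Moderated differential expression

Per probe, the two-group fit gives log₂FC = mean(cluster 1) − mean(cluster
2), pooled within-group variance s² on df = n − 2, after dropping
zero-variance probes (count logged). Variances are assumed exchangeable
with a scaled inverse-χ²(d₀, s₀²) prior whose hyperparameters are fitted
by the method of moments on log s², using the exact χ² log-moments
(digamma/trigamma; the inverse trigamma is solved by Newton iteration).
Posterior variances s²_post = (d₀s₀² + df·s²)/(d₀ + df) feed
t = log₂FC/√(s²_post(1/n₁ + 1/n₂)) on df + d₀ degrees of freedom. When the
observed spread of log s² does not exceed χ² sampling noise the prior df
is infinite and every probe receives s₀² = mean(s²). With d₀ forced to 0
the ordinary two-sample t is recovered exactly. P-values are adjusted by
the Benjamini–Hochberg step-up (delegated to statsmodels behind the module
function); "differentially regulated" means fdr < 0.05 (configurable; the
significance level applied to adjusted p-values). The total df is d₀ + df
exactly as defined, without an additional cap at the pooled residual df;
the difference is negligible except for astronomically large d₀.

## Pathway enrichment

Probes collapse to genes by the minimum differential-expression p; genes
are ranked ascending (rank 1 = most significant, ties averaged). Each
pathway's member ranks are compared with the complement by a Wilcoxon
rank-sum test, one-sided for "members rank better". Exact enumeration is
used when the smaller side has ≤ 10 genes, the universe ≤ 25 and no ties;
otherwise the normal approximation with tie and continuity corrections.
Pathways covering none or all of the ranked universe are flagged
untestable rather than erroring; symbols absent from the universe are
logged, since pathway and array vocabularies drift. Shipped pathway lists
(`data/kegg_pathways_synthetic.tsv`) are synthetic representative member
sets for the nine pathways of interest: real enrichment analyses should
supply release-pinned lists, because member sets — and hence p-values —
are database-version dependent.

## IHC cohort analytics

Ordinal grades: LEF1 and β-catenin 0–3+ (0 %, 1–25 %, 25–50 %, > 50 %
positive nuclei), TCF4 0–4+ (0 %, 1–33 %, 33–66 %, 66–99 %, > 99 %), Ki67
in percent, TTF1 an opaque numeric score. Dichotomization: Ki67-high at
≥ 10 % (the baseline-table definition; a strict > 10 % override exists
because prose and table disagree on the boundary case), TTF1-positive
> 3, LEF1-positive ≥ 1+, TCF4 top bin = 4+, β-catenin-positive ≥ 1+, and
the combined stratum LEF1+ AND TCF4(4+), which is by construction a subset
of both parents. Marker–marker association uses Pearson r on the numeric
codes (matching how such correlations are conventionally reported with
Fisher-z CIs; Spearman is a config option). The univariate scan fits one
Cox model and one log-rank test per binary parameter, splits age at the
cohort median, excludes patients missing that parameter (logged), and
skips single-level parameters with a warning.

## Synthetic data: what it emulates, what it does not

- `gen_anchor_correlated_matrix` (default n = 19, the brain-metastasis
  cohort size): a latent standard-normal anchor signal per sample; planted
  genes are ρ·A + √(1−ρ²)·ε so their population correlation to the anchor
  is exactly ρ; null genes are independent; everything is mapped affinely
  onto a log2-like range (center 8, spread 1.5).
- `gen_clustered_cohort` (default n = 58, the primary cohort size): two
  latent clusters, signature probes shifted by δ = 2 log2 units in cluster
  1 (a strong but not degenerate separation), survival exponential
  (Weibull shape exposed for robustness checks) with cluster 1 at hazard
  λ = ln2/20 months and cluster 2 at λ/HR; the default true HR is 3.125,
  i.e. 0.32 for cluster 2 vs 1 — the study's effect size. Censoring is
  uniform on (0, u) with u bisected so the expected censored fraction
  matches the requested 0.30, a realistic figure for an early-stage
  surgical cohort (no published value exists to pin it).
- `gen_ihc_cohort` (default n = 25): Bernoulli marker states at the
  baseline-table prevalences, expressed as ordinal grades consistent with
  the observed grade distributions; survival from an exponential PH model
  whose planted per-marker hazard ratios default to the baseline-table
  point estimates.

All generators are pure functions of (parameters, seed). They do **not**
emulate probe-level Affymetrix noise (MAS5/RMA artifacts), batch effects,
correlated null genes, non-proportional hazards, or informative censoring
— so passing tests demonstrate that the estimators recover the structure
they model, not that the model is adequate for any particular real
dataset.

## Problem sizes in the checks

The test suite and `scripts/acceptance.py` use: signature recovery at
ρ = 0.8, n = 50 samples, 10 planted + 50 null genes × 100 seeds; cluster
recovery at δ = 3 SD × 100 seeds; study-sized end-to-end runs (n = 58)
× 40 seeds; Cox recovery at n = 1000 × 100 seeds; a 2000-probe global null
× 20 seeds; 1000 random vectors for the FDR oracle. Medians over seeds are
reported for stochastic quantities because single study-sized replicates
are (correctly) noisy.

## Known limitations

- The differential-expression engine is the two-group contrast only; no
  general design matrices, array weights, or duplicate correlation.
- The Cox implementation has no time-varying covariates, stratification,
  or frailty terms; likelihood-ratio intervals are not offered.
- GEO series-matrix parsing covers the table block of the standard
  dialect; CEL-level processing and normalization are out of scope — the
  expression values are assumed normalized upstream (only an optional
  log2 transform is applied).
- Shipped panel and pathway fixtures are synthetic stand-ins (see their
  headers); real analyses must supply their own curated TSVs.
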