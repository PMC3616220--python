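# wntsig

Derivation of WNT-pathway gene-expression signatures and survival
stratification for lung-adenocarcinoma cohorts.

## The problem

In brain metastases of lung adenocarcinomas, the nuclear WNT effectors LEF1
and TCF4 and the canonical WNT/β-catenin target AXIN2 mark potentially
distinct transcriptional programs. `wntsig` implements the computational
workflow for asking whether such programs are prognostic:

1. **Signature derivation.** In a brain-metastasis expression matrix
   (probe × sample, log2 scale), every probe of a curated WNT-target panel
   is correlated with the probes of an anchor set (LEF1/TCF4 pooled, or
   AXIN2). A probe enters the signature when its mean Pearson correlation
   r̄ over the anchor probes satisfies r̄ ≥ 0.4 or r̄ ≤ −0.4; gene and probe
   counts are reported separately.
2. **Stratification.** Samples of an independent primary-tumour cohort are
   clustered on the signature probes (Euclidean distance, complete-linkage
   agglomeration, tree cut at k = 2; cluster 1 = signature-high).
3. **Prognosis.** The split is quantified with a self-implemented survival
   stack: Kaplan–Meier product-limit curves, the Mantel–Cox log-rank test,
   and a Newton–Raphson Cox proportional-hazards fit (Efron or Breslow
   ties), reporting HR = exp(β̂) with Wald 95 % CIs for cluster 2 vs 1.
4. **Downstream biology.** Differential expression between the clusters
   uses empirical-Bayes moderated t-statistics
   (t = log₂FC / √(s²_post(1/n₁+1/n₂)), s²_post the posterior variance
   under a scaled inverse-χ² prior fitted by moments of log s²) with
   Benjamini–Hochberg FDR, and pathway enrichment uses a one-sided Wilcoxon
   rank-sum test on the p-value gene ranks per KEGG pathway.
5. **IHC cohort analytics.** Ordinal immunohistochemistry scores (LEF1,
   TCF4, β-catenin, Ki67, TTF1) are dichotomized with the study cuts and
   scanned univariately (Cox + log-rank), including the combined
   LEF1+/TCF4(4+) stratum.

A synthetic-data module generates every input with known ground truth
(planted anchor-correlated genes, two-cluster cohorts with a
cluster-dependent hazard, ordinally scored IHC cohorts), so the whole
pipeline is testable without any external download.

## Worked example

```bash
wntsig simulate --preset metastasis --seed 3 --out sim/
wntsig derive --matrix sim/matrix.tsv --anchors LEF1,TCF4 \
    --panel sim/panel.tsv --annotation sim/annotation.tsv \
    --threshold 0.4 --out sig.tsv
# LEF1/TCF4: 37 genes / 37 probes
```

The metastasis preset plants eight genes at correlation ρ = 0.8 to the
anchor signal among 200 null genes at the study's sample size (n = 19);
the derived signature recovers the planted genes plus, at this small n,
an occasional null correlate — exactly the behaviour the threshold rule has
on real data. The same can be done end-to-end from Python:

```python
from wntsig import PipelineConfig, run_full
report = run_full(PipelineConfig(..., out_dir="out/"))
report["stages"]["survival"]
# {'hr_cluster2_vs_1': 0.379, 'ci95': [0.189, 0.759], 'wald_p': 0.0062,
#  'logrank_chi2': 7.99, 'logrank_p': 0.0047, 'n': 58, 'n_events': 39}
```

i.e. on a synthetic primary cohort with a planted hazard ratio of 3.125
for the signature-high cluster, the recovered protective effect for
cluster 2 is HR ≈ 0.38 (true 0.32) with a significant log-rank split.

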