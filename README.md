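# epitrain

Endurance training remodels the activity of gene enhancers in human
skeletal muscle, and the remodeled enhancers are enriched for genetic
variants associated with complex traits and diseases.  `epitrain`
re-implements that analysis as a tested, fully synthetic pipeline: it is
aimed at computational biologists who want the statistical machinery of
the study — dual-histone-mark enhancer annotation, paired differential
testing, enhancer–gene link integration, and LD-aware GWAS-SNP
enrichment — as reusable, verifiable components that run without any
external data.

## What it computes

**Enhancer identification.** Enhancers are H3K27ac consensus peaks that
share at least one base with an H3K4me1 consensus peak.  Consensus peaks
are maximal runs of bases covered by at least `min_support` of the
per-sample peak sets (default ⌈n/2⌉) — a deterministic coverage rule in
place of pseudo-replicate reproducibility pipelines.

**Paired differential testing (ChIP and RNA).** For each region or gene,
counts follow a negative-binomial log-linear model

    y_ij ~ NB(μ_ij, α_i),   log μ_ij = log N_j + participant_j + τ_i · training_j

with library-size offsets `N_j`, participant fixed effects, and a
training indicator (0 = untrained, 1 = trained).  The training effect
`τ_i` (natural-log fold change) is tested by a likelihood ratio against
the participant-only model.  Dispersion `α_i` is estimated per feature
by Cox–Reid adjusted profile likelihood, and the 1-df statistic is
referred to F(1, n − p) so the test stays calibrated at n = 8 pairs.
Benjamini–Hochberg FDR < 0.1 defines up-/down-regulated sets; a
Bonferroni option exists for the expression arm.

**Enhancer–gene links.** Scored links (EpiMap-style) attach to enhancers
by single-base overlap.  Promoters are grouped by their linked
enhancers' regulation (None / Up / Down / Both), group lnFC
distributions are compared by two-sample Kolmogorov–Smirnov ECDF shifts,
and enhancer-activity vs gene-expression fold changes are correlated
(Pearson, strongest-link reduction by interaction score).

**GWAS enrichment.** The variant arm filters an association catalog to
genome-wide-significant single variants (p < 5×10⁻⁸), LD-clumps at
R² ≥ 0.5 (strongest p per correlated group), draws two covariate-matched
control SNPs per index (MAF ± 0.05 absolute; gene density, distance to
nearest gene, and LD-buddy count ± 50%), deduplicates controls per trait
category, expands every lead to its perfect proxies (R² = 1), counts at
most one enhancer overlap per LD block, and estimates per-category odds
ratios with Wald 95% CIs by logistic regression:

    logit P(overlap) = β₀ + β₁ · 1[GWAS SNP],   OR = exp(β₁)

**Synthetic data.** A seeded generator produces every input with the
study's structure: 8 participants sampled pre/post training, planted
region effects (predominantly deacetylation), gene effects transmitted
from linked enhancers, and an LD-block SNP panel in 19 trait categories
whose case/control enhancer-overlap odds encode planted odds ratios —
so every stage is testable against known truth.

## Worked example

```bash
epitrain pipeline --seed 1 --out demo
```

prints

```
1600 enhancers; 47 up / 133 down; combined GWAS OR 0.88
```

and writes the result tables to `demo/`.  Reading them: of 2,000
simulated regions, 1,600 carry both marks and are retained as enhancers;
at FDR < 0.1 the paired test calls 47 up- and 133 down-regulated (the
generator planted 160 regulated regions, three quarters of them down).
`demo/link_summary.tsv` shows the link integration:

```
mean_enhancers_per_gene  mean_genes_per_enhancer  mean_distance_bp  concordance_r  n_pairs  n_concordant_significant
2.14                     2.30                     22695             0.53           1600     78
```

a positive enhancer-activity/expression correlation (r = 0.53) with 78
enhancer–gene pairs significantly changed in the same direction.
`demo/enrichment.tsv` holds the per-category odds-ratio table; at this
desk scale (1,500 case SNPs) the per-category confidence intervals are
wide — the study-scale behaviour of the estimator is exercised by
`scripts/acceptance.py` below.  Re-running the command with the same
seed reproduces every output byte for byte.

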