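# Methods

## Study design being emulated

The pipeline models a paired exercise-training study: skeletal-muscle
biopsies from `n_participants = 8` individuals before and after a
training block, assayed by H3K4me1 and H3K27ac ChIP-seq (region counts)
and RNA-seq (gene counts), followed by integration with enhancer–gene
links and with GWAS variants.  All inputs are produced by the seeded
generator in `epitrain.simulate`; nothing is downloaded.

## Coordinates and overlap

All internal coordinates are 0-based half-open (BED).  1-based inclusive
spans from browser-style tables or variant catalogs are converted at the
parser boundary (`read_bed` comments, `read_snp_table` subtracts 1 from
the on-disk `pos`).  Overlap between two intervals, and between a SNP
position and an interval, requires a single shared base; strand is
ignored everywhere.

## Consensus peaks and enhancer calling

Per-sample peak lists are combined by a coverage rule: a base belongs to
the consensus iff at least `min_support` samples cover it (default
⌈n_samples/2⌉); maximal such runs are the consensus peaks.  This is a
deliberate replacement for reproducibility pipelines built on pooled
pseudo-replicates: the role those play — a deterministic, reproducible
peak list — is served by a simpler rule that is exactly testable against
a per-base oracle.  Enhancers are the H3K27ac consensus peaks
overlapping at least one H3K4me1 consensus peak; the H3K27ac peak (its
coordinates unchanged) is the unit of all downstream analysis.  Peak
calling itself is out of scope: per-sample peaks are inputs.

## Paired negative-binomial differential test

Per feature: `y ~ NB(μ, α)`, `log μ = log N + participant + τ·training`,
library size `N` as offset.  `τ = 0` is tested by likelihood ratio
against the participant-only model.  Choices that matter:

- **Dispersion.** Per-feature, no information sharing, estimated by
  maximizing the Cox–Reid adjusted profile likelihood
  (log-likelihood − ½·log det(XᵀWX)) on a 45-point log-spaced grid over
  [10⁻⁴, ~32] with parabolic refinement, floored at 10⁻⁴.  Plain ML is
  biased low when the mean model uses 9 of 16 degrees of freedom; the
  adjustment removes most of that bias.
- **Reference distribution.** With dispersion estimated from the same 16
  samples, the LRT referred to χ²(1) is anticonservative (~0.085
  rejection at nominal 0.05 in our null simulations).  The statistic is
  therefore referred to F(1, n − p_full) — the quasi-likelihood-style
  small-sample reference — which restores ~0.05.  When a dispersion is
  supplied externally (oracle comparisons), χ²(1) is used and is
  well calibrated.
- **Normalization.** Library-size offsets only; CPM is the descriptive
  quantity.  No trimmed-mean scaling factors: the generator draws
  library sizes, so composition bias is not simulated.
- **logFC** is the fitted training coefficient in natural log (the Wald
  estimate); all-zero features are reported with NaN p/q and excluded
  from the BH adjustment.
- **Fitting.** IRLS batched across features (stacked p×p normal
  equations, one batched solve per iteration); ~2,000 features fit in
  under a second.  Verified coefficient-level against an independent GLM
  implementation at fixed dispersion and against the closed-form paired
  MLE log(Σpost/Σpre).

Up/down sets are q < 0.1 split by logFC sign.  The non-regulated
contrast set takes the n features with the largest q (ties: larger p,
then lexicographically smaller id), mirroring the highest-FDR selection
used for the published contrast.

## Expression arm specifics

The paired LRT (~participant vs ~participant + training) is identical
machinery at the gene level; adjustment defaults to BH with a Bonferroni
flag because both appear in the source analyses (which one produced the
published gene counts is ambiguous, so neither is asserted).
Secreted-factor enrichment is a Pearson χ² (1 df, no continuity
correction) of regulated × annotated over the expressed-gene universe;
the annotation set is intersected with the universe first, and expected
cells < 1 attach a warning rather than an error.  The MDS diagnostic
removes participant effects by centering each participant's log2-CPM
(prior count 0.5) profile, uses the root-mean-square of the 500 largest
absolute per-pair log differences as the distance (the `--mds-top`
default; the source does not specify the gene subset), and embeds by
classical (Torgerson) MDS with a deterministic sign convention.

## Enhancer–gene links

Links carry interval geometry, a target gene, an interaction score, and
a midpoint-to-TSS distance.  Attachment is single-base overlap; link
statistics deduplicate (enhancer, gene) pairs, keeping the
highest-scoring duplicate.  Promoter groups: Both ⇔ linked to ≥1 up and
≥1 down enhancer; Up/Down ⇔ at least one of that kind and none of the
other (an unregulated co-link does not demote — the "at least one"
reading); None ⇔ only unregulated links; unlinked genes are excluded.
Group lnFC distributions are compared by two-sample KS with asymptotic
p; the source presents ECDFs without naming a test statistic, so KS is
this package's choice and no published value is asserted.  Concordance
uses Pearson on (enhancer lnFC, linked-gene lnFC) — the source plots
lnFC against lnFC without naming a coefficient; Spearman is available by
flag, and both strongest-link and all-links pairings are exposed because
the published pair count could have used either.

## GWAS enrichment

- **Catalog filter:** keep single variants (haplotype-flagged records
  dropped) with known position and p < 5×10⁻⁸ strictly; duplicate
  (snp_id, trait) records collapse to the smallest p.
- **Clumping:** greedy by ascending p (ties: position, then id); each
  index removes all remaining SNPs with R² ≥ 0.5 to it.  No distance
  window is applied (none is stated); within-block semantics make the
  greedy decomposable and order-independent.  Equivalence with a
  brute-force oracle on random R² matrices is asserted in the tests.
- **Matching:** per index SNP, 2 controls drawn seeded and without
  replacement from the pool members inside every window (MAF ± 0.05
  absolute; gene density, nearest-gene distance, LD buddies ± 50%
  relative — the documented semantics of the matching tool the study
  used).  Shortfalls return fewer controls and a flag; windows are never
  silently relaxed.  Controls are deduplicated within each category,
  first occurrence in index-position order winning.
- **Tag expansion and overlap:** each lead expands to universe SNPs at
  R² ≥ 1; a lead scores 1 iff any proxy position lies in any enhancer,
  never more than 1 per LD block.  `run_enrichment` computes these flags
  vectorized over the panel; the per-lead operations are the reference
  semantics and a test asserts both routes agree.
- **Test:** logistic regression of overlap on case status (IRLS via GLM
  with frequency-weighted 2×2), Wald 95% CI, which for the saturated
  binary predictor equals the cross-product OR with the standard log-OR
  SE (asserted to 6 digits).  Zero margins yield flagged degenerate
  results.  The combined analysis pools categories and deduplicates
  leads by snp_id (the source's handling of cross-category duplicates is
  unstated; pooling+dedup is this package's choice).  Categories under
  150 SNPs are tested but logged as under-populated; empty ones are
  skipped with a log entry.

## LD model

LD is block-structured: disjoint blocks, each SNP carrying a proxy tier
r ∈ [0.5, 1] (its R² to the block lead); pairwise R² is min(tier_a,
tier_b) within a block, 0 across, 1 on the diagonal.  The procedure only
ever thresholds R² at 0.5 and 1.0, so no continuous recombination model
is needed.  An explicit pairwise-R² reference (`PairwiseLd`) supports
arbitrary matrices for oracle tests.

## Synthetic-data generator: what it emulates, and what it does not

Fixed study conditions: 8 participants, 19 trait categories, 1:2
matching, FDR 0.1, genome-wide threshold 5×10⁻⁸, clumping R² 0.5, tag
R² 1.0.  Conditions chosen once where the sources are silent:

- Genome: 4 chromosomes, consensus regions every ~10 kb, widths
  0.8–3 kb; per-sample peak edges jitter ≤10% of width.  80% of regions
  carry both marks; 10% of dual regions carry planted training effects,
  21% of them positive (matching the published predominance of
  deacetylation); planted magnitudes are `effect_logfc_mean +
  |N(0, effect_logfc_sd)|` (default 1.5 + half-normal 0.25), so every
  planted effect reaches the configured scale.
- Counts: NB with dispersion 0.1, lognormal relative abundances,
  library sizes uniform in 0.8–1.2 M, participant effects N(0, 0.3) on
  the log scale drawn once and shared between the ChIP and RNA arms of
  the same participant (paired-design realism).
- Links: each dual region links to 1–5 of its 8 nearest genes
  (1 + Poisson(1.3), capped), scores U(0.2, 1), geometry shifted ≤20% of
  width so single-base overlap is preserved.  A gene's planted lnFC is
  `coupling` (default 0.8) times the score-weighted mean of its linked
  enhancers' planted lnFC plus N(0, 0.1) noise.
- SNP panel: each case lead owns an LD block with Poisson tags; half
  the tags are perfect proxies.  Three pool leads per case lead are
  drawn inside the matching windows, guaranteeing 1:2 matchability
  (asserted at generation).  Block-level enhancer overlap is Bernoulli:
  control odds `baseline_overlap = 0.018` (the published control overlap
  rate), case odds multiplied by the planted per-category OR — by
  default 1.44 (the published combined effect) for the five categories
  reported enriched and 1.0 elsewhere.  The catalog table additionally
  carries haplotype-flagged and duplicated records so the filter has
  work to do.
- Secreted-factor annotations: genes are labelled "secreted" at 15%
  (UniProt-like) and 30% (ExoCarta-like) baseline rates, raised to 28%
  and 45% among planted-regulated genes, giving the qualitative
  overrepresentation pattern.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: genomic sequence and mappability
artifacts, composition bias between libraries (no trimmed-mean
normalization is needed or implemented), realistic human LD (block
model only), the genome-scale published counts (7,018 regulated
enhancers, 641/176 genes, 75%/45% mark overlap, 599 concordant pairs —
all data-dependent and only reachable from the deposited data), and
transcript-level quantification (the expression arm is gene-level by
construction).

## Problem sizes

Default study: 2,000 regions, 2,000 genes, ~20,000 panel SNPs
(~1,500 case leads) — a desk-scale configuration that keeps a full
pipeline run around two seconds.  The calibration and recovery studies
use the sizes their questions demand: ~13,000 case leads (the published
panel size) for enrichment recovery, 19 × ~400 leads for null
calibration, 2,000 dual regions for effect recovery, 500 regions × 3
seeds for type-I error.

## Known limitations

- Dispersion is estimated per feature with no shrinkage; power at very
  low counts is below what moderated methods achieve.
- The Wald CI for the odds ratio is poor when overlap counts are ~2 or
  fewer; such categories are reported with wide or degenerate CIs
  rather than switched to exact methods.
- The block LD model cannot represent partial cross-block correlation;
  clumping behaviour between blocks is exactly zero.
- `match_controls_all` scans the MAF window per index; for panels far
  beyond ~10⁵ SNPs a k-d structure would be preferable.
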