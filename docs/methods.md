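# Methods

## Statistical model

Every inference in the package is built on one Gaussian linear model with
known heteroscedastic noise. An observation is the posterior mean
`log_mean` of a gene's natural-log expression in one sample (and, for F1
samples, one allele), with its reported posterior sd `log_sd`; upstream
quantifiers of allele-specific expression emit exactly this summary. For a
gene with observation vector y,

y ~ N(Xβ, diag(log_sd² + residual_sd²)),   β ~ N(0, diag(τ²)),

so the marginal likelihood is the closed-form multivariate-Gaussian
density N(y; 0, X diag(τ²) Xᵀ + Σ). Baseline (nuisance) coefficients get a
vague prior (τ = `baseline_prior_sd`, default 10 on the log-e scale) and
effect coefficients a unit prior (τ = `effect_prior_sd`, default 1 log-e ≈
1.44 log2 units). `residual_sd` (default 0) adds gene-level noise in
quadrature for data whose reported sds are optimistic. The upstream
literature's model-comparison machinery does not publish its exact priors,
so these are the package's own stated choices, exposed in `PriorConfig`
and enforced to keep the baseline prior at least 10× vaguer than the
effect prior. A singular marginal covariance raises rather than being
regularized silently.

### Model designs

*Imprinting scan* (F1 groups only): both models carry per-cross baselines.
The null adds one shared allelic difference d (Cast − B6 allele in both
crosses); the imprinting model adds one effect m entering +m in the
B6♂×Cast♀ cross and −m in the reciprocal. BF = exp(logM_imp − logM_null).
Direction maps through cross orientation: the Cast allele is maternal in
the B6♂×Cast♀ cross, so posterior mean m > 0 ⇒ maternal. Tiers: BF ≥ 30
extreme, ≥ 10 high, > 3 possible (strictly greater; genes in this tier are
excluded from the four-way classification), else none.

*Four-way classification* (F0 + F1): one F0 baseline, one pooled F1
allele-level baseline (the six F1 replicates per allele are pooled across
crosses — imprinted genes having been filtered first), and effects per
model: conserved none; cis a single δ shared by F0 strain and F1 allele
contrasts; trans δ₀ only; cis-and-trans δ₀ and δ₁ free. Posteriors use
equal 1/4 priors, computed in log space with max-subtraction; a winner
needs posterior > 0.5 and ≥ 2× the runner-up, otherwise the gene is
`unclassified` with reason `low_confidence`. Exclusions apply in pipeline
order: `nonpolymorphic` (no allele-resolved F1 data exists), then
`imprinted_bf_gt_3`, then confidence. Genes missing a required group
series are reported `missing_group`, never imputed.

Because the baseline prior is proper, Bayes factors are invariant to
shifting all of a gene's observations only in the vague-baseline limit:
the residual dependence is O(shift·ȳ/τ²) ≈ 10⁻² in log-BF at τ = 10 and
≈ 10⁻⁸ at τ = 10⁴. The property test asserts invariance at 10⁻⁶ using the
vaguer prior; at the default the effect is negligible relative to any
decision threshold but not exactly zero.

### Verification

Closed-form marginals are checked against two independent oracles:
prior-sampling Monte-Carlo integration (50 random instances, 3 MC standard
errors, with a larger-sample re-check because 50 simultaneous 3-SE tests
produce occasional chance exceedances) and 1-D quadrature for the
baseline-only model. Exact enrichment tails are checked against exhaustive
enumeration for small populations, and the two-tailed Fisher p (authored
here by hypergeometric probability-mass summation, kept separate from the
scipy reference) against `scipy.stats.fisher_exact`.

## Effect estimation

The weighted mean Σ(mᵢ/vᵢ)/Σ(1/vᵢ) uses the posterior variance vᵢ =
`log_sd`² of each replicate; fold changes are differences of weighted
means converted from log-e to log2 at a single point. x is the F1 allelic
fold change (Cast vs B6 alleles, both crosses pooled), y the F0 strain
fold change. Subcategories follow the printed inequalities exactly;
points with x·y = 0, |x| = |y| or |y| = 2|x| in the same-direction
half-plane are not covered by them and receive an explicit `boundary`
label rather than a silent tie-break (reachable with rounded input
values). The opposite-direction half-plane (x·y < 0) is wholly TRANS−cis
and has no magnitude boundary. Stabilizing = opposite-direction
subcategories; destabilizing = same-direction.

Cross-tissue comparison admits a gene to the cis comparison only when it
is cis in one tissue and conserved-or-cis in the other (symmetrically for
trans); genes cis in one tissue and trans in the other are excluded from
both sets. Pearson correlations over shared-cis genes use the weighted
log2 fold changes (x with x, y with y), not raw expression.

## Regulatory annotation

Containment uses the peak center (floor midpoint of the 0-based half-open
interval) against gene spans, which makes assignment total and
deterministic for span-straddling peaks; peaks outside every span go to
the nearest TSS on their chromosome. Ties (equidistant TSSs) and nested
genes are resolved deterministically (nearest TSS, then lexicographically
smallest id) and flagged. Central windows are half-open
[center − 500, center + 500); sliding windows default to 50 bp stepping
25 bp across 2 kb (79 windows; an interior variant falls in exactly 2
windows, a span-edge variant in 1). Indels are counted at their VCF POS
anchor base. Heterozygous and missing-genotype VCF records are dropped at
read time with a counted log line.

The variant-frequency enrichment test is exact hypergeometric with **base
pairs as draw units**: population = all peaks × span bp with the observed
variants marked, draws = subset peaks × span bp. A per-kb discretization
(one draw per peak-kb) fails whenever variants outnumber kilobases, which
is the realistic regime (≈ 8.5 variants per kb), so the per-bp
construction is used; at most one variant can occupy a base, which the
generator enforces and real VCFs satisfy per position. The source studies
do not print their test construction; this is the package's reading.

## Synthetic data

The generator emulates the study design: per gene, a scenario drawn from
`scenario_mix` (defaults proportioned to the published retina fractions,
54/30/7/6% conserved/cis/trans/cis-and-trans plus 3% imprinted split
evenly), true effects of magnitude `effect_size_log2` (default 1 log2,
random sign; optionally half-normal magnitudes), baselines drawn
uniformly (F1 allele-level baseline offset by −ln 2 as roughly half the
diploid total — only differences matter downstream), and i.i.d. Gaussian
noise of sd `measurement_sd` (default 0.15 log-e) on each of 3 replicates
per class. Reported `log_sd` equals the generating sd (well-calibrated
case) unless `sd_miscalibration` ≠ 1. Combined cis-and-trans genes draw
the allelic component δ₁ and the trans component δ₀ − δ₁ with independent
signs, so about half stabilize — the generator takes no stance on the
direction bias observed in real tissues. Non-polymorphic genes (default
17%, matching the autosomal polymorphic fraction of the strain pair) emit
F0 rows only. The toy genome lays genes end-to-end on one chromosome with
non-overlapping peak slots inside gene bodies; central kilobases of peaks
linked to true-cis genes receive 9.69 variants/kb versus 8.35 elsewhere
and 8.0/kb background, matching the published per-kb frequencies.

What the generator does **not** emulate: read-level sampling (no
reference-mapping bias, no count overdispersion), per-gene variation in
posterior-sd magnitude, correlated replicates, X-linked dosage, gene
families with shared sequence, or clustering of imprinted genes. Passing
the recovery benchmark therefore shows the inference machinery is correct
and well-calibrated under its stated model, not that real-data headline
counts would be reproduced.

## Problem sizes and defaults

The recovery benchmark runs 2,000 genes × 3 replicates at effect 1 log2
and sd 0.15 with a mix of 22% per non-imprinted class and 12% imprinted —
sizes at which classification accuracy is measured stably in seconds.
Acceptance reporting also classifies 2,000 genes under the default mix and
profiles ~2,200 peaks on a 1,500-gene toy genome. The Monte-Carlo oracle
uses 4×10⁵ prior draws per instance (2×10⁶ on re-check).

## Known limitations

* The Gaussian-known-variance formulation approximates the original
  model-comparison machinery; genome-wide counts from the source studies
  (numbers of classified or excluded genes) are not expected to reproduce
  exactly, and no attempt is made to do so.
* The imprinting null/alternative pair is symmetric (one free parameter
  each), so under conserved truth roughly 10% of genes at 3 replicates
  reach BF > 3; the exclusion tier is deliberately permissive — it
  protects the cis/trans classification rather than asserting imprinting.
* Boundary subcategory labels are reported, not resolved; consumers
  needing a forced bin must decide their own tie-break.
* FPKM-scale values are plain exponentials of log-expression estimates;
  no library-size renormalization is applied.
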