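# cistrans

Dissecting gene-regulatory divergence between two inbred strains from F0
homozygote and reciprocal-F1 hybrid allele-specific expression data.

In an F1 hybrid, both alleles of a gene sit in the same nucleus and see the
same trans environment. A **cis** regulatory difference therefore shows up as
allelic expression imbalance (AEI) in the F1 that recapitulates the strain
ratio in the F0s; a **trans** difference shows up as F0 divergence with
balanced F1 alleles; and a parent-of-origin (imprinting) effect shows up as
an allelic bias that flips sign between the reciprocal crosses. `cistrans`
implements this whole analysis as a tested Python library, exercised
end-to-end on synthetic data with known truth:

* **Imprinting scan** — Bayes factor comparing a null model (allelic
  difference shared by both crosses) against an imprinting model (equal
  magnitude, opposite sign), with parental-direction calls and the tier
  thresholds BF ≥ 30 (extreme), ≥ 10 (high), > 3 (excluded from the
  cis/trans analysis).
* **Four-way classification** — Gaussian-marginal Bayesian comparison of
  *conserved* (δ₀ = δ₁ = 0), *cis* (δ₀ = δ₁ free), *trans* (δ₀ free,
  δ₁ = 0) and *cis-and-trans* (δ₀, δ₁ free) models, where δ₀ is the F0
  strain log-expression difference and δ₁ the F1 allelic difference. A gene
  is confidently classified when the winning model's posterior exceeds 0.5
  and is at least twice the runner-up's (equal 1/4 priors).
* **Effect estimation** — inverse-posterior-variance weighted log2 fold
  changes x (F1 allelic) and y (F0 strain); the subcategorization of
  combined cis-and-trans genes (`x·y>0, |x|>|y|` → CIS−trans; `x·y<0` →
  TRANS−cis; `x·y>0, |x|<|y|<2|x|` → CIS+trans; `x·y>0, |y|>2|x|` →
  TRANS+cis); replicate concordance; rank enrichment of known imprinted
  genes; Fisher-exact direction-bias tests; cross-tissue sharing of cis and
  trans effects.
* **Regulatory annotation** — peak-to-gene assignment (containment, else
  nearest TSS), sliding-window variant-density profiles (50 bp windows
  stepping 25 bp across 2 kb), central-1-kb variant tabulation, per-kb
  frequencies, and exact hypergeometric enrichment tests.
* **Synthetic data** — a seeded generator for the full study design
  (2 F0 classes + 4 F1 cross×allele series, 3 replicates each, additive
  cis/trans/imprinting effects on the log scale) plus toy gene models,
  peaks (BED) and variants (VCF) with planted densities.

## Worked example

```python
from cistrans import (SimulationConfig, PriorConfig, simulate_expression,
                      classify_imprinting, classify_dataset)

cfg = SimulationConfig(n_genes=400, seed=11)
measurements, truth = simulate_expression(cfg)
imprinting = classify_imprinting(measurements)
table, summary = classify_dataset(measurements, PriorConfig(),
                                  imprinting=imprinting)
print(summary["counts"])
```

prints

```
genes simulated: 400, confidently classified: 284
excluded: {'nonpolymorphic': 66, 'low_confidence': 27, 'imprinted_bf_gt_3': 23}
  conserved       150  (52.8%)
  cis              93  (32.7%)
  trans            27  (9.5%)
  cis_and_trans    14  (4.9%)
agreement with simulation truth among classified genes: 97.2%
```

(`examples/classify_regulatory_divergence.py`): of 400 simulated genes, the
non-polymorphic ones carry no allele-resolved F1 data and drop out first,
genes with imprinting Bayes factor > 3 are filtered next, and 284 genes
pass the posterior-confidence rule; 97% of those land in their true
generating category. The other scripts in `examples/` walk through the
imprinting scan, weighted fold changes/subcategories, and CRE variant
density the same way.

A thin CLI mirrors the pipeline stages
(`cistrans simulate | imprinting | classify | effects | annotate |
compare-tissues | all`); run `cistrans all --n-genes 500 --seed 7
--out-dir out/` for the full chain with TSV/BED/VCF/JSON artifacts and a
run manifest.

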