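"""Variant density in candidate cis-regulatory elements.

Builds a toy genome for a simulated gene set, assigns regulatory peaks to
genes, profiles variant density in sliding windows around peak centers,
and tests whether peaks linked to cis-effect genes carry more variants in
their central kilobase than peaks overall.
"""

import math

from cistrans import AnnotationConfig, SimulationConfig, simulate_annotation, \
    simulate_expression
from cistrans.annotation import (
    assign_peaks_to_genes,
    central_window_counts,
    count_histogram,
    sliding_window_profile,
    variant_frequency_enrichment,
)

cfg = SimulationConfig(n_genes=800, seed=3)
_, truth = simulate_expression(cfg)
genes, peaks, variants = simulate_annotation(truth, AnnotationConfig(), seed=3)

assignment = assign_peaks_to_genes(peaks, genes)
print(f"{len(peaks)} peaks assigned to genes "
      f"({(assignment['method'] == 'contained').sum()} by containment)")

profile = sliding_window_profile(peaks, variants)
print(f"sliding-window profile: {len(profile.counts)} windows of 50 bp "
      f"stepping 25 bp across 2 kb; total window hits {profile.counts.sum()}")

counts = central_window_counts(peaks, variants)
gene_of = dict(zip(assignment["name"], assignment["gene_id"]))
cis_genes = set(truth.loc[truth["true_class"] == "cis", "gene_id"])
cis_counts = counts[[gene_of.get(n) in cis_genes for n in counts.index]]
res = variant_frequency_enrichment(cis_counts.to_numpy(), counts.to_numpy())
print(f"variants per kb: all peaks {res['total_freq_per_kb']:.2f}, "
      f"cis-linked peaks {res['subset_freq_per_kb']:.2f}")
print(f"hypergeometric enrichment: P = {res['p_upper']:.3g} "
      f"(-log10 P = {-math.log10(max(res['p_upper'], 1e-320)):.1f})")
hist = count_histogram(counts, normalize=True)
print(f"per-peak count histogram over {len(hist)} distinct counts "
      f"(masses sum to {hist.sum():.3f})")
# An elevated per-kb frequency in cis-linked peaks with a small P supports
# the reading that sequence variants inside these elements drive the
# allele-linked expression differences.
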