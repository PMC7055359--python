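"""CPM-normalize counts, apply the highly-expressed filter and call
differential genes.

The filter keeps genes with log2(max group-mean CPM + 1) > 4 (the microglia
convention); differential genes must pass both a p < 0.05 gate (Welch t on
log2(CPM+1), BH-adjusted q also reported) and a >1.5 fold-change gate.
"""

from npsle import DECriteria, SyntheticConfig, cpm_normalize, differential_genes, filter_highly_expressed, generate_cohort

_, counts, _ = generate_cohort(SyntheticConfig(seed=1))
expr = cpm_normalize(counts)
print(f"CPM column sums: {expr.values.sum(axis=0).iloc[0]:,.0f} (per million by construction)")

universe = filter_highly_expressed(expr, counts.groups, threshold=4.0)
print(f"highly expressed universe: {len(universe)} of {len(counts.gene_ids)} genes")

de = differential_genes(
    counts, "case", "control", universe=universe,
    criteria=DECriteria(max_p=0.05, min_fold_change=1.5),
)
flagged = de[de["significant"]]
print(f"differential genes (p<0.05, FC>1.5): {len(flagged)}")
print(flagged.sort_values("p").head(5).round(4))
print("\nGenes named sig### are the planted signature; their enrichment among")
print("the flagged genes shows the severity coupling is detectable at n=4 vs 4.")
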