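"""Detect genes whose isoform usage shifts between stimulation conditions.

Per gene, isoform read counts are tabulated by condition; genes with >=50
reads in >=2 conditions are tested with a chi-squared contingency test and
Bonferroni-corrected. Genes are ranked by p-value with the maximum
per-isoform usage standard deviation as the effect summary.
"""

import isokit

cfg = isokit.SimulationConfig(
    n_observed_isoforms=300, switch_fraction=0.2, reads_distribution="fixed",
    reads_per_gene_per_condition=400,
)
ds = isokit.simulate_dataset(cfg, seed=7)
classifications = isokit.classify_all(ds.models, ds.annotation)
gene_of = {i: c.assigned_gene for i, c in classifications.items()}

results, untestable = isokit.run_diu(ds.records, ds.sample_map, gene_of, alpha=0.05)
sig = [r for r in results if r.significant]
print(f"genes tested: {len(results)}  (untestable: {len(untestable)})")
print(f"significant after Bonferroni (alpha=0.05): {len(sig)}")
print(f"true switch genes: {sorted(ds.truth.switch_genes)}")
print("top 5 by p-value:")
for r in results[:5]:
    star = "*" if r.gene_id in ds.truth.switch_genes else " "
    print(f"  {star} {r.gene_id}  chi2={r.chi2_stat:8.1f} df={r.df} "
          f"p_bonf={r.p_bonferroni:.2e} maxSD={r.max_usage_sd:.1f}")

# Genes the generator gave a usage swap (marked *) should dominate the top
# of the ranking; maxSD is the largest per-isoform standard deviation of
# relative usage (percentage points) across conditions — the effect-size
# axis of the max-SD ranking plot.
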