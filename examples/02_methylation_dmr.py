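"""Call differentially methylated regions between the two genomes.

Generates paired bisulphite counts with planted DMRs (|delta| = context
threshold + 10 points), applies the region filters (>= 5 methylated
cytosines at >= 5x/10x coverage), and calls DMRs with the context
thresholds CpG >= 50 / CHG >= 25 / CHH >= 10 points at q < 0.05.
"""

import ploidycomp as pc
from ploidycomp.methylation import (
    call_dmrs,
    pseudogene_comparison,
    region_methylation_table,
    weighted_methylation_by_context,
)

cfg = pc.GeneratorConfig(seed=2, n_genes=150)
genes_d, genes_h, pairs = pc.synth.generate_gene_models(cfg)
sites_d, sites_h, truth = pc.synth.generate_methylation_pair(cfg, genes_d, genes_h, pairs)

print("weighted methylation by context (diploid sites):")
for ctx, level in sorted(weighted_methylation_by_context(sites_d).items()):
    print(f"  {ctx}: {100 * level:.1f}%")

regions_d = region_methylation_table(sites_d, genes_d, min_sites=5, min_cov=5)
regions_h = region_methylation_table(sites_h, genes_h, min_sites=5, min_cov=10)
print(f"\nregions passing filters: diploid {len(regions_d)}, hexaploid {len(regions_h)}")

hex2dip = dict(zip(pairs["hexaploid_gene_id"], pairs["diploid_gene_id"]))
dmrs = call_dmrs(regions_d, regions_h, id_map=hex2dip)
called = dmrs[dmrs["is_dmr"]]
print(f"DMRs called: {len(called)} of {len(dmrs)} tested regions")
print(called.groupby(["context", "region_kind"]).size())

merged = called.merge(truth, left_on=["gene_id", "region_kind", "context"],
                      right_on=["diploid_gene_id", "region_kind", "context"])
print(f"of which planted: {int(merged['is_dmr_true'].sum())} "
      "(the rest are false positives; q < 0.05 keeps them near zero)")

delta = pseudogene_comparison(regions_d, genes_d)
print("\npseudogene minus gene methylation (gene bodies):")
for ctx, d in sorted(delta.items()):
    print(f"  {ctx}: {100 * d:+.1f} points  (planted +13.2 CpG / +12.6 CHG / 0 CHH)")
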