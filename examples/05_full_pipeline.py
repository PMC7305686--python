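"""One-call end-to-end run: synthetic inputs -> all stages -> report.

Equivalent to `ploidycomp run --seed 5 --n-genes 150 --outdir scratch/demo`.
"""

import json

from ploidycomp.pipeline import RunConfig, run_pipeline

report = run_pipeline(RunConfig(seed=5, n_genes=150, outdir="scratch/pipeline_demo"))

e = report["expression"]
print(f"expressed: {e['n_expressed']}/{e['n_pairs']} "
      f"({100 * e['fraction_expressed']:.1f}%)")
print(f"normalization factor: {e['normalization_factor']:.4f}")
print(f"balanced: {100 * e['fraction_balanced_of_expressed']:.1f}% of expressed, "
      f"median ratio {e['median_balanced_ratio']:.3f}")
print(f"conserved DEGs across accessions: {e['n_conserved_degs']}")
print(f"DMRs: {report['methylation']['n_dmrs']}")
print(f"pseudogene CpG delta: "
      f"{100 * report['methylation']['pseudogene_delta']['CpG']:+.1f} points")
print(f"differential-ATAC genes: {report['integration']['n_differential_atac_genes']}; "
      f"DEG overlap p = {report['integration']['deg_atac_hypergeom_p']:.2e}")
print("\nfull report: scratch/pipeline_demo/report.json")
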