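"""End-to-end orchestration: synthetic data -> expression classification ->
methylation/DMR analysis -> ATAC post-processing -> integration statistics,
with a consolidated JSON + TSV report.

Every number in the report is recomputed from stage outputs; nothing exists
only in the report. Reruns with the same config are bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import atac as atac_mod
from . import expression as expr_mod
from . import methylation as meth_mod
from . import stats as stats_mod
from . import synth
from .io import read_bed, read_gff3, read_tpm_matrix, write_bed, write_gff3, write_tpm_matrix

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline configuration; thresholds default to the study's values."""

    seed: int = 0
    outdir: str = "ploidycomp_run"
    inputs_dir: str | None = None   # read a previously written dataset instead
    n_genes: int = 200
    tpm_min: float = 1.0
    fold: float = 4.0
    normalization: str = "median_ratio"   # or "fixed"
    fixed_factor: float = expr_mod.DEFAULT_FIXED_FACTOR
    min_meth_sites: int = 5
    min_cov_diploid: int = 5
    min_cov_hexaploid: int = 10
    dmr_alpha: float = 0.05
    merge_gap: int = 10
    promoter_upstream: int = 2000
    atac_min_fold: float = 2.0
    atac_min_abs: int = 50
    generator_overrides: dict = field(default_factory=dict)

    def generator_config(self) -> synth.GeneratorConfig:
        return synth.GeneratorConfig(
            seed=self.seed, n_genes=self.n_genes, **self.generator_overrides
        )


def null_preset_overrides() -> dict:
    """Generator overrides with all planted effects removed."""
    return {
        "balanced_fraction": 1.0, "deg_fraction": 0.0, "balanced_ratio": 1.0,
        "dmr_fraction": 0.0, "atac_diff_fraction": 0.0,
        "meth_rates": {
            "hexaploid": {"CpG": 0.871, "CHG": 0.534, "CHH": 0.034},
            "diploid": {"CpG": 0.871, "CHG": 0.534, "CHH": 0.034},
        },
    }


def write_dataset(cfg: synth.GeneratorConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate the full synthetic dataset and write it as standard formats
    (GFF3, TSV, BED, cytosine reports) plus truth-label sidecars."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    genes_d, genes_h, pairs = synth.generate_gene_models(cfg)
    tpm_d, tpm_h, truth_expr = synth.generate_expression(cfg, pairs)
    accessions = synth.generate_accession_tpms(cfg, tpm_d, n_accessions=2)
    sites_d, sites_h, truth_dmr = synth.generate_methylation_pair(cfg, genes_d, genes_h, pairs)
    reps_d, reps_h, truth_atac = synth.generate_atac_pair(cfg, genes_d, genes_h, pairs)
    _, frags_d = synth.generate_atac(cfg, genes_d, "diploid")
    _, frags_h = synth.generate_atac(cfg, genes_h, "hexaploid")

    paths: dict[str, Path] = {}

    def _save(name: str, writer, *args) -> None:
        paths[name] = out / name
        writer(*args, paths[name])

    _save("diploid.gff3", write_gff3, genes_d)
    _save("hexaploid.gff3", write_gff3, genes_h)
    pairs.to_csv(out / "pairs.tsv", sep="\t", index=False)
    paths["pairs.tsv"] = out / "pairs.tsv"
    _save("tpm_diploid.tsv", write_tpm_matrix, tpm_d)
    _save("tpm_hexaploid.tsv", write_tpm_matrix, tpm_h)
    for i, acc in enumerate(accessions, 2):
        _save(f"tpm_accession{i}.tsv", write_tpm_matrix, acc)
    for name, frame in (("cx_diploid.tsv", sites_d), ("cx_hexaploid.tsv", sites_h)):
        f = frame.copy()
        f["pos"] = f["pos"] + 1
        f["n_unmeth"] = f["n_total"] - f["n_meth"]
        f[["chrom", "pos", "strand", "n_meth", "n_unmeth", "context"]].to_csv(
            out / name, sep="\t", header=False, index=False
        )
        paths[name] = out / name
    for genome, reps in (("diploid", reps_d), ("hexaploid", reps_h)):
        for r, rep in enumerate(reps, 1):
            _save(f"atac_{genome}_rep{r}.bed", write_bed, rep)
    _save("fragments_diploid.bed", write_bed, frags_d)
    _save("fragments_hexaploid.bed", write_bed, frags_h)
    truth_expr.to_csv(out / "truth_expression.tsv", sep="\t", index=False)
    truth_dmr.to_csv(out / "truth_dmr.tsv", sep="\t", index=False)
    truth_atac.to_csv(out / "truth_atac.tsv", sep="\t", index=False)
    return paths


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on the synthetic preset (or a saved dataset) and
    return the consolidated report dict; also writes report.json/report.tsv
    and the serialized config into ``config.outdir``."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config.generator_config()

    if config.inputs_dir is not None:
        src = Path(config.inputs_dir)
        if not src.is_dir():
            raise FileNotFoundError(f"inputs_dir {src} does not exist")
        required = ["diploid.gff3", "hexaploid.gff3", "pairs.tsv",
                    "tpm_diploid.tsv", "tpm_hexaploid.tsv"]
        for name in required:
            if not (src / name).exists():
                raise FileNotFoundError(f"missing input file {src / name}")
        dataset = src
    else:
        write_dataset(cfg, out / "inputs")
        dataset = out / "inputs"

    genes_d = read_gff3(dataset / "diploid.gff3")
    genes_h = read_gff3(dataset / "hexaploid.gff3")
    pairs = pd.read_csv(dataset / "pairs.tsv", sep="\t")
    tpm_d_raw = read_tpm_matrix(dataset / "tpm_diploid.tsv")
    tpm_h_raw = read_tpm_matrix(dataset / "tpm_hexaploid.tsv")
    hex_to_dip = dict(zip(pairs["hexaploid_gene_id"], pairs["diploid_gene_id"]))

    # ---- expression -------------------------------------------------------
    design = {c: c.rsplit("_rep", 1)[0] for c in tpm_d_raw.columns}
    tpm_d = expr_mod.aggregate_replicates(tpm_d_raw, design)
    tpm_h = expr_mod.aggregate_replicates(tpm_h_raw, design)
    expressed = expr_mod.flag_expressed(pairs, tpm_d, tpm_h, config.tpm_min)
    norm = expr_mod.compute_normalization_factor(
        pairs, tpm_d, tpm_h, expressed,
        method=config.normalization, fixed_factor=config.fixed_factor,
    )
    classes = expr_mod.classify_pairs(pairs, tpm_d, tpm_h, expressed,
                                      norm.factor, fold=config.fold)
    summary = expr_mod.stage_specific_summary(classes)
    n_exp = int(expressed.sum())
    balanced_mask = classes["overall_class"] == expr_mod.CLASS_BALANCED
    median_balanced_ratio = float(classes.loc[balanced_mask, "mean_raw_ratio"].median())

    deg_sets = {"accession1": expr_mod.deg_directions(classes, "leaf", key="diploid_gene_id")}
    acc_files = sorted(dataset.glob("tpm_accession*.tsv"))
    for i, path in enumerate(acc_files, 2):
        acc = expr_mod.aggregate_replicates(read_tpm_matrix(path), design)
        acc_expressed = expr_mod.flag_expressed(pairs, acc, tpm_h, config.tpm_min)
        acc_norm = expr_mod.compute_normalization_factor(
            pairs, acc, tpm_h, acc_expressed, method=config.normalization,
            fixed_factor=config.fixed_factor)
        acc_classes = expr_mod.classify_pairs(pairs, acc, tpm_h, acc_expressed,
                                              acc_norm.factor, fold=config.fold)
        deg_sets[f"accession{i}"] = expr_mod.deg_directions(
            acc_classes, "leaf", key="diploid_gene_id")
    conserved = expr_mod.conserved_degs(deg_sets) if len(deg_sets) >= 2 else set()
    classes.to_csv(out / "expression_classes.tsv", sep="\t", index=False)

    # ---- methylation ------------------------------------------------------
    cx_d = pd.read_csv(dataset / "cx_diploid.tsv", sep="\t", header=None,
                       names=["chrom", "pos", "strand", "n_meth", "n_unmeth", "context"])
    cx_h = pd.read_csv(dataset / "cx_hexaploid.tsv", sep="\t", header=None,
                       names=["chrom", "pos", "strand", "n_meth", "n_unmeth", "context"])
    for f in (cx_d, cx_h):
        f["pos"] = f["pos"] - 1
        f["n_total"] = f["n_meth"] + f["n_unmeth"]
    rates_d = meth_mod.weighted_methylation_by_context(cx_d)
    rates_h = meth_mod.weighted_methylation_by_context(cx_h)
    regions_d = meth_mod.region_methylation_table(
        cx_d, genes_d, min_sites=config.min_meth_sites, min_cov=config.min_cov_diploid,
        promoter_upstream=config.promoter_upstream)
    regions_h = meth_mod.region_methylation_table(
        cx_h, genes_h, min_sites=config.min_meth_sites, min_cov=config.min_cov_hexaploid,
        promoter_upstream=config.promoter_upstream)
    dmrs = meth_mod.call_dmrs(regions_d, regions_h, alpha=config.dmr_alpha,
                              id_map=hex_to_dip)
    deg_dip_ids = set(classes.loc[classes["overall_class"] == "deg", "diploid_gene_id"])
    dmr_deg = meth_mod.dmr_deg_overlap(dmrs, deg_dip_ids)
    pseudo_delta = meth_mod.pseudogene_comparison(regions_d, genes_d)
    expressed_dip = set(classes.loc[classes["expressed"], "diploid_gene_id"])
    try:
        tss_test = meth_mod.tss_window_test(cx_d, genes_d, expressed_dip)
        tss_result = {"t": tss_test.t, "df": tss_test.df, "p": tss_test.p}
    except ValueError:
        tss_result = {"t": None, "df": None, "p": None}
    dmrs.to_csv(out / "dmrs.tsv", sep="\t", index=False)

    # ---- ATAC -------------------------------------------------------------
    report_atac = {}
    diff_table = None
    acc_tables = {}
    for genome, genes in (("diploid", genes_d), ("hexaploid", genes_h)):
        reps = [read_bed(p) for p in sorted(dataset.glob(f"atac_{genome}_rep*.bed"))]
        peaks = atac_mod.merge_close_peaks(
            atac_mod.reproducible_peaks(reps), max_gap=config.merge_gap)
        annotated = atac_mod.annotate_peaks(
            peaks, genes, promoter_upstream=config.promoter_upstream)
        cdf = atac_mod.tss_distance_cdf(annotated)
        counts = {cls: sum(p.region_class == cls for p in annotated)
                  for cls in atac_mod.REGION_CLASSES}
        frag = read_bed(dataset / f"fragments_{genome}.bed")
        period = atac_mod.fragment_periodicity(np.array([len(iv) for iv in frag]))
        acc_tables[genome] = atac_mod.gene_accessibility(annotated, genes)
        report_atac[genome] = {
            "n_reproducible_peaks": len(peaks),
            "peak_class_counts": counts,
            "tss_cdf": {str(k): v for k, v in cdf.items()},
            "fragment_period_bp": period.period,
            "fragment_period_significant": period.significant,
        }
        write_bed(peaks, out / f"peaks_{genome}.bed")
    diff_table = atac_mod.differential_accessibility(
        acc_tables["diploid"], acc_tables["hexaploid"], id_map=hex_to_dip,
        min_fold=config.atac_min_fold, min_abs=config.atac_min_abs)
    leaf_degs = set(deg_sets["accession1"])
    venn = atac_mod.deg_atac_overlap(diff_table, leaf_degs)
    diff_ids = set(diff_table.loc[diff_table["is_differential"], "gene_id"])
    universe = set(pairs["diploid_gene_id"])
    overlap_stat = stats_mod.hypergeometric_overlap(
        universe, diff_ids & universe, leaf_degs & universe)
    diff_table.to_csv(out / "differential_atac.tsv", sep="\t", index=False)

    # ---- report -----------------------------------------------------------
    report = {
        "expression": {
            "n_pairs": int(len(pairs)),
            "n_expressed": n_exp,
            "fraction_expressed": n_exp / len(pairs),
            "normalization_factor": norm.factor,
            "normalization_method": norm.method,
            "n_balanced": int(balanced_mask.sum()),
            "fraction_balanced_of_expressed": float(balanced_mask.sum() / n_exp) if n_exp else None,
            "median_balanced_ratio": median_balanced_ratio,
            "deg_per_tissue": summary.to_dict(orient="index"),
            "n_conserved_degs": len(conserved),
        },
        "methylation": {
            "weighted_rates_diploid": rates_d,
            "weighted_rates_hexaploid": rates_h,
            "n_regions_diploid": int(len(regions_d)),
            "n_regions_hexaploid": int(len(regions_h)),
            "n_dmrs": int(dmrs["is_dmr"].sum()) if len(dmrs) else 0,
            "dmr_deg_table": dmr_deg.to_dict(orient="records"),
            "pseudogene_delta": pseudo_delta,
            "tss_window_test": tss_result,
        },
        "atac": report_atac,
        "integration": {
            "n_differential_atac_genes": len(diff_ids),
            "deg_atac_venn": venn,
            "deg_atac_hypergeom_p": overlap_stat.p_hyper,
        },
    }
    (out / "config.json").write_text(
        json.dumps(dataclasses.asdict(config), indent=2, default=str) + "\n")
    (out / "report.json").write_text(json.dumps(report, indent=2, default=float) + "\n")
    with open(out / "report.tsv", "w") as fh:
        for key, value in _flatten(report):
            fh.write(f"{key}\t{value}\n")
    return report


def _flatten(obj, prefix=""):
    if isinstance(obj, dict):
        for k, v in obj.items():
            yield from _flatten(v, f"{prefix}{k}." if prefix else f"{k}.")
    elif isinstance(obj, list):
        for i, v in enumerate(obj):
            yield from _flatten(v, f"{prefix}{i}.")
    else:
        yield prefix.rstrip("."), obj
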