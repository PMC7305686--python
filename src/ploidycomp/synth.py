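"""Synthetic data with the statistical structure of a diploid/hexaploid
chromosome-arm comparison.

The generators emulate the study design the analysis modules expect:

* collinear 1:1 syntenic gene pairs along one chromosome arm of a diploid
  progenitor ("diploid", cf. *Ae. tauschii* 3L) and a hexaploid derivative
  ("hexaploid", cf. bread-wheat 3DL), with a configurable pseudogene fraction;
* TPM tables in which ~70% of expressed pairs are "proportionately reduced"
  (hexaploid mean ~= 0.40 x diploid, multiplicative log-normal noise) and
  ~30% are differentially expressed at >=4-fold after cross-ploidy
  normalization;
* per-cytosine bisulphite counts whose context means sit at the genome-wide
  methylation rates (hexaploid CpG/CHG/CHH 89.9/59.4/3.8%, diploid
  87.1/53.4/3.4%), with gene-level Beta overdispersion, binomial read
  sampling and elevated pseudogene CpG/CHG methylation;
* ATAC peak replicates concentrated near TSSs — tighter and narrower in the
  hexaploid — and fragment lengths carrying a ~10.5 bp multiplicative comb.

Every generator is a pure function of (config, seed); truth labels are
returned alongside the data (and written as sidecar TSVs by the CLI) but are
never consumed by the analysis stages themselves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CytosineSite, GeneModel, Interval

#: context-specific DMR |delta| thresholds, percentage points
DMR_THRESHOLDS = {"CpG": 50.0, "CHG": 25.0, "CHH": 10.0}

# stream labels so each generator draws from an independent, reproducible
# stream of the same master seed
_STREAMS = {
    "genes": 11,
    "expression": 12,
    "accessions": 13,
    "methylation_diploid": 21,
    "methylation_hexaploid": 22,
    "methylation_pair": 23,
    "atac_diploid": 31,
    "atac_hexaploid": 32,
    "atac_pair": 33,
    "fragments": 34,
}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic study; defaults follow the real study's
    printed rates where it prints them (see docs/methods.md)."""

    seed: int = 0
    n_genes: int = 200
    gene_spacing: int = 20_000          # bp of chromosome per gene slot
    chrom_len: int | None = None        # derived from n_genes if None
    pseudogene_fraction: float = 0.05

    # expression
    tissues: tuple[str, ...] = ("leaf", "seedling", "root", "grain_10dap", "grain_27dap")
    replicates: int = 3
    expressed_fraction: float = 0.69
    balanced_fraction: float = 0.70
    balanced_ratio: float = 0.40
    deg_fraction: float = 0.30
    deg_min_fold: float = 4.0
    tpm_noise_sd: float = 0.2           # log-scale pair-level ratio noise
    replicate_noise_sd: float = 0.10    # log-scale replicate noise
    tissue_effect_sd: float = 0.30
    base_log_tpm_mean: float = 2.0
    base_log_tpm_sd: float = 1.0
    accession_noise_sd: float = 0.15

    # methylation
    meth_rates: dict = field(default_factory=lambda: {
        "hexaploid": {"CpG": 0.899, "CHG": 0.594, "CHH": 0.038},
        "diploid": {"CpG": 0.871, "CHG": 0.534, "CHH": 0.034},
    })
    pseudogene_offsets: dict = field(default_factory=lambda: {
        "CpG": 0.132, "CHG": 0.126, "CHH": 0.0,
    })
    beta_concentration: float = 20.0    # gene-level overdispersion
    coverage_mean: float = 10.0         # reads/site, Poisson
    site_density: float = 0.02          # cytosines per bp
    context_probs: dict = field(default_factory=lambda: {
        "CpG": 0.3, "CHG": 0.3, "CHH": 0.4,
    })
    promoter_upstream: int = 2000
    # optional coupling of TSS-proximal methylation to expression (off by
    # default so marginal context rates equal meth_rates exactly)
    tss_dip_depth: float = 0.0
    tss_dip_depth_nonexpressed: float = 0.0
    tss_dip_width: float = 150.0

    # paired-genome DMR generation
    dmr_fraction: float = 0.10
    dmr_delta_extra: float = 10.0       # planted |delta| = threshold + this, points
    dmr_coverage_mean: float = 50.0
    dmr_sites_per_region: int = 14      # expected sites per region per context

    # ATAC
    atac: dict = field(default_factory=lambda: {
        "diploid": {"peak_rate": 2.0, "tss_scale": 25_000.0,
                    "width_meanlog": np.log(500.0), "width_sdlog": 0.4},
        "hexaploid": {"peak_rate": 1.0, "tss_scale": 4_330.0,
                      "width_meanlog": np.log(300.0), "width_sdlog": 0.4},
    })
    atac_jitter_sd: float = 15.0
    atac_noise_rate: float = 0.15       # replicate-specific noise peaks / true peak
    atac_replicates: int = 3
    atac_diff_fraction: float = 0.15    # genes losing hexaploid promoter peaks
    fragment_period: float = 10.5
    fragment_comb_amplitude: float = 0.35
    n_fragments: int = 20_000

    def __post_init__(self) -> None:
        for name in ("pseudogene_fraction", "expressed_fraction",
                     "balanced_fraction", "balanced_ratio", "deg_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(self.balanced_fraction + self.deg_fraction - 1.0) > 1e-9:
            raise ValueError("balanced_fraction + deg_fraction must be 1 among expressed pairs")
        if self.deg_min_fold <= 1:
            raise ValueError("deg_min_fold must exceed 1")
        if self.chrom_len is None:
            self.chrom_len = self.n_genes * self.gene_spacing
        min_len = self.n_genes * 6000  # ~4 kb max gene + breathing room
        if self.chrom_len < min_len:
            raise ValueError(
                f"chrom_len={self.chrom_len} too small for {self.n_genes} genes "
                f"(minimum {min_len})"
            )


def _rng(cfg: GeneratorConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), _STREAMS[stream]])


# ---------------------------------------------------------------------------
# gene models


def generate_gene_models(
    cfg: GeneratorConfig,
) -> tuple[list[GeneModel], list[GeneModel], pd.DataFrame]:
    """Collinear 1:1 syntenic gene pairs on one chromosome arm per genome.

    Returns (diploid_genes, hexaploid_genes, pair_table). The pair table has
    columns diploid_gene_id, hexaploid_gene_id, pair_index, is_pseudogene.
    Pairs sorted by diploid position are also sorted by hexaploid position.
    """
    if cfg.n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    rng = _rng(cfg, "genes")
    spacing = cfg.chrom_len // cfg.n_genes
    n_pseudo = int(round(cfg.pseudogene_fraction * cfg.n_genes))
    pseudo_idx = set(rng.choice(cfg.n_genes, size=n_pseudo, replace=False).tolist())

    # one structural draw per pair: syntenic homologs share gene geometry
    geometry = []
    for i in range(cfg.n_genes):
        length = int(rng.integers(1500, 4000))
        offset = int(rng.integers(2500, max(2501, spacing - length - 2500 + 1)))
        strand = "+" if rng.random() < 0.5 else "-"
        utr5 = int(rng.integers(100, 400))
        intron_len = int(rng.integers(80, 300))
        geometry.append((length, offset, strand, utr5, intron_len))

    def _one_genome(prefix: str, chrom: str) -> list[GeneModel]:
        genes = []
        for i, (length, offset, strand, utr5, intron_len) in enumerate(geometry):
            start = i * spacing + offset
            end = start + length
            tss = start if strand == "+" else end - 1
            tts = end - 1 if strand == "+" else start
            atg = start + utr5 if strand == "+" else end - 1 - utr5
            # two exons with one internal intron
            intron_s = start + length // 3
            exons = [(start, intron_s), (intron_s + intron_len, end)]
            genes.append(GeneModel(
                gene_id=f"{prefix}_{i:04d}", chrom=chrom, start=start, end=end,
                strand=strand, tss=tss, tts=tts, atg=atg, exons=exons,
                biotype="pseudogene" if i in pseudo_idx else "gene",
            ))
        return genes

    diploid = _one_genome("AT3L", "3L")
    hexaploid = _one_genome("TA3DL", "3DL")
    pairs = pd.DataFrame({
        "pair_index": np.arange(cfg.n_genes),
        "diploid_gene_id": [g.gene_id for g in diploid],
        "hexaploid_gene_id": [g.gene_id for g in hexaploid],
        "is_pseudogene": [g.is_pseudogene for g in diploid],
    })
    return diploid, hexaploid, pairs


# ---------------------------------------------------------------------------
# expression


def generate_expression(
    cfg: GeneratorConfig, pairs: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-replicate TPM tables for both genomes plus truth labels.

    Expressed pairs split into "balanced" (hexaploid mean =
    balanced_ratio x diploid x lognormal(0, tpm_noise_sd)) and DEG pairs
    planted at folds log-uniform in [deg_min_fold, 4 x deg_min_fold] *after*
    the implied cross-ploidy normalization, direction random. Replicate noise
    is multiplicative log-normal. Truth columns: expressed, true_class,
    true_fold, true_ratio.
    """
    rng = _rng(cfg, "expression")
    n = len(pairs)
    n_exp = int(round(cfg.expressed_fraction * n))
    expressed = np.zeros(n, dtype=bool)
    expressed[rng.choice(n, size=n_exp, replace=False)] = True

    true_class = np.full(n, "not_expressed", dtype=object)
    exp_idx = np.flatnonzero(expressed)
    n_bal = int(round(cfg.balanced_fraction * n_exp))
    bal_idx = rng.choice(exp_idx, size=n_bal, replace=False)
    true_class[bal_idx] = "balanced"
    deg_idx = np.setdiff1d(exp_idx, bal_idx)
    up_hex = rng.random(deg_idx.size) < 0.5
    true_class[deg_idx[up_hex]] = "deg_up_hexaploid"
    true_class[deg_idx[~up_hex]] = "deg_up_diploid"

    base = np.exp(rng.normal(cfg.base_log_tpm_mean, cfg.base_log_tpm_sd, size=n))
    n_tis = len(cfg.tissues)
    tissue_eff = np.exp(rng.normal(0.0, cfg.tissue_effect_sd, size=(n, n_tis)))
    dip_mean = base[:, None] * tissue_eff

    ratio = np.full(n, np.nan)
    fold = np.full(n, np.nan)
    is_bal = true_class == "balanced"
    ratio[is_bal] = cfg.balanced_ratio * np.exp(
        rng.normal(0.0, cfg.tpm_noise_sd, size=is_bal.sum())
    )
    is_deg = np.isin(true_class, ["deg_up_hexaploid", "deg_up_diploid"])
    f = np.exp(rng.uniform(np.log(cfg.deg_min_fold),
                           np.log(4 * cfg.deg_min_fold), size=is_deg.sum()))
    fold[is_deg] = f
    signed = np.where(true_class[is_deg] == "deg_up_hexaploid", f, 1.0 / f)
    ratio[is_deg] = cfg.balanced_ratio * signed

    hex_mean = dip_mean * np.where(expressed, ratio, 1.0)[:, None]
    low = rng.uniform(0.0, 0.3, size=(n, n_tis))
    dip_mean = np.where(expressed[:, None], dip_mean, low)
    hex_mean = np.where(expressed[:, None],
                        hex_mean, rng.uniform(0.0, 0.3, size=(n, n_tis)))

    cols = [f"{t}_rep{r + 1}" for t in cfg.tissues for r in range(cfg.replicates)]

    def _replicates(mean: np.ndarray, index: Sequence[str]) -> pd.DataFrame:
        noise = np.exp(rng.normal(0.0, cfg.replicate_noise_sd,
                                  size=(n, n_tis, cfg.replicates)))
        vals = (mean[:, :, None] * noise).reshape(n, n_tis * cfg.replicates)
        return pd.DataFrame(vals, index=pd.Index(index, name="gene_id"), columns=cols)

    tpm_d = _replicates(dip_mean, pairs["diploid_gene_id"])
    tpm_h = _replicates(hex_mean, pairs["hexaploid_gene_id"])
    truth = pd.DataFrame({
        "diploid_gene_id": pairs["diploid_gene_id"],
        "hexaploid_gene_id": pairs["hexaploid_gene_id"],
        "expressed": expressed,
        "true_class": true_class,
        "true_fold": fold,
        "true_ratio": ratio,
    })
    return tpm_d, tpm_h, truth


def generate_accession_tpms(
    cfg: GeneratorConfig, tpm_diploid: pd.DataFrame, n_accessions: int = 2
) -> list[pd.DataFrame]:
    """Noisy TPM copies emulating additional diploid accessions."""
    rng = _rng(cfg, "accessions")
    out = []
    for _ in range(n_accessions):
        noise = np.exp(rng.normal(0.0, cfg.accession_noise_sd, size=tpm_diploid.shape))
        out.append(tpm_diploid * noise)
    return out


# ---------------------------------------------------------------------------
# methylation


def _gene_level_means(
    cfg: GeneratorConfig, genes: Sequence[GeneModel], genome: str,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Per-gene latent methylation fractions per context (Beta-overdispersed
    around the context rate, pseudogenes elevated, clipped into (0, 1))."""
    c = cfg.beta_concentration
    out = {}
    pseudo = np.array([g.is_pseudogene for g in genes])
    for ctx, rate in cfg.meth_rates[genome].items():
        mean = np.full(len(genes), rate)
        mean[pseudo] += cfg.pseudogene_offsets.get(ctx, 0.0)
        if (mean > 1.0).any() or (mean < 0.0).any():
            warnings.warn(
                f"{ctx} rate outside [0,1] after pseudogene offset; clipped",
                stacklevel=3,
            )
            mean = np.clip(mean, 0.0, 1.0)
        out[ctx] = _beta_or_degenerate(rng, mean, c)
    return out


def _beta_or_degenerate(
    rng: np.random.Generator, mean: np.ndarray | float, concentration: float
) -> np.ndarray:
    """Beta draws around ``mean``; exactly 0 or 1 passes through unchanged
    (fully (un)methylated is deterministic, not overdispersed)."""
    mean = np.atleast_1d(np.asarray(mean, dtype=float))
    out = mean.copy()
    mid = (mean > 0.0) & (mean < 1.0)
    m = np.clip(mean[mid], 0.001, 0.999)
    out[mid] = rng.beta(m * concentration, (1 - m) * concentration)
    return out


def generate_methylation(
    cfg: GeneratorConfig,
    genes: Sequence[GeneModel],
    genome: str,
    expressed_ids: set[str] | None = None,
    as_frame: bool = False,
) -> list[CytosineSite] | pd.DataFrame:
    """Per-cytosine bisulphite counts for one genome.

    Sites are scattered uniformly along the chromosome at ``site_density``;
    each gets a context (categorical), a true methylation probability (the
    gene-level latent fraction inside gene bodies/promoters, a fresh Beta
    draw around the context rate elsewhere), Poisson(coverage_mean) total
    reads and Binomial methylated reads. With ``tss_dip_depth > 0`` and
    ``expressed_ids`` given, probabilities within ``tss_dip_width`` of the
    TSS are multiplicatively suppressed, more strongly for expressed genes.
    """
    rng = _rng(cfg, f"methylation_{genome}")
    chrom = genes[0].chrom
    span = cfg.chrom_len
    n_sites = int(cfg.site_density * span)
    pos = np.sort(rng.choice(span, size=n_sites, replace=False))
    ctx_names = list(cfg.context_probs)
    ctx_p = np.array([cfg.context_probs[c] for c in ctx_names], dtype=float)
    ctx_idx = rng.choice(len(ctx_names), size=n_sites, p=ctx_p / ctx_p.sum())
    strand = np.where(rng.random(n_sites) < 0.5, "+", "-")

    gene_means = _gene_level_means(cfg, genes, genome, rng)
    # background: fresh Beta per site around the context rate
    c = cfg.beta_concentration
    p = np.empty(n_sites)
    for k, ctx in enumerate(ctx_names):
        m = float(cfg.meth_rates[genome][ctx])
        sel = ctx_idx == k
        p[sel] = _beta_or_degenerate(rng, np.full(int(sel.sum()), m), c)

    # overwrite sites inside gene bodies / promoters with gene-level values
    for gi, g in enumerate(genes):
        if g.strand == "+":
            lo, hi = g.start - cfg.promoter_upstream, g.end
        else:
            lo, hi = g.start, g.end + cfg.promoter_upstream
        i0, i1 = np.searchsorted(pos, lo), np.searchsorted(pos, hi)
        idx = np.arange(i0, i1)
        for k, ctx in enumerate(ctx_names):
            p[idx[ctx_idx[idx] == k]] = gene_means[ctx][gi]
        if cfg.tss_dip_depth > 0 and expressed_ids is not None:
            depth = (cfg.tss_dip_depth if g.gene_id in expressed_ids
                     else cfg.tss_dip_depth_nonexpressed)
            if depth > 0:
                d = np.abs(pos[idx] - g.tss)
                p[idx] *= 1.0 - depth * np.exp(-d / cfg.tss_dip_width)

    n_total = rng.poisson(cfg.coverage_mean, size=n_sites)
    n_meth = rng.binomial(n_total, p)

    frame = pd.DataFrame({
        "chrom": chrom,
        "pos": pos,
        "strand": strand,
        "context": np.array(ctx_names, dtype=object)[ctx_idx],
        "n_meth": n_meth,
        "n_total": n_total,
    })
    if as_frame:
        return frame
    return [
        CytosineSite(chrom, int(r.pos), r.strand, r.context, int(r.n_meth), int(r.n_total))
        for r in frame.itertuples()
    ]


def _region_span(g: GeneModel, kind: str, upstream: int) -> tuple[int, int]:
    """0-based half-open span of a gene body or its strand-aware promoter."""
    if kind == "gene_body":
        return g.start, g.end
    if g.strand == "+":
        return max(0, g.start - upstream), g.start
    return g.end, g.end + upstream


def generate_methylation_pair(
    cfg: GeneratorConfig,
    genes_diploid: Sequence[GeneModel],
    genes_hexaploid: Sequence[GeneModel],
    pairs: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Coordinated bisulphite counts for both genomes with planted DMRs.

    Genes without a planted DMR share the same latent region-level
    methylation fraction in both genomes, so null regions differ only by
    read sampling. A fraction ``dmr_fraction`` of (gene, region, context)
    triples gets a planted |delta| of the context DMR threshold plus
    ``dmr_delta_extra`` percentage points, signed toward the feasible side.
    Coverage is ``dmr_coverage_mean``. Returns (sites_diploid_frame,
    sites_hexaploid_frame, truth).
    """
    rng = _rng(cfg, "methylation_pair")
    c = cfg.beta_concentration
    contexts = list(DMR_THRESHOLDS)
    rows_d, rows_h, truth_rows = [], [], []
    for _, pair in pairs.iterrows():
        gd = genes_diploid[pair.pair_index]
        gh = genes_hexaploid[pair.pair_index]
        for kind in ("gene_body", "promoter"):
            for ctx in contexts:
                base_rate = cfg.meth_rates["diploid"][ctx]
                if gd.is_pseudogene:
                    base_rate += cfg.pseudogene_offsets.get(ctx, 0.0)
                base_rate = float(np.clip(base_rate, 0.001, 0.999))
                level_d = float(rng.beta(base_rate * c, (1 - base_rate) * c))
                is_dmr = rng.random() < cfg.dmr_fraction
                if is_dmr:
                    delta = (DMR_THRESHOLDS[ctx] + cfg.dmr_delta_extra) / 100.0
                    up_ok = level_d + delta <= 0.995
                    down_ok = level_d - delta >= 0.005
                    if up_ok and down_ok:
                        sign = 1.0 if rng.random() < 0.5 else -1.0
                    else:
                        sign = 1.0 if up_ok else -1.0
                    level_h = level_d + sign * delta
                else:
                    level_h = level_d
                truth_rows.append({
                    "diploid_gene_id": gd.gene_id,
                    "hexaploid_gene_id": gh.gene_id,
                    "region_kind": kind, "context": ctx,
                    "level_diploid": level_d, "level_hexaploid": level_h,
                    "is_dmr_true": is_dmr,
                    "delta_true_points": (level_h - level_d) * 100.0,
                })
                for g, level, rows in ((gd, level_d, rows_d), (gh, level_h, rows_h)):
                    lo, hi = _region_span(g, kind, cfg.promoter_upstream)
                    n_sites = max(8, int(rng.poisson(cfg.dmr_sites_per_region)))
                    positions = np.sort(rng.integers(lo, hi, size=n_sites))
                    n_total = rng.poisson(cfg.dmr_coverage_mean, size=n_sites)
                    n_meth = rng.binomial(n_total, level)
                    for ps, nt, nm in zip(positions, n_total, n_meth):
                        rows.append((g.chrom, int(ps), "+", ctx, int(nm), int(nt)))
    cols = ["chrom", "pos", "strand", "context", "n_meth", "n_total"]
    return (
        pd.DataFrame(rows_d, columns=cols),
        pd.DataFrame(rows_h, columns=cols),
        pd.DataFrame(truth_rows),
    )


def generate_tss_window_dataset(
    cfg: GeneratorConfig,
    window: int = 20,
    context: str = "CpG",
    expressed_shift: float = -0.25,
    coverage: int = 20,
) -> tuple[pd.DataFrame, list[GeneModel], list[GeneModel], set[str]]:
    """Bisulphite counts fully covering the TSS +- ``window`` bp of every
    diploid gene — one covered cytosine per offset per gene — for exercising
    the TSS-window expression contrast.

    Expressed genes (a random ~half) have their per-gene methylation
    probability shifted by ``expressed_shift`` inside the window (clipped to
    [0.01, 0.99]); 0 gives identical group distributions. Returns
    (sites_frame, diploid_genes, hexaploid_genes, expressed_ids).
    """
    rng = _rng(cfg, "methylation_pair")
    genes_d, genes_h, _ = generate_gene_models(cfg)
    n = len(genes_d)
    expressed_ids = set(
        g.gene_id for g in
        (genes_d[i] for i in rng.choice(n, size=n // 2, replace=False))
    )
    rate = cfg.meth_rates["diploid"][context]
    offsets = np.arange(-window, window + 1)
    rows = []
    for g in genes_d:
        base = float(_beta_or_degenerate(rng, rate, cfg.beta_concentration)[0])
        p = base + (expressed_shift if g.gene_id in expressed_ids else 0.0)
        p = float(np.clip(p, 0.01, 0.99))
        pos = g.tss + offsets if g.strand == "+" else g.tss - offsets
        n_meth = rng.binomial(coverage, p, size=offsets.size)
        for ps, nm in zip(pos, n_meth):
            rows.append((g.chrom, int(ps), "+", context, int(nm), coverage))
    frame = pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context", "n_meth", "n_total"]
    ).drop_duplicates(subset=["chrom", "pos"]).reset_index(drop=True)
    return frame, genes_d, genes_h, expressed_ids


# ---------------------------------------------------------------------------
# ATAC


def sample_fragment_lengths(
    cfg: GeneratorConfig, n: int, rng: np.random.Generator | None = None,
    period: float | None = None,
) -> np.ndarray:
    """Fragment lengths from a sub-nucleosomal + mono/di-nucleosome mixture
    modulated by a multiplicative comb of the configured period."""
    rng = rng if rng is not None else _rng(cfg, "fragments")
    period = cfg.fragment_period if period is None else period
    lengths = np.arange(30, 601)
    base = (
        0.55 * np.exp(-(lengths - 30) / 100.0)
        + 0.30 * np.exp(-0.5 * ((lengths - 200) / 30.0) ** 2)
        + 0.15 * np.exp(-0.5 * ((lengths - 390) / 45.0) ** 2)
    )
    comb = 1.0 + cfg.fragment_comb_amplitude * np.cos(2 * np.pi * lengths / period)
    w = base * comb
    return rng.choice(lengths, size=n, p=w / w.sum())


def _true_peaks(
    cfg: GeneratorConfig, genes: Sequence[GeneModel], genome: str,
    rng: np.random.Generator,
    drop_promoter_ids: set[str] | None = None,
) -> list[Interval]:
    params = cfg.atac[genome]
    peaks = []
    for g in genes:
        n = rng.poisson(params["peak_rate"])
        for j in range(n):
            offset = rng.exponential(params["tss_scale"])
            sign = 1.0 if rng.random() < 0.5 else -1.0
            center = g.tss + sign * offset
            width = np.exp(rng.normal(params["width_meanlog"], params["width_sdlog"]))
            start = int(round(center - width / 2))
            end = int(round(center + width / 2))
            start, end = max(0, start), min(cfg.chrom_len, end)
            if end - start < 20:
                continue
            if drop_promoter_ids and g.gene_id in drop_promoter_ids and offset < 2000:
                continue
            peaks.append(Interval(g.chrom, start, end, f"{g.gene_id}_pk{j}"))
    peaks.sort(key=lambda p: (p.chrom, p.start, p.end))
    return peaks


def _replicate_sets(
    cfg: GeneratorConfig, true_peaks: list[Interval], rng: np.random.Generator,
) -> list[list[Interval]]:
    reps = []
    for r in range(cfg.atac_replicates):
        rep = []
        for p in true_peaks:
            if cfg.atac_jitter_sd > 0:
                ds = int(round(rng.normal(0, cfg.atac_jitter_sd)))
                de = int(round(rng.normal(0, cfg.atac_jitter_sd)))
            else:
                ds = de = 0
            s, e = max(0, p.start + ds), p.end + de
            if e - s >= 20:
                rep.append(Interval(p.chrom, s, e, p.name))
        if cfg.atac_noise_rate > 0 and true_peaks:
            n_noise = rng.poisson(cfg.atac_noise_rate * len(true_peaks))
            chrom = true_peaks[0].chrom
            for k in range(n_noise):
                s = int(rng.integers(0, cfg.chrom_len - 600))
                w = int(rng.integers(80, 400))
                rep.append(Interval(chrom, s, s + w, f"noise_r{r}_{k}"))
        rep.sort(key=lambda p: (p.chrom, p.start, p.end))
        reps.append(rep)
    return reps


def generate_atac(
    cfg: GeneratorConfig, genes: Sequence[GeneModel], genome: str,
) -> tuple[list[list[Interval]], list[Interval]]:
    """Replicate ATAC peak sets plus fragment intervals for one genome.

    Latent true peaks are placed around TSSs with an exponential distance
    scale and log-normal widths (both genome-specific; the hexaploid is
    tighter and narrower). Replicates are jittered copies plus
    replicate-specific noise peaks. Fragments carry the configured length
    periodicity.
    """
    rng = _rng(cfg, f"atac_{genome}")
    true_peaks = _true_peaks(cfg, genes, genome, rng)
    reps = _replicate_sets(cfg, true_peaks, rng)
    lengths = sample_fragment_lengths(cfg, cfg.n_fragments, rng)
    starts = rng.integers(0, cfg.chrom_len - 601, size=cfg.n_fragments)
    chrom = genes[0].chrom
    fragments = [
        Interval(chrom, int(s), int(s + L), f"frag{i}")
        for i, (s, L) in enumerate(zip(starts, lengths))
    ]
    return reps, fragments


def generate_atac_pair(
    cfg: GeneratorConfig,
    genes_diploid: Sequence[GeneModel],
    genes_hexaploid: Sequence[GeneModel],
    pairs: pd.DataFrame,
    width_ratio: float = 0.62,
) -> tuple[list[list[Interval]], list[list[Interval]], pd.DataFrame]:
    """Coordinated replicate peak sets for both genomes with planted
    promoter-accessibility losses.

    Diploid latent peaks are generated from the diploid genome parameters;
    each is carried over to the syntenic hexaploid gene at the same
    TSS-relative offset with its width shrunk by ``width_ratio`` (so genic
    accessibility is conserved but narrower, below the default 2-fold
    differential threshold). A fraction ``atac_diff_fraction`` of pairs with
    at least one TSS-proximal (<2 kb) peak loses all such hexaploid peaks.
    Truth column: atac_diff_true (True only where a loss was actually
    planted and observable).
    """
    rng = _rng(cfg, "atac_pair")
    rng_d = _rng(cfg, "atac_diploid")
    gene_by_id = {g.gene_id: g for g in genes_diploid}
    hex_by_index = {int(r.pair_index): genes_hexaploid[int(r.pair_index)]
                    for r in pairs.itertuples()}
    dip_index = {genes_diploid[int(r.pair_index)].gene_id: int(r.pair_index)
                 for r in pairs.itertuples()}

    # latent diploid peaks, tracked with their source gene and TSS offset
    latent: list[tuple[GeneModel, float, float]] = []  # (gene, signed_offset, width)
    params = cfg.atac["diploid"]
    for g in genes_diploid:
        for _ in range(rng_d.poisson(params["peak_rate"])):
            offset = rng_d.exponential(params["tss_scale"])
            sign = 1.0 if rng_d.random() < 0.5 else -1.0
            width = np.exp(rng_d.normal(params["width_meanlog"], params["width_sdlog"]))
            latent.append((g, sign * offset, width))

    proximal_genes = {g.gene_id for g, off, _ in latent if abs(off) < 2000}
    candidates = sorted(proximal_genes)
    n_diff = int(round(cfg.atac_diff_fraction * len(pairs)))
    n_diff = min(n_diff, len(candidates))
    diff_dip_ids = set(rng.choice(candidates, size=n_diff, replace=False).tolist())

    def _mk(chrom: str, center: float, width: float, name: str) -> Interval | None:
        s = max(0, int(round(center - width / 2)))
        e = min(cfg.chrom_len, int(round(center + width / 2)))
        return Interval(chrom, s, e, name) if e - s >= 20 else None

    true_d: list[Interval] = []
    true_h: list[Interval] = []
    for i, (g, off, width) in enumerate(latent):
        iv = _mk(g.chrom, g.tss + off, width, f"{g.gene_id}_pk{i}")
        if iv:
            true_d.append(iv)
        gh = hex_by_index[dip_index[g.gene_id]]
        if g.gene_id in diff_dip_ids and abs(off) < 2000:
            continue  # planted hexaploid promoter loss
        ivh = _mk(gh.chrom, gh.tss + off, width * width_ratio, f"{gh.gene_id}_pk{i}")
        if ivh:
            true_h.append(ivh)
    true_d.sort(key=lambda p: (p.chrom, p.start, p.end))
    true_h.sort(key=lambda p: (p.chrom, p.start, p.end))
    reps_d = _replicate_sets(cfg, true_d, rng_d)
    rng_h = _rng(cfg, "atac_hexaploid")
    reps_h = _replicate_sets(cfg, true_h, rng_h)

    truth = pairs[["diploid_gene_id", "hexaploid_gene_id"]].copy()
    truth["atac_diff_true"] = truth["diploid_gene_id"].isin(diff_dip_ids)
    return reps_d, reps_h, truth
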