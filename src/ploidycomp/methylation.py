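"""Context-resolved DNA-methylation analysis.

Levels are *weighted* methylation: summed methylated reads over summed total
reads across the cytosines of interest, so deeply covered sites carry more
weight than shallow ones. Region-level aggregates apply the study's filters
(>= 5 methylated cytosines per region, each with a minimum coverage — 5x for
the diploid, 10x for the hexaploid by default) before a region is reported.
Differentially methylated regions (DMRs) require both a BH-adjusted
two-proportion test q < 0.05 and a context-specific absolute difference:
>= 50 percentage points for CpG, >= 25 for CHG, >= 10 for CHH.

Metaprofiles use fixed-width flank bins (3 kb up/downstream of the TSS/TTS)
and normalized-length gene-body bins, strand-aware throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import CytosineSite, GeneModel

#: context-specific DMR |delta| thresholds in percentage points
DMR_THRESHOLDS = {"CpG": 50.0, "CHG": 25.0, "CHH": 10.0}

SITE_COLUMNS = ["chrom", "pos", "strand", "context", "n_meth", "n_total"]


def sites_to_frame(sites) -> pd.DataFrame:
    """Normalize a site collection (CytosineSite list or DataFrame) to a
    DataFrame with SITE_COLUMNS, sorted by (chrom, pos)."""
    if isinstance(sites, pd.DataFrame):
        frame = sites[SITE_COLUMNS].copy()
    else:
        frame = pd.DataFrame(
            [(s.chrom, s.pos, s.strand, s.context, s.n_meth, s.n_total) for s in sites],
            columns=SITE_COLUMNS,
        )
    return frame.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# context calling


def call_context(
    reference: Mapping[str, str], chrom: str, pos: int, strand: str
) -> str | None:
    """Classify a cytosine into CpG / CHG / CHH from the reference sequence.

    ``pos`` is 0-based; for strand "-" the context is read on the reverse
    complement. Returns None (with a warning) when the site is within 2 bp of
    the contig end; raises if the strand-corrected base is not a cytosine.
    """
    seq = reference[chrom]
    if strand == "+":
        if seq[pos] != "C":
            raise ValueError(f"{chrom}:{pos}(+) is {seq[pos]}, not C")
        if pos + 2 >= len(seq):
            warnings.warn(f"{chrom}:{pos}: too close to contig end; context undeterminable")
            return None
        nxt1, nxt2 = seq[pos + 1], seq[pos + 2]
    elif strand == "-":
        comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
        if seq[pos] != "G":  # C on the reverse strand
            raise ValueError(f"{chrom}:{pos}(-) is {comp.get(seq[pos], '?')}, not C")
        if pos - 2 < 0:
            warnings.warn(f"{chrom}:{pos}: too close to contig end; context undeterminable")
            return None
        nxt1, nxt2 = comp[seq[pos - 1]], comp[seq[pos - 2]]
    else:
        raise ValueError(f"bad strand {strand!r}")
    if nxt1 == "G":
        return "CpG"
    if nxt2 == "G":
        return "CHG"
    return "CHH"


# ---------------------------------------------------------------------------
# weighted methylation


def weighted_methylation(sites) -> float:
    """Sum(n_meth) / Sum(n_total) over sites with any coverage; NaN if none."""
    frame = sites if isinstance(sites, pd.DataFrame) else sites_to_frame(sites)
    total = int(frame["n_total"].sum())
    if total == 0:
        return float("nan")
    return float(frame["n_meth"].sum() / total)


def weighted_methylation_by_context(sites) -> dict[str, float]:
    frame = sites if isinstance(sites, pd.DataFrame) else sites_to_frame(sites)
    out = {}
    for ctx, sub in frame.groupby("context"):
        out[str(ctx)] = weighted_methylation(sub)
    return out


# ---------------------------------------------------------------------------
# metaprofiles


@dataclass
class Metaprofile:
    """Binned mean methylation around and across genes of one group."""

    context: str
    group: str
    bins: np.ndarray        # bin means in [0, 1] (NaN where uncovered)
    bin_counts: np.ndarray  # total reads per bin
    layout: tuple[int, int, int]


def _signed_offset(pos: np.ndarray, gene: GeneModel) -> np.ndarray:
    """Strand-aware position relative to the TSS (0 at the TSS, negative
    upstream, increasing through the gene body toward the TTS)."""
    if gene.strand == "+":
        return pos - gene.tss
    return gene.tss - pos


def metaprofile(
    sites,
    genes: Sequence[GeneModel],
    expressed_ids: set[str],
    context: str,
    bins: tuple[int, int, int] = (50, 40, 50),
    flank: int = 3000,
) -> dict[str, Metaprofile]:
    """TSS-to-TTS metaprofiles for expressed vs non-expressed genes.

    Upstream/downstream flanks use fixed-width bins over ``flank`` bp; the
    gene body is rescaled to ``bins[1]`` normalized-length bins, so genes
    shorter than the bin count still contribute (each site lands in the bin
    containing its fractional position). Bin values are weighted methylation.
    """
    frame = sites_to_frame(sites)
    frame = frame[frame["context"] == context]
    n_up, n_body, n_down = bins
    n_bins = n_up + n_body + n_down
    acc = {
        g: (np.zeros(n_bins), np.zeros(n_bins))
        for g in ("expressed", "non_expressed")
    }
    for chrom, sub in frame.groupby("chrom"):
        pos = sub["pos"].to_numpy()
        meth = sub["n_meth"].to_numpy(float)
        total = sub["n_total"].to_numpy(float)
        for gene in genes:
            if gene.chrom != chrom:
                continue
            group = "expressed" if gene.gene_id in expressed_ids else "non_expressed"
            L = gene.length
            lo, hi = gene.start - flank, gene.end + flank
            i0, i1 = np.searchsorted(pos, lo), np.searchsorted(pos, hi)
            if i0 == i1:
                continue
            s = _signed_offset(pos[i0:i1], gene)
            idx = np.full(s.shape, -1)
            up = (s >= -flank) & (s < 0)
            idx[up] = ((s[up] + flank) * n_up) // flank
            body = (s >= 0) & (s < L)
            idx[body] = n_up + (s[body] * n_body) // L
            down = (s >= L) & (s < L + flank)
            idx[down] = n_up + n_body + ((s[down] - L) * n_down) // flank
            valid = idx >= 0
            np.add.at(acc[group][0], idx[valid], meth[i0:i1][valid])
            np.add.at(acc[group][1], idx[valid], total[i0:i1][valid])
    out = {}
    for group, (m, t) in acc.items():
        with np.errstate(invalid="ignore", divide="ignore"):
            means = np.where(t > 0, m / np.where(t > 0, t, 1), np.nan)
        out[group] = Metaprofile(context, group, means, t, (n_up, n_body, n_down))
    return out


# ---------------------------------------------------------------------------
# TSS +-20 bp test


@dataclass(frozen=True)
class TssWindowTest:
    t: float
    df: int
    p: float
    n_positions: int  # positions retained per group (41 when fully covered)


def tss_window_test(
    sites,
    genes: Sequence[GeneModel],
    expressed_ids: set[str],
    context: str = "CpG",
    window: int = 20,
) -> TssWindowTest:
    """Pooled two-sample t-test on per-position mean methylation in the TSS
    +- ``window`` bp window, expressed vs non-expressed genes.

    For each strand-aware offset in [-window, window], the per-group value is
    the mean over genes of the weighted methylation of that gene's covered
    site at that offset. Offsets uncovered in either group are dropped from
    both vectors (the degrees of freedom shrink accordingly); with all 41
    positions covered the test has df = 2 * 41 - 2 = 80.
    """
    frame = sites_to_frame(sites)
    frame = frame[(frame["context"] == context) & (frame["n_total"] > 0)]
    offsets = np.arange(-window, window + 1)
    sums = {g: np.zeros(offsets.size) for g in ("expressed", "non_expressed")}
    counts = {g: np.zeros(offsets.size) for g in ("expressed", "non_expressed")}
    for chrom, sub in frame.groupby("chrom"):
        pos = sub["pos"].to_numpy()
        level = (sub["n_meth"] / sub["n_total"]).to_numpy()
        for gene in genes:
            if gene.chrom != chrom:
                continue
            group = "expressed" if gene.gene_id in expressed_ids else "non_expressed"
            want = gene.tss + offsets if gene.strand == "+" else gene.tss - offsets
            j = np.searchsorted(pos, want)
            hit = (j < pos.size) & (pos[np.minimum(j, pos.size - 1)] == want)
            sums[group][hit] += level[j[hit]]
            counts[group][hit] += 1
    cov = (counts["expressed"] > 0) & (counts["non_expressed"] > 0)
    n_pos = int(cov.sum())
    if n_pos < 2:
        raise ValueError("fewer than 2 window positions covered in both groups")
    va = sums["expressed"][cov] / counts["expressed"][cov]
    vb = sums["non_expressed"][cov] / counts["non_expressed"][cov]
    t, p = sps.ttest_ind(va, vb, equal_var=True)
    return TssWindowTest(float(t), 2 * n_pos - 2, float(p), n_pos)


# ---------------------------------------------------------------------------
# region aggregation and DMRs


@dataclass(frozen=True)
class RegionMethylation:
    gene_id: str
    region_kind: str
    context: str
    n_sites_qualifying: int
    meth_reads: int
    total_reads: int
    level: float


def aggregate_region(
    sites,
    region: tuple[str, int, int],
    context: str,
    min_sites: int = 5,
    min_cov: int = 5,
    gene_id: str = "",
    region_kind: str = "",
) -> RegionMethylation | None:
    """Read-weighted methylation of one region, or None if it fails filters.

    A qualifying cytosine matches the context, has coverage >= ``min_cov``
    and at least one methylated read; the region is reported only when >=
    ``min_sites`` cytosines qualify.
    """
    chrom, start, end = region
    frame = sites_to_frame(sites)
    sel = frame[
        (frame["chrom"] == chrom)
        & (frame["pos"] >= start)
        & (frame["pos"] < end)
        & (frame["context"] == context)
        & (frame["n_total"] >= min_cov)
        & (frame["n_meth"] >= 1)
    ]
    if len(sel) < min_sites:
        return None
    meth, total = int(sel["n_meth"].sum()), int(sel["n_total"].sum())
    return RegionMethylation(
        gene_id, region_kind, context, len(sel), meth, total, meth / total
    )


def promoter_span(gene: GeneModel, upstream: int = 2000, anchor: str = "tss") -> tuple[int, int]:
    """Strand-aware promoter interval: ``upstream`` bp 5' of the anchor
    (TSS by default; ATG available for accessibility-style windows)."""
    a = gene.tss if anchor == "tss" else gene.atg
    if gene.strand == "+":
        return max(0, a - upstream), a
    return a + 1, a + 1 + upstream


def region_methylation_table(
    sites,
    genes: Sequence[GeneModel],
    min_sites: int = 5,
    min_cov: int = 5,
    contexts: Iterable[str] = ("CpG", "CHG", "CHH"),
    promoter_upstream: int = 2000,
    promoter_anchor: str = "tss",
) -> pd.DataFrame:
    """Region-level methylation for every gene body and promoter passing the
    filters; one row per (gene_id, region_kind, context)."""
    frame = sites_to_frame(sites)
    rows = []
    for ctx in contexts:
        cframe = frame[(frame["context"] == ctx)]
        for chrom, sub in cframe.groupby("chrom"):
            pos = sub["pos"].to_numpy()
            meth = sub["n_meth"].to_numpy()
            total = sub["n_total"].to_numpy()
            ok = (total >= min_cov) & (meth >= 1)
            for gene in genes:
                if gene.chrom != chrom:
                    continue
                spans = {
                    "gene_body": (gene.start, gene.end),
                    "promoter": promoter_span(gene, promoter_upstream, promoter_anchor),
                }
                for kind, (lo, hi) in spans.items():
                    i0, i1 = np.searchsorted(pos, lo), np.searchsorted(pos, hi)
                    q = ok[i0:i1]
                    if int(q.sum()) < min_sites:
                        continue
                    m = int(meth[i0:i1][q].sum())
                    t = int(total[i0:i1][q].sum())
                    rows.append({
                        "gene_id": gene.gene_id, "region_kind": kind,
                        "context": ctx, "n_sites": int(q.sum()),
                        "meth_reads": m, "total_reads": t, "level": m / t,
                    })
    return pd.DataFrame(
        rows, columns=["gene_id", "region_kind", "context", "n_sites",
                       "meth_reads", "total_reads", "level"],
    )


def _two_proportion_p(m1: int, n1: int, m2: int, n2: int) -> float:
    """Two-sided two-proportion z-test with continuity correction."""
    if n1 == 0 or n2 == 0:
        return float("nan")
    p1, p2 = m1 / n1, m2 / n2
    pp = (m1 + m2) / (n1 + n2)
    se2 = pp * (1 - pp) * (1 / n1 + 1 / n2)
    if se2 <= 0:
        return 1.0
    cc = 0.5 * (1 / n1 + 1 / n2)
    z = max(0.0, abs(p1 - p2) - cc) / np.sqrt(se2)
    return float(2 * sps.norm.sf(z))


def call_dmrs(
    regions_diploid: pd.DataFrame,
    regions_hexaploid: pd.DataFrame,
    thresholds: Mapping[str, float] = DMR_THRESHOLDS,
    alpha: float = 0.05,
    id_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Call DMRs between matched (gene, region, context) aggregates.

    ``id_map`` translates hexaploid gene ids to their diploid syntenic
    partner ids so regions can be matched across genomes. The p-value is a
    continuity-corrected two-proportion z-test on the pooled read counts; BH
    adjustment runs within each context. A region is a DMR when q < alpha
    AND |delta| (hexaploid - diploid, percentage points) meets the context
    threshold.
    """
    from statsmodels.stats.multitest import multipletests

    hexa = regions_hexaploid.copy()
    if id_map is not None:
        hexa["gene_id"] = hexa["gene_id"].map(lambda g: id_map.get(g, g))
    keys = ["gene_id", "region_kind", "context"]
    merged = regions_diploid.merge(hexa, on=keys, suffixes=("_d", "_h"))
    merged = merged[(merged["total_reads_d"] > 0) & (merged["total_reads_h"] > 0)]
    if merged.empty:
        return pd.DataFrame(columns=keys + ["level_diploid", "level_hexaploid",
                                            "delta_points", "p", "q", "is_dmr"])
    p_vals = [
        _two_proportion_p(r.meth_reads_h, r.total_reads_h, r.meth_reads_d, r.total_reads_d)
        for r in merged.itertuples()
    ]
    out = merged[keys].copy()
    out["level_diploid"] = merged["level_d"].to_numpy()
    out["level_hexaploid"] = merged["level_h"].to_numpy()
    out["delta_points"] = (merged["level_h"] - merged["level_d"]).to_numpy() * 100.0
    out["p"] = p_vals
    out["q"] = np.nan
    for ctx in out["context"].unique():
        sel = out["context"] == ctx
        out.loc[sel, "q"] = multipletests(out.loc[sel, "p"], method="fdr_bh")[1]
    thr = out["context"].map(thresholds).to_numpy(float)
    out["is_dmr"] = (out["q"] < alpha) & (out["delta_points"].abs() >= thr)
    return out.reset_index(drop=True)


def dmr_deg_overlap(dmrs: pd.DataFrame, deg_ids: set[str]) -> pd.DataFrame:
    """Per (context, region_kind) counts of DMRs and DMR-DEG co-occurrence,
    plus an 'all' row over unique differentially methylated genes."""
    rows = []
    called = dmrs[dmrs["is_dmr"]]
    for (ctx, kind), sub in called.groupby(["context", "region_kind"]):
        n = len(sub)
        k = int(sub["gene_id"].isin(deg_ids).sum())
        rows.append({"context": ctx, "region_kind": kind, "n_dmr": n,
                     "n_dmr_and_deg": k, "proportion": k / n if n else 0.0})
    uniq = called["gene_id"].unique()
    n = len(uniq)
    k = int(pd.Series(uniq).isin(deg_ids).sum())
    rows.append({"context": "all", "region_kind": "all", "n_dmr": n,
                 "n_dmr_and_deg": k, "proportion": k / n if n else 0.0})
    return pd.DataFrame(rows)


def pseudogene_comparison(
    regions: pd.DataFrame, genes: Sequence[GeneModel], region_kind: str = "gene_body"
) -> dict[str, float]:
    """Per-context difference of mean region methylation, pseudogene minus
    intact gene (unweighted means of region levels)."""
    pseudo_ids = {g.gene_id for g in genes if g.is_pseudogene}
    sub = regions[regions["region_kind"] == region_kind]
    out = {}
    for ctx, csub in sub.groupby("context"):
        is_p = csub["gene_id"].isin(pseudo_ids)
        if is_p.sum() == 0 or (~is_p).sum() == 0:
            out[str(ctx)] = float("nan")
            continue
        out[str(ctx)] = float(csub.loc[is_p, "level"].mean() - csub.loc[~is_p, "level"].mean())
    return out
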