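"""ATAC-seq post-processing: Tn5 read shifting, reproducible peaks across
replicates, close-peak merging, region-class annotation, TSS-distance
summaries, fragment-length periodicity and per-gene differential
accessibility.

Conventions taken from the study design this implements: forward-strand
reads are offset by +4 bp and reverse-strand reads by -5 bp (the Tn5
insertion geometry); only genomic positions covered by a peak in every
replicate count as reproducible; peaks whose proximal ends are < 10 bp
apart are merged; peaks are classified into four region classes —
5'UTR+promoter (ATG to 2 kb upstream), CDS+introns, 3'UTR+downstream
(to 2 kb), and intergenic (> 2 kb from any gene window).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GeneModel, Interval, filter_by_contig

logger = logging.getLogger(__name__)

FORWARD_SHIFT = 4
REVERSE_SHIFT = -5

REGION_CLASSES = ("promoter5utr", "cds_intron", "utr3_downstream", "intergenic")
_PRECEDENCE = {"promoter5utr": 0, "cds_intron": 1, "utr3_downstream": 2}


@dataclass(frozen=True)
class ShiftedRead:
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("read end must exceed start")


def shift_reads(reads: Iterable[ShiftedRead]) -> list[ShiftedRead]:
    """Apply the Tn5 +4/-5 bp offsets; lengths are preserved except when a
    shift would push the start below zero (clipped with a warning)."""
    out = []
    for r in reads:
        shift = FORWARD_SHIFT if r.strand == "+" else REVERSE_SHIFT
        s, e = r.start + shift, r.end + shift
        if s < 0:
            warnings.warn(f"read at {r.chrom}:{r.start} shifted below 0; clipped")
            s = 0
        out.append(ShiftedRead(r.chrom, s, e, r.strand))
    return out


def filter_organelle(reads: Iterable, organelle_contigs: Sequence[str]) -> list:
    """Drop reads on mitochondrial/chloroplast contigs (by contig name)."""
    return filter_by_contig(reads, organelle_contigs)


# ---------------------------------------------------------------------------
# peak algebra


def reproducible_peaks(
    replicates: Sequence[Sequence[Interval]],
) -> list[Interval]:
    """Positions covered by >= 1 peak in EVERY replicate, as maximal runs.

    Implemented as a sweep over union-merged replicate coverage; equivalent
    to a per-base boolean AND.
    """
    if len(replicates) < 2:
        raise ValueError("need >= 2 replicate peak sets")
    n_reps = len(replicates)
    if any(len(rep) == 0 for rep in replicates):
        return []
    events: dict[str, list[tuple[int, int]]] = {}
    for rep in replicates:
        merged = merge_close_peaks(rep, max_gap=1)  # union (overlap or touch)
        for iv in merged:
            events.setdefault(iv.chrom, []).append((iv.start, +1))
            events.setdefault(iv.chrom, []).append((iv.end, -1))
    out: list[Interval] = []
    for chrom in sorted(events):
        evs = sorted(events[chrom])
        depth, run_start, i = 0, None, 0
        for pos, delta in evs:
            new_depth = depth + delta
            if depth < n_reps <= new_depth:
                run_start = pos
            elif depth >= n_reps > new_depth and run_start is not None:
                if pos > run_start:
                    out.append(Interval(chrom, run_start, pos, f"rp{len(out)}"))
                run_start = None
            depth = new_depth
        # events are balanced, so depth returns to 0 and runs always close
    return out


def merge_close_peaks(peaks: Sequence[Interval], max_gap: int = 10) -> list[Interval]:
    """Merge overlapping peaks and peaks whose gap is < ``max_gap`` bp
    (exclusive: a gap of exactly ``max_gap`` stays unmerged). Transitive;
    output is sorted and non-overlapping; idempotent."""
    if not peaks:
        return []
    ordered = sorted(peaks, key=lambda p: (p.chrom, p.start, p.end))
    out: list[Interval] = []
    cur = ordered[0]
    cur_start, cur_end = cur.start, cur.end
    for p in ordered[1:]:
        if p.chrom == cur.chrom and p.start - cur_end < max_gap:
            cur_end = max(cur_end, p.end)
        else:
            out.append(Interval(cur.chrom, cur_start, cur_end, cur.name))
            cur, cur_start, cur_end = p, p.start, p.end
    out.append(Interval(cur.chrom, cur_start, cur_end, cur.name))
    return out


# ---------------------------------------------------------------------------
# annotation


@dataclass(frozen=True)
class AnnotatedPeak:
    interval: Interval
    region_class: str
    assigned_gene_id: str | None
    tss_distance: float  # strand-signed midpoint-to-nearest-TSS distance


def _gene_windows(
    gene: GeneModel, promoter_upstream: int, downstream: int
) -> dict[str, tuple[int, int]]:
    """Strand-aware genomic spans of the three genic region classes."""
    if gene.strand == "+":
        return {
            "promoter5utr": (max(0, gene.atg - promoter_upstream), gene.atg),
            "cds_intron": (gene.atg, gene.end),
            "utr3_downstream": (gene.end, gene.end + downstream),
        }
    return {
        "promoter5utr": (gene.atg + 1, gene.atg + 1 + promoter_upstream),
        "cds_intron": (gene.start, gene.atg + 1),
        "utr3_downstream": (max(0, gene.start - downstream), gene.start),
    }


def annotate_peaks(
    peaks: Sequence[Interval],
    genes: Sequence[GeneModel],
    promoter_upstream: int = 2000,
    downstream: int = 2000,
) -> list[AnnotatedPeak]:
    """Assign each peak a region class, gene and signed TSS distance.

    Overlap with multiple genes resolves to the gene whose TSS is nearest
    the peak midpoint; overlap with several windows of that gene resolves by
    precedence promoter5utr > cds_intron > utr3_downstream. Peaks outside
    every window are intergenic (no assigned gene) but still carry the
    distance to the nearest TSS. Raises for peaks on contigs absent from the
    annotation.
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    tss_by_chrom: dict[str, tuple[np.ndarray, list[GeneModel]]] = {}
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, gs in by_chrom.items():
        tree = IntervalTree()
        for g in gs:
            for cls, (lo, hi) in _gene_windows(g, promoter_upstream, downstream).items():
                if hi > lo:
                    tree[lo:hi] = (g, cls)
        trees[chrom] = tree
        order = np.argsort([g.tss for g in gs])
        tss_by_chrom[chrom] = (
            np.array([gs[i].tss for i in order]),
            [gs[i] for i in order],
        )

    out: list[AnnotatedPeak] = []
    for peak in peaks:
        if peak.chrom not in trees:
            raise ValueError(f"peak on contig {peak.chrom!r} absent from annotation")
        mid = peak.midpoint
        tss_arr, gene_list = tss_by_chrom[peak.chrom]
        j = int(np.clip(np.searchsorted(tss_arr, mid), 0, len(tss_arr) - 1))
        cand = [j - 1, j, j + 1]
        nearest = min(
            (gene_list[k] for k in cand if 0 <= k < len(gene_list)),
            key=lambda g: abs(mid - g.tss),
        )
        hits = trees[peak.chrom][peak.start:peak.end]
        if not hits:
            g = nearest
            dist = (mid - g.tss) if g.strand == "+" else (g.tss - mid)
            out.append(AnnotatedPeak(peak, "intergenic", None, float(dist)))
            continue
        hit_genes: dict[str, tuple[GeneModel, list[str]]] = {}
        for h in hits:
            g, cls = h.data
            hit_genes.setdefault(g.gene_id, (g, []))[1].append(cls)
        best_g, classes = min(
            hit_genes.values(), key=lambda gc: abs(mid - gc[0].tss)
        )
        cls = min(classes, key=_PRECEDENCE.__getitem__)
        dist = (mid - best_g.tss) if best_g.strand == "+" else (best_g.tss - mid)
        out.append(AnnotatedPeak(peak, cls, best_g.gene_id, float(dist)))
    return out


def tss_distance_cdf(
    annotated_peaks: Sequence[AnnotatedPeak],
    thresholds: Sequence[int] = (3000, 100_000),
) -> dict[int, float]:
    """Fraction of peaks with |TSS distance| <= each threshold (monotone
    nondecreasing in the threshold)."""
    if not annotated_peaks:
        return {int(t): float("nan") for t in thresholds}
    d = np.abs([p.tss_distance for p in annotated_peaks])
    return {int(t): float((d <= t).mean()) for t in thresholds}


# ---------------------------------------------------------------------------
# fragment periodicity


@dataclass(frozen=True)
class PeriodicityResult:
    period: float          # bp; NaN when nothing significant in the band
    amplitude: float       # spectral peak power / median band power
    significant: bool
    low_confidence: bool   # fewer than min_fragments observations


def fragment_periodicity(
    fragment_lengths: Sequence[int] | np.ndarray,
    band: tuple[float, float] = (5.0, 15.0),
    min_fragments: int = 1000,
    amplitude_threshold: float = 8.0,
) -> PeriodicityResult:
    """Dominant short-range period of the fragment-length histogram.

    The integer-length histogram is detrended with a centred moving average
    (window ~ 2 x band maximum) and Fourier-transformed; the dominant
    frequency within ``band`` bp is refined by parabolic interpolation. The
    amplitude is the peak power over the median band power; below
    ``amplitude_threshold`` no period is reported (flat histograms).
    """
    lengths = np.asarray(fragment_lengths, dtype=int)
    low_conf = lengths.size < min_fragments
    if low_conf:
        warnings.warn(f"only {lengths.size} fragments; periodicity is low-confidence")
    if lengths.size == 0:
        return PeriodicityResult(float("nan"), 0.0, False, True)
    lo, hi = int(lengths.min()), int(lengths.max())
    hist = np.bincount(lengths - lo, minlength=hi - lo + 1).astype(float)
    win = int(2 * band[1]) | 1
    kernel = np.ones(win) / win
    trend = np.convolve(hist, kernel, mode="same")
    resid = hist - trend
    n_fft = 1 << 14
    power = np.abs(np.fft.rfft(resid, n_fft)) ** 2
    freqs = np.fft.rfftfreq(n_fft, d=1.0)
    in_band = (freqs >= 1.0 / band[1]) & (freqs <= 1.0 / band[0])
    if not in_band.any():
        return PeriodicityResult(float("nan"), 0.0, False, low_conf)
    band_power = power[in_band]
    band_freqs = freqs[in_band]
    k = int(np.argmax(band_power))
    med = float(np.median(band_power))
    amp = float(band_power[k] / med) if med > 0 else float("inf")
    # parabolic refinement on log power around the peak
    gk = int(np.flatnonzero(in_band)[k])
    if 0 < gk < power.size - 1 and power[gk - 1] > 0 and power[gk + 1] > 0:
        y0, y1, y2 = np.log(power[gk - 1 : gk + 2])
        denom = y0 - 2 * y1 + y2
        shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        f_peak = freqs[gk] + shift * (freqs[1] - freqs[0])
    else:
        f_peak = band_freqs[k]
    significant = amp >= amplitude_threshold and not low_conf
    period = float(1.0 / f_peak) if significant else float("nan")
    return PeriodicityResult(period, amp, significant, low_conf)


# ---------------------------------------------------------------------------
# per-gene accessibility


def gene_accessibility(
    annotated_peaks: Sequence[AnnotatedPeak], genes: Sequence[GeneModel]
) -> pd.DataFrame:
    """Per-gene peak counts and total peak bp, overall and per region class.

    Indexed by gene_id; genes without peaks get zeros. Totals are conserved
    under splitting a peak at an interior point.
    """
    cols = ["n_peaks_any", "bp_any"]
    for cls in ("promoter5utr", "cds_intron", "utr3_downstream"):
        cols += [f"n_peaks_{cls}", f"bp_{cls}"]
    table = pd.DataFrame(
        0, index=pd.Index([g.gene_id for g in genes], name="gene_id"), columns=cols
    )
    for p in annotated_peaks:
        if p.assigned_gene_id is None:
            continue
        L = len(p.interval)
        table.loc[p.assigned_gene_id, "n_peaks_any"] += 1
        table.loc[p.assigned_gene_id, "bp_any"] += L
        table.loc[p.assigned_gene_id, f"n_peaks_{p.region_class}"] += 1
        table.loc[p.assigned_gene_id, f"bp_{p.region_class}"] += L
    return table


def differential_accessibility(
    acc_diploid: pd.DataFrame,
    acc_hexaploid: pd.DataFrame,
    id_map: Mapping[str, str] | None = None,
    min_fold: float = 2.0,
    min_abs: int = 50,
) -> pd.DataFrame:
    """Genes whose accessibility differs between genomes, with the region
    class of the difference.

    A gene is flagged in a region class when peak presence/absence differs,
    or when total peak bp differs by >= ``min_fold`` AND >= ``min_abs`` bp.
    ``id_map`` translates hexaploid ids to diploid partner ids. Genes present
    in only one genome's table are skipped (logged).
    """
    hexa = acc_hexaploid.copy()
    if id_map is not None:
        hexa.index = [id_map.get(g, g) for g in hexa.index]
    common = acc_diploid.index.intersection(hexa.index)
    n_skip = (len(acc_diploid) - len(common)) + (len(hexa) - len(common))
    if n_skip:
        logger.info("differential_accessibility: %d genes present in one genome only", n_skip)
    rows = []
    for gid in common:
        d, h = acc_diploid.loc[gid], hexa.loc[gid]
        diff_classes = []
        for cls in ("promoter5utr", "cds_intron", "utr3_downstream"):
            bd, bh = int(d[f"bp_{cls}"]), int(h[f"bp_{cls}"])
            if (bd == 0) != (bh == 0):
                diff_classes.append(cls)
            elif bd > 0 and bh > 0:
                fold = max(bd, bh) / min(bd, bh)
                if fold >= min_fold and abs(bd - bh) >= min_abs:
                    diff_classes.append(cls)
        rows.append({
            "gene_id": gid,
            "is_differential": bool(diff_classes),
            "diff_classes": ";".join(diff_classes),
        })
    return pd.DataFrame(rows)


def deg_atac_overlap(
    differential: pd.DataFrame | set[str], deg_ids: set[str]
) -> dict[str, float | int | dict[str, int]]:
    """Venn tallies between differentially accessible genes and DEGs.

    Returns |A| (differential-ATAC genes), |B| (DEGs), |A and B|, the
    fraction of DEGs with differential peaks, and — when a differential
    table is given — a per-region-class breakdown of the overlap.
    """
    if isinstance(differential, pd.DataFrame):
        flagged = differential[differential["is_differential"]]
        a = set(flagged["gene_id"])
        class_of = dict(zip(flagged["gene_id"], flagged["diff_classes"]))
    else:
        a, class_of = set(differential), {}
    b = set(deg_ids)
    inter = a & b
    by_class: dict[str, int] = {}
    for gid in inter:
        for cls in class_of.get(gid, "").split(";"):
            if cls:
                by_class[cls] = by_class.get(cls, 0) + 1
    return {
        "n_differential_atac": len(a),
        "n_deg": len(b),
        "n_overlap": len(inter),
        "fraction_deg_with_diff_peaks": len(inter) / len(b) if b else float("nan"),
        "overlap_by_class": by_class,
    }
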