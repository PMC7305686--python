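"""Readers and writers for the standard formats the pipeline consumes.

All coordinates are held internally as 0-based half-open intervals (the BED
convention). GFF3's 1-based closed coordinates are converted at the boundary
and converted back on write, so a read -> write round trip is exact.

Strandedness convention: for a "+" gene the TSS is the smaller genomic
coordinate (``start``) and the TTS the larger (``end - 1``); for a "-" gene
the TSS is ``end - 1`` and the TTS is ``start``. All "upstream/downstream"
logic elsewhere in the package is defined relative to this.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

VALID_CONTEXTS = ("CpG", "CHG", "CHH")

#: aliases seen in Bismark cytosine / CX reports
_CONTEXT_ALIASES = {"CG": "CpG", "CPG": "CpG", "CpG": "CpG", "CHG": "CHG", "CHH": "CHH"}


class ParseError(ValueError):
    """Raised for malformed input files; message names the offending line."""


@dataclass(frozen=True)
class Interval:
    """A genomic interval, 0-based half-open (BED-style)."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass(frozen=True)
class CytosineSite:
    """A single cytosine with bisulphite read counts.

    ``pos`` is 0-based. ``context`` is one of CpG / CHG / CHH (plant
    methylation contexts; H = A, C or T).
    """

    chrom: str
    pos: int
    strand: str
    context: str
    n_meth: int
    n_total: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_meth <= self.n_total):
            raise ValueError(
                f"invalid counts at {self.chrom}:{self.pos}: "
                f"n_meth={self.n_meth}, n_total={self.n_total}"
            )
        if self.context not in VALID_CONTEXTS:
            raise ValueError(f"unknown methylation context {self.context!r}")

    @property
    def level(self) -> float:
        """Per-site methylation level; NaN if uncovered."""
        return self.n_meth / self.n_total if self.n_total else float("nan")


@dataclass
class GeneModel:
    """A gene (or pseudogene) model in internal 0-based half-open coordinates.

    ``tss``/``tts``/``atg`` are single base positions. For strand "-" genes
    the TSS is the larger genomic coordinate.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    tss: int
    tts: int
    atg: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    biotype: str = "gene"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start >= end")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if not (self.start <= self.tss < self.end):
            raise ValueError(f"gene {self.gene_id}: tss outside gene span")
        if self.strand == "-" and self.tss < self.tts:
            raise ValueError(f"gene {self.gene_id}: '-' gene must have tss >= tts")
        if self.strand == "+" and self.tss > self.tts:
            raise ValueError(f"gene {self.gene_id}: '+' gene must have tss <= tts")
        ex = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 < e1:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
        self.exons = ex

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_pseudogene(self) -> bool:
        return self.biotype == "pseudogene"


# ---------------------------------------------------------------------------
# GFF3


def _validate_gff3_lines(path: str | Path) -> None:
    """Cheap pre-pass so malformed lines fail with a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}: line {lineno}: expected 9 columns, got {len(fields)}")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if end < start:
                raise ParseError(f"{path}: line {lineno}: end < start")
            if fields[6] not in ("+", "-", ".", "?"):
                raise ParseError(f"{path}: line {lineno}: bad strand {fields[6]!r}")


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS features from a GFF3 file.

    Coordinates are converted from GFF3 1-based closed to 0-based half-open.
    The TSS is the strand-aware 5' end of the gene; the ATG is the strand-aware
    5' end of the first CDS segment. Gene-biotype records without any CDS are
    kept and flagged with a warning (pseudogenes legitimately have none).
    """
    import gffutils

    _validate_gff3_lines(path)
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for feat in db.features_of_type(("gene", "pseudogene"), order_by="start"):
        start, end = feat.start - 1, feat.end  # to half-open
        strand = feat.strand if feat.strand in "+-" else "+"
        biotype = (
            "pseudogene"
            if feat.featuretype == "pseudogene"
            or feat.attributes.get("biotype", [""])[0] == "pseudogene"
            else "gene"
        )
        exons = sorted(
            (e.start - 1, e.end) for e in db.children(feat, featuretype="exon")
        )
        cds = sorted((c.start - 1, c.end) for c in db.children(feat, featuretype="CDS"))
        tss = start if strand == "+" else end - 1
        tts = end - 1 if strand == "+" else start
        if cds:
            atg = cds[0][0] if strand == "+" else cds[-1][1] - 1
        else:
            if biotype == "gene":
                warnings.warn(
                    f"gene {feat.id} has no CDS; using TSS as ATG", stacklevel=2
                )
            atg = tss
        genes.append(
            GeneModel(
                gene_id=feat.id,
                chrom=feat.seqid,
                start=start,
                end=end,
                strand=strand,
                tss=tss,
                tts=tts,
                atg=atg,
                exons=exons,
                biotype=biotype,
            )
        )
    return genes


def write_gff3(genes: Sequence[GeneModel], path: str | Path, source: str = "ploidycomp") -> None:
    """Write gene models back to GFF3 (1-based closed); inverse of read_gff3
    on gene/exon coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            ftype = "pseudogene" if g.is_pseudogene else "gene"
            fh.write(
                f"{g.chrom}\t{source}\t{ftype}\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};biotype={g.biotype}\n"
            )
            fh.write(
                f"{g.chrom}\t{source}\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.1;Parent={g.gene_id}\n"
            )
            for i, (es, ee) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\t{source}\texon\t{es + 1}\t{ee}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.1.exon{i};Parent={g.gene_id}.1\n"
                )
            if not g.is_pseudogene:
                # single CDS segment from ATG to the 3' gene end
                cs, ce = (g.atg, g.end) if g.strand == "+" else (g.start, g.atg + 1)
                fh.write(
                    f"{g.chrom}\t{source}\tCDS\t{cs + 1}\t{ce}\t.\t{g.strand}\t0\t"
                    f"ID={g.gene_id}.1.cds;Parent={g.gene_id}.1\n"
                )


# ---------------------------------------------------------------------------
# Cytosine report


def read_cytosine_report(path: str | Path) -> list[CytosineSite]:
    """Read a Bismark-style cytosine report.

    Expected columns: chrom, pos (1-based), strand, count_methylated,
    count_unmethylated, context[, trinucleotide]. Positions are converted to
    0-based; counts are preserved exactly. Sites with zero coverage are kept
    (coverage filters are applied downstream, not here).
    """
    sites: list[CytosineSite] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}: line {lineno}: expected >=6 columns")
            chrom, pos_s, strand, n_meth_s, n_unmeth_s, context = fields[:6]
            try:
                pos, n_meth, n_unmeth = int(pos_s), int(n_meth_s), int(n_unmeth_s)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer field") from exc
            if n_meth < 0 or n_unmeth < 0:
                raise ParseError(f"{path}: line {lineno}: negative count")
            if context not in _CONTEXT_ALIASES:
                raise ParseError(f"{path}: line {lineno}: unknown context {context!r}")
            sites.append(
                CytosineSite(
                    chrom=chrom,
                    pos=pos - 1,
                    strand=strand,
                    context=_CONTEXT_ALIASES[context],
                    n_meth=n_meth,
                    n_total=n_meth + n_unmeth,
                )
            )
    return sites


def write_cytosine_report(sites: Iterable[CytosineSite], path: str | Path) -> None:
    """Write sites in Bismark cytosine-report layout (1-based positions)."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.pos + 1}\t{s.strand}\t{s.n_meth}\t"
                f"{s.n_total - s.n_meth}\t{s.context}\n"
            )


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[Interval]:
    """Read BED4/BED6 (or BED3) into Intervals; coordinates kept as-is."""
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >=3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 else "."
            try:
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-numeric score") from exc
            try:
                out.append(Interval(fields[0], start, end, name, score))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[Interval], path: str | Path) -> None:
    """Write BED4; read_bed(write_bed(x)) round-trips exactly."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")


# ---------------------------------------------------------------------------
# Expression matrices


def read_tpm_matrix(path: str | Path) -> pd.DataFrame:
    """Read a TSV expression matrix: gene_id column + one column per sample."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ParseError(f"{path}: missing 'gene_id' column")
    return df.set_index("gene_id")


def write_tpm_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into a {name: sequence} mapping (uppercased)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def filter_by_contig(
    items: Iterable, organelle_contigs: Sequence[str] | set[str]
) -> list:
    """Drop intervals/reads whose ``chrom`` is in the organelle contig list.

    Stands in for the removal of mitochondrial/chloroplast reads: alignment
    happened upstream, so membership is decided by contig name alone.
    """
    organelles = set(organelle_contigs)
    items = list(items)
    kept = [x for x in items if x.chrom not in organelles]
    logger.info(
        "filter_by_contig: kept %d of %d items (%d organelle)",
        len(kept), len(items), len(items) - len(kept),
    )
    return kept
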