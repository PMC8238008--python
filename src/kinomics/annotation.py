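"""Genome annotation container with GFF3 round-trip.

All intervals are held internally as 0-based half-open ``(start, end)``
tuples on the forward strand; GFF3 is read and written with the standard
1-based inclusive convention.  The model covers the gene → mRNA →
exon/CDS/UTR hierarchy used throughout the package and deliberately
nothing else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gffutils

Interval = tuple[int, int]


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        self.utr5 = sorted(self.utr5)
        self.utr3 = sorted(self.utr3)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def genomic_span(self) -> int:
        return self.end - self.start


@dataclass
class Gene:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)


@dataclass
class GenomeAnnotation:
    """Ordered collection of genes plus chromosome lengths."""

    chrom_lengths: dict[str, int]
    genes: dict[str, Gene] = field(default_factory=dict)

    def add_gene(self, gene: Gene) -> None:
        if gene.gene_id in self.genes:
            raise ValueError(f"duplicate gene id {gene.gene_id!r}")
        self.genes[gene.gene_id] = gene

    def genes_on(self, chrom: str) -> list[Gene]:
        """Genes on one chromosome sorted by (start, end, id)."""
        sel = [g for g in self.genes.values() if g.chrom == chrom]
        return sorted(sel, key=lambda g: (g.start, g.end, g.gene_id))

    # ------------------------------------------------------------------ GFF3

    def write_gff3(self, path: str | Path) -> None:
        lines = ["##gff-version 3"]
        for chrom, length in self.chrom_lengths.items():
            lines.append(f"##sequence-region {chrom} 1 {length}")
        for chrom in self.chrom_lengths:
            for gene in self.genes_on(chrom):
                lines.append(_feature_line(
                    chrom, "gene", gene.start, gene.end, gene.strand,
                    f"ID={gene.gene_id}"))
                for tx in gene.transcripts:
                    lines.append(_feature_line(
                        chrom, "mRNA", tx.start, tx.end, tx.strand,
                        f"ID={tx.transcript_id};Parent={gene.gene_id}"))
                    for kind, ivs in (("exon", tx.exons), ("CDS", tx.cds),
                                      ("five_prime_UTR", tx.utr5),
                                      ("three_prime_UTR", tx.utr3)):
                        for s, e in ivs:
                            lines.append(_feature_line(
                                chrom, kind, s, e, tx.strand,
                                f"Parent={tx.transcript_id}"))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read_gff3(cls, path: str | Path) -> "GenomeAnnotation":
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique",
            keep_order=True)
        chrom_lengths: dict[str, int] = {}
        for directive in db.directives:
            if directive.startswith("sequence-region"):
                _, chrom, _start, end = directive.split()
                chrom_lengths[chrom] = int(end)
        ann = cls(chrom_lengths=chrom_lengths)
        for g in db.features_of_type("gene", order_by=("seqid", "start")):
            gene = Gene(g.id, g.seqid, g.start - 1, g.end, g.strand)
            for m in db.children(g, featuretype="mRNA", order_by="start"):
                kinds = {"exon": [], "CDS": [],
                         "five_prime_UTR": [], "three_prime_UTR": []}
                for child in db.children(m, order_by="start"):
                    if child.featuretype in kinds:
                        kinds[child.featuretype].append(
                            (child.start - 1, child.end))
                gene.transcripts.append(Transcript(
                    m.id, g.id, g.seqid, m.strand,
                    exons=kinds["exon"], cds=kinds["CDS"],
                    utr5=kinds["five_prime_UTR"],
                    utr3=kinds["three_prime_UTR"]))
            ann.add_gene(gene)
        if not chrom_lengths:
            # fall back to the rightmost feature per chromosome
            for gene in ann.genes.values():
                prev = ann.chrom_lengths.get(gene.chrom, 0)
                ann.chrom_lengths[gene.chrom] = max(prev, gene.end)
        return ann


def _feature_line(chrom: str, kind: str, start: int, end: int,
                  strand: str, attrs: str) -> str:
    return "\t".join([chrom, "kinomics", kind, str(start + 1), str(end),
                      ".", strand, ".", attrs])


def map_transcript_interval(exons: list[Interval], strand: str,
                            t_start: int, t_end: int) -> list[Interval]:
    """Project a transcript-coordinate interval onto genomic intervals.

    Transcript coordinate 0 is the 5' end of the mature transcript: the
    leftmost exonic base for ``+`` genes and the rightmost for ``-``.
    """
    if strand == "-":
        total = sum(e - s for s, e in exons)
        t_start, t_end = total - t_end, total - t_start
    out: list[Interval] = []
    offset = 0
    for s, e in sorted(exons):
        length = e - s
        lo, hi = max(t_start - offset, 0), min(t_end - offset, length)
        if lo < hi:
            out.append((s + lo, s + hi))
        offset += length
    return out
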