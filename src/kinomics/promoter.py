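"""Promoter extraction, PWM scanning and motif-enrichment testing.

Promoters are the 1 kb immediately upstream of the annotated gene start
(strand-aware, reverse-complemented for minus-strand genes, clipped at
chromosome ends).  Position weight matrices come in as JASPAR-format
count matrices, are normalized with a pseudocount and scored as log-odds
against a background distribution; a promoter "contains" a motif when
some window on either strand reaches a fraction of the maximum attainable
score.  Per-family enrichment is an upper-tail hypergeometric test on the
number of motif-containing promoters in the family against the genome
background, with Benjamini–Hochberg correction across motifs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from Bio.Seq import Seq
from scipy.stats import hypergeom

from .annotation import GenomeAnnotation
from .expression import bh_fdr

BASES = "ACGT"
UNIFORM_BACKGROUND = {b: 0.25 for b in BASES}


@dataclass
class Promoter:
    gene_id: str
    chrom: str
    start: int  # 0-based half-open genomic interval
    end: int
    strand: str
    sequence: str  # 5'->3' relative to the gene
    clipped: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PWM:
    motif_id: str
    counts: np.ndarray  # 4 x width, rows in A, C, G, T order

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape[0] != 4:
            raise ValueError("PWM needs 4 nucleotide rows (A, C, G, T)")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))


@dataclass
class MotifEnrichmentResult:
    family: str
    motif_id: str
    k: int  # foreground promoters with >= 1 hit
    n: int  # foreground size
    K: int  # background promoters with >= 1 hit
    N: int  # background size
    p: float
    q: float
    enriched: bool


def extract_promoters(annotation: GenomeAnnotation,
                      genome: dict[str, str], length: int = 1000,
                      gene_ids=None) -> list[Promoter]:
    """Upstream promoter per gene, clipped at chromosome boundaries."""
    out = []
    for gene_id in (gene_ids if gene_ids is not None else annotation.genes):
        gene = annotation.genes[gene_id]
        if gene.chrom not in genome:
            raise ValueError(
                f"chromosome {gene.chrom!r} of gene {gene_id!r} absent "
                "from genome")
        chrom_seq = genome[gene.chrom]
        if gene.strand == "+":
            start = max(gene.start - length, 0)
            end = gene.start
            seq = chrom_seq[start:end]
        else:
            start = gene.end
            end = min(gene.end + length, len(chrom_seq))
            seq = str(Seq(chrom_seq[start:end]).reverse_complement())
        out.append(Promoter(gene_id, gene.chrom, start, end, gene.strand,
                            seq, clipped=(end - start) < length))
    return out


def read_jaspar_pfm(path: str | Path) -> list[PWM]:
    """Parse a JASPAR-format PFM file into PWM count matrices.

    Malformed matrices raise with the offending line number.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    # quick structural validation so errors can carry line numbers
    row_count = 0
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(">"):
            if row_count not in (0, 4):
                raise ValueError(
                    f"{path.name}:{lineno}: matrix with {row_count} rows "
                    "(expected 4) before this header")
            row_count = 0
        else:
            row_count += 1
            body = stripped.split("[")[-1].split("]")[0]
            fields = body.replace(",", " ").split()
            if fields and fields[0] in "ACGT":
                fields = fields[1:]
            if not fields or any(not _is_number(f) for f in fields):
                raise ValueError(
                    f"{path.name}:{lineno}: malformed matrix row "
                    f"{stripped!r}")
    if row_count not in (0, 4):
        raise ValueError(f"{path.name}: last matrix has {row_count} rows "
                         "(expected 4)")
    with open(path) as handle:
        records = bio_motifs.parse(handle, "jaspar")
    out = []
    for rec in records:
        counts = np.array([rec.counts[b] for b in BASES], dtype=float)
        out.append(PWM(motif_id=rec.matrix_id or rec.name, counts=counts))
    return out


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def write_jaspar_pfm(pwms: list[PWM], path: str | Path) -> None:
    lines = []
    for pwm in pwms:
        lines.append(f">{pwm.motif_id} {pwm.motif_id}")
        for i, base in enumerate(BASES):
            vals = " ".join(f"{v:g}" for v in pwm.counts[i])
            lines.append(f"{base}  [ {vals} ]")
    Path(path).write_text("\n".join(lines) + "\n")


def pfm_to_logodds(pwm: PWM, background: dict[str, float] | None = None,
                   pseudocount: float = 0.5) -> np.ndarray:
    """Counts -> probabilities with pseudocount -> log2 odds matrix."""
    bg = background or UNIFORM_BACKGROUND
    counts = pwm.counts
    colsum = counts.sum(axis=0) + 4.0 * pseudocount
    probs = (counts + pseudocount) / colsum
    bg_vec = np.array([bg[b] for b in BASES])[:, None]
    return np.log2(probs / bg_vec)


def scan_promoter(scoring_matrix: np.ndarray, promoter: Promoter | str,
                  threshold_fraction: float = 0.8) -> list[tuple]:
    """All motif occurrences on both strands of one promoter.

    Returns ``(offset, strand, score)`` tuples; a window is a hit when
    its score reaches ``threshold_fraction`` times the maximum
    attainable score.  Promoters shorter than the motif yield an empty
    list with a warning.
    """
    import warnings

    seq = promoter.sequence if isinstance(promoter, Promoter) else promoter
    width = scoring_matrix.shape[1]
    if len(seq) < width:
        warnings.warn("promoter shorter than motif; no scan performed",
                      stacklevel=2)
        return []
    max_score = scoring_matrix.max(axis=0).sum()
    threshold = threshold_fraction * max_score
    base_idx = {b: i for i, b in enumerate(BASES)}
    idx = np.array([base_idx.get(c, -1) for c in seq.upper()])
    rc = str(Seq(seq).reverse_complement()).upper()
    idx_rc = np.array([base_idx.get(c, -1) for c in rc])

    hits = []
    cols = np.arange(width)
    for strand, arr in (("+", idx), ("-", idx_rc)):
        windows = np.lib.stride_tricks.sliding_window_view(arr, width)
        valid = (windows >= 0).all(axis=1)
        scores = scoring_matrix[np.where(windows >= 0, windows, 0),
                                cols].sum(axis=1)
        for off in np.nonzero(valid & (scores >= threshold))[0]:
            pos = int(off) if strand == "+" else len(seq) - width - int(off)
            hits.append((pos, strand, float(scores[off])))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def promoters_with_hit(pwm: PWM, promoters: list[Promoter],
                       background: dict[str, float] | None = None,
                       pseudocount: float = 0.5,
                       threshold_fraction: float = 0.8) -> set[str]:
    lod = pfm_to_logodds(pwm, background, pseudocount)
    out = set()
    for prom in promoters:
        if len(prom.sequence) < pwm.width:
            continue
        if scan_promoter(lod, prom, threshold_fraction):
            out.add(prom.gene_id)
    return out


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    return float(hypergeom.sf(k - 1, N, K, n))


def family_motif_enrichment(foreground: list[Promoter],
                            background: list[Promoter],
                            pwms: list[PWM], family: str = "",
                            p_cutoff: float = 1e-2,
                            q_cutoff: float = 1e-2,
                            threshold_fraction: float = 0.8,
                            pseudocount: float = 0.5
                            ) -> list[MotifEnrichmentResult]:
    """Per-motif hypergeometric enrichment of a promoter family.

    The foreground must be a subset of the background; BH correction is
    applied across the supplied motifs.
    """
    if not foreground:
        raise ValueError("empty foreground promoter set")
    bg_ids = {p.gene_id for p in background}
    fg_ids = {p.gene_id for p in foreground}
    if not fg_ids <= bg_ids:
        raise ValueError("foreground promoters not a subset of background")
    N, n = len(bg_ids), len(fg_ids)
    raw = []
    for pwm in pwms:
        with_hit = promoters_with_hit(
            pwm, background, pseudocount=pseudocount,
            threshold_fraction=threshold_fraction)
        K = len(with_hit)
        k = len(with_hit & fg_ids)
        p = hypergeom_upper_tail(k, N, K, n)
        raw.append((pwm.motif_id, k, K, p))
    qvals = bh_fdr([r[3] for r in raw])
    out = []
    for (motif_id, k, K, p), q in zip(raw, qvals):
        out.append(MotifEnrichmentResult(
            family=family, motif_id=motif_id, k=k, n=n, K=K, N=N,
            p=p, q=q, enriched=(p < p_cutoff and q < q_cutoff)))
    return out


def enrichment_table(results: list[MotifEnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
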