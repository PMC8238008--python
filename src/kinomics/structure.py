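"""Per-gene structural features and basic protein properties.

The twelve gene-structure features (transcript length, exon/intron/CDS/UTR
counts and total lengths, plus the kinase-domain count carried over from the
catalog) are computed on the primary transcript: the mRNA with the longest
mature (spliced) sequence, ties broken by lexicographic id.  "Transcript
length" is the mature spliced length; the genomic span is reported
separately since annotations differ on whether introns are included.

Protein molecular weight uses standard average residue masses plus one
water; the isoelectric point solves net charge(pH) = 0 with a
Henderson–Hasselbalch model and a documented, configurable pKa table.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import pandas as pd

from .annotation import GenomeAnnotation, Transcript

#: Average (isotope-abundance weighted) residue masses, daltons.
AVERAGE_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594,
    "N": 114.1038, "D": 115.0886, "Q": 128.1307, "K": 128.1741,
    "E": 129.1155, "M": 131.1926, "H": 137.1411, "F": 147.1766,
    "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MASS = 18.0153

#: Default pKa table for the charge model (termini + ionizable side chains).
DEFAULT_PKA = {
    "nterm": 9.69, "cterm": 2.34,
    "K": 10.5, "R": 12.4, "H": 6.0,          # positive groups
    "D": 3.9, "E": 4.1, "C": 8.3, "Y": 10.1,  # negative groups
}


@dataclass
class GeneFeatures:
    gene_id: str
    transcript_id: str
    transcript_length: int
    n_exons: int
    exon_length_total: int
    n_introns: int
    intron_length_total: int
    n_cds_chunks: int
    cds_length_total: int
    n_utr5: int
    utr5_length_total: int
    n_utr3: int
    utr3_length_total: int
    n_kinase_domains: int
    genomic_span: int

    def as_dict(self) -> dict:
        return asdict(self)


FEATURE_COLUMNS = [
    "transcript_length", "n_exons", "exon_length_total", "n_introns",
    "intron_length_total", "n_cds_chunks", "cds_length_total",
    "n_utr5", "utr5_length_total", "n_utr3", "utr3_length_total",
    "n_kinase_domains",
]


def primary_transcript(transcripts: list[Transcript]) -> Transcript:
    """Longest mature transcript; ties go to the lexicographically
    smallest transcript id."""
    best = max(t.spliced_length for t in transcripts)
    return min((t for t in transcripts if t.spliced_length == best),
               key=lambda t: t.transcript_id)


def _derive_utrs(tx: Transcript) -> tuple[list, list]:
    """UTR intervals from exon minus CDS when UTR records are absent."""
    if not tx.cds:
        return [], []
    cds_lo = tx.cds[0][0]
    cds_hi = tx.cds[-1][1]
    left, right = [], []
    for s, e in tx.exons:
        if s < cds_lo:
            left.append((s, min(e, cds_lo)))
        if e > cds_hi:
            right.append((max(s, cds_hi), e))
    return (left, right) if tx.strand == "+" else (right, left)


def compute_gene_features(annotation: GenomeAnnotation, gene_id: str,
                          domain_counts: dict[str, int] | None = None
                          ) -> GeneFeatures:
    gene = annotation.genes[gene_id]
    if not gene.transcripts:
        raise ValueError(f"gene {gene_id!r} has no mRNA")
    tx = primary_transcript(gene.transcripts)
    if not tx.exons:
        raise ValueError(f"transcript {tx.transcript_id!r} has no exons")
    for (s1, e1), (s2, e2) in zip(tx.exons, tx.exons[1:]):
        if s2 < e1:
            raise ValueError(
                f"overlapping exons in {tx.transcript_id!r}: "
                f"({s1},{e1}) and ({s2},{e2})")
    for cs, ce in tx.cds:
        if not any(s <= cs and ce <= e for s, e in tx.exons):
            raise ValueError(
                f"CDS ({cs},{ce}) outside exons in {tx.transcript_id!r}")

    introns = [(e1, s2) for (_, e1), (s2, _) in zip(tx.exons, tx.exons[1:])]
    utr5, utr3 = tx.utr5, tx.utr3
    if not utr5 and not utr3:
        utr5, utr3 = _derive_utrs(tx)
    dom = (domain_counts or {}).get(gene_id, 0)
    return GeneFeatures(
        gene_id=gene_id,
        transcript_id=tx.transcript_id,
        transcript_length=tx.spliced_length,
        n_exons=len(tx.exons),
        exon_length_total=tx.spliced_length,
        n_introns=len(introns),
        intron_length_total=sum(e - s for s, e in introns),
        n_cds_chunks=len(tx.cds),
        cds_length_total=sum(e - s for s, e in tx.cds),
        n_utr5=len(utr5),
        utr5_length_total=sum(e - s for s, e in utr5),
        n_utr3=len(utr3),
        utr3_length_total=sum(e - s for s, e in utr3),
        n_kinase_domains=dom,
        genomic_span=tx.genomic_span,
    )


def family_feature_summary(catalog: pd.DataFrame,
                           features: dict[str, GeneFeatures]
                           ) -> pd.DataFrame:
    """Arithmetic means of the 12 features per family, with member counts.

    Families whose members all lack features are skipped with a warning.
    """
    import warnings

    rows = []
    for family, sub in catalog.dropna(subset=["family"]).groupby("family"):
        members = [features[p] for p in sub["protein_id"] if p in features]
        if not members:
            warnings.warn(f"family {family!r} has no feature records; "
                          "skipped", stacklevel=2)
            continue
        row = {"family": family, "n_members": len(members)}
        for col in FEATURE_COLUMNS:
            row[col] = sum(getattr(m, col) for m in members) / len(members)
        rows.append(row)
    return (pd.DataFrame(rows)
            .sort_values("family")
            .reset_index(drop=True))


def protein_mw(sequence: str,
               mass_table: dict[str, float] | None = None) -> float:
    """Average molecular weight in daltons (residues + one water)."""
    table = mass_table or AVERAGE_RESIDUE_MASS
    bad = sorted({c for c in sequence if c not in table})
    if bad:
        raise ValueError(f"non-standard residues: {''.join(bad)!r}")
    return sum(table[c] for c in sequence) + WATER_MASS


def net_charge(sequence: str, ph: float,
               pka: dict[str, float] | None = None) -> float:
    table = pka or DEFAULT_PKA
    counts = {c: sequence.count(c) for c in "KRHDECY"}
    pos = 1.0 / (1.0 + 10 ** (ph - table["nterm"]))
    for res in "KRH":
        pos += counts[res] / (1.0 + 10 ** (ph - table[res]))
    neg = 1.0 / (1.0 + 10 ** (table["cterm"] - ph))
    for res in "DECY":
        neg += counts[res] / (1.0 + 10 ** (table[res] - ph))
    return pos - neg


def protein_pi(sequence: str, tolerance: float = 1e-4,
               pka: dict[str, float] | None = None) -> float:
    """Isoelectric point by bisection on the strictly decreasing charge."""
    table = pka or DEFAULT_PKA
    bad = sorted({c for c in sequence if c not in AVERAGE_RESIDUE_MASS})
    if bad:
        raise ValueError(f"non-standard residues: {''.join(bad)!r}")
    lo, hi = 0.0, 14.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        charge = net_charge(sequence, mid, table)
        if abs(charge) < tolerance:
            return mid
        if charge > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
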