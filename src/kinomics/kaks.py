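"""Pairwise Ka/Ks by Nei–Gojobori (1986) counting with Jukes–Cantor
correction.

Synonymous/nonsynonymous *sites* are counted per codon as the fraction of
the three single-nucleotide changes that are synonymous under the standard
genetic code, with changes creating stop codons counted as nonsynonymous;
site totals are averaged over the two sequences.  *Differences* between a
codon pair are averaged over all minimal mutational pathways with equal
weights, excluding pathways that pass through a stop codon (weights
renormalized; if every pathway is blocked, all are kept and stop steps
count as nonsynonymous).  The proportions pS = Sd/S and pN = Nd/N are
corrected for multiple hits with d = -(3/4) ln(1 - (4/3) p).

Ka/Ks < 1 indicates purifying selection, = 1 neutral evolution and > 1
positive selection on the pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

from Bio.Data.CodonTable import unambiguous_dna_by_id

_TABLE = unambiguous_dna_by_id[1]  # standard genetic code
CODON_AA: dict[str, str] = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    CODON_AA[_stop] = "*"
STOP_CODONS = frozenset(_TABLE.stop_codons)
BASES = "ACGT"

NEUTRAL_TOL = 1e-9


class UndefinedDistance(ValueError):
    """Raised when the Jukes–Cantor correction is outside its domain."""


def jukes_cantor(p: float) -> float:
    """Multiple-hit corrected distance d = -(3/4) ln(1 - (4/3) p)."""
    if p < 0:
        raise ValueError("proportion of differences must be >= 0")
    if p >= 0.75:
        raise UndefinedDistance(
            f"Jukes-Cantor correction undefined for p = {p} >= 3/4")
    if p == 0:
        return 0.0
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def kaks_classify(ratio: float | None) -> str:
    """Selection regime from a Ka/Ks ratio (None passes through)."""
    if ratio is None:
        return "undefined"
    if abs(ratio - 1.0) <= NEUTRAL_TOL:
        return "neutral"
    return "purifying" if ratio < 1.0 else "positive"


@dataclass
class CodonAlignment:
    codons_a: list[str]
    codons_b: list[str]
    n_excluded: int  # codon columns dropped pairwise

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("codon lists differ in length")

    @property
    def n_codons(self) -> int:
        return len(self.codons_a)


@dataclass
class KaKsResult:
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float | None
    Ka: float | None
    ratio: float | None
    selection: str


def _codons(seq: str) -> list[str]:
    seq = seq.upper().replace("U", "T")
    if len(seq) % 3:
        raise ValueError("CDS length not divisible by 3")
    return [seq[i:i + 3] for i in range(0, len(seq), 3)]


def translate_cds(seq: str) -> str:
    return "".join(CODON_AA[c] for c in _codons(seq))


def codon_align(protein_alignment: tuple[str, str],
                cds_pair: tuple[str, str]) -> CodonAlignment:
    """Back-translate a pairwise protein alignment onto the CDS pair.

    Columns gapped in either protein, or whose codon contains an
    ambiguous nucleotide or encodes a stop, are dropped pairwise and
    counted in ``n_excluded``.
    """
    out_a: list[str] = []
    out_b: list[str] = []
    excluded = 0
    streams = []
    for name, aln, cds in zip("ab", protein_alignment, cds_pair):
        codons = _codons(cds)
        ungapped = aln.replace("-", "")
        if len(ungapped) != len(codons):
            raise ValueError(
                f"CDS/protein length mismatch for sequence {name!r}: "
                f"{len(codons)} codons vs {len(ungapped)} residues")
        streams.append(iter(codons))
    aln_a, aln_b = protein_alignment
    if len(aln_a) != len(aln_b):
        raise ValueError("protein alignment rows differ in length")
    it_a, it_b = streams
    for col_a, col_b in zip(aln_a, aln_b):
        ca = next(it_a) if col_a != "-" else None
        cb = next(it_b) if col_b != "-" else None
        if ca is None or cb is None:
            excluded += 1
            continue
        if (any(ch not in BASES for ch in ca + cb)
                or ca in STOP_CODONS or cb in STOP_CODONS):
            excluded += 1
            continue
        out_a.append(ca)
        out_b.append(cb)
    return CodonAlignment(out_a, out_b, excluded)


def syn_fraction(codon: str) -> float:
    """Synonymous-site count of one codon: the sum over the three
    positions of (synonymous single-nt changes) / 3.  Changes to stop
    codons are nonsynonymous."""
    aa = CODON_AA[codon]
    total = 0.0
    for pos in range(3):
        syn = 0
        for base in BASES:
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1:]
            if mut not in STOP_CODONS and CODON_AA[mut] == aa:
                syn += 1
        total += syn / 3.0
    return total


def pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(Sd, Nd) for one codon pair, averaged with equal weights over all
    minimal mutational pathways that avoid stop codons."""
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    blocked: list[tuple[int, int]] = []
    for order in permutations(diff_pos):
        current = codon_a
        sd = nd = 0
        through_stop = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            if nxt in STOP_CODONS:
                through_stop = True
            if (nxt not in STOP_CODONS and current not in STOP_CODONS
                    and CODON_AA[nxt] == CODON_AA[current]):
                sd += 1
            else:
                nd += 1
            current = nxt
        (blocked if through_stop else valid).append((sd, nd))
    paths = valid if valid else blocked
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def nei_gojobori(aln: CodonAlignment) -> KaKsResult:
    """NG86 site and difference counts plus JC-corrected rates."""
    if aln.n_codons == 0:
        raise ValueError("empty codon alignment")
    s_a = sum(syn_fraction(c) for c in aln.codons_a)
    s_b = sum(syn_fraction(c) for c in aln.codons_b)
    S = 0.5 * (s_a + s_b)
    N = 3.0 * aln.n_codons - S
    Sd = Nd = 0.0
    for ca, cb in zip(aln.codons_a, aln.codons_b):
        sd, nd = pathway_differences(ca, cb)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    try:
        Ks = jukes_cantor(pS)
    except UndefinedDistance:
        Ks = None
    try:
        Ka = jukes_cantor(pN)
    except UndefinedDistance:
        Ka = None
    if Ka is None or Ks is None or Ks == 0.0:
        ratio = None
    else:
        ratio = Ka / Ks
    return KaKsResult(S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN,
                      Ks=Ks, Ka=Ka, ratio=ratio,
                      selection=kaks_classify(ratio))


def kaks_pair(cds_a: str, cds_b: str,
              protein_alignment: tuple[str, str] | None = None
              ) -> KaKsResult:
    """Convenience wrapper: codon-align two CDSs and run NG86.

    Without an explicit protein alignment the CDSs must be the same
    length (gap-free codon correspondence).
    """
    if protein_alignment is None:
        if len(cds_a) != len(cds_b):
            raise ValueError(
                "equal-length CDSs required when no protein alignment "
                "is given")
        protein_alignment = (translate_cds(cds_a), translate_cds(cds_b))
    return nei_gojobori(codon_align(protein_alignment, (cds_a, cds_b)))
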