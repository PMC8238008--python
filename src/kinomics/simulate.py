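"""Seeded synthetic genomes with machine-readable ground truth.

The generator emits everything the analysis stages consume — a
multi-chromosome genome with intron/exon/UTR gene models (GFF3 +
FASTA), planted kinase families with domain- and family-HMM hit
tables, planted duplication classes realized as low-divergence sequence
copies at controlled gene ranks, intra- and inter-genome collinear
chains, CDS pairs evolved under a controlled selection intensity
(omega), promoters with planted motifs, DE/GO/Ct tables with planted
effects — together with truth tables that every downstream module can
be scored against.

Planted duplication geometry follows the classifier's rank semantics:
tandem copies sit at adjacent ranks, proximal copies at rank gaps of
2–19 on the same chromosome, dispersed copies on different chromosomes,
and WGD/segmental copies inside planted collinear chains of >= 5 pairs.
Fixed seed implies byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation, Gene, Transcript, \
    map_transcript_interval
from .kaks import CODON_AA, STOP_CODONS, translate_cds
from .promoter import PWM, write_jaspar_pfm

BASES = "ACGT"
NON_STOP_CODONS = sorted(c for c in CODON_AA if c not in STOP_CODONS)

#: Built-in planted motif consensi (JASPAR-style ids are synthetic).
MOTIF_CONSENSUS = {
    "MCRE001": "TGACGTCAGC",
    "MCRE002": "CACGTGGCTA",
    "MCRE003": "AGCCGCCTTA",
}

GO_TERM_POOL = [f"GO:{7000000 + i}" for i in range(15)]
PLANTED_GO_TERM = "GO:0009651"  # planted salt/osmotic-stress-like term


def motif_pwms() -> list[PWM]:
    """Count matrices for the built-in motifs (12 counts on the
    consensus base, 1 elsewhere)."""
    out = []
    for mid, cons in MOTIF_CONSENSUS.items():
        counts = np.ones((4, len(cons)))
        for j, base in enumerate(cons):
            counts[BASES.index(base), j] = 12.0
        out.append(PWM(motif_id=mid, counts=counts))
    return out


def _default_family_sizes() -> dict[str, int]:
    return {
        "RLK-Pelle_DLSV": 8,
        "RLK-Pelle_LRR-XI-1": 5,
        "CAMK_CDPK": 5,
        "CMGC_CDK-CRK7-CDK9": 4,
        "STE_STE11": 3,
        "TKL_CTR1-DRK-2": 3,
        "AGC_RSK-2": 2,
        "CK1_CK1": 1,
    }


@dataclass
class SimConfig:
    """Study conditions for one synthetic genome."""

    n_chromosomes: int = 3
    chrom_length: int = 300_000
    n_genes: int = 120
    family_sizes: dict[str, int] = field(
        default_factory=_default_family_sizes)
    #: list of (class, n_pairs) with class in tandem/proximal/dispersed
    duplication_plan: list[tuple[str, int]] = field(
        default_factory=lambda: [("tandem", 4), ("proximal", 3),
                                 ("dispersed", 3)])
    #: list of (chrom_index_a, chrom_index_b, n_gene_pairs)
    collinear_block_plan: list[tuple[int, int, int]] = field(
        default_factory=lambda: [(0, 1, 6)])
    #: (family, motif_id) -> (foreground_fraction, background_fraction);
    #: the default family has only 8 members, so the planted motif is
    #: given a high per-promoter rate to represent a strongly associated
    #: cis-element
    promoter_motif_plan: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: {
            ("RLK-Pelle_DLSV", "MCRE001"): (0.9, 0.05)})
    #: family -> (n_up, mean_log2FC)
    de_plan: dict[str, tuple[int, float]] = field(
        default_factory=lambda: {"RLK-Pelle_DLSV": (4, 2.5),
                                 "CAMK_CDPK": (2, 2.0)})
    #: selection intensities (Ka/Ks-style omega) cycled over planted
    #: duplicate pairs; the default is purifying-dominated with a
    #: minority of neutral/positive pairs, as tandem kinome duplicates
    #: typically show
    omega_plan: list[float] = field(
        default_factory=lambda: [0.2, 0.3, 0.5, 0.2, 0.4, 0.3, 0.6,
                                 0.2, 1.0, 5.0])
    seed: int = 0
    duplicate_divergence: float = 0.02
    family_divergence: float = 0.05
    kinase_cds_codons: int = 210
    promoter_length: int = 1000
    de_noise_sd: float = 0.5
    ct_noise_sd: float = 0.15
    qpcr_efficiency: float = 2.0
    #: planted GO-term annotation rates (5x foreground enrichment)
    go_fg_rate: float = 0.85
    go_bg_rate: float = 0.17
    assays: tuple[str, ...] = ("injury_cabmv", "injury_cpsmv",
                               "root_dehydration")
    crosstalk_n: int = 2

    def validate(self) -> None:
        for name in ("n_chromosomes", "chrom_length", "n_genes",
                     "kinase_cds_codons", "promoter_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for fam, size in self.family_sizes.items():
            if size <= 0:
                raise ValueError(f"family size for {fam!r} must be positive")
        for cls, n in self.duplication_plan:
            if cls not in ("tandem", "proximal", "dispersed"):
                raise ValueError(f"unknown duplication class {cls!r}")
            if n <= 0:
                raise ValueError("duplication pair counts must be positive")
        for ca, cb, n in self.collinear_block_plan:
            if not (0 <= ca < self.n_chromosomes
                    and 0 <= cb < self.n_chromosomes):
                raise ValueError("collinear block chromosome out of range")
            if n <= 0:
                raise ValueError("collinear pair counts must be positive")
        for key, (fg, bg) in self.promoter_motif_plan.items():
            if not (0 <= fg <= 1 and 0 <= bg <= 1):
                raise ValueError(
                    f"motif fractions for {key} must lie in [0, 1]")
        if any(w < 0 for w in self.omega_plan):
            raise ValueError("omega values must be >= 0")
        if not (0 <= self.go_bg_rate <= 1 and 0 <= self.go_fg_rate <= 1):
            raise ValueError("GO planting rates must lie in [0, 1]")


@dataclass
class TruthTables:
    true_family: dict[str, str] = field(default_factory=dict)
    true_n_domains: dict[str, int] = field(default_factory=dict)
    true_duplication_class: dict[str, str] = field(default_factory=dict)
    true_blocks: list[list[tuple[str, str]]] = field(default_factory=list)
    true_omega: dict[tuple[str, str], float] = field(default_factory=dict)
    true_de: dict[tuple[str, str], float] = field(default_factory=dict)
    true_enriched_terms: list[str] = field(default_factory=list)
    true_ratios: dict[str, float] = field(default_factory=dict)
    true_gene_features: dict[str, dict] = field(default_factory=dict)
    true_motif_sites: list[tuple[str, str, int]] = field(
        default_factory=list)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        pd.DataFrame(
            [{"gene_id": g, "family": f}
             for g, f in self.true_family.items()]
        ).to_csv(outdir / "truth_family.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"gene_id": g, "class": c}
             for g, c in self.true_duplication_class.items()]
        ).to_csv(outdir / "truth_duplication.tsv", sep="\t", index=False)
        rows = [{"block": i, "order": j, "gene_a": a, "gene_b": b}
                for i, blk in enumerate(self.true_blocks, 1)
                for j, (a, b) in enumerate(blk, 1)]
        pd.DataFrame(rows, columns=["block", "order", "gene_a", "gene_b"]
                     ).to_csv(outdir / "truth_blocks.tsv", sep="\t",
                              index=False)
        pd.DataFrame(
            [dict(gene_id=g, **feats)
             for g, feats in self.true_gene_features.items()]
        ).to_csv(outdir / "truth_features.tsv", sep="\t", index=False)


@dataclass
class GenomeBundle:
    config: SimConfig
    annotation: GenomeAnnotation
    genome: dict[str, str]
    cds: dict[str, str]
    proteins: dict[str, str]
    domain_hits: pd.DataFrame
    family_hits: pd.DataFrame
    similarity: pd.DataFrame
    truth: TruthTables

    @property
    def kinase_ids(self) -> list[str]:
        return sorted(self.truth.true_family)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.annotation.write_gff3(outdir / "annotation.gff3")
        _write_fasta(self.genome, outdir / "genome.fa")
        _write_fasta(self.cds, outdir / "cds.fa")
        _write_fasta(self.proteins, outdir / "proteins.fa")
        self.domain_hits.to_csv(outdir / "domain_hits.tsv", sep="\t",
                                index=False)
        self.family_hits.to_csv(outdir / "family_hits.tsv", sep="\t",
                                index=False)
        self.similarity.to_csv(outdir / "similarity.tsv", sep="\t",
                               index=False)
        write_jaspar_pfm(motif_pwms(), outdir / "motifs.pfm")
        self.truth.write(outdir)


def _write_fasta(seqs: dict[str, str], path: Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


# --------------------------------------------------------- sequence utils

def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(NON_STOP_CODONS), size=n_codons)
    return "".join(NON_STOP_CODONS[i] for i in idx)


def mutate_cds(rng: np.random.Generator, cds: str, rate: float) -> str:
    """Substitute ~rate of the nucleotides without creating in-frame
    stop codons."""
    seq = list(cds)
    n_mut = int(round(rate * len(seq)))
    if n_mut == 0:
        return cds
    positions = rng.choice(len(seq), size=min(n_mut, len(seq)),
                           replace=False)
    for pos in positions:
        ci = (pos // 3) * 3
        alternatives = [b for b in BASES if b != seq[pos]]
        rng.shuffle(alternatives)
        for base in alternatives:
            codon = "".join(seq[ci:ci + 3][:pos - ci] + [base]
                            + seq[ci:ci + 3][pos - ci + 1:])
            if codon not in STOP_CODONS:
                seq[pos] = base
                break
    return "".join(seq)


def evolve_cds_pair(cds: str, omega: float, n_events: int,
                    seed: int | None = None
                    ) -> tuple[str, list[tuple[int, str, str, bool]]]:
    """Evolve a derived CDS under selection intensity omega.

    Uniform random single-nucleotide changes are proposed; for
    ``omega <= 1`` synonymous proposals are accepted with probability 1
    and nonsynonymous ones with probability ``omega``.  For
    ``omega > 1`` (positive selection) acceptance probabilities cannot
    exceed 1, so the same rate ratio is realized by accepting
    nonsynonymous proposals with probability 1 and synonymous ones with
    probability ``1/omega``.  Proposals creating a stop codon, or
    falling on a stop codon, are rejected.  ``n_events`` counts
    *accepted* substitutions; the log records each accepted change as
    (position, old_base, new_base, synonymous).
    """
    if len(cds) % 3:
        raise ValueError("CDS length must be divisible by 3")
    if omega < 0:
        raise ValueError("omega must be >= 0")
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    if any(c in STOP_CODONS for c in codons[:-1]):
        raise ValueError("CDS contains internal stop codons")
    rng = np.random.default_rng(seed)
    seq = list(cds.upper())
    log: list[tuple[int, str, str, bool]] = []
    accept_nonsyn = min(omega, 1.0)
    accept_syn = 1.0 if omega <= 1.0 else 1.0 / omega
    while len(log) < n_events:
        pos = int(rng.integers(0, len(seq)))
        ci = (pos // 3) * 3
        old_codon = "".join(seq[ci:ci + 3])
        if old_codon in STOP_CODONS:
            continue
        new_base = BASES[int(rng.integers(0, 4))]
        if new_base == seq[pos]:
            continue
        new_codon = (old_codon[:pos - ci] + new_base
                     + old_codon[pos - ci + 1:])
        if new_codon in STOP_CODONS:
            continue
        syn = CODON_AA[new_codon] == CODON_AA[old_codon]
        accept_p = accept_syn if syn else accept_nonsyn
        if accept_p >= 1.0 or rng.random() < accept_p:
            log.append((pos, seq[pos], new_base, syn))
            seq[pos] = new_base
    return "".join(seq), log


# ------------------------------------------------------------ genome gen

@dataclass
class _Slot:
    chrom: int
    rank: int
    dup_class: str = "singleton"
    pair_key: str | None = None
    in_block: int | None = None  # block index
    family: str | None = None
    cds: str | None = None


def _allocate_slots(config: SimConfig):
    """Assign duplication classes, block membership and pairings to
    rank slots; raises when the plan does not fit the genome."""
    n_chrom = config.n_chromosomes
    counts = [config.n_genes // n_chrom
              + (1 if c < config.n_genes % n_chrom else 0)
              for c in range(n_chrom)]
    slots: dict[tuple[int, int], _Slot] = {}
    next_free = [1] * n_chrom

    def take(chrom: int, n: int) -> list[int]:
        start = next_free[chrom]
        if start + n - 1 > counts[chrom]:
            raise ValueError(
                "plan infeasible: chromosome "
                f"{chrom} needs {start + n - 1} genes but only "
                f"{counts[chrom]} are planned (raise n_genes or shrink "
                "the duplication/collinearity plan)")
        next_free[chrom] = start + n
        ranks = list(range(start, start + n))
        for r in ranks:
            slots[(chrom, r)] = _Slot(chrom, r)
        return ranks

    blocks: list[list[tuple[tuple[int, int], tuple[int, int]]]] = []
    block_chrom_pairs: set[tuple[int, int]] = set()
    for bi, (ca, cb, n_pairs) in enumerate(config.collinear_block_plan):
        if ca == cb:
            raise ValueError("plan infeasible: collinear block must span "
                             "two different chromosomes")
        cpair = (min(ca, cb), max(ca, cb))
        if cpair in block_chrom_pairs:
            raise ValueError(
                "plan infeasible: at most one collinear block per "
                "chromosome pair (adjacent blocks would chain together)")
        block_chrom_pairs.add(cpair)
        ranks_a = take(ca, n_pairs)
        ranks_b = take(cb, n_pairs)
        chain = []
        cls = "wgd_segmental" if n_pairs >= 5 else "dispersed"
        for ra, rb in zip(ranks_a, ranks_b):
            sa, sb = slots[(ca, ra)], slots[(cb, rb)]
            sa.dup_class = sb.dup_class = cls
            sa.in_block = sb.in_block = bi
            sa.pair_key = sb.pair_key = f"blk{bi}.{ra}"
            chain.append(((ca, ra), (cb, rb)))
        blocks.append(chain)

    # Spurious chains are impossible only when fewer than min_block_size
    # matches can fall on any one chromosome pair outside planted blocks:
    # cap tandem+proximal matches per chromosome and dispersed matches per
    # chromosome pair at 4, and keep dispersed pairs off block pairs.
    pair_slots: list[tuple[tuple[int, int], tuple[int, int]]] = []
    plain_extra: list[tuple[int, int]] = []
    chrom_cycle = 0
    prox_i = 0
    same_chrom_matches = [0] * n_chrom
    dispersed_per_pair: dict[tuple[int, int], int] = {}
    dispersed_pairs = [
        (c1, c2) for c1 in range(n_chrom) for c2 in range(c1 + 1, n_chrom)
        if (c1, c2) not in block_chrom_pairs]
    disp_cycle = 0
    for cls, n_pairs in config.duplication_plan:
        for i in range(n_pairs):
            if cls in ("tandem", "proximal"):
                for _ in range(n_chrom + 1):
                    c = chrom_cycle % n_chrom
                    chrom_cycle += 1
                    if same_chrom_matches[c] < 4:
                        break
                else:
                    raise ValueError(
                        "plan infeasible: more than 4 tandem/proximal "
                        "pairs per chromosome would form spurious "
                        "collinear chains")
                same_chrom_matches[c] += 1
                if cls == "tandem":
                    r1, r2 = take(c, 2)
                    a, b = (c, r1), (c, r2)
                else:
                    gap = 2 + (prox_i % 5)  # rank gaps 2..6
                    prox_i += 1
                    ranks = take(c, gap + 1)
                    a, b = (c, ranks[0]), (c, ranks[-1])
                    plain_extra.extend((c, r) for r in ranks[1:-1])
            else:  # dispersed: different chromosomes, off block pairs
                if not dispersed_pairs:
                    raise ValueError(
                        "plan infeasible: no chromosome pair free of "
                        "collinear blocks for dispersed duplicates")
                for _ in range(len(dispersed_pairs) + 1):
                    cpair = dispersed_pairs[disp_cycle
                                            % len(dispersed_pairs)]
                    disp_cycle += 1
                    if dispersed_per_pair.get(cpair, 0) < 4:
                        break
                else:
                    raise ValueError(
                        "plan infeasible: more than 4 dispersed pairs "
                        "per chromosome pair would form spurious "
                        "collinear chains")
                dispersed_per_pair[cpair] = (
                    dispersed_per_pair.get(cpair, 0) + 1)
                c1, c2 = cpair
                a = (c1, take(c1, 1)[0])
                b = (c2, take(c2, 1)[0])
            for key in (a, b):
                slots[key].dup_class = cls
                slots[key].pair_key = f"{cls}{len(pair_slots)}"
            pair_slots.append((a, b))

    for c in range(n_chrom):
        for r in range(next_free[c], counts[c] + 1):
            slots[(c, r)] = _Slot(c, r)
            plain_extra.append((c, r))
    return counts, slots, blocks, pair_slots, sorted(plain_extra)


def _assign_families(config: SimConfig, slots, pair_slots, plain_slots):
    """Spread kinase-family membership over pair slots (both members of
    a pair share the family) and then plain slots."""
    pair_queue = list(pair_slots)
    single_queue = list(plain_slots)
    fams = sorted(config.family_sizes.items(),
                  key=lambda kv: (-kv[1], kv[0]))
    for fam, size in fams:
        remaining = size
        while remaining >= 2 and pair_queue:
            a, b = pair_queue.pop(0)
            slots[a].family = slots[b].family = fam
            remaining -= 2
        while remaining:
            if not single_queue:
                raise ValueError(
                    "plan infeasible: not enough gene slots for family "
                    f"{fam!r} (raise n_genes)")
            slots[single_queue.pop(0)].family = fam
            remaining -= 1


def gen_genome(config: SimConfig,
               seed: int | None = None) -> GenomeBundle:
    """Generate one annotated genome with planted ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    counts, slots, blocks, pair_slots, plain_slots = _allocate_slots(config)
    _assign_families(config, slots, pair_slots, plain_slots)

    chrom_names = [f"Chr{c + 1:02d}" for c in range(config.n_chromosomes)]

    def gene_id(key: tuple[int, int]) -> str:
        return f"VuG{key[0] + 1:02d}g{key[1]:04d}"

    # ---- CDS sequences: family founders first, then per-slot sequences
    founders = {fam: random_cds(rng, config.kinase_cds_codons)
                for fam in sorted(config.family_sizes)}
    ordered_keys = sorted(slots)
    # duplicate copies diverge under the planted selection intensity:
    # ~duplicate_divergence of the sites substituted through
    # evolve_cds_pair with omega cycled from omega_plan
    omega_cycle = list(config.omega_plan) or [0.5]
    pair_omegas: list[tuple[tuple[int, int], tuple[int, int], float]] = []
    for idx, (a, b) in enumerate(pair_slots):
        sa, sb = slots[a], slots[b]
        if sa.family is not None:
            base = mutate_cds(rng, founders[sa.family],
                              config.family_divergence)
        else:
            base = random_cds(rng, int(rng.integers(120, 260)))
        sa.cds = base
        omega = omega_cycle[idx % len(omega_cycle)]
        n_events = max(1, int(round(config.duplicate_divergence
                                    * len(base))))
        sb.cds, _ = evolve_cds_pair(
            base, omega, n_events, seed=int(rng.integers(2**31 - 1)))
        pair_omegas.append((a, b, omega))
    for chain in blocks:
        for a, b in chain:
            sa, sb = slots[a], slots[b]
            sa.cds = random_cds(rng, int(rng.integers(120, 260)))
            sb.cds = mutate_cds(rng, sa.cds, config.duplicate_divergence)
    for key in ordered_keys:
        slot = slots[key]
        if slot.cds is not None:
            continue
        if slot.family is not None:
            slot.cds = mutate_cds(rng, founders[slot.family],
                                  config.family_divergence)
        else:
            slot.cds = random_cds(rng, int(rng.integers(100, 240)))

    # ---- gene models and chromosome sequences
    truth = TruthTables()
    annotation = GenomeAnnotation(
        chrom_lengths={name: config.chrom_length for name in chrom_names})
    chrom_seqs = {name: rng.choice(list(BASES), size=config.chrom_length)
                  for name in chrom_names}

    for c, chrom in enumerate(chrom_names):
        cursor = config.promoter_length + 500
        for rank in range(1, counts[c] + 1):
            slot = slots[(c, rank)]
            gid = gene_id((c, rank))
            cds = slot.cds
            utr5_len = int(rng.integers(60, 200))
            utr3_len = int(rng.integers(60, 220))
            tx_len = utr5_len + len(cds) + utr3_len
            n_exons = int(rng.integers(1, 6))
            if n_exons > 1:
                cuts = sorted(rng.choice(
                    np.arange(1, tx_len), size=n_exons - 1, replace=False))
            else:
                cuts = []
            seg_bounds = [0] + list(cuts) + [tx_len]
            seg_lens = [int(b - a) for a, b in
                        zip(seg_bounds, seg_bounds[1:])]
            intron_lens = [int(rng.integers(60, 301))
                           for _ in range(n_exons - 1)]
            strand = "+" if rng.random() < 0.5 else "-"

            gap = 1200 + int(rng.integers(0, 601))
            start = cursor + gap
            exons = []
            pos = start
            for i, seg in enumerate(seg_lens):
                exons.append((pos, pos + seg))
                pos += seg
                if i < len(intron_lens):
                    pos += intron_lens[i]
            end = pos
            if end + 100 > config.chrom_length:
                raise ValueError(
                    f"plan infeasible: genes do not fit on {chrom} "
                    f"(need > {end} bp, chrom_length "
                    f"= {config.chrom_length})")
            cursor = end

            cds_iv = map_transcript_interval(
                exons, strand, utr5_len, utr5_len + len(cds))
            utr5_iv = map_transcript_interval(exons, strand, 0, utr5_len)
            utr3_iv = map_transcript_interval(
                exons, strand, utr5_len + len(cds), tx_len)
            tid = gid + ".1"
            tx = Transcript(tid, gid, chrom, strand, exons=exons,
                            cds=cds_iv, utr5=utr5_iv, utr3=utr3_iv)
            annotation.add_gene(Gene(gid, chrom, start, end, strand,
                                     transcripts=[tx]))

            # write the mature transcript into the chromosome
            utr5_seq = "".join(rng.choice(list(BASES), size=utr5_len))
            utr3_seq = "".join(rng.choice(list(BASES), size=utr3_len))
            mature = utr5_seq + cds + utr3_seq
            placed = mature if strand == "+" else _revcomp(mature)
            offset = 0
            for s, e in exons:
                chrom_seqs[chrom][s:e] = list(placed[offset:offset + e - s])
                offset += e - s

            truth.true_gene_features[gid] = {
                "transcript_length": tx_len,
                "n_exons": n_exons,
                "exon_length_total": tx_len,
                "n_introns": n_exons - 1,
                "intron_length_total": sum(intron_lens),
                "n_cds_chunks": len(cds_iv),
                "cds_length_total": len(cds),
                "n_utr5": len(utr5_iv),
                "utr5_length_total": utr5_len,
                "n_utr3": len(utr3_iv),
                "utr3_length_total": utr3_len,
                "genomic_span": end - start,
            }
            truth.true_duplication_class[gid] = slot.dup_class
            if slot.family is not None:
                truth.true_family[gid] = slot.family

    truth.true_blocks = [[(gene_id(a), gene_id(b)) for a, b in chain]
                         for chain in blocks]
    truth.true_omega = {(gene_id(a), gene_id(b)): omega
                        for a, b, omega in pair_omegas}

    # ---- planted promoter motifs
    genome = {c: "".join(s.tolist()) for c, s in chrom_seqs.items()}
    genome = _plant_motifs(config, rng, annotation, genome, truth)

    # ---- hit tables
    domain_rows, family_rows = [], []
    kinase_genes = sorted(truth.true_family)
    for gid in kinase_genes:
        fam = truth.true_family[gid]
        n_dom = int(rng.integers(1, 4))
        truth.true_n_domains[gid] = n_dom
        for _ in range(n_dom):
            cov = rng.uniform(0.55, 0.95)
            span = max(int(round(cov * 264)), 1)
            frm = int(rng.integers(1, 264 - span + 2))
            domain_rows.append({
                "protein_id": gid, "model_id": "PF00069",
                "model_from": frm, "model_to": frm + span - 1,
                "model_length": 264,
                "evalue": 10.0 ** -rng.uniform(20, 60),
                "bit_score": float(np.round(rng.uniform(100, 400), 1))})
        family_rows.append({
            "protein_id": gid, "model_id": fam,
            "model_from": 1, "model_to": 200, "model_length": 200,
            "evalue": 10.0 ** -rng.uniform(8, 30),
            "bit_score": float(np.round(rng.uniform(200, 600), 1))})
        # sub-cutoff decoy family hit, ignored by the e-value rule
        other = sorted(f for f in config.family_sizes if f != fam)
        if other:
            family_rows.append({
                "protein_id": gid,
                "model_id": other[int(rng.integers(0, len(other)))],
                "model_from": 1, "model_to": 150, "model_length": 200,
                "evalue": 10.0 ** -rng.uniform(1, 4),
                "bit_score": float(np.round(rng.uniform(20, 60), 1))})
    # decoy kinase-domain hits below the 50% coverage rule
    non_kinase = [g for g in annotation.genes if g not in truth.true_family]
    for gid in non_kinase[:5]:
        cov = rng.uniform(0.15, 0.45)
        span = max(int(round(cov * 264)), 1)
        domain_rows.append({
            "protein_id": gid, "model_id": "PF00069",
            "model_from": 1, "model_to": span, "model_length": 264,
            "evalue": 10.0 ** -rng.uniform(6, 12),
            "bit_score": float(np.round(rng.uniform(30, 90), 1))})

    sim_rows = []
    pair_lists = [((gene_id(a), gene_id(b)))
                  for a, b in pair_slots]
    pair_lists += [(gene_id(a), gene_id(b))
                   for chain in blocks for a, b in chain]
    for ga, gb in pair_lists:
        ident = float(np.round(100.0 * (1 - config.duplicate_divergence)
                               + rng.uniform(-0.5, 0.5), 2))
        bits = float(np.round(rng.uniform(500, 1500), 1))
        sim_rows.append({"query": ga, "subject": gb,
                         "identity": ident, "bit_score": bits})
        sim_rows.append({"query": gb, "subject": ga,
                         "identity": ident, "bit_score": bits})

    cds_seqs = {gene_id(k) + ".1": slots[k].cds for k in ordered_keys}
    proteins = {tid: translate_cds(s) for tid, s in cds_seqs.items()}

    hit_cols = ["protein_id", "model_id", "model_from", "model_to",
                "model_length", "evalue", "bit_score"]
    return GenomeBundle(
        config=config, annotation=annotation, genome=genome,
        cds=cds_seqs, proteins=proteins,
        domain_hits=pd.DataFrame(domain_rows, columns=hit_cols),
        family_hits=pd.DataFrame(family_rows, columns=hit_cols),
        similarity=pd.DataFrame(
            sim_rows, columns=["query", "subject", "identity",
                               "bit_score"]),
        truth=truth)


def _revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[c] for c in reversed(seq))


def _plant_motifs(config: SimConfig, rng: np.random.Generator,
                  annotation: GenomeAnnotation, genome: dict[str, str],
                  truth: TruthTables) -> dict[str, str]:
    if not config.promoter_motif_plan:
        return genome
    mutable = {c: list(s) for c, s in genome.items()}
    length = config.promoter_length
    for (family, motif_id), (fg, bg) in sorted(
            config.promoter_motif_plan.items()):
        cons = MOTIF_CONSENSUS[motif_id]
        for gid in annotation.genes:
            gene = annotation.genes[gid]
            frac = fg if truth.true_family.get(gid) == family else bg
            if rng.random() >= frac:
                continue
            if gene.strand == "+":
                pstart = max(gene.start - length, 0)
                pend = gene.start
            else:
                pstart = gene.end
                pend = min(gene.end + length, len(mutable[gene.chrom]))
            if pend - pstart < len(cons):
                continue
            off = int(rng.integers(0, pend - pstart - len(cons) + 1))
            piece = cons if gene.strand == "+" else _revcomp(cons)
            gpos = pstart + off
            mutable[gene.chrom][gpos:gpos + len(cons)] = list(piece)
            truth.true_motif_sites.append((gid, motif_id, off))
    return {c: "".join(s) for c, s in mutable.items()}


# -------------------------------------------------- expression datasets

def gen_expression_tables(config: SimConfig, truth: TruthTables,
                          transcripts: list[str],
                          seed: int | None = None):
    """DE tables per assay, a GO annotation table, a qPCR Ct table and
    the matching truth slice.

    Planted up-regulated transcripts get log2FC ~ Normal(mean, sd)
    truncated above 1 with p/FDR safely below the thresholds; null
    transcripts get log2FC ~ Normal(0, 0.6*sd), p ~ Uniform(0, 1) and
    BH-adjusted FDR.  Ct values follow base - log_E(expression ratio)
    with Normal(0, ct_noise_sd) replicate noise.
    """
    from .expression import bh_fdr

    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    fam_members = {fam: sorted(t for t in transcripts
                               if truth.true_family.get(t[:-2]) == fam)
                   for fam in config.de_plan}
    # crosstalk transcripts: planted up in every assay
    crosstalk: list[str] = []
    if config.de_plan:
        biggest = max(sorted(config.de_plan),
                      key=lambda f: config.de_plan[f][0])
        crosstalk = fam_members.get(biggest, [])[:config.crosstalk_n]

    de_tables: dict[str, pd.DataFrame] = {}
    planted_by_assay: dict[str, set[str]] = {}
    for assay in config.assays:
        planted: set[str] = set(crosstalk)
        for fam, (n_up, _mean) in sorted(config.de_plan.items()):
            pool = [t for t in fam_members.get(fam, [])
                    if t not in planted]
            need = max(n_up - sum(1 for t in crosstalk
                                  if t in fam_members.get(fam, [])), 0)
            if need > len(pool):
                raise ValueError(
                    f"de_plan infeasible: family {fam!r} has "
                    f"{len(fam_members.get(fam, []))} transcripts, "
                    f"{n_up} planted up requested")
            take = list(rng.choice(pool, size=need, replace=False)) \
                if need else []
            planted.update(take)
        planted_by_assay[assay] = planted

        rows = []
        for treatment in ("early", "late"):
            null_p = {}
            for tid in transcripts:
                if tid in planted:
                    fam = truth.true_family.get(tid[:-2])
                    mean = config.de_plan.get(fam, (0, 2.5))[1]
                    if config.de_noise_sd == 0:
                        lfc = mean
                    else:
                        lfc = 0.0
                        while lfc <= 1.0:
                            lfc = rng.normal(mean, config.de_noise_sd)
                    p = 10.0 ** -rng.uniform(3, 8)
                    fdr = 10.0 ** -rng.uniform(2, 6)
                    truth.true_de[(assay, tid)] = lfc
                else:
                    lfc = rng.normal(0.0, 0.6 * config.de_noise_sd)
                    p = rng.uniform(0.0, 1.0)
                    fdr = None
                    null_p[tid] = p
                rows.append({"transcript_id": tid, "treatment": treatment,
                             "log2FC": float(lfc), "p": float(p),
                             "fdr": fdr})
            # BH-adjust the null p-values within this treatment
            if null_p:
                adj = bh_fdr(list(null_p.values()))
                adj_map = dict(zip(null_p, adj))
                for row in rows:
                    if (row["treatment"] == treatment
                            and row["fdr"] is None):
                        row["fdr"] = float(adj_map[row["transcript_id"]])
        de_tables[assay] = pd.DataFrame(
            rows, columns=["transcript_id", "treatment", "log2FC", "p",
                           "fdr"])

    # ---- GO annotations; plant one enriched term in the dehydration set
    fg_assay = config.assays[-1]
    fg = planted_by_assay[fg_assay]
    go_rows = []
    for tid in transcripts:
        n_terms = int(rng.integers(1, 4))
        terms = set(rng.choice(GO_TERM_POOL, size=n_terms, replace=False))
        p_plant = config.go_fg_rate if tid in fg else config.go_bg_rate
        if rng.random() < p_plant:
            terms.add(PLANTED_GO_TERM)
        for term in sorted(terms):
            go_rows.append({"gene": tid, "term": term,
                            "name": f"synthetic process {term[-4:]}"})
    go_table = pd.DataFrame(go_rows, columns=["gene", "term", "name"])
    truth.true_enriched_terms = [PLANTED_GO_TERM]

    # ---- qPCR Ct table for two planted targets + two references
    e = config.qpcr_efficiency
    targets = sorted(fg)[:2]
    genes = {t: 2.0 ** truth.true_de[(fg_assay, t)] for t in targets}
    genes["reference_actin"] = 1.0
    genes["reference_ubc"] = 1.0
    ct_rows = []
    for gene, ratio in genes.items():
        base = rng.uniform(22.0, 26.0)
        for rep in range(1, 4):
            ct_rows.append({
                "gene": gene, "condition": "control", "replicate": rep,
                "Ct": float(base + rng.normal(0, config.ct_noise_sd))})
        for rep in range(1, 4):
            ct_rows.append({
                "gene": gene, "condition": "treated", "replicate": rep,
                "Ct": float(base - np.log(ratio) / np.log(e)
                            + rng.normal(0, config.ct_noise_sd))})
        if gene in targets:
            truth.true_ratios[gene] = ratio
    ct_table = pd.DataFrame(
        ct_rows, columns=["gene", "condition", "replicate", "Ct"])
    return de_tables, go_table, ct_table, {
        "planted_by_assay": planted_by_assay,
        "crosstalk": set(crosstalk),
        "targets": targets,
    }


# ----------------------------------------------------- dual-genome pairs

def gen_genome_pair(config_a: SimConfig, config_b: SimConfig,
                    inter_block_plan: list[tuple[int, int, int]],
                    seed: int = 0):
    """Two genomes plus an inter-genome hit table with planted
    collinear chains.

    ``inter_block_plan``: (chrom_index_in_A, chrom_index_in_B, n_pairs).
    Planted chains use consecutive gene ranks on both sides, separated
    far enough that distinct chains cannot merge.
    """
    bundle_a = gen_genome(config_a, seed=seed)
    bundle_b = gen_genome(config_b, seed=seed + 1)
    rng = np.random.default_rng(seed + 2)
    ranks_a = {c: bundle_a.annotation.genes_on(c)
               for c in bundle_a.annotation.chrom_lengths}
    ranks_b = {c: bundle_b.annotation.genes_on(c)
               for c in bundle_b.annotation.chrom_lengths}
    chroms_a = sorted(ranks_a)
    chroms_b = sorted(ranks_b)
    cursor_a = {c: 0 for c in chroms_a}
    cursor_b = {c: 0 for c in chroms_b}
    sep = 26  # > default max_rank_gap, so chains cannot merge
    rows = []
    true_blocks = []
    for ca_i, cb_i, n_pairs in inter_block_plan:
        ca, cb = chroms_a[ca_i], chroms_b[cb_i]
        sa, sb = cursor_a[ca], cursor_b[cb]
        if (sa + n_pairs > len(ranks_a[ca])
                or sb + n_pairs > len(ranks_b[cb])):
            raise ValueError(
                f"plan infeasible: not enough genes on {ca}/{cb} for a "
                f"{n_pairs}-pair block")
        chain = []
        for i in range(n_pairs):
            ga = ranks_a[ca][sa + i].gene_id
            gb = ranks_b[cb][sb + i].gene_id
            rows.append({"query": ga, "subject": gb,
                         "identity": float(np.round(
                             rng.uniform(90, 99), 2)),
                         "bit_score": float(np.round(
                             rng.uniform(500, 1500), 1))})
            chain.append((ga, gb))
        true_blocks.append(chain)
        cursor_a[ca] = sa + n_pairs + sep
        cursor_b[cb] = sb + n_pairs + sep
    hits = pd.DataFrame(rows, columns=["query", "subject", "identity",
                                       "bit_score"])
    return bundle_a, bundle_b, hits, true_blocks
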