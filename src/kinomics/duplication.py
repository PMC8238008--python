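"""Gene-duplication origin classification and collinear-block detection.

The classifier follows the MCScanX duplicate_gene_classifier logic on gene
ranks (a gene's 1-based position among all annotated genes on its
chromosome, ordered by start coordinate): genes without similarity hits are
singletons; any hit makes a gene a dispersed duplicate; a same-chromosome
partner at rank gap 2..proximal_max_gap upgrades it to proximal, rank gap
exactly 1 to tandem, and anchoring in a collinear block to WGD/segmental.
The final call is the highest label in the priority order
wgd_segmental > tandem > proximal > dispersed > singleton.

Collinear blocks are maximal chains of homologous gene pairs with strictly
monotone ranks on both genomes (same or inverted orientation) and a bounded
per-step rank gap, extracted greedily by descending chain length with each
match used at most once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .annotation import GenomeAnnotation

CLASS_PRIORITY = ["singleton", "dispersed", "proximal", "tandem",
                  "wgd_segmental"]
_PRIO = {c: i for i, c in enumerate(CLASS_PRIORITY)}


def gene_ranks(annotation: GenomeAnnotation) -> pd.DataFrame:
    """Ranks over ALL annotated genes, per chromosome, by ascending start
    (ties: end, then id)."""
    rows = []
    for chrom in annotation.chrom_lengths:
        for rank, gene in enumerate(annotation.genes_on(chrom), start=1):
            rows.append({"gene_id": gene.gene_id, "chromosome": chrom,
                         "rank": rank, "start": gene.start,
                         "end": gene.end})
    df = pd.DataFrame(rows, columns=["gene_id", "chromosome", "rank",
                                     "start", "end"])
    if df["gene_id"].duplicated().any():
        dupes = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene ids: {dupes}")
    return df


def top_hits_per_gene(hits: pd.DataFrame, n_top: int = 5) -> set[tuple]:
    """Symmetrized similarity pairs, keeping each gene's ``n_top``
    strongest non-self hits by bit score.

    Expects columns ``query``, ``subject`` and (optionally) ``bit_score``;
    without scores all non-self pairs are kept.
    """
    df = hits[hits["query"] != hits["subject"]]
    if "bit_score" in df.columns and n_top is not None:
        df = (df.sort_values(["query", "bit_score", "subject"],
                             ascending=[True, False, True])
                .groupby("query", sort=False)
                .head(n_top))
    return {tuple(sorted((q, s)))
            for q, s in zip(df["query"], df["subject"])}


@dataclass
class CollinearBlock:
    chrom_a: str
    chrom_b: str
    pairs: list[tuple[str, str]]  # ordered anchor gene pairs
    orientation: str = "same"     # or "inverted"
    block_id: int = 0

    @property
    def size(self) -> int:
        return len(self.pairs)

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.pairs:
            out.update((a, b))
        return out


def classify_duplicates(ranks: pd.DataFrame, hits, blocks=None,
                        proximal_max_gap: int = 19) -> pd.DataFrame:
    """One duplication class per ranked gene.

    ``hits`` is an iterable of unordered gene-id pairs (self-hits are
    ignored); ``blocks`` a list of :class:`CollinearBlock` whose anchor
    genes outrank everything else.
    """
    info = {r.gene_id: (r.chromosome, r.rank)
            for r in ranks.itertuples(index=False)}
    partners: dict[str, set[str]] = {g: set() for g in info}
    for a, b in hits:
        if a == b:
            continue
        for g in (a, b):
            if g not in info:
                raise ValueError(f"hit references unranked gene {g!r}")
        partners[a].add(b)
        partners[b].add(a)
    anchors: set[str] = set()
    for blk in blocks or []:
        anchors.update(blk.genes)

    rows = []
    for gene in info:
        chrom, rank = info[gene]
        label = "singleton"
        if partners[gene]:
            label = "dispersed"
            for other in partners[gene]:
                ochrom, orank = info[other]
                if ochrom != chrom:
                    continue
                gap = abs(rank - orank)
                if gap == 1:
                    label = _max_label(label, "tandem")
                elif 2 <= gap <= proximal_max_gap:
                    label = _max_label(label, "proximal")
        if gene in anchors:
            label = _max_label(label, "wgd_segmental")
        rows.append({"gene_id": gene, "class": label})
    return pd.DataFrame(rows, columns=["gene_id", "class"])


def pairs_to_matches(ranks: pd.DataFrame, pairs) -> list[tuple]:
    """Rank-anchored match list for collinearity, one per unordered pair.

    Canonical orientation: chromosome A <= chromosome B (rank A < rank B
    for same-chromosome pairs), so chaining is orientation-stable.
    """
    info = {r.gene_id: (r.chromosome, r.rank)
            for r in ranks.itertuples(index=False)}
    matches = []
    for a, b in sorted(tuple(sorted(p)) for p in pairs):
        ca, ra = info[a]
        cb, rb = info[b]
        if (cb, rb) < (ca, ra):
            a, b, ca, ra, cb, rb = b, a, cb, rb, ca, ra
        matches.append((a, ca, ra, b, cb, rb))
    return matches


def _max_label(a: str, b: str) -> str:
    return a if _PRIO[a] >= _PRIO[b] else b


def find_collinear_blocks(matches, min_block_size: int = 5,
                          max_rank_gap: int = 25) -> list[CollinearBlock]:
    """Chain rank-anchored matches into collinear blocks.

    ``matches``: iterable of ``(gene_a, chrom_a, rank_a, gene_b, chrom_b,
    rank_b)``.  Within each chromosome pair, chains must be strictly
    monotone on both sides (increasing or decreasing on the B side) with
    per-step rank gaps <= ``max_rank_gap`` on each side.  Maximal
    non-overlapping chains of size >= ``min_block_size`` are reported
    greedily by descending size; each match is used at most once.
    """
    by_pair: dict[tuple[str, str], list[tuple]] = {}
    for m in matches:
        ga, ca, ra, gb, cb, rb = m
        by_pair.setdefault((ca, cb), []).append(
            (int(ra), int(rb), ga, gb))

    blocks: list[CollinearBlock] = []
    for (ca, cb) in sorted(by_pair):
        remaining = sorted(by_pair[(ca, cb)])
        while True:
            chain, orient = _longest_chain(remaining, max_rank_gap)
            if len(chain) < min_block_size:
                break
            blocks.append(CollinearBlock(
                chrom_a=ca, chrom_b=cb,
                pairs=[(m[2], m[3]) for m in chain],
                orientation=orient))
            used = set(chain)
            remaining = [m for m in remaining if m not in used]
    blocks.sort(key=lambda b: (-b.size, b.chrom_a, b.chrom_b,
                               b.pairs[0]))
    for i, blk in enumerate(blocks, start=1):
        blk.block_id = i
    return blocks


def _longest_chain(matches: list[tuple], max_rank_gap: int
                   ) -> tuple[list[tuple], str]:
    """Longest strictly monotone chain via O(n^2) DP, both orientations."""
    best: list[tuple] = []
    best_orient = "same"
    for sign, orient in ((1, "same"), (-1, "inverted")):
        order = sorted(matches, key=lambda m: (m[0], sign * m[1]))
        n = len(order)
        length = [1] * n
        prev = [-1] * n
        for i in range(n):
            ra_i, rb_i = order[i][0], order[i][1]
            for j in range(i):
                ra_j, rb_j = order[j][0], order[j][1]
                if (ra_j < ra_i and sign * rb_j < sign * rb_i
                        and ra_i - ra_j <= max_rank_gap
                        and abs(rb_i - rb_j) <= max_rank_gap
                        and length[j] + 1 > length[i]):
                    length[i] = length[j] + 1
                    prev[i] = j
        if n:
            end = max(range(n), key=lambda i: (length[i], -i))
            chain = []
            while end != -1:
                chain.append(order[end])
                end = prev[end]
            chain.reverse()
            if len(chain) > len(best):
                best, best_orient = chain, orient
    return best, best_orient


def dual_synteny(annot_a: GenomeAnnotation, annot_b: GenomeAnnotation,
                 hits: pd.DataFrame, kinase_ids: set[str],
                 min_block_size: int = 5, max_rank_gap: int = 25):
    """Inter-genome collinearity with a kinase-anchored block count.

    ``hits`` needs columns ``query`` (genome A gene) and ``subject``
    (genome B gene).  Returns ``(blocks, dotplot_table,
    n_kinase_blocks)`` where the dot-plot table lists each block's
    anchor coordinates.
    """
    import warnings

    if hits.empty:
        warnings.warn("empty hit table; no synteny computed", stacklevel=2)
        return [], pd.DataFrame(columns=[
            "block_id", "gene_a", "chrom_a", "start_a",
            "gene_b", "chrom_b", "start_b"]), 0

    ranks_a = gene_ranks(annot_a).set_index("gene_id")
    ranks_b = gene_ranks(annot_b).set_index("gene_id")
    matches = []
    for q, s in zip(hits["query"], hits["subject"]):
        if q not in ranks_a.index or s not in ranks_b.index:
            raise ValueError(f"hit references unknown gene {q!r}/{s!r}")
        ra, rb = ranks_a.loc[q], ranks_b.loc[s]
        matches.append((q, ra["chromosome"], ra["rank"],
                        s, rb["chromosome"], rb["rank"]))
    blocks = find_collinear_blocks(matches, min_block_size=min_block_size,
                                   max_rank_gap=max_rank_gap)
    rows = []
    for blk in blocks:
        for ga, gb in blk.pairs:
            rows.append({
                "block_id": blk.block_id,
                "gene_a": ga, "chrom_a": blk.chrom_a,
                "start_a": annot_a.genes[ga].start,
                "gene_b": gb, "chrom_b": blk.chrom_b,
                "start_b": annot_b.genes[gb].start,
            })
    dotplot = pd.DataFrame(rows, columns=[
        "block_id", "gene_a", "chrom_a", "start_a",
        "gene_b", "chrom_b", "start_b"])
    n_kin = sum(1 for blk in blocks if blk.genes & set(kinase_ids))
    return blocks, dotplot, n_kin
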