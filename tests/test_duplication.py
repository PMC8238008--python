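"""Gene ranks, the duplicate classifier and collinearity chaining."""

import numpy as np
import pandas as pd
import pytest

from helpers import (classify_bruteforce, is_valid_chain,
                     longest_chain_bruteforce)
from kinomics import duplication as dup
from kinomics.annotation import Gene, GenomeAnnotation, Transcript
from kinomics.simulate import SimConfig, gen_genome, gen_genome_pair


def _toy_annotation(genes):
    """genes: list of (gene_id, chrom, start)."""
    ann = GenomeAnnotation(chrom_lengths={c: 10**6
                                          for _, c, _ in genes})
    for gid, chrom, start in genes:
        tx = Transcript(gid + ".1", gid, chrom, "+",
                        exons=[(start, start + 500)],
                        cds=[(start, start + 300)])
        ann.add_gene(Gene(gid, chrom, start, start + 500, "+", [tx]))
    return ann


def _ranks_df(entries):
    """entries: list of (gene_id, chrom, rank)."""
    return pd.DataFrame([{"gene_id": g, "chromosome": c, "rank": r,
                          "start": r * 1000, "end": r * 1000 + 500}
                         for g, c, r in entries])


class TestGeneRanks:
    def test_rank_follows_start_coordinate(self):
        ann = _toy_annotation([("g1", "chr1", 100), ("g2", "chr1", 500),
                               ("g3", "chr1", 900)])
        ranks = dup.gene_ranks(ann)
        assert list(ranks["rank"]) == [1, 2, 3]

    def test_chromosomes_are_independent(self):
        ann = _toy_annotation([("a", "chr1", 100), ("b", "chr2", 50),
                               ("c", "chr1", 900)])
        ranks = dup.gene_ranks(ann).set_index("gene_id")
        assert ranks.loc["a", "rank"] == 1
        assert ranks.loc["c", "rank"] == 2
        assert ranks.loc["b", "rank"] == 1

    def test_shuffled_insertion_order_same_ranks(self, rng):
        genes = [(f"g{i}", "chr1", int(s))
                 for i, s in enumerate(rng.choice(10**6, size=30,
                                                  replace=False))]
        r1 = dup.gene_ranks(_toy_annotation(genes))
        shuffled = list(genes)
        rng.shuffle(shuffled)
        r2 = dup.gene_ranks(_toy_annotation(shuffled))
        m1 = dict(zip(r1["gene_id"], r1["rank"]))
        m2 = dict(zip(r2["gene_id"], r2["rank"]))
        assert m1 == m2
        # sort-based oracle
        expected = {g: i + 1 for i, (g, _, _) in
                    enumerate(sorted(genes, key=lambda x: x[2]))}
        assert m1 == expected


class TestClassifier:
    def test_rank_gap_one_is_tandem(self):
        ranks = _ranks_df([("a", "c1", 7), ("b", "c1", 8)])
        calls = dup.classify_duplicates(ranks, {("a", "b")})
        assert set(calls["class"]) == {"tandem"}

    def test_rank_gap_six_is_proximal(self):
        ranks = _ranks_df([("a", "c1", 3), ("b", "c1", 9)])
        calls = dup.classify_duplicates(ranks, {("a", "b")})
        assert set(calls["class"]) == {"proximal"}

    def test_cross_chromosome_is_dispersed_and_no_hit_singleton(self):
        ranks = _ranks_df([("a", "c1", 1), ("b", "c2", 1),
                           ("c", "c1", 5)])
        calls = dup.classify_duplicates(ranks, {("a", "b")})
        m = dict(zip(calls["gene_id"], calls["class"]))
        assert m == {"a": "dispersed", "b": "dispersed", "c": "singleton"}

    def test_unranked_gene_in_hit_raises(self):
        ranks = _ranks_df([("a", "c1", 1)])
        with pytest.raises(ValueError, match="unranked"):
            dup.classify_duplicates(ranks, {("a", "zz")})

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_rule_oracle(self, seed):
        rng = np.random.default_rng(seed)
        genes = {}
        rows = []
        for c in ("c1", "c2"):
            for r in range(1, 21):
                gid = f"{c}g{r:02d}"
                genes[gid] = (c, r)
                rows.append((gid, c, r))
        ids = sorted(genes)
        pairs = set()
        while len(pairs) < 25:
            a, b = rng.choice(ids, size=2, replace=False)
            pairs.add(tuple(sorted((a, b))))
        # one planted block over c1 ranks 1-5 x c2 ranks 1-5
        block = dup.CollinearBlock(
            "c1", "c2",
            pairs=[(f"c1g{r:02d}", f"c2g{r:02d}") for r in range(1, 6)])
        calls = dup.classify_duplicates(_ranks_df(rows), pairs, [block])
        got = dict(zip(calls["gene_id"], calls["class"]))
        assert got == classify_bruteforce(genes, pairs, block.genes)

    def test_adding_a_hit_never_lowers_class(self, rng):
        rows = [(f"g{r}", "c1", r) for r in range(1, 15)]
        ranks = _ranks_df(rows)
        order = {c: i for i, c in enumerate(dup.CLASS_PRIORITY)}
        pairs = {("g1", "g9")}
        base = dict(zip(*dup.classify_duplicates(ranks, pairs)
                        [["gene_id", "class"]].T.values))
        for extra in [("g1", "g2"), ("g5", "g6"), ("g3", "g13")]:
            pairs.add(extra)
            now = dict(zip(*dup.classify_duplicates(ranks, pairs)
                           [["gene_id", "class"]].T.values))
            for g in base:
                assert order[now[g]] >= order[base[g]]
            base = now

    def test_tandem_calls_satisfy_gap_one_postcondition(self, bundle):
        ranks = dup.gene_ranks(bundle.annotation)
        pairs = dup.top_hits_per_gene(bundle.similarity)
        calls = dup.classify_duplicates(ranks, pairs)
        info = {r.gene_id: (r.chromosome, r.rank)
                for r in ranks.itertuples(index=False)}
        for g in calls.loc[calls["class"] == "tandem", "gene_id"]:
            ok = any(
                info[a if b == g else b][0] == info[g][0]
                and abs(info[a if b == g else b][1] - info[g][1]) == 1
                for a, b in pairs if g in (a, b))
            assert ok


class TestCollinearity:
    @staticmethod
    def _matches(points, ca="c1", cb="c2"):
        return [(f"a{ra}", ca, ra, f"b{rb}", cb, rb)
                for ra, rb in points]

    def test_five_pair_diagonal_is_one_block(self):
        blocks = dup.find_collinear_blocks(
            self._matches([(i, i) for i in range(1, 6)]))
        assert len(blocks) == 1 and blocks[0].size == 5

    def test_four_pairs_below_minimum(self):
        blocks = dup.find_collinear_blocks(
            self._matches([(i, i) for i in range(1, 5)]))
        assert blocks == []

    def test_inverted_orientation_detected(self):
        blocks = dup.find_collinear_blocks(
            self._matches([(i, 10 - i) for i in range(1, 7)]))
        assert len(blocks) == 1
        assert blocks[0].orientation == "inverted"

    def test_gap_bound_respected(self):
        pts = [(1, 1), (2, 2), (3, 3), (40, 4), (41, 5), (42, 6),
               (43, 7), (44, 8)]
        blocks = dup.find_collinear_blocks(self._matches(pts),
                                           max_rank_gap=25)
        assert len(blocks) == 1 and blocks[0].size == 5

    @pytest.mark.parametrize("seed", range(10))
    def test_random_matches_against_bruteforce_dp(self, seed):
        rng = np.random.default_rng(seed)
        pts = {(int(rng.integers(1, 40)), int(rng.integers(1, 40)))
               for _ in range(30)}
        matches = self._matches(sorted(pts))
        blocks = dup.find_collinear_blocks(matches, min_block_size=5,
                                           max_rank_gap=25)
        ranked = [(ra, rb) for ra, rb in sorted(pts)]
        # the first extracted block has the brute-force maximum length
        best = longest_chain_bruteforce(
            [(ra, rb) for ra, rb in ranked], 25)
        if best >= 5:
            assert blocks and blocks[0].size == best
        else:
            assert blocks == []
        # every reported block is a valid monotone chain, matches disjoint
        seen = set()
        for blk in blocks:
            pairs_ranked = [(int(a[1:]), int(b[1:]))
                            for a, b in blk.pairs]
            assert is_valid_chain(pairs_ranked, 25)
            assert not (set(blk.pairs) & seen)
            seen.update(blk.pairs)

    def test_planted_blocks_recovered_exactly(self):
        cfg = SimConfig(collinear_block_plan=[(0, 1, 6), (1, 2, 5)])
        b = gen_genome(cfg, seed=4)
        ranks = dup.gene_ranks(b.annotation)
        pairs = dup.top_hits_per_gene(b.similarity)
        blocks = dup.find_collinear_blocks(
            dup.pairs_to_matches(ranks, pairs))
        got = sorted(sorted(blk.pairs) for blk in blocks)
        want = sorted(sorted(chain) for chain in b.truth.true_blocks)
        assert got == want


class TestDualSynteny:
    def test_identical_genomes_one_block_per_chromosome(self):
        cfg = SimConfig(collinear_block_plan=[], duplication_plan=[])
        a = gen_genome(cfg, seed=6)
        b = gen_genome(cfg, seed=6)
        hits = pd.DataFrame({"query": sorted(a.annotation.genes),
                             "subject": sorted(b.annotation.genes)})
        blocks, dotplot, n_kin = dup.dual_synteny(
            a.annotation, b.annotation, hits, set())
        assert len(blocks) == cfg.n_chromosomes
        per_chrom = {blk.chrom_a: blk.size for blk in blocks}
        for chrom in a.annotation.chrom_lengths:
            assert per_chrom[chrom] == len(a.annotation.genes_on(chrom))
        assert n_kin == 0
        assert len(dotplot) == len(a.annotation.genes)

    def test_planted_inter_genome_blocks_and_kinase_count(self):
        cfg = SimConfig(collinear_block_plan=[], duplication_plan=[])
        a, b, hits, true_blocks = gen_genome_pair(
            cfg, cfg, [(0, 0, 6), (1, 2, 7)], seed=8)
        kinase_ids = set(a.truth.true_family)
        blocks, _, n_kin = dup.dual_synteny(
            a.annotation, b.annotation, hits, kinase_ids)
        got = sorted(sorted(blk.pairs) for blk in blocks)
        assert got == sorted(sorted(c) for c in true_blocks)
        expected_kin = sum(
            1 for chain in true_blocks
            if any(ga in kinase_ids for ga, _ in chain))
        assert n_kin == expected_kin

    def test_empty_hits_warns_and_returns_empty(self):
        cfg = SimConfig(collinear_block_plan=[], duplication_plan=[])
        a = gen_genome(cfg, seed=6)
        with pytest.warns(UserWarning, match="empty"):
            blocks, dotplot, n_kin = dup.dual_synteny(
                a.annotation, a.annotation,
                pd.DataFrame(columns=["query", "subject"]), set())
        assert blocks == [] and dotplot.empty and n_kin == 0
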