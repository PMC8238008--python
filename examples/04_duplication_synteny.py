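"""Classify gene-duplication origins and find collinear blocks.

Every gene gets exactly one class (priority WGD/segmental > tandem >
proximal > dispersed > singleton) from gene ranks and similarity hits;
collinear blocks are chains of >= 5 rank-monotone anchor pairs.
"""

from collections import Counter

from kinomics import duplication as dup
from kinomics.simulate import SimConfig, gen_genome, gen_genome_pair

bundle = gen_genome(SimConfig(), seed=1)
ranks = dup.gene_ranks(bundle.annotation)
pairs = dup.top_hits_per_gene(bundle.similarity)
blocks = dup.find_collinear_blocks(dup.pairs_to_matches(ranks, pairs))
calls = dup.classify_duplicates(ranks, pairs, blocks)

print("class counts:", dict(Counter(calls["class"])))
print("collinear blocks:", [(b.chrom_a, b.chrom_b, b.size)
                            for b in blocks])
truth = bundle.truth.true_duplication_class
agree = sum(1 for g, c in zip(calls["gene_id"], calls["class"])
            if truth[g] == c)
print(f"agreement with planted truth: {agree}/{len(truth)}")

# inter-genome synteny: two genomes with two planted collinear chains
cfg = SimConfig(collinear_block_plan=[], duplication_plan=[])
a, b, hits, true_blocks = gen_genome_pair(cfg, cfg, [(0, 0, 6), (1, 1, 5)],
                                          seed=2)
blocks_ab, dotplot, n_kin = dup.dual_synteny(
    a.annotation, b.annotation, hits, set(a.truth.true_family))
print(f"\ninter-genome blocks: {[blk.size for blk in blocks_ab]}, "
      f"{n_kin} contain a kinase locus")
print(dotplot.head(3).to_string(index=False))
# the dot-plot table (block, anchor coordinates in both genomes) is the
# input for a macrosynteny figure
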