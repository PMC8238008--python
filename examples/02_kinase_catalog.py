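"""Build a kinase catalog: domain mining, family assignment and
NJ-tree concordance.

Candidates need a hit covering >= 50% of a kinase Pfam model
(PF00069/PF07714/PF00481); families come from the best family-HMM hit
below e-value 1e-5; the assignment is kept (bona fide) only when the
protein groups with family peers in a neighbor-joining tree.
"""

from kinomics import catalog as cat
from kinomics import phylo
from kinomics.simulate import SimConfig, gen_genome

bundle = gen_genome(SimConfig(), seed=1)
hits = [cat.DomainHit(**r) for r in bundle.domain_hits.to_dict("records")]
fhits = [cat.DomainHit(**r) for r in bundle.family_hits.to_dict("records")]

counts = cat.identify_kinases(hits)          # candidate -> n domains
families = cat.assign_family(fhits)          # candidate -> family

genes = sorted(counts)
msa = {g: bundle.proteins[g + ".1"] for g in genes}
labels, D = phylo.p_distance_matrix(msa)
tree = phylo.bootstrap_support(msa, n_replicates=100, seed=1)
status = cat.concordance_filter(tree, {g: families[g] for g in genes})

catalog = cat.build_catalog(counts, families, status)
print(catalog.head(8).to_string(index=False))
n_bona = (catalog["status"] == "bona_fide").sum()
print(f"\n{len(catalog)} candidates, {n_bona} bona fide, "
      f"{len(catalog) - n_bona} UNK")
print("groups:", sorted(catalog['group'].unique()))
# bona fide means the HMM family assignment and the tree grouping agree;
# UNK marks proteins whose nearest tree neighbours belong to other
# families
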