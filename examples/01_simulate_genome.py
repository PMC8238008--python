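"""Generate a seeded synthetic genome with planted ground truth.

Builds a 3-chromosome genome with kinase families, planted duplication
classes, a collinear block and planted promoter motifs, then writes
GFF3/FASTA/TSV files plus truth tables an analysis can be scored
against.
"""

from collections import Counter
from pathlib import Path

from kinomics.simulate import SimConfig, gen_genome

outdir = Path("scratch/example_genome")
config = SimConfig()
bundle = gen_genome(config, seed=1)
bundle.write(outdir)

print(f"wrote {outdir}/: annotation.gff3, genome.fa, cds.fa, "
      "proteins.fa, hit tables, truth tables")
print(f"genes: {len(bundle.annotation.genes)} on "
      f"{config.n_chromosomes} chromosomes")
print(f"planted kinases: {len(bundle.truth.true_family)} in "
      f"{len(set(bundle.truth.true_family.values()))} families")
print("planted duplication classes:",
      dict(Counter(bundle.truth.true_duplication_class.values())))
# the class counts are the ground truth the duplication classifier must
# reproduce; the similarity table carries one hit per planted pair
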