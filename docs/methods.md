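# Methods

This note documents the models and procedures implemented in `kinomics`,
the parameters that matter, what the synthetic-data generator does and
does not emulate, and the numerical choices made where the design was
genuinely open.

## Kinase catalog and tree concordance

Candidate kinases are mined from a tabular profile-domain hit file (a
`domtblout`-like TSV); no HMM engine is run by the package — the table is
the contract. A protein qualifies when at least one hit to a kinase Pfam
model (PF00069 protein kinase, PF07714 tyrosine kinase, PF00481 PP2C-like
set) covers at least `min_model_coverage = 0.5` of the model, measured as
`(model_to − model_from + 1) / model_length` on 1-based inclusive model
coordinates; the qualifying-hit count is reported as the protein's
kinase-domain number. Family assignment takes the best family-HMM hit
with e-value strictly below `1e-5`; ties break by lower e-value, higher
bit score, then lexicographic model id, so re-running on permuted input
is bit-stable. The kinase *group* is the family prefix before the first
underscore (`RLK-Pelle_DLSV` → `RLK-Pelle`); families without an
underscore are their own group.

The tree step is classical distance phylogenetics: p-distances with
pairwise gap deletion (a pair with zero comparable columns is an error
naming the pair), Saitou–Nei neighbor joining on the Q-criterion, and
bootstrap support as the percentage of column-resampled replicate trees
containing the same bipartition (default 1,000 replicates; support is
undefined below 4 taxa). Two deterministic choices are part of the
contract: Q-matrix ties join the pair with the lexicographically smallest
cluster labels (a cluster is labelled by its smallest leaf), and negative
branch-length estimates are clamped to zero *before* any patristic
computation so nearest-leaf logic operates on metric-like distances.

"Grouped with their peers" is not a formal criterion, so the concordance
filter offers two operationalizations. The default (`nearest`): a protein
is bona fide iff at least one of its `neighbor_depth` (default 1) nearest
other leaves by patristic distance shares its family, ties broken
lexicographically; singleton families are bona fide by definition. The
alternative (`clade`): the smallest edge-side of the unrooted tree
containing the leaf plus at least one other leaf must hold ≥ 50%
same-family leaves among the others. Depth 1 is the strictest reading; it
also means that relabelling experiments can produce collateral UNK calls
(removing a protein's only nearby peer), which is why recovery tests that
require "exactly the k mislabelled proteins become UNK" evaluate at depth
2. Bootstrap support does not influence the bona fide decision.

## Gene structure and protein properties

Features are computed on the primary transcript — the mRNA with the
longest mature (spliced) length, ties to the lexicographically smallest
id. Coordinates are handled internally as 0-based half-open and read and
written as 1-based inclusive GFF3 (GFF3 I/O is built on `gffutils`).
"Transcript length" is the mature length (sum of exon lengths); the
genomic span (exons + introns) is emitted separately because annotations
disagree on which one "transcript length" means. Introns are the gaps
between sorted exons; UTRs come from `five_prime_UTR`/`three_prime_UTR`
records when present and are otherwise derived as exon-minus-CDS on the
strand-appropriate side. Overlapping exons and CDS outside exons are
hard errors. Family summaries are arithmetic means with member counts;
empty families are skipped with a warning.

Molecular weight is the sum of standard average residue masses plus one
water (18.0153 Da). The isoelectric point solves net charge(pH) = 0 for
a Henderson–Hasselbalch model with positive groups (N-terminus 9.69,
K 10.5, R 12.4, H 6.0) and negative groups (C-terminus 2.34, D 3.9,
E 4.1, C 8.3, Y 10.1) by bisection on (0, 14) to |charge| < 1e-4 in at
most 60 iterations — charge is strictly decreasing in pH, so the root is
unique and bracket-independent. The pKa table is a configuration
parameter: published tables differ by a few tenths of a pH unit and
online predictors rarely disclose theirs, so per-protein agreement with
any specific external tool is not an expected property.

## Duplication classes and collinearity

Gene ranks are 1-based positions among *all* annotated genes per
chromosome by ascending start (ties: end, then id). The classifier
applies the MCScanX rules: every gene starts as a singleton; any
similarity hit makes it dispersed; a same-chromosome partner at rank gap
2–`proximal_max_gap` (default 19, i.e. "< 20" with gap 1 reserved)
upgrades it to proximal; rank gap exactly 1 to tandem; anchoring in a
collinear block to WGD/segmental; the final class is the maximum in the
priority order WGD/segmental > tandem > proximal > dispersed >
singleton. Cross-chromosome hits can only yield dispersed — rank
differences across chromosomes are meaningless. Whole-genome and
segmental duplications are not distinguished. Before classification the
similarity table is reduced to each gene's top 5 non-self hits by bit
score (configurable); this mirrors standard collinearity practice and
keeps promiscuous hub genes from linking everything.

Collinear blocks are found per chromosome pair by O(n²) dynamic
programming over rank-anchored matches: chains must be strictly monotone
on both sides (same or inverted orientation) with per-step rank gaps
≤ `max_rank_gap` (default 25) on each side; maximal non-overlapping
chains of ≥ `min_block_size` (default 5, the "at least five genes"
floor) are extracted greedily by descending length with each match used
once. Chaining operates in rank space, not base pairs. Dual-genome
synteny computes ranks per genome, chains the inter-genome hits, and
reports a dot-plot table plus the number of blocks containing at least
one kinase locus.

## Ka/Ks

Codon alignments are built by back-translating a pairwise protein
alignment; columns gapped in either sequence, containing ambiguous
nucleotides, or encoding stops are dropped pairwise and counted
(pairwise deletion). Site counting follows NG86: per codon, the
synonymous-site count is the sum over the three positions of
(synonymous single-nucleotide changes)/3, with changes *to* stop codons
counted as nonsynonymous; S is averaged over the two sequences and
N = 3·codons − S. Differences are averaged with equal weights over all
minimal mutational pathways between the two codons, excluding pathways
through stop codons (weights renormalized; if every pathway is blocked,
all are kept with stop steps scored nonsynonymous). Both proportions are
corrected with Jukes–Cantor, d = −¾ ln(1 − 4p/3), which is undefined at
p ≥ 3/4 and signalled rather than returned as NaN. The ratio is Ka/Ks
(nonsynonymous in the numerator) and is undefined when Ks = 0 or a
correction is undefined; classification uses a 1e-9 neutrality tolerance
since exact equality is measure-zero in floating point.

## Promoters and motif enrichment

Promoters are the `length` (default 1,000) bp immediately 5' of the
annotated gene start — for minus-strand genes the 1,000 bp 3' of the
gene end, reverse-complemented — clipped at chromosome boundaries and
flagged when short. Anchoring at the gene start rather than a TSS keeps
the definition reproducible from annotation alone. PFMs are read and
written in JASPAR text format (parsing via `Bio.motifs`, with a
structural pre-pass so malformed rows fail with a line number),
converted to probabilities with pseudocount 0.5 and scored as log2-odds
against a uniform background. A window on either strand is an
occurrence when its score reaches `threshold_fraction = 0.8` of the
maximum attainable score — a common PWM operating point; there is no
analog of a motif-discovery e-value here because scanning supplied
matrices replaces de novo discovery. Family enrichment is the
hypergeometric upper tail of motif-containing promoters in the family
against the background, BH-corrected across motifs, enriched iff
p < 10⁻² and q < 10⁻².

## Expression statistics

The DE rule is strict at all three thresholds: up iff log2FC > 1 and
p < 0.05 and FDR < 0.05; down symmetrically (the inequality pair
"−1 > log2FC > 1" read as a disjunction — the literal conjunction is
empty). BH is the step-up estimator computed by sorted cumulative
minima, returned in input order and capped at 1. GO enrichment is the
same hypergeometric machinery over an annotation table; terms are tested
as given with no ontology-graph propagation, and terms with zero
foreground genes are skipped. Crosstalk is the intersection of
up-regulated transcript sets across assays, with pairwise intersections
reported alongside.

qPCR ratios follow the efficiency-corrected convention: ratio =
E_target^ΔCt(target) / geometric-mean over references of E_ref^ΔCt(ref),
ΔCt = mean control Ct − mean treated Ct, with percent efficiencies
converted as E = 1 + pct/100 (so 100% = 2.0). Significance comes from a
fixed-reallocation randomization test: the replicate (a column across
target and all reference genes jointly) is the permutation unit;
control/treated labels are reassigned, and the p-value is the fraction
of reallocations whose ratio is at least as fold-extreme relative to 1
as observed (extremeness max(r, 1/r)). Enumeration is exhaustive when
the number of label splits is ≤ `n_permutations` (C(6,3) = 20 for 3v3),
Monte Carlo otherwise. The exact reallocation scheme of published qPCR
randomization tools is not fully specified; this scheme is documented
here and oracle-tested by exhaustive enumeration, not claimed to match
any tool bit-for-bit. Note the two-sided p-value at 3v3 cannot go below
2/20 = 0.1.

## The synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions the test suite runs under. A default genome has 3 chromosomes
of 300 kb, 120 non-overlapping genes (strand uniform) with
intron/exon/UTR structure (1–5 exons, introns 60–300 bp, UTRs 60–220 bp,
CDS 100–260 codons), 31 kinase genes in 8 families whose sizes mirror a
kinome in miniature (one large receptor-like-kinase family, several
mid-sized families, one singleton), a duplication plan of 4 tandem + 3
proximal + 3 dispersed pairs, and one 6-pair collinear block. Fixed
seeds give byte-identical output files.

Planted geometry follows the classifier's semantics exactly: tandem
copies at adjacent ranks, proximal copies at same-chromosome gaps 2–6,
dispersed copies on different chromosomes, WGD/segmental copies inside
cross-chromosome chains of ≥ 5 pairs. The allocator *guarantees* the
planted truth is the unique correct answer by construction: at most one
block per chromosome pair, at most 4 tandem/proximal matches per
chromosome, at most 4 dispersed pairs per chromosome pair and none on
block pairs — otherwise unplanned rank-monotone chains of length ≥ 5
could form and legitimately reclassify planted genes; infeasible plans
raise with the violated constraint named.

Kinase family members derive from a per-family founder CDS at 5%
divergence; duplicate copies diverge from their source by ~2% of sites,
realized through the selection-aware evolver with a per-pair ω cycled
from `omega_plan` (default purifying-dominated: eight values below 1,
one at 1, one at 5), recorded in the truth tables. The evolver proposes
uniform single-nucleotide changes and accepts synonymous ones with
probability 1 and nonsynonymous ones with probability ω (for ω > 1 the
same rate ratio is realized by accepting nonsynonymous changes always
and synonymous ones with probability 1/ω); proposals creating or landing
on stop codons are rejected, and `n_events` counts accepted
substitutions. All kinase CDSs share one length (210 codons) so the
candidate protein set is trivially column-aligned — the pipeline treats
the MSA as an input, and this sidesteps running an aligner inside the
generator.

The expression layer plants per-family up-regulation (log2FC ~
Normal(mean, 0.5) truncated above 1, p and FDR drawn safely below the
thresholds), null transcripts at log2FC ~ Normal(0, 0.3) with uniform p
and BH-adjusted FDR, a crosstalk set forced up in every assay, one
GO term annotated at a 5× foreground rate (0.85 vs 0.17 — high absolute
rates because the planted foreground is only ~8 transcripts), and Ct
values as base − log_E(ratio) + Normal(0, 0.15) per replicate with two
unit-ratio reference genes. The planted promoter motif goes into 90% of
the target family's promoters and 5% of the background; with 10-bp
motifs and a 0.8 score threshold, random 1-kb promoters also yield ~6%
chance occurrences, which the enrichment background absorbs.

What the generator does **not** emulate: read-level RNA-seq,
transposable elements, indels (substitution-only divergence), alignment
uncertainty (kinase proteins are gap-free by construction), genuine
all-vs-all similarity noise (the hit table lists exactly the planted
homolog pairs, emulating pre-filtered top hits), and ontology structure
(GO terms are flat labels). Passing tests therefore demonstrate that
each engine implements its rule correctly and recovers planted signal
under clean-to-moderate noise; they do not demonstrate robustness to
misannotation, alignment error or hub-gene hit inflation in real
genomes.

## Problem sizes

The test suite and the acceptance script run at desk scale, chosen so
the full suite completes in well under a minute of compute per module:
120-gene genomes (≤ 20 seeds per property), 600-codon/60-event evolved
pairs (200 seeds per ω in the acceptance suite, 100 in the script),
100 random trees of ≤ 12 taxa for NJ consistency, bootstrap tests at
50–200 replicates (the 1,000-replicate default is for real analyses),
exhaustive hypergeometric checks at N ≤ 60, and 500-run qPCR null
calibrations at 5v5 replicates (252 exhaustive reallocations, fine
enough for a Kolmogorov–Smirnov uniformity check, where the 3v3 grid of
20 would be too coarse).

## Known limitations

- NJ is O(n³) in pure numpy/Python; comfortable to a few hundred taxa,
  not thousands.
- The concordance rule is an interpretation (two variants provided); no
  bootstrap-support gating is applied.
- NG86 here is the unweighted variant (no transition/transversion
  weighting) with equal pathway weights.
- PWM scanning has no background-model calibration beyond the fractional
  score threshold; motif discovery is out of scope.
- The qPCR randomization scheme treats replicates as exchangeable
  columns across genes; unpaired designs with unequal replicate counts
  are permuted within the pooled labels only.
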