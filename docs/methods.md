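# Methods

`islekit` reimplements, as one tested pipeline, the comparative-genomics
chain used to characterize horizontally transferred genomic islands in
bacterial genomes: multi-locus supermatrix phylogenetics over single-copy
orthologs, island boundary delineation from tRNA-anchored direct repeats,
flanking-synteny verification against non-carrier relatives, anchor-based
core-gene expansion, mobility classification, and an island-vs-backbone
SNP divergence contrast that distinguishes recent independent acquisition
from vertical inheritance. Because the corresponding real datasets require
external downloads and tool stacks whose parameters are not fully
reproducible, every stage is validated against a forward genome-evolution
simulator that plants islands with known coordinates and transfer
histories.

## Simulator

**Species tree.** A Yule (pure-birth) process starting from two lineages:
with *k* lineages the next speciation waits Exp(*k*), a uniformly chosen
lineage splits, and a final Exp(*n*) waiting time separates the last split
from the present. Branch lengths are rescaled so every root-to-tip path
equals the requested depth (in expected substitutions per site) exactly.
We sample the waiting time after the last split explicitly so that
pendant branches are never zero — without it the two most recently
diverged strains would be identical, which is not a realistic study
condition.

**Sequences.** Substitutions only, Jukes–Cantor: each branch of length
*b* draws Poisson(*b·L*) events; each event picks a uniform site and
jumps to one of the other three bases uniformly. This reproduces the JC
closed form — expected observed difference `p = (3/4)(1 − e^(−4d/3))` at
path distance *d* — including multiple hits, and conserves sequence
length, so planted differences can be scored base-for-base against
called SNPs. Indels, rearrangements, within-backbone recombination and
realistic codon usage are deliberately out of scope; passing tests
therefore say nothing about indel- or rearrangement-robustness on real
drafts.

**Ancestral genome.** One contig; CDS are built as ATG + random non-stop
codons + stop on both strands; tRNAs (76 bp) are interleaved among the
genes; intergenic slack is split multinomially. Whole-genome GC is
calibrated to the configured fraction (stop-codon rejection biases it by
well under half a percent at GC 0.5).

**Island integration.** The island cassette (anchor genes `pcrA` and
`cld`, a `xerD`-like recombinase for the tRNA-integrative kind,
conjugation/replication genes for the ICE kind, terminal IS copies for
the composite-transposon kind, plus accessory filler genes) is inserted
immediately 3′ of a target tRNA, and the tRNA's terminal 48 bp are
duplicated at the island's distal end. This leaves an intact tRNA
flanked by two identical direct repeats — the single supported
integration geometry — and defines the island interval as *end of
proximal repeat copy → end of distal copy*, so the tRNA itself stays
outside the island.

**Transfer scenarios.** In the `recent` scenario each carrier's island
copy descends from a single donor sequence and accrues only a residual
divergence (default 5 × 10⁻⁵ substitutions/site per carrier, i.e.
~0.01 % between two carriers) while backbones diverge normally (default
tree depth 0.01 → ~2 % between strains on opposite sides of the root;
the observed JC difference at path 0.02 is 1.97 %). In the `vertical`
scenario the island evolves along the same tree as the backbone, so
island and backbone divergence match. These defaults mirror the
contrast this class of analysis is designed to detect: a ~200-fold
depletion of island SNPs (~3–6 SNPs over a 30-kb island) against a ~2 %
divergent backbone.

**Pseudogenization.** Gene inactivation by exactly one base change:
`start_loss` makes the first codon a non-start (not ATG/GTG/TTG);
`nonsense` turns an internal codon into a stop. Both edits are recorded
in the truth bundle.

**Truth bundle.** Newick tree, per-branch realized event counts, island
coordinates (BED + GFF3 `mobile_genetic_element` features), transfer
event log, pseudogene list, and per-leaf difference maps against the
root (backbone) and the donor island. Planted per-pair SNPs are
reconstructed by composing these maps — including the target-site
duplication copy, whose bases track each genome's own tRNA suffix — so
exactness tests do not depend on re-aligning anything.

## Orthology

All-vs-all Smith–Waterman local alignment (BLOSUM62; affine gaps, open
11 / extend 1 applied as −11 for the first gap position and −1 per
additional position), a shared-5-mer prefilter to skip obviously
unrelated pairs (disabled by setting `min_shared_kmers=0`), reciprocal
best hits with a conservative tie rule (a query with two equal best
subjects is excluded), clusters as connected components of the pooled
RBH graph, and the supermatrix locus filter: clusters with exactly one
member in every genome. Hit thresholds default to score ≥ 50 and
coverage ≥ 0.5 of the shorter sequence (aligned residue pairs / shorter
length); identity is matches / traceback columns with gaps counting as
columns. Proteomes translate annotated CDS full-length with internal
stops as `X` (alphabet: 20 amino acids + X), so pseudogenes remain
alignable; truncation at the first stop is available as an option.
A greedy longest-first identity clusterer (default threshold 0.90) is
provided for redundancy reduction in single-gene phylogeny workflows;
the main pipeline does not call it.

## Alignment, trimming, trees

The progressive aligner orders profile–profile global alignments
(BLOSUM62 column scores weighted by residue frequencies; gap columns
contribute zero; affine penalties on newly introduced gap columns) by a
UPGMA guide tree over shared 3-mer distances. Residues are never
altered, only gap columns inserted; for two sequences the procedure is
exactly pairwise Needleman–Wunsch.

Conserved-block trimming uses a relaxed, fully specified rule set
(chosen to favour retention of informative sites): a column is
*conserved* when its most frequent residue reaches just over half the
taxa and its gap fraction is ≤ 0.5, *highly conserved* at ≥ 0.85; runs
of more than 8 consecutive non-conserved columns are removed and break
blocks; surviving blocks shorter than 5 columns are kept only with
highly conserved flanking columns. Trimming is applied per locus, and
all parameters are config-exposed.

Distances are Poisson-corrected protein distances `d = −ln(1 − p)` with
*p* the mismatch fraction over shared ungapped columns; pairs at
*p* ≥ 0.95 are flagged saturated and capped. Trees come from neighbor
joining — the package's deliberate substitution for maximum-likelihood
search: the claims this pipeline makes (clade membership, support
values, topology recovery at the simulated depths) are testable at desk
scale with NJ, while the relaxed-PHYLIP supermatrix and RAxML-style
partition file keep external ML refinement open. NJ ties on the Q
criterion resolve to the smallest (row, col) index pair, so permuting
taxa relabels but never rewires the tree; negative branch lengths are
clamped to zero with the deficit moved to the sister edge, preserving
the joined pair's path length. Branch support is the rounded percentage
of column-bootstrap replicate NJ trees containing each bipartition;
zero-divergence data yields supports of 0 (nothing is resolvable).

## Island delineation

Direct repeats are found by exact 16-mer seeding with maximal greedy
extension (Hamming mismatches up to a configurable budget, 0 by
default), reporting maximal pairs with length ≥ 40 bp and inner
separation within [5 kb, 200 kb] — the ceiling comfortably exceeds the
largest island this geometry is expected to span (~145 kb) while
bounding search cost. Pairs contained in longer pairs are suppressed.
A repeat pair with a copy overlapping a tRNA becomes an island call;
when several pairs share a tRNA the longest span wins and the rest are
kept as alternates. Flanking synteny maps the m=5 genes on each side of
the island through the ortholog clusters into a non-carrier relative
and asks whether the two mapped blocks are adjacent up to a 1-gene
tolerance (orientation-agnostic). Core/accessory partition walks
outward from the `pcrA`/`cld` anchor clusters, admitting genes whose
cluster occurs in ≥ 2 islands and stopping a direction after 3
consecutive island-specific genes. Mobility classification is
keyword-based over product annotations (token-prefix matching;
configurable marker lists), with priority tRNA-integrative > ICE >
composite transposon and all evidence reported; "near-identical"
flanking IS copies default to ≥ 500 bp at ≥ 95 % identity — a declared
default, since no quantitative threshold is standard. Profile-HMM
marker search and read-level IS verification are out of scope. Islands
at contig ends are reported with partial evidence rather than
suppressed.

## SNP divergence and the acquisition contrast

Whole-genome comparison chains maximal exact matches that are unique in
both sequences (≥ 20 bp) by a maximum-weight colinear-subsequence DP
(weight = anchor length; uniqueness avoids repeat-induced chimeric
chains — the repeats themselves are the island module's business).
Inter-anchor gaps close by direct column pairing when ref and query gap
lengths are equal (always true under the substitution-only simulator)
and by unit-cost global alignment (edlib) when both gaps are ≤ 5 kb;
anything larger is flagged unaligned. SNPs are mismatched aligned
columns with unambiguous bases; indel and N columns are skipped.

Frequencies divide SNP counts by **aligned** reference bp by default —
draft comparisons leave unaligned holes, and using raw lengths would
deflate rates — with the raw-length denominator available and both
reported. The backbone excludes the island interval. The contrast is a
one-sided exact binomial tail `P(X ≤ k₁), X ~ Binomial(n₁, k₂/n₂)`
(depletion is the signal of interest; a two-sided variant is a flag),
classified as `recent_independent` when p < 0.01 and the
island/backbone frequency ratio < 0.1, `ancestral_vertical` when the
ratio lies in [0.5, 2], else `indeterminate`. The thresholds are
declared defaults motivated by the ~200-fold contrast the recent
scenario produces, and they are config-exposed; with several regions
tested in one run a Bonferroni correction across regions applies.
Codon-level effects (synonymous / nonsynonymous with `X<pos>Y` strings /
nonsense / start-loss) are annotated strand-aware under the standard
code; a CDS whose length is not divisible by 3 is reported unclassified.

## Pipeline, determinism, problem sizes

Stages exchange plain standard-format files (FASTA, GFF3, BED6, minimal
VCF, bedGraph, relaxed PHYLIP, Newick, TSV/JSON), so any stage can be
run standalone or swapped for an external tool. The YAML config is
schema-validated with unknown keys rejected; a single mandatory seed
feeds hash-derived per-stage seeds, and fixed config + seed reproduces
byte-identical outputs (the manifest records per-file SHA-256 checksums
and lets completed stages be skipped on resume).

Validation batteries run at stated problem sizes chosen to keep the
whole suite at desk scale while preserving the island:genome ratio and
the divergence structure: island recovery at the default 200 kb backbone
/ 30 kb island (20 carriers); the classification and SNP-exactness
replicate batteries at 60 kb / 9 kb with divergences unchanged
(backbone ~2 %, recent island ~0.01 %); tree recovery on 10 taxa × 60
loci at depth 0.05. The locus count for tree recovery is sized to the
resolution floor of the condition itself: a Yule tree on 10 taxa will
occasionally contain an internal branch of ~1e-4 expected
substitutions/site, and such a branch must span enough aligned coding
sequence (~54 kb here) to realize more than a handful of substitutions
before *any* distance method can place it; seeds whose shortest branch
realizes ≲2 substitutions remain irreducibly ambiguous. At these sizes expected island SNP counts in the
recent scenario (~1–3) sit near the real data's regime (~3–6), so the
contrast test is exercised in the same low-count corner.

## Known limitations

- No indel or rearrangement simulation; the aligner's unaligned-interval
  handling is exercised only by island presence/absence.
- NJ is not ML; deep or rate-heterogeneous phylogenies may need the
  exported supermatrix refined externally.
- Mobility classes rest on annotation keywords, not profile models.
- The binomial contrast treats sites as independent; linked substitution
  processes would need a different null.
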