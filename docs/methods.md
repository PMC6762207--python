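# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `riderscout`. It is written for users who need to know exactly
what the package computes, what its synthetic benchmarks do and do not show,
and where design decisions were genuinely open.

## Structural detection of full-length elements

### Model

A full-length LTR retrotransposon is modelled as two direct repeats (the
LTRs) of 100–5,000 bp whose start positions lie 4,000–30,000 bp apart,
flanked by a 3–20-bp target-site duplication created at integration,
beginning with `TG` and ending with `CA` (at most one mismatch summed over
both termini), and carrying a primer-binding site complementary to the
3′-terminal bases of a host tRNA within 10 bp of the 5′ LTR's inner edge.
These thresholds are the package defaults (`DetectorParams`) and are all
configurable; they correspond to the parameterisation commonly used for
consistent cross-genome annotation of *Copia*/*Gypsy* elements.

### Repeat-pair search

The repeat search is seed-and-extend. Exact 20-mers occurring at two
positions with LTR-like spacing seed diagonals; seeds on one diagonal within
one maximal LTR length of each other are chained, extended outward with
ungapped x-drop scoring (match +2, mismatch −2; extension stops when the
running score falls more than `xdrop = 7` below its maximum), and trimmed to
the maximal-scoring sub-alignment (Kadane). Pairs are kept when both copies
have an allowed length, their start-to-start distance is in range and their
ungapped identity reaches `min_pair_identity = 0.80`. Overlapping extensions
from different diagonals are merged, keeping the best-scoring candidate per
locus.

The 20-mer seed length is chosen so that a 100-bp LTR pair at the 80 %
identity floor still contains an exact shared 20-mer with probability above
0.98; the ±2/−3 score set makes the expected per-column score positive down
to 67 % identity, so x-drop termination is driven by the repeat boundary,
not by within-repeat divergence. The start-to-start reading of the
4–30 kb distance constraint follows the convention of structural annotators
(configurable to element-span).

### Boundary refinement: TSD and terminal motif jointly

The x-drop alignment locates LTR edges only to within a few bases, so
boundaries are refined by the TSD search: all exact duplications of length
3–20 between the 80-bp vicinity window spanning the 5′ boundary and the one
spanning the 3′ boundary are enumerated; each defines an adjusted element
whose duplication copies immediately flank it. Candidates are ranked by

  score = duplication length − 0.5 × (total boundary adjustment, bp),

preferring candidates whose adjusted termini preserve `TG…CA` within the
motif-mismatch budget; ties go to the longer duplication, then the smaller
adjustment, then the leftmost. The adjustment penalty matters: two 80-bp
windows of background sequence are expected to share more than one chance
≥5-bp substring, so an unpenalised longest-duplication rule misplaces
boundaries on a third of planted elements. Penalising each moved base by
0.5 encodes that a boundary shift contradicts the repeat alignment's
evidence; with it, recovery on planted genomes is exact to within the TSD
length. When no motif-consistent duplication exists the search falls back to
the unconstrained rule, and an element with no flanking duplication at all
keeps its alignment boundaries and an empty TSD.

### PBS, ORFs, quality and overlaps

The PBS screen locally aligns (match +1, mismatch −1, gap −2) the reverse
complement of each tRNA's 3′-terminal 40 nt against the 60 bp inside the
element following the 5′ LTR, keeping the best hit with alignment length
8–40, offset ≤ 10 and identity ≥ 0.8 (ties: higher identity, lower offset,
tRNA id). ORFs are counted by a 6-frame ATG-to-stop scan at ≥ 300 nt — only
a count is needed because the default ORF requirement is zero. The quality
predicate is TSD present ∧ terminal motif ∧ PBS present; this concretises a
boolean "quality filter" switch whose exact definition is not fixed by
convention, and is documented here as a package decision. Externally
produced protein-domain hits (gag/pol Pfam scans) are annotated when a table
is supplied but never required; profile-HMM scanning is out of scope.
Overlap resolution (mode `no`) greedily keeps, within any set of mutually
overlapping calls, the element with the highest LTR identity (ties: longer,
then leftmost). Both strands are scanned — the repeat-pair signature is
strand-symmetric, so plus/minus calls at one locus are merged preferring the
orientation whose PBS/motif evidence passes the quality filter.

## Family clustering and identity

Global identity uses a Needleman–Wunsch alignment with match +2, mismatch
−2, gap open −10, gap extend −1. Terminal gaps are *scored* in the dynamic
programme but *excluded* from the identity denominator: identity = matches /
alignment columns excluding terminal-gap columns. Scoring the terminal gaps
is deliberate — with fully free end gaps the optimal alignment of two
unrelated sequences collapses to a short high-identity overlap, which at an
85 % threshold would merge unrelated sequences into one cluster; excluding
the terminal columns from the denominator still keeps length overhangs from
diluting the identity of homologous cores.

Clustering is greedy and centroid-based in the `cluster_fast` style:
sequences in order of decreasing length (input order on ties), each query
joining the first centroid at ≥ 85 % identity on either strand, else
founding a new cluster. Family assignment against a reference element uses
the same identity, strictly greater than the threshold.

## Insertion dating

After insertion the two LTRs of one element accumulate substitutions
independently, so their pairwise divergence *d* grows at twice the
per-lineage rate: *t* = *d* / (2 *r*) with *r* = 6.96 × 10⁻⁹
substitutions · site⁻¹ · year⁻¹ (tomato average). Divergence is the
p-distance 1 − identity by default; a Jukes–Cantor multiple-hit correction
is available (`correction="jc"`) but p-distance is the default because the
age-class boundaries are defined on raw identity (0.02 / 2*r* ≈ 1.4 My at
the 98 % boundary) and within-family divergences are small enough that
multiple hits are second-order. Age classes partition [0.85, 1]:
98–100 %, 95–98 %, 85–95 %; identity below 0.85 (outside the family
definition) is unclassified.

## Phylogeny

TN93 distances are computed from the two transition proportions (A↔G, C↔T),
the transversion proportion, and base frequencies averaged over both
sequences, with gap/ambiguous columns dropped pairwise; a non-positive
logarithm argument (saturation) returns infinity and such pairs are excluded
from tree building. Neighbour joining is the classic Saitou–Nei
agglomeration with ties in the Q-matrix broken by the lexicographically
smallest label pair; negative branch lengths are clamped to zero with the
deficit moved to the sibling branch, preserving the pair's path length.
Branch lengths are written at 6 decimals, so the additive round-trip
(patristic distances of the output tree equal the input matrix) is exact to
1e-9 only for matrices representable on that grid; for arbitrary matrices
the formatting contributes up to ~1e-6 per path. Patristic distances are
read back through dendropy.

## Motif enrichment

Motifs are IUPAC strings scanned exactly, overlaps allowed, coordinates
1-based inclusive; minus-strand scanning is available but the default is
forward-only because promoter logic is directional. Enrichment builds a 2×2
table per motif of per-sequence presence/absence (an occurrence-count mode
exists behind a flag; presence is the default because "count data" per
sequence is the less assumption-laden reading) in foreground LTRs versus a
background, and applies the two-sided Fisher exact test (minimum-likelihood
summation). The odds ratio is the sample odds ratio with a 0.5 Haldane
correction when any cell is zero. Two backgrounds are provided: 400-bp
gene-promoter windows upstream of each TSS (minus-strand genes reverse
complemented; edge-truncated windows below 50 bp skipped), and random loci
sampled uniformly over all valid genome-wide start positions with the strand
vector copied from the annotated elements. Random loci with more than 10 %
N are resampled (up to 1000 attempts) so gap runs do not enter the
background. Random loci are *not* excluded from overlapping annotated
elements; with realistic family copy numbers the contamination is a fraction
of a percent of the background and biases enrichment conservatively.

The shipped catalogue takes the two MYB-core variants (`CTGTTG`, `CTGTTA`)
verbatim from the documented element structure; the CGCG box (`VCGCGB`),
ABRE-like, CE3 and CBF consensi are PLACE-style defaults chosen by this
package and marked as such in the catalogue file.

## Homolog screening

BLAST tabular (outfmt-6) hits are parsed with range validation;
`sstart > send` encodes the minus strand. The family-like filter keeps hits
with percent identity ≥ 50 and alignment length ≥ 50 % of the query length —
the reading of "50 % coverage (= homology)" as percent identity is a
documented interpretation, and the alternative (query-coverage) is one
configuration change. Coverage profiles count, per query position, the hits
spanning it (clipped to the query); LTR-query hits are classed long
(350–450 bp) or short (150–300 bp) by alignment length after the homology
filter. Reciprocal confirmation checks whether any of the top-5 (by
bitscore) reverse hits of a subject region overlaps a known family locus by
≥ 1 bp. E-value statistics are not reproduced; a naive local-alignment
scanner is included for self-contained fixtures only.

## Per-locus quantification

Methylation per context (CG/CHG/CHH) is the weighted level
100 × Σ meth / Σ covered over cytosines inside the locus at or above the
coverage floor — weighted rather than a mean of per-site levels because it is
robust at low coverage; a context with no qualifying cytosine is missing,
never zero. siRNA RPKM divides reads of a size class overlapping the locus
by ≥ 1 bp by locus length (kb) and library size (millions); the 21–22-nt
class is the union of lengths 21 and 22. Compartments are assigned by
element midpoint (elements may straddle boundaries); gene proximity is
boundary-to-boundary distance ≤ 2 kb, strand-ignorant, overlap counting as
zero. Summary percentages are rounded half-up to one decimal.
Pericentromere/arm boundaries are consumed as user-supplied labelled
intervals, never derived. In-silico PCR requires a plus-strand forward-primer
site and a downstream minus-strand reverse-primer site within the product
cap, with the mismatch budget applied per primer and no indels (the
per-primer reading is the natural parameterisation of "k mismatches
allowed"; a shared-budget mode is behind a flag).

## Synthetic data: what it emulates and what it does not

The generator plants, on an i.i.d. background at tomato-like GC (0.35),
intact elements (LTR + PBS + ORF-bearing internal region + polypurine tract
+ LTR), solo LTRs and 5′-truncated copies, with TSDs duplicated on both
flanks and strands drawn uniformly. Each LTR copy is independently
point-mutated at rate d/2 so expected pair identity is 1 − d; mutations are
substitutions only by default (realized identity then has a clean binomial
model and is recomputed by direct alignment, never taken from the nominal
rate); an indel mode exists for robustness tests. Planted features are kept
≥ 300 bp apart so vicinity windows never touch a neighbouring feature, and
each element's sequence is drawn independently, so solo LTRs cannot pair
with a neighbouring element's LTR — detector specificity claims therefore
concern chance background structure, not unresolved family homology.
Default study conditions: 200-kb genome, 12 intact + 3 solo + 2 truncated,
400-bp LTRs, 5-kb internal regions, TSDs of 4–6 bp, PBS of 18 nt at offset
2 against a fixed synthetic initiator-tRNA.

What passing tests show: the detector recovers planted structure at the
default thresholds, boundaries are exact to within the TSD, strand calls are
symmetric, and every downstream statistic matches its independent oracle.
What they do not show: behaviour on nested/fragmented repeat landscapes,
real tRNA repertoires, sequencing error, or assemblies with collapsed
repeats — the background is deliberately repeat-free to keep false-positive
analysis interpretable.

The 4,867-bp "stand-in reference" element used by the acceptance script is
synthetic: it reproduces the documented element architecture (MYB cores at
LTR positions 176 and 204, CGCG box at 89, canonical TSD/PBS) but is not a
database sequence; it is rejected-and-redrawn so the planted motif
occurrences are the first in the LTR, and it is embedded between N-run
flanks so boundary refinement sees only the real TSD.

## Problem sizes

The test suite and acceptance script run at desk scale by design:
parameter-recovery uses 25 seeded ~120-kb genomes with 6 intact elements
each; the exact-test oracle enumerates every 2×2 table up to total 40; the
type-I control runs 200 replicates of 100 foreground / 300 background 300-bp
sequences with a motif planted at an identical 40 % rate in both groups
(group sizes chosen so the discrete Fisher test's attained size, ≈ 0.045, is
close to nominal); trees use 4–9 taxa. These sizes exercise every code path
while keeping the default run reproducible in minutes on one CPU.

## Known limitations

- No nested-element dissection, TRIM/LARD models, or chromatin-aware
  detection.
- The repeat-pair extension is ungapped; heavily indel-diverged LTR pairs
  will be trimmed or split (the synthetic indel mode quantifies this).
- Geneious-style cost-matrix pairwise alignment is approximated by the NW
  aligner + TN93 distances, not replicated bit-for-bit.
- BLAST E-values and the 110-genome download orchestration are out of
  scope; real hit tables are consumed, not produced.
- Bisulfite/sRNA read processing is upstream of this package; it consumes
  per-cytosine and per-read summary tables.
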