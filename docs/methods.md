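# Methods

## Scope and model

plastokit analyses annotated chloroplast genomes (plastomes): circular
molecules of ~120-170 kb organised as a large single-copy region (LSC), a
small single-copy region (SSC) and two exact reverse-complementary inverted
repeats (IRa/IRb). The package computes the comparative statistics used to
characterise a newly assembled plastome against a congeneric reference:
quadripartite structure metrics, gene inventories, codon usage, perfect
microsatellites, transition/transversion spectra, and per-feature
nucleotide diversity for marker discovery. Annotation is consumed, never
inferred.

## Coordinate model

All coordinates are 0-based half-open; GenBank's 1-based inclusive
convention exists only at the file boundary. Feature parts are stored in
transcription order with per-part strands, so splicing is a concatenation
of strand-resolved parts and a trans-spliced gene (exons at distant loci,
possibly on both strands) needs no special casing. Rotating a circular
record splits any part that would straddle the new origin; such split parts
inflate the structural intron count of that one copy, which is why
analyses are run on the canonical rotation where genes were annotated away
from the origin.

## Inverted-repeat detection

Detection is exact-match only: 25-mer anchors between the genome and its
reverse complement are extended base-by-base across the circular sequence;
the longest pair of disjoint, exactly reverse-complementary intervals at or
above `min_ir_len` (default 10,000 bp, CLI-tunable) is the IR pair. Exact
matching is a deliberate restriction — in the genomes this package targets
the two IRs are identical copies — and gives determinism plus a simple
exhaustive oracle (diagonal scan of the sequence against its reverse
complement) for testing. Mismatched or nested IRs are out of scope. The
longer single-copy gap is LSC; in the (never-observed) tie the gap with the
smaller start coordinate is taken. `canonical_rotation` puts the first LSC
base at position 0 (order LSC-IRb-SSC-IRa); it is a pure rotation by
default, and with `normalize_orientation=True` it also canonicalises the
strand by returning the lexicographically smaller of the two rotated
orientations, making the result invariant to strand flips.

## GC content

GC is (G+C)/(A+C+G+T) with N excluded from both sides; the IR value is
computed on one copy (the copies are exact reverse complements, so the
value is shared). Gene-class values concatenate the spliced sequences of
unique genes, one copy per duplicated gene. Empty classes report NA, never
zero. Reports round to one decimal as percentages.

## Gene inventory and splicing calls

Unique genes are distinct gene symbols (case-sensitive; `trnfM-CAU` and
`trnM-CAU` are distinct). A gene is "duplicated in IR" only when full
copies lie entirely within IRa and IRb respectively; junction-overlapping
genes stay single-copy. Functional categories come from a packaged static
classification of the standard land-plant plastid gene complement; unknown
symbols are reported as unclassified with a warning. Trans-splicing is
called structurally — exons in different quadripartite regions, on both
strands, or non-colinear — rather than by gene name, so the call
generalises beyond rps12. Intron count is parts-1 per gene copy.

## Codon usage

The bacterial/plastid genetic code (translation table 11) is used. RSCU is
count over the mean of the synonymous family; empty families give NA, and
the three stop codons form their own family reported under `*`. Duplicated
IR genes are counted once by default (`--both-copies` reverses this); the
trans-spliced gene is included by default. CDS lengths not divisible by
three are truncated to whole codons with a log note, and internal stops are
counted, never raised: annotation slippage should degrade gracefully.

## Microsatellites

`find_ssrs` reports all maximal perfect tandem repeats of 1-6 bp units at
MISA-style thresholds (10/5/4/3/3/3 minimum repeats by unit length). A
locus is reported at the smallest period of its unit only; N breaks every
run. Motif classes are the lexicographically smallest rotation over the
unit and its reverse complement ("A/T", "AT/AT", ...). Compound-SSR merging
is intentionally absent. Circularity is handled by scanning an appended
overlap window and de-duplicating loci whose circular footprint is
contained in a longer one. The scanner is validated against an exhaustive
(start, period, length) brute-force oracle.

## Pairwise divergence

Regions are aligned globally with affine gaps (match +2, mismatch -3, gap
open 10, extend 0.5 — tuned for >95%-identity congeneric sequences, all
CLI-exposed). Inputs above 20 kb are split by a co-linear chain of shared
unique 31-mers (longest increasing subsequence) and only inter-anchor
stretches are aligned; an inconsistent chain raises rather than silently
misaligning a rearrangement. Substitution spectra count columns with two
distinct A/C/G/T bases as unordered pairs; gap or N columns are excluded;
Ts = A/G + C/T. The IR spectrum is computed on one IR copy to avoid
double-counting the duplicated sequence, whose two copies are not
independent observations. Ts/Tv is NA when no transversions exist.

## Nucleotide diversity

For two sequences Nei's pi reduces to S/L: substitution columns over
gap-free columns. No multiple-hit correction is applied — at congeneric
divergence the statistics should remain the directly observable alignment
quantities, and the reported columns satisfy exact arithmetic identities
(pi = S/L; gap-free + gap columns = alignment length; missing % =
100·gap/alignment). "Indels" means gap-containing columns, not indel
events. Each genome's spacers are taken from its own annotation and matched
by flanking-gene name; unmatched features are logged and skipped. Category
summaries report both the unweighted mean of per-feature pi and the pooled
value (total S over total L), which answer different questions; both are
always printed. Reports round pi to 5 decimals and missing % to 1 decimal.

## Synthetic genomes

The generator emulates the statistical structure the analyses assume, with
defaults matching the study conditions of a ~152 kb Asteraceae plastome
pair: LSC/SSC/IR of 83,911/18,248/25,027 bp, single-copy AT fraction 0.65
with a +0.08 GC uplift in the IRs, a mononucleotide-dominated A/T-rich
planted SSR set (24 mono, 4 di, 2 tri, 1 tetra, 0 penta, 1 hexa), and a
mutated partner with 429/169/20 substitutions in LSC/SSC/IR at Ts/Tv odds
1.1 plus a few 1-30 bp indels. Gene content is 24 CDS / 12 tRNA / 4 rRNA
(plus one trans-spliced CDS): enough to exercise every inventory code path
while leaving room for the placement rules below; real plastomes are far
denser, and no analysis stage depends on absolute gene counts.

Construction guarantees that make recovery tests exact rather than
statistical:

- IRa is built as the reverse complement of IRb, and every IR mutation is
  applied symmetrically to both copies, so the IRs stay byte-exact.
- The four junction-adjacent bases are pinned so no chance complementary
  base extends the detected IR beyond the planted coordinates, and
  mutation avoids those bases.
- Planted SSR flanks are fixed so each locus is maximal at exactly the
  planted repeat number, and an iterative purge breaks every detectable
  repeat that was not deliberately planted (edited symmetrically inside
  IRs, away from planted loci and CDS start/stop codons).
- Substitutions avoid planted SSRs; indels go into gene-free single-copy
  stretches at least 10 bp from any substitution, so alignment recovers
  substitution counts exactly.
- Coding sequences are whole ORFs (ATG ... stop) sampled from a
  leucine-rich, cysteine-poor amino-acid distribution with a 3:1 preference
  for A/T third positions, reproducing the A/T-ending codon bias
  (RSCU > 1) real plastomes show.

What the generator does not emulate: IR boundary shifts between the two
genomes, rearrangements, imperfect/compound repeats, pseudogenes,
annotation disagreement between genomes, and sequencing artefacts. Passing
recovery tests therefore demonstrates correctness of the measurement code
under the stated model, not robustness to annotation noise in real
records.

## Numerical and degenerate-input conventions

Undefined values (empty GC class, zero-transversion Ts/Tv, zero-length
diversity denominator, empty RSCU family) are NA, never 0. Ranking ties
break by more substitutions, then name. All randomness flows from a single
integer seed through `numpy.random.default_rng`; identical parameters and
seed give byte-identical genomes and TSVs.

## Problem sizes

The test suite runs most unit tests on a compact ~26 kb genome with the
same structure, and the end-to-end checks on full-size ~152 kb pairs: 50
simulated genomes for partition recovery, 20 random sequences (2-10 kb)
for the SSR oracle, 500 planted substitutions for spectrum recovery. The
acceptance script re-runs the same checks at 20 genomes / 10 oracle
sequences.
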