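# Methods

This note documents the models, numerical choices, and limitations behind
each stage of the pipeline. Coordinates are 0-based half-open everywhere in
memory; the single conversion to 1-based inclusive happens at GFF3 output.

## Profile model and glocal scoring

The monomer model is a position-specific scoring matrix built from a seed
alignment of monomer copies. Columns whose gap fraction exceeds
`gap_col_threshold` (default 0.5) are treated as insert columns and
dropped; the remaining L columns become match positions. Emission scores
are log-odds in bits:

    e[i, b] = log2( (count[i, b] + c) / (n_rows + 4c) / q[b] )

with pseudocount c = 1, background q uniform (0.25 each) so scores are
genome-independent, and N residues contributing 1/4 count to each base.
The consensus is the per-column emission argmax; its self-score (the sum of
per-column maxima) is the natural score ceiling.

Sequences are scored by an affine-gap Viterbi-style dynamic program that is
global over the profile and local over the sequence: a monomer may start
and end anywhere in a genomic window, but all L match positions must be
accounted for (matched or deleted). Defaults: gap open −8 bits, gap extend
−1 bit. Tie-breaks are fixed (match > delete > insert; leftmost endpoint)
so tracebacks are deterministic. N in the target scores the column's mean
emission. A full profile HMM (forward algorithm, Dirichlet priors) is
deliberately out of scope: best-path scores with fixed tie-breaks are
reproducible and sufficient for monomer location, and the empirical null
(1000 random background sequences) sits far below half the self-score,
which is the relevant margin for the scan threshold.

## Genome scanning

Candidate windows are seeded by exact 12-mer matches against the consensus
(both strands, step 1); positions voting for a common monomer start
(diagonal clustering, >= 3 seeds) define candidates, which are then scored
with the glocal aligner against a window padded by 80 bp. Hits scoring at
least 40% of the consensus self-score are kept — a threshold that admits
the ~25–28% divergence observed between satellite subfamilies while
excluding random background by a wide margin. Overlaps (> 50% reciprocal)
are resolved greedily by descending score, ties to the leftmost start then
the + strand.

Seeding can miss a copy that still clears the score threshold when its
mutations are dense enough to destroy nearly all exact 12-mers. A rescue
pass therefore re-scores monomer-sized gaps (>= 0.85 L) between
consecutive hits directly, iterating to a fixpoint. Copies below the score
threshold itself are reported missing; on the default scenario these are
the deepest birth-chain copies (~27% diverged), and recall is 0.98–1.0.

## Blocks, filtering, naming, arms

Tandem blocks group consecutive same-chromosome hits separated by at most
`max_gap` = 600 bp (one monomer plus slack; note a single missed interior
copy does not split a block, since 528 < 600). The cleaning filter runs in
fixed order: (1) first and last element of every block (a 1-unit block
loses its unit, a 2-unit block both); (2) units with length <= 500 bp
(strict > 500 retention); (3) units containing N. The report's four
removal tallies are disjoint by construction and sum to raw − retained.

Centromeres are located from the centromeric satellite monomers: 12-mer
seeded candidate windows are verified by edlib alignment at identity >=
0.8, hits merged within 100 kb, and the largest cluster (by summed hit
length) wins, labeled with its repeat family. Units wholly before the
interval are S, wholly after are L, overlapping are C; without a located
centromere the S/L split falls at the chromosome midpoint with a warning.
The 5' side of each sequence is called the short arm by convention —
without karyotype input the assembly orientation is the only anchor.
Names are `<prefix><chrom><arm>k#####` with per-chromosome ordinals 10,
20, 30, … 5'→3'.

## Implied MSA

Each retained unit is mapped onto the L match positions via its glocal
traceback: deletions become gaps, insertions relative to the profile are
discarded. This gives a deterministic O(n) alignment whose columns are
comparable across all units — the appropriate regime for thousands of
near-full-length monomers, where a gap-averse progressive aligner would
converge to the same positional alignment at far greater cost. Units with
fewer than 50% of columns aligned are excluded with a warning.

## Recombination screen

For a child and two parents, aligned columns where the parents differ and
the child matches exactly one of them are informative. At each candidate
breakpoint the 2x2 table (left/right x matches-A/matches-B) is scored by
chi-square with Yates continuity correction; the maximizing breakpoint is
reported with p from chi2(1 df). Margins are enforced in
informative-column space: candidate breakpoints must leave at least
`min_margin` = 20 informative columns on each side. This is the standard
polymorphic-site formulation; margins in raw alignment columns admit edge
tables with two or three informative entries on one side, which are the
statistic's classic false-positive mode (we observed a chi-square of 40 at
an edge breakpoint in a recombination-free family before adopting it).

Screening every unit against all parent pairs is O(n^3); instead each
child is tested against pairs drawn from four candidates: its two nearest
neighbors by p-distance — skipping neighbors within 2% of the child, since
a near-identical copy is the child's sibling and cannot act as a parent —
and two far candidates, the furthest neighbor plus a maximin choice
(maximizing the minimum distance to both the child and the first far
candidate) so that when two divergent source lineages exist both are
represented. All C(4,2) = 6 pairs are tested per child; a seeded random
subsample applies above `n_triplets_cap`. Bonferroni correction uses the
number of triplets actually tested; calls with corrected p <= 0.001 mark
the child for removal. Note the raw p of a maximized statistic is
anti-conservative in principle; with informative-column margins, the
continuity correction and Bonferroni, the realized false-call rate was 0
in 40 recombination-free 50-unit replicates, while 5/5 planted mid-monomer
mosaics between 15%-divergent lineages are detected.

## Distances, tree, supports, clades

p-distances use pairwise deletion (sites gapped or ambiguous in either row
are excluded for that pair). The Jukes–Cantor correction
d = −(3/4)·ln(1 − 4p/3) is capped at d = 5.0 substitutions/site for
p >= 0.75 (saturation). Neighbor joining is the canonical Q-criterion
algorithm with ties broken toward the smallest index pair, negative branch
estimates clamped to zero, and the final three taxa joined by the
three-point formulas; on tree-additive matrices it provably recovers the
generating topology, which the test suite checks against an exhaustive
least-squares search over all (2n−5)!! topologies for n <= 8. Supports are
the fraction of 100 column-bootstrap NJ replicates containing each
bipartition of the main tree (canonicalized as the smaller leaf set).

Major clades are extracted greedily from the midpoint-rooted tree: a node
founds a clade when its support strictly exceeds 0.75 (honoring a ">75%"
reading of the threshold) and it holds at least max(2, 2% of leaves)
tips; its subtree is not descended further, so major clades are disjoint.
One subtlety: with a bifurcating root, both root children correspond to
the same edge, so the complement of a well-supported clade would inherit
its support while being paraphyletic; root children are therefore treated
as unsupported containers and always descended. The practical consequence
is that a very large lineage adjacent to the root is reported as several
pure subclades rather than one clade — clade labels (A, B, … by
decreasing size) are descriptive, not identifiable lineage estimates.

## Concordance

The clade-by-location table (locations like `04S`, `10L`, with centromeric
units aggregated per chromosome as e.g. `08C`) yields: arms-per-clade,
clades-per-arm, and dominance (largest single-arm fraction of a clade's
units). "Spread" clades occupy >= 2 arms; "locally duplicated" clades have
dominance >= 0.8. Both thresholds are package conventions quantifying
qualitative claims, and both are configurable. The exchange report lists
clades containing both C and S/L units and whether all centromeric units
fall in a single clade. No formal association test is performed — counts
only.

## Assembly QC

Contigs are placed by chaining k-mers (k = 31) unique in both contig and
genome, banded at 2 kb to absorb small indels; the longest chain fixes the
target interval and orientation, extended to the contig's implied extent.
Edit-free substrings are recovered to the base. Unit pairing is greedy
one-to-one by descending edlib identity (NW, normalized by the longer
sequence) above 0.95; locally-unmatched contig units are searched against
all genome units, and hits at identity >= 1.0 lying on another chromosome
(or > 1 Mb away on the same one) are flagged as misassembly candidates.
Full-unit identity is used throughout. At identity 1.0 the flag has zero
false positives whenever every genuine copy carries at least one
substitution — the regime the simulator's per-copy mutation rate
guarantees with high probability.

## Simulator

The generator emulates the dynamics the analysis is meant to detect.
Per chromosome (default 3 x 2 Mb, i.i.d. uniform background): a
centromeric satellite array (150-bp monomer, 400 copies, 1% per-copy
divergence) in the middle tenth; satellite blocks in the distal 300 kb of
each arm (a desk-scaled stand-in for the ~5 Mb subtelomeric zone of a
~50 Mb chromosome). Eight founder lineages diverge 8% from a common
ancestral monomer (528 bp) and are homed round-robin on arms. Each arm
draws Poisson(6.5) blocks — matching the ~40 blocks / ~300 units scale of
the default scenario — of geometric size (mean 8, truncated at 55, per the
2–55 copy range typical of such arrays). A block grows as a birth chain:
each new copy mutates (mu = 0.03 substitutions/site) from a uniformly
chosen existing member, so blocks carry internal phylogenetic structure
and their deepest copies can be ~25% diverged. With probability tau the
block's founder comes from another chromosome's lineage (interchromosomal
transfer); with probability rho a copy is a two-parent mosaic (breakpoint
uniform in the middle 60%); with probability kappa a block relocates into
the centromeric array — but only when its lineage keeps at least one arm
block on that chromosome, because an exchange needs a subtelomeric source
(this also makes "every centromeric clade has subtelomeric relatives" a
structural property of the truth, not a lucky draw). Centromeric blocks
overwrite the array's interior with compact 0.7–1.5 kb separations so
they remain distinct blocks (> max_gap) inside the satellite-defined
centromere interval. Mutations are substitutions only by default; a small
indel rate exercises gap handling when enabled. Truth tables record every
unit (coordinates, strand, genome-slice sequence, lineage, block,
recombinant parents), block, and centromere interval; the emitted FASTA
slice equals the recorded sequence exactly, and everything is
bit-reproducible for a fixed seed.

What the simulator does not emulate: transposable-element background,
unequal crossing-over, telomeric repeats, higher-order repeat structure,
sequencing/assembly error (QC scenarios edit annotations deliberately
instead). Passing tests therefore demonstrate correct recovery of this
generative model, not performance on a real 600-Mb assembly, where the
scan threshold and block-gap parameters would need the same kind of
empirical tuning any satellite census requires.

## Problem sizes and determinism

The default scenario (seed 42) is 3 chromosomes x 2 Mb with ~220 planted
units — chosen so the full pipeline (scan through bootstrap tree) runs in
well under a minute and multi-replicate experiments (20 paired seeds for
the transfer contrast, 20 recombination-free replicates for type-I) stay
desk-scale. The transfer contrast is computed on simulator truth lineages
through the concordance module (lineage = clade), which isolates the
claim — transfer raises arms-per-clade — from tree-estimation noise. All
stage randomness (bootstrap resampling, triplet subsampling, simulation)
flows from one root seed split per stage; pipeline runs with the same
config and seed produce identical output checksums, which the test suite
asserts.
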