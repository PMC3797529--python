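# satscan

Genome-wide annotation and evolutionary analysis of subtelomeric satellite
DNA, built around the kind of ~528-bp tandem repeat that accumulates in
discrete head-to-tail blocks at plant chromosome ends.

Subtelomeres are among the fastest-evolving regions of eukaryotic genomes.
A satellite family that lives there poses three linked questions that this
package answers computationally:

1. **Where are the monomers?** Every copy of the repeat is mined from an
   assembly with a position-specific scoring profile (log-odds emissions
   over the monomer's match positions, affine-gap glocal alignment: global
   over the profile, local over the sequence), on both strands, then
   cleaned: the first and last element of every tandem block are dropped
   (boundary copies are often truncated), as are units ≤ 500 bp or
   containing N. Units are named `<prefix><chrom><arm>k<ordinal>` — e.g.
   `Pv01Sk00010` is the first unit on chromosome 01's short arm — with
   ordinals in increments of 10 along the chromosome, and S/C/L arm codes
   derived from centromere intervals located via the centromeric satellite
   families (CentPv1/CentPv2-style).
2. **How do the copies relate?** Retained units are anchored to the
   profile columns (an *implied MSA* — no progressive alignment needed for
   thousands of near-identical monomers), screened for recombinant mosaics
   by triplet maximum chi-square scanning (breakpoint-wise 2x2 contrast of
   parental matches, Bonferroni-corrected, alpha = 0.001), and placed on a
   neighbor-joining tree under Jukes–Cantor distances,
   d = −(3/4)·ln(1 − 4p/3), with support from 100 column-bootstrap
   replicates.
3. **What does the geography say about the dynamics?** Cross-tabulating
   major clades (support > 0.75) against chromosome-arm locations
   quantifies the two expansion modes — clades spanning many arms witness
   interchromosomal exchange between non-homologous subtelomeres; clades
   dominated by one arm witness local tandem duplication — and flags
   clades mixing centromeric with arm units (centromere–subtelomere
   exchange). A contig-vs-assembly QC stage places an independently
   sequenced contig by unique 31-mer anchor chaining and reports units
   missing from the assembly and 100%-identity cross-location twins
   (misassembly candidates).

Because real assemblies of this size are not shipped with the package, a
first-class simulator (`satscan.synthetic_genome`) plants satellite arrays
under an explicit model — lineages homed on arms, blocks grown by birth-
chain copying with per-copy mutation rate mu, interchromosomal transfer
rate tau, recombinant rate rho, centromeric placement rate kappa — and
emits the ground truth every stage is tested against.

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic scenario (3 chromosomes x 2 Mb, seed 42):

```bash
python analysis/01_simulate_genome.py     # genome + truth under results/data/
python analysis/02_annotate_units.py      # profile, scan, filter, count matrix
python analysis/03_phylogeny_recombination.py
python analysis/04_concordance.py
python analysis/05_assembly_qc.py
```

`01` plants 221 units in 33 blocks. `02` then reports:

```
profile: 528 positions, self-score 933 bits, scan threshold 373
218 raw hits in 33 blocks; removed 60 terminal, 0 short, 0 with N; 158 retained
recovery vs truth: recall 0.986, precision 1.000, boundary MAE 0.00 bp

                short_arm  centromere  long_arm  total
chr01                   2           0         5      7
chr02                  14           0       109    123
chr03                   3           0        25     28
Total                  19           0       139    158
```

i.e. the scanner recovers the planted arrays essentially exactly (the three
missed copies are the most mutation-saturated ones, below the 40%-of-self-
score threshold), and the retained count equals the terminal-filter
arithmetic sum(max(block size − 2, 0)). `03` removes 0 recombinants (none
were planted), builds the bootstrap NJ tree, and extracts 14 major clades,
every one confined to a single chromosome arm — exactly what a
transfer-free (tau = 0) history should look like; `04` prints the
clade-by-arm table showing 0 spread clades and 14 locally-duplicated
clades, and an empty centromere-exchange report. `05` places a 149-kb
synthetic BAC to the base, reports the 3 deleted units as a local gap, and
flags their verbatim copies at another chromosome's centromere at identity
1.000 — the satellite misassembly signature.

The same stages are exposed as a CLI (`satscan simulate | scan | regions |
recomb | phylo | concord | qc | run`) for use on real FASTA/GFF3 inputs.

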