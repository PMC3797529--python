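"""Simulate the study genome: 3 x 2 Mb chromosomes with planted satellite
arrays, a centromeric satellite per chromosome, and full ground truth.

Writes the genome FASTA, the truth annotation (GFF3 with lineage labels),
the centromeric monomer, and a seed alignment for profile construction
under results/data/.
"""

import dataclasses
import json
import sys
from pathlib import Path

from satscan.io_core import GenomeSequence, write_fasta, write_gff3
from satscan.synthetic_genome import SimParams, make_seed_alignment, simulate

OUT = Path("results/data")


def main(seed: int = 42) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    params = SimParams(seed=seed)
    genome, truth = simulate(params)

    write_fasta(genome, OUT / "genome.fasta")
    write_gff3(truth.to_gff3_records(), OUT / "truth_units.gff3")
    write_fasta([GenomeSequence("CentSim1", truth.cent_monomer)],
                OUT / "cent_repeats.fasta")
    seed_aln = make_seed_alignment(truth.monomer, n_rows=20, divergence=0.03,
                                   seed=1)
    with open(OUT / "seed_alignment.fasta", "w") as fh:
        for name, row in seed_aln:
            fh.write(f">{name}\n{row}\n")
    with open(OUT / "sim_params.json", "w") as fh:
        json.dump(dataclasses.asdict(params), fh, indent=2)

    per_arm = truth.per_arm_counts()
    per_arm.to_csv(OUT / "truth_per_arm_counts.tsv", sep="\t", index=False)
    print(f"simulated {params.n_chrom} chromosomes x {params.chrom_length:,} bp")
    print(f"planted {len(truth.units)} units in {len(truth.blocks)} blocks "
          f"({truth.blocks['size'].max()} units in the largest)")
    print(per_arm.to_string(index=False))


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 42)
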