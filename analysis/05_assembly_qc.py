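"""Assembly QC against a synthetic independently-sequenced contig.

Cuts a BAC-sized contig out of the simulated genome and edits the
"assembly"-side unit annotation: three interior units are deleted from the
local window and planted verbatim at another chromosome's centromere,
mimicking the classic satellite misassembly mode (collapsed local array,
relocated copies).  The QC stage must place the contig to the base, report
the deleted units as a local gap, and flag the relocated copies at 100%
identity.
"""

from pathlib import Path

import pandas as pd

from satscan.assembly_qc import qc_report
from satscan.io_core import AnnotationRecord, GenomeSequence, read_fasta
from satscan.synthetic_genome import SimParams, simulate
import json

DATA = Path("results/data")
OUT = Path("results")


def main() -> None:
    params = SimParams(**json.load(open(DATA / "sim_params.json")))
    genome, truth = simulate(params)

    # use the chromosome whose short arm is densest in planted units
    counts = truth.units[truth.units.end < 150_000].groupby("chrom").size()
    donor = {g.id: g for g in genome}[counts.idxmax()]
    window = truth.units[
        (truth.units.chrom == donor.id) & (truth.units.end < 150_000)
    ].sort_values("start")
    contig = GenomeSequence("bacA", donor.residues[1_000:150_000])

    contig_units, contig_seqs = [], {}
    for i, (_, r) in enumerate(window.iterrows()):
        name = f"PvA{donor.id[-2:]}Ak{(i + 1) * 10:05d}"
        contig_units.append(
            AnnotationRecord("bacA", r["start"] - 1_000, r["end"] - 1_000,
                             r["strand"], "satellite_unit", 0.0, {"Name": name})
        )
        contig_seqs[name] = r["sequence"]

    # assembly-side annotation: three interior units vanish locally and
    # reappear verbatim at another chromosome's centromere
    genome_units, genome_seqs = [], {}
    dropped = set(window.index[3:6])
    for i, (idx, r) in enumerate(window.iterrows()):
        if idx in dropped:
            continue
        name = f"Pv{donor.id[-2:]}Sk{(i + 1) * 10:05d}"
        genome_units.append(
            AnnotationRecord(donor.id, r["start"], r["end"], r["strand"],
                             "satellite_unit", 0.0, {"Name": name})
        )
        genome_seqs[name] = r["sequence"]
    target = next(g.id for g in genome if g.id != donor.id)
    for j, (_, r) in enumerate(window.iloc[3:6].iterrows()):
        name = f"Pv{target[-2:]}Ck{(j + 1) * 10:05d}"
        genome_units.append(
            AnnotationRecord(target, 950_000 + j * 600, 950_000 + j * 600 + 528,
                             r["strand"], "satellite_unit", 0.0, {"Name": name})
        )
        genome_seqs[name] = r["sequence"]

    rep = qc_report(contig, genome, contig_units, genome_units,
                    contig_seqs, genome_seqs)
    p = rep.placement
    print(f"contig {p.contig_id} placed on {p.seq_id}:{p.start}-{p.end} "
          f"({p.orientation}), {p.n_anchors} anchors")
    print(f"{rep.n_paired} units paired, {rep.n_contig_only} contig-only "
          f"(missing from assembly), {rep.n_genome_only} genome-only")
    for s, e in rep.gap_spans:
        print(f"  missing span on contig: {s}-{e} ({e - s} bp)")
    print(f"{len(rep.cross_location_hits)} cross-location flags "
          f"(misassembly candidates):")
    for c, g, ident in rep.cross_location_hits:
        print(f"  {c} == {g} at identity {ident:.3f}")

    pd.DataFrame(
        [{"contig_unit": q.contig_unit, "genome_unit": q.genome_unit,
          "identity": q.identity} for q in rep.pairings]
    ).to_csv(OUT / "qc_pairings.tsv", sep="\t", index=False)
    pd.DataFrame(
        rep.cross_location_hits,
        columns=["contig_unit", "genome_unit", "identity"],
    ).to_csv(OUT / "qc_cross_location.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
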