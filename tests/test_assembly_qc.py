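import numpy as np
import pytest

from satscan.assembly_qc import (
    PlacementError,
    flag_cross_location,
    pair_units,
    place_contig,
    qc_report,
)
from satscan.io_core import AnnotationRecord, GenomeSequence
from satscan.profile_model import reverse_complement
from satscan.synthetic_genome import SimParams, simulate


@pytest.fixture(scope="module")
def sim():
    params = SimParams(
        n_chrom=2, chrom_length=400_000, subtelomere_span=80_000,
        cent_copies=100, blocks_per_arm_mean=3.0, seed=11,
    )
    return simulate(params)


class TestPlaceContig:
    def test_exact_substring_placed_to_the_base(self, sim):
        genome, _ = sim
        contig = GenomeSequence("bac1", genome[0].residues[30_000:130_000])
        p = place_contig(contig, genome)
        assert (p.seq_id, p.start, p.end, p.orientation) == (
            "chr01", 30_000, 130_000, "+")
        assert not p.length_flagged

    def test_reverse_complement_substring(self, sim):
        genome, _ = sim
        contig = GenomeSequence(
            "bac2", reverse_complement(genome[1].residues[50_000:150_000])
        )
        p = place_contig(contig, genome)
        assert (p.seq_id, p.start, p.end, p.orientation) == (
            "chr02", 50_000, 150_000, "-")

    def test_unplaceable_contig_raises(self, sim):
        genome, _ = sim
        rng = np.random.default_rng(0)
        junk = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 5_000)])
        with pytest.raises(PlacementError):
            place_contig(GenomeSequence("bacX", junk), genome)

    def test_contig_with_insertion_spans_flanks(self, sim):
        genome, _ = sim
        g = genome[0].residues
        rng = np.random.default_rng(1)
        insert = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 10_000)])
        contig = GenomeSequence(
            "bac3", g[30_000:80_000] + insert + g[80_000:130_000]
        )
        p = place_contig(contig, genome)
        assert p.seq_id == "chr01"
        assert p.start <= 30_100 and p.end >= 129_900


def _rec(seq_id, start, end, name):
    return AnnotationRecord(seq_id, start, end, "+", "satellite_unit", 1.0,
                            {"Name": name})


class TestPairUnits:
    def test_identical_sets_all_paired(self):
        cu = [_rec("bac", 0, 528, "b1"), _rec("bac", 600, 1128, "b2")]
        gu = [_rec("chr01", 100, 628, "g1"), _rec("chr01", 700, 1228, "g2")]
        seqs_c = {"b1": "ACGT" * 132, "b2": "TTGC" * 132}
        seqs_g = {"g1": "ACGT" * 132, "g2": "TTGC" * 132}
        pairs = pair_units(cu, gu, seqs_c, seqs_g)
        matched = {(p.contig_unit, p.genome_unit) for p in pairs if p.genome_unit}
        assert matched == {("b1", "g1"), ("b2", "g2")}
        assert all(p.identity == 1.0 for p in pairs if p.genome_unit)

    def test_swap_symmetry_of_counts(self):
        cu = [_rec("bac", 0, 528, "b1"), _rec("bac", 600, 1128, "b2")]
        gu = [_rec("chr01", 100, 628, "g1")]
        seqs_c = {"b1": "ACGT" * 132, "b2": "GGGG" * 132}
        seqs_g = {"g1": "ACGT" * 132}
        fwd = pair_units(cu, gu, seqs_c, seqs_g)
        rev = pair_units(gu, cu, seqs_g, seqs_c)
        fwd_only = sum(1 for p in fwd if p.contig_unit and p.genome_unit is None)
        rev_only = sum(1 for p in rev if not p.contig_unit)
        assert fwd_only == rev_only == 1


class TestCrossLocationFlags:
    def test_relocated_block_flagged_without_false_positives(self, sim):
        """Units copied verbatim to a distant locus are all flagged; units
        that differ by even one substitution are not."""
        genome, truth = sim
        g1 = genome[0]
        # take three planted units from chr01 and relocate them to chr02
        donors = truth.units[truth.units.chrom == "chr01"].head(3)
        relocated_seqs = list(donors["sequence"])
        contig_units = [
            _rec("bac", i * 600, i * 600 + 528, f"b{i}") for i in range(3)
        ]
        contig_seqs = {f"b{i}": s for i, s in enumerate(relocated_seqs)}
        genome_units = [
            _rec("chr02", 300_000 + i * 600, 300_000 + i * 600 + 528, f"g{i}")
            for i in range(3)
        ] + [_rec("chr02", 350_000, 350_528, "gmut")]
        genome_seqs = {f"g{i}": s for i, s in enumerate(relocated_seqs)}
        mutated = "T" + relocated_seqs[0][1:] if relocated_seqs[0][0] != "T" \
            else "A" + relocated_seqs[0][1:]
        genome_seqs["gmut"] = mutated
        placement = place_contig(
            GenomeSequence("bac", g1.residues[10_000:120_000]), genome
        )
        hits = flag_cross_location(
            contig_units, genome_units, contig_seqs, genome_seqs, placement,
            identity_exact=1.0,
        )
        flagged_pairs = {(c, g) for c, g, _ in hits}
        assert flagged_pairs == {(f"b{i}", f"g{i}") for i in range(3)}

    def test_no_unmatched_units_no_flags(self, sim):
        genome, _ = sim
        placement = place_contig(
            GenomeSequence("bac", genome[0].residues[10_000:120_000]), genome
        )
        assert flag_cross_location([], [], {}, {}, placement) == []


class TestQcReport:
    def test_missing_units_reported_as_gap(self, sim):
        genome, truth = sim
        g = genome[0]
        window = truth.units[
            (truth.units.chrom == "chr01") & (truth.units.start < 80_000)
        ]
        assert len(window) >= 3
        contig = GenomeSequence("bac", g.residues[1_000:81_000])
        contig_units = []
        contig_seqs = {}
        for i, (_, r) in enumerate(window.iterrows()):
            name = f"b{i}"
            contig_units.append(
                _rec("bac", r["start"] - 1_000, r["end"] - 1_000, name)
            )
            contig_seqs[name] = r["sequence"]
        # genome annotation misses the middle unit: simulates a collapsed array
        genome_units, genome_seqs = [], {}
        for i, (_, r) in enumerate(window.iterrows()):
            if i == 1:
                continue
            name = f"g{i}"
            genome_units.append(_rec("chr01", r["start"], r["end"], name))
            genome_seqs[name] = r["sequence"]
        rep = qc_report(contig, genome, contig_units, genome_units,
                        contig_seqs, genome_seqs)
        assert rep.n_paired == len(window) - 1
        assert rep.n_contig_only == 1
        assert rep.n_paired + rep.n_contig_only == len(contig_units)
        assert len(rep.gap_spans) == 1
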