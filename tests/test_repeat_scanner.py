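import numpy as np
import pytest

from satscan.io_core import GenomeSequence
from satscan.profile_model import reverse_complement
from satscan.repeat_scanner import (
    UnitHit,
    assign_names,
    call_raw_blocks,
    filter_units,
    scan_genome,
)
from satscan.synthetic_genome import mutate


def _background(length, seed=0):
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


def _hit(seq_id, start, end, seq=None, strand="+", score=100.0):
    return UnitHit(seq_id, start, end, strand, score, seq or "A" * (end - start))


class TestScanGenome:
    def test_exact_consensus_planted(self, default_profile):
        cons = default_profile.consensus
        bg = _background(30_000, seed=1)
        genome = [GenomeSequence("c1", bg[:10_000] + cons + bg[10_000:])]
        hits = scan_genome(default_profile, genome,
                          0.4 * default_profile.self_score)
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.strand) == (10_000, 10_000 + len(cons), "+")
        assert h.sequence == cons

    def test_reverse_complement_planting_gives_minus_strand(self, default_profile):
        cons = default_profile.consensus
        bg = _background(30_000, seed=2)
        genome = [
            GenomeSequence("c1", bg[:10_000] + reverse_complement(cons) + bg[10_000:])
        ]
        hits = scan_genome(default_profile, genome,
                          0.4 * default_profile.self_score)
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.strand) == (10_000, 10_000 + len(cons), "-")
        assert h.sequence == cons  # read back in monomer orientation

    def test_divergent_tandem_copies_recovered(self, default_profile):
        """20 copies at 5% divergence are all recovered within 5 bp."""
        rng = np.random.default_rng(9)
        cons = default_profile.consensus
        bg = _background(60_000, seed=3)
        pieces, truth = [], []
        cursor = 20_000
        pieces.append(bg[:cursor])
        for _ in range(20):
            copy = mutate(cons, 0.05, rng)
            truth.append((cursor, cursor + len(copy)))
            pieces.append(copy)
            cursor += len(copy)
            gap = bg[cursor : cursor + 5]
            pieces.append(gap)
            cursor += 5
        pieces.append(bg[20_000:])
        genome = [GenomeSequence("c1", "".join(pieces))]
        hits = scan_genome(default_profile, genome,
                          0.4 * default_profile.self_score)
        assert len(hits) == 20
        for h, (ts, te) in zip(hits, truth):
            assert abs(h.start - ts) <= 5 and abs(h.end - te) <= 5

    def test_empty_genome_gives_empty_list(self, default_profile):
        assert scan_genome(default_profile, [], 10.0) == []

    def test_mirror_coordinates_on_reverse_complemented_chromosome(
        self, default_profile
    ):
        cons = default_profile.consensus
        bg = _background(20_000, seed=4)
        fwd = bg[:5_000] + cons + bg[5_000:]
        genome_f = [GenomeSequence("c1", fwd)]
        genome_r = [GenomeSequence("c1", reverse_complement(fwd))]
        thr = 0.4 * default_profile.self_score
        hf = scan_genome(default_profile, genome_f, thr)
        hr = scan_genome(default_profile, genome_r, thr)
        assert len(hf) == len(hr) == 1
        n = len(fwd)
        assert hr[0].start == n - hf[0].end
        assert hr[0].end == n - hf[0].start
        assert {hf[0].strand, hr[0].strand} == {"+", "-"}


class TestRawBlocks:
    def test_gap_below_max_groups(self):
        hits = [_hit("c1", 0, 528), _hit("c1", 628, 1156)]
        assert len(call_raw_blocks(hits, max_gap=600)) == 1

    def test_large_gap_splits(self):
        hits = [_hit("c1", 0, 528), _hit("c1", 11_000, 11_528)]
        assert len(call_raw_blocks(hits, max_gap=600)) == 2

    def test_chromosomes_never_share_blocks(self):
        hits = [_hit("c1", 0, 528), _hit("c2", 0, 528)]
        assert len(call_raw_blocks(hits, max_gap=10**9)) == 2

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            call_raw_blocks([_hit("c1", 600, 1128), _hit("c1", 0, 528)])


class TestFilterUnits:
    def clean_block(self, n, seq_id="c1", length=528):
        return [
            _hit(seq_id, i * 600, i * 600 + length, seq="G" * length)
            for i in range(n)
        ]

    def test_terminal_exclusion(self):
        retained, rep = filter_units([self.clean_block(5)])
        assert len(retained) == 3
        assert rep.n_terminal_removed == 2

    @pytest.mark.parametrize("length,kept", [(501, True), (500, False), (499, False)])
    def test_length_threshold_strict(self, length, kept):
        block = self.clean_block(3)
        block[1] = _hit("c1", 600, 600 + length, seq="G" * length)
        retained, rep = filter_units([block], min_len=500)
        assert (len(retained) == 1) == kept
        assert rep.n_short_removed == (0 if kept else 1)

    def test_interior_n_removed_and_counted(self):
        block = self.clean_block(3)
        block[1] = _hit("c1", 600, 1128, seq="G" * 527 + "N")
        retained, rep = filter_units([block])
        assert retained == []
        assert rep.n_ambiguous_removed == 1

    def test_report_counts_conserved(self):
        blocks = [self.clean_block(n) for n in (1, 2, 5, 8)]
        retained, rep = filter_units(blocks)
        assert rep.n_raw == 16
        assert rep.n_retained == len(retained) == 3 + 6
        assert (
            rep.n_raw
            - rep.n_terminal_removed
            - rep.n_short_removed
            - rep.n_ambiguous_removed
            == rep.n_retained
        )


class TestAssignNames:
    def units(self):
        return [
            _hit("chr01", 100, 628),
            _hit("chr01", 700, 1228),
            _hit("chr11", 0, 528),
            _hit("chr11", 600, 1128),
            _hit("chr11", 1200, 1728),
        ]

    def test_increments_of_ten_per_chromosome(self):
        records = assign_names(self.units(), ["S", "S", "L", "L", "L"])
        names = [r.name for r in records]
        assert names == [
            "Pv01Sk00010",
            "Pv01Sk00020",
            "Pv11Lk00010",
            "Pv11Lk00020",
            "Pv11Lk00030",
        ]

    def test_missing_arm_assignment_rejected(self):
        with pytest.raises(ValueError):
            assign_names(self.units(), ["S", "S", "L", "L"])


class TestDeterminism:
    def test_retained_set_independent_of_scan_order(self, small_run):
        _, genome, _, result = small_run
        profile = result.profile
        thr = result.config.min_score_frac * profile.self_score
        again = scan_genome(profile, list(reversed(genome)), thr)
        key = lambda h: (h.seq_id, h.start, h.end, h.strand)
        assert sorted(map(key, again)) == sorted(map(key, result.hits))
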