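"""Contig-versus-assembly QC for satellite regions.

An independently sequenced contig (e.g. a Sanger-sequenced BAC) is placed
on the assembly by unique k-mer anchor chaining, its satellite units are
paired one-to-one with the assembly's units in the placed window, and
contig units missing locally are searched genome-wide: a unit identical to
a unit far from the placement is a misassembly candidate (satellite blocks
are the classic failure mode of short-read assemblies).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from .io_core import AnnotationRecord, GenomeSequence
from .profile_model import encode

DEFAULT_ANCHOR_K = 31
DEFAULT_BAND = 2_000
DEFAULT_PAIR_IDENTITY = 0.95
DISTANT_BP = 1_000_000


class PlacementError(RuntimeError):
    pass


@dataclass
class ContigPlacement:
    contig_id: str
    seq_id: str
    start: int
    end: int
    orientation: str
    n_anchors: int
    length_flagged: bool = False


@dataclass
class UnitPairing:
    contig_unit: str
    genome_unit: str | None
    identity: float


@dataclass
class QcReport:
    placement: ContigPlacement
    pairings: list[UnitPairing]
    n_paired: int
    n_contig_only: int
    n_genome_only: int
    gap_spans: list[tuple[int, int]]
    cross_location_hits: list[tuple[str, str, float]] = field(default_factory=list)


def _unique_kmer_codes(enc: np.ndarray, k: int):
    from .repeat_scanner import _kmer_codes

    codes = _kmer_codes(enc, k)
    valid = codes >= 0
    vals, first_idx, counts = np.unique(codes[valid], return_index=True,
                                        return_counts=True)
    pos = np.nonzero(valid)[0]
    unique = counts == 1
    return vals[unique], pos[first_idx[unique]]


def place_contig(
    contig: GenomeSequence,
    genome: list[GenomeSequence],
    k: int = DEFAULT_ANCHOR_K,
    band: int = DEFAULT_BAND,
    min_anchors: int = 5,
) -> ContigPlacement:
    """Place a contig by chaining k-mers unique in both contig and genome."""
    if contig.length < 10 * k:
        raise ValueError("contig too short for anchor placement")
    c_vals, c_pos = _unique_kmer_codes(encode(contig.residues), k)
    from .profile_model import reverse_complement

    rc_vals, rc_pos = _unique_kmer_codes(encode(reverse_complement(contig.residues)), k)

    best = None
    for chrom in genome:
        g_vals, g_pos = _unique_kmer_codes(encode(chrom.residues), k)
        for orientation, vals, pos in (("+", c_vals, c_pos), ("-", rc_vals, rc_pos)):
            common, ci, gi = np.intersect1d(vals, g_vals, return_indices=True)
            if len(common) == 0:
                continue
            cpos, gpos = pos[ci], g_pos[gi]
            offsets = gpos - cpos
            order = np.argsort(offsets)
            offsets_sorted = offsets[order]
            # band offsets into chains; the largest chain wins
            breaks = np.nonzero(np.diff(offsets_sorted) > band)[0]
            bounds = np.concatenate([[0], breaks + 1, [len(offsets_sorted)]])
            for lo, hi in zip(bounds[:-1], bounds[1:]):
                if hi - lo < min_anchors:
                    continue
                idx = order[lo:hi]
                g_lo = int(gpos[idx].min())
                g_hi = int(gpos[idx].max()) + k
                # extend to the full contig extent implied by the anchors
                if orientation == "+":
                    lead = int(cpos[idx][np.argmin(gpos[idx])])
                    trail = contig.length - (int(cpos[idx][np.argmax(gpos[idx])]) + k)
                else:
                    lead = int(cpos[idx][np.argmin(gpos[idx])])
                    trail = contig.length - (int(cpos[idx][np.argmax(gpos[idx])]) + k)
                start = max(0, g_lo - lead)
                end = min(chrom.length, g_hi + trail)
                cand = (hi - lo, chrom.id, start, end, orientation)
                if best is None or cand[0] > best[0]:
                    best = cand
    if best is None:
        raise PlacementError(
            f"contig {contig.id}: fewer than {min_anchors} unique-k-mer anchors"
        )
    n_anchors, seq_id, start, end, orientation = best
    span = end - start
    flagged = not (0.5 * contig.length <= span <= 2.0 * contig.length)
    return ContigPlacement(
        contig_id=contig.id,
        seq_id=seq_id,
        start=start,
        end=end,
        orientation=orientation,
        n_anchors=n_anchors,
        length_flagged=flagged,
    )


def _identity(a: str, b: str) -> float:
    if not a or not b:
        return 0.0
    res = edlib.align(a, b, mode="NW", task="distance")
    return 1.0 - res["editDistance"] / max(len(a), len(b))


def pair_units(
    contig_units: list[AnnotationRecord],
    genome_units: list[AnnotationRecord],
    contig_seqs: dict[str, str],
    genome_seqs: dict[str, str],
    min_identity: float = DEFAULT_PAIR_IDENTITY,
) -> list[UnitPairing]:
    """Greedy one-to-one pairing by descending identity.

    ``contig_seqs`` / ``genome_seqs`` map unit names to monomer-orientation
    sequences.  Unmatched units appear with genome_unit None (contig side)
    or as trailing pairings with contig_unit '' (genome side).
    """
    cand = []
    for cu in contig_units:
        for gu in genome_units:
            ident = _identity(contig_seqs[cu.name], genome_seqs[gu.name])
            if ident >= min_identity:
                cand.append((ident, cu.name, gu.name))
    # descending identity; positional (input) order breaks ties deterministically
    cand.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_c, used_g = set(), set()
    pairings = []
    for ident, cn, gn in cand:
        if cn in used_c or gn in used_g:
            continue
        used_c.add(cn)
        used_g.add(gn)
        pairings.append(UnitPairing(contig_unit=cn, genome_unit=gn, identity=ident))
    for cu in contig_units:
        if cu.name not in used_c:
            pairings.append(UnitPairing(contig_unit=cu.name, genome_unit=None,
                                        identity=0.0))
    for gu in genome_units:
        if gu.name not in used_g:
            pairings.append(UnitPairing(contig_unit="", genome_unit=gu.name,
                                        identity=0.0))
    return pairings


def flag_cross_location(
    unmatched_contig_units: list[AnnotationRecord],
    all_genome_units: list[AnnotationRecord],
    contig_seqs: dict[str, str],
    genome_seqs: dict[str, str],
    placement: ContigPlacement,
    identity_exact: float = 1.0,
    distant_bp: int = DISTANT_BP,
) -> list[tuple[str, str, float]]:
    """Search locally-unmatched contig units genome-wide for identical twins.

    A hit is flagged when it lies on a different chromosome than the
    placement, or more than ``distant_bp`` away on the same chromosome.
    """
    hits = []
    for cu in unmatched_contig_units:
        cseq = contig_seqs[cu.name]
        for gu in all_genome_units:
            if gu.seq_id != placement.seq_id:
                distant = True
            else:
                if gu.end <= placement.start:
                    sep = placement.start - gu.end
                elif gu.start >= placement.end:
                    sep = gu.start - placement.end
                else:
                    sep = 0
                distant = sep > distant_bp
            if not distant:
                continue
            ident = _identity(cseq, genome_seqs[gu.name])
            if ident >= identity_exact:
                hits.append((cu.name, gu.name, ident))
    return hits


def qc_report(
    contig: GenomeSequence,
    genome: list[GenomeSequence],
    contig_units: list[AnnotationRecord],
    genome_units: list[AnnotationRecord],
    contig_seqs: dict[str, str],
    genome_seqs: dict[str, str],
    min_identity: float = DEFAULT_PAIR_IDENTITY,
    identity_exact: float = 1.0,
    gap_min: int = 1_000,
) -> QcReport:
    """Full contig-vs-assembly comparison."""
    placement = place_contig(contig, genome)
    local = [
        gu
        for gu in genome_units
        if gu.seq_id == placement.seq_id
        and gu.start < placement.end
        and gu.end > placement.start
    ]
    pairings = pair_units(contig_units, local, contig_seqs, genome_seqs,
                          min_identity=min_identity)
    paired = [p for p in pairings if p.contig_unit and p.genome_unit]
    contig_only = [p for p in pairings if p.contig_unit and p.genome_unit is None]
    genome_only = [p for p in pairings if not p.contig_unit]

    # gaps: runs of consecutive contig-only units mark missing assembly spans
    unit_by_name = {u.name: u for u in contig_units}
    missing = sorted(
        (unit_by_name[p.contig_unit].start, unit_by_name[p.contig_unit].end)
        for p in contig_only
    )
    gap_spans: list[tuple[int, int]] = []
    for s, e in missing:
        if gap_spans and s - gap_spans[-1][1] <= gap_min:
            gap_spans[-1] = (gap_spans[-1][0], e)
        else:
            gap_spans.append((s, e))

    cross = flag_cross_location(
        [unit_by_name[p.contig_unit] for p in contig_only],
        genome_units,
        contig_seqs,
        genome_seqs,
        placement,
        identity_exact=identity_exact,
    )
    return QcReport(
        placement=placement,
        pairings=pairings,
        n_paired=len(paired),
        n_contig_only=len(contig_only),
        n_genome_only=len(genome_only),
        gap_spans=gap_spans,
        cross_location_hits=cross,
    )
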