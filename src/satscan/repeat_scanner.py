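"""Genome scanning for satellite monomer units, filtering, and naming.

Candidate windows are seeded by exact k-mer matches against the profile
consensus (both strands), then scored with the affine-gap glocal aligner.
Overlapping hits are resolved greedily by score; the retained set is
produced by the cleaning rules used for satellite census work: drop the
first and last element of every tandem block (boundary units are often
truncated or divergent), drop short units, drop units containing N.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_core import AnnotationRecord, GenomeSequence, UnitName, render_unit_name
from .profile_model import GlocalAlignment, ProfileModel, encode, reverse_complement, score_glocal

logger = logging.getLogger(__name__)

DEFAULT_MIN_SCORE_FRAC = 0.4
DEFAULT_SEED_K = 12
DEFAULT_MIN_SEEDS = 3
DEFAULT_MAX_GAP = 600
DEFAULT_MIN_LEN = 500


@dataclass
class UnitHit:
    """One located monomer copy.

    ``sequence`` always reads in monomer orientation (reverse-complemented
    for minus-strand hits).
    """

    seq_id: str
    start: int
    end: int
    strand: str
    score: float
    sequence: str
    alignment: GlocalAlignment | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class FilterReport:
    n_raw: int
    n_terminal_removed: int
    n_short_removed: int
    n_ambiguous_removed: int
    n_retained: int

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tcount\n")
            for k, v in vars(self).items():
                fh.write(f"{k}\t{v}\n")


def _kmer_codes(encoded: np.ndarray, k: int) -> np.ndarray:
    """2-bit pack all k-mers; k-mers containing N are coded -1."""
    n = len(encoded)
    if n < k:
        return np.empty(0, dtype=np.int64)
    valid = encoded < 4
    e = np.where(valid, encoded, 0).astype(np.int64)
    codes = np.zeros(n - k + 1, dtype=np.int64)
    ok = np.ones(n - k + 1, dtype=bool)
    for off in range(k):
        codes = (codes << 2) | e[off : off + n - k + 1]
        ok &= valid[off : off + n - k + 1]
    codes[~ok] = -1
    return codes


def _seed_candidates(
    chrom_enc: np.ndarray,
    consensus_enc: np.ndarray,
    k: int,
    min_seeds: int,
    monomer_len: int,
) -> list[int]:
    """Candidate monomer start positions from diagonal k-mer seed clusters."""
    cons_codes = _kmer_codes(consensus_enc, k)
    lookup: dict[int, list[int]] = {}
    for off, code in enumerate(cons_codes):
        if code >= 0:
            lookup.setdefault(int(code), []).append(off)

    gen_codes = _kmer_codes(chrom_enc, k)
    table = np.zeros(4**k, dtype=bool)
    cons_valid = cons_codes[cons_codes >= 0]
    table[cons_valid] = True
    hit_mask = (gen_codes >= 0) & table[np.clip(gen_codes, 0, None)]
    hit_pos = np.nonzero(hit_mask)[0]
    if hit_pos.size == 0:
        return []

    # implied monomer start (diagonal) for every (genome pos, consensus offset)
    diags = []
    for pos in hit_pos:
        for off in lookup[int(gen_codes[pos])]:
            diags.append(pos - off)
    diags = np.sort(np.array(diags, dtype=np.int64))

    # cluster diagonals within half a monomer; keep clusters with enough seeds
    starts: list[int] = []
    tol = max(monomer_len // 3, 50)
    i = 0
    while i < len(diags):
        j = i
        while j + 1 < len(diags) and diags[j + 1] - diags[j] <= tol:
            j += 1
        if j - i + 1 >= min_seeds:
            starts.append(int(np.median(diags[i : j + 1])))
        i = j + 1
    return starts


def _score_window(
    profile: ProfileModel,
    chrom: GenomeSequence,
    cand_start: int,
    strand: str,
    pad: int,
) -> UnitHit | None:
    L = profile.length
    w_start = max(0, cand_start - pad)
    w_end = min(chrom.length, cand_start + L + pad)
    window = chrom.residues[w_start:w_end]
    if not window:
        return None
    if strand == "-":
        window = reverse_complement(window)
    aln = score_glocal(profile, window)
    if strand == "+":
        start = w_start + aln.seq_start
        end = w_start + aln.seq_end
    else:
        start = w_end - aln.seq_end
        end = w_end - aln.seq_start
    if end <= start:
        return None
    seq = chrom.residues[start:end]
    if strand == "-":
        seq = reverse_complement(seq)
    return UnitHit(
        seq_id=chrom.id,
        start=start,
        end=end,
        strand=strand,
        score=aln.score,
        sequence=seq,
        alignment=aln,
    )


def _reciprocal_overlap(a: UnitHit, b: UnitHit) -> float:
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return 0.0
    return min(ov / a.length, ov / b.length)


def scan_genome(
    profile: ProfileModel,
    genome: list[GenomeSequence],
    min_score: float,
    seed_k: int = DEFAULT_SEED_K,
    min_seeds: int = DEFAULT_MIN_SEEDS,
    pad: int = 80,
    rescue: bool = True,
) -> list[UnitHit]:
    """Scan both strands of every sequence for monomer units.

    Overlapping hits (>50% reciprocal overlap) are resolved greedily by
    descending score; ties go to the leftmost start, then the + strand.
    With ``rescue``, monomer-sized gaps between consecutive hits are
    re-scored directly: a highly divergent interior copy can fall below the
    k-mer seeding sensitivity while still clearing the score threshold.
    """
    if min_score <= 0:
        raise ValueError("min_score must be positive")
    cons_enc = encode(profile.consensus)
    cons_rc_enc = encode(reverse_complement(profile.consensus))
    L = profile.length

    all_hits: list[UnitHit] = []
    for chrom in genome:
        chrom_enc = encode(chrom.residues)
        hits: list[UnitHit] = []
        for strand, cenc in (("+", cons_enc), ("-", cons_rc_enc)):
            cands = _seed_candidates(chrom_enc, cenc, seed_k, min_seeds, L)
            for cand in cands:
                hit = _score_window(profile, chrom, cand, strand, pad)
                if hit is not None and hit.score >= min_score:
                    hits.append(hit)
        hits = _resolve_overlaps(hits)
        if rescue:
            hits = _rescue_gaps(profile, chrom, hits, min_score, pad)
        logger.info("%s: %d unit hits", chrom.id, len(hits))
        all_hits.extend(hits)
    all_hits.sort(key=lambda h: (h.seq_id, h.start, h.end))
    return all_hits


def _rescue_gaps(
    profile: ProfileModel,
    chrom: GenomeSequence,
    hits: list[UnitHit],
    min_score: float,
    pad: int,
) -> list[UnitHit]:
    """Score monomer-sized gaps between consecutive hits (seeding misses)."""
    L = profile.length
    changed = True
    while changed:
        changed = False
        hits.sort(key=lambda h: (h.start, h.end))
        for prev, nxt in zip(hits, hits[1:]):
            gap = nxt.start - prev.end
            if gap < 0.85 * L:
                continue
            strands = [prev.strand] + (["-"] if prev.strand == "+" else ["+"])
            for strand in strands:
                cand = _score_window(profile, chrom, prev.end + 2, strand, pad)
                if (
                    cand is not None
                    and cand.score >= min_score
                    and cand.start >= prev.end - 10
                    and all(_reciprocal_overlap(cand, h) <= 0.5 for h in hits)
                ):
                    hits.append(cand)
                    changed = True
                    break
            if changed:
                break
    hits.sort(key=lambda h: (h.start, h.end))
    return hits


def _resolve_overlaps(hits: list[UnitHit]) -> list[UnitHit]:
    order = sorted(
        hits, key=lambda h: (-h.score, h.start, 0 if h.strand == "+" else 1)
    )
    kept: list[UnitHit] = []
    for h in order:
        if all(_reciprocal_overlap(h, k) <= 0.5 for k in kept):
            kept.append(h)
    kept.sort(key=lambda h: (h.seq_id, h.start))
    return kept


def call_raw_blocks(hits: list[UnitHit], max_gap: int = DEFAULT_MAX_GAP) -> list[list[UnitHit]]:
    """Group sorted hits into tandem blocks separated by > max_gap."""
    order = [(h.seq_id, h.start) for h in hits]
    if order != sorted(order):
        raise ValueError("hits must be sorted by (seq_id, start)")
    blocks: list[list[UnitHit]] = []
    for h in hits:
        if (
            blocks
            and blocks[-1][-1].seq_id == h.seq_id
            and h.start - blocks[-1][-1].end <= max_gap
        ):
            blocks[-1].append(h)
        else:
            blocks.append([h])
    return blocks


def filter_units(
    blocks: list[list[UnitHit]], min_len: int = DEFAULT_MIN_LEN
) -> tuple[list[UnitHit], FilterReport]:
    """Apply the cleaning rules in fixed order: terminal, length, ambiguity.

    The first and last element of every block are removed (a 1-unit block
    loses its unit, a 2-unit block loses both); of the remainder, units with
    length <= min_len are removed (strict > min_len retention), then units
    whose sequence contains N.
    """
    n_raw = sum(len(b) for b in blocks)
    n_terminal = 0
    n_short = 0
    n_ambig = 0
    retained: list[UnitHit] = []
    for block in blocks:
        interior = block[1:-1] if len(block) > 2 else []
        n_terminal += len(block) - len(interior)
        for unit in interior:
            if unit.length <= min_len:
                n_short += 1
            elif "N" in unit.sequence:
                n_ambig += 1
            else:
                retained.append(unit)
    report = FilterReport(
        n_raw=n_raw,
        n_terminal_removed=n_terminal,
        n_short_removed=n_short,
        n_ambiguous_removed=n_ambig,
        n_retained=len(retained),
    )
    return retained, report


def assign_names(
    retained: list[UnitHit],
    arms: dict[int, str] | list,
    prefix: str = "Pv",
    chrom_labels: dict[str, str] | None = None,
) -> list[AnnotationRecord]:
    """Name retained units per chromosome, 5'->3', ordinals 10, 20, 30, ...

    ``arms`` maps unit index (position in ``retained``) or is a parallel
    list of arm codes.  ``chrom_labels`` maps seq_id to the 2-digit label
    used in names (defaults to digits found in the seq_id, else a running
    index).
    """
    if isinstance(arms, dict):
        arm_list = [arms.get(i) for i in range(len(retained))]
    else:
        arm_list = list(arms)
    if len(arm_list) != len(retained) or any(a is None for a in arm_list):
        raise ValueError("every retained unit needs an arm assignment")

    if chrom_labels is None:
        chrom_labels = {}
        seq_ids = sorted({h.seq_id for h in retained})
        for idx, sid in enumerate(seq_ids, start=1):
            digits = "".join(c for c in sid if c.isdigit())
            chrom_labels[sid] = digits[-2:].zfill(2) if digits else f"{idx:02d}"

    records: list[AnnotationRecord] = []
    counter: dict[str, int] = {}
    for unit, arm in zip(retained, arm_list):
        counter[unit.seq_id] = counter.get(unit.seq_id, 0) + 10
        name = render_unit_name(
            UnitName(
                genotype_prefix=prefix,
                chrom_label=chrom_labels[unit.seq_id],
                arm_code=arm,
                ordinal=counter[unit.seq_id],
            )
        )
        records.append(
            AnnotationRecord(
                seq_id=unit.seq_id,
                start=unit.start,
                end=unit.end,
                strand=unit.strand,
                feature_type="satellite_unit",
                score=unit.score,
                attributes={
                    "Name": name,
                    "arm": arm,
                    "location": f"{chrom_labels[unit.seq_id]}{arm}",
                },
            )
        )
    return records
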