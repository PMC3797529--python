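"""Tandem-block calling, centromere localization, arm codes, count matrix.

Chromosome arms are coded S (short arm, the 5' side of the pseudomolecule),
C (centromere interval), and L (long arm).  The centromere interval is
located from local-alignment hits of the centromeric satellite monomers
(e.g. CentPv1/CentPv2): hits above an identity threshold are clustered and
the largest cluster wins.  The per-chromosome S/C/L unit counts form the
census matrix of the analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

from .io_core import GenomeSequence
from .profile_model import encode, reverse_complement
from .repeat_scanner import UnitHit, _seed_candidates, call_raw_blocks

logger = logging.getLogger(__name__)

DEFAULT_CENT_MIN_IDENTITY = 0.8
DEFAULT_CENT_MERGE_GAP = 100_000
SUBTELOMERE_SPAN = 5_000_000  # distal span regarded as subtelomeric in reports


@dataclass
class BlockRecord:
    """A maximal tandem array of retained units."""

    seq_id: str
    units: list[str]  # unit names (or placeholder ids)
    start: int
    end: int

    @property
    def size(self) -> int:
        return len(self.units)


@dataclass
class CentromereInterval:
    seq_id: str
    start: int
    end: int
    n_hits: int
    repeat_family: str


def call_blocks(
    retained: list[UnitHit],
    max_gap: int,
    names: list[str] | None = None,
) -> list[BlockRecord]:
    """Group the retained units into final blocks (same rule as raw blocks)."""
    groups = call_raw_blocks(retained, max_gap=max_gap)
    if names is None:
        names = [f"{h.seq_id}:{h.start}-{h.end}" for h in retained]
    name_of = {id(h): nm for h, nm in zip(retained, names)}
    return [
        BlockRecord(
            seq_id=g[0].seq_id,
            units=[name_of[id(h)] for h in g],
            start=g[0].start,
            end=g[-1].end,
        )
        for g in groups
    ]


def block_size_histogram(blocks: list[BlockRecord]) -> pd.DataFrame:
    sizes = pd.Series([b.size for b in blocks], dtype=int)
    hist = sizes.value_counts().sort_index()
    return hist.rename_axis("block_size").reset_index(name="n_blocks")


def _identity_hits(
    chrom: GenomeSequence, repeat: GenomeSequence, min_identity: float
) -> list[tuple[int, int]]:
    """Spans of local hits of one repeat family (both strands)."""
    chrom_enc = encode(chrom.residues)
    rep_len = len(repeat.residues)
    max_dist = int(round((1 - min_identity) * rep_len))
    spans: list[tuple[int, int]] = []
    for rep_seq in (repeat.residues, reverse_complement(repeat.residues)):
        cands = _seed_candidates(
            chrom_enc, encode(rep_seq), k=12, min_seeds=2, monomer_len=rep_len
        )
        for cand in cands:
            w_start = max(0, cand - 30)
            w_end = min(chrom.length, cand + rep_len + 30)
            window = chrom.residues[w_start:w_end]
            res = edlib.align(rep_seq, window, mode="HW", task="locations",
                              k=max_dist)
            if res["editDistance"] < 0:
                continue
            loc = res["locations"][0]
            spans.append((w_start + loc[0], w_start + loc[1] + 1))
    return spans


def locate_centromere(
    chrom: GenomeSequence,
    cent_repeats: list[GenomeSequence],
    min_identity: float = DEFAULT_CENT_MIN_IDENTITY,
    merge_gap: int = DEFAULT_CENT_MERGE_GAP,
) -> CentromereInterval | None:
    """Locate the centromere as the largest cluster of satellite hits.

    Returns None when no repeat family hits the chromosome above the
    identity threshold (the arm split then falls back to the midpoint).
    """
    if not cent_repeats:
        raise ValueError("cent_repeats must be non-empty")
    best: CentromereInterval | None = None
    best_summed = -1
    for rep in cent_repeats:
        spans = sorted(_identity_hits(chrom, rep, min_identity))
        if not spans:
            continue
        # merge spans closer than merge_gap into clusters
        clusters: list[list[tuple[int, int]]] = [[spans[0]]]
        for s in spans[1:]:
            if s[0] - clusters[-1][-1][1] <= merge_gap:
                clusters[-1].append(s)
            else:
                clusters.append([s])
        for cl in clusters:
            summed = sum(e - s for s, e in cl)
            cand = CentromereInterval(
                seq_id=chrom.id,
                start=cl[0][0],
                end=cl[-1][1],
                n_hits=len(cl),
                repeat_family=rep.id,
            )
            if best is None or summed > best_summed:
                best, best_summed = cand, summed
    if best is None:
        logger.warning("%s: no centromeric satellite hits; midpoint fallback",
                       chrom.id)
    return best


def assign_arms(
    units: list[UnitHit],
    centromere: CentromereInterval | None,
    chrom_length: int | None = None,
) -> list[str]:
    """Arm code per unit: S before, C overlapping, L after the centromere.

    Without a centromere interval the S/L split falls at the chromosome
    midpoint (requires ``chrom_length``).
    """
    codes = []
    for u in units:
        if centromere is None:
            if chrom_length is None:
                raise ValueError("chrom_length required for midpoint fallback")
            codes.append("S" if u.start < chrom_length // 2 else "L")
        elif u.end <= centromere.start:
            codes.append("S")
        elif u.start >= centromere.end:
            codes.append("L")
        else:
            codes.append("C")
    return codes


def count_matrix(
    assignments: list[tuple[str, str]], chrom_order: list[str] | None = None
) -> pd.DataFrame:
    """Per-chromosome S/C/L counts. ``assignments`` is (seq_id, arm_code)."""
    df = pd.DataFrame(assignments, columns=["seq_id", "arm"])
    if chrom_order is None:
        chrom_order = sorted(df["seq_id"].unique()) if len(df) else []
    mat = pd.DataFrame(0, index=chrom_order,
                       columns=["short_arm", "centromere", "long_arm"])
    label = {"S": "short_arm", "C": "centromere", "L": "long_arm"}
    for (sid, arm), cnt in df.value_counts(["seq_id", "arm"]).items():
        if sid in mat.index:
            mat.loc[sid, label[arm]] = cnt
    mat["total"] = mat.sum(axis=1)
    mat.loc["Total"] = mat.sum(axis=0)
    mat.index.name = "pseudomolecule"
    return mat
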