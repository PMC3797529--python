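"""Readers and writers for the formats the pipeline touches, plus unit naming.

Internal coordinates are 0-based half-open everywhere; the single conversion
to 1-based inclusive happens at GFF3 serialization.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import TreeNode

logger = logging.getLogger(__name__)

_VALID_RESIDUES = set("ACGTN")
_NON_ACGTN = re.compile(r"[^ACGTN]")


class FormatError(ValueError):
    """Raised on malformed input files."""


@dataclass
class GenomeSequence:
    """One DNA sequence (chromosome, pseudomolecule, or contig)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid sequence id: {self.id!r}")

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass
class AnnotationRecord:
    """A located feature: 0-based half-open interval on a sequence."""

    seq_id: str
    start: int
    end: int
    strand: str
    feature_type: str
    score: float
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_id}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def name(self) -> Optional[str]:
        return self.attributes.get("Name")


@dataclass(frozen=True)
class UnitName:
    """Satellite unit name of the form <prefix><chrom><arm>k<5-digit ordinal>.

    ``Pv01Sk00010`` is the first unit on pseudomolecule 01, short arm.
    Contig-derived units omit the arm code (``PvA05Ak00010``).  Ordinals run
    in increments of 10 along each sequence 5'->3'.
    """

    genotype_prefix: str
    chrom_label: str
    arm_code: Optional[str]  # S, C, L, or None for contig units
    ordinal: int


def render_unit_name(name: UnitName) -> str:
    if name.ordinal <= 0 or name.ordinal % 10 != 0:
        raise ValueError(f"ordinal must be a positive multiple of 10: {name.ordinal}")
    if name.ordinal > 99999:
        raise ValueError(f"ordinal too large for 5 digits: {name.ordinal}")
    if name.arm_code is not None and name.arm_code not in ("S", "C", "L"):
        raise ValueError(f"invalid arm code {name.arm_code!r}")
    arm = name.arm_code or ""
    return f"{name.genotype_prefix}{name.chrom_label}{arm}k{name.ordinal:05d}"


def read_fasta(path) -> list[GenomeSequence]:
    """Read a FASTA file; residues uppercased, non-ACGTN replaced by N."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"header {rec.id!r} has no sequence")
        n_bad = len(_NON_ACGTN.findall(seq))
        if n_bad:
            logger.warning(
                "%s: %d non-ACGTN residues replaced by N in %s", path, n_bad, rec.id
            )
            seq = _NON_ACGTN.sub("N", seq)
        records.append(GenomeSequence(id=rec.id, residues=seq))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(seqs: list[GenomeSequence], path, width: int = 80) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def _format_attributes(attrs: dict) -> str:
    if not attrs:
        return "."
    # Name first for readability, then the rest in insertion order.
    keys = sorted(attrs, key=lambda k: (k != "Name",))
    return ";".join(f"{k}={attrs[k]}" for k in keys)


def write_gff3(records: list[AnnotationRecord], path) -> None:
    """Write GFF3 (1-based inclusive coordinates). Input must be pre-sorted."""
    order = [(r.seq_id, r.start) for r in records]
    if order != sorted(order):
        raise ValueError("records must be sorted by (seq_id, start)")
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in records:
            score = "." if r.score is None else f"{r.score:.6g}"
            fh.write(
                "\t".join(
                    [
                        r.seq_id,
                        "satscan",
                        r.feature_type,
                        str(r.start + 1),
                        str(r.end),
                        score,
                        r.strand,
                        ".",
                        _format_attributes(r.attributes),
                    ]
                )
                + "\n"
            )


def read_gff3(path) -> list[AnnotationRecord]:
    """Parse GFF3 written by :func:`write_gff3` back into records."""
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"bad GFF3 line: {line!r}")
            attrs = {}
            if cols[8] != ".":
                for kv in cols[8].split(";"):
                    if kv:
                        k, _, v = kv.partition("=")
                        attrs[k] = v
            records.append(
                AnnotationRecord(
                    seq_id=cols[0],
                    start=int(cols[3]) - 1,
                    end=int(cols[4]),
                    strand=cols[6],
                    feature_type=cols[2],
                    score=float(cols[5]) if cols[5] != "." else 0.0,
                    attributes=attrs,
                )
            )
    return records


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path) -> TreeNode:
    try:
        return TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises several parse error types
        raise FormatError(f"malformed newick in {path}: {exc}") from exc


def read_newick_string(s: str) -> TreeNode:
    try:
        return TreeNode.read(io.StringIO(s), format="newick")
    except Exception as exc:
        raise FormatError(f"malformed newick: {exc}") from exc
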