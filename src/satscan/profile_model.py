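"""Position-specific scoring profile of a satellite monomer.

The profile is built from a seed alignment of monomer copies: columns that
are mostly gaps are treated as insert columns and dropped, the remaining
columns become match positions with log-odds emission scores (log base 2
against a background composition).  Sequences are scored against the
profile with an affine-gap "glocal" dynamic program -- global over the
profile, local over the sequence -- so a monomer may start and end anywhere
inside a genomic window.  This scorer plays the role a profile-HMM search
plays in classical satellite annotation, but with fully specified,
deterministic semantics (Viterbi-style best path, fixed tie-breaks).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io_core import FormatError, read_fasta

_BASES = "ACGT"
_ENCODE = {c: i for i, c in enumerate("ACGTN")}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_NEG = -1.0e30

# traceback state codes
_START, _M, _D, _I = 0, 1, 2, 3


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode ACGTN to 0..4 (anything else is an error upstream)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for base, code in _ENCODE.items():
        out[arr == ord(base)] = code
    return out


@dataclass
class SeedAlignment:
    """Aligned monomer copies: equal-length rows over {A,C,G,T,N,-}."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("seed alignment needs at least 2 rows")
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) != 1:
            raise ValueError("seed alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])


def read_seed_alignment(path) -> SeedAlignment:
    """Read an aligned FASTA (gaps as ``-``)."""
    rows = []
    from Bio import SeqIO

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace(".", "-")
        seq = "".join(c if c in "ACGTN-" else "N" for c in seq)
        rows.append((rec.id, seq))
    if not rows:
        raise FormatError(f"no records in {path}")
    return SeedAlignment(rows=rows)


@dataclass
class ProfileModel:
    """Log-odds scoring model over L match positions.

    emissions[i, b] is the score in bits for base b at match position i.
    gap_open / gap_extend are negative scores applied per gap event/column.
    """

    emissions: np.ndarray  # (L, 4) float
    background: np.ndarray  # (4,) frequencies summing to 1
    gap_open: float
    gap_extend: float
    consensus: str

    @property
    def length(self) -> int:
        return self.emissions.shape[0]

    @property
    def self_score(self) -> float:
        """Score of the consensus against the profile (gap-free path)."""
        return float(self.emissions.max(axis=1).sum())

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("position\tA\tC\tG\tT\tconsensus\n")
            fh.write(f"#background\t{self.background[0]:.6f}\t{self.background[1]:.6f}"
                     f"\t{self.background[2]:.6f}\t{self.background[3]:.6f}\t-\n")
            fh.write(f"#gap\t{self.gap_open:.6f}\t{self.gap_extend:.6f}\t.\t.\t-\n")
            for i in range(self.length):
                e = self.emissions[i]
                fh.write(
                    f"{i}\t{e[0]:.6f}\t{e[1]:.6f}\t{e[2]:.6f}\t{e[3]:.6f}"
                    f"\t{self.consensus[i]}\n"
                )

    @classmethod
    def from_tsv(cls, path) -> "ProfileModel":
        rows, consensus = [], []
        background = np.full(4, 0.25)
        gap_open, gap_extend = -8.0, -1.0
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("position"):
                raise FormatError(f"bad profile TSV header in {path}")
            for line in fh:
                cols = line.rstrip("\n").split("\t")
                if cols[0] == "#background":
                    background = np.array([float(x) for x in cols[1:5]])
                elif cols[0] == "#gap":
                    gap_open, gap_extend = float(cols[1]), float(cols[2])
                else:
                    rows.append([float(x) for x in cols[1:5]])
                    consensus.append(cols[5])
        return cls(
            emissions=np.array(rows),
            background=background,
            gap_open=gap_open,
            gap_extend=gap_extend,
            consensus="".join(consensus),
        )


def build_profile(
    seed: SeedAlignment,
    gap_col_threshold: float = 0.5,
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
    gap_open: float = -8.0,
    gap_extend: float = -1.0,
) -> ProfileModel:
    """Build a profile from a seed alignment.

    Columns whose gap fraction exceeds ``gap_col_threshold`` are dropped
    (insert columns); the rest become match positions.  Emission scores are
    log2((count + pseudocount) / (n_rows + 4*pseudocount) / background),
    with N residues contributing 1/4 count to each base.
    """
    if not 0 < gap_col_threshold <= 1:
        raise ValueError("gap_col_threshold must be in (0, 1]")
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)

    mat = np.array(
        [[_ENCODE.get(c, 5) for c in seq.replace("-", "?")] for _, seq in seed.rows],
        dtype=np.int8,
    )
    # re-encode gaps (the '?' placeholder maps to 5)
    n_rows, n_cols = mat.shape
    gap_frac = (mat == 5).mean(axis=0)
    keep = gap_frac <= gap_col_threshold
    if not keep.any():
        raise ValueError("all columns exceed the gap threshold")
    mat = mat[:, keep]

    counts = np.zeros((mat.shape[1], 4))
    for b in range(4):
        counts[:, b] = (mat == b).sum(axis=0)
    counts += (mat == 4).sum(axis=0)[:, None] / 4.0  # N spread over bases

    freqs = (counts + pseudocount) / (n_rows + 4 * pseudocount)
    emissions = np.log2(freqs / background)
    consensus = "".join(_BASES[i] for i in np.argmax(emissions, axis=1))
    return ProfileModel(
        emissions=emissions,
        background=background,
        gap_open=gap_open,
        gap_extend=gap_extend,
        consensus=consensus,
    )


@dataclass
class GlocalAlignment:
    """Best glocal alignment of a profile to a sequence window."""

    score: float
    aligned_columns: list  # length L: residue char or '-' per match position
    seq_start: int  # 0-based start of the consumed sequence span
    seq_end: int  # 0-based half-open end
    n_insertions: int


def score_glocal(profile: ProfileModel, seq: str) -> GlocalAlignment:
    """Align ``seq`` to the profile: global over the profile, local over seq.

    Affine gaps; deterministic traceback with tie-break match > delete >
    insert.  N residues score the mean emission of the position.
    """
    if len(seq) == 0:
        raise ValueError("empty sequence")
    s = encode(seq)
    n = len(s)
    L = profile.length
    emis = profile.emissions
    emis_n = emis.mean(axis=1)
    go, ge = profile.gap_open, profile.gap_extend

    m_ptr = np.zeros((L + 1, n + 1), dtype=np.int8)
    d_ptr = np.zeros((L + 1, n + 1), dtype=np.int8)
    i_idx = np.zeros((L + 1, n + 1), dtype=np.int32)

    js = np.arange(n + 1)
    m_prev = np.full(n + 1, _NEG)
    d_prev = np.full(n + 1, _NEG)
    i_prev = np.full(n + 1, _NEG)
    start_row = np.zeros(n + 1)

    s_clip = np.minimum(s, 3)
    is_n = s == 4

    for i in range(1, L + 1):
        e = emis[i - 1, s_clip]
        if is_n.any():
            e = np.where(is_n, emis_n[i - 1], e)

        if i == 1:
            pm, pd, pi = start_row, None, None
            best_prev = pm
            best_state = np.full(n + 1, _START, dtype=np.int8)
        else:
            pm, pd, pi = m_prev, d_prev, i_prev
            best_prev = pm.copy()
            best_state = np.full(n + 1, _M, dtype=np.int8)
            better = pd > best_prev
            best_prev[better] = pd[better]
            best_state[better] = _D
            better = pi > best_prev
            best_prev[better] = pi[better]
            best_state[better] = _I

        m_cur = np.full(n + 1, _NEG)
        m_cur[1:] = e + best_prev[:-1]
        m_ptr[i, 1:] = best_state[:-1]

        # delete state: open from M (or I), extend from D
        open_from = pm + go
        open_state = np.full(n + 1, _START if i == 1 else _M, dtype=np.int8)
        if pd is not None:
            ext = pd + ge
            take = ext > open_from
            d_cur = np.where(take, ext, open_from)
            d_state = np.where(take, _D, open_state).astype(np.int8)
            open_i = pi + go
            take = open_i > d_cur
            d_cur[take] = open_i[take]
            d_state[take] = _I
        else:
            d_cur = open_from.copy()
            d_state = open_state
        d_ptr[i] = d_state

        # insert state along the sequence: I[j] = max_k<j M[k] + go + (j-1-k)*ge
        t = m_cur + go - js * ge
        run = np.maximum.accumulate(t)
        idx = np.maximum.accumulate(np.where(t >= run, js, -1))
        i_cur = np.full(n + 1, _NEG)
        i_cur[1:] = run[:-1] + js[1:] * ge - ge  # (j-1)*ge added back
        i_idx[i, 1:] = idx[:-1]

        m_prev, d_prev, i_prev = m_cur, d_cur, i_cur

    # free end over the sequence; prefer M over D, leftmost endpoint on ties
    end_m = int(np.argmax(m_prev))
    end_d = int(np.argmax(d_prev))
    if m_prev[end_m] >= d_prev[end_d]:
        state, j = _M, end_m
        score = float(m_prev[end_m])
    else:
        state, j = _D, end_d
        score = float(d_prev[end_d])

    cols: list[str] = ["-"] * L
    n_ins = 0
    seq_end = j
    i = L
    while i > 0:
        if state == _M:
            cols[i - 1] = seq[j - 1]
            state = int(m_ptr[i, j])
            i -= 1
            j -= 1
            if state == _START:
                break
        elif state == _D:
            state = int(d_ptr[i, j])
            i -= 1
            if state == _START:
                break
        else:  # insert run back to its anchoring M on the same row
            k = int(i_idx[i, j])
            n_ins += j - k
            j = k
            state = _M
    seq_start = j
    return GlocalAlignment(
        score=score,
        aligned_columns=cols,
        seq_start=seq_start,
        seq_end=seq_end,
        n_insertions=n_ins,
    )
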