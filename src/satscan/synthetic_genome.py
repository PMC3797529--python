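"""Synthetic genomes with planted satellite arrays and full ground truth.

The generative model mirrors the dynamics inferred for subtelomeric
satellites: independent monomer lineages seeded on particular chromosome
arms, tandem blocks grown by iterative local copying with per-copy point
mutation (a birth chain, so blocks carry internal phylogenetic structure),
occasional interchromosomal transfer of a lineage to a foreign arm (rate
tau), occasional two-parent recombinant copies (rate rho), and occasional
placement of a block inside the centromere (rate kappa).  A distinct
centromeric satellite (150-bp monomer) is planted as a long tandem array
in every centromere interval.

Defaults give the desk-scale scenario used throughout the test suite:
3 chromosomes x 2 Mb, 8 lineages, about 40 blocks and 300 units with
mu = 0.03 substitutions/site per copy event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import AnnotationRecord, GenomeSequence
from .profile_model import reverse_complement

_BASES = np.array(list("ACGT"))


@dataclass
class SimParams:
    n_chrom: int = 3
    chrom_length: int = 2_000_000
    monomer: str | None = None  # random 528-mer when None
    monomer_length: int = 528
    n_founders: int = 8
    lineage_divergence: float = 0.08  # founder divergence from the ancestral monomer
    blocks_per_arm_mean: float = 6.5  # Poisson
    block_size_mean: float = 8.0  # geometric, truncated
    block_size_max: int = 55
    mu: float = 0.03  # substitutions/site per copy event
    tau: float = 0.0  # interchromosomal transfer probability per block
    rho: float = 0.0  # recombinant probability per copy
    kappa: float = 0.0  # probability a block is placed in the centromere
    subtelomere_span: int = 300_000  # distal span receiving blocks (scaled)
    centromere_frac: tuple = (0.45, 0.55)  # centromere interval as chromosome fractions
    cent_monomer_length: int = 150
    cent_copies: int = 400
    cent_mu: float = 0.01
    intra_block_gap: int = 20  # max random spacer between tandem copies
    inter_block_gap: tuple = (2_000, 8_000)  # uniform gap range between blocks
    indel_rate: float = 0.0  # optional small-indel rate per copy event
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("mu", "tau", "rho", "kappa", "cent_mu", "indel_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.monomer is not None and len(self.monomer) < 100:
            raise ValueError("monomer must be at least 100 bp")


@dataclass
class TruthSet:
    units: pd.DataFrame  # chrom,start,end,strand,sequence,lineage,block_id,recombinant,parent_a,parent_b,arm
    blocks: pd.DataFrame  # block_id,chrom,start,end,size,region
    centromeres: pd.DataFrame  # chrom,start,end
    monomer: str
    cent_monomer: str
    lineage_founders: list[str] = field(default_factory=list)

    def per_arm_counts(self) -> pd.DataFrame:
        return (
            self.units.groupby(["chrom", "arm"]).size().rename("n_units").reset_index()
        )

    def arms_per_lineage(self) -> pd.Series:
        df = self.units
        return df.groupby("lineage").apply(
            lambda g: g[["chrom", "arm"]].drop_duplicates().shape[0],
            include_groups=False,
        )

    def to_gff3_records(self) -> list[AnnotationRecord]:
        recs = []
        for _, row in self.units.sort_values(["chrom", "start"]).iterrows():
            recs.append(
                AnnotationRecord(
                    seq_id=row["chrom"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=row["strand"],
                    feature_type="planted_unit",
                    score=0.0,
                    attributes={
                        "Name": f"truth_{row['chrom']}_{int(row['start'])}",
                        "lineage": str(row["lineage"]),
                        "recombinant": str(bool(row["recombinant"])),
                    },
                )
            )
        return recs


_ASCII = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return _ASCII[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each position to a different base with probability rate."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    hit = rng.random(len(arr)) < rate
    idx = np.nonzero(hit)[0]
    if len(idx) == 0:
        return seq
    for i in idx:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def _indel(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    out = []
    for c in seq:
        r = rng.random()
        if r < rate / 2:  # deletion
            continue
        out.append(c)
        if r > 1 - rate / 2:  # insertion of a random base
            out.append(str(_BASES[rng.integers(0, 4)]))
    return "".join(out)


def make_seed_alignment(
    monomer: str, n_rows: int = 20, divergence: float = 0.03, seed: int = 0
) -> list[tuple[str, str]]:
    """Ungapped seed alignment: mutated copies of a monomer."""
    rng = np.random.default_rng(seed)
    return [(f"seed_{i:02d}", mutate(monomer, divergence, rng)) for i in range(n_rows)]


def simulate(params: SimParams) -> tuple[list[GenomeSequence], TruthSet]:
    rng = np.random.default_rng(params.seed)
    monomer = params.monomer or _random_dna(rng, params.monomer_length)
    cent_monomer = _random_dna(rng, params.cent_monomer_length)

    founders = [
        mutate(monomer, params.lineage_divergence, rng)
        for _ in range(params.n_founders)
    ]
    arms = [
        (f"chr{c + 1:02d}", arm) for c in range(params.n_chrom) for arm in ("S", "L")
    ]
    home_arm = {f: arms[f % len(arms)] for f in range(params.n_founders)}
    lineages_on_arm: dict[tuple, list[int]] = {a: [] for a in arms}
    for f, a in home_arm.items():
        lineages_on_arm[a].append(f)

    unit_rows = []
    block_rows = []
    cent_rows = []
    chroms: list[GenomeSequence] = []
    block_counter = 0

    for c in range(params.n_chrom):
        chrom_id = f"chr{c + 1:02d}"
        length = params.chrom_length
        seq = _ASCII[rng.integers(0, 4, size=length)]

        cen_start = int(params.centromere_frac[0] * length)
        cen_end = int(params.centromere_frac[1] * length)
        cent_rows.append({"chrom": chrom_id, "start": cen_start, "end": cen_end})

        # centromeric satellite array in the middle of the centromere span
        array_len = params.cent_copies * params.cent_monomer_length
        array_start = (cen_start + cen_end - array_len) // 2
        cursor = array_start
        for _ in range(params.cent_copies):
            copy = mutate(cent_monomer, params.cent_mu, rng)
            seq[cursor : cursor + len(copy)] = np.frombuffer(copy.encode(), np.uint8)
            cursor += len(copy)

        # plan blocks for the two subtelomeric regions and the centromere
        # kappa blocks overwrite the middle of the centromeric array, so they
        # sit inside the satellite-defined centromere interval
        regions = {
            "S": [1_000, params.subtelomere_span],
            "L": [length - params.subtelomere_span, length - 1_000],
            "C": [array_start + array_len // 8, array_start + 7 * array_len // 8],
        }
        planned: dict[str, list] = {"S": [], "L": [], "C": []}
        for arm in ("S", "L"):
            n_blocks = rng.poisson(params.blocks_per_arm_mean)
            for _ in range(n_blocks):
                if rng.random() < params.tau:
                    foreign = [
                        f
                        for f in range(params.n_founders)
                        if home_arm[f][0] != chrom_id
                    ]
                    lineage = int(rng.choice(foreign)) if foreign else 0
                else:
                    local = lineages_on_arm[(chrom_id, arm)] or [
                        f for f in range(params.n_founders)
                        if home_arm[f][0] == chrom_id
                    ] or list(range(params.n_founders))
                    lineage = int(rng.choice(local))
                size = min(
                    int(rng.geometric(1.0 / params.block_size_mean)),
                    params.block_size_max,
                )
                planned[arm].append((lineage, size))

        # centromere-subtelomere exchange: with probability kappa a block
        # moves into the centromere, but only if its lineage keeps at least
        # one arm block here -- an exchange needs a subtelomeric source
        if params.kappa > 0:
            arm_lineage_counts: dict[int, int] = {}
            for arm in ("S", "L"):
                for lineage, _ in planned[arm]:
                    arm_lineage_counts[lineage] = arm_lineage_counts.get(lineage, 0) + 1
            for arm in ("S", "L"):
                kept = []
                for lineage, size in planned[arm]:
                    if arm_lineage_counts[lineage] >= 2 and rng.random() < params.kappa:
                        planned["C"].append((lineage, size))
                        arm_lineage_counts[lineage] -= 1
                    else:
                        kept.append((lineage, size))
                planned[arm] = kept

        for region, blocks in planned.items():
            lo, hi = regions[region]
            # the centromeric slot is narrow: keep blocks distinct (> the
            # block-calling gap) but compact
            gap_range = params.inter_block_gap if region != "C" else (700, 1_500)
            cursor = lo
            for lineage, size in blocks:
                cursor += int(rng.integers(*gap_range))
                strand = "+" if rng.random() < 0.5 else "-"
                members: list[dict] = []
                rep = founders[lineage]
                block_id = f"B{block_counter:04d}"
                for _ in range(size):
                    if members and rng.random() < params.rho:
                        others = [f for f in range(params.n_founders) if f != lineage]
                        other = int(rng.choice(others))
                        lo_bp = int(0.2 * len(rep))
                        hi_bp = int(0.8 * len(rep))
                        bp = int(rng.integers(lo_bp, hi_bp))
                        mosaic = founders[lineage][:bp] + founders[other][bp:]
                        copy = mutate(mosaic, params.mu, rng)
                        rec = {"recombinant": True, "parent_a": lineage,
                               "parent_b": other}
                    else:
                        src = members[rng.integers(0, len(members))]["monomer_seq"] \
                            if members else rep
                        copy = mutate(src, params.mu, rng)
                        rec = {"recombinant": False, "parent_a": lineage,
                               "parent_b": -1}
                    copy = _indel(copy, params.indel_rate, rng)
                    members.append({"monomer_seq": copy, **rec})

                block_start = cursor
                for m in members:
                    planted = (
                        m["monomer_seq"] if strand == "+"
                        else reverse_complement(m["monomer_seq"])
                    )
                    end = cursor + len(planted)
                    if end > hi:
                        raise ValueError(
                            f"{chrom_id}{region}: blocks overflow the region; "
                            "reduce block counts or sizes"
                        )
                    seq[cursor:end] = np.frombuffer(planted.encode(), np.uint8)
                    unit_rows.append(
                        {
                            "chrom": chrom_id,
                            "start": cursor,
                            "end": end,
                            "strand": strand,
                            "sequence": planted,
                            "lineage": lineage,
                            "block_id": block_id,
                            "recombinant": m["recombinant"],
                            "parent_a": m["parent_a"],
                            "parent_b": m["parent_b"],
                            "arm": region,
                        }
                    )
                    cursor = end + int(rng.integers(0, params.intra_block_gap + 1))
                block_rows.append(
                    {
                        "block_id": block_id,
                        "chrom": chrom_id,
                        "start": block_start,
                        "end": unit_rows[-1]["end"],
                        "size": size,
                        "region": region,
                    }
                )
                block_counter += 1

        chroms.append(
            GenomeSequence(id=chrom_id, residues=seq.tobytes().decode("ascii"))
        )

    units = pd.DataFrame(unit_rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    truth = TruthSet(
        units=units,
        blocks=pd.DataFrame(block_rows),
        centromeres=pd.DataFrame(cent_rows),
        monomer=monomer,
        cent_monomer=cent_monomer,
        lineage_founders=founders,
    )
    return chroms, truth


def truth_compare(
    truth: TruthSet,
    called: list,
    slack: int = 10,
) -> tuple[float, float, float]:
    """(recall, precision, boundary MAE) of calls against planted units.

    A call matches a truth unit when the intervals overlap at least 50%
    reciprocally; matching is one-to-one, greedy by overlap.  ``called``
    accepts AnnotationRecords, UnitHits, or (seq_id, start, end) tuples.
    """
    def coords(obj):
        if isinstance(obj, tuple):
            return obj
        return (obj.seq_id, obj.start, obj.end)

    calls = [coords(c) for c in called]
    truth_units = list(
        truth.units[["chrom", "start", "end"]].itertuples(index=False, name=None)
    )
    cand = []
    for ti, (tc, ts, te) in enumerate(truth_units):
        for ci, (cc, cs, ce) in enumerate(calls):
            if cc != tc:
                continue
            ov = min(te, ce) - max(ts, cs)
            if ov <= 0:
                continue
            if ov / (te - ts) >= 0.5 and ov / (ce - cs) >= 0.5:
                cand.append((ov, ti, ci))
    cand.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_t: set[int] = set()
    used_c: set[int] = set()
    errors = []
    for ov, ti, ci in cand:
        if ti in used_t or ci in used_c:
            continue
        used_t.add(ti)
        used_c.add(ci)
        tc, ts, te = truth_units[ti]
        cc, cs, ce = calls[ci]
        errors.append((abs(ts - cs) + abs(te - ce)) / 2.0)
    recall = len(used_t) / len(truth_units) if truth_units else 1.0
    precision = len(used_c) / len(calls) if calls else 1.0
    mae = float(np.mean(errors)) if errors else 0.0
    return recall, precision, mae
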