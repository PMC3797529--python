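"""End-to-end orchestration: profile -> scan -> filter -> regions -> names ->
recombination screen -> implied MSA -> tree -> clades -> concordance [-> QC].

All randomness flows from one root seed, split per stage.  A manifest of
every written file (with sha256 checksums) makes runs auditable and lets
reproducibility be asserted as checksum equality.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    block_region,
    concordance,
    io_core,
    phylogeny,
    profile_model,
    recomb_screen,
    repeat_scanner,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    genome: str | None = None
    seed_alignment: str | None = None
    cent_repeats: str | None = None
    contigs: str | None = None
    out_dir: str = "satscan_out"
    prefix: str = "Pv"
    # profile
    gap_col_threshold: float = 0.5
    pseudocount: float = 1.0
    # scan
    min_score_frac: float = repeat_scanner.DEFAULT_MIN_SCORE_FRAC
    seed_k: int = repeat_scanner.DEFAULT_SEED_K
    min_seeds: int = repeat_scanner.DEFAULT_MIN_SEEDS
    max_gap: int = repeat_scanner.DEFAULT_MAX_GAP
    min_len: int = repeat_scanner.DEFAULT_MIN_LEN
    # centromere
    cent_min_identity: float = block_region.DEFAULT_CENT_MIN_IDENTITY
    cent_merge_gap: int = block_region.DEFAULT_CENT_MERGE_GAP
    # recombination screen
    alpha: float = recomb_screen.DEFAULT_ALPHA
    min_margin: int = recomb_screen.DEFAULT_MIN_MARGIN
    triplet_cap: int = recomb_screen.DEFAULT_TRIPLET_CAP
    # phylogeny
    n_reps: int = phylogeny.DEFAULT_N_REPS
    min_support: float = phylogeny.DEFAULT_MIN_SUPPORT
    min_size_frac: float = phylogeny.DEFAULT_MIN_SIZE_FRAC
    seed: int = 1

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class PipelineResult:
    config: RunConfig
    profile: profile_model.ProfileModel
    hits: list
    retained: list
    filter_report: repeat_scanner.FilterReport
    records: list
    centromeres: dict
    blocks: list
    count_matrix: pd.DataFrame
    msa: phylogeny.ImpliedMSA
    removed: set
    recomb_calls: list
    tree: object
    clades: list
    unplaced: list
    cross_table: pd.DataFrame
    metrics: object
    exchange: object
    manifest: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(
    config: RunConfig,
    genome: list | None = None,
    seed_alignment: profile_model.SeedAlignment | None = None,
    cent_repeats: list | None = None,
) -> PipelineResult:
    """Run every stage.  In-memory inputs override the configured paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(path: Path):
        written.append(path)
        return path

    if genome is None:
        if config.genome is None:
            raise ValueError("no genome given")
        genome = io_core.read_fasta(config.genome)
    if seed_alignment is None:
        if config.seed_alignment is None:
            raise ValueError("no seed alignment given")
        seed_alignment = profile_model.read_seed_alignment(config.seed_alignment)
    if cent_repeats is None and config.cent_repeats is not None:
        cent_repeats = io_core.read_fasta(config.cent_repeats)

    rng = np.random.default_rng(config.seed)
    stage_seeds = {
        name: int(rng.integers(0, 2**31 - 1))
        for name in ("screen", "bootstrap")
    }

    # --- profile
    profile = profile_model.build_profile(
        seed_alignment,
        gap_col_threshold=config.gap_col_threshold,
        pseudocount=config.pseudocount,
    )
    profile.to_tsv(emit(out / "profile.tsv"))
    min_score = config.min_score_frac * profile.self_score
    logger.info("profile: L=%d, self-score %.1f bits, threshold %.1f",
                profile.length, profile.self_score, min_score)

    # --- scan and filter
    hits = repeat_scanner.scan_genome(
        profile, genome, min_score=min_score,
        seed_k=config.seed_k, min_seeds=config.min_seeds,
    )
    raw_blocks = repeat_scanner.call_raw_blocks(hits, max_gap=config.max_gap)
    retained, report = repeat_scanner.filter_units(raw_blocks, min_len=config.min_len)
    report.to_tsv(emit(out / "filter_report.tsv"))
    logger.info("scan: %d raw hits in %d blocks; %d retained",
                report.n_raw, len(raw_blocks), report.n_retained)

    # --- centromeres and arms
    centromeres: dict[str, block_region.CentromereInterval | None] = {}
    chrom_len = {g.id: g.length for g in genome}
    for g in genome:
        centromeres[g.id] = (
            block_region.locate_centromere(
                g, cent_repeats,
                min_identity=config.cent_min_identity,
                merge_gap=config.cent_merge_gap,
            )
            if cent_repeats
            else None
        )
    arms = []
    for h in retained:
        arms.extend(
            block_region.assign_arms([h], centromeres[h.seq_id],
                                     chrom_length=chrom_len[h.seq_id])
        )

    # --- names and annotations
    records = repeat_scanner.assign_names(retained, arms, prefix=config.prefix)
    io_core.write_gff3(records, emit(out / "units.gff3"))
    names = [r.name for r in records]
    locations = {r.name: r.attributes["location"] for r in records}

    # --- blocks and count matrix
    blocks = block_region.call_blocks(retained, max_gap=config.max_gap, names=names)
    blocks_df = pd.DataFrame(
        [
            {"block_id": i, "seq_id": b.seq_id, "start": b.start, "end": b.end,
             "size": b.size}
            for i, b in enumerate(blocks)
        ]
    )
    blocks_df.to_csv(emit(out / "blocks.tsv"), sep="\t", index=False)
    block_region.block_size_histogram(blocks).to_csv(
        emit(out / "block_size_histogram.tsv"), sep="\t", index=False
    )
    matrix = block_region.count_matrix(
        [(h.seq_id, a) for h, a in zip(retained, arms)],
        chrom_order=[g.id for g in genome],
    )
    matrix.to_csv(emit(out / "count_matrix.tsv"), sep="\t")

    # --- implied MSA and recombination screen
    msa = phylogeny.implied_msa(
        profile, retained, names=names, arms=[locations[n] for n in names]
    )
    removed, calls = recomb_screen.screen_all(
        msa.names, msa.rows,
        alpha=config.alpha, min_margin=config.min_margin,
        n_triplets_cap=config.triplet_cap, seed=stage_seeds["screen"],
    )
    msa.write_fasta(emit(out / "msa.fasta"))
    with open(emit(out / "removed_recombinants.txt"), "w") as fh:
        for name in sorted(removed):
            fh.write(name + "\n")
    logger.info("recombination screen: %d/%d units removed", len(removed),
                len(msa.names))

    keep_idx = [i for i, n in enumerate(msa.names) if n not in removed]
    analyzed_names = [msa.names[i] for i in keep_idx]
    analyzed_rows = msa.rows[keep_idx]

    # --- tree, clades, concordance
    tree = phylogeny.bootstrap_support(
        analyzed_names, analyzed_rows, n_reps=config.n_reps,
        seed=stage_seeds["bootstrap"],
    )
    io_core.write_newick(tree, emit(out / "tree.nwk"))
    min_size = max(2, int(np.ceil(config.min_size_frac * len(analyzed_names))))
    clades, unplaced = phylogeny.extract_major_clades(
        tree, min_support=config.min_support, min_size=min_size, arm_of=locations
    )
    clade_df = pd.DataFrame(
        [
            {"clade": c.clade_id, "unit": m, "location": locations[m],
             "support": c.support}
            for c in clades
            for m in c.members
        ]
    )
    clade_df.to_csv(emit(out / "clades.tsv"), sep="\t", index=False)

    table = concordance.cross_tab(clades, locations) if clades else pd.DataFrame()
    if not table.empty:
        table.to_csv(emit(out / "clade_location_table.tsv"), sep="\t")
        metrics = concordance.spread_metrics(table)
        metrics.to_frame().to_csv(emit(out / "spread_metrics.tsv"), sep="\t",
                                  index=False)
        exchange = concordance.centromere_exchange(table)
        exchange.to_frame().to_csv(emit(out / "centromere_exchange.tsv"), sep="\t",
                                   index=False)
    else:
        metrics = None
        exchange = concordance.ExchangeReport()

    config.to_json(emit(out / "config.json"))
    manifest = {
        str(p.relative_to(out)): _sha256(p) for p in written
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return PipelineResult(
        config=config,
        profile=profile,
        hits=hits,
        retained=retained,
        filter_report=report,
        records=records,
        centromeres=centromeres,
        blocks=blocks,
        count_matrix=matrix,
        msa=msa,
        removed=removed,
        recomb_calls=calls,
        tree=tree,
        clades=clades,
        unplaced=unplaced,
        cross_table=table,
        metrics=metrics,
        exchange=exchange,
        manifest=manifest,
    )
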