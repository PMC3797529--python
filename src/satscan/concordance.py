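"""Clade-by-location concordance: spreading, local duplication, exchange.

Cross-tabulating phylogenetic clades against chromosome-arm locations
quantifies the two expansion modes of a subtelomeric satellite: a clade
present on many arms indicates interchromosomal spreading, while a clade
dominated by a single arm indicates local (tandem) duplication.  Clades
mixing centromere-assigned and arm-assigned units witness
centromere-subtelomere exchange.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .phylogeny import CladeRecord

SPREAD_MIN_ARMS = 2
LOCAL_DOMINANCE = 0.8


def cross_tab(clades: list[CladeRecord], locations: dict[str, str]) -> pd.DataFrame:
    """Contingency table clade x location (location like '04S', '08C').

    Every clade member must have a location; marginals equal the input
    counts by construction.
    """
    rows = []
    for clade in clades:
        for member in clade.members:
            if member not in locations:
                raise ValueError(f"unit {member} has no location assignment")
            rows.append((clade.clade_id, locations[member]))
    if not rows:
        return pd.DataFrame()
    df = pd.DataFrame(rows, columns=["clade", "location"])
    table = pd.crosstab(df["clade"], df["location"])
    return table


@dataclass
class SpreadMetrics:
    arms_per_clade: dict[str, int]
    clades_per_arm: dict[str, int]
    dominance: dict[str, float]
    n_spread_clades: int = 0
    n_local_clades: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"clade": c, "n_arms": self.arms_per_clade[c],
             "dominance": self.dominance[c]}
            for c in sorted(self.arms_per_clade)
        ]
        return pd.DataFrame(rows)


def spread_metrics(
    table: pd.DataFrame,
    spread_min_arms: int = SPREAD_MIN_ARMS,
    local_dominance: float = LOCAL_DOMINANCE,
) -> SpreadMetrics:
    """Per-clade arm occupancy and dominance; per-arm clade diversity."""
    if table.empty:
        raise ValueError("empty clade-location table")
    arms_per_clade = (table > 0).sum(axis=1).to_dict()
    clades_per_arm = (table > 0).sum(axis=0).to_dict()
    dominance = (table.max(axis=1) / table.sum(axis=1)).to_dict()
    return SpreadMetrics(
        arms_per_clade=arms_per_clade,
        clades_per_arm=clades_per_arm,
        dominance=dominance,
        n_spread_clades=sum(1 for v in arms_per_clade.values() if v >= spread_min_arms),
        n_local_clades=sum(1 for v in dominance.values() if v >= local_dominance),
    )


@dataclass
class ExchangeReport:
    """Clades containing both centromeric and arm (S/L) units."""

    flagged: list[dict] = field(default_factory=list)
    all_c_in_one_clade: bool = False
    n_centromeric_units: int = 0

    def to_frame(self) -> pd.DataFrame:
        if not self.flagged:
            return pd.DataFrame(
                columns=["clade", "n_centromeric", "co_occurring_arms"]
            )
        return pd.DataFrame(self.flagged)


def centromere_exchange(table: pd.DataFrame) -> ExchangeReport:
    """Identify clades witnessing centromere-subtelomere sequence exchange.

    Centromeric locations are those whose label ends in 'C'.
    """
    if table.empty:
        return ExchangeReport()
    c_cols = [c for c in table.columns if str(c).endswith("C")]
    arm_cols = [c for c in table.columns if not str(c).endswith("C")]
    if not c_cols:
        return ExchangeReport()
    c_counts = table[c_cols].sum(axis=1)
    arm_counts = table[arm_cols].sum(axis=1) if arm_cols else 0 * c_counts
    flagged = []
    for clade in table.index:
        if c_counts[clade] > 0 and arm_counts[clade] > 0:
            arms = [c for c in arm_cols if table.loc[clade, c] > 0]
            flagged.append(
                {
                    "clade": clade,
                    "n_centromeric": int(c_counts[clade]),
                    "co_occurring_arms": ",".join(map(str, arms)),
                }
            )
    clades_with_c = (c_counts > 0).sum()
    return ExchangeReport(
        flagged=flagged,
        all_c_in_one_clade=bool(clades_with_c == 1),
        n_centromeric_units=int(c_counts.sum()),
    )
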