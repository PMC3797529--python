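"""Triplet maximum chi-square screening for recombinant (mosaic) monomers.

For a candidate child and two parents, aligned columns where the parents
differ and the child matches one of them are informative.  At every
candidate breakpoint the 2x2 table (left/right of breakpoint x child
matches parent A / parent B) is scored by chi-square with continuity
correction; the maximizing breakpoint is the putative crossover.  Children
whose Bonferroni-corrected p-value falls at or below alpha are removed
before tree building, since mosaics violate the single-tree assumption.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2 as chi2_dist

DEFAULT_ALPHA = 0.001
DEFAULT_MIN_MARGIN = 20
DEFAULT_TRIPLET_CAP = 200_000


@dataclass
class RecombinationCall:
    child: str
    parent_a: str
    parent_b: str
    breakpoint: int
    chi2: float
    p_raw: float
    p_corrected: float
    accepted: bool


def _chi2_cc(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Vectorized 2x2 chi-square with Yates continuity correction."""
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    denom = r1 * r2 * c1 * c2
    num = np.abs(a * d - b * c) - n / 2.0
    num = np.clip(num, 0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(denom > 0, n * num**2 / denom, 0.0)
    return stat


def max_chi2_triplet(
    child: str | np.ndarray,
    parent_a: str | np.ndarray,
    parent_b: str | np.ndarray,
    min_margin: int = DEFAULT_MIN_MARGIN,
) -> tuple[int, float, float] | None:
    """Scan all breakpoints; return (breakpoint, chi2, p_raw) or None.

    The breakpoint index b splits the alignment into columns [0, b) and
    [b, n).  Only columns where the parents differ and the child matches
    exactly one parent count; candidate breakpoints must leave at least
    ``min_margin`` informative columns on each side (margins in
    informative-column space, as in polymorphic-site scans: small-count
    edge tables are the statistic's classic false-positive mode).  Returns
    None (no-call) when fewer than 2*min_margin informative columns exist.
    """
    if min_margin < 10:
        raise ValueError("min_margin must be >= 10")
    ch = np.asarray(list(child)) if isinstance(child, str) else np.asarray(child)
    pa = np.asarray(list(parent_a)) if isinstance(parent_a, str) else np.asarray(parent_a)
    pb = np.asarray(list(parent_b)) if isinstance(parent_b, str) else np.asarray(parent_b)
    if not (len(ch) == len(pa) == len(pb)):
        raise ValueError("aligned sequences must have equal length")
    n = len(ch)

    valid = np.isin(ch, list("ACGT")) & np.isin(pa, list("ACGT")) & np.isin(pb, list("ACGT"))
    informative = valid & (pa != pb) & ((ch == pa) | (ch == pb))
    match_a = informative & (ch == pa)
    match_b = informative & (ch == pb)
    if informative.sum() < 2 * min_margin:
        return None

    cum_a = np.concatenate([[0], np.cumsum(match_a)]).astype(float)
    cum_b = np.concatenate([[0], np.cumsum(match_b)]).astype(float)
    tot_a, tot_b = cum_a[-1], cum_b[-1]

    cum_inf = np.concatenate([[0], np.cumsum(informative)])
    total_inf = cum_inf[-1]
    all_bps = np.arange(1, n)
    ok = (cum_inf[all_bps] >= min_margin) & (
        total_inf - cum_inf[all_bps] >= min_margin
    )
    bps = all_bps[ok]
    if bps.size == 0:
        return None
    left_a = cum_a[bps]
    left_b = cum_b[bps]
    stats = _chi2_cc(left_a, left_b, tot_a - left_a, tot_b - left_b)
    best = int(np.argmax(stats))  # first occurrence -> smallest breakpoint
    chi2 = float(stats[best])
    p_raw = float(chi2_dist.sf(chi2, df=1))
    return int(bps[best]), chi2, p_raw


def screen_all(
    names: list[str],
    rows: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    min_margin: int = DEFAULT_MIN_MARGIN,
    n_triplets_cap: int = DEFAULT_TRIPLET_CAP,
    seed: int = 0,
    dedup_eps: float = 0.02,
) -> tuple[set[str], list[RecombinationCall]]:
    """Screen every unit as a potential mosaic of two neighbors.

    Parent candidates per child are its two nearest and two furthest
    neighbors by p-distance; all pairs among those four form the tested
    triplets.  Two refinements make the heuristic robust: neighbors within
    ``dedup_eps`` of the child are skipped when filling the nearest slots
    (a near-identical copy is the child's sibling, not a plausible parent),
    and the second far candidate is chosen maximin -- maximizing its
    minimum distance to both the child and the first far candidate -- so
    that when two divergent source lineages exist, both are represented.
    When the total exceeds ``n_triplets_cap`` a seeded random subsample is
    tested.  Bonferroni correction uses the number of triplets actually
    tested.
    """
    n = len(names)
    if n < 3:
        raise ValueError("need at least 3 sequences")
    from .phylogeny import p_distance_matrix

    rows = np.asarray(rows)
    p = p_distance_matrix(rows)

    triplets: list[tuple[int, int, int]] = []
    for child in range(n):
        order = np.argsort(p[child])
        others = [int(i) for i in order if i != child]
        near = [i for i in others if p[child, i] >= dedup_eps][:2] or others[:2]
        far1 = others[-1]
        far2 = max(
            (i for i in others if i != far1),
            key=lambda i: (min(p[child, i], p[far1, i]), i),
        )
        cand = list(dict.fromkeys(near + [far1, far2]))
        for i in range(len(cand)):
            for j in range(i + 1, len(cand)):
                triplets.append((child, cand[i], cand[j]))
    if len(triplets) > n_triplets_cap:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(triplets), size=n_triplets_cap, replace=False)
        triplets = [triplets[i] for i in sorted(idx)]

    n_tests = len(triplets)
    calls: list[RecombinationCall] = []
    removal: set[str] = set()
    for child, a, b in triplets:
        res = max_chi2_triplet(rows[child], rows[a], rows[b], min_margin=min_margin)
        if res is None:
            continue
        bp, chi2, p_raw = res
        p_corr = min(1.0, p_raw * n_tests)
        accepted = p_corr <= alpha
        calls.append(
            RecombinationCall(
                child=names[child],
                parent_a=names[a],
                parent_b=names[b],
                breakpoint=bp,
                chi2=chi2,
                p_raw=p_raw,
                p_corrected=p_corr,
                accepted=accepted,
            )
        )
        if accepted:
            removal.add(names[child])
    return removal, calls
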