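"""Profile-anchored MSA, Jukes-Cantor distances, neighbor joining, clades.

Every retained unit is anchored to the profile's match positions by its
glocal alignment, so all units share one column space without progressive
alignment (insertions relative to the profile are discarded, deletions
become gaps).  Pairwise distances use the Jukes-Cantor correction of the
p-distance computed with pairwise deletion of gapped sites.  Trees are
built by canonical neighbor joining with deterministic tie-breaks, and
internal-edge support comes from column-bootstrap replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

from .profile_model import ProfileModel, score_glocal
from .repeat_scanner import UnitHit

logger = logging.getLogger(__name__)

JC_SATURATION_CAP = 5.0
DEFAULT_N_REPS = 100
DEFAULT_MIN_SUPPORT = 0.75
DEFAULT_MIN_SIZE_FRAC = 0.02


@dataclass
class ImpliedMSA:
    """Units anchored to the profile's L match positions."""

    names: list[str]
    rows: np.ndarray  # (n, L) array of single characters incl. '-'
    arms: list[str] = field(default_factory=list)  # optional location labels

    @property
    def n_columns(self) -> int:
        return self.rows.shape[1]

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, row in zip(self.names, self.rows):
                fh.write(f">{name}\n{''.join(row)}\n")


def implied_msa(
    profile: ProfileModel,
    units: list[UnitHit],
    names: list[str] | None = None,
    arms: list[str] | None = None,
    min_aligned_frac: float = 0.5,
) -> ImpliedMSA:
    """Map each unit onto the profile columns via its glocal alignment.

    Units with fewer than ``min_aligned_frac`` of columns aligned are
    excluded with a warning.
    """
    if names is None:
        names = [f"{u.seq_id}:{u.start}-{u.end}" for u in units]
    keep_names, keep_rows, keep_arms = [], [], []
    for i, unit in enumerate(units):
        aln = unit.alignment or score_glocal(profile, unit.sequence)
        cols = aln.aligned_columns
        aligned = sum(c != "-" for c in cols)
        if aligned < min_aligned_frac * profile.length:
            logger.warning("unit %s: only %d/%d columns aligned; excluded",
                           names[i], aligned, profile.length)
            continue
        keep_names.append(names[i])
        keep_rows.append(list(cols))
        if arms is not None:
            keep_arms.append(arms[i])
    return ImpliedMSA(
        names=keep_names,
        rows=np.array(keep_rows, dtype="<U1"),
        arms=keep_arms,
    )


def p_distance_matrix(rows: np.ndarray) -> np.ndarray:
    """Pairwise p-distance with pairwise deletion of gap/N sites."""
    bases = "ACGT"
    valid = np.isin(rows, list(bases)).astype(np.float64)
    matches = np.zeros((rows.shape[0],) * 2)
    for b in bases:
        m = (rows == b).astype(np.float64)
        matches += m @ m.T
    shared = valid @ valid.T
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(shared > 0, 1.0 - matches / shared, 0.0)
    p = np.clip(p, 0.0, 1.0)
    np.fill_diagonal(p, 0.0)
    return p


def jc_distance(p):
    """Jukes-Cantor distance d = -(3/4) ln(1 - 4p/3), capped at saturation.

    Accepts a scalar or array; p >= 0.75 maps to the cap (5.0
    substitutions/site).  p outside [0, 1] is an error.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("p must be in [0, 1]")
    safe = np.where(arr < 0.75, arr, 0.0)
    d = np.where(arr < 0.75, -0.75 * np.log1p(-4.0 * safe / 3.0), JC_SATURATION_CAP)
    if np.isscalar(p) or arr.ndim == 0:
        return float(d)
    return d


def jc_distance_matrix(rows: np.ndarray) -> np.ndarray:
    return jc_distance(p_distance_matrix(rows))


def nj_tree(dm: np.ndarray, ids: list[str]) -> TreeNode:
    """Canonical neighbor joining; deterministic smallest-index tie-break.

    Returns an unrooted tree (trifurcating root).  Negative branch-length
    estimates are clamped to zero.
    """
    dm = np.asarray(dm, dtype=float)
    if dm.shape[0] != dm.shape[1] or not np.allclose(dm, dm.T):
        raise ValueError("distance matrix must be square and symmetric")
    n = dm.shape[0]
    if n < 3:
        raise ValueError("need at least 3 taxa")
    nodes = [TreeNode(name=i) for i in ids]
    d = dm.copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        iu = np.triu_indices(m, k=1)
        flat = q[iu]
        best = int(np.argmin(flat))  # first occurrence = smallest (i, j)
        i, j = int(iu[0][best]), int(iu[1][best])

        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        parent = TreeNode()
        a, b = nodes[i], nodes[j]
        a.length = max(0.0, li)
        b.length = max(0.0, lj)
        parent.append(a)
        parent.append(b)

        du = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        new_d = np.empty((m - 1, m - 1))
        new_d[:-1, :-1] = d[np.ix_(keep, keep)]
        new_d[-1, :-1] = du[keep]
        new_d[:-1, -1] = du[keep]
        new_d[-1, -1] = 0.0
        d = new_d
        nodes = [nodes[x] for x in keep] + [parent]

    # three-point termination (unrooted trifurcation)
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    root = TreeNode()
    for node, ln in zip(nodes, (la, lb, lc)):
        node.length = max(0.0, ln)
        root.append(node)
    return root


def midpoint_root(tree: TreeNode) -> TreeNode:
    return tree.copy().root_at_midpoint()


def _bipartitions(tree: TreeNode) -> set[frozenset]:
    """Canonical bipartitions (smaller side; lexicographic on ties)."""
    all_leaves = frozenset(t.name for t in tree.tips())
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        canonical = min(side, all_leaves - side,
                        key=lambda s: (len(s), tuple(sorted(s))))
        parts.add(canonical)
    return parts


def bootstrap_support(
    names: list[str],
    rows: np.ndarray,
    n_reps: int = DEFAULT_N_REPS,
    seed: int = 0,
) -> TreeNode:
    """NJ tree of the full MSA with column-bootstrap supports.

    Support of an internal edge = fraction of replicates whose NJ tree
    contains the same bipartition of the leaf set.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rows = np.asarray(rows)
    n, L = rows.shape
    main = nj_tree(jc_distance_matrix(rows), names)

    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        rep_tree = nj_tree(jc_distance_matrix(rows[:, cols]), names)
        for part in _bipartitions(rep_tree):
            counts[part] = counts.get(part, 0) + 1

    all_leaves = frozenset(names)
    for node in main.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        canonical = min(side, all_leaves - side,
                        key=lambda s: (len(s), tuple(sorted(s))))
        node.support = counts.get(canonical, 0) / n_reps
        node.name = f"{node.support:g}"
    return main


@dataclass
class CladeRecord:
    clade_id: str
    members: list[str]
    support: float
    arm_composition: dict[str, int] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.members)


def _clade_labels():
    import itertools
    import string

    for size in range(1, 3):
        for combo in itertools.product(string.ascii_uppercase, repeat=size):
            yield "".join(combo)


def extract_major_clades(
    tree: TreeNode,
    min_support: float = DEFAULT_MIN_SUPPORT,
    min_size: int = 2,
    arm_of: dict[str, str] | None = None,
) -> tuple[list[CladeRecord], list[str]]:
    """Greedy extraction of disjoint, well-supported clades from the root.

    A node founds a major clade when its bootstrap support exceeds
    ``min_support`` (strict, honoring a ">X%" reading) and it holds at
    least ``min_size`` leaves; its subtree is then not descended further.
    With a bifurcating root, both root children carry the same edge (one
    bipartition), so "support" attached to the complement of a strong
    clade is an artifact; root children are treated as containers and
    always descended.  Returns (clades labeled A, B, ... by decreasing
    size, unplaced leaves).
    """
    rooted = tree if len(tree.children) == 2 else midpoint_root(tree)
    if len(rooted.children) == 2:
        stack = [c for child in rooted.children for c in child.children]
        stack += [c for c in rooted.children if c.is_tip()]
    else:
        stack = list(rooted.children)
    found = []
    while stack:
        node = stack.pop()
        if node.is_tip():
            continue
        support = getattr(node, "support", None)
        if support is None:
            try:
                support = float(node.name) if node.name else 0.0
            except ValueError:
                support = 0.0
        leaves = [t.name for t in node.tips()]
        if support > min_support and len(leaves) >= min_size:
            found.append((leaves, support))
        else:
            stack.extend(node.children)

    found.sort(key=lambda x: (-len(x[0]), sorted(x[0])))
    clades = []
    placed = set()
    for label, (leaves, support) in zip(_clade_labels(), found):
        comp: dict[str, int] = {}
        if arm_of:
            for leaf in leaves:
                loc = arm_of.get(leaf)
                if loc is not None:
                    comp[loc] = comp.get(loc, 0) + 1
        clades.append(CladeRecord(clade_id=label, members=leaves,
                                  support=support, arm_composition=comp))
        placed.update(leaves)
    unplaced = [t.name for t in rooted.tips() if t.name not in placed]
    return clades, unplaced
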