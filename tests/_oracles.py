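"""Independent oracles used by the acceptance tests.

These deliberately avoid the package's own algorithms: tree topologies are
enumerated exhaustively and fitted by least squares; the chi-square scan is
a naive per-breakpoint loop over scipy's contingency test.
"""

from __future__ import annotations

import collections
import functools

import numpy as np
from scipy.stats import chi2_contingency


# ---------------------------------------------------------------- trees

def enumerate_unrooted_topologies(n: int) -> list[list[tuple[int, int]]]:
    """All (2n-5)!! unrooted binary topologies on leaves 0..n-1.

    Trees are edge lists; internal nodes are numbered from n upward.
    Built by inserting each new leaf into every edge of every smaller tree.
    """
    assert n >= 3
    trees = [[(0, n), (1, n), (2, n)]]
    for leaf in range(3, n):
        mid = n + leaf - 2  # new internal node id at this growth step
        new_trees = []
        for tree in trees:
            for i, (u, v) in enumerate(tree):
                grown = tree[:i] + tree[i + 1 :] + [
                    (u, mid), (mid, v), (leaf, mid)
                ]
                new_trees.append(grown)
        trees = new_trees
    return trees


def _leaf_paths(tree: list[tuple[int, int]], n: int) -> np.ndarray:
    """Incidence matrix: rows = leaf pairs (i<j), cols = edges on the path."""
    adj = collections.defaultdict(list)
    for e, (u, v) in enumerate(tree):
        adj[u].append((v, e))
        adj[v].append((u, e))
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    A = np.zeros((len(pairs), len(tree)))
    for row, (i, j) in enumerate(pairs):
        # DFS from i recording edge paths
        stack = [(i, None, [])]
        seen = {i}
        while stack:
            x, _, path = stack.pop()
            if x == j:
                A[row, path] = 1.0
                break
            for y, e in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append((y, x, path + [e]))
    return A


def tree_bipartitions(tree: list[tuple[int, int]], n: int) -> frozenset:
    """Canonical non-trivial bipartitions of an edge-list tree."""
    adj = collections.defaultdict(list)
    for u, v in tree:
        adj[u].append(v)
        adj[v].append(u)
    parts = set()
    for u, v in tree:
        # leaves on v's side when edge (u, v) is cut
        stack, seen = [v], {u, v}
        side = set()
        while stack:
            x = stack.pop()
            if x < n:
                side.add(x)
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        other = frozenset(range(n)) - frozenset(side)
        if 1 < len(side) < n - 1:
            parts.add(min(frozenset(side), other,
                          key=lambda s: (len(s), tuple(sorted(s)))))
    return frozenset(parts)


@functools.lru_cache(maxsize=None)
def _ls_machinery(n: int):
    """Per-n cache: topologies, their residual projectors, bipartitions."""
    topologies = enumerate_unrooted_topologies(n)
    projectors = []
    biparts = []
    for tree in topologies:
        A = _leaf_paths(tree, n)
        P = A @ np.linalg.pinv(A)
        projectors.append(P)
        biparts.append(tree_bipartitions(tree, n))
    return topologies, np.array(projectors), biparts


def least_squares_best_topology(dm: np.ndarray) -> frozenset:
    """Bipartition set of the LS-optimal topology by exhaustive search."""
    n = dm.shape[0]
    _, projectors, biparts = _ls_machinery(n)
    iu = np.triu_indices(n, k=1)
    d = dm[iu]
    fitted = np.einsum("tij,j->ti", projectors, d)
    residuals = ((fitted - d) ** 2).sum(axis=1)
    return biparts[int(np.argmin(residuals))]


# ---------------------------------------------------------- chi-square

def naive_max_chi2(child: str, pa: str, pb: str, min_margin: int = 20):
    """Brute-force maximum chi-square scan (scipy per breakpoint).

    Candidate breakpoints must leave >= min_margin informative columns on
    each side.
    """
    n = len(child)
    informative = [
        i for i in range(n) if pa[i] != pb[i] and child[i] in (pa[i], pb[i])
    ]
    if len(informative) < 2 * min_margin:
        return None
    best = None
    for b in range(1, n):
        n_left = sum(1 for i in informative if i < b)
        if n_left < min_margin or len(informative) - n_left < min_margin:
            continue
        a = sum(1 for i in informative if i < b and child[i] == pa[i])
        bb = sum(1 for i in informative if i < b and child[i] == pb[i])
        c = sum(1 for i in informative if i >= b and child[i] == pa[i])
        d = sum(1 for i in informative if i >= b and child[i] == pb[i])
        table = np.array([[a, bb], [c, d]])
        if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
            stat = 0.0
        else:
            stat = chi2_contingency(table, correction=True)[0]
        if best is None or stat > best[1]:
            best = (b, stat)
    return best
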