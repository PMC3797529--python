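import numpy as np
import pytest

from satscan.phylogeny import (
    _bipartitions,
    bootstrap_support,
    extract_major_clades,
    implied_msa,
    jc_distance,
    jc_distance_matrix,
    nj_tree,
    p_distance_matrix,
)
from satscan.profile_model import score_glocal
from satscan.repeat_scanner import UnitHit
from satscan.synthetic_genome import mutate


def _unit(profile, seq):
    return UnitHit("c1", 0, len(seq), "+", 0.0, seq,
                   alignment=score_glocal(profile, seq))


class TestImpliedMsa:
    def test_consensus_maps_gap_free(self, default_profile):
        msa = implied_msa(default_profile, [_unit(default_profile,
                                                  default_profile.consensus)])
        assert "".join(msa.rows[0]) == default_profile.consensus

    def test_deletion_becomes_gap_with_correct_anchoring(self, default_profile):
        cons = default_profile.consensus
        deleted = cons[:100] + cons[101:]
        msa = implied_msa(default_profile, [_unit(default_profile, deleted)])
        row = "".join(msa.rows[0])
        assert row.count("-") == 1
        gap_pos = row.index("-")
        assert abs(gap_pos - 100) <= 2  # adjacent identical bases can shift it
        without_gap = row.replace("-", "")
        assert without_gap == deleted

    def test_substitution_count_preserved_between_rows(self, default_profile):
        rng = np.random.default_rng(2)
        cons = default_profile.consensus
        positions = rng.choice(len(cons), size=10, replace=False)
        mutated = list(cons)
        for p in positions:
            mutated[p] = next(b for b in "ACGT" if b != cons[p])
        msa = implied_msa(
            default_profile,
            [_unit(default_profile, cons), _unit(default_profile, "".join(mutated))],
        )
        diffs = (msa.rows[0] != msa.rows[1]).sum()
        assert diffs == 10

    def test_barely_alignable_unit_excluded(self, default_profile):
        rng = np.random.default_rng(3)
        junk = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 100)])
        msa = implied_msa(
            default_profile,
            [_unit(default_profile, default_profile.consensus),
             _unit(default_profile, junk)],
        )
        assert len(msa.names) == 1


class TestJukesCantor:
    def test_identity(self):
        assert jc_distance(0.0) == 0.0

    def test_closed_form_value(self):
        assert jc_distance(0.1) == pytest.approx(0.107326, abs=1e-6)

    def test_saturation_capped(self):
        assert jc_distance(0.75) == 5.0
        assert jc_distance(0.9) == 5.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            jc_distance(-0.01)
        with pytest.raises(ValueError):
            jc_distance(1.01)

    def test_correction_exceeds_p(self):
        grid = np.arange(0.01, 0.75, 0.01)
        assert (jc_distance(grid) > grid).all()


def _dist_from_tree(edges, n_leaves):
    """Path-length matrix of a tree given as {(u, v): length}."""
    import collections

    adj = collections.defaultdict(list)
    for (u, v), w in edges.items():
        adj[u].append((v, w))
        adj[v].append((u, w))
    d = np.zeros((n_leaves, n_leaves))
    for src in range(n_leaves):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            x = stack.pop()
            for y, w in adj[x]:
                if y not in dist:
                    dist[y] = dist[x] + w
                    stack.append(y)
        for dst in range(n_leaves):
            d[src, dst] = dist[dst]
    return d


class TestNeighborJoining:
    def test_four_taxon_additive_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:1)) as an edge set with internal nodes 4,5
        edges = {(0, 4): 1.0, (1, 4): 2.0, (4, 5): 1.0, (2, 5): 3.0, (3, 5): 1.0}
        d = _dist_from_tree(edges, 4)
        tree = nj_tree(d, list("ABCD"))
        parts = _bipartitions(tree)
        assert frozenset({"A", "B"}) in parts
        # branch lengths exact: leaf edges 1,2,3,1
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0, "D": 1.0})

    def test_three_taxon_point_formulas(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = nj_tree(d, list("ABC"))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)

    def test_equal_distances_resolved_deterministically(self):
        d = np.ones((5, 5)) - np.eye(5)
        t1 = nj_tree(d, list("ABCDE"))
        t2 = nj_tree(d, list("ABCDE"))
        assert str(t1) == str(t2)

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1, 2], [1, 0, 3], [2, 3.5, 0]])
        with pytest.raises(ValueError):
            nj_tree(d, list("ABC"))

    def test_matches_scikit_bio_on_random_additive_matrices(self):
        """Independent cross-check against scikit-bio's NJ implementation."""
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(4)
        for _ in range(10):
            n = int(rng.integers(4, 9))
            d = _random_additive_matrix(rng, n)
            ids = [f"t{i}" for i in range(n)]
            ours = _bipartitions(nj_tree(d, ids))
            theirs = _bipartitions(skbio_nj(DistanceMatrix(d, ids)))
            assert ours == theirs


def _random_additive_matrix(rng, n):
    """Distances from a random binary tree with positive edge lengths."""
    edges = {}
    next_node = n
    # start from a 3-leaf star
    center = next_node
    next_node += 1
    for leaf in range(3):
        edges[(leaf, center)] = float(rng.uniform(0.1, 1.0))
    for leaf in range(3, n):
        u, v = list(edges)[rng.integers(0, len(edges))]
        w = edges.pop((u, v))
        mid = next_node
        next_node += 1
        split = rng.uniform(0.25, 0.75)
        edges[(u, mid)] = w * split
        edges[(mid, v)] = w * (1 - split)
        edges[(leaf, mid)] = float(rng.uniform(0.1, 1.0))
    d = _dist_from_tree(edges, n)
    return (d + d.T) / 2.0  # symmetrize float summation order


class TestBootstrap:
    def _two_clade_msa(self, seed=5):
        rng = np.random.default_rng(seed)
        anc = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 528)])
        fa = mutate(anc, 0.15, rng)
        fb = mutate(anc, 0.15, rng)
        names, rows = [], []
        for i in range(6):
            names.append(f"a{i}")
            rows.append(list(mutate(fa, 0.01, rng)))
        for i in range(6):
            names.append(f"b{i}")
            rows.append(list(mutate(fb, 0.01, rng)))
        return names, np.array(rows)

    def test_separating_edge_strongly_supported(self):
        names, rows = self._two_clade_msa()
        tree = bootstrap_support(names, rows, n_reps=100, seed=1)
        part = frozenset(n for n in names if n.startswith("a"))
        supports = {
            frozenset(t.name for t in node.tips()): node.support
            for node in tree.non_tips(include_self=False)
        }
        matching = [s for side, s in supports.items() if side in (part,)]
        assert matching and matching[0] >= 0.95

    def test_single_replicate_gives_binary_supports(self):
        names, rows = self._two_clade_msa(seed=6)
        tree = bootstrap_support(names, rows, n_reps=1, seed=2)
        for node in tree.non_tips(include_self=False):
            assert node.support in (0.0, 1.0)

    def test_same_seed_reproducible(self):
        names, rows = self._two_clade_msa(seed=7)
        t1 = bootstrap_support(names, rows, n_reps=25, seed=3)
        t2 = bootstrap_support(names, rows, n_reps=25, seed=3)
        assert str(t1) == str(t2)

    def test_supports_invariant_to_leaf_order(self):
        names, rows = self._two_clade_msa(seed=8)
        perm = np.random.default_rng(0).permutation(len(names))
        t1 = bootstrap_support(names, rows, n_reps=25, seed=4)
        t2 = bootstrap_support([names[i] for i in perm], rows[perm],
                               n_reps=25, seed=4)
        s1 = {frozenset(t.name for t in n.tips()): n.support
              for n in t1.non_tips(include_self=False)}
        s2 = {frozenset(t.name for t in n.tips()): n.support
              for n in t2.non_tips(include_self=False)}
        shared = set(s1) & set(s2)
        assert shared
        # bipartitions present in both trees carry similar support
        for k in shared:
            assert abs(s1[k] - s2[k]) <= 0.2


class TestMajorClades:
    def test_star_tree_has_no_major_clades(self):
        rng = np.random.default_rng(9)
        rows = np.array(
            [list("".join(np.array(list("ACGT"))[rng.integers(0, 4, 100)]))
             for _ in range(8)]
        )
        names = [f"u{i}" for i in range(8)]
        tree = bootstrap_support(names, rows, n_reps=10, seed=1)
        # force supports to zero: a star-like tree from iid noise
        for node in tree.non_tips(include_self=False):
            node.support = 0.0
        clades, unplaced = extract_major_clades(tree, min_support=0.75, min_size=2)
        assert clades == []
        assert sorted(unplaced) == sorted(names)

    def test_simulated_lineages_recovered_as_pure_clades(self, default_run):
        """Major clades on the default scenario are pure for one lineage."""
        _, _, truth, result = default_run
        assert len(result.clades) >= 5
        start_to_lineage = {
            (r["chrom"], r["start"]): r["lineage"]
            for _, r in truth.units.iterrows()
        }
        unit_lineage = {}
        for hit, rec in zip(result.retained, result.records):
            key = min(
                start_to_lineage,
                key=lambda k: abs(k[1] - hit.start) if k[0] == hit.seq_id else 1e12,
            )
            unit_lineage[rec.name] = start_to_lineage[key]
        for clade in result.clades:
            lineages = [unit_lineage[m] for m in clade.members]
            purity = max(lineages.count(x) for x in set(lineages)) / len(lineages)
            assert purity >= 0.95

    def test_strict_support_threshold(self):
        from skbio import TreeNode

        tree = TreeNode.read(
            iter(["((A:1,B:1)N1:1,((C:1,D:1)N2:1,(E:1,F:1)N3:1)N4:1);"])
        )
        sup = {"N1": 0.75, "N2": 0.90, "N3": 0.60, "N4": 0.2}
        for node in tree.non_tips(include_self=False):
            node.support = sup[node.name]
        clades, unplaced = extract_major_clades(tree, min_support=0.75, min_size=2)
        ids = {frozenset(c.members) for c in clades}
        assert frozenset({"C", "D"}) in ids  # 0.90 > 0.75 qualifies
        assert frozenset({"A", "B"}) not in ids  # exactly 0.75 is excluded
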