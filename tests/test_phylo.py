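"""Progressive alignment, neighbor joining, bootstrap and clade counting."""

import itertools

import numpy as np
import pytest

from conftest import random_protein
from sialoseq.phylo import (MSA, DistanceMatrix, Node, bipartitions,
                            bootstrap_support, count_supported_clades,
                            neighbor_joining, pdistance_matrix,
                            progressive_align, topologies_equal)


def random_additive_tree(rng, n_leaves):
    """Random binary topology with branch lengths; returns (distance
    matrix over leaves, bipartition set)."""
    nodes = {f"L{i:02d}": {f"L{i:02d}": 0.0} for i in range(n_leaves)}
    # dist maps: for each live cluster, distances from every member leaf
    active = {name: ({name: 0.0},) for name in nodes}
    clusters = {name: [name] for name in nodes}
    dist = {name: {name: 0.0} for name in nodes}
    leaf_dist = {n: {} for n in list(nodes)}
    # simpler: build tree recursively and compute path lengths
    leaves = [f"L{i:02d}" for i in range(n_leaves)]
    items = [(leaf, None) for leaf in leaves]
    tree = {}
    parent_len = {}
    next_id = [0]

    def new_internal():
        next_id[0] += 1
        return f"I{next_id[0]}"

    frontier = list(leaves)
    children = {}
    while len(frontier) > 1:
        i, j = sorted(rng.choice(len(frontier), size=2, replace=False))
        b = frontier.pop(j)
        a = frontier.pop(i)
        u = new_internal()
        children[u] = (a, b)
        parent_len[a] = float(rng.uniform(0.05, 1.0))
        parent_len[b] = float(rng.uniform(0.05, 1.0))
        frontier.append(u)
    root = frontier[0]

    def leafset(x):
        if x in children:
            a, b = children[x]
            return leafset(a) | leafset(b)
        return {x}

    def depth_paths(x, acc, out):
        if x in children:
            a, b = children[x]
            depth_paths(a, acc + [a], out)
            depth_paths(b, acc + [b], out)
        else:
            out[x] = acc

    paths = {}
    depth_paths(root, [], paths)
    D = np.zeros((n_leaves, n_leaves))
    for ia, a in enumerate(leaves):
        for ib, b in enumerate(leaves):
            if ia >= ib:
                continue
            pa, pb = paths[a], paths[b]
            shared = 0
            for x, y in zip(pa, pb):
                if x == y:
                    shared += 1
                else:
                    break
            d = sum(parent_len[x] for x in pa[shared:]) + \
                sum(parent_len[x] for x in pb[shared:])
            D[ia, ib] = D[ib, ia] = d
    all_leaves = frozenset(leaves)
    bips = set()
    for u in children:
        side = frozenset(leafset(u))
        if "L00" in side:
            side = all_leaves - side
        if 2 <= len(side) <= n_leaves - 2:
            bips.add(side)
    return DistanceMatrix(tuple(leaves), D), bips


class TestProgressiveAlign:
    def test_identical_pair_gap_free(self):
        msa = progressive_align({"a": "MKVLF", "b": "MKVLF"})
        assert msa.rows == ("MKVLF", "MKVLF")

    def test_self_triplicate_identical_rows(self):
        msa = progressive_align({"a": "MKVLFAEQ", "b": "MKVLFAEQ",
                                 "c": "MKVLFAEQ"})
        assert len(set(msa.rows)) == 1
        assert "-" not in msa.rows[0]

    def test_three_toys_match_exhaustive_sum_of_pairs(self):
        # linear gap costs so a 3-way DP oracle is tractable
        seqs = {"a": "MKVLF", "b": "MKVLF", "c": "MKILF"}
        gap = 4.0
        msa = progressive_align(seqs, gap_open=gap, gap_extend=gap)

        from sialoseq.scoring import BLOSUM62

        def sp_score(rows):
            total = 0.0
            for r1, r2 in itertools.combinations(rows, 2):
                for x, y in zip(r1, r2):
                    if x == "-" and y == "-":
                        continue
                    if x == "-" or y == "-":
                        total -= gap
                    else:
                        total += BLOSUM62[x, y]
            return total

        def brute_best(a, b, c):
            best = None
            # exhaustive 3D DP over 7 moves, linear gaps
            from functools import lru_cache

            @lru_cache(maxsize=None)
            def rec(i, j, k):
                if i == j == k == 0:
                    return 0.0
                cands = []
                if i and j and k:
                    cands.append(rec(i-1, j-1, k-1)
                                 + BLOSUM62[a[i-1], b[j-1]]
                                 + BLOSUM62[a[i-1], c[k-1]]
                                 + BLOSUM62[b[j-1], c[k-1]])
                if i and j:
                    cands.append(rec(i-1, j-1, k)
                                 + BLOSUM62[a[i-1], b[j-1]] - 2 * gap)
                if i and k:
                    cands.append(rec(i-1, j, k-1)
                                 + BLOSUM62[a[i-1], c[k-1]] - 2 * gap)
                if j and k:
                    cands.append(rec(i, j-1, k-1)
                                 + BLOSUM62[b[j-1], c[k-1]] - 2 * gap)
                if i:
                    cands.append(rec(i-1, j, k) - 2 * gap)
                if j:
                    cands.append(rec(i, j-1, k) - 2 * gap)
                if k:
                    cands.append(rec(i, j, k-1) - 2 * gap)
                return max(cands)

            return rec(len(a), len(b), len(c))

        rows = {i: r for i, r in zip(msa.ids, msa.rows)}
        assert sp_score(msa.rows) == pytest.approx(
            brute_best(seqs["a"], seqs["b"], seqs["c"]))

    def test_alignment_columns_preserve_sequences(self):
        rng = np.random.default_rng(600)
        seqs = {f"s{i}": random_protein(rng, 40 + i) for i in range(4)}
        msa = progressive_align(seqs)
        for sid, row in zip(msa.ids, msa.rows):
            assert row.replace("-", "") == seqs[sid]


class TestPDistance:
    def test_identical_rows_zero(self):
        msa = MSA(("a", "b"), ("MKVLF", "MKVLF"))
        assert pdistance_matrix(msa).d[0, 1] == 0.0

    def test_two_of_ten_differences(self):
        msa = MSA(("a", "b"), ("ACDEFGHIKL", "ACDEFGHIWW"))
        assert pdistance_matrix(msa).d[0, 1] == pytest.approx(0.2)

    def test_gapped_columns_excluded(self):
        msa = MSA(("a", "b"), ("AC-EF", "ACDEF"))
        assert pdistance_matrix(msa).d[0, 1] == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(610)
        msa = progressive_align(
            {f"s{i}": random_protein(rng, 30) for i in range(4)})
        d = pdistance_matrix(msa).d
        assert np.allclose(d, d.T)


class TestNeighborJoining:
    def test_three_leaves_closed_form(self):
        dm = DistanceMatrix(("a", "b", "c"),
                            np.array([[0.0, 0.3, 0.5],
                                      [0.3, 0.0, 0.6],
                                      [0.5, 0.6, 0.0]]))
        tree = neighbor_joining(dm)
        lengths = {c.name: c.length for c in tree.children}
        assert lengths["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_five_leaf_additive_matrix_recovered_exactly(self):
        rng = np.random.default_rng(620)
        dm, bips = random_additive_tree(rng, 5)
        tree = neighbor_joining(dm)
        assert {b for _, b in bipartitions(tree)} == bips
        # additivity: path lengths between leaves reproduce the matrix
        paths = _leaf_path_lengths(tree)
        for i, a in enumerate(dm.ids):
            for j, b in enumerate(dm.ids):
                if i < j:
                    assert paths[(a, b)] == pytest.approx(dm.d[i, j],
                                                          abs=1e-9)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(630)
        dm, _ = random_additive_tree(rng, 7)
        perm = rng.permutation(len(dm.ids))
        dm2 = DistanceMatrix(tuple(dm.ids[i] for i in perm),
                             dm.d[np.ix_(perm, perm)])
        assert topologies_equal(neighbor_joining(dm), neighbor_joining(dm2))

    def test_matches_skbio_on_random_matrices(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(640)
        dm, _ = random_additive_tree(rng, 8)
        mine = neighbor_joining(dm)
        sk_dm = skbio.DistanceMatrix(dm.d, ids=list(dm.ids))
        sk_tree = skbio.tree.nj(sk_dm)
        sk_bips = set()
        all_leaves = frozenset(dm.ids)
        for node in sk_tree.non_tips():
            side = frozenset(t.name for t in node.tips())
            if min(all_leaves) in side:
                side = all_leaves - side
            if 2 <= len(side) <= len(all_leaves) - 2:
                sk_bips.add(side)
        assert {b for _, b in bipartitions(mine)} == sk_bips

    def test_fewer_than_three_leaves_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(("a", "b"),
                                            np.array([[0.0, 1.0],
                                                      [1.0, 0.0]])))

    @pytest.mark.parametrize("seed", range(12))
    def test_additive_recovery_property(self, seed):
        rng = np.random.default_rng(700 + seed)
        n = int(rng.integers(4, 13))
        dm, bips = random_additive_tree(rng, n)
        tree = neighbor_joining(dm)
        assert {b for _, b in bipartitions(tree)} == bips


def _leaf_path_lengths(tree):
    out = {}

    def walk(node, acc):
        if node.is_leaf:
            out[node.name] = acc + node.length
            return
        for c in node.children:
            walk(c, acc + (node.length if node is not tree else 0.0))

    # accumulate per-leaf depth from root, then combine via LCA logic:
    # easier: collect leaf depths and leafsets per node
    depths = {}

    def walk2(node, acc):
        for c in node.children:
            walk2(c, acc + c.length)
        if node.is_leaf:
            depths[node.name] = acc

    walk2(tree, 0.0)

    def leafset(node):
        return node.leaf_names()

    pairs = {}
    leaves = sorted(depths)
    for i, a in enumerate(leaves):
        for b in leaves[i + 1:]:
            # find deepest node containing both
            best_depth = 0.0
            stack = [(tree, 0.0)]
            while stack:
                node, acc = stack.pop()
                if a in leafset(node) and b in leafset(node):
                    best_depth = max(best_depth, acc)
                    for c in node.children:
                        stack.append((c, acc + c.length))
            pairs[(a, b)] = depths[a] + depths[b] - 2 * best_depth
    return pairs


class TestBootstrap:
    def make_clade_msa(self, n_clades=4, per_clade=3, length=150, seed=650):
        rng = np.random.default_rng(seed)
        rows, ids = [], []
        bases = [random_protein(rng, length) for _ in range(n_clades)]
        from sialoseq.simulate import perturb_protein
        for ci, base in enumerate(bases):
            for m in range(per_clade):
                ids.append(f"c{ci}m{m}")
                rows.append(perturb_protein(base, 0.03, rng, 0))
        return MSA(tuple(ids), tuple(rows))

    def test_single_replicate_supports_are_zero_or_hundred(self):
        msa = self.make_clade_msa()
        tree = bootstrap_support(msa, n_replicates=1, seed=1)
        supports = [n.support for n, _ in bipartitions(tree)]
        assert supports and all(s in (0.0, 100.0) for s in supports)

    def test_supports_bounded(self):
        msa = self.make_clade_msa(seed=651)
        tree = bootstrap_support(msa, n_replicates=20, seed=2)
        for node, _ in bipartitions(tree):
            assert 0.0 <= node.support <= 100.0

    def test_well_separated_clades_reach_high_support(self):
        msa = self.make_clade_msa(seed=652)
        tree = bootstrap_support(msa, n_replicates=200, seed=3)
        by_bip = {b: n.support for n, b in bipartitions(tree)}
        for ci in range(4):
            clade = frozenset(f"c{ci}m{m}" for m in range(3))
            if min(msa.ids) in clade:
                clade = frozenset(msa.ids) - clade
            assert by_bip.get(clade, 0.0) >= 95.0

    def test_fixed_seed_reproducible(self):
        msa = self.make_clade_msa(seed=653)
        t1 = bootstrap_support(msa, n_replicates=30, seed=9)
        t2 = bootstrap_support(msa, n_replicates=30, seed=9)
        s1 = sorted(n.support for n, _ in bipartitions(t1))
        s2 = sorted(n.support for n, _ in bipartitions(t2))
        assert s1 == s2


class TestCladeCounting:
    @staticmethod
    def leaf(name):
        return Node(name=name, length=1.0)

    def test_no_support_above_hundred(self):
        inner = Node(support=99.0, children=[self.leaf("a"), self.leaf("b")])
        root = Node(children=[inner, self.leaf("c"), self.leaf("d")])
        assert count_supported_clades(root, 100)[0] == 0

    def test_star_tree_counts_zero(self):
        msa_like = Node(children=[self.leaf(x) for x in "abcd"])
        assert count_supported_clades(msa_like, 0)[0] == 0

    def test_maximality_rule_on_hand_built_tree(self):
        # ((a,b)90,(c,(d,e)85)60,f): threshold 70 -> clades {a,b} and {d,e}
        ab = Node(support=90.0, children=[self.leaf("a"), self.leaf("b")])
        de = Node(support=85.0, children=[self.leaf("d"), self.leaf("e")])
        cde = Node(support=60.0, children=[self.leaf("c"), de])
        root = Node(children=[ab, cde, self.leaf("f")])
        n, clades = count_supported_clades(root, 70)
        assert n == 2
        assert set(clades) == {frozenset("ab"), frozenset("de")}

    def test_nested_supported_clade_counted_once(self):
        de = Node(support=85.0, children=[self.leaf("d"), self.leaf("e")])
        cde = Node(support=90.0, children=[self.leaf("c"), de])
        root = Node(children=[cde, self.leaf("a"), self.leaf("b")])
        n, clades = count_supported_clades(root, 70)
        assert n == 1
        assert clades == [frozenset("cde")]

    def test_monotone_in_threshold(self):
        ab = Node(support=90.0, children=[self.leaf("a"), self.leaf("b")])
        de = Node(support=60.0, children=[self.leaf("d"), self.leaf("e")])
        root = Node(children=[ab, de, self.leaf("f")])
        counts = [count_supported_clades(root, t)[0]
                  for t in (0, 50, 70, 95)]
        assert counts == sorted(counts, reverse=True)


class TestNewick:
    def test_export_contains_supports_and_leaves(self):
        msa = MSA(("a", "b", "c", "d"),
                  ("MKVLF", "MKVLF", "MKWWF", "MKWWF"))
        tree = bootstrap_support(msa, n_replicates=5, seed=4)
        nwk = tree.to_newick()
        assert nwk.endswith(";")
        for leaf in "abcd":
            assert leaf in nwk
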