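"""Progressive alignment, p-distances, neighbor joining and bootstrap
clade support.

Distances are plain p-distances (fraction of differing residues over
shared non-gap columns), matching tree scale bars phrased as "% amino
acid divergence".  Trees are built with canonical neighbor joining
(Q-matrix selection, standard branch-length formulas) with a
deterministic tie-break on the smallest pair of cluster representatives,
and bootstrap supports come from column resampling of the fixed multiple
alignment: the tree is rebuilt per replicate and each original internal
bipartition is scored by the percentage of replicates containing it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .families import pairwise_identity
from .scoring import BLOSUM62, GAP_EXTEND, GAP_OPEN, sanitize_protein

_ALPHABET = "ACDEFGHIKLMNPQRSTVWYBZX*"
_AA_INDEX = {c: i for i, c in enumerate(_ALPHABET)}
_SCORE = np.zeros((len(_ALPHABET), len(_ALPHABET)))
for _a, _i in _AA_INDEX.items():
    for _b, _j in _AA_INDEX.items():
        _SCORE[_i, _j] = BLOSUM62[_a, _b]
_GAP_BYTE = ord("-")


@dataclass(frozen=True)
class MSA:
    """A multiple alignment: equal-length gapped rows, one per id."""

    ids: Tuple[str, ...]
    rows: Tuple[str, ...]

    def __post_init__(self):
        if len(self.ids) != len(self.rows) or not self.ids:
            raise ValueError("ids and rows must align and be nonempty")
        if len({len(r) for r in self.rows}) != 1:
            raise ValueError("rows must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for i, r in zip(self.ids, self.rows):
                fh.write(f">{i}\n{r}\n")


@dataclass
class DistanceMatrix:
    ids: Tuple[str, ...]
    d: np.ndarray

    def __post_init__(self):
        self.ids = tuple(self.ids)
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T) or not np.allclose(
                np.diag(self.d), 0.0):
            raise ValueError("matrix must be symmetric with zero diagonal")
        if (self.d < -1e-12).any():
            raise ValueError("negative distances")


@dataclass
class Node:
    """A rooted representation of an (unrooted) phylogeny."""

    name: Optional[str] = None
    length: float = 0.0
    support: Optional[float] = None  # percent, internal edges only
    children: List["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> frozenset:
        if self.is_leaf:
            return frozenset([self.name])
        return frozenset().union(*(c.leaf_names() for c in self.children))

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def to_newick(self, with_support: bool = True) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if with_support and node.support is not None:
                label = f"{node.support:g}"
            return f"({inner}){label}:{node.length:.6f}"
        inner = ",".join(fmt(c) for c in self.children)
        return f"({inner});"


# ---------------------------------------------------------------------------
# progressive multiple alignment


def _profile_freqs(rows: Sequence[str]) -> np.ndarray:
    """Column x symbol residue counts (gaps contribute nothing)."""
    L = len(rows[0])
    F = np.zeros((L, len(_ALPHABET)))
    for r in rows:
        for j, c in enumerate(r):
            if c != "-":
                F[j, _AA_INDEX.get(c, _AA_INDEX["X"])] += 1
    return F


def _align_profiles(rows_a: List[str], rows_b: List[str],
                    gap_open: float, gap_extend: float
                    ) -> Tuple[List[str], List[str]]:
    """Affine-gap (Gotoh) global alignment of two profiles.

    Column-column score is the mean pairwise substitution score across
    all row pairs (residue-gap pairs contribute zero); gap penalties are
    profile-level scalars.  Deterministic traceback preference:
    diagonal, then gap-in-B, then gap-in-A.
    """
    FA, FB = _profile_freqs(rows_a), _profile_freqs(rows_b)
    la, lb = FA.shape[0], FB.shape[0]
    col = (FA @ _SCORE @ FB.T) / (len(rows_a) * len(rows_b))
    NEG = -1e30
    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)  # gap in B (consume A)
    Y = np.full((la + 1, lb + 1), NEG)  # gap in A (consume B)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, lb + 1):
        Y[0, j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, la + 1):
        ci = col[i - 1]
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        for j in range(1, lb + 1):
            Mi[j] = ci[j - 1] + max(Mi1[j - 1], Xi1[j - 1], Yi1[j - 1])
            Xi[j] = max(Mi1[j] - gap_open, Xi1[j] - gap_extend,
                        Yi1[j] - gap_open)
            Yi[j] = max(Mi[j - 1] - gap_open, Yi[j - 1] - gap_extend,
                        Xi[j - 1] - gap_open)
    # traceback
    i, j = la, lb
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    ops: List[str] = []
    while i > 0 or j > 0:
        if state == 0:
            ops.append("D")
            prev = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            target = M[i, j] - col[i - 1, j - 1]
            i, j = i - 1, j - 1
        elif state == 1:
            ops.append("A")
            prev = [M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend,
                    Y[i - 1, j] - gap_open]
            target = X[i, j]
            i -= 1
        else:
            ops.append("B")
            prev = [M[i, j - 1] - gap_open, X[i, j - 1] - gap_open,
                    Y[i, j - 1] - gap_extend]
            target = Y[i, j]
            j -= 1
        if i == 0 and j == 0:
            break
        state = int(np.argmax([1e-9 - abs(p - target) for p in prev]))
    ops.reverse()
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op == "D":
            for k, r in enumerate(rows_a):
                out_a[k] += r[ia]
            for k, r in enumerate(rows_b):
                out_b[k] += r[ib]
            ia += 1
            ib += 1
        elif op == "A":
            for k, r in enumerate(rows_a):
                out_a[k] += r[ia]
            for k in range(len(rows_b)):
                out_b[k] += "-"
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k] += "-"
            for k, r in enumerate(rows_b):
                out_b[k] += r[ib]
            ib += 1
    return out_a, out_b


def progressive_align(proteins: Mapping[str, str],
                      gap_open: float = GAP_OPEN,
                      gap_extend: float = GAP_EXTEND) -> MSA:
    """Guide-tree progressive alignment.

    The guide tree is average-linkage clustering of pairwise
    (1 - identity) distances; profiles are merged in guide order with
    the same substitution scoring used by the homology searches.
    """
    ids = sorted(proteins)
    seqs = {i: sanitize_protein(proteins[i]) for i in ids}
    if not ids:
        raise ValueError("no sequences")
    if len(ids) == 1:
        return MSA((ids[0],), (seqs[ids[0]],))
    if len(ids) == 2:
        a, b = _align_profiles([seqs[ids[0]]], [seqs[ids[1]]],
                               gap_open, gap_extend)
        return MSA(tuple(ids), (a[0], b[0]))
    n = len(ids)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident, _ = pairwise_identity(seqs[ids[i]], seqs[ids[j]])
            dm[i, j] = dm[j, i] = 1.0 - ident
    Z = linkage(squareform(dm, checks=False), method="average")
    clusters: Dict[int, Tuple[List[str], List[str]]] = {
        i: ([ids[i]], [seqs[ids[i]]]) for i in range(n)}
    for step, (a, b, _, _) in enumerate(Z):
        ids_a, rows_a = clusters.pop(int(a))
        ids_b, rows_b = clusters.pop(int(b))
        new_a, new_b = _align_profiles(rows_a, rows_b, gap_open, gap_extend)
        clusters[n + step] = (ids_a + ids_b, new_a + new_b)
    out_ids, out_rows = clusters[n + len(Z) - 1]
    order = sorted(range(len(out_ids)), key=lambda k: out_ids[k])
    return MSA(tuple(out_ids[k] for k in order),
               tuple(out_rows[k] for k in order))


# ---------------------------------------------------------------------------
# distances and neighbor joining


def _msa_bytes(msa: MSA) -> np.ndarray:
    return np.array([np.frombuffer(r.encode(), dtype=np.uint8)
                     for r in msa.rows])


def pdistance_matrix(msa: MSA,
                     columns: Optional[np.ndarray] = None) -> DistanceMatrix:
    """Pairwise p-distance over columns where both rows are non-gap.

    ``columns`` optionally selects (possibly repeated) column indices,
    which is how bootstrap replicates are formed.  Pairs sharing no
    non-gap column get distance 1.
    """
    mat = _msa_bytes(msa)
    if columns is not None:
        mat = mat[:, columns]
    n = mat.shape[0]
    d = np.zeros((n, n))
    nongap = mat != _GAP_BYTE
    for i in range(n):
        for j in range(i + 1, n):
            shared = nongap[i] & nongap[j]
            ns = int(shared.sum())
            if ns == 0:
                dij = 1.0
            else:
                dij = float((mat[i, shared] != mat[j, shared]).sum()) / ns
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(tuple(msa.ids), d)


def neighbor_joining(dm: DistanceMatrix) -> Node:
    """Canonical neighbor joining with deterministic tie-breaks.

    Pair selection minimizes the Q criterion; ties resolve to the
    smallest (representative id) pair.  Branch lengths use the standard
    formulas, clamped at zero.  The returned tree is rooted at the final
    three-way join (an arbitrary rooting of the unrooted topology).
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 leaves")
    D: Dict[str, Dict[str, float]] = {
        a: {b: float(dm.d[i, j]) for j, b in enumerate(dm.ids) if a != b}
        for i, a in enumerate(dm.ids)}
    nodes: Dict[str, Node] = {a: Node(name=a) for a in dm.ids}
    active = sorted(dm.ids)
    while len(active) > 3:
        m = len(active)
        r = {a: sum(D[a][b] for b in active if b != a) for a in active}
        best = None
        for ii, a in enumerate(active):
            for b in active[ii + 1:]:
                q = (m - 2) * D[a][b] - r[a] - r[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        dab = D[a][b]
        la = dab / 2 + (r[a] - r[b]) / (2 * (m - 2))
        la = min(max(la, 0.0), dab)
        lb = max(dab - la, 0.0)
        child_a, child_b = nodes.pop(a), nodes.pop(b)
        child_a.length, child_b.length = la, lb
        u = Node(children=[child_a, child_b])
        rep = min(a, b)
        newd = {}
        for c in active:
            if c in (a, b):
                continue
            newd[c] = max((D[a][c] + D[b][c] - dab) / 2, 0.0)
        for c in newd:
            D[c].pop(a, None)
            D[c].pop(b, None)
            D[c][rep] = newd[c]
        D.pop(a, None)
        D.pop(b, None)
        D[rep] = newd
        nodes[rep] = u
        active = sorted(set(active) - {a, b} | {rep})
    a, b, c = active
    la = (D[a][b] + D[a][c] - D[b][c]) / 2
    lb = (D[a][b] + D[b][c] - D[a][c]) / 2
    lc = (D[a][c] + D[b][c] - D[a][b]) / 2
    for name, ln in ((a, la), (b, lb), (c, lc)):
        nodes[name].length = max(ln, 0.0)
    return Node(children=[nodes[a], nodes[b], nodes[c]])


def bipartitions(root: Node) -> List[Tuple[Node, frozenset]]:
    """Canonical internal-edge bipartitions of an (unrooted) tree.

    Each internal node except the root defines one internal edge; the
    bipartition is canonicalized as the side not containing the
    reference leaf (the smallest leaf id).
    """
    all_leaves = root.leaf_names()
    ref = min(all_leaves)
    out = []
    for node in root.walk():
        if node is root or node.is_leaf:
            continue
        side = node.leaf_names()
        if ref in side:
            side = all_leaves - side
        if 2 <= len(side) <= len(all_leaves) - 2:
            out.append((node, frozenset(side)))
    return out


def topologies_equal(t1: Node, t2: Node) -> bool:
    """Unrooted topology comparison via bipartition sets."""
    if t1.leaf_names() != t2.leaf_names():
        return False
    b1 = {b for _, b in bipartitions(t1)}
    b2 = {b for _, b in bipartitions(t2)}
    return b1 == b2


def bootstrap_support(msa: MSA, n_replicates: int = 1000,
                      seed: int = 0) -> Node:
    """Neighbor-joining tree with bootstrap supports on internal edges.

    Alignment columns are resampled with replacement ``n_replicates``
    times; each original internal bipartition's support is the percent
    of replicate trees containing it.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    tree = neighbor_joining(pdistance_matrix(msa))
    orig = bipartitions(tree)
    counts = {bip: 0 for _, bip in orig}
    rng = np.random.default_rng(seed)
    L = msa.n_columns
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        rep_tree = neighbor_joining(pdistance_matrix(msa, columns=cols))
        rep_bips = {b for _, b in bipartitions(rep_tree)}
        for bip in counts:
            if bip in rep_bips:
                counts[bip] += 1
    for node, bip in orig:
        node.support = 100.0 * counts[bip] / n_replicates
    return tree


def count_supported_clades(tree: Node, min_support_pct: float,
                           min_size: int = 2
                           ) -> Tuple[int, List[frozenset]]:
    """Count maximal clades with support strictly above a threshold.

    A clade is the leafward side of an internal edge with >= ``min_size``
    leaves; nested supported clades are represented only by their
    maximal (largest) qualifying ancestor.
    """
    qualifying = []
    for node in tree.walk():
        if node is tree or node.is_leaf or node.support is None:
            continue
        leaves = node.leaf_names()
        if node.support > min_support_pct and len(leaves) >= min_size:
            qualifying.append(leaves)
    qualifying.sort(key=lambda s: (-len(s), sorted(s)))
    maximal: List[frozenset] = []
    for clade in qualifying:
        if not any(clade <= kept for kept in maximal):
            maximal.append(frozenset(clade))
    return len(maximal), maximal
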