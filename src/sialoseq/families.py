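"""Progressive protein-family clustering, gene-count estimation and
PROSITE-style motif scanning.

Deduced proteins are clusterized by single linkage over pairwise percent
identity, progressively from 25% to 99%, with each link also required to
span at least half of the longer sequence.  Clusters at each threshold
are ranked by summed read abundance and labelled "<threshold>-<rank>"
(so the 33rd most abundant cluster at the 40% level is "40-33").

Gene counts within a family follow the >20%-divergence convention:
members linked at >=80% identity are treated as alleles or near-copies of
one gene, so the number of putative genes is the number of single-linkage
clusters at the 80% level.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

from .scoring import make_protein_aligner, sanitize_protein

#: identity level at which members count as copies of one gene
GENE_IDENTITY_PCT = 80
#: minimum fraction of the longer sequence a clustering link must span
DEFAULT_MIN_COVERAGE = 0.5


def pairwise_identity(a: str, b: str) -> Tuple[float, float]:
    """(identity fraction, coverage of the longer sequence).

    Global alignment with free terminal gaps; identity is matches over
    the aligned columns between the first and last column where both
    sequences have a residue (internal gaps count against identity),
    and coverage is the longer sequence's span inside that window over
    its full length.
    """
    if not a or not b:
        raise ValueError("empty protein")
    sa, sb = sanitize_protein(a), sanitize_protein(b)
    aligner = make_protein_aligner("overlap")
    alignment = aligner.align(sa, sb)[0]
    ia, ib = alignment.indices
    both = [(int(i), int(j)) for i, j in zip(ia, ib) if i >= 0 and j >= 0]
    if not both:
        return 0.0, 0.0
    first = (both[0][0], both[0][1])
    last = (both[-1][0], both[-1][1])
    # columns in the window = alignment columns between the bounding pairs
    cols = 0
    matches = 0
    in_window = False
    for i, j in zip(ia, ib):
        i, j = int(i), int(j)
        if (i, j) == first:
            in_window = True
        if in_window:
            cols += 1
            if i >= 0 and j >= 0 and sa[i] == sb[j]:
                matches += 1
        if (i, j) == last:
            break
    longer, lo, hi = ((sa, first[0], last[0]) if len(sa) >= len(sb)
                      else (sb, first[1], last[1]))
    coverage = (hi - lo + 1) / len(longer)
    return matches / cols, coverage


@dataclass(frozen=True)
class FamilyCluster:
    threshold_pct: int
    rank: int
    label: str
    member_ids: frozenset
    total_reads: int
    member_count: int

    def __post_init__(self):
        if self.label != f"{self.threshold_pct}-{self.rank}":
            raise ValueError("label must be '<threshold>-<rank>'")
        if not self.member_ids:
            raise ValueError("empty cluster")


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def identity_matrix(proteins: Mapping[str, str]
                    ) -> Dict[Tuple[str, str], Tuple[float, float]]:
    """All-pairs (identity, coverage); keys are sorted id pairs."""
    ids = sorted(proteins)
    out: Dict[Tuple[str, str], Tuple[float, float]] = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            out[(a, b)] = pairwise_identity(proteins[a], proteins[b])
    return out


def _components(ids: Sequence[str],
                pairs: Mapping[Tuple[str, str], Tuple[float, float]],
                threshold_pct: float, min_coverage: float) -> List[Set[str]]:
    uf = _UnionFind(ids)
    for (a, b), (ident, cov) in pairs.items():
        if ident * 100 >= threshold_pct - 1e-9 and cov >= min_coverage:
            uf.union(a, b)
    comp: Dict[str, Set[str]] = {}
    for x in ids:
        comp.setdefault(uf.find(x), set()).add(x)
    return list(comp.values())


def cluster_at(proteins: Mapping[str, str], read_counts: Mapping[str, int],
               threshold_pct: int,
               min_coverage: float = DEFAULT_MIN_COVERAGE,
               _pairs=None) -> List[FamilyCluster]:
    """Single-linkage clusters at one identity threshold.

    Clusters are ranked by descending summed read counts (ties by the
    smallest member id) and labelled "<threshold>-<rank>".
    """
    if not (1 <= threshold_pct <= 100):
        raise ValueError("threshold_pct must be in [1, 100]")
    pairs = identity_matrix(proteins) if _pairs is None else _pairs
    comps = _components(sorted(proteins), pairs, threshold_pct, min_coverage)
    ranked = sorted(
        comps, key=lambda c: (-sum(read_counts.get(m, 1) for m in c), min(c)))
    return [FamilyCluster(
        threshold_pct=threshold_pct, rank=i + 1,
        label=f"{threshold_pct}-{i + 1}",
        member_ids=frozenset(c),
        total_reads=sum(read_counts.get(m, 1) for m in c),
        member_count=len(c)) for i, c in enumerate(ranked)]


def progressive_clusters(proteins: Mapping[str, str],
                         read_counts: Mapping[str, int],
                         thresholds: Sequence[int] = tuple(range(25, 100)),
                         min_coverage: float = DEFAULT_MIN_COVERAGE
                         ) -> Dict[int, List[FamilyCluster]]:
    """Cluster at every threshold of the progressive 25..99% sweep,
    computing the pairwise identity matrix once."""
    pairs = identity_matrix(proteins)
    return {t: cluster_at(proteins, read_counts, t, min_coverage, _pairs=pairs)
            for t in thresholds}


def estimate_gene_count(members: Sequence[str],
                        min_coverage: float = DEFAULT_MIN_COVERAGE) -> int:
    """Putative gene number among related proteins.

    Sequences >20% divergent at the amino-acid level count as separate
    genes; members linked at >=80% identity are treated as alleles or
    near-copies.  Invariant under duplication of any member.
    """
    if not members:
        raise ValueError("empty member list")
    proteins = {f"m{i}": p for i, p in enumerate(members)}
    pairs = identity_matrix(proteins)
    return len(_components(sorted(proteins), pairs,
                           GENE_IDENTITY_PCT, min_coverage))


def write_cluster_table(clusters: Mapping[int, List[FamilyCluster]], path) -> None:
    with open(path, "w") as fh:
        fh.write("threshold_pct\tlabel\tmember_count\ttotal_reads\tmember_ids\n")
        for t in sorted(clusters):
            for c in clusters[t]:
                fh.write(f"{t}\t{c.label}\t{c.member_count}\t{c.total_reads}\t"
                         f"{','.join(sorted(c.member_ids))}\n")


# ---------------------------------------------------------------------------
# PROSITE-style motif patterns


class MotifParseError(ValueError):
    pass


@dataclass(frozen=True)
class MotifElement:
    residues: Optional[frozenset]  # None = wildcard x
    min_n: int
    max_n: int

    def __post_init__(self):
        if self.min_n < 0 or self.min_n > self.max_n:
            raise MotifParseError("invalid repeat range")
        if self.residues is not None and not self.residues:
            raise MotifParseError("empty residue set")


@dataclass(frozen=True)
class MotifPattern:
    elements: Tuple[MotifElement, ...]
    text: str = ""


_TOKEN_RE = re.compile(
    r"^(?:\[(?P<set>[A-Z]+)\]|(?P<lit>[A-Z])|(?P<wild>x))"
    r"(?:\((?P<n>\d+)(?:,(?P<m>\d+))?\))?$")


def parse_motif(pattern_text: str) -> MotifPattern:
    """Parse the dashed pattern grammar: literals, [SETS], x, x(n), x(n,m).

    Malformed tokens raise :class:`MotifParseError` naming the position.
    """
    text = pattern_text.strip()
    if not text:
        raise MotifParseError("empty pattern")
    elements: List[MotifElement] = []
    pos = 0
    for token in text.split("-"):
        m = _TOKEN_RE.match(token)
        if m is None:
            raise MotifParseError(
                f"malformed element {token!r} at character {pos}")
        n = int(m.group("n")) if m.group("n") else 1
        mx = int(m.group("m")) if m.group("m") else n
        if n > mx:
            raise MotifParseError(
                f"descending repeat range in {token!r} at character {pos}")
        if m.group("wild"):
            residues = None
        elif m.group("set"):
            residues = frozenset(m.group("set"))
        else:
            residues = frozenset(m.group("lit"))
        elements.append(MotifElement(residues, n, mx))
        pos += len(token) + 1
    return MotifPattern(tuple(elements), text)


def scan_motif(protein: str, pattern: MotifPattern
               ) -> List[Tuple[int, int]]:
    """All (start, end) half-open spans matching the pattern.

    Every alternative span length admitted by range elements is
    enumerated, so overlapping matches and multiple end points from the
    same start are all reported.
    """
    n = len(protein)
    spans: List[Tuple[int, int]] = []
    for start in range(n):
        frontier = {start}
        for elem in pattern.elements:
            nxt = set()
            for p in frontier:
                for k in range(elem.min_n, elem.max_n + 1):
                    if p + k > n:
                        break
                    if elem.residues is not None and any(
                            protein[p + i] not in elem.residues
                            for i in range(k)):
                        continue
                    nxt.add(p + k)
            frontier = nxt
            if not frontier:
                break
        spans.extend((start, end) for end in sorted(frontier))
    return sorted(spans)
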