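"""Iterative word-size-scheduled read clusterization and consensus assembly.

The strategy mirrors large-scale EST clusterization pipelines built on a
seed-then-assemble loop: sequences sharing at least one exact word (on
either strand) are grouped transitively, each group is assembled to
consensus by a greedy overlap-layout-consensus step, and the resulting
consensus sequences (with derived qualities) are fed to the next round
with a smaller word size.  The default word-size schedule is
200, 134, 90, 60, 40, 40.

The grouping trigger is exact word sharing; the quality of each candidate
join is enforced by the assembler's overlap-length and overlap-identity
gates, not by alignment statistics at grouping time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import edlib

from .scoring import make_nucleotide_overlap_aligner

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: cap on per-column consensus quality carried between rounds
MAX_CONSENSUS_QUAL = 60

#: seed length used to pre-screen candidate overlap pairs inside a group
_OVERLAP_SEED = 16


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Read:
    """A single sequencing read with per-base phred qualities."""

    id: str
    bases: str
    quals: Tuple[int, ...]

    def __post_init__(self):
        if not self.bases:
            raise ValueError(f"read {self.id}: empty sequence")
        if len(self.quals) != len(self.bases):
            raise ValueError(
                f"read {self.id}: {len(self.quals)} qualities for "
                f"{len(self.bases)} bases")
        object.__setattr__(self, "quals", tuple(self.quals))


@dataclass
class Contig:
    """Consensus sequence plus exact accounting of member reads."""

    id: str
    consensus: str
    consensus_quals: Tuple[int, ...]
    member_read_ids: frozenset

    def __post_init__(self):
        if len(self.consensus_quals) != len(self.consensus):
            raise ValueError(f"contig {self.id}: quality/sequence length mismatch")
        self.member_read_ids = frozenset(self.member_read_ids)
        if not self.member_read_ids:
            raise ValueError(f"contig {self.id}: no member reads")
        self.consensus_quals = tuple(self.consensus_quals)

    @property
    def read_count(self) -> int:
        return len(self.member_read_ids)


@dataclass(frozen=True)
class AssemblySchedule:
    """Round-by-round word sizes and overlap gates for the iterative loop."""

    word_sizes: Tuple[int, ...] = (200, 134, 90, 60, 40, 40)
    max_matches_per_query: int = 1000
    min_overlap_nt: int = 40
    min_overlap_identity: float = 0.9

    def __post_init__(self):
        if not self.word_sizes:
            raise ValueError("schedule needs at least one word size")
        if any(w < 4 for w in self.word_sizes):
            raise ValueError("word sizes must be >= 4")
        if any(a < b for a, b in zip(self.word_sizes, self.word_sizes[1:])):
            raise ValueError("word sizes must be nonincreasing")
        if self.min_overlap_nt < 1 or not (0 < self.min_overlap_identity <= 1):
            raise ValueError("invalid overlap gates")


def _validate_alphabet(seq_id: str, bases: str) -> None:
    bad = set(bases) - set("ACGTN")
    if bad:
        raise ValueError(
            f"sequence {seq_id}: non-ACGTN symbol(s) {sorted(bad)}")


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        p = self.parent
        while p[x] != x:
            p[x] = p[p[x]]
            x = p[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # keep the lexicographically smaller id as root for determinism
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def _canonical_words(bases: str, k: int, both_strands: bool):
    rc = revcomp(bases) if both_strands else None
    for i in range(len(bases) - k + 1):
        w = bases[i:i + k]
        if "N" in w:
            continue
        if both_strands:
            w2 = rc[len(bases) - k - i:len(bases) - i]
            if w2 < w:
                w = w2
        yield w


def shared_word_groups(sequences: Mapping[str, str], word_size: int,
                       both_strands: bool = True) -> List[frozenset]:
    """Partition sequence ids into transitive shared-exact-word groups.

    Two ids land in the same group iff they are connected by a chain of
    pairs sharing at least one exact word of length ``word_size`` (on
    either strand when ``both_strands``).  Sequences shorter than the word
    size are singletons.  The result is independent of input order.
    """
    if word_size < 4:
        raise ValueError("word_size must be >= 4")
    for sid, bases in sequences.items():
        _validate_alphabet(sid, bases)
    uf = _UnionFind(sequences)
    buckets: Dict[str, str] = {}
    for sid in sorted(sequences):
        for w in _canonical_words(sequences[sid], word_size, both_strands):
            other = buckets.setdefault(w, sid)
            if other != sid:
                uf.union(other, sid)
    groups: Dict[str, set] = {}
    for sid in sequences:
        groups.setdefault(uf.find(sid), set()).add(sid)
    return sorted((frozenset(g) for g in groups.values()), key=lambda g: min(g))


# ---------------------------------------------------------------------------
# greedy overlap-layout-consensus within one group


def _as_working(obj) -> Contig:
    if isinstance(obj, Contig):
        return obj
    return Contig(id=obj.id, consensus=obj.bases,
                  consensus_quals=tuple(obj.quals),
                  member_read_ids=frozenset([obj.id]))


def _overlap_columns(alignment):
    """(target, query) index arrays per alignment column (-1 marks a gap)."""
    ind = alignment.indices
    return ind[0], ind[1]


def _kmer_index(seq: str, k: int = _OVERLAP_SEED) -> Dict[str, List[int]]:
    index: Dict[str, List[int]] = {}
    for i in range(len(seq) - k + 1):
        w = seq[i:i + k]
        if "N" in w:
            continue
        hits = index.setdefault(w, [])
        if len(hits) < 8:  # cap per-word positions against low-complexity runs
            hits.append(i)
    return index


def _estimate_overlap(s1: str, index2: Dict[str, List[int]], s2_len: int,
                      s2: str, k: int = _OVERLAP_SEED):
    """Seed-vote the relative offset of s2 against s1, then measure the
    implied overlap with a banded edit-distance alignment.

    Returns (overlap_len, identity_estimate) or None without seed support.
    The modal diagonal (offset of s2's start on s1) defines the overlap
    window; identity is estimated as 1 - edits/overlap over that window.
    """
    votes: Dict[int, int] = {}
    for i in range(len(s1) - k + 1):
        for j in _kmer_index_lookup(index2, s1[i:i + k]):
            d = i - j
            votes[d] = votes.get(d, 0) + 1
    if not votes:
        return None
    d = max(sorted(votes), key=lambda x: (votes[x], -abs(x)))
    a = s1[d:] if d >= 0 else s1
    b = s2 if d >= 0 else s2[-d:]
    if not a or not b:
        return None
    query, target = (a, b) if len(a) <= len(b) else (b, a)
    result = edlib.align(query, target, mode="SHW", task="distance")
    dist = result["editDistance"]
    ovl = len(query)
    return ovl, max(0.0, 1.0 - dist / ovl)


def _kmer_index_lookup(index: Dict[str, List[int]], word: str) -> List[int]:
    return index.get(word, ()) if "N" not in word else ()


def _best_overlap(c1: Contig, c2: Contig, indexes) -> object:
    """Best estimated overlap across both orientations, or None."""
    best = None
    for orient in ("+", "-"):
        index2, s2 = indexes[c2.id][orient]
        est = _estimate_overlap(c1.consensus, index2, len(s2), s2)
        if est is None:
            continue
        cand = (est[0], est[1], orient)
        if best is None or (cand[0], cand[1]) > (best[0], best[1]):
            best = cand
    return best


def _merge(aligner, c1: Contig, c2: Contig, orient: str) -> Contig:
    s2 = c2.consensus if orient == "+" else revcomp(c2.consensus)
    q2 = c2.consensus_quals if orient == "+" else tuple(reversed(c2.consensus_quals))
    alignment = aligner.align(c1.consensus, s2)[0]
    ind1, ind2 = _overlap_columns(alignment)
    s1, q1 = c1.consensus, c1.consensus_quals
    bases: List[str] = []
    quals: List[int] = []
    for i, j in zip(ind1, ind2):
        i, j = int(i), int(j)
        if i >= 0 and j >= 0:
            a, b = s1[i], s2[j]
            qa, qb = q1[i], q2[j]
            if a == b:
                bases.append(a)
                quals.append(min(qa + qb, MAX_CONSENSUS_QUAL))
            else:
                # quality-weighted majority of two: higher phred wins,
                # ties resolved alphabetically
                if qa > qb or (qa == qb and a < b):
                    bases.append(a)
                else:
                    bases.append(b)
                quals.append(max(abs(qa - qb), 2))
        elif i >= 0:
            bases.append(s1[i])
            quals.append(min(q1[i], MAX_CONSENSUS_QUAL))
        else:
            bases.append(s2[j])
            quals.append(min(q2[j], MAX_CONSENSUS_QUAL))
    return Contig(id=min(c1.id, c2.id), consensus="".join(bases),
                  consensus_quals=tuple(quals),
                  member_read_ids=c1.member_read_ids | c2.member_read_ids)


def _polish(aligner, draft: Contig,
            constituents: List[Tuple[Contig, str]]) -> Contig:
    """Column-vote consensus polish of a merged draft.

    Each constituent is realigned to the draft in its merge orientation
    and every draft column is re-called by quality-weighted majority over
    bases and gaps; junction positions where a majority of spanning
    constituents carry an extra base get it inserted back.  Ties go to
    the higher summed phred, then the alphabetically first base, with a
    base preferred over a gap.
    """
    L = len(draft.consensus)
    base_votes: List[Dict[str, int]] = [dict() for _ in range(L)]
    gap_votes = [0] * L
    ins_votes: List[Dict[str, int]] = [dict() for _ in range(L + 1)]
    span_cov = [0] * (L + 1)  # constituents spanning each junction
    for ctg, orient in constituents:
        seq = ctg.consensus if orient == "+" else revcomp(ctg.consensus)
        quals = (ctg.consensus_quals if orient == "+"
                 else tuple(reversed(ctg.consensus_quals)))
        alignment = aligner.align(draft.consensus, seq)[0]
        di, mi = _overlap_columns(alignment)
        pairs = [(int(i), int(j)) for i, j in zip(di, mi)]
        both = [c for c, (i, j) in enumerate(pairs) if i >= 0 and j >= 0]
        if not both:
            continue
        lo, hi = both[0], both[-1]
        first_d, last_d = pairs[lo][0], pairs[hi][0]
        for j in range(first_d, last_d + 2):
            span_cov[j] += 1
        pending_ins: List[Tuple[str, int]] = []
        last_q = 30
        for c in range(lo, hi + 1):
            i, j = pairs[c]
            if i >= 0 and j >= 0:
                for b, q in pending_ins:
                    iv = ins_votes[i]
                    iv[b] = iv.get(b, 0) + q
                pending_ins = []
                bv = base_votes[i]
                bv[seq[j]] = bv.get(seq[j], 0) + quals[j]
                last_q = quals[j]
            elif i >= 0:  # constituent lacks this draft base
                gap_votes[i] += last_q
            else:  # constituent carries an extra base at this junction
                pending_ins.append((seq[j], quals[j]))
        for b, q in pending_ins:
            iv = ins_votes[last_d + 1]
            iv[b] = iv.get(b, 0) + q
    out_bases: List[str] = []
    out_quals: List[int] = []

    def emit_insertions(junction: int):
        iv = ins_votes[junction]
        if not iv:
            return
        total = sum(iv.values())
        b, q = min(iv.items(), key=lambda kv: (-kv[1], kv[0]))
        # insert when a majority of spanning constituents carry the base
        if total > 30 * span_cov[junction] - total:
            out_bases.append(b)
            out_quals.append(max(min(q, MAX_CONSENSUS_QUAL), 2))

    for i in range(L):
        emit_insertions(i)
        bv = base_votes[i]
        if not bv:
            out_bases.append(draft.consensus[i])
            out_quals.append(draft.consensus_quals[i])
            continue
        b, q = min(bv.items(), key=lambda kv: (-kv[1], kv[0]))
        if gap_votes[i] > q:
            continue  # majority says this base is an insertion artifact
        runner = max([v for k, v in bv.items() if k != b] + [gap_votes[i]],
                     default=0)
        out_bases.append(b)
        out_quals.append(max(min(q - runner if runner else q,
                                 MAX_CONSENSUS_QUAL), 2))
    emit_insertions(L)
    if not out_bases:
        return draft
    return Contig(id=draft.id, consensus="".join(out_bases),
                  consensus_quals=tuple(out_quals),
                  member_read_ids=draft.member_read_ids)


def assemble_group(members: Sequence, min_overlap_nt: int = 40,
                   min_overlap_identity: float = 0.9) -> List[Contig]:
    """Greedy overlap-layout-consensus of one shared-word group.

    Repeatedly merges the pair with the longest overlap meeting the length
    and identity gates (either orientation); consensus columns are decided
    by quality-weighted majority, with a final column-vote polish of each
    multi-member contig against its constituents.  Reads that never meet
    the gates remain singleton contigs.  Deterministic: ties break on
    identity then on the lexicographic id pair.
    """
    if not members:
        raise ValueError("assemble_group: empty member list")
    working = {c.id: c for c in (_as_working(m) for m in members)}
    if len(working) != len(members):
        raise ValueError("duplicate sequence ids in group")
    constituents: Dict[str, List[Tuple[Contig, str]]] = {
        cid: [(c, "+")] for cid, c in working.items()}
    aligner = make_nucleotide_overlap_aligner()

    def make_indexes(c: Contig):
        rc = revcomp(c.consensus)
        return {"+": (_kmer_index(c.consensus), c.consensus),
                "-": (_kmer_index(rc), rc)}

    indexes = {cid: make_indexes(c) for cid, c in working.items()}

    def admissible(ovl):
        return (ovl is not None and ovl[0] >= min_overlap_nt
                and ovl[1] >= min_overlap_identity)

    pair_cache: Dict[Tuple[str, str], object] = {}

    def pair_overlap(a: str, b: str):
        key = (a, b) if a < b else (b, a)
        if key not in pair_cache:
            pair_cache[key] = _best_overlap(working[key[0]],
                                            working[key[1]], indexes)
        return pair_cache[key]

    ids = sorted(working)
    candidates = {(a, b) for i, a in enumerate(ids) for b in ids[i + 1:]}
    while True:
        best_key, best_val = None, None
        # iterate in sorted id-pair order with strict improvement so that
        # ties on (overlap, identity) resolve to the smallest id pair
        for key in sorted(candidates):
            ovl = pair_overlap(*key)
            if not admissible(ovl):
                continue
            rank = (ovl[0], ovl[1])
            if best_val is None or rank > best_val:
                best_key, best_val = key, rank
        if best_key is None:
            break
        a, b = best_key
        ovl = pair_overlap(a, b)
        merged = _merge(aligner, working[a], working[b], ovl[2])
        flip = {"+": "-", "-": "+"}
        merged_constituents = constituents[a] + [
            (ctg, orient if ovl[2] == "+" else flip[orient])
            for ctg, orient in constituents[b]]
        for cid in (a, b):
            del working[cid]
            del indexes[cid]
            del constituents[cid]
        constituents[merged.id] = merged_constituents
        candidates = {k for k in candidates if a not in k and b not in k}
        pair_cache = {k: v for k, v in pair_cache.items()
                      if a not in k and b not in k}
        working[merged.id] = merged
        indexes[merged.id] = make_indexes(merged)
        for cid in working:
            if cid != merged.id:
                candidates.add(tuple(sorted((cid, merged.id))))
    return [_polish(aligner, working[cid], constituents[cid])
            if len(constituents[cid]) > 1 else working[cid]
            for cid in sorted(working)]


def iterative_clusterize(reads: Sequence[Read],
                         schedule: AssemblySchedule = AssemblySchedule()
                         ) -> List[Contig]:
    """Run the decreasing word-size inclusion loop to a final contig set.

    Every input read id appears in exactly one final contig (read
    conservation) and the number of contigs is nonincreasing across
    rounds.  Final contigs are renamed ``CT%06d`` in order of descending
    read count (ties by smallest member read id).
    """
    contigs = [_as_working(r) for r in reads]
    all_ids = frozenset(r.id for r in reads)
    if len(all_ids) != len(reads):
        raise ValueError("duplicate read ids")
    for word_size in schedule.word_sizes:
        if not contigs:
            break
        partition = shared_word_groups(
            {c.id: c.consensus for c in contigs}, word_size)
        by_id = {c.id: c for c in contigs}
        next_contigs: List[Contig] = []
        for group in partition:
            members = [by_id[cid] for cid in sorted(group)]
            if len(members) == 1:
                next_contigs.extend(members)
            else:
                next_contigs.extend(assemble_group(
                    members, schedule.min_overlap_nt,
                    schedule.min_overlap_identity))
        assembled_ids = frozenset().union(
            *(c.member_read_ids for c in next_contigs)) if next_contigs else frozenset()
        if assembled_ids != all_ids or sum(
                c.read_count for c in next_contigs) != len(all_ids):
            raise AssertionError("read conservation violated during assembly")
        if len(next_contigs) > len(contigs):
            raise AssertionError("contig count increased across a round")
        contigs = next_contigs
    ordered = sorted(contigs, key=lambda c: (-c.read_count, min(c.member_read_ids)))
    return [Contig(id=f"CT{i + 1:06d}", consensus=c.consensus,
                   consensus_quals=c.consensus_quals,
                   member_read_ids=c.member_read_ids)
            for i, c in enumerate(ordered)]


def filter_contigs(contigs: Sequence[Contig], min_len_nt: int = 150,
                   min_reads: int = 1) -> List[Contig]:
    """Keep contigs with length >= ``min_len_nt`` and >= ``min_reads`` reads.

    The length gate implements the 'larger than 149 nt' convention, i.e.
    150 nt and longer pass.  Output is ordered by descending read count,
    then id.
    """
    if min_len_nt < 0 or min_reads < 0:
        raise ValueError("thresholds must be >= 0")
    kept = [c for c in contigs
            if len(c.consensus) >= min_len_nt and c.read_count >= min_reads]
    return sorted(kept, key=lambda c: (-c.read_count, c.id))
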