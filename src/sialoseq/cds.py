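"""Translated homology search and frameshift-repairing CDS extraction.

Contigs are translated in all six frames and searched against a protein
reference set with Smith-Waterman local alignment (BLOSUM62, gaps 11/1).
Each gapless aligned block becomes one HSP; HSPs to the same subject on
the same strand are chained by increasing subject coordinate.  When the
reading frame changes between adjacent HSPs in a chain — the signature of
a pyrosequencing indel surviving into the consensus — the bridging
nucleotides are replaced by N placeholders and one N is added or removed
so the downstream HSP returns to frame.  Codons containing N translate to
X, so a repaired coding sequence stays a whole-codon string whose
translation is stop-free inside aligned regions.

Extraction is attempted only for chains covering at least half of the
subject protein, and the coding sequence is extended upstream to an
in-frame methionine when one occurs within the first 300 codons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .assembly import Contig, revcomp
from .reference import ReferenceDB
from .scoring import (BLOSUM62, evalue_like, make_protein_aligner,
                      sanitize_protein)
from .simulate import translate_cds

#: maximum unaligned query stretch (nt) bridged inside one HSP chain
MAX_QUERY_GAP_NT = 90

#: default minimum local-alignment score for reporting a hit
DEFAULT_MIN_SCORE = 65.0

#: how far upstream (in codons) an initiator Met is sought
MET_WINDOW_AA = 300


class ChainError(ValueError):
    """An HSP chain violating strand/order constraints."""


@dataclass(frozen=True)
class AlignmentHSP:
    """One gapless aligned block between a contig frame and a subject."""

    query_id: str
    subject_id: str
    q_start: int  # 0-based half-open nt coords on the strand used
    q_end: int
    frame: int    # one of +1,+2,+3,-1,-2,-3
    s_start: int  # 0-based half-open aa coords on the subject
    s_end: int
    identities: int
    score: float
    evalue_like: float

    def __post_init__(self):
        if (self.q_end - self.q_start) != 3 * (self.s_end - self.s_start):
            raise ValueError("HSP query span must be 3x the subject span")
        if self.identities > self.s_end - self.s_start:
            raise ValueError("identities exceed aligned length")


@dataclass
class CDSRecord:
    """A frameshift-repaired coding sequence with its evidence trail."""

    id: str
    contig_id: str
    cds_nt: str
    protein: str
    read_count: int
    best_hits: Dict[str, Tuple[str, float, float]] = field(default_factory=dict)
    n_frameshift_repairs: int = 0
    #: (start, end) aa spans of the CDS translation covered by chained HSPs
    aligned_aa_ranges: Tuple[Tuple[int, int], ...] = ()

    def __post_init__(self):
        if translate_cds(self.cds_nt) != self.protein:
            raise ValueError(f"{self.id}: protein is not the CDS translation")

    @property
    def best_coverage(self) -> Optional[float]:
        if not self.best_hits:
            return None
        return max(cov for _, cov, _ in self.best_hits.values())

    @property
    def best_evalue(self) -> Optional[float]:
        if not self.best_hits:
            return None
        return min(ev for _, _, ev in self.best_hits.values())


def six_frame_translate(contig) -> Dict[int, str]:
    """Standard-code translation of all six frames (stops '*', N-codons 'X')."""
    seq = contig.consensus if isinstance(contig, Contig) else str(contig)
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    frames: Dict[int, str] = {}
    rc = revcomp(seq)
    for off in range(3):
        for frame, s in ((off + 1, seq), (-(off + 1), rc)):
            sub = s[off:]
            sub = sub[:len(sub) - len(sub) % 3]
            frames[frame] = translate_cds(sub) if sub else ""
    return frames


def met_segments(translations: Dict[int, str],
                 window_aa: int = 300) -> List[Tuple[int, int, str]]:
    """Candidate peptides from each Met in the first ``window_aa`` residues.

    Returns (frame, 0-based Met index, peptide-to-first-stop-or-end)
    triples for every frame.
    """
    if window_aa < 1:
        raise ValueError("window_aa must be >= 1")
    out: List[Tuple[int, int, str]] = []
    for frame in sorted(translations, key=lambda f: (f < 0, abs(f))):
        aa = translations[frame]
        for i, c in enumerate(aa[:window_aa]):
            if c != "M":
                continue
            stop = aa.find("*", i)
            seg = aa[i:stop] if stop >= 0 else aa[i:]
            out.append((frame, i, seg))
    return out


def _block_stats(qseq: str, sseq: str, qs: int, qe: int, ss: int):
    """(identities, substitution score) for a gapless block."""
    ident, score = 0, 0.0
    for k in range(qe - qs):
        a, b = qseq[qs + k], sseq[ss + k]
        if a == b:
            ident += 1
        score += BLOSUM62[a, b]
    return ident, score


def search_translated(contig: Contig, db: ReferenceDB,
                      min_score: float = DEFAULT_MIN_SCORE
                      ) -> List[AlignmentHSP]:
    """Six-frame local search of a contig against a protein database.

    Local alignments scoring at least ``min_score`` are decomposed into
    gapless blocks, each reported as one HSP with query coordinates in
    nucleotides on the strand searched.  Deterministic ordering: score
    descending, then subject id.
    """
    if not len(db):
        raise ValueError("empty reference database")
    aligner = make_protein_aligner("local")
    frames = six_frame_translate(contig)
    n_db = db.total_residues
    hsps: List[AlignmentHSP] = []
    for frame in sorted(frames, key=lambda f: (f < 0, abs(f))):
        prot = sanitize_protein(frames[frame])
        if len(prot) < 5:
            continue
        off = abs(frame) - 1
        for ref in db.records:
            subject = sanitize_protein(ref.protein)
            if aligner.score(prot, subject) < min_score:
                continue
            alignment = aligner.align(prot, subject)[0]
            t_blocks, s_blocks = alignment.aligned
            for (ts, te), (ss, se) in zip(t_blocks, s_blocks):
                ts, te, ss, se = int(ts), int(te), int(ss), int(se)
                ident, bscore = _block_stats(prot, subject, ts, te, ss)
                hsps.append(AlignmentHSP(
                    query_id=contig.id, subject_id=ref.id,
                    q_start=off + 3 * ts, q_end=off + 3 * te,
                    frame=frame, s_start=ss, s_end=se,
                    identities=ident, score=bscore,
                    evalue_like=evalue_like(bscore, max(len(prot), 1), n_db)))
    hsps.sort(key=lambda h: (-h.score, h.subject_id, h.s_start))
    return hsps


def _trim_hsp(h: AlignmentHSP, n_aa: int) -> Optional[AlignmentHSP]:
    """Drop ``n_aa`` residues from the start of an HSP (None if exhausted)."""
    if n_aa <= 0:
        return h
    if h.s_start + n_aa >= h.s_end:
        return None
    frac = (h.s_end - h.s_start - n_aa) / (h.s_end - h.s_start)
    return AlignmentHSP(
        query_id=h.query_id, subject_id=h.subject_id,
        q_start=h.q_start + 3 * n_aa, q_end=h.q_end, frame=h.frame,
        s_start=h.s_start + n_aa, s_end=h.s_end,
        identities=min(int(h.identities * frac), h.s_end - h.s_start - n_aa),
        score=h.score * frac, evalue_like=h.evalue_like)


def _trim_hsp_end(h: AlignmentHSP, new_s_end: int) -> Optional[AlignmentHSP]:
    """Shorten an HSP so it ends at subject position ``new_s_end``."""
    if new_s_end >= h.s_end:
        return h
    if new_s_end <= h.s_start:
        return None
    frac = (new_s_end - h.s_start) / (h.s_end - h.s_start)
    return AlignmentHSP(
        query_id=h.query_id, subject_id=h.subject_id,
        q_start=h.q_start, q_end=h.q_start + 3 * (new_s_end - h.s_start),
        frame=h.frame, s_start=h.s_start, s_end=new_s_end,
        identities=min(int(h.identities * frac), new_s_end - h.s_start),
        score=h.score * frac, evalue_like=h.evalue_like)


def _hsp_residue(frames: Dict[int, str], h: AlignmentHSP, s: int) -> str:
    """Query residue aligned to subject position ``s`` under HSP ``h``."""
    off = abs(h.frame) - 1
    return frames[h.frame][(h.q_start - off) // 3 + (s - h.s_start)]


def _best_crossover(frames: Dict[int, str], subject: str,
                    prev: AlignmentHSP, cur: AlignmentHSP) -> int:
    """Optimal subject split point inside the overlap of two HSPs.

    A frameshifted translation keeps weak similarity to the true protein
    (adjacent frames share two of three codon bases), so the upstream
    alignment routinely overextends past the indel.  The split maximizes
    the summed substitution score of taking upstream residues before the
    split and downstream residues after it.
    """
    lo, hi = cur.s_start, min(prev.s_end, cur.s_end)
    best_k, best_score = hi, None
    suffix_down = 0.0
    down = [float(BLOSUM62[_hsp_residue(frames, cur, s), subject[s]])
            for s in range(lo, hi)]
    up = [float(BLOSUM62[_hsp_residue(frames, prev, s), subject[s]])
          for s in range(lo, hi)]
    # evaluate all split points k in [lo, hi]
    prefix_up = [0.0]
    for v in up:
        prefix_up.append(prefix_up[-1] + v)
    suffix_down = [0.0]
    for v in reversed(down):
        suffix_down.append(suffix_down[-1] + v)
    suffix_down.reverse()
    for idx, k in enumerate(range(lo, hi + 1)):
        total = prefix_up[idx] + suffix_down[idx]
        if best_score is None or total > best_score:
            best_k, best_score = k, total
    return best_k


def build_chain(hsps: Sequence[AlignmentHSP],
                frames: Optional[Dict[int, str]] = None,
                subject: Optional[str] = None,
                max_query_gap_nt: int = MAX_QUERY_GAP_NT
                ) -> List[AlignmentHSP]:
    """Chain HSPs to one subject on one strand.

    Blocks are taken in subject order.  Where adjacent blocks overlap on
    the subject, the crossover point is optimized against the subject
    when frame translations are supplied (otherwise the downstream block
    is trimmed); blocks that would still move backwards on either
    sequence, or jump more than ``max_query_gap_nt`` on the query, are
    skipped.
    """
    if not hsps:
        return []
    subject_id = hsps[0].subject_id
    sign = hsps[0].frame > 0
    for h in hsps:
        if h.subject_id != subject_id or (h.frame > 0) != sign:
            raise ChainError(
                f"mixed subjects/strands in chain for {h.query_id}")
    ordered = sorted(hsps, key=lambda h: (h.s_start, h.q_start, -h.score))
    # blocks under 3 aa carry no reliable frame signal; drop them unless
    # nothing else is left
    substantial = [h for h in ordered if h.s_end - h.s_start >= 3]
    if frames is not None and subject is not None:
        # frameshifted translations keep weak similarity to the true
        # protein, producing low-identity junk blocks; require real
        # identity before a block can join a chain
        strong = []
        for h in substantial:
            ident = sum(
                1 for s in range(h.s_start, h.s_end)
                if _hsp_residue(frames, h, s) == subject[s])
            if ident / (h.s_end - h.s_start) >= 0.5 or h.score >= 50:
                strong.append(h)
        substantial = strong or substantial
    ordered = substantial or ordered
    chain: List[AlignmentHSP] = []
    for h in ordered:
        if not chain:
            chain.append(h)
            continue
        prev = chain[-1]
        cur: Optional[AlignmentHSP] = h
        new_prev = prev
        if cur.s_start < prev.s_end:
            if frames is not None and subject is not None and cur.s_end > prev.s_end:
                k = _best_crossover(frames, subject, prev, cur)
                trimmed_prev = _trim_hsp_end(prev, k)
                cur = _trim_hsp(cur, k - cur.s_start)
                if trimmed_prev is not None and cur is not None:
                    new_prev = trimmed_prev
                else:
                    cur = _trim_hsp(h, prev.s_end - h.s_start)
                    new_prev = prev
            else:
                cur = _trim_hsp(cur, prev.s_end - cur.s_start)
        if cur is not None and cur.q_start < new_prev.q_end:
            need = -(-(new_prev.q_end - cur.q_start) // 3)  # ceil division
            cur = _trim_hsp(cur, need)
        if cur is None:
            continue
        if cur.q_start < new_prev.q_end or cur.s_start < new_prev.s_end:
            continue
        if cur.q_start - new_prev.q_end > max_query_gap_nt:
            continue
        chain[-1] = new_prev
        chain.append(cur)
    if frames is not None and subject is not None:
        chain = _widen_frameshift_masks(chain, frames, subject)
    return chain


def _widen_frameshift_masks(chain: List[AlignmentHSP],
                            frames: Dict[int, str], subject: str,
                            limit: int = 4) -> List[AlignmentHSP]:
    """Fold junction-adjacent mismatches into the masked bridge.

    Residues immediately flanking a frame change that disagree with the
    subject belong to the uncertain frameshift region; trimming them off
    the HSPs (up to ``limit`` per side) widens the N mask instead of
    keeping frameshift-garbled residues in the repaired translation.
    """
    out = list(chain)
    for idx in range(len(out) - 1):
        a, b = out[idx], out[idx + 1]
        if (b.q_start - a.q_end) % 3 == 0:
            continue  # same frame, no frameshift at this junction
        t = 0
        while (t < limit and a.s_end - 1 - t > a.s_start and
               _hsp_residue(frames, a, a.s_end - 1 - t)
               != subject[a.s_end - 1 - t]):
            t += 1
        if t:
            a = _trim_hsp_end(a, a.s_end - t) or a
        lead = 0
        while (lead < limit and b.s_start + lead < b.s_end - 1 and
               _hsp_residue(frames, b, b.s_start + lead)
               != subject[b.s_start + lead]):
            lead += 1
        if lead:
            b = _trim_hsp(b, lead) or b
        out[idx], out[idx + 1] = a, b
    return out


def chain_coverage(chain: Sequence[AlignmentHSP], subject_len: int) -> float:
    return sum(h.s_end - h.s_start for h in chain) / subject_len


def extract_cds(contig: Contig, hsp_chain: Sequence[AlignmentHSP],
                subject: str, min_subject_coverage: float = 0.5,
                met_window_aa: int = MET_WINDOW_AA) -> CDSRecord:
    """Extract the frameshift-repaired coding sequence under an HSP chain.

    Between adjacent HSPs whose frames differ the bridge is replaced by
    N's, with one N added or subtracted (whichever is the smaller edit)
    so the downstream HSP returns to frame.  The CDS is extended upstream
    to the furthest in-frame Met reachable without crossing a stop codon
    within ``met_window_aa`` codons.
    """
    if not hsp_chain:
        raise ChainError(f"{contig.id}: empty HSP chain")
    sid = hsp_chain[0].subject_id
    sign = hsp_chain[0].frame > 0
    for h in hsp_chain:
        if h.subject_id != sid:
            raise ChainError(f"{contig.id}: chain spans multiple subjects")
        if (h.frame > 0) != sign:
            raise ChainError(f"{contig.id}: chain mixes strands")
    for a, b in zip(hsp_chain, hsp_chain[1:]):
        if b.s_start < a.s_end or b.q_start < a.q_end:
            raise ChainError(
                f"{contig.id}: out-of-order coordinates in chain to {sid}")
    coverage = chain_coverage(hsp_chain, len(subject))
    if coverage < min_subject_coverage:
        raise ChainError(
            f"{contig.id}: chain covers {coverage:.2f} of {sid}, below "
            f"{min_subject_coverage}")

    seq = contig.consensus if sign else revcomp(contig.consensus)

    # upstream in-frame Met scan, stopping at a stop codon
    p = hsp_chain[0].q_start
    best_atg = p if seq[p:p + 3] == "ATG" else None
    steps = 0
    while p >= 3 and steps < met_window_aa:
        codon = seq[p - 3:p]
        if translate_cds(codon) == "*":
            break
        if codon == "ATG":
            best_atg = p - 3
        p -= 3
        steps += 1
    cds_start = best_atg if best_atg is not None else hsp_chain[0].q_start

    pieces: List[str] = [seq[cds_start:hsp_chain[0].q_start]]
    length_so_far = hsp_chain[0].q_start - cds_start
    n_repairs = 0
    aa_ranges: List[Tuple[int, int]] = []
    for i, h in enumerate(hsp_chain):
        aa_start = length_so_far // 3
        pieces.append(seq[h.q_start:h.q_end])
        length_so_far += h.q_end - h.q_start
        aa_ranges.append((aa_start, length_so_far // 3))
        if i + 1 < len(hsp_chain):
            nxt = hsp_chain[i + 1]
            gap = nxt.q_start - h.q_end
            if gap % 3 == 0:
                pieces.append(seq[h.q_end:nxt.q_start])
                length_so_far += gap
            else:
                n_repairs += 1
                fixed = gap - 1 if gap % 3 == 1 else gap + 1
                pieces.append("N" * fixed)
                length_so_far += fixed
    cds_nt = "".join(pieces)
    return CDSRecord(
        id=f"{contig.id}", contig_id=contig.id, cds_nt=cds_nt,
        protein=translate_cds(cds_nt), read_count=contig.read_count,
        n_frameshift_repairs=n_repairs,
        aligned_aa_ranges=tuple(aa_ranges))


def extract_from_contig(contig: Contig, db: ReferenceDB,
                        min_score: float = DEFAULT_MIN_SCORE,
                        min_subject_coverage: float = 0.5
                        ) -> Optional[CDSRecord]:
    """Search one contig and extract the best-supported coding sequence.

    Chains are built per (subject, strand); the chain with the highest
    total score whose combined subject coverage reaches the gate wins
    (ties by subject id).  Returns None when no chain qualifies.
    """
    hsps = search_translated(contig, db, min_score=min_score)
    frames = {f: sanitize_protein(t)
              for f, t in six_frame_translate(contig).items()}
    groups: Dict[Tuple[str, bool], List[AlignmentHSP]] = {}
    for h in hsps:
        groups.setdefault((h.subject_id, h.frame > 0), []).append(h)
    best = None
    for (sid, sign), group in sorted(groups.items()):
        chain = build_chain(group, frames, sanitize_protein(db[sid].protein))
        if not chain:
            continue
        cov = chain_coverage(chain, len(db[sid].protein))
        if cov < min_subject_coverage:
            continue
        total = sum(h.score for h in chain)
        key = (-total, sid)
        if best is None or key < best[0]:
            best = (key, chain, sid, cov, total)
    if best is None:
        return None
    _, chain, sid, cov, total = best
    record = extract_cds(contig, chain, db[sid].protein,
                         min_subject_coverage=min_subject_coverage)
    qlen = max(len(f) for f in six_frame_translate(contig).values())
    record.best_hits[db.name] = (
        sid, cov, evalue_like(total, max(qlen, 1), db.total_residues))
    return record


def coverage_tally(cds_set: Sequence[CDSRecord],
                   coverage_threshold: float = 0.75,
                   evalue_threshold: float = 1e-15) -> Tuple[int, int]:
    """Count CDS with best-hit coverage strictly above the threshold, and
    CDS whose best expectation value is at or below the threshold."""
    n_high = sum(1 for c in cds_set
                 if c.best_coverage is not None
                 and c.best_coverage > coverage_threshold)
    n_low = sum(1 for c in cds_set
                if c.best_evalue is not None
                and c.best_evalue <= evalue_threshold)
    return n_high, n_low
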