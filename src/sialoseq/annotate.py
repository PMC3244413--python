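"""Multi-evidence functional classification of extracted coding sequences.

Each coding sequence is classified into one of four top classes —
Secreted (S), Housekeeping (H), Unknown (U) or Transposable Element (TE)
— and into a finer subcategory drawn from an editable controlled
vocabulary of roughly thirty entries covering the protein families
recurrent in tick saliva (Kunitz, TIL, lipocalin, evasin, mucin,
metalloprotease, basic tail, glycine rich, ...).

Sequence signals (signal peptide, transmembrane helices, mucin-type
O-glycosylation density, furin cleavage motifs) are produced by built-in
deterministic heuristics with the same interfaces as the external
predictors practitioners would normally call, and verdicts from such
external tools can be substituted through a per-protein tab-separated
file.  The classifier itself is a fixed precedence over rule firings, so
permuting the order of evidence databases never changes the outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .cds import CDSRecord
from .reference import ReferenceDB
from .scoring import evalue_like, make_protein_aligner, sanitize_protein

#: hydropathy gate shared by the signal-peptide and TM-helix heuristics
HYDROPATHY_CUTOFF = 1.6
#: default expectation-value gate for an informative database hit
INFORMATIVE_EVALUE = 1e-5

_SMALL_CLEAVAGE = set("AGSCT")


# ---------------------------------------------------------------------------
# built-in sequence-signal heuristics (pluggable predictor stand-ins)


def _mean_kd(window: str) -> float:
    vals = [KYTE_DOOLITTLE.get(c, 0.0) for c in window]
    return sum(vals) / len(vals) if vals else 0.0


def predict_signal_peptide(protein: str) -> Tuple[bool, Optional[int]]:
    """Heuristic secretion-signal call on an N-terminal leader.

    Requires, within the first 35 residues, an 8-residue window of mean
    Kyte-Doolittle hydropathy >= 1.6 followed within 6 residues by a
    small residue (A, G, S, C, T) marking the cleavage position.
    Returns (flag, 1-based cleavage position).
    """
    if not protein:
        raise ValueError("empty protein")
    if protein[0] != "M":
        return False, None
    limit = min(35, len(protein))
    for start in range(1, limit - 8 + 1):
        window = protein[start:start + 8]
        if _mean_kd(window) < HYDROPATHY_CUTOFF:
            continue
        for j in range(start + 8, min(start + 8 + 6, len(protein))):
            if protein[j] in _SMALL_CLEAVAGE:
                return True, j + 1
    return False, None


def count_tm_helices(protein: str, after: int = 0) -> int:
    """Count disjoint >=19-residue windows of mean hydropathy >= 1.6.

    ``after`` is a 0-based offset (e.g. a signal cleavage position) from
    which scanning starts, so a cleaved leader is not called a helix.
    """
    n = 0
    i = max(after, 0)
    while i + 19 <= len(protein):
        if _mean_kd(protein[i:i + 19]) >= HYDROPATHY_CUTOFF:
            n += 1
            i += 19
        else:
            i += 1
    return n


def count_oglyc_sites(protein: str) -> int:
    """Count S/T residues whose surrounding 11-mer holds >= 5 S/T/P."""
    n = 0
    for i, c in enumerate(protein):
        if c not in "ST":
            continue
        window = protein[max(0, i - 5):i + 6]
        if sum(1 for x in window if x in "STP") >= 5:
            n += 1
    return n


def find_furin_sites(protein: str) -> List[int]:
    """All R-X-[KR]-R motifs, reported as 1-based positions of the final R,
    including overlapping occurrences."""
    sites = []
    for i in range(len(protein) - 3):
        if (protein[i] == "R" and protein[i + 2] in "KR"
                and protein[i + 3] == "R"):
            sites.append(i + 4)
    return sites


def load_signal_verdicts(path) -> Dict[str, Tuple[bool, Optional[int]]]:
    """External-predictor adapter: per-protein tab-separated verdicts.

    Columns: protein id, Y/N flag, optional 1-based cleavage position.
    """
    out: Dict[str, Tuple[bool, Optional[int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            flag = parts[1].upper() in ("Y", "YES", "1", "TRUE")
            pos = int(parts[2]) if flag and len(parts) > 2 and parts[2] else None
            out[parts[0]] = (flag, pos)
    return out


# ---------------------------------------------------------------------------
# evidence and rules


@dataclass(frozen=True)
class DBHit:
    subject_id: str
    keywords: Tuple[str, ...]
    evalue_like: float
    coverage: float


@dataclass
class EvidenceBundle:
    db_hits: Dict[str, DBHit] = field(default_factory=dict)
    signal_peptide: Tuple[bool, Optional[int]] = (False, None)
    tm_helix_count: int = 0
    oglyc_site_count: int = 0
    furin_sites: Tuple[int, ...] = ()
    contaminant_hit: Optional[str] = None  # "rRNA" | "mito"

    def __post_init__(self):
        flag, pos = self.signal_peptide
        if flag != (pos is not None):
            raise ValueError("cleavage position present iff signal flag set")


@dataclass(frozen=True)
class ClassRule:
    keyword: str
    top_class: str  # S | H | U | TE
    subcategory: str
    max_evalue: float = INFORMATIVE_EVALUE


#: controlled vocabulary: keyword tag -> (class, subcategory).  Editable
#: and extensible through load_rules(); these defaults cover the secreted
#: families recurrent in tick sialomes plus broad housekeeping roles.
DEFAULT_RULES: Tuple[ClassRule, ...] = tuple(
    ClassRule(k, c, s) for k, c, s in [
        # transposable elements
        ("transposase", "TE", "transposable element - transposase"),
        ("retroelement", "TE", "transposable element - retroelement"),
        # secreted families
        ("kunitz", "S", "protease inhibitor - Kunitz"),
        ("til", "S", "protease inhibitor - TIL"),
        ("thyropin", "S", "protease inhibitor - thyropin"),
        ("cystatin", "S", "protease inhibitor - cystatin"),
        ("serpin", "S", "protease inhibitor - serpin"),
        ("kazal", "S", "protease inhibitor - Kazal"),
        ("carboxypeptidase-inhibitor", "S", "protease inhibitor - carboxypeptidase"),
        ("pebp", "S", "PEBP family"),
        ("metalloprotease", "S", "enzyme - metalloprotease"),
        ("serine-protease", "S", "enzyme - serine protease"),
        ("legumain", "S", "enzyme - legumain"),
        ("endonuclease", "S", "enzyme - endonuclease"),
        ("apyrase", "S", "enzyme - 5'-nucleotidase/apyrase"),
        ("lipase", "S", "enzyme - lipase/esterase"),
        ("glycosidase", "S", "enzyme - glycosidase"),
        ("sulfatase", "S", "enzyme - sulfatase"),
        ("lipocalin", "S", "lipocalin"),
        ("antigen-5", "S", "antigen-5/CRISP"),
        ("prokineticin", "S", "prokineticin"),
        ("serum-amyloid", "S", "serum amyloid"),
        ("mucin", "S", "mucin"),
        ("antimicrobial", "S", "immunity/antimicrobial peptide"),
        ("glycine-rich", "S", "glycine-rich/cement"),
        ("ggy", "S", "GGY peptide"),
        ("ixodegrin", "S", "ixodegrin"),
        ("disintegrin", "S", "disintegrin"),
        ("salp15", "S", "Salp15-like"),
        ("basic-tail", "S", "basic tail/18.3 kDa"),
        ("23-kda", "S", "23 kDa family"),
        ("8.9-kda", "S", "8.9 kDa family"),
        ("ixostatin", "S", "ixostatin"),
        ("one-of-each", "S", "one-of-each family"),
        ("evasin", "S", "evasin"),
        ("dap-36", "S", "DAP-36 immunosuppressant"),
        ("13-kda", "S", "13 kDa family"),
        # housekeeping roles
        ("ribosomal", "H", "protein synthesis machinery"),
        ("elongation-factor", "H", "protein synthesis machinery"),
        ("actin", "H", "cytoskeletal"),
        ("tubulin", "H", "cytoskeletal"),
        ("histone", "H", "nuclear regulation"),
        ("proteasome", "H", "proteasome machinery"),
        ("cytochrome", "H", "energy metabolism"),
        ("heat-shock", "H", "protein modification/chaperone"),
        ("transporter", "H", "transporters/channels"),
        ("kinase", "H", "signal transduction"),
    ])

VALID_CLASSES = ("S", "H", "U", "TE")
UNKNOWN_SUBCATEGORY = "unknown"
PUTATIVE_SECRETED = "putative secreted, unknown family"
CONTAMINANT_SUBCATEGORY = "rRNA/mitochondrial contaminant"


@dataclass(frozen=True)
class Classification:
    top_class: str
    subcategory: str
    rationale: Tuple[str, ...]

    def __post_init__(self):
        if self.top_class not in VALID_CLASSES:
            raise ValueError(f"unknown class {self.top_class}")


def load_rules(path) -> Tuple[ClassRule, ...]:
    """Read a (keyword, class, subcategory, max_evalue) rules table.

    Malformed class tokens are a configuration error raised at load time.
    """
    rules: List[ClassRule] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("keyword\t"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: expected >=3 tab-separated fields")
            kw, cls, sub = parts[0], parts[1], parts[2]
            if cls not in VALID_CLASSES:
                raise ValueError(
                    f"{path}:{ln}: unknown class {cls!r} (expected one of "
                    f"{VALID_CLASSES})")
            if not kw:
                raise ValueError(f"{path}:{ln}: empty keyword")
            ev = float(parts[3]) if len(parts) > 3 and parts[3] else INFORMATIVE_EVALUE
            rules.append(ClassRule(kw, cls, sub, ev))
    if not rules:
        raise ValueError(f"{path}: empty rules table")
    return tuple(rules)


def write_rules(rules: Sequence[ClassRule], path) -> None:
    with open(path, "w") as fh:
        fh.write("keyword\tclass\tsubcategory\tmax_evalue\n")
        for r in rules:
            fh.write(f"{r.keyword}\t{r.top_class}\t{r.subcategory}\t{r.max_evalue:g}\n")


# ---------------------------------------------------------------------------
# evidence collection and the classifier


def build_evidence(cds: CDSRecord, dbs: Sequence[ReferenceDB],
                   contaminants: Optional[Dict[str, str]] = None,
                   signal_override: Optional[Tuple[bool, Optional[int]]] = None,
                   min_score: float = 65.0) -> EvidenceBundle:
    """Collect per-database best hits and sequence signals for one CDS.

    ``contaminants`` maps contig ids to "rRNA"/"mito" for contigs matched
    against contaminant nucleotide sets upstream.  ``signal_override``
    substitutes an external predictor verdict for the built-in heuristic.
    """
    aligner = make_protein_aligner("local")
    prot = sanitize_protein(cds.protein)
    hits: Dict[str, DBHit] = {}
    for db in dbs:
        best = None
        for ref in db.records:
            score = aligner.score(prot, sanitize_protein(ref.protein))
            if score < min_score:
                continue
            key = (-score, ref.id)
            if best is None or key < best[0]:
                best = (key, ref, score)
        if best is not None:
            _, ref, score = best
            alignment = aligner.align(prot, sanitize_protein(ref.protein))[0]
            s_blocks = alignment.aligned[1]
            covered = sum(int(e) - int(s) for s, e in s_blocks)
            hits[db.name] = DBHit(
                subject_id=ref.id, keywords=(ref.keyword,) if ref.keyword else (),
                evalue_like=evalue_like(score, max(len(prot), 1),
                                        db.total_residues),
                coverage=covered / len(ref.protein))
    signal = (signal_override if signal_override is not None
              else predict_signal_peptide(cds.protein) if cds.protein and
              cds.protein[0] == "M" else (False, None))
    cleave = signal[1] if signal[0] else 0
    return EvidenceBundle(
        db_hits=hits,
        signal_peptide=signal,
        tm_helix_count=count_tm_helices(cds.protein, after=cleave or 0),
        oglyc_site_count=count_oglyc_sites(cds.protein),
        furin_sites=tuple(find_furin_sites(cds.protein)),
        contaminant_hit=(contaminants or {}).get(cds.contig_id))


def _rule_hits(ev: EvidenceBundle, rules_by_kw: Dict[str, ClassRule],
               wanted_class: str):
    """(evalue, db, rule, hit) for informative hits of a given class."""
    found = []
    for db_name in sorted(ev.db_hits):
        hit = ev.db_hits[db_name]
        for kw in hit.keywords:
            rule = rules_by_kw.get(kw)
            if (rule is not None and rule.top_class == wanted_class
                    and hit.evalue_like <= rule.max_evalue):
                found.append((hit.evalue_like, db_name, rule, hit))
    found.sort(key=lambda t: (t[0], t[1]))
    return found


def classify(cds: CDSRecord, ev: EvidenceBundle,
             rules: Sequence[ClassRule] = DEFAULT_RULES) -> Classification:
    """Deterministic precedence classifier.

    1. contaminant hit            -> H, rRNA/mito contaminant
    2. transposon keyword hit     -> TE
    3. signal peptide, <=1 TM helix, and a secreted-family keyword hit
       (or no informative hit at all) -> S
    4. housekeeping keyword hit   -> H
    5. otherwise                  -> U
    """
    if not rules:
        raise ValueError("empty rules table")
    rules_by_kw: Dict[str, ClassRule] = {}
    for r in rules:
        rules_by_kw.setdefault(r.keyword, r)
    rationale: List[str] = []

    if ev.contaminant_hit:
        rationale.append(f"contaminant:{ev.contaminant_hit}")
        return Classification("H", CONTAMINANT_SUBCATEGORY, tuple(rationale))
    rationale.append("no-contaminant")

    te = _rule_hits(ev, rules_by_kw, "TE")
    if te:
        evl, db_name, rule, hit = te[0]
        rationale.append(f"te-hit:{db_name}:{hit.subject_id}:{evl:.2e}")
        return Classification("TE", rule.subcategory, tuple(rationale))
    rationale.append("no-te-hit")

    any_informative = any(
        hit.evalue_like <= rules_by_kw[kw].max_evalue
        for hit in ev.db_hits.values() for kw in hit.keywords
        if kw in rules_by_kw)
    signal_ok = ev.signal_peptide[0] and ev.tm_helix_count <= 1
    if signal_ok:
        sec = _rule_hits(ev, rules_by_kw, "S")
        if sec:
            evl, db_name, rule, hit = sec[0]
            rationale.append(
                f"signal+secreted-hit:{db_name}:{hit.subject_id}:{evl:.2e}")
            return Classification("S", rule.subcategory, tuple(rationale))
        if not any_informative:
            rationale.append("signal+no-informative-hit")
            return Classification("S", PUTATIVE_SECRETED, tuple(rationale))
        rationale.append("signal-but-informative-nonsecreted-hit")
    else:
        rationale.append("no-secretion-signal"
                         if not ev.signal_peptide[0] else "signal-but-multi-TM")

    hk = _rule_hits(ev, rules_by_kw, "H")
    if hk:
        evl, db_name, rule, hit = hk[0]
        rationale.append(f"housekeeping-hit:{db_name}:{hit.subject_id}:{evl:.2e}")
        return Classification("H", rule.subcategory, tuple(rationale))
    rationale.append("fallback-unknown")
    return Classification("U", UNKNOWN_SUBCATEGORY, tuple(rationale))


def detect_contaminants(contigs, contaminant_seqs: Dict[str, Tuple[str, str]],
                        word_size: int = 60) -> Dict[str, str]:
    """Flag contigs sharing an exact ``word_size``-mer with a contaminant.

    ``contaminant_seqs`` maps sequence id -> (kind, nucleotides) with kind
    "rRNA" or "mito".  Returns contig id -> kind.
    """
    from .assembly import revcomp
    words: Dict[str, str] = {}
    for _, (kind, seq) in sorted(contaminant_seqs.items()):
        for s in (seq, revcomp(seq)):
            for i in range(len(s) - word_size + 1):
                words.setdefault(s[i:i + word_size], kind)
    out: Dict[str, str] = {}
    for c in contigs:
        for i in range(len(c.consensus) - word_size + 1):
            kind = words.get(c.consensus[i:i + word_size])
            if kind:
                out[c.id] = kind
                break
    return out
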