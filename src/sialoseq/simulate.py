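"""Synthetic ground truth: multigene transcript families and 454-style reads.

The generator emulates the salient features of a normalized salivary-gland
cDNA library sequenced on a 454-type platform:

* multigene families produced by gene duplication, with controlled
  within-family amino-acid divergence (p-distance scale);
* planted N-terminal signal peptides on a configurable fraction of
  families (secreted families), the rest carrying housekeeping roles;
* log-normal expression skew across transcripts;
* reads of ~344 nt mean length with per-base phred qualities and
  homopolymer-biased insertion/deletion errors, the dominant
  pyrosequencing error mode and the reason the downstream CDS extractor
  repairs frameshifts.

Every simulated error is recorded in a per-read origin ledger so that
recovery of assembly, extraction and classification can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Data import CodonTable

from .assembly import Read, revcomp
from .reference import ReferenceDB, ReferenceProtein

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: leader-grammar alphabets for planted signal peptides; the hydrophobic
#: set deliberately avoids residues in the small cleavage-site set so the
#: planted cleavage position is unambiguous
_SIGNAL_HYDROPHOBIC = "LIVFM"
_SIGNAL_SMALL = "AGS"

SECRETED_KEYWORDS = (
    "kunitz", "lipocalin", "evasin", "mucin", "antigen-5", "basic-tail",
    "glycine-rich", "serpin", "cystatin", "til", "ixodegrin",
    "metalloprotease",
)
HOUSEKEEPING_KEYWORDS = (
    "ribosomal", "actin", "tubulin", "histone", "proteasome",
    "cytochrome", "elongation-factor", "heat-shock",
)

_table = CodonTable.unambiguous_dna_by_id[1]
CODONS_BY_AA: Dict[str, Tuple[str, ...]] = {}
for codon, aa in _table.forward_table.items():
    CODONS_BY_AA.setdefault(aa, tuple())
    CODONS_BY_AA[aa] = CODONS_BY_AA[aa] + (codon,)
STOP_CODONS = tuple(_table.stop_codons)


def translate_cds(cds_nt: str) -> str:
    """Table-driven translation; any codon containing N yields 'X'."""
    if len(cds_nt) % 3:
        raise ValueError("CDS length not divisible by 3")
    out = []
    for i in range(0, len(cds_nt), 3):
        codon = cds_nt[i:i + 3]
        if "N" in codon:
            out.append("X")
        elif codon in STOP_CODONS:
            out.append("*")
        else:
            out.append(_table.forward_table[codon])
    return "".join(out)


@dataclass(frozen=True)
class TruthTranscript:
    id: str
    family_id: str
    cds_nt: str
    protein: str
    has_signal_peptide: bool
    signal_cleavage_pos: Optional[int]  # 1-based residue index
    expression_weight: float

    def __post_init__(self):
        if len(self.cds_nt) % 3:
            raise ValueError(f"{self.id}: CDS length not divisible by 3")
        if translate_cds(self.cds_nt) != self.protein or "*" in self.protein:
            raise ValueError(f"{self.id}: CDS does not translate to protein")
        if self.has_signal_peptide:
            if not (self.signal_cleavage_pos and
                    1 <= self.signal_cleavage_pos <= 40):
                raise ValueError(f"{self.id}: invalid signal cleavage position")
        if self.expression_weight <= 0:
            raise ValueError(f"{self.id}: nonpositive expression weight")


@dataclass(frozen=True)
class PlantedEdit:
    """One simulated sequencing error, in emitted-template coordinates."""
    pos: int
    kind: str  # ins | del | sub


@dataclass(frozen=True)
class ReadOrigin:
    transcript_id: str
    start: int
    strand: str
    edits: Tuple[PlantedEdit, ...]


@dataclass
class TruthSet:
    transcripts: List[TruthTranscript]
    read_origins: Dict[str, ReadOrigin] = field(default_factory=dict)
    decoy_proteins: List[Tuple[str, str, str]] = field(default_factory=list)
    #: family id -> (keyword tag, planted top class "S"/"H")
    family_roles: Dict[str, Tuple[str, str]] = field(default_factory=dict)

    def transcript(self, tid: str) -> TruthTranscript:
        return next(t for t in self.transcripts if t.id == tid)


def perturb_protein(protein: str, rate: float, rng: np.random.Generator,
                    protect_prefix: int = 1) -> str:
    """Substitute each residue past ``protect_prefix`` with prob ``rate``."""
    out = list(protein)
    for i in range(protect_prefix, len(out)):
        if rng.random() < rate:
            choices = [a for a in AA_ALPHABET if a != out[i]]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _random_protein(n_aa: int, rng: np.random.Generator) -> str:
    return "".join(AA_ALPHABET[i] for i in rng.integers(0, 20, size=n_aa))


#: polar/charged-enriched residues typical of cytosolic N-termini
_POLAR = "DEKRNQSTHGP"


def _random_nterm(n_aa: int, rng: np.random.Generator) -> str:
    """N-terminal stretch for non-secreted proteins.

    Cytosolic protein N-termini are depleted of the long hydrophobic
    stretches that define signal peptides; residues draw from a
    polar-enriched pool 70% of the time and uniformly otherwise.
    """
    out = []
    for _ in range(n_aa):
        if rng.random() < 0.7:
            out.append(_POLAR[rng.integers(len(_POLAR))])
        else:
            out.append(AA_ALPHABET[rng.integers(20)])
    return "".join(out)


def _encode(protein: str, rng: np.random.Generator) -> List[str]:
    return [CODONS_BY_AA[aa][rng.integers(len(CODONS_BY_AA[aa]))]
            for aa in protein]


def generate_families(n_families: int, copies_per_family: int,
                      target_aa_divergence: float, mean_cds_len_nt: int,
                      signal_fraction: float, seed: int) -> TruthSet:
    """Generate ``n_families`` x ``copies_per_family`` transcripts.

    Family members derive from a common ancestor by per-residue
    substitution at rate ``1 - sqrt(1 - d)`` so the realized pairwise
    amino-acid p-distance within a family approximates the target ``d``.
    A ``signal_fraction`` of families receive a planted signal-peptide
    leader and a secreted-family keyword; the remainder carry
    housekeeping keywords.  Member coding sequences reuse the ancestor's
    codons except at substituted residues, so nucleotide divergence
    tracks amino-acid divergence.
    """
    if n_families < 1 or copies_per_family < 1:
        raise ValueError("n_families and copies_per_family must be positive")
    if mean_cds_len_nt % 3:
        raise ValueError(
            f"mean_cds_len_nt={mean_cds_len_nt} is not divisible by 3; "
            "coding sequences are whole codons")
    if mean_cds_len_nt < 90:
        raise ValueError("mean_cds_len_nt must be >= 90")
    if not (0 <= target_aa_divergence < 1):
        raise ValueError("target_aa_divergence must be in [0, 1)")
    if not (0 <= signal_fraction <= 1):
        raise ValueError("signal_fraction must be in [0, 1]")

    rng = np.random.default_rng(seed)
    member_rate = 1.0 - math.sqrt(1.0 - target_aa_divergence)
    n_signal = int(round(signal_fraction * n_families))
    signal_flags = np.zeros(n_families, dtype=bool)
    signal_flags[rng.permutation(n_families)[:n_signal]] = True

    transcripts: List[TruthTranscript] = []
    family_roles: Dict[str, Tuple[str, str]] = {}
    mean_aa = mean_cds_len_nt // 3
    for f in range(n_families):
        fam_id = f"FAM{f + 1:03d}"
        has_signal = bool(signal_flags[f])
        if has_signal:
            keyword = SECRETED_KEYWORDS[rng.integers(len(SECRETED_KEYWORDS))]
            family_roles[fam_id] = (keyword, "S")
        else:
            keyword = HOUSEKEEPING_KEYWORDS[rng.integers(len(HOUSEKEEPING_KEYWORDS))]
            family_roles[fam_id] = (keyword, "H")
        n_aa = int(round(rng.normal(mean_aa, 0.1 * mean_aa)))
        n_aa = int(np.clip(n_aa, max(30, int(0.8 * mean_aa)),
                           int(1.2 * mean_aa)))
        if has_signal:
            leader = ("M"
                      + "".join(_SIGNAL_HYDROPHOBIC[i] for i in
                                rng.integers(0, len(_SIGNAL_HYDROPHOBIC), 12))
                      + _SIGNAL_SMALL[rng.integers(len(_SIGNAL_SMALL))])
            cleavage = len(leader)  # 1-based index of the small residue
            ancestor = leader + _random_protein(n_aa - len(leader), rng)
            protect = cleavage  # leave the whole leader untouched
        else:
            cleavage = None
            nterm = min(30, n_aa - 1)
            ancestor = ("M" + _random_nterm(nterm, rng)
                        + _random_protein(n_aa - 1 - nterm, rng))
            protect = 1
        anc_codons = _encode(ancestor, rng)
        for c in range(copies_per_family):
            prot = perturb_protein(ancestor, member_rate, rng, protect)
            codons = list(anc_codons)
            for i, (old, new) in enumerate(zip(ancestor, prot)):
                if old != new:
                    codons[i] = CODONS_BY_AA[new][rng.integers(len(CODONS_BY_AA[new]))]
            transcripts.append(TruthTranscript(
                id=f"{fam_id}_T{c + 1}",
                family_id=fam_id,
                cds_nt="".join(codons),
                protein=prot,
                has_signal_peptide=has_signal,
                signal_cleavage_pos=cleavage,
                expression_weight=float(rng.lognormal(mean=0.0, sigma=0.75)),
            ))
    return TruthSet(transcripts=transcripts, family_roles=family_roles)


# ---------------------------------------------------------------------------
# 454-style read simulation


def _homopolymer_runs(seq: str) -> np.ndarray:
    """Run length of the homopolymer containing each position."""
    runs = np.ones(len(seq), dtype=int)
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        runs[i:j] = j - i
        i = j
    return runs


def _quality_profile(length: int) -> Tuple[int, ...]:
    # phred 30 baseline decaying 0.02 per base toward the read end
    return tuple(max(2, int(round(30 - 0.02 * i))) for i in range(length))


def simulate_reads_454(truth: TruthSet, mean_read_len: int, depth: float,
                       indel_rate: float = 0.0, sub_rate: float = 0.0,
                       homopolymer_bias: float = 0.0,
                       seed: int = 0) -> List[Read]:
    """Sample 454-style reads; origins are recorded in ``truth.read_origins``.

    Reads are assigned to transcripts proportionally to expression weight,
    sampled from both strands, with length drawn from a clipped normal of
    mean ``mean_read_len`` (sd 10% of the mean).  The per-base indel
    probability is ``indel_rate * (1 + homopolymer_bias * (run - 1))``
    where ``run`` is the homopolymer run length at the template position;
    insertions duplicate the template base (the 454 overcall mode).
    """
    if not truth.transcripts:
        raise ValueError("empty truth set")
    shortest = min(len(t.cds_nt) for t in truth.transcripts)
    if mean_read_len > shortest:
        raise ValueError(
            f"mean_read_len {mean_read_len} exceeds shortest transcript "
            f"({shortest} nt)")
    if not (0 <= indel_rate < 1 and 0 <= sub_rate < 1):
        raise ValueError("error rates must be in [0, 1)")
    total_nt = sum(len(t.cds_nt) for t in truth.transcripts)
    n_reads = int(round(depth * total_nt / mean_read_len))
    if n_reads < 1:
        raise ValueError(
            f"depth {depth} yields zero reads for {total_nt} nt of transcripts")

    rng = np.random.default_rng(seed)
    weights = np.array([t.expression_weight for t in truth.transcripts])
    probs = weights / weights.sum()
    sd = 0.1 * mean_read_len
    reads: List[Read] = []
    for r in range(n_reads):
        t = truth.transcripts[int(rng.choice(len(truth.transcripts), p=probs))]
        lo = max(40, int(0.5 * mean_read_len))
        hi = min(len(t.cds_nt), int(1.5 * mean_read_len))
        rlen = int(np.clip(int(round(rng.normal(mean_read_len, sd))), lo, hi))
        # fragment model: sonication fragments are anchored at transcript
        # termini, so both ends of the transcript are properly covered
        raw = rng.uniform(-0.5 * rlen, len(t.cds_nt) - 0.5 * rlen)
        start = int(np.clip(round(raw), 0, len(t.cds_nt) - rlen))
        strand = "+" if rng.random() < 0.5 else "-"
        template = t.cds_nt[start:start + rlen]
        runs = _homopolymer_runs(template)
        out: List[str] = []
        edits: List[PlantedEdit] = []
        for i, base in enumerate(template):
            p_ind = min(0.4, indel_rate * (1 + homopolymer_bias * (runs[i] - 1)))
            u = rng.random()
            if u < p_ind:
                if rng.random() < 0.5:
                    out.append(base)
                    out.append(base)
                    edits.append(PlantedEdit(pos=len(out) - 1, kind="ins"))
                else:
                    edits.append(PlantedEdit(pos=len(out), kind="del"))
            else:
                if rng.random() < sub_rate:
                    choices = [b for b in "ACGT" if b != base]
                    out.append(choices[rng.integers(3)])
                    edits.append(PlantedEdit(pos=len(out) - 1, kind="sub"))
                else:
                    out.append(base)
        bases = "".join(out)
        if not bases:  # pathological all-deleted read; keep one base
            bases = template[0]
        if strand == "-":
            bases = revcomp(bases)
        rid = f"R{r + 1:06d}"
        reads.append(Read(id=rid, bases=bases,
                          quals=_quality_profile(len(bases))))
        truth.read_origins[rid] = ReadOrigin(
            transcript_id=t.id, start=start, strand=strand,
            edits=tuple(edits))
    return reads


def make_reference_db(truth: TruthSet, n_decoys_per_role: int,
                      roles: Sequence[str], seed: int,
                      name: str = "ref") -> ReferenceDB:
    """Build a keyword-tagged protein database around the truth proteins.

    Every truth protein is present verbatim under its transcript id,
    tagged with its family keyword; ``n_decoys_per_role`` random decoy
    proteins are added per role tag.
    """
    if not roles:
        raise ValueError("roles must be nonempty")
    if n_decoys_per_role < 0:
        raise ValueError("n_decoys_per_role must be >= 0")
    rng = np.random.default_rng(seed)
    records = [ReferenceProtein(t.id, t.protein,
                                truth.family_roles.get(t.family_id, ("", ""))[0])
               for t in truth.transcripts]
    for role in roles:
        for i in range(n_decoys_per_role):
            prot = "M" + _random_protein(int(rng.integers(120, 250)), rng)
            rid = f"DECOY_{role}_{i + 1}"
            records.append(ReferenceProtein(rid, prot, role))
            truth.decoy_proteins.append((rid, prot, role))
    return ReferenceDB(name=name, records=records)


# ---------------------------------------------------------------------------
# plain-text export of the ground truth


def write_reads_fasta_qual(reads: Sequence[Read], fasta_path, qual_path) -> None:
    with open(fasta_path, "w") as fa, open(qual_path, "w") as qu:
        for r in reads:
            fa.write(f">{r.id}\n{r.bases}\n")
            qu.write(f">{r.id}\n{' '.join(map(str, r.quals))}\n")


def write_truth_tables(truth: TruthSet, transcripts_path, origins_path) -> None:
    with open(transcripts_path, "w") as fh:
        fh.write("transcript_id\tfamily_id\tkeyword\tplanted_class\t"
                 "has_signal\tcleavage_pos\texpression_weight\tcds_nt\tprotein\n")
        for t in truth.transcripts:
            kw, cls = truth.family_roles.get(t.family_id, ("", ""))
            fh.write("\t".join([
                t.id, t.family_id, kw, cls,
                "1" if t.has_signal_peptide else "0",
                str(t.signal_cleavage_pos or ""),
                f"{t.expression_weight:.6f}", t.cds_nt, t.protein]) + "\n")
    with open(origins_path, "w") as fh:
        fh.write("read_id\ttranscript_id\tstart\tstrand\tedits\n")
        for rid in sorted(truth.read_origins):
            o = truth.read_origins[rid]
            edits = ",".join(f"{e.kind}:{e.pos}" for e in o.edits)
            fh.write(f"{rid}\t{o.transcript_id}\t{o.start}\t{o.strand}\t{edits}\n")
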