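"""FASTA + sibling qual input for reads and contigs."""

from __future__ import annotations

from typing import Dict, List

from Bio import SeqIO

from .assembly import Contig, Read


def read_fasta_qual(fasta_path, qual_path) -> List[Read]:
    """Load reads from a FASTA file and its whitespace-separated phred
    qual sibling (same ids, same order)."""
    seqs = list(SeqIO.parse(fasta_path, "fasta"))
    quals = SeqIO.to_dict(SeqIO.parse(qual_path, "qual"))
    reads = []
    for rec in seqs:
        if rec.id not in quals:
            raise ValueError(f"no qualities for {rec.id}")
        q = quals[rec.id].letter_annotations["phred_quality"]
        reads.append(Read(id=rec.id, bases=str(rec.seq).upper(),
                          quals=tuple(q)))
    return reads


def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(path, "fasta")}


def contigs_from_files(fasta_path, qual_path,
                       membership_path=None) -> List[Contig]:
    """Rebuild contig objects from exported FASTA/qual (+membership)."""
    members: Dict[str, frozenset] = {}
    if membership_path is not None:
        with open(membership_path) as fh:
            next(fh)
            for line in fh:
                cid, _, rids = line.rstrip("\n").split("\t")
                members[cid] = frozenset(rids.split(","))
    reads = read_fasta_qual(fasta_path, qual_path)
    return [Contig(id=r.id, consensus=r.bases, consensus_quals=r.quals,
                   member_read_ids=members.get(r.id, frozenset([r.id])))
            for r in reads]
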