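"""Summary accounting and end-to-end pipeline orchestration.

The class summary mirrors the canonical sialotranscriptome table: one row
per top class (Secreted, Housekeeping, Unknown, Transposable Elements)
with CDS count, read count, reads per CDS to one decimal and percent of
classified reads to one decimal, rounding half away from zero.  The
percent denominator is the summed reads of all classified CDS; the
separate whole-run percentages (reads captured by the >149 nt contig
subset, reads captured by the CDS set) use the total input read count,
and both denominators are explicit in the outputs.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

from . import __version__
from .annotate import (DEFAULT_RULES, Classification, build_evidence,
                       classify)
from .assembly import (AssemblySchedule, Contig, Read, filter_contigs,
                       iterative_clusterize)
from .cds import CDSRecord, coverage_tally, extract_from_contig
from .families import FamilyCluster, progressive_clusters, write_cluster_table
from .simulate import (TruthSet, generate_families, make_reference_db,
                       simulate_reads_454, write_reads_fasta_qual,
                       write_truth_tables)

CLASS_ORDER = ("S", "H", "U", "TE")
CLASS_NAMES = {"S": "Secreted", "H": "Housekeeping", "U": "Unknown",
               "TE": "Transposable Elements"}


def _round1(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), ROUND_HALF_UP))


def _round0(x: float) -> int:
    return int(Decimal(repr(x)).quantize(Decimal("1"), ROUND_HALF_UP))


@dataclass(frozen=True)
class ClassSummaryRow:
    class_name: str
    n_cds: int
    n_reads: int
    reads_per_cds: Optional[float]  # 1 decimal
    pct_of_total_reads: float       # 1 decimal


@dataclass(frozen=True)
class ClassSummary:
    rows: Tuple[ClassSummaryRow, ...]
    total_cds: int
    total_reads: int

    def to_tsv(self) -> str:
        lines = ["Class\tNumber of CDS\tNumber of Reads\tReads/CDS\t"
                 "Percent of Total Reads"]
        for r in self.rows:
            rpc = "" if r.reads_per_cds is None else f"{r.reads_per_cds:.1f}"
            lines.append(f"{r.class_name}\t{r.n_cds}\t{r.n_reads}\t{rpc}\t"
                         f"{r.pct_of_total_reads:.1f}")
        lines.append(f"Total\t{self.total_cds}\t{self.total_reads}\t\t")
        return "\n".join(lines) + "\n"


def summarize_classes(class_counts: Mapping[str, Tuple[int, int]]
                      ) -> ClassSummary:
    """Build the class summary from {class: (n_cds, n_reads)} counts.

    Classes are reported in the fixed order S, H, U, TE; the percent
    denominator is the summed reads over all classes (i.e. the classified
    CDS reads).  Unknown class keys are rejected.
    """
    bad = set(class_counts) - set(CLASS_ORDER)
    if bad:
        raise ValueError(f"unknown class keys: {sorted(bad)}")
    total_reads = sum(n for _, n in class_counts.values())
    total_cds = sum(c for c, _ in class_counts.values())
    if total_reads == 0:
        raise ValueError("no reads to summarize")
    rows = []
    for cls in CLASS_ORDER:
        n_cds, n_reads = class_counts.get(cls, (0, 0))
        rows.append(ClassSummaryRow(
            class_name=CLASS_NAMES[cls], n_cds=n_cds, n_reads=n_reads,
            reads_per_cds=_round1(n_reads / n_cds) if n_cds else None,
            pct_of_total_reads=_round1(100.0 * n_reads / total_reads)))
    return ClassSummary(tuple(rows), total_cds, total_reads)


def summarize_records(records: Sequence[Tuple[CDSRecord,
                                              Optional[Classification]]]
                      ) -> ClassSummary:
    """Class summary from classified CDS records (errors on unclassified)."""
    missing = [c.id for c, cl in records if cl is None]
    if missing:
        raise ValueError(f"unclassified CDS: {missing}")
    counts: Dict[str, List[int]] = {c: [0, 0] for c in CLASS_ORDER}
    for c, cl in records:
        counts[cl.top_class][0] += 1
        counts[cl.top_class][1] += c.read_count
    return summarize_classes({k: (v[0], v[1]) for k, v in counts.items()})


def _read_stats(reads) -> Tuple[int, int]:
    if isinstance(reads, tuple):
        return reads  # (n_reads, total_bases)
    return len(reads), sum(len(r.bases) for r in reads)


def global_read_accounting(reads, contigs_gt149, cds_set
                           ) -> Tuple[int, int, int]:
    """(pct reads in the >149 nt subset, pct reads in the CDS set,
    mean read length) against the total input reads.

    ``reads`` may be a list of reads or a (count, total bases) tuple;
    the other arguments may be object lists or plain read counts.
    Percentages and the mean length round half away from zero to
    integers.
    """
    n_reads, total_bases = _read_stats(reads)
    if n_reads == 0:
        raise ValueError("no reads")
    in_contigs = (contigs_gt149 if isinstance(contigs_gt149, int)
                  else sum(c.read_count for c in contigs_gt149))
    in_cds = (cds_set if isinstance(cds_set, int)
              else sum(c.read_count for c in cds_set))
    return (_round0(100.0 * in_contigs / n_reads),
            _round0(100.0 * in_cds / n_reads),
            _round0(total_bases / n_reads))


# ---------------------------------------------------------------------------
# pipeline orchestration


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    outdir: Union[str, Path] = "sialoseq-run"
    seed: int = 1
    # synthetic library
    n_families: int = 20
    copies_per_family: int = 3
    target_aa_divergence: float = 0.10
    mean_cds_len_nt: int = 600
    signal_fraction: float = 0.5
    mean_read_len: int = 344
    depth: float = 15.0
    indel_rate: float = 0.01
    sub_rate: float = 0.002
    homopolymer_bias: float = 0.3
    n_decoys_per_role: int = 2
    decoy_roles: Tuple[str, ...] = ("transposase", "ribosomal", "hypothetical")
    # assembly and extraction
    schedule: AssemblySchedule = field(default_factory=AssemblySchedule)
    min_contig_len: int = 150
    min_reads_per_contig: int = 5
    min_subject_coverage: float = 0.5
    min_hit_score: float = 65.0
    # family clustering
    family_thresholds: Tuple[int, ...] = (25, 40, 60, 80, 90, 99)


@dataclass
class PipelineResult:
    truth: TruthSet
    reads: List[Read]
    contigs: List[Contig]
    kept_contigs: List[Contig]
    cds: List[CDSRecord]
    classifications: Dict[str, Classification]
    clusters: Dict[int, List[FamilyCluster]]
    summary: ClassSummary
    accounting: Tuple[int, int, int]
    outdir: Path


def write_membership_table(contigs: Sequence[Contig], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tread_count\tread_ids\n")
        for c in contigs:
            fh.write(f"{c.id}\t{c.read_count}\t"
                     f"{','.join(sorted(c.member_read_ids))}\n")


def write_contigs(contigs: Sequence[Contig], fasta_path, qual_path) -> None:
    with open(fasta_path, "w") as fa, open(qual_path, "w") as qu:
        for c in contigs:
            fa.write(f">{c.id}\n{c.consensus}\n")
            qu.write(f">{c.id}\n{' '.join(map(str, c.consensus_quals))}\n")


def write_cds_tables(cds: Sequence[CDSRecord],
                     classifications: Mapping[str, Classification],
                     cds_fasta, protein_fasta, annotation_path) -> None:
    with open(cds_fasta, "w") as fn, open(protein_fasta, "w") as fp:
        for c in cds:
            fn.write(f">{c.id}\n{c.cds_nt}\n")
            fp.write(f">{c.id}\n{c.protein}\n")
    with open(annotation_path, "w") as fh:
        fh.write("cds_id\tcontig_id\tread_count\tclass\tsubcategory\t"
                 "best_db\tbest_subject\tcoverage\tevalue_like\t"
                 "n_frameshift_repairs\trationale\n")
        for c in cds:
            cl = classifications[c.id]
            best_db, best = "", ("", 0.0, float("inf"))
            for db_name, hit in sorted(c.best_hits.items()):
                if hit[2] <= best[2]:
                    best_db, best = db_name, hit
            fh.write("\t".join([
                c.id, c.contig_id, str(c.read_count), cl.top_class,
                cl.subcategory, best_db, best[0], f"{best[1]:.3f}",
                f"{best[2]:.3e}", str(c.n_frameshift_repairs),
                ";".join(cl.rationale)]) + "\n")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run simulate -> assemble -> filter -> extract -> classify ->
    cluster -> summarize, writing every intermediate plus a run log."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        truth = generate_families(
            config.n_families, config.copies_per_family,
            config.target_aa_divergence, config.mean_cds_len_nt,
            config.signal_fraction, seed=config.seed)
        reads = simulate_reads_454(
            truth, config.mean_read_len, config.depth, config.indel_rate,
            config.sub_rate, config.homopolymer_bias, seed=config.seed + 1)
        db = make_reference_db(truth, config.n_decoys_per_role,
                               config.decoy_roles, seed=config.seed + 2)
        write_reads_fasta_qual(reads, outdir / "reads.fasta",
                               outdir / "reads.fasta.qual")
        write_truth_tables(truth, outdir / "truth_transcripts.tsv",
                           outdir / "truth_read_origins.tsv")
        db.write_fasta(outdir / "reference_proteins.fasta")

        stage = "assemble"
        contigs = iterative_clusterize(reads, config.schedule)
        write_contigs(contigs, outdir / "contigs.fasta",
                      outdir / "contigs.fasta.qual")
        write_membership_table(contigs, outdir / "contig_membership.tsv")
        kept = filter_contigs(contigs, config.min_contig_len,
                              config.min_reads_per_contig)

        stage = "extract_cds"
        cds: List[CDSRecord] = []
        for contig in kept:
            rec = extract_from_contig(
                contig, db, min_score=config.min_hit_score,
                min_subject_coverage=config.min_subject_coverage)
            if rec is not None:
                cds.append(rec)

        stage = "classify"
        classifications: Dict[str, Classification] = {}
        for rec in cds:
            ev = build_evidence(rec, [db], min_score=config.min_hit_score)
            classifications[rec.id] = classify(rec, ev, DEFAULT_RULES)
        write_cds_tables(cds, classifications, outdir / "cds.fasta",
                         outdir / "cds_proteins.fasta",
                         outdir / "annotation.tsv")

        stage = "cluster_families"
        proteins = {c.id: c.protein for c in cds}
        read_counts = {c.id: c.read_count for c in cds}
        clusters = (progressive_clusters(proteins, read_counts,
                                         config.family_thresholds)
                    if cds else {t: [] for t in config.family_thresholds})
        write_cluster_table(clusters, outdir / "family_clusters.tsv")

        stage = "summarize"
        summary = summarize_records(
            [(c, classifications[c.id]) for c in cds])
        accounting = global_read_accounting(
            reads, filter_contigs(contigs, 150, 1), cds)
        (outdir / "class_summary.tsv").write_text(summary.to_tsv())
        n_high, n_low = coverage_tally(cds)
        run_log = {
            "package": "sialoseq",
            "version": __version__,
            "python": platform.python_version(),
            "seed": config.seed,
            "config": {k: (dataclasses.asdict(v)
                           if dataclasses.is_dataclass(v) else
                           str(v) if isinstance(v, Path) else v)
                       for k, v in dataclasses.asdict(config).items()},
            "n_reads": len(reads),
            "n_contigs": len(contigs),
            "n_contigs_kept": len(kept),
            "n_cds": len(cds),
            "n_cds_high_coverage": n_high,
            "n_cds_low_evalue": n_low,
            "pct_reads_in_gt149": accounting[0],
            "pct_reads_in_cds": accounting[1],
            "mean_read_len": accounting[2],
        }
        (outdir / "run_log.json").write_text(json.dumps(run_log, indent=2))
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc
    return PipelineResult(truth=truth, reads=reads, contigs=contigs,
                          kept_contigs=kept, cds=cds,
                          classifications=classifications, clusters=clusters,
                          summary=summary, accounting=accounting,
                          outdir=outdir)


# ---------------------------------------------------------------------------
# ground-truth scoring of a synthetic run


def score_against_truth(result: PipelineResult) -> Dict[str, float]:
    """Fraction of extracted CDS assigned to the correct planted class and
    family, resolved through the read-origin ledger."""
    truth = result.truth
    tid_to_family = {t.id: t.family_id for t in truth.transcripts}
    correct_class = correct_family = 0
    n = 0
    for rec in result.cds:
        contig = next(c for c in result.kept_contigs
                      if c.id == rec.contig_id)
        fams: Dict[str, int] = {}
        for rid in contig.member_read_ids:
            fam = tid_to_family[truth.read_origins[rid].transcript_id]
            fams[fam] = fams.get(fam, 0) + 1
        true_family = max(sorted(fams), key=lambda f: fams[f])
        true_class = truth.family_roles[true_family][1]
        n += 1
        if result.classifications[rec.id].top_class == true_class:
            correct_class += 1
        best_subject = min(rec.best_hits.values(), key=lambda h: h[2])[0]
        pred_family = tid_to_family.get(best_subject)
        if pred_family == true_family:
            correct_family += 1
    if n == 0:
        return {"n_cds": 0, "class_accuracy": 0.0, "family_accuracy": 0.0}
    return {"n_cds": n, "class_accuracy": correct_class / n,
            "family_accuracy": correct_family / n}
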