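"""Translated homology search and frameshift-repairing CDS extraction."""

import numpy as np
import pytest
from Bio.Seq import Seq

from conftest import random_dna, random_protein
from sialoseq.assembly import Contig
from sialoseq.cds import (ChainError, coverage_tally, extract_cds,
                          extract_from_contig, met_segments,
                          search_translated, six_frame_translate)
from sialoseq.reference import ReferenceDB, ReferenceProtein
from sialoseq.scoring import evalue_like
from sialoseq.simulate import generate_families


def contig_of(seq, cid="c1", reads=1):
    return Contig(id=cid, consensus=seq, consensus_quals=(30,) * len(seq),
                  member_read_ids=frozenset(f"{cid}_r{i}"
                                            for i in range(reads)))


def single_protein_db(pid, protein, keyword="kunitz"):
    return ReferenceDB(name="ref",
                       records=[ReferenceProtein(pid, protein, keyword)])


class TestSixFrameTranslate:
    def test_forward_frame_one(self):
        assert six_frame_translate("ATG")[1] == "M"

    def test_reverse_frame_one(self):
        assert six_frame_translate("CAT")[-1] == "M"

    def test_n_codons_become_x(self):
        assert six_frame_translate("ATGNNT")[1] == "MX"

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            six_frame_translate("AT")

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_independent_translator(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_dna(rng, 300)
        frames = six_frame_translate(seq)
        rc = str(Seq(seq).reverse_complement())
        for off in range(3):
            fwd = seq[off:off + 3 * ((300 - off) // 3)]
            rev = rc[off:off + 3 * ((300 - off) // 3)]
            assert frames[off + 1] == str(Seq(fwd).translate())
            assert frames[-(off + 1)] == str(Seq(rev).translate())


class TestMetSegments:
    def test_met_to_stop(self):
        segs = met_segments({1: "MAAA*"})
        assert [(f, i, s) for f, i, s in segs] == [(1, 0, "MAAA")]

    def test_met_past_window_excluded(self):
        aa = "A" * 300 + "MKKK"
        segs = met_segments({1: aa}, window_aa=300)
        assert segs == []

    def test_nested_met_segments(self):
        segs = met_segments({1: "MAMK*"})
        assert [(i, s) for _, i, s in segs] == [(0, "MAMK"), (2, "MK")]
        assert segs[1][2] == segs[0][2][2:]  # suffix property

    def test_window_must_be_positive(self):
        with pytest.raises(ValueError):
            met_segments({1: "MA"}, window_aa=0)


class TestSearchTranslated:
    def test_exact_encoding_full_coverage_hit(self):
        truth = generate_families(1, 1, 0.0, 300, 0.0, seed=61)
        t = truth.transcripts[0]
        hsps = search_translated(contig_of(t.cds_nt),
                                 single_protein_db(t.id, t.protein))
        top = hsps[0]
        assert top.subject_id == t.id
        assert (top.s_start, top.s_end) == (0, len(t.protein))
        assert top.identities == len(t.protein)
        assert top.frame == 1

    def test_random_pair_scores_below_threshold(self):
        rng = np.random.default_rng(62)
        hits = 0
        for i in range(20):
            contig = contig_of(random_dna(rng, 300))
            db = single_protein_db("decoy", random_protein(rng, 150),
                                   "hypothetical")
            hits += bool(search_translated(contig, db))
        assert hits == 0  # threshold calibrated above the decoy null

    def test_hsp_query_span_is_three_times_subject_span(self):
        truth = generate_families(1, 1, 0.0, 300, 0.0, seed=63)
        t = truth.transcripts[0]
        for h in search_translated(contig_of(t.cds_nt),
                                   single_protein_db(t.id, t.protein)):
            assert h.q_end - h.q_start == 3 * (h.s_end - h.s_start)

    def test_local_score_matches_brute_force_on_toys(self):
        from sialoseq.scoring import BLOSUM62, make_protein_aligner

        def brute_local(a, b, gap_open=11, gap_extend=1):
            # exhaustive affine local DP
            NEG = float("-inf")
            n, m = len(a), len(b)
            M = [[0.0] * (m + 1) for _ in range(n + 1)]
            X = [[NEG] * (m + 1) for _ in range(n + 1)]
            Y = [[NEG] * (m + 1) for _ in range(n + 1)]
            best = 0.0
            for i in range(1, n + 1):
                for j in range(1, m + 1):
                    X[i][j] = max(M[i - 1][j] - gap_open,
                                  X[i - 1][j] - gap_extend)
                    Y[i][j] = max(M[i][j - 1] - gap_open,
                                  Y[i][j - 1] - gap_extend)
                    diag = max(M[i - 1][j - 1], X[i - 1][j - 1],
                               Y[i - 1][j - 1])
                    M[i][j] = max(0.0, diag
                                  + BLOSUM62[a[i - 1], b[j - 1]])
                    best = max(best, M[i][j], X[i][j], Y[i][j])
            return best

        rng = np.random.default_rng(64)
        aligner = make_protein_aligner("local")
        for _ in range(20):
            a = random_protein(rng, int(rng.integers(4, 11)))
            b = random_protein(rng, int(rng.integers(4, 11)))
            assert aligner.score(a, b) == pytest.approx(brute_local(a, b))

    def test_empty_db_rejected(self):
        with pytest.raises(ValueError):
            search_translated(contig_of("ATGGCT" * 20),
                              ReferenceDB(name="ref", records=[]))


class TestEvalueLike:
    def test_monotone_decreasing_in_score(self):
        scores = np.linspace(10, 200, 25)
        values = [evalue_like(s, 100, 10000) for s in scores]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            evalue_like(50, 0, 100)


class TestExtractCDS:
    def test_exact_contig_yields_unmodified_cds(self):
        truth = generate_families(1, 1, 0.0, 300, 0.0, seed=71)
        t = truth.transcripts[0]
        rec = extract_from_contig(contig_of(t.cds_nt),
                                  single_protein_db(t.id, t.protein))
        assert rec is not None
        assert rec.cds_nt == t.cds_nt
        assert rec.protein == t.protein
        assert rec.n_frameshift_repairs == 0

    def test_reverse_strand_contig_extracted(self):
        from sialoseq.assembly import revcomp
        truth = generate_families(1, 1, 0.0, 300, 0.0, seed=72)
        t = truth.transcripts[0]
        rec = extract_from_contig(contig_of(revcomp(t.cds_nt)),
                                  single_protein_db(t.id, t.protein))
        assert rec is not None
        assert rec.protein == t.protein

    @pytest.mark.parametrize("kind", ["del", "ins"])
    def test_single_indel_repaired(self, kind):
        truth = generate_families(1, 1, 0.0, 600, 0.0, seed=73)
        t = truth.transcripts[0]
        pos = len(t.cds_nt) // 2
        if kind == "del":
            mutated = t.cds_nt[:pos] + t.cds_nt[pos + 1:]
        else:
            mutated = t.cds_nt[:pos] + t.cds_nt[pos] + t.cds_nt[pos:]
        rec = extract_from_contig(contig_of(mutated),
                                  single_protein_db(t.id, t.protein))
        assert rec is not None
        assert rec.n_frameshift_repairs == 1
        assert len(rec.cds_nt) % 3 == 0
        # repaired translation identical to truth outside the masked window
        assert rec.protein.replace("X", "") in _drop_window(t.protein,
                                                            rec.protein)
        for a, b in rec.aligned_aa_ranges:
            assert "*" not in rec.protein[a:b]

    def test_mixed_strand_chain_rejected(self):
        truth = generate_families(1, 1, 0.0, 300, 0.0, seed=74)
        t = truth.transcripts[0]
        contig = contig_of(t.cds_nt)
        hsps = search_translated(contig, single_protein_db(t.id, t.protein))
        flipped = hsps[0].__class__(**{**hsps[0].__dict__, "frame": -1})
        with pytest.raises(ChainError):
            extract_cds(contig, [hsps[0], flipped], t.protein)

    def test_out_of_order_chain_rejected(self):
        truth = generate_families(1, 1, 0.0, 300, 0.0, seed=75)
        t = truth.transcripts[0]
        contig = contig_of(t.cds_nt)
        hsps = search_translated(contig, single_protein_db(t.id, t.protein))
        with pytest.raises(ChainError):
            extract_cds(contig, [hsps[0], hsps[0]], t.protein)

    def test_low_coverage_chain_not_extracted(self):
        truth = generate_families(1, 1, 0.0, 600, 0.0, seed=76)
        t = truth.transcripts[0]
        # only the first 40% of the subject is present in the contig
        fragment = t.cds_nt[:int(len(t.cds_nt) * 0.4)]
        rec = extract_from_contig(contig_of(fragment),
                                  single_protein_db(t.id, t.protein))
        assert rec is None


def _drop_window(truth_protein, repaired_protein):
    """Accept repaired translations whose non-X residues read through the
    truth protein with at most a two-residue window removed."""
    candidates = {truth_protein}
    for w in range(1, 3):
        for i in range(len(truth_protein) - w + 1):
            candidates.add(truth_protein[:i] + truth_protein[i + w:])
    return candidates


class TestCoverageTally:
    def make_record(self, cid, coverage, evalue):
        truth = generate_families(1, 1, 0.0, 300, 0.0, seed=81)
        t = truth.transcripts[0]
        rec = extract_from_contig(contig_of(t.cds_nt, cid=cid),
                                  single_protein_db(t.id, t.protein))
        rec.best_hits["ref"] = (t.id, coverage, evalue)
        return rec

    def test_empty_set(self):
        assert coverage_tally([]) == (0, 0)

    def test_coverage_threshold_is_strict(self):
        rec = self.make_record("c1", 0.75, 1e-16)
        assert coverage_tally([rec]) == (0, 1)

    def test_planted_coverages_counted(self):
        recs = [self.make_record("a", 0.8, 1e-20),
                self.make_record("b", 0.9, 1e-3),
                self.make_record("c", 0.5, 1e-16)]
        assert coverage_tally(recs) == (2, 2)
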