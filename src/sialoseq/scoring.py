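"""Shared alignment scoring used across the pipeline.

All translated (protein-level) searches and identity computations use the
same substitution model: BLOSUM62 with affine gap costs 11 (open) / 1
(extend), the de facto defaults for translated database searches.
Nucleotide overlap detection during assembly uses a simple match/mismatch
model with affine gaps tolerant of pyrosequencing indels.

A Karlin-Altschul-style expectation value is provided for ranking and
thresholding hits.  Its constants are fixed, documented surrogates chosen
for the gapped BLOSUM62 11/1 regime; only the ordering and thresholding
behaviour of the value matters downstream, and both are monotone in the
raw score.
"""

from __future__ import annotations

import math

from Bio.Align import PairwiseAligner, substitution_matrices

BLOSUM62 = substitution_matrices.load("BLOSUM62")

#: default affine gap costs for protein alignments (positive magnitudes)
GAP_OPEN = 11.0
GAP_EXTEND = 1.0

#: Karlin-Altschul-style constants for the gapped BLOSUM62 11/1 regime
KA_LAMBDA = 0.267
KA_K = 0.041


def _free_end_gaps(aligner: PairwiseAligner) -> None:
    try:
        aligner.open_end_gap_score = 0.0
        aligner.extend_end_gap_score = 0.0
    except AttributeError:  # attribute names before Biopython 1.88
        aligner.end_open_gap_score = 0.0
        aligner.end_extend_gap_score = 0.0


def make_protein_aligner(mode: str = "local",
                         gap_open: float = GAP_OPEN,
                         gap_extend: float = GAP_EXTEND) -> PairwiseAligner:
    """Return a configured protein aligner.

    ``mode`` is ``"local"`` (Smith-Waterman), ``"global"`` (Needleman-Wunsch)
    or ``"overlap"`` (global with free terminal gaps, the model used for
    percent-identity computations over the shared span of two proteins).
    """
    aligner = PairwiseAligner()
    aligner.substitution_matrix = BLOSUM62
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    if mode == "overlap":
        aligner.mode = "global"
        _free_end_gaps(aligner)
    else:
        aligner.mode = mode
    return aligner


def make_nucleotide_overlap_aligner(match: float = 2.0,
                                    mismatch: float = -3.0,
                                    gap_open: float = 5.0,
                                    gap_extend: float = 2.0) -> PairwiseAligner:
    """Aligner for read/contig overlap detection: free terminal gaps."""
    aligner = PairwiseAligner()
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    aligner.mode = "global"
    _free_end_gaps(aligner)
    return aligner


def sanitize_protein(seq: str) -> str:
    """Map residues outside the BLOSUM62 alphabet to 'X'."""
    alphabet = set(BLOSUM62.alphabet)
    return "".join(c if c in alphabet else "X" for c in seq.upper())


def evalue_like(score: float, query_len: int, db_residues: int) -> float:
    """Expectation-style statistic: E = K * m * n * exp(-lambda * S).

    Monotone decreasing in ``score`` for fixed search-space size, which is
    the only property the classification thresholds rely on.
    """
    if query_len <= 0 or db_residues <= 0:
        raise ValueError("query_len and db_residues must be positive")
    return KA_K * query_len * db_residues * math.exp(-KA_LAMBDA * score)
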