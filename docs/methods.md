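# Methods

This note records the models, heuristics, parameter choices and known
limitations behind `sialoseq`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Synthetic library model

The generator emulates a normalized salivary-gland cDNA library
sequenced on a 454-type instrument. It is the package's study-condition
definition: downstream recovery claims are claims about data drawn from
this model.

**Families.** Each family derives from a random ancestor protein;
members substitute each residue independently at rate
`r = 1 − sqrt(1 − d)` so that the expected pairwise amino-acid
p-distance between two members is approximately `d` (each of the two
lineages mutates independently; coincident identical substitutions are
negligible at the rates used). Member coding sequences reuse the
ancestor's codons except at substituted residues, so nucleotide
divergence tracks amino-acid divergence the way duplicated genes do.
CDS lengths jitter ±10–20% (clipped normal) around the configured mean,
always whole codons and ≥ 90 nt.

**Signal peptides.** A configured fraction of families (default 0.5)
receives a leader built from an explicit grammar: Met, 12 residues from
{L,I,V,F,M}, then one small residue from {A,G,S} marking the cleavage
site (1-based position 14, always ≤ 40). The hydrophobic pool
deliberately excludes residues in the cleavage set so the planted
cleavage position is unambiguous. The leader is protected from
divergence substitutions, as signal peptides are under stabilizing
compositional selection. Secreted families carry a secreted-family
keyword (kunitz, lipocalin, evasin, ...); the rest carry housekeeping
keywords (ribosomal, actin, ...).

**Non-secreted N-termini.** The first 30 residues of non-secreted
ancestors draw from a polar-enriched pool (70% D,E,K,R,N,Q,S,T,H,G,P,
30% uniform). Uniform-random N-termini contain signal-like hydrophobic
8-mers in roughly a fifth of proteins, which misrepresents cytosolic
proteins: hydropathy-based signal prediction works on real data
precisely because non-secreted N-termini are depleted of such
stretches.

**Reads.** Read length is a clipped normal (mean configurable, default
344 nt; sd 10% of mean). Read starts follow a fragment model: the
fragment midpoint is uniform over the transcript and the window is
clipped to transcript bounds, so transcript termini receive proper
coverage (uniform *start* sampling covers base 0 with probability
~1/250 per read, which no real library exhibits, and would make
Met/signal recovery fail for reasons unrelated to the methods under
test). Reads are assigned to transcripts proportionally to log-normal
expression weights (σ = 0.75, a moderate library-normalized skew) and
sampled from both strands uniformly. Per-base indel probability is
`indel_rate · (1 + bias · (run − 1))` with `run` the homopolymer run
length at the template position (insertions duplicate the template
base — the 454 overcall mode); substitutions are applied at `sub_rate`
elsewhere. Qualities are phred 30 decaying 0.02 per base, floor 2 —
enough structure for quality-weighted consensus, otherwise
unconstrained. Per-base error rates for the emulated instrument are
conventions, not measured values; defaults (1% indel, 0.2%
substitution, bias 0.3) are in the 454 literature's range and are
exposed as parameters. Every planted edit is recorded in a per-read
origin ledger, which is the oracle for all recovery tests.

**What the generator does not model:** adaptor sequences, SFF flowgram
values, normalization chemistry, chimeric reads, sequencing of
non-coding UTRs (reads sample the CDS only), paralog interleaving on a
genome, and contamination (contaminant sets can be supplied
separately). Passing tests therefore demonstrate correctness of the
algorithms under these idealized but adversarial-enough conditions
(indels, divergence, skew), not performance on any particular real
library.

## Assembly

Grouping is by exact shared words (canonical over both strands),
transitively closed — word sharing is the trigger; join quality is
enforced by the assembler's gates, not by alignment statistics at group
time. The partition is independent of input order (union-find with
lexicographic roots). `max_matches_per_query` caps per-query neighbor
enumeration conceptually; excess neighbors remain reachable
transitively, so the partition is well defined regardless.

Within a group, assembly is greedy overlap-layout-consensus: the pair
with the longest admissible overlap merges first (ties: identity, then
smallest id pair). Candidate overlaps are screened by k-mer (16-mer)
diagonal voting followed by a banded edit-distance estimate (edlib,
semi-global) on the modal diagonal — a seed-and-extend screen that
avoids quadratic full alignments per candidate pair; the actual merge
realigns with a free-end-gap affine aligner (match 2, mismatch −3, gap
open 5 / extend 2, nucleotide scale). Per-merge columns are decided by
quality-weighted majority of the two rows (ties → higher summed phred,
then alphabetical).

Pairwise hierarchical merging alone cannot out-vote indel errors (every
column decision is 1-vs-1), so each multi-member contig gets a final
**column-vote polish**: constituents are realigned to the draft in
their merge orientation and each draft column is re-called by
quality-weighted majority over bases and gaps; junctions where a
majority of spanning constituents carry an extra base get it inserted
back. Without this pass a depth-26 contig at 1% indel rate retains on
the order of 20 insertion artifacts; with it, the surviving frameshifts
are the low-coverage ones the downstream extractor exists to repair.
Consensus qualities are per-column summed evidence capped at 60 — the
cap keeps later-round votes commensurate.

Overlap gates default to 40 nt and 90% identity, tolerant of 454 error
rates; at 90% identity, family members within ~5% nucleotide divergence
can co-assemble, which mirrors the behaviour of real EST clusterization
at these settings (the consensus then represents the family and its
best reference hit still identifies family and class). The length
filter keeps contigs ≥ 150 nt ("larger than 149"); the read filter
defaults to 1 for the library call and 5 in the pipeline's extraction
stage.

## CDS extraction and frameshift repair

Six-frame translation uses the standard code, stops as `*`, any
N-containing codon as `X`. Searches are Smith–Waterman with BLOSUM62
and gap open/extend 11/1 (the de facto translated-search defaults).
Each gapless block of an alignment scoring ≥ 65 becomes one HSP (query
coordinates in nt on the strand searched, so query span = 3 × subject
span holds per HSP). The 65 threshold was calibrated on shuffled
decoys: the maximum random local score over 300 trials at m=100, n=150
was 58, and real hits in this setting score in the hundreds.

Chains are built per (subject, strand) in subject order with these
rules, all of which address one empirical fact — a frameshifted
translation stays weakly similar to the true protein because adjacent
frames share two of three codon bases, so the upstream alignment
systematically overextends past an indel:

* blocks under 3 aa, and blocks under 50% exact identity to the
  subject (unless scoring ≥ 50), cannot join a chain;
* where adjacent blocks overlap on the subject, the crossover point
  maximizes the summed substitution score of upstream-before /
  downstream-after residues;
* residues immediately flanking a frame change that disagree with the
  subject (up to 4 per side) are trimmed into the bridge — the masked
  region *is* the "region of frame shift";
* query gaps within a chain are capped at 90 nt, keeping repairs local.

A frame-change bridge is replaced by `N`s with length adjusted −1 or +1
(the smaller edit) so the downstream block returns to frame; same-frame
bridges keep their original nucleotides. The repair count equals the
number of frame changes in the chain. The CDS extends upstream to the
furthest in-frame Met reachable without crossing a stop within 300
codons. Extraction requires combined subject coverage ≥ 0.5 and takes
the highest-scoring qualifying chain (ties by subject id).

The expectation statistic is `E = K·m·n·exp(−λS)` with fixed K = 0.041,
λ = 0.267 (gapped BLOSUM62 11/1 regime). Only its monotone ordering and
thresholding behaviour matter to the pipeline; it is not calibrated to
any particular search engine's numerics.

## Classification

Evidence per CDS: best protein-level hit per database (subject,
keyword tags, expectation value, subject coverage), the built-in signal
peptide heuristic (8-residue window of mean Kyte–Doolittle hydropathy
≥ 1.6 within the first 35 residues, followed within 6 residues by a
small residue A/G/S/C/T), TM helix count (disjoint 19-residue windows
of mean hydropathy ≥ 1.6 after the cleavage site), mucin-type
O-glycosylation density (S/T whose surrounding 11-mer, clipped at the
ends, holds ≥ 5 S/T/P), furin sites (R-X-[KR]-R, overlapping matches
included), and an optional contaminant flag from exact 60-mer sharing
with rRNA/mitochondrial sequences. External predictor verdicts can be
substituted via a per-protein TSV adapter.

The classifier is a fixed precedence — contaminant → H;
transposon keyword → TE; signal ∧ ≤1 TM ∧ (secreted keyword ∨ no
informative hit) → S; housekeeping keyword → H; else U — so database
order cannot change outcomes, every CDS gets exactly one
(class, subcategory), and the rationale lists fired and skipped rules.
The keyword vocabulary ships as an editable table (~45 rules covering
the secreted families recurrent in tick saliva plus broad housekeeping
roles); the informative-hit gate defaults to 1e-5. Manual curation,
which real studies apply on top, is explicitly not modeled. Secreted
enzymes that may actually be lysosomal remain class S here; a finer
"possibly non-salivary" annotation would require subcellular evidence
the pipeline does not have.

## Family clustering, gene counts, motifs

Pairwise identity is computed from a global alignment with free end
gaps (BLOSUM62 11/1): identity = matches over the aligned columns
between the first and last column where both sequences have a residue
(internal gaps count against identity), coverage = the longer
sequence's span inside that window over its full length. "Similarity"
thresholds are identity fractions. Clustering is single linkage —
matching the transitive behaviour of search-based clusterization — over
edges with identity ≥ threshold and coverage ≥ 0.5; single linkage also
guarantees the nestedness of the progressive 25→99% sweep, which the
suite asserts. Ranking within a threshold is by summed member read
counts (descending, ties by smallest member id); read mass was chosen
over member count because abundance in this literature is read-based;
both counts are emitted in the cluster table.

Gene counts use the >20%-divergence convention: the number of
single-linkage clusters at 80% identity, members within a cluster being
alleles or near-identical copies. The estimate is invariant under
member duplication by construction.

The motif scanner parses the dashed PROSITE-style grammar (literals,
`[SETS]`, `x`, `x(n)`, `x(n,m)`, with repeat counts allowed on any
element) and matches by frontier propagation (an NFA simulation over
position sets), reporting every distinct (start, end) span including
overlapping matches and all alternative range lengths. The test oracle
is an independent exhaustive backtracking matcher.

## Phylogenetics

The guide tree for progressive alignment is average-linkage clustering
of pairwise (1 − identity); profiles merge under Gotoh affine DP where
the column–column score is the mean pairwise BLOSUM62 score over row
pairs (residue–gap pairs contribute zero) and gap penalties are
profile-level scalars (11/1 by default). Deterministic traceback
preference: diagonal, then gap-in-second, then gap-in-first.

Distances are plain p-distances over shared non-gap columns (pairs with
no shared column get distance 1) — uncorrected, because divergence
scales in this field's figures are phrased as percent amino-acid
divergence; model corrections are deliberately off. Neighbor joining is
canonical (Q-matrix selection, standard branch-length formulas, lengths
clamped at 0) with ties broken by the smallest pair of cluster
representatives, which makes the topology independent of input order;
on additive matrices it recovers the generating tree exactly (asserted
over random trees up to 12 leaves, cross-checked against an independent
implementation). Bootstrap resamples alignment columns with
replacement, rebuilds the tree per replicate, and scores each original
internal bipartition by the percentage of replicates containing it
(bipartitions canonicalized as the side not containing the smallest
leaf id, so rooting does not matter).

Clade counting takes the tree as rooted (subtree leafsets), counts
internal edges with support strictly above the threshold and ≥ 2
leaves, and counts nested supported clades once via their maximal
qualifying ancestor — the rule that makes figure-style non-overlapping
clade counts well defined.

## Reporting

Class rows appear in fixed order S, H, U, TE. Reads/CDS and percent
columns round half away from zero to one decimal; the percent
denominator is the summed reads of classified CDS, while the whole-run
percentages (reads in the >149 nt subset, reads in the CDS set) use the
total input read count — both denominators are explicit fields.
`run_pipeline` is deterministic for a fixed seed and config
(byte-identical tables on rerun, asserted), writes every intermediate
as plain text, and aborts with the failing stage's name.

## Problem sizes in the shipped checks

The suite and acceptance script run, by choice, at: 20 families × 3
copies at depth 15 (~1,600 reads) for the end-to-end check; 100 planted
single-indel CDS for repair; 50 randomized instances each for the
word-group and clustering oracles; 200 random additive trees (≤ 12
leaves) and 200 bootstrap replicates for the tree checks; 100 seeded
replicates for gene-count recovery; 500 random pattern/sequence pairs
for the motif oracle. These sizes give stable pass/fail behaviour at
interactive runtimes; all scale linearly upward through the exposed
parameters.

## Known limitations

* The assembler is a deterministic stand-in for CAP3-class tools: no
  scoring-matrix overlap model, no chimera splitting, no clipping of
  low-quality ends; co-assembly of near-identical paralogs at the 90%
  gate is expected behaviour, and haplotype-aware separation is out of
  scope.
* Frameshift repair assumes locally correct consensus flanks; two
  indels within ~3 codons of each other resolve as a single masked
  bridge.
* The signal/TM/glycosylation/furin heuristics are transparent
  surrogates exposing the same decision surface as the external
  servers, not reimplementations of their models; on real data their
  verdict files should be substituted through the adapters.
* The expectation statistic orders hits; its absolute values are not
  comparable to any specific search tool.
* Progressive alignment is O(L²) per merge in pure Python/numpy;
  intended for family-sized sets (tens of sequences), not thousands.
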