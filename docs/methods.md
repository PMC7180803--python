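# Methods

## Disorder annotation

A residue of a crystallographic chain is labelled `U` (unstructured)
iff it appears in the chain's declared full sequence (SEQRES) but has
no resolved atoms — whether or not the deposition also lists it under
the missing-residue remark; any residue with at least one atom is `S`.
This is the universal convention for "disordered in X-ray": partial
side-chain disorder is deliberately ignored. Structures are read with
gemmi; the SEQRES↔ATOM correspondence uses gemmi's label-sequence
assignment, which aligns resolved residues to the declared sequence by
residue name and order, so conflicting author numbering is tolerated.
Modified residues are mapped to their parent amino acid through the
entry's MODRES record or the tabulated chemical-component list;
unmappable residues become `X`, which never satisfies a non-wildcard
pattern position. A chain with coordinates but no SEQRES is
reconstructed from the coordinates (all `S`, with a warning); a chain
present only in SEQRES is fully `U`.

Inclusion filters: X-ray method, resolution ≤ 3.0 Å ("better than
3 Å" — smaller number), length ≥ 40 residues; both bounds inclusive.
Internally all intervals are 0-based half-open; user-facing tables are
1-based inclusive.

## Identity and clustering

Identity between two chains is
`Id = I/(L₁ + L₂ − I) × 100`, with `I` the number of identical aligned
pairs in the optimal local alignment and `L₁`, `L₂` the full chain
lengths. This is a Jaccard-style measure: two identical chains score
100; a 5-residue peptide inside a 10-residue homopolymer scores
5/(10+5−5) = 50. Alignments use Biopython's deterministic
dynamic-programming `PairwiseAligner` in local mode with BLOSUM62 and
affine gaps (open 11, extend 1) — the default parametrisation of
standard local-alignment search tools. Because identity depends only
on the sequences, byte-identical chains are deduplicated before
alignment; this is exact, not a heuristic.

C100 groups identical sequences. Coarser levels (75/50/25/5 by
default) merge clusters of the previous level by **single linkage**:
any cross-cluster pair at or above the threshold merges the clusters,
iterated to a fixed point (equivalently, connected components of the
thresholded identity graph). The linkage rule and the all-pairs scope
are design choices — the alternatives (complete linkage,
representative-only comparison) give different forests; a
representative-only mode would be an approximation and is not the
tested contract. Nesting (every finer cluster wholly inside one
coarser cluster) is guaranteed by construction and checked by
`ClusterForest.check_nesting`.

## Two-level weighted statistics

The unit of observation is the C75 cluster, not the chain. Counts are
averaged in two stages: an unweighted mean over the chains of each
C100 sub-cluster, then an unweighted mean over the sub-clusters. A
protein deposited forty times therefore counts once. For the worked
example with per-chain (U, S) counts (23, 8), (24, 7), (31, 0),
(31, 0) in one sub-cluster and (8, 0), (6, 2) in another, the
sub-cluster means are (27.25, 3.75) and (7, 1) and the cluster mean is
(17.125, 2.375). Values are kept at full float precision internally;
`round_half_up` is provided for two-decimal report formatting.

Positional statistics label each residue N-terminal, middle or
C-terminal. The default rule is structural: the maximal disordered run
touching position 1 is the N-terminal region, the run touching
position L the C-terminal region, everything else middle — terminal
missing density is what distinguishes chain ends in this data. A fully
disordered chain counts as N-terminal (deterministic tie-break). A
fixed-width alternative (`terminal_window=K`) is available for
sensitivity checks. Every residue carries weight 1; no discount for
terminal occurrence is applied (no such scheme is specified for the
selection score either, see below).

## Low-complexity segments

An AC2 run is a maximal X-free segment whose residue set is exactly
two amino acids; maximality is containment-maximality, so overlapping
maximal segments with different pairs are all reported and a residue
covered by several runs counts once in coverage. The default minimum
length is 8, the basis length of the pattern library (detection at
other lengths via `min_length`). Each run's binary template (first
seen type → 0) is classified with precedence:

1. `homo_adjacent` — one symbol occurs exactly once, at either end;
2. `internal_repeat` — the template is a whole or truncated repetition
   of a period-2 or period-4 word (dipeptide repeats `01`, tetrapeptide
   repeats `0001`, `0010`, `0011`, `0100`, `0110`, `0111`);
3. `other` — everything else.

Longer periods intentionally fall into `other`. The null probability
that a random length-L sequence is AC2 is the inclusion–exclusion sum
over unordered pairs; the uniform-frequency special case is
`190·(0.1^L − 2·0.05^L)` ≈ 1.9×10⁻⁶ at L = 8. Both forms are verified
against exhaustive enumeration on small alphabets.

## Pattern mining

**Candidates.** For each C100 cluster, the per-position disorder
fraction over member chains is computed; maximal runs with fraction
≥ 0.5 (inclusive) and length ≥ 3 become candidates. Duplicate letter
strings are dropped, first occurrence kept; clusters are processed in
deterministic id order.

**Homologue merging.** A homologue of a length-L candidate may differ
at up to `ceil(L/5) − 1` positions (none for 3–5, one for 6–10, two
for 11–15, …), i.e. stays above 80 % identity. Homologues are sought
among the candidates themselves (equal length, Hamming distance within
the band); searching all sequence windows is a possible extension but
not the default. Diverging positions are masked with `X`; mask sets
are combined pairwise (set union) to a fixed point, the candidate
itself retained. The full closure is generated — for the 11-mer
example with mismatch sets {2}, {4,5}, {6,7} this yields all eight
combinations, a superset of any hand-pruned list.

**Statistics.** For a pattern and a C75 cluster, each member chain
contributes the count of residues covered by the pattern's matches
(all covered positions, X positions included) and not yet consumed,
split into disordered/ordered; the counts are two-level averaged.
`N_u`/`N_f` sum these means over clusters containing at least one
match; `C_u`/`C_f` count clusters whose mean is majority-disordered or
not; `D = N_u − N_f`.

**Greedy selection.** Each round filters candidates by C1 (`C_u ≥ 5`),
C2 (`C_u > C_f`) and C3 (`N_u > N_f`) on the current consumption
state, selects the maximum-D candidate (ties: larger effective length,
then lexicographically smaller letters — documented and tested), then
marks every residue covered by its matches as consumed so later rounds
cannot re-count them. Iteration stops when no candidate passes or the
best remaining D ≤ 0. The returned library keeps patterns whose
at-selection D is ≥ 25 — the weight of five whole five-residue
disordered patterns in five clusters. Homologue synthesis runs once,
up front; it is not repeated between rounds (recomputation only
affects the statistics, not the candidate set). Homo-repeat and AC2
candidates (no X, at most two residue types) are removed before
selection; they belong to the separate low-complexity catalogues.

**Histidine-tag proximity.** Purification tags (His runs) are
artificial, usually unresolved, and would otherwise contaminate the
library. For each pattern, `PC` is the percentage of its occurrences
lying within 40 residues of a His run of length ≥ 4 in the same chain
(overlap = distance 0; the 40-residue bound is strict). Patterns are
binned at PC = 0, (0, 33), [33, 67], (67, 100) and 100 %; a pattern
with no occurrence reports `n/a`.

## Null models

Expected occurrences of a pattern with effective (non-X) length L in a
corpus of `n_res` residues: `n_res·(1/20)^L` under uniform
frequencies, or the product of observed per-letter frequencies over
the non-X positions. For the reference corpus size 6.3×10⁸ this gives
≈ 197 (≈ 200) at L = 5 and ≈ 9.8 (≈ 10) at L = 6. Observed counts
include overlapping occurrences by default (`overlap=False` for greedy
non-overlapping counting). Random proteomes preserve the real length
list and draw residues independently from the frequency vector using
numpy's PCG64 generator with an explicit integer seed, so output is
byte-identical across platforms.

## Synthetic fixtures

The fixture module emulates the features the pipeline consumes, not
real structural data: CA-only coordinate files with prescribed missing
intervals (one atom is enough to mark a residue ordered); chain
families mutated at shared positions with member-distinct letters, so
every pair differs at exactly k positions and the identity lands on
`(L−k)/(L+k)·100` (within 3 points of the requested target); and
motif-planting, which inserts each motif into dedicated single-chain
clusters with a structured random background that avoids all motif
strings and His runs. Fixtures are byte-reproducible from their seed
and return ground-truth placement tables.

What passing tests on these fixtures shows: the machinery —
annotation, clustering, weighting, matching, consumption, selection —
is correct on inputs with known answers. What it does not show:
behaviour on real redundancy structure (fixtures plant one chain per
cluster unless asked otherwise), on real disorder/length distributions,
or at database scale; absolute library sizes from the full archive are
version-dependent and out of scope. Test problem sizes (≤ a few
hundred chains, motif sets ≤ 5) were chosen so the full suite runs in
seconds while still exercising every rule; they are stated here as the
package's own test design.

## Numerical and degenerate-input choices

- Identity of identical sequences is returned as exactly 100 without
  alignment; empty sequences are rejected.
- Co-optimal local alignments can differ in identity count, so the
  sequence pair is put into a canonical order (shorter, then
  lexicographically smaller, first) before aligning; the measure is
  therefore symmetric by construction.
- `two_level_average` rejects empty groups rather than guessing.
- Cluster ids are renumbered by smallest member key, so forests are
  reproducible regardless of input order.
- Fully disordered chains: whole chain N-terminal; fully ordered:
  all middle.
- Patterns shorter than 3 are never produced by candidate extraction;
  `match` itself accepts any non-empty pattern (used by the counting
  utilities).
- An all-X pattern matches everywhere and has `N_o = n_res` (empty
  product); it is useful only as a degenerate test case.
- Frequency vectors must sum to 1 within 1e-9.

## Known limitations

- mmCIF input is not parsed (PDB-format text only).
- B-factor-based or predicted disorder is out of scope; only missing
  density counts.
- Single-linkage clustering can chain distant sequences through
  intermediates at low thresholds; this mirrors the construction it
  implements rather than a biological claim.
- The all-pairs aligner is quadratic in the number of unique
  sequences; it is intended for curated sets, not the full archive,
  and no representative-sampling shortcut is enabled by default.
- Homologue search is restricted to the candidate list; genuinely
  divergent homologues present in the chains but never extracted as
  candidates are not merged.
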