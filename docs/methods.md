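# Methods

## The reduced alphabet

The eight groups partition the 20 standard amino acids by side-chain
chemistry: G1 Acidic {D,E}, G2 Basic {R,H,K}, G3 Aromatic {Y,F,W},
G4 Aliphatic {I,L,V,A,G}, G5 Cyclic {P}, G6 Sulfur-containing {M,C},
G7 Hydroxyl-containing {S,T}, G8 Acidic-amide {Q,N}. The partition is
asserted at import time (20 members, pairwise disjoint). Group names
follow the chemistry of the member sets — {Y,F,W} is named Aromatic and
{I,L,V,A,G} Aliphatic.

Nonstandard residues (B, J, O, U, X, Z, gaps, stops) are a hard error by
default, carrying the offending character and its 1-based position; a
skip policy drops them with a warning and records the dropped positions.
Silent coercion is never done, because every downstream report is
position-based and would be silently shifted. Gap characters are always
an error: this package is alignment-free by design and an aligned input
is almost certainly a mistake.

## Composition and dissimilarity

Group counts are exact integers; percents are computed at full float
precision (count/length × 100) and only rounded — to 4 decimals — in
written reports. The dissimilarity D between two sequences is the L1
distance between their 8-dimensional percent vectors. D lives in
[0, 200], is symmetric, satisfies the triangle inequality, and is zero
exactly when the percent vectors coincide (different sequences of equal
composition are 0 apart by construction — the statistic deliberately
ignores residue order; order information is carried by the digraph layer
instead).

Compositions are computed over the full input sequence, signal peptide
included; the packaged reference tables for the c7 cytochromes follow
the same convention (their row sums equal the full deposited lengths).
Chain extraction is available by slicing the input before encoding.

## Single-linkage tree

Nearest-distance agglomeration: the distance between two clusters is the
minimum pairwise dissimilarity across them. The merge loop is written
out explicitly rather than delegated to a library call so that the
tie-break is defined: among all cluster pairs at the minimal distance,
the pair with the lexicographically smallest active-cluster indices
(creation order) merges first. The choice only matters for exactly tied
distances, which do not occur in the reference data; the test suite
cross-checks the merge heights against scipy's single-linkage
implementation on random matrices. Single linkage is monotone, so merge
heights are non-decreasing and the result is ultrametric: the merge
height of any two leaves never exceeds their pairwise entry.

Newick output uses branch lengths of half the parent–child height
difference with leaves at height zero, so leaf-to-leaf path lengths
reproduce merge heights (standard dendrogram display). Because the
display convention is a choice, raw merge heights are also written to a
sidecar TSV.

## Order-pair digraph

For a reduced sequence T of length L, each consecutive ordered pair
(T(i), T(i+1)) is a directed edge; self-loops are legal. The classical
adjacency matrix is binary (presence only); this implementation also
keeps the occurrence count of every ordered pair (summing to L−1) and
the list of 1-based *source* positions of each occurrence, so "the edge
at residues 41–42" is indexed by position 41. Group comparisons report
edges present in every member of one group and absent from every member
of the other, plus the edges common to all; the three-way status
(in-all / in-some / in-none) is always derivable from the stored sets.

## Cycles and subdomain windows

Simple directed cycles (each intermediate node visited once) of bounded
length — default 3..6, at most 8 on these graphs — are enumerated via
networkx's bounded simple-cycle search and verified in the tests against
an exhaustive DFS oracle and against the closed-form count
C(n,k)·(k−1)! on complete digraphs. Cycles are canonicalized by rotating
to start at the smallest node code and are printed without repeating the
first node (the cycle 2→3→6→2 prints as `236`).

A cycle is *present* in a digraph when all of its edges are in the edge
set — not necessarily traversed contiguously in the sequence. This is
the only reading under which a 3-cycle can span a wide residue window.
The subdomain windows of a present cycle are computed by choosing one
occurrence position per edge in all combinations, forming the candidate
span [min position, max position + 1] (the +1 covers the target residue
of the latest pair), and keeping exactly the minimal candidates (those
containing no other candidate), sorted by start. Minimality is this
package's defined behavior where several spans are possible.

## Pattern search

Patterns are words over the codes 1..8; matching compares the group code
at each offset and tolerates at most `max_mismatch` deviations, with
mismatch offsets reported 1-based within the pattern. Matching is
directional (a pattern and its reversal are different queries).
Discovery is exact k-mer intersection over group codes: conserved k-mers
occur in every member of a set; group-specific k-mers are conserved in
one set and absent from every member of the other. A hit additionally
notes when all sequences carry the identical residue at a position only
if the caller compares residues itself — residue-level conservation is a
secondary annotation, and multiple alignment is out of scope.

## Synthetic sequences

The generator draws a sequence with prescribed per-group counts: within
each group residues are chosen uniformly (no residue-level model is
assumed — only group structure feeds any downstream computation), then
the concatenation is shuffled by an explicit seeded `numpy` generator.
Percent-mode targets are converted to counts by largest-remainder
rounding with ties to the lower group code. Identical seeds give
identical sequences. The generator reproduces composition-level
structure only: no positional motifs, heme-binding spacing or signal
peptides. Tests passing on synthetic sequences therefore validate the
arithmetic and the graph/pattern machinery, not any biological claim
about real cytochromes; the reference count tables packaged with the
library anchor the numbers to real sequences at the composition level.

## Problem sizes and numerical choices

The reference computations are desk-scale: five sequences of ~90
residues, 8-dimensional vectors, digraphs on ≤8 nodes. Randomized test
suites use 100–200 seeded instances (sequences up to ~150 residues,
digraphs up to 8 nodes), which exercise every code path in well under a
minute. Comparisons against 4-decimal reference values use an absolute
tolerance of 5e-4 (5e-5 for the composition table, whose cells are exact
rationals); internal oracle equivalences use 1e-9 to 1e-12. Degenerate
inputs are errors, not silent results: empty sequences, length-1
sequences fed to the digraph builder, cycle bounds outside 1..8,
duplicate FASTA ids, count vectors whose sum contradicts the stated
length, and absent cycles queried for subdomains.

## Known limitations

- Composition dissimilarity is blind to residue order and to sequence
  length differences beyond their effect on percentages.
- Edge/cycle uniqueness is a set-level statement across groups; it does
  not test statistical significance.
- The percent-identity similarity scale of alignment tools has no
  defined transform to/from the dissimilarity D; none is implemented.
- Cycle subdomain minimality can differ from hand-curated spans when an
  edge occurs many times.
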