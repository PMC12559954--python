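# Methods

This note documents the models, conventions, and design choices behind
`sigtax`, and what the synthetic-data tests do and do not establish about
real environmental-sequence data.

## The diagnostic problem

A molecular diagnosis must separate a target taxon from all related taxa
using fixed, citable characters. `sigtax` operationalises this as three
cooperating computations on an annotated multiple alignment (IUPAC symbols,
`-` gaps; per-sequence lineages at phylum–species ranks; rRNA-operon
regions SSU, ITS1, 5.8S, ITS2, LSU given as alignment-column intervals):

1. **Signatures.** For a window of columns, the target's motif is the
   per-column IUPAC union of its member sequences (so every member matches
   the motif exactly, by construction). Candidate windows must be gap-free
   in all target members — printed signatures are contiguous barcodes — and
   carry at most `max_ambiguous` degenerate symbols (default 2; published
   signatures carry 0–2). With `d_min` the minimum mismatch count of any
   non-target against the motif (a non-target gap column counts as a
   mismatch), the allowed-mismatch budget is `m = d_min − 1`, clamped at 0;
   a window qualifies iff `d_min ≥ 1`. The search enumerates every window
   of each length in `[min_len, max_len]` (default 20, the conventional
   signature length; the printed range spans roughly 8–33) in every region,
   ranked by `d_min` descending, then ambiguity ascending, then region
   priority (ITS2, LSU, 5.8S, SSU — ITS2 is the fungal barcode fragment of
   choice), then leftmost column. The ranking is total, so the output is
   deterministic; the published workflow chose "most characteristic"
   windows manually, which a reproducible tool cannot imitate.
2. **Disjunctions.** When no single motif qualifies (a target with deeply
   split subclades would need too many degenerate symbols), members are
   partitioned by complete-linkage clustering of window-restricted mismatch
   distances into at most `max_alternatives` groups (default 3), one union
   motif per group, smallest feasible group count first. A sequence counts
   as the target if it is within `m` of *any* alternative; every non-target
   must exceed `m` against *all* alternatives. With a homogeneous target
   this degenerates to the single-motif result.
3. **Verification** is a separate contract from derivation: a signature
   record (motif(s), columns, `m`) can be re-checked against any alignment,
   so a published budget smaller than `d_min − 1` (expert conservatism)
   still validates.

## Distances and the barcode gap

`p-distance = differing comparable sites / comparable sites`. Default
policy: sites with `-` or `n` in either sequence are excluded from both
numerator and denominator; IUPAC-compatible symbol pairs (intersecting
expansions) count as matches; a distance is undefined below `min_overlap`
comparable sites (default 50). Gap exclusion is the default because
repeat-length polymorphism otherwise dominates intraspecific values; a
`gaps-as-difference` switch exists because published per-taxon numbers may
reflect either convention. Intraspecific variability is reported as the
*maximum* over member pairs, interspecific distance as the *minimum* over
(member, non-member) pairs — the conservative ends of both distributions.
"Related" non-members default to congeners when a genus is annotated, else
all non-members. Percentages print at 1 decimal. No model correction
(K2P etc.) is applied: the published values are raw proportions.

## Reference coordinates

Printed signature positions are region-local ungapped positions on a
designated reference row: the holotype-derived legitype for ITS, an
external rDNA reference (supplied as an alignment member with role
`reference`, never downloaded) for SSU/5.8S/LSU. Position 1 is the
reference's first base at or after the region start; upstream bases count
−1, −2, … with **no zero**. The convention is inferred from boundary-
spanning ranges like `−2–18`, which cover exactly 20 bases only if 0 is
skipped; since the inference cannot be confirmed from text alone, an
`include-zero` convention is available as a switch. Column↔position is a
bijection on non-gap reference columns (property-tested), and a rendered
interval's position count equals the motif length for gap-free spans.

## Delimitation and richness

Every formal taxon must form a monophyletic, least inclusive clade; higher
taxa additionally need bootstrap support **strictly** greater than 95.
Trees are read with dendropy; supports on a 0–1 scale are rescaled to
0–100. On unrooted trees, clades are bipartition sides away from a declared
outgroup tip — evaluated directly per edge rather than by rerooting, which
avoids support-label migration. Richness within a lineage is estimated by
single-linkage clustering of ITS2 p-distances: at single linkage the
clusters at threshold *t* are exactly the connected components of the graph
joining pairs with distance ≤ *t* (computed via scipy's sparse
connected-components; an independent BFS oracle lives in the tests).
Single linkage was chosen as the OTU-style convention robust to chaining
within species; the threshold defaults to the type species' maximum
intraspecific ITS2 distance, both overridable. ITS2 is the default region,
with a flag, since the source workflow is ambiguous between ITS2 and full
ITS. Undefined (low-overlap) distances never join clusters.

## Synthetic data: what it emulates and what it does not

The generator stands in for archived environmental reads. Defaults are the
study conditions the tests assume: region lengths SSU 1700, ITS1 250,
5.8S 160, ITS2 300, LSU 1400 nt; `d_inter = 0.10` (minimum interspecific
p-distance per region — the published ITS2 interspecific range is roughly
3–20 %); `d_intra_max = 0.02` (published intraspecific maxima are mostly
1–4 %); `ambiguity_rate = 0.005`; 6 species with 3–6 reads each, matching
small per-genus alignments; indels and repeat noise off unless enabled.

Construction guarantees rather than hopes: species ancestors are mutated
from a shared root (Jukes–Cantor-style uniform substitutions — no model
fitting is needed for diagnosis, so realism beyond distances is not
attempted) and rejection-sampled until every pair reaches
`d_inter + d_intra_max` in every region, so read-level interspecific
distances still reach `d_inter` after intraspecific noise; per-read
substitution counts are capped at `d_intra_max·L/2` per region, so no
intraspecific pair can exceed `d_intra_max`. Infeasible requests
(`d_inter + d_intra_max > 0.7`, or a rejection cap of 1000 attempts) fail
loudly. Ambiguity recoding replaces a base with a two-base degenerate code
containing it. Indels are species-level events realized as shared gap
columns (an insertion is modelled as every *other* species gapping), which
keeps the alignment width fixed. Repeat noise writes homopolymer (≥ 6 nt)
and dinucleotide (≥ 4 unit) loci into the ITS regions of the root and
drops 1–3 units per read as gaps — length polymorphism realized as
deletions relative to the longest allele; under the default gap-excluding
distance policy it leaves p-distances untouched, under gaps-as-difference
it inflates intraspecific values, mirroring the published repeat-driven
outliers (9.8 %, 11.4 %). Planted signatures overwrite a window of the
target ancestor with a fresh random motif, push every other ancestor to at
least the configured margin within the window, and protect the window from
all read-level noise, so the planted contrast is exact by construction.

Randomness: one seed; per-species substreams seeded by (seed, species
index), so outputs are bit-identical across runs and stable under species
addition. The truth object records planted windows, realized per-species
maximum intra- and minimum interspecific distances (computed post hoc with
the package's own distance code — the distance code itself is validated
against an independent per-site oracle).

What passing synthetic tests does **not** show: real reads have
platform-specific error profiles, chimeras, uneven coverage, and
phylogenetic (non-star) correlation structure among species; none of these
are modelled. Synthetic results establish algorithmic correctness
(agreement with oracles, recovery of planted truth), not field
performance.

## The taxon ledger

The packaged fixture transcribes the published table of newly proposed
taxa (31 rows) plus the separately noted new combination, with one family
per new order taken from the formal descriptions, rank-level
previously-described flags from the table footnotes, and both spellings of
one species epithet recorded as aliases. It is data entry, not
computation, and is guarded by a SHA-256 checksum at load time. Counts are
of *distinct* names flagged new at a rank: shared names across rows count
once; previously described names and combinations are excluded. The
species-rank count from the ledger is 30, while the published headline
says 29 new species; the discrepancy is in the source and is reported
as-is rather than reconciled. The count of distinct highest-rank novel
lineages (each row contributing its highest newly proposed rank,
deduplicated) is 30, matching the headline count of described lineages.

## Numerical choices and degenerate inputs

- IUPAC symbols are 4-bit base masks; compatibility is a non-empty mask
  intersection, so all symbol comparisons are integer operations. Gap has
  mask 0 and is compatible with nothing, including itself.
- Window statistics (gap presence, ambiguity counts, per-non-target
  mismatch counts) are sliding sums over cumulative arrays: the search is
  O(sequences × columns) per window length.
- Ties in every ranking are broken lexicographically (documented above), so
  equal-scoring windows order by region then column; no randomness exists
  anywhere in the search path.
- Single-member taxa report `max_intra = 0.0` with a `single_member` flag;
  empty taxa, empty contrast sets, empty regions, ragged alignments,
  non-IUPAC symbols, duplicate ids, and overlapping regions raise typed
  errors with the messages tests assert on.
- `?` and `.` in input sequences normalise to `n` and `-` with a warning;
  case is non-semantic and canonicalised to lower.

## Problem sizes

Module tests run on toy alignments (tens of columns). The deeper checks
use 200 random alignments of ≤ 12 sequences × 200 columns for
search-vs-brute-force equality, 100 seeded replicates at generator
defaults for planted-signature recovery and for richness recovery, 10⁴
random pairs for the distance oracle, 10³ gapped references for coordinate
round trips, and 500 random 7-tip trees for the clade oracle. These sizes
were chosen to exercise the combinatorics thoroughly while keeping the
full suite fast enough to run on every change.

## Known limitations

- No probe thermodynamics: signatures are purely combinatorial, as in the
  source workflow.
- No alignment, trimming, tree inference, or chimera screening: the
  pipeline consumes upstream artifacts (MAFFT/ClipKIT/IQ-TREE outputs).
- Published per-taxon values (specific motifs, positions, percentages)
  cannot be reproduced without the archived accession sequences; the test
  strategy substitutes property-based checks against independent oracles.
- The disjunctive search is greedy over windows and group counts; it is
  exhaustive for the window and the partition granularity but does not
  search non-hierarchical partitions.
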