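# Methods

This note records the models, algorithms, numerical conventions and design
choices behind `angiopn`, and what the test suite does and does not
establish.

## Net model and incidence algebra

Nets are ordinary place/transition nets: bipartite, weighted (weights ≥ 1),
at most one arc per ordered (source, target) pair — duplicate arc
declarations in input files are an error, never weight-summed, because the
modelled nets are simple bipartite graphs.  Markings are value-semantic:
firing returns a new marking, so callers never observe partial updates, and
firing a disabled transition raises instead of producing negative tokens.

Structural classification follows the standard definitions: *ordinary* (all
weights 1), *homogeneous* (per place, all outgoing arcs share one weight),
*pure* (no place/transition pair connected in both directions, i.e. no read
arcs), *connected* on the undirected shadow graph and *strongly connected*
on the directed graph (isolated vertices disconnect a net), *structurally
conflict-free* (no place with two or more outgoing arcs).

## Minimal invariants

t-invariants solve *A·x* = 0 over non-negative integers; p-invariants solve
the transposed system.  Only support-minimal, gcd-normalised solutions are
computed, by the classical Fourier–Motzkin/Farkas tableau: starting from
[*Aᵀ* | *I*], one place constraint is eliminated per round (the one
minimising the positive×negative row-pair count) by forming all
non-negative combinations of opposite-sign rows; after every round, rows
whose solution support strictly contains another row's support are pruned
and every row is divided by its gcd.  Support-superset pruning at
intermediate steps is what keeps the tableau small; a `limit` (default
100 000 rows) turns pathological growth into an explicit
`InvariantLimitError` carrying the row count, never silent truncation.

All arithmetic uses Python integers, so results are exact at any magnitude;
every returned vector is re-verified against *A* before being returned.
Canonical output order is (support size, lexicographic support), making
fixtures and diffs stable.  Completeness is tested against a bounded
exhaustive enumerator on random 4×6 matrices (coefficient grid 0..6 — the
oracle is provably complete for invariants within that bound, and the
comparison restricts both sides to it).

Feasibility is reported as *preconditions only*, exactly the argument used
for this model class: when the net is pure and the minimal p-invariant set
is empty, no t-invariant can be blocked by read arcs or by an
under-tokenised conservation law, so all of them may be treated as
realisable.  No reachability analysis is attempted (out of scope).

## MCT sets

Occurrence columns of the binary support matrix are hashed byte-wise;
identical nonzero columns form one class, all-zero columns (uncovered
transitions) are collected separately.  The O(m²) pairwise comparison
survives as the test oracle.  Canonical order is size-descending then
lexicographic, with names `m1…` for non-trivial and `s1…` for trivial sets.
Induced-subnet connectivity (an MCT set plus its adjacent places) is
reported but disconnected sets are *not* decomposed further into connected
sub-units — for this model family the single disconnected set is a
2-transition set whose decomposition would only produce trivial sets.
Places shared between two sets never merge them; adjacency is taken per set
independently.

## Clustering and the MSS index

Clustering operates on binary occurrence vectors (a flag of the distance
layer accepts raw coefficient vectors, but the shipped data are supports
only).  Distances: `binary` is the Jaccard fraction of discordant nonzero
coordinates over coordinates where either vector is nonzero; `canberra`
skips 0/0 coordinates; `correlation` is 1 − Pearson *r* on the 0/1 values
(no continuity correction) and `uncentered` is 1 − cosine; the norm metrics
are standard, with Minkowski defaulting to *p* = 2 (configurable).  Rows
with zero variance/norm under the correlation metrics get the defined
fallback distance 0 to identical rows and 1 otherwise, with a logged
warning rather than a crash.

Agglomeration is an in-package Lance–Williams loop, for three reasons: the
deterministic tie-break (among minimal-distance pairs, merge the smallest
(i, j) cluster indices in creation order) must be stated and stable across
platforms; both Ward variants are wanted (`ward` = squared-distance update
with heights reported on the original scale, `ward_d` = the classic update
on raw dissimilarities); and centroid/median must accept arbitrary
dissimilarities.  On tie-free data the implementation is verified
merge-for-merge against `scipy.cluster.hierarchy.linkage` for all seven
shared methods, and against an exhaustive recomputation oracle for
single/complete.  Cutting into *k* clusters undoes the last *k* − 1 merges;
for the non-monotone centroid/median linkages (inversions permitted) this
differs from scipy's `cut_tree` flattening, which is why only trees, not
cuts, are compared there.

The cluster-quality index is a Mean-Split-Silhouette-style score: each
element receives the classical silhouette width
*s(i)* = (*b* − *a*)/max(*a*, *b*) of the top-level partition, elements of
singleton clusters receive 0, per-cluster values are member means, and the
global value is the mean over all elements (identically the size-weighted
mean of per-cluster values — asserted exactly for every computed
clustering).  This is a deliberate approximation of the recursive
split-silhouette index from the cluster-number-selection literature, chosen
because the published per-cluster values assign 0.00 to singletons and
nonzero values to 2-element clusters, which the recursive variant would
not.  Values are never rounded internally; reports round per-cluster values
to 2 decimals and global values to 4.

On the shipped 48×74 matrix, binary+UPGMA cut at 11 reproduces the
published structure exactly (largest cluster 28, global MSS 0.5856), and
correlation+UPGMA cut at 13 reproduces the published cluster-size *pattern*
with a global MSS of 0.4621; the run is bit-identical to the reference R
route (`1 - cor(t(m))`, `hclust(average)`, `cutree(13)`).  The residual
difference from the originally published 13-cluster membership (85 %
pairwise co-membership) and MSS (0.5088) is attributable to the original
input file, which is not reconstructible from the printed support tables;
the MSS difference stays inside the ±0.05 band that the ambiguity of the
index variant warrants.

## Knockout analysis

*Structural*: for a unit *U* (an MCT set or one trivial transition), the
affected percentage is 100·|{i : supp(xᵢ) ∩ U ≠ ∅}|/N, rounded half-up to 2
decimals at the report layer only; rows sort by impact descending, ties by
unit name.  All members of one MCT set produce identical rows by
construction, so one row per set suffices.

*Dynamic*: the token game runs in a synchronous-like mode.  Per step, the
enabled set is computed from the current marking; every enabled,
non-disabled transition independently "wills" to fire with probability
`firing_probability` (default 0.5); willing transitions are then resolved
in a uniformly random order.  Two conflict semantics are provided because
the published description does not pin one down:

* `sequential` (default): enabledness is re-checked on the evolving marking
  before each individual firing, so within-step products are immediately
  available downstream;
* `maximal`: consumption is checked against the start-of-step marking minus
  what earlier transitions in the preference order already consumed, and
  production becomes visible only at the step boundary.

Both guarantee non-negative token counts by construction (and the simulator
asserts it).  Token statistics sample the marking at the end of each step.
"Average firing chance" uses total steps as denominator (a per-step
fraction), not steps-while-enabled.  Each repetition draws its own
generator seeded by (master seed, repetition index), so repetitions are
independent, order-insensitive and reproducible; the same seed yields a
bit-identical package.  Statuses: OFFLINE exactly for manually disabled
transitions, KNOCKOUT exactly for never-disabled transitions with zero
firings across all repetitions (their firing chance is exactly 0), ACTIVE
otherwise.  Differences in comparison tables are knockout minus reference
in percentage points for ACTIVE transitions; OFFLINE/KNOCKOUT rows carry a
"disabled" label instead of a number.

Default simulation scale follows the published protocol (10 000 steps ×
4 000 repetitions, firing probability 0.5); the packaged analysis script
and the acceptance checks run a 1 000 × 400 scale-down, which leaves the
per-transition firing-chance estimates' standard errors well below the
percentage-point tolerances in use.

## Synthetic data

`generate_covered_net` builds nets as unions of directed circuits that
partition the transitions and share only places; each circuit is then a
t-invariant of the union net, so coverage holds by construction — but tests
re-derive all claimed properties (ordinary, pure, connected, covered)
through the analysis modules rather than trusting the generator.  Circuits
have length ≥ 2 (a 1-transition circuit is a read-arc self-loop), every
place needs a fresh cycle slot (n_places ≤ n_transitions − n_circuits + 1)
and no circuit can visit more distinct places than exist; violations raise
before generation starts.  Cross-circuit overlaps can create read-arc pairs
by chance; generation then retries with a derived seed, keeping results a
pure function of the seed.  Each circuit's entry place receives one initial
token so the token game is live.  What the generator does *not* emulate:
the long signalling cascades, shared hub places with high fan-out, and the
source/sink structure of real curated models — passing tests on generated
nets therefore certify the algorithms' contracts, not biological realism.

`generate_block_support_matrix` plants groups of identical columns (MCT
blocks) given (size, row-subset) specs; duplicate row subsets are rejected
because they would merge into one class and make the planted partition
unrecoverable.  Optional independent per-cell flip noise (default 0)
degrades the blocks.

The angiogenesis fixture is packaged as plain CSV: the composition of each
of the 48 invariant supports (as MCT-set names plus single transitions),
the 11 non-trivial MCT memberships, and the 26-row expected knockout
ranking; `load_angiogenesis_fixture` expands these to the 48×74 binary
matrix at run time.  The net's arc list is not part of the package — it
exists only in the study's supplementary Snoopy file, which the SPPED
reader consumes when provided locally.

## File formats

The SPPED reader supports a read-only subset (places, transitions, edges,
markings, logical places); Snoopy's full schema (hierarchy, graphics,
colours) is out of scope, and writing SPPED is unsupported.  Logical
(shadow) place copies sharing a name are merged into one vertex; arc
collisions created by the merge sum their weights, which preserves the
incidence matrix of the pre-merge multigraph; copies carrying conflicting
nonzero token counts are an error naming the place.  PNML targets the basic
Place/Transition subset, ignoring unknown elements with a logged warning.
The incidence-CSV codec writes a `# pure=` flag line because the matrix
cannot represent read arcs; the reader refuses files flagged non-pure.  The
support-matrix CSV uses a header of transition labels and one labelled row
per invariant, comma-separated — the layout common to R clustering scripts
in this field.  All writers emit deterministically ordered, byte-stable
output.

## Known limitations

* The invariant tableau is exponential in the worst case; the `limit`
  guard makes that explicit but does not avoid it.
* The recursive split-silhouette index is approximated by top-level
  silhouettes (see above); both published MSS targets are treated with the
  corresponding tolerance.
* Simulated firing statistics depend on the conflict-resolution semantics;
  both provided modes are plausible readings of "synchronous-like", and
  quantitative comparisons between tools should state the mode.
* No reachability, liveness or boundedness analysis; no timed, continuous,
  hybrid or coloured net extensions; no inhibitor arcs or capacities.
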