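# Methods

## Genome model and distance

A genome is a set of linear chromosomes over `n` distinct signed genes;
gene `g` contributes a tail extremity `2g−1` and a head `2g`.  Two gene
orders are treated as equal up to chromosome order and whole-chromosome
reversal-with-negation; the canonical form flips each chromosome so its
first absolute gene id is smaller than its last (single-gene chromosomes
are canonically positive) and sorts chromosomes by first id.  Circular
chromosomes are rejected on input and never produced.

Distances are DCJ distances computed from the breakpoint graph as
`d = n' − κ`.  Telomeres are capped lazily inside the distance routine:
blue-side caps for the first genome, red-side caps for the second; a path
between two blue-side caps counts as a cycle closed by a red edge, one
between two red-side caps as a cycle closed by a blue edge (that closing
edge is included in `n'`), and a mixed path as a cycle with its caps
collapsed.  `n'` is therefore `n + c₁ + (paths with two red-side caps)`
with `c₁` the first genome's chromosome count.  The formula is validated
in the test suite against breadth-first search over adjacency matchings —
an oracle that deliberately allows circular intermediate states, because
shortest DCJ scenarios may pass through them (e.g. sorting `3 2 1` into
`1 2 3` takes two operations only via an excised circle; any
linear-intermediate scenario needs three).

## Pathgroups and the greedy

For each ancestor and each of its (up to three) incident tree branches the
solver maintains the partially built breakpoint graph of that branch as a
set of alternating paths.  Internally a path endpoint is the pair
(vertex, which side of the branch still has to contribute an edge there);
a vertex with neither side decided is an isolated path whose two endpoints
are its own two sides.  This single representation covers the median
(leaves supply complete blue material from the start) and the general
small-phylogeny case, where a pathgroup next to undecided ancestors simply
has "missing" paths that are isolated vertices until the neighbour decides
an adjacency.  Adjacent ancestors share the branch's graph, so a red edge
fixed at one ancestor is immediately blue material for the other — the
propagation requires no copying and is exact by construction.

Fragments (runs of genes joined by chosen red edges) are tracked by an
endpoint-partner map; a candidate red edge is rejected exactly when its two
ends are the two ends of one fragment, which is the only way a circular
chromosome could arise.  Red edges are never directed at caps, and
pathgroups are never anchored at caps.

Each step processes the pathgroup with the best priority key, compared
lexicographically:

1. **cycles** (1–3): the most cycles a single red edge can close now;
2. **best next** (1–3): under that edge, the best cycle count available in
   any pathgroup whose paths the edge changes (the *secondary* groups);
3. **net delta** (refined and two-step schemes): the net change in
   potential cycles over the affected pathgroups, clamped to ±4;
4. **second step** (two-step scheme): the best cycle count available after
   greedily processing the best secondary group, again 1–3.

The enumerated tables have 7, 55 and 165 classes: the 3-cycle class is not
sub-classified by look-ahead (closing all three paths sets up no secondary
group), 2- and 1-cycle classes split 3 × 9 ways in the refined scheme, and
the two-step scheme triples every class.  Three choices behind those
numbers are this package's own design: *best next* is clamped to {1,2,3}
(a step whose affected groups can complete nothing is binned with the
weakest class); *net delta* is clamped to ±4 because the at most four
secondary groups dominate the net change, and wider swings are binned at
the extremes; and under the two-step scheme the 3-cycle classes with
second-step values 2 and 3 exist in the table but are not realised by the
greedy (no secondary group exists to provide them).  Tertiary pathgroups —
partners of secondary ones — keep their paths and fragment constraints
unchanged, so their potential-cycle count is invariant and they contribute
nothing to *net delta*; their priorities are still recomputed after every
applied step, as the look-ahead fields may shift.  All look-ahead
evaluation runs on overlay dictionaries over the locally affected groups,
never on a state copy, keeping per-step work constant.

Ties inside a priority class are broken first-in-first-out (updated groups
re-enter at the back), and ties among a group's equally good candidate
edges by the smallest target vertex id, making every solve deterministic.

At termination (no pathgroup anywhere has a priority) each surviving
fragment becomes one linear chromosome; no post-hoc joining is attempted.
Groups anchored at vertices that are telomeres in every input never
receive a priority and simply remain, which is how ancestral telomeres
emerge.

### Known limitation: cycle count versus distance

Maximising cycles is a proxy for minimising distance that ignores the
ancestor's own chromosome-count term in the capped formula.  A 1-cycle
step that joins two fragments always gains a cycle but can worsen the
summed distance — the smallest case is an identical pair `G1 = G2` with
`G3` their fusion, where the greedy reconstructs the fused genome (total
2) instead of `G1` (total 1).  When the third genome differs only by
interior, telomere-preserving inversions this cannot happen, and the
greedy provably returns the shared genome; the general behaviour is the
method's documented precision trade-off at chromosome ends.  The greedy
never beats the exhaustive optimum (verified against a brute-force median
oracle on small universes) and matches it in the moderate-rearrangement
regime the method targets.

## Small phylogeny and refinement

The tree solver is the same engine over all `N−2` ancestors' pathgroups at
once; with `N = 3` it *is* the median solver (bit-identical output).  The
refinement pass performs a fixed number of sweeps (default 50, after which
gains are marginal); each sweep visits the internal nodes in a seeded
random permutation and re-solves the median of the node's three current
neighbour genomes, replacing the node's genome when the sum of its three
incident branch distances does not increase.  Acceptance of equal-cost
proposals is the annealing ingredient; there is no temperature schedule.
The total objective is non-increasing by construction.  Random
initialisation draws each ancestor as an independent uniform signed
arrangement cut into 10 chromosomes by default (or `n` when smaller).

## Simulator

Experiments evolve a random ancestor (default 10 chromosomes) outward
along a balanced-as-possible (or random) unrooted binary topology, with a
fixed operation count per branch: 90% inversions, 10% reciprocal
translocations by default.  Breakpoints are genome-wide uniform — a
chromosome is hit in proportion to its length.  This choice was settled
empirically: per-chromosome-uniform breakpoints concentrate operations on
short chromosomes, and already the *true* scenario then measures
`d/τ ≈ 0.95` at a per-branch rate of `0.2 n`, which would make the
accuracy regime unreachable by any reconstruction; with length-weighted
breakpoints the true scenario measures `d/τ = 1.000` at that rate.
Zero-length inversions are redrawn so every counted operation cuts the
genome (whole-chromosome inversions remain possible and are silent
no-ops under genome equivalence — they are rare enough not to matter);
a translocation drawn on a single-chromosome genome is resampled as an
inversion, and exchanges that would empty a chromosome are redrawn so the
chromosome count stays fixed.  Every branch satisfies
`d(parent, child) ≤ ops performed`.

`run_experiment` hides the simulated ancestors, reconstructs (single pass,
optionally plus refinement sweeps), and reports per-replicate `d`, `τ`
(total operations over all branches) and `d/τ`, flagging the degenerate
`τ = 0` case instead of dividing.  Replicates are seeded independently
from the master seed; every run is byte-reproducible.

## Problem sizes used by the test and acceptance suites

The headline accuracy check runs medians at `n = 1000`, per-branch rate
`0.2 n`, ten replicates, refined scheme (mean `d/τ` within 0.02 of 1).
The bounded-update check instruments over 10⁴ greedy steps at `n = 200`
(max four secondary, eight tertiary groups per step).  Scheme-ordering
experiments use 10-leaf trees at `n = 200` (single-pass) and `n = 100`
(with 50 refinement sweeps); these sizes reproduce the qualitative
ordering of the accuracy curves while keeping the whole suite to a few
minutes on one CPU.  What passing these simulations shows is recovery of
the generator's own operation classes (inversions and reciprocal
translocations at uniform breakpoints) on a correct topology; real data
add unequal gene content, transpositions and duplications, rate
heterogeneity across lineages and topology uncertainty, none of which the
generator emulates.
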