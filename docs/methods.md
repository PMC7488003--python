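# Methods

## Problem setting

A B-cell clone's affinity maturation is modelled as a rooted directed tree
over unique nucleotide sequences: the root is the germline (known from
V(D)J annotation and supplied as input, not inferred), and each edge is one
base substitution, insertion or deletion. Repertoire sequencing reveals an
arbitrary subset of the tree's nodes — internal nodes and the root
included. Reconstruction fills in unobserved intermediates so that every
observed sequence is reachable from the root through unit-edit edges, and
maximum parsimony prefers the smallest such tree. This is a rooted Steiner
minimal tree problem in edit space and is NP-complete, so the package
implements a greedy heuristic with a post-hoc improvement phase.

## Edit-distance geometry

Distances are unit-cost Levenshtein; plain distance queries are delegated
to `edlib`. The quantity the growth step actually consumes is the
*first-step operation set* of an ordered pair (a, b): every one-base
operation on `a` whose result is at distance d(a, b) − 1 from `b`. When
several minimal edit scripts exist their first steps are pooled, each
unique (kind, position, base) triple once. Operations deeper along a
minimal script are *not* recorded: their coordinates are only meaningful
after earlier edits have shifted positions, and the growth loop re-derives
fresh first-step sets from every newly added node anyway, so nothing is
lost.

First-step sets are computed by a compiled O(|Σ| · m · n) dynamic program
(`_kernels.py`): with prefix distances D[i, j] = d(a[:i], b[:j]) and suffix
distances S[i, j] = d(a[i:], b[j:]), the distance of any single-edit
variant of `a` is a min over one split column, at the cost of one extra
Wagner–Fischer row per (position, base) candidate. The test suite verifies
the kernel against brute-force enumeration of every one-base operation with
an independent pure-Python distance.

Positions are 1-based; an insertion at position p makes the inserted base
the p-th character. Sequences are validated against the alphabet (default
`ACGT`, configurable) at every public entry point; off-alphabet characters
fail fast rather than being treated as a fifth symbol. Costs are unweighted
— no transition/transversion preference — matching the unweighted parsimony
objective.

## Growth

The reconstructed part starts as the root alone; observed sequences are
deduplicated into standby nodes carrying multiplicities (an observed
sequence equal to the root marks the root observed). Each iteration:

1. An MST is built over the reconstructed part contracted into a single
   zero-weight component plus all standby nodes, with edit-distance
   weights. At iteration one this is a plain MST over root + observed;
   later it connects standby nodes to the nearest parts of the growing
   tree. Prim's algorithm with (weight, node-id) ordering makes the MST
   deterministic; it consumes no randomness.
2. Cutting the MST at its tree/standby crossing edges partitions the
   standby nodes into clusters, each with an origination node in the tree
   (the nearest tree node to the crossing standby node; distance ties go to
   the earliest-created node).
3. For every cluster member the first-step set from its origination is
   tallied per (origination, operation) pair; clusters sharing an
   origination aggregate. The maximal-count pair is selected, ties broken
   uniformly at random from the single seeded generator — the only place
   randomness enters.
4. The selected operation applied to its origination yields one new child:
   a recruited standby node if the sequence is observed, else an inferred
   intermediate. If the sequence already exists in the tree (the heuristic
   can propose this; the case is not specified by the growth rule itself)
   the pair is discarded from the current tallies and the next-best pair is
   taken. Should every tallied candidate collide, the tallies are
   recomputed with each standby node assigned to its *nearest* tree node:
   from a nearest node, a first-step operation landing on an existing tree
   node is impossible (that node would be strictly nearer), so this
   fallback always makes progress and the loop — one node per iteration —
   terminates.

Distances from each new tree node to the remaining standby nodes are
computed once and cached; the MST is rebuilt each iteration from the cache.

## Trimming and rewiring

Trimming removes every unobserved node with no observed descendant (the
root always stays). It is idempotent and never touches observed nodes.

Rewiring considers as movable every observed node and every branching node
(out-degree > 1). A move detaches the subtree, re-attaches it under any
node outside the subtree — inserting d − 1 intermediates along a canonical
minimal edit path when the edit distance d to the new parent exceeds one —
and removes the chain of unobserved ancestors upstream of the old
attachment point that lose their last observed descendant. On a trimmed
tree that chain is exactly computable from subtree observed-counts, so
candidate deltas are evaluated analytically without copying. Each pass
applies the move with the **largest** size reduction (best-improvement;
ties by breadth-first scan order), then re-trims; passes repeat until no
move reduces the size. First-improvement scanning was considered and
rejected: a shallow observed node's small saving can preempt a deeper
node's larger one and strand the tree at a worse fixed point (a six-node
two-branch example settles at five nodes under first-improvement but
reaches the four-node optimum under best-improvement). Termination is
guaranteed because every accepted move strictly decreases the integer node
count.

The canonical path prefers, at each tie, substitution over deletion over
insertion and then the smallest position and base, making rewired output
deterministic. If a path intermediate would duplicate a surviving tree
sequence the candidate is skipped and the next-best move is taken;
sequence uniqueness is invariant.

## Simulator

`simulate_tree` draws a uniformly random root of the configured length,
picks a target size uniformly from the tree-size range, and grows the tree
by repeatedly choosing an existing node uniformly, drawing an operation
kind from (p_sub, p_ins, p_del), a uniform position and a uniform valid
base, and attaching the result when it is globally novel (bounded redraws,
then an error — reachable only in degenerate settings). Defaults are the
benchmark's study conditions: tree sizes uniform in [20, 80], observed
counts uniform in [2, 24] (capped at size − 1), 500 replicates per setting,
and the nine settings cross root lengths {300, 80, 20} with operation
triples {(1, 0, 0), (0.98, 0.01, 0.01), (0.90, 0.05, 0.05)}. Shorter roots
concentrate the same number of events on fewer positions and so emulate
higher per-site mutation rates.

The simulator is deliberately simpler than real somatic hypermutation: no
hotspot motifs, no framework/CDR rate partition, no selection, and
independent uniform positions. Benchmark results therefore speak to the
combinatorics of parsimony reconstruction under increasing event density,
not to sequence-context biology.

**Ground truth for comparison.** A reconstruction is compared against the
simulated tree *pruned to the observed nodes' ancestor closure* — the
latent process minus branches that left no observed trace. The unobserved
remainder is unknowable from the data, and no reconstruction should be
charged for not inventing it; against the full latent tree every method
would trivially score "smaller" on nearly every replicate and the
comparison would order nothing. A replicate is a success when the
reconstructed size is ≤ the pruned-truth size; "smaller" outcomes are
legitimate (the true history need not be minimal for the revealed subset).
Under these conditions the success rates across the nine settings fall from
~99–100% (length 300) through ~93–95% (length 80) to ~90% (length 20),
reproducing the expected difficulty ordering.

Tree-shape comparisons normalize per-feature differences by the feature's
range over the ground-truth sample and aggregate the mean of squares
(mean absolute difference available via a flag).

## Tree-shape features

Twelve statistics: size; root out-degree; mean out-degree (identically
(N − 1)/N in any rooted tree); their ratio; max and min root-to-leaf depth;
mean root-to-node depth; minimum branching-node depth; the two
first-branching offsets (computed as depth differences from the previous
two, which is the arithmetic the feature definitions imply); and min/mean
distance from each branching node to its nearest branching ancestor
(branching nodes without one contribute nothing). A "branching node" has
out-degree > 1. Features undefined on a tree (no branching node; no
branching-ancestor pair) are reported as `NA` and excluded pairwise from
comparisons. All distances are edge counts, which equal mutational
distances by construction.

## Determinism and problem sizes

All randomness flows from one seed per entry point (library `seed`
argument, CLI `--seed`); benchmark replicates draw independent child
streams from a seed sequence, so runs are reproducible and
order-independent. The test suite exercises reconstruction on hundreds of
simulated instances; its benchmark checks use the full 500-replicate
protocol at root lengths 300, 80 and 20, which completes in under a minute
thanks to the compiled kernels and distance caching. The tiny-instance
optimality comparison uses a two-letter alphabet and roots of length ≤ 5,
where the exact Steiner optimum is computable by Dreyfus–Wagner dynamic
programming; the heuristic is never below the optimum there and matches it
on most instances (the match rate is reported by the test, not asserted).

## Known limitations

- Greedy growth with local rewiring carries no optimality guarantee; on
  short sequences with dense repeated edits it can exceed the parsimony
  optimum (the "larger" benchmark column).
- Abundances are carried as node multiplicities but do not influence the
  objective; isotype and timepoint metadata are out of scope.
- The root must be supplied; germline inference, clone partitioning and
  read preprocessing belong to upstream tools.
- Rewiring evaluates single-subtree moves only; coordinated multi-subtree
  rearrangements are not searched.
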