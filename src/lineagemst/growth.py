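"""Iterative MST-guided growth of a lineage tree.

The reconstruction starts from the germline root and repeatedly extends the
reconstructed part of the tree by a single node until every observed
sequence has been recruited.  Each iteration:

1. builds a minimum spanning tree over the reconstructed part (contracted to
   a single zero-weight component) and the still-standby observed nodes,
   with edit-distance weights — the MST approximates the landscape of the
   observed sequences around the growing tree;
2. cuts the MST at its tree/standby crossing edges, which partitions the
   standby nodes into clusters, each hanging off one *origination* node of
   the reconstructed part;
3. tallies, per (origination, operation) pair, how many cluster members the
   operation moves one step closer to (first-step operation sets);
4. applies the most frequent pair (ties broken uniformly at random from the
   seeded stream) to create one new child of the origination — either a
   recruited observed node, if the produced sequence is standby, or a new
   inferred intermediate.

The loop adds exactly one node per iteration and therefore terminates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .edit_space import DNA_ALPHABET, EditOperation, apply_operation, edit_distance, first_step_operations, validate_sequence
from .tree import LineageNode, LineageTree

__all__ = [
    "GrowthState",
    "Cluster",
    "initialize",
    "build_guide_mst",
    "assign_clusters",
    "tally_operations",
    "select_origination_operation",
    "grow_step",
    "reconstruct",
]


class SequenceCollisionError(ValueError):
    """The proposed intermediate duplicates a sequence already in the tree."""


@dataclass(frozen=True)
class Cluster:
    """Standby nodes reached through one MST crossing edge.

    ``origination`` is the reconstructed node the cluster hangs off; several
    clusters may share an origination.
    """

    origination: int
    members: tuple[int, ...]


@dataclass
class GrowthState:
    """The reconstructed part, the standby pool and all growth-time caches."""

    tree: LineageTree
    standby: dict[int, LineageNode]
    rng: np.random.Generator
    alphabet: str = DNA_ALPHABET
    # symmetric edit-distance cache keyed by unordered node-id pair
    _dist: dict[tuple[int, int], int] = field(default_factory=dict)
    # standby id -> (distance, reconstructed node id) of its nearest tree node;
    # ties go to the smallest (earliest-created) node id
    _anchor: dict[int, tuple[int, int]] = field(default_factory=dict)
    # (origination id, standby id) -> first-step operation set
    _first: dict[tuple[int, int], frozenset[EditOperation]] = field(default_factory=dict)

    def sequence_of(self, node_id: int) -> str:
        if node_id in self.standby:
            return self.standby[node_id].sequence
        return self.tree.node(node_id).sequence

    def distance(self, a: int, b: int) -> int:
        key = (a, b) if a < b else (b, a)
        d = self._dist.get(key)
        if d is None:
            d = edit_distance(self.sequence_of(a), self.sequence_of(b), self.alphabet)
            self._dist[key] = d
        return d

    def first_steps(self, origination: int, member: int) -> frozenset[EditOperation]:
        key = (origination, member)
        ops = self._first.get(key)
        if ops is None:
            ops = first_step_operations(
                self.tree.node(origination).sequence,
                self.standby[member].sequence,
                self.alphabet,
            )
            self._first[key] = ops
        return ops

    def _register_tree_node(self, node_id: int) -> None:
        """Update every standby node's nearest-tree-node anchor."""
        for sid in self.standby:
            d = self.distance(node_id, sid)
            if d < self._anchor[sid][0]:
                self._anchor[sid] = (d, node_id)


def initialize(
    root: str,
    observed: list[str],
    rng: np.random.Generator | None = None,
    alphabet: str = DNA_ALPHABET,
) -> GrowthState:
    """Set up the growth state: root-only tree, deduplicated standby pool.

    Duplicate observed sequences collapse into one standby node carrying
    their multiplicity.  An observed sequence equal to the root marks the
    root itself as observed.
    """
    validate_sequence(root, alphabet, "root sequence")
    if not observed:
        raise ValueError("need at least one observed sequence")
    for i, seq in enumerate(observed):
        validate_sequence(seq, alphabet, f"observed sequence {i}")
    if rng is None:
        rng = np.random.default_rng(0)

    counts: dict[str, int] = {}
    for seq in observed:
        counts[seq] = counts.get(seq, 0) + 1

    tree = LineageTree(root, observed=root in counts, multiplicity=counts.pop(root, 0), alphabet=alphabet)
    standby: dict[int, LineageNode] = {}
    for i, (seq, mult) in enumerate(counts.items(), start=1):
        standby[i] = LineageNode(i, seq, observed=True, multiplicity=mult)
    state = GrowthState(tree=tree, standby=standby, rng=rng, alphabet=alphabet)
    tree._next_id = len(standby) + 1
    for sid in standby:
        state._anchor[sid] = (state.distance(tree.root_id, sid), tree.root_id)
    return state


def build_guide_mst(state: GrowthState) -> list[tuple[int, int, int]]:
    """MST over the contracted reconstructed part plus the standby nodes.

    The reconstructed part counts as one zero-weight component, so the MST
    reduces to Prim's algorithm over a star of standby nodes around a
    super-node; crossing edges are reported with the concrete nearest
    reconstructed node as their tree-side endpoint.  Equal-weight choices
    are resolved by (weight, endpoint-id) order so the MST is deterministic
    and consumes no randomness.
    """
    if not state.standby:
        raise ValueError("no standby nodes to span")
    SUPER = -1
    remaining = sorted(state.standby)
    # best known connection of each standby node into the partial MST
    best: dict[int, tuple[int, int]] = {
        sid: (state._anchor[sid][0], state._anchor[sid][1]) for sid in remaining
    }
    edges: list[tuple[int, int, int]] = []
    in_mst: set[int] = {SUPER}
    while remaining:
        sid = min(remaining, key=lambda s: (best[s][0], best[s][1], s))
        w, frm = best[sid]
        edges.append((frm, sid, w))
        in_mst.add(sid)
        remaining.remove(sid)
        for other in remaining:
            d = state.distance(sid, other)
            if (d, sid) < best[other]:
                best[other] = (d, sid)
    return edges


def assign_clusters(mst: list[tuple[int, int, int]], state: GrowthState) -> list[Cluster]:
    """Partition standby nodes into clusters by cutting the MST crossing edges.

    Each connected component of standby-only MST edges attaches to the
    reconstructed part through exactly one crossing edge, whose tree-side
    endpoint is the cluster's origination.
    """
    adjacency: dict[int, list[int]] = {sid: [] for sid in state.standby}
    crossings: list[tuple[int, int]] = []  # (origination, standby endpoint)
    for u, v, _w in mst:
        if u in state.standby:
            adjacency[u].append(v)
            adjacency[v].append(u)
        else:
            crossings.append((u, v))
    clusters = []
    for origination, seed in crossings:
        members = [seed]
        seen = {seed}
        stack = [seed]
        while stack:
            cur = stack.pop()
            for nxt in adjacency[cur]:
                if nxt not in seen:
                    seen.add(nxt)
                    members.append(nxt)
                    stack.append(nxt)
        clusters.append(Cluster(origination, tuple(sorted(members))))
    return clusters


def tally_operations(
    clusters: list[Cluster], state: GrowthState
) -> dict[tuple[int, EditOperation], int]:
    """Count, per (origination, operation), how many cluster members the
    operation steps toward.  Clusters sharing an origination aggregate."""
    tallies: dict[tuple[int, EditOperation], int] = {}
    for cluster in clusters:
        for member in cluster.members:
            for op in state.first_steps(cluster.origination, member):
                key = (cluster.origination, op)
                tallies[key] = tallies.get(key, 0) + 1
    return tallies


def select_origination_operation(
    tallies: dict[tuple[int, EditOperation], int], rng: np.random.Generator
) -> tuple[int, EditOperation]:
    """Pick a maximal-count pair; ties are broken uniformly at random."""
    if not tallies:
        raise ValueError("no origination-operation candidates")
    top = max(tallies.values())
    candidates = sorted(
        (key for key, count in tallies.items() if count == top),
        key=lambda key: (key[0], key[1].sort_key),
    )
    if len(candidates) == 1:
        return candidates[0]
    return candidates[int(rng.integers(len(candidates)))]


def grow_step(state: GrowthState, selection: tuple[int, EditOperation]) -> GrowthState:
    """Apply the selected operation to its origination, adding one node.

    Recruits a standby node when the produced sequence is observed, else
    creates an inferred intermediate.  Raises
    :class:`SequenceCollisionError` when the sequence already sits in the
    reconstructed tree (the caller then discards the pair and re-selects).
    """
    origination, op = selection
    new_seq = apply_operation(state.tree.node(origination).sequence, op, state.alphabet)
    if state.tree.has_sequence(new_seq):
        raise SequenceCollisionError(
            f"operation {op} at node {origination} reproduces an existing tree sequence"
        )
    standby_hit = None
    for sid, node in state.standby.items():
        if node.sequence == new_seq:
            standby_hit = sid
            break
    if standby_hit is not None:
        node = state.standby.pop(standby_hit)
        del state._anchor[standby_hit]
        state.tree.add_child(
            origination,
            new_seq,
            op,
            observed=True,
            multiplicity=node.multiplicity,
            node_id=standby_hit,
        )
        state._register_tree_node(standby_hit)
    else:
        nid = state.tree.add_child(origination, new_seq, op)
        state._register_tree_node(nid)
    return state


def _nearest_anchor_tallies(state: GrowthState) -> dict[tuple[int, EditOperation], int]:
    """Fallback tallies with each standby node assigned to its nearest tree node.

    Used when every MST-guided candidate collides with an existing tree
    sequence.  From a *nearest* tree node no first-step operation can land on
    another tree node (that node would be strictly nearer), so at least one
    candidate here always makes progress.
    """
    clusters: dict[int, list[int]] = {}
    for sid in state.standby:
        clusters.setdefault(state._anchor[sid][1], []).append(sid)
    return tally_operations(
        [Cluster(orig, tuple(sorted(members))) for orig, members in clusters.items()],
        state,
    )


def reconstruct(
    root: str,
    observed: list[str],
    seed: int = 0,
    do_trim: bool = True,
    do_rewire: bool = True,
    rng: np.random.Generator | None = None,
    alphabet: str = DNA_ALPHABET,
) -> LineageTree:
    """Reconstruct a maximum-parsimony lineage tree from observed sequences.

    Grows the tree along successive MSTs until every observed sequence is
    recruited, then (optionally) trims unobserved dead branches and rewires
    subtrees wherever that shrinks the tree.  With a fixed seed the result
    is fully deterministic.
    """
    from .refine import rewire, trim  # local import to avoid a cycle

    if rng is None:
        rng = np.random.default_rng(seed)
    state = initialize(root, observed, rng, alphabet)
    while state.standby:
        mst = build_guide_mst(state)
        clusters = assign_clusters(mst, state)
        tallies = tally_operations(clusters, state)
        while True:
            if not tallies:
                tallies = _nearest_anchor_tallies(state)
            selection = select_origination_operation(tallies, state.rng)
            try:
                grow_step(state, selection)
                break
            except SequenceCollisionError:
                del tallies[selection]
    result = state.tree
    if do_trim:
        result = trim(result)
    if do_rewire:
        result = rewire(result)
    return result
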