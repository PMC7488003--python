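"""Post-processing of grown lineage trees: trimming and subtree rewiring.

The MST-guided growth occasionally leaves branches whose leaves were never
observed; those explain nothing and are removed (*trimming*).  It can also
place a subtree under a suboptimal ancestor; detaching the subtree,
re-attaching it elsewhere (inserting intermediates along one canonical
minimal edit path when the gap is larger than one operation) and trimming
the now-dead upstream chain can shrink the tree (*rewiring*).  Rewiring
repeats until no move reduces the tree size; every accepted move strictly
decreases the integer node count, so the procedure terminates.
"""

from __future__ import annotations

from dataclasses import dataclass

from .edit_space import EditOperation, canonical_edit_path, edit_distance
from .tree import LineageTree

__all__ = ["RewireMove", "trim", "rewire_once", "rewire"]


@dataclass(frozen=True)
class RewireMove:
    """A candidate subtree relocation and its effect on tree size."""

    subtree_root: int
    old_parent: int
    new_parent: int
    size_delta: int  # new size - old size; accepted moves are < 0


def _observed_below(tree: LineageTree) -> dict[int, int]:
    """Number of observed nodes in each node's subtree (inclusive)."""
    counts = {nid: int(tree.node(nid).observed) for nid in tree.node_ids()}
    for nid in reversed(tree.bfs_ids()):
        parent = tree.parent_of(nid)
        if parent is not None:
            counts[parent] += counts[nid]
    return counts


def trim(tree: LineageTree) -> LineageTree:
    """Remove every unobserved node with no observed descendant.

    The root is always kept.  Idempotent; never touches observed nodes.
    """
    counts = _observed_below(tree)
    dead = {
        nid
        for nid in tree.node_ids()
        if nid != tree.root_id and not tree.node(nid).observed and counts[nid] == 0
    }
    if not dead:
        return tree
    out = tree.copy()
    out.delete_nodes(dead)
    return out


def _dead_chain(
    tree: LineageTree,
    counts: dict[int, int],
    old_parent: int,
    obs_in_subtree: int,
    new_parent: int,
) -> list[int]:
    """Nodes that die when a subtree holding ``obs_in_subtree`` observed
    nodes is moved from under ``old_parent`` to under ``new_parent``.

    On a trimmed tree the dead nodes form a chain of unobserved ancestors of
    the old attachment point whose only observed descendants lived in the
    moved subtree; the chain stops at (and excludes) the new parent, which
    regains the subtree.
    """
    chain = []
    node = old_parent
    while (
        node != tree.root_id
        and node != new_parent
        and not tree.node(node).observed
        and counts[node] == obs_in_subtree
    ):
        chain.append(node)
        node = tree.parent_of(node)
    return chain


def rewire_once(tree: LineageTree) -> tuple[LineageTree, bool]:
    """Apply the single best size-reducing subtree move, if one exists.

    Candidate subtree roots are all observed nodes and all branching nodes
    (out-degree > 1), scanned in breadth-first order; candidate new parents
    are every node outside the moving subtree, in node-id order.  Among all
    strictly size-reducing moves the one with the largest reduction is
    applied (ties by scan order).  Returns ``(tree, improved)``; the input
    tree is never mutated.

    The input is expected to be trimmed; the output is trimmed again.
    """
    counts = _observed_below(tree)
    movable = [
        nid
        for nid in tree.bfs_ids()
        if nid != tree.root_id
        and (tree.node(nid).observed or tree.out_degree(nid) > 1)
    ]
    candidates: list[RewireMove] = []
    for v in movable:
        sub = set(tree.subtree_ids(v))
        obs_sub = counts[v]
        old_parent = tree.parent_of(v)
        v_seq = tree.node(v).sequence
        for target in sorted(tree.node_ids()):
            if target in sub or target == old_parent:
                continue
            d = edit_distance(tree.node(target).sequence, v_seq, tree.alphabet)
            removed = len(_dead_chain(tree, counts, old_parent, obs_sub, target))
            delta = (d - 1) - removed
            if delta < 0:
                candidates.append(RewireMove(v, old_parent, target, delta))
    candidates.sort(key=lambda m: m.size_delta)
    for move in candidates:
        out = _apply_move(tree, counts, move)
        if out is not None:
            return out, True
    return tree, False


def _apply_move(
    tree: LineageTree, counts: dict[int, int], move: RewireMove
) -> LineageTree | None:
    """Execute a rewire move on a copy; ``None`` when the canonical
    reattachment path collides with a surviving tree sequence."""
    chain = _dead_chain(
        tree, counts, move.old_parent, counts[move.subtree_root], move.new_parent
    )
    path = canonical_edit_path(
        tree.node(move.new_parent).sequence,
        tree.node(move.subtree_root).sequence,
        tree.alphabet,
    )
    surviving = set(tree.node_ids()) - set(chain)
    taken = {tree.node(nid).sequence for nid in surviving}
    if any(seq in taken for _op, seq in path[:-1]):
        return None

    out = tree.copy()
    # hold the subtree aside so the dead chain becomes deletable
    sub_root = move.subtree_root
    out._children[out.parent_of(sub_root)].remove(sub_root)
    del out._parent[sub_root]
    out.delete_nodes(set(chain))
    parent = move.new_parent
    for op, seq in path[:-1]:
        parent = out.add_child(parent, seq, op)
    final_op = path[-1][0]
    # re-hang the subtree under the last intermediate (or the new parent)
    out._parent[sub_root] = parent
    out._children[parent].append(sub_root)
    out._edge_op[sub_root] = final_op
    return trim(out)


def rewire(tree: LineageTree) -> LineageTree:
    """Repeat size-reducing subtree moves until none remains (fixed point)."""
    current = trim(tree)
    improved = True
    while improved:
        current, improved = rewire_once(current)
    return current
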