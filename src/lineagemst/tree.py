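"""Rooted lineage trees whose edges are single one-base edits.

A lineage tree models the microevolution of a B-cell receptor clone: the
root is the unmutated germline sequence, every node carries one unique
nucleotide sequence, and every directed edge is exactly one substitution,
insertion or deletion.  Observed nodes are sequences present in the
sequencing data (with a multiplicity for collapsed duplicate reads);
unobserved nodes are inferred intermediates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

from .edit_space import (
    DNA_ALPHABET,
    EditOperation,
    apply_operation,
    edit_distance,
    validate_sequence,
)

ROOT_ID = 0


@dataclass
class LineageNode:
    id: int
    sequence: str
    observed: bool = False
    multiplicity: int = 0


class LineageTree:
    """Mutable rooted directed tree over unique sequences.

    Node ids are integers assigned in creation order; the root is always 0.
    Every non-root node stores the :class:`EditOperation` that produces its
    sequence from its parent's, which pins each edge to edit distance one.
    """

    def __init__(
        self,
        root_sequence: str,
        observed: bool = False,
        multiplicity: int = 0,
        alphabet: str = DNA_ALPHABET,
    ) -> None:
        validate_sequence(root_sequence, alphabet, "root sequence")
        self.alphabet = alphabet
        root = LineageNode(ROOT_ID, root_sequence, observed, multiplicity)
        self._nodes: dict[int, LineageNode] = {ROOT_ID: root}
        self._parent: dict[int, int] = {}
        self._children: dict[int, list[int]] = {ROOT_ID: []}
        self._edge_op: dict[int, EditOperation] = {}
        self._seq_index: dict[str, int] = {root_sequence: ROOT_ID}
        self._next_id = 1

    # ------------------------------------------------------------------ views

    @property
    def root_id(self) -> int:
        return ROOT_ID

    @property
    def root(self) -> LineageNode:
        return self._nodes[ROOT_ID]

    @property
    def size(self) -> int:
        return len(self._nodes)

    def node(self, node_id: int) -> LineageNode:
        return self._nodes[node_id]

    def node_ids(self) -> list[int]:
        return list(self._nodes)

    def nodes(self) -> Iterator[LineageNode]:
        return iter(self._nodes.values())

    def parent_of(self, node_id: int) -> int | None:
        return self._parent.get(node_id)

    def children_of(self, node_id: int) -> list[int]:
        return list(self._children[node_id])

    def out_degree(self, node_id: int) -> int:
        return len(self._children[node_id])

    def operation_of(self, child_id: int) -> EditOperation:
        """The one-base operation labelling the edge into ``child_id``."""
        return self._edge_op[child_id]

    def edges(self) -> Iterator[tuple[int, int, EditOperation]]:
        for child, parent in self._parent.items():
            yield parent, child, self._edge_op[child]

    def has_sequence(self, seq: str) -> bool:
        return seq in self._seq_index

    def id_of_sequence(self, seq: str) -> int:
        return self._seq_index[seq]

    def observed_ids(self) -> list[int]:
        return [n.id for n in self._nodes.values() if n.observed]

    def bfs_ids(self) -> list[int]:
        order = [ROOT_ID]
        i = 0
        while i < len(order):
            order.extend(self._children[order[i]])
            i += 1
        return order

    def subtree_ids(self, node_id: int) -> list[int]:
        """Preorder ids of the subtree rooted at ``node_id`` (inclusive)."""
        order = [node_id]
        i = 0
        while i < len(order):
            order.extend(self._children[order[i]])
            i += 1
        return order

    def depths(self) -> dict[int, int]:
        depth = {ROOT_ID: 0}
        for nid in self.bfs_ids()[1:]:
            depth[nid] = depth[self._parent[nid]] + 1
        return depth

    # -------------------------------------------------------------- mutation

    def add_child(
        self,
        parent_id: int,
        sequence: str,
        op: EditOperation,
        observed: bool = False,
        multiplicity: int = 0,
        node_id: int | None = None,
    ) -> int:
        if parent_id not in self._nodes:
            raise KeyError(f"no node {parent_id}")
        if sequence in self._seq_index:
            raise ValueError("sequence already present in the tree")
        if apply_operation(self._nodes[parent_id].sequence, op, self.alphabet) != sequence:
            raise ValueError(f"operation {op} does not produce the child sequence")
        if node_id is None:
            node_id = self._next_id
        elif node_id in self._nodes:
            raise ValueError(f"node id {node_id} already in use")
        self._next_id = max(self._next_id, node_id + 1)
        self._nodes[node_id] = LineageNode(node_id, sequence, observed, multiplicity)
        self._parent[node_id] = parent_id
        self._children[parent_id].append(node_id)
        self._children[node_id] = []
        self._edge_op[node_id] = op
        self._seq_index[sequence] = node_id
        return node_id

    def set_parent(self, node_id: int, new_parent: int, op: EditOperation) -> None:
        """Reattach ``node_id`` (and its subtree) under ``new_parent``."""
        if node_id == ROOT_ID:
            raise ValueError("cannot reparent the root")
        if new_parent in self.subtree_ids(node_id):
            raise ValueError("reattachment target is inside the moving subtree")
        if apply_operation(self._nodes[new_parent].sequence, op, self.alphabet) != self._nodes[node_id].sequence:
            raise ValueError(f"operation {op} does not produce the child sequence")
        old = self._parent[node_id]
        self._children[old].remove(node_id)
        self._parent[node_id] = new_parent
        self._children[new_parent].append(node_id)
        self._edge_op[node_id] = op

    def delete_nodes(self, ids: set[int]) -> None:
        """Remove a set of nodes; every child of a removed node must also be removed."""
        if ROOT_ID in ids:
            raise ValueError("cannot delete the root")
        for nid in ids:
            for child in self._children[nid]:
                if child not in ids:
                    raise ValueError(f"node {child} would be orphaned")
        for nid in ids:
            parent = self._parent.pop(nid)
            if parent not in ids:
                self._children[parent].remove(nid)
            del self._children[nid]
            del self._edge_op[nid]
            del self._seq_index[self._nodes[nid].sequence]
            del self._nodes[nid]

    def copy(self) -> "LineageTree":
        dup = LineageTree.__new__(LineageTree)
        dup.alphabet = self.alphabet
        dup._nodes = {
            nid: LineageNode(n.id, n.sequence, n.observed, n.multiplicity)
            for nid, n in self._nodes.items()
        }
        dup._parent = dict(self._parent)
        dup._children = {nid: list(ch) for nid, ch in self._children.items()}
        dup._edge_op = dict(self._edge_op)
        dup._seq_index = dict(self._seq_index)
        dup._next_id = self._next_id
        return dup

    # ------------------------------------------------------------ diagnostics

    def validate(self) -> None:
        """Check all structural invariants; raise ``AssertionError`` on violation."""
        assert ROOT_ID in self._nodes and ROOT_ID not in self._parent
        assert len(self._seq_index) == len(self._nodes), "duplicate sequences"
        reachable = set(self.bfs_ids())
        assert reachable == set(self._nodes), "unreachable nodes (cycle or orphan)"
        for child, parent in self._parent.items():
            op = self._edge_op[child]
            assert (
                apply_operation(self._nodes[parent].sequence, op, self.alphabet)
                == self._nodes[child].sequence
            ), f"edge op {op} inconsistent at node {child}"
            assert (
                edit_distance(
                    self._nodes[parent].sequence,
                    self._nodes[child].sequence,
                    self.alphabet,
                )
                == 1
            ), f"edge into {child} is not a single one-base operation"

    def __repr__(self) -> str:
        n_obs = len(self.observed_ids())
        return f"<LineageTree size={self.size} observed={n_obs}>"
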