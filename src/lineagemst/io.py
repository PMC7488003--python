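"""File formats: FASTA input, edge-list TSV, Newick and GraphML trees.

The edge-list TSV is the canonical interchange format: one row per edge
(child_id, parent_id, child sequence, observed flag, multiplicity, and the
one-base operation relative to the parent, e.g. ``sub:3:G``), preceded by a
``# root`` comment line carrying the root node.  Reading an edge list back
reproduces the written tree exactly, ids included.
"""

from __future__ import annotations

import csv
from pathlib import Path

from Bio import SeqIO

from .edit_space import DNA_ALPHABET, EditOperation, validate_sequence, AlphabetError
from .features import FEATURE_NAMES, FeatureVector
from .tree import LineageTree

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_tree",
    "read_tree",
    "write_features",
    "write_benchmark",
]

TREE_FORMATS = ("tsv", "newick", "graphml")
_TSV_COLUMNS = ["child_id", "parent_id", "sequence", "observed", "multiplicity", "operation"]


def read_fasta(path: str | Path, alphabet: str = DNA_ALPHABET) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs in file order; sequences are uppercased.

    Rejects empty files, duplicate record ids and off-alphabet characters
    with errors naming the offending record.
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA record id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        try:
            validate_sequence(seq, alphabet, name=f"record {rec.id!r}")
        except AlphabetError as exc:
            raise AlphabetError(f"{path}: {exc}") from None
        records.append((rec.id, seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(path: str | Path, records: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------- edge lists

def _write_edgelist(tree: LineageTree, path: Path) -> None:
    root = tree.root
    with open(path, "w", newline="") as fh:
        fh.write(
            f"# root\t{root.id}\t{root.sequence}\t{int(root.observed)}\t{root.multiplicity}\n"
        )
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_COLUMNS)
        for nid in tree.bfs_ids()[1:]:
            node = tree.node(nid)
            writer.writerow(
                [
                    node.id,
                    tree.parent_of(nid),
                    node.sequence,
                    int(node.observed),
                    node.multiplicity,
                    str(tree.operation_of(nid)),
                ]
            )


def read_tree(path: str | Path, alphabet: str = DNA_ALPHABET) -> LineageTree:
    """Read an edge-list TSV written by :func:`write_tree` back into a tree."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines or not lines[0].startswith("# root\t"):
        raise ValueError(f"{path}: missing '# root' line; not a lineage tree edge list")
    _tag, root_id, root_seq, root_obs, root_mult = lines[0].split("\t")
    if int(root_id) != 0:
        raise ValueError(f"{path}: root id must be 0, got {root_id}")
    tree = LineageTree(
        root_seq, observed=bool(int(root_obs)), multiplicity=int(root_mult), alphabet=alphabet
    )
    rows = list(csv.reader(lines[1:], delimiter="\t"))
    if rows and rows[0] == _TSV_COLUMNS:
        rows = rows[1:]
    for row in rows:
        child_id, parent_id, seq, obs, mult, op_text = row
        tree.add_child(
            int(parent_id),
            seq,
            EditOperation.parse(op_text),
            observed=bool(int(obs)),
            multiplicity=int(mult),
            node_id=int(child_id),
        )
    return tree


# ------------------------------------------------------------------- newick

def _newick_label(tree: LineageTree, nid: int) -> str:
    return f"{nid}_obs" if tree.node(nid).observed else str(nid)


def _newick(tree: LineageTree, nid: int) -> str:
    children = sorted(tree.children_of(nid))
    label = _newick_label(tree, nid)
    if not children:
        return label
    inner = ",".join(f"{_newick(tree, c)}:1" for c in children)
    return f"({inner}){label}"


def _write_newick(tree: LineageTree, path: Path) -> None:
    Path(path).write_text(_newick(tree, tree.root_id) + ";\n")


# ------------------------------------------------------------------ graphml

def _write_graphml(tree: LineageTree, path: Path) -> None:
    import networkx as nx

    graph = nx.DiGraph()
    for node in tree.nodes():
        graph.add_node(
            node.id,
            sequence=node.sequence,
            observed=int(node.observed),
            multiplicity=node.multiplicity,
        )
    for parent, child, op in tree.edges():
        graph.add_edge(parent, child, operation=str(op))
    nx.write_graphml(graph, str(path))


def write_tree(tree: LineageTree, path: str | Path, fmt: str = "tsv") -> None:
    """Serialize a lineage tree as ``tsv`` (edge list), ``newick`` or ``graphml``."""
    path = Path(path)
    if fmt == "tsv":
        _write_edgelist(tree, path)
    elif fmt == "newick":
        _write_newick(tree, path)
    elif fmt == "graphml":
        _write_graphml(tree, path)
    else:
        raise ValueError(f"unknown tree format {fmt!r}; expected one of {TREE_FORMATS}")


# ------------------------------------------------------------------- tables

def write_features(path: str | Path, vectors: list[FeatureVector]) -> None:
    """Feature vectors as TSV, one row per tree; undefined values as ``NA``."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(FEATURE_NAMES)
        for fv in vectors:
            writer.writerow(
                ["NA" if v is None else f"{v:g}" for v in fv.as_dict().values()]
            )


def write_benchmark(path: str | Path, rows: list) -> None:
    """Benchmark rows as TSV mirroring the standard size-comparison table."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["root_length", "p_mut", "p_ins", "p_del", "replicates", "larger", "same", "smaller", "success"]
        )
        for row in rows:
            s = row.setting
            writer.writerow(
                [
                    s.root_length,
                    *[f"{p:g}" for p in s.op_probs],
                    row.replicates,
                    row.larger,
                    row.same,
                    row.smaller,
                    row.success,
                ]
            )
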