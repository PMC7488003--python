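"""Edit-distance geometry on nucleotide sequences.

Sequences are plain Python strings over a fixed alphabet (A/C/G/T by
default).  Beyond the unit-cost Levenshtein distance, the module exposes the
*first-step operation set* between two sequences: every one-base
substitution, insertion or deletion applicable to the source that moves it
one step closer to the target along some minimal edit path.  When several
minimal edit paths exist, the first steps of all of them are collected, each
unique operation once.  These sets are the "directions" in sequence space
that the tree-growth heuristic consumes.

Positions are 1-based.  An insertion at position p places the new base so
that it becomes the p-th character of the result.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import edlib
import numpy as np

from ._kernels import first_step_masks

DNA_ALPHABET = "ACGT"

SUBSTITUTION = "sub"
INSERTION = "ins"
DELETION = "del"

#: canonical ordering of operation kinds used wherever a deterministic
#: tie-break among operations is required
_KIND_RANK = {SUBSTITUTION: 0, DELETION: 1, INSERTION: 2}


class AlphabetError(ValueError):
    """A sequence contains characters outside the configured alphabet."""


class InvalidOperationError(ValueError):
    """An edit operation cannot be applied to the given sequence."""


class EnumerationLimitError(RuntimeError):
    """Minimal-script enumeration refused: distance exceeds the cap."""


@dataclass(frozen=True)
class EditOperation:
    """A single one-base edit at a 1-based position.

    ``base`` is the inserted/substituted character; deletions carry no base.
    Two operations are equal iff kind, position and base all match.
    """

    kind: str
    position: int
    base: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KIND_RANK:
            raise ValueError(f"unknown operation kind {self.kind!r}")
        if self.position < 1:
            raise ValueError("operation positions are 1-based")
        if self.kind == DELETION:
            if self.base is not None:
                raise ValueError("deletions carry no base")
        elif not (isinstance(self.base, str) and len(self.base) == 1):
            raise ValueError(f"{self.kind} requires a single base")

    @property
    def sort_key(self) -> tuple[int, int, str]:
        return (_KIND_RANK[self.kind], self.position, self.base or "")

    def __str__(self) -> str:
        if self.kind == DELETION:
            return f"del:{self.position}"
        return f"{self.kind}:{self.position}:{self.base}"

    @classmethod
    def parse(cls, text: str) -> "EditOperation":
        parts = text.strip().split(":")
        if len(parts) == 2 and parts[0] == DELETION:
            return cls(DELETION, int(parts[1]))
        if len(parts) == 3 and parts[0] in (SUBSTITUTION, INSERTION):
            return cls(parts[0], int(parts[1]), parts[2])
        raise ValueError(f"cannot parse edit operation {text!r}")


def validate_sequence(seq: str, alphabet: str = DNA_ALPHABET, name: str = "sequence") -> str:
    if not isinstance(seq, str):
        raise AlphabetError(f"{name} must be a string, got {type(seq).__name__}")
    bad = set(seq) - set(alphabet)
    if bad:
        raise AlphabetError(
            f"{name} contains characters outside alphabet {alphabet!r}: "
            + ", ".join(sorted(repr(c) for c in bad))
        )
    return seq


def edit_distance(a: str, b: str, alphabet: str = DNA_ALPHABET) -> int:
    """Unit-cost Levenshtein distance between two sequences (symmetric)."""
    validate_sequence(a, alphabet, "first sequence")
    validate_sequence(b, alphabet, "second sequence")
    if a == b:
        return 0
    if not a or not b:
        return len(a) or len(b)
    return edlib.align(a, b, task="distance")["editDistance"]


def apply_operation(s: str, op: EditOperation, alphabet: str = DNA_ALPHABET) -> str:
    """Apply a single one-base edit to ``s`` and return the new sequence."""
    validate_sequence(s, alphabet)
    p = op.position
    if op.kind == INSERTION:
        if not 1 <= p <= len(s) + 1:
            raise InvalidOperationError(
                f"insertion position {p} out of range for length {len(s)}"
            )
        if op.base not in alphabet:
            raise InvalidOperationError(f"base {op.base!r} outside alphabet")
        return s[: p - 1] + op.base + s[p - 1 :]
    if not 1 <= p <= len(s):
        raise InvalidOperationError(
            f"{op.kind} position {p} out of range for length {len(s)}"
        )
    if op.kind == DELETION:
        return s[: p - 1] + s[p:]
    if op.base not in alphabet:
        raise InvalidOperationError(f"base {op.base!r} outside alphabet")
    if s[p - 1] == op.base:
        raise InvalidOperationError(
            f"substitution at position {p} would not change the sequence"
        )
    return s[: p - 1] + op.base + s[p:]


@lru_cache(maxsize=8)
def _code_table(alphabet: str) -> np.ndarray:
    lut = np.full(256, -1, np.int64)
    for i, ch in enumerate(alphabet):
        lut[ord(ch)] = i
    return lut


def _encode(s: str, alphabet: str) -> np.ndarray:
    raw = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    return _code_table(alphabet)[raw]


def first_step_operations(
    a: str, b: str, alphabet: str = DNA_ALPHABET
) -> frozenset[EditOperation]:
    """All one-base operations on ``a`` that move one step toward ``b``.

    Returns exactly the set of valid operations ``op`` with
    ``edit_distance(apply_operation(a, op), b) == edit_distance(a, b) - 1``.
    Empty iff ``a == b``.
    """
    validate_sequence(a, alphabet, "first sequence")
    validate_sequence(b, alphabet, "second sequence")
    if a == b:
        return frozenset()
    del_mask, sub_mask, ins_mask = first_step_masks(
        _encode(a, alphabet), _encode(b, alphabet), len(alphabet)
    )
    ops: list[EditOperation] = []
    for p in np.flatnonzero(del_mask):
        ops.append(EditOperation(DELETION, int(p) + 1))
    for p, c in zip(*np.nonzero(sub_mask)):
        ops.append(EditOperation(SUBSTITUTION, int(p) + 1, alphabet[int(c)]))
    for p, c in zip(*np.nonzero(ins_mask)):
        ops.append(EditOperation(INSERTION, int(p) + 1, alphabet[int(c)]))
    return frozenset(ops)


@dataclass(frozen=True)
class DistanceRecord:
    """A distance together with the recorded first-step operation set."""

    distance: int
    first_step_ops: frozenset[EditOperation]


def distance_record(a: str, b: str, alphabet: str = DNA_ALPHABET) -> DistanceRecord:
    return DistanceRecord(
        edit_distance(a, b, alphabet), first_step_operations(a, b, alphabet)
    )


def enumerate_minimal_scripts(
    a: str, b: str, cap: int = 6, alphabet: str = DNA_ALPHABET
) -> list[tuple[EditOperation, ...]]:
    """Every distinct minimal-length operation sequence turning ``a`` into ``b``.

    Built by recursive expansion of the first-step sets, so each script's
    positions refer to the sequence current at the time the operation is
    applied.  Exponential in the distance; refuses when the distance exceeds
    ``cap``.
    """
    d = edit_distance(a, b, alphabet)
    if d > cap:
        raise EnumerationLimitError(
            f"distance {d} exceeds enumeration cap {cap}"
        )

    def expand(cur: str, remaining: int) -> list[tuple[EditOperation, ...]]:
        if remaining == 0:
            return [()]
        scripts = []
        for op in sorted(first_step_operations(cur, b, alphabet), key=lambda o: o.sort_key):
            nxt = apply_operation(cur, op, alphabet)
            scripts.extend((op,) + tail for tail in expand(nxt, remaining - 1))
        return scripts

    return expand(a, d)


def canonical_edit_path(
    a: str, b: str, alphabet: str = DNA_ALPHABET
) -> list[tuple[EditOperation, str]]:
    """One deterministic minimal edit path from ``a`` to ``b``.

    At every step the first-step operation with the smallest sort key is
    taken (substitution before deletion before insertion, then smallest
    position, then smallest base).  Returns ``[(op, sequence_after_op), ...]``
    of length ``edit_distance(a, b)``.
    """
    path = []
    cur = a
    while cur != b:
        op = min(first_step_operations(cur, b, alphabet), key=lambda o: o.sort_key)
        cur = apply_operation(cur, op, alphabet)
        path.append((op, cur))
    return path


def pairwise_distances(seqs: list[str], alphabet: str = DNA_ALPHABET) -> np.ndarray:
    """Symmetric matrix of pairwise edit distances (zero diagonal)."""
    if not seqs:
        raise ValueError("need at least one sequence")
    for s in seqs:
        validate_sequence(s, alphabet)
    n = len(seqs)
    mat = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = edit_distance(seqs[i], seqs[j], alphabet)
    return mat
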