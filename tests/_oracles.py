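"""Independent brute-force oracles used only by the tests.

Everything here is deliberately naive and self-contained (no imports from
the package under test beyond the EditOperation value type), so that
agreement with the package is evidence rather than tautology.
"""

from __future__ import annotations

import heapq

from lineagemst.edit_space import DELETION, INSERTION, SUBSTITUTION, EditOperation


def slow_levenshtein(a: str, b: str) -> int:
    """Textbook O(mn) dynamic program, pure Python."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def all_one_base_ops(seq: str, alphabet: str = "ACGT") -> list[EditOperation]:
    """Every valid one-base operation on ``seq``."""
    ops = []
    for p in range(1, len(seq) + 1):
        ops.append(EditOperation(DELETION, p))
        for c in alphabet:
            if c != seq[p - 1]:
                ops.append(EditOperation(SUBSTITUTION, p, c))
    for p in range(1, len(seq) + 2):
        for c in alphabet:
            ops.append(EditOperation(INSERTION, p, c))
    return ops


def apply_op(seq: str, op: EditOperation) -> str:
    p = op.position
    if op.kind == DELETION:
        return seq[: p - 1] + seq[p:]
    if op.kind == SUBSTITUTION:
        return seq[: p - 1] + op.base + seq[p:]
    return seq[: p - 1] + op.base + seq[p - 1 :]


def brute_first_steps(a: str, b: str, alphabet: str = "ACGT") -> frozenset[EditOperation]:
    """First-step set by trying every one-base operation."""
    d = slow_levenshtein(a, b)
    return frozenset(
        op
        for op in all_one_base_ops(a, alphabet)
        if slow_levenshtein(apply_op(a, op), b) == d - 1
    )


def count_minimal_scripts(a: str, b: str, alphabet: str = "ACGT") -> int:
    """Number of distinct minimal operation sequences from ``a`` to ``b``,
    counted by exhaustive depth-first search over shortest paths."""
    d = slow_levenshtein(a, b)

    def count(cur: str, remaining: int) -> int:
        if remaining == 0:
            return 1
        total = 0
        for op in all_one_base_ops(cur, alphabet):
            if slow_levenshtein(apply_op(cur, op), b) == remaining - 1:
                total += count(apply_op(cur, op), remaining - 1)
        return total

    return count(a, d)


# ------------------------------------------------------- optimal Steiner tree

def _universe(max_len: int, alphabet: str) -> list[str]:
    seqs = [""]
    frontier = [""]
    for _ in range(max_len):
        frontier = [s + c for s in frontier for c in alphabet]
        seqs.extend(frontier)
    return seqs


def _neighbors(seq: str, alphabet: str, max_len: int) -> set[str]:
    out = set()
    for op in all_one_base_ops(seq, alphabet):
        nxt = apply_op(seq, op)
        if len(nxt) <= max_len:
            out.add(nxt)
    return out


def steiner_optimum(root: str, observed: list[str], alphabet: str = "AC") -> int:
    """Minimum node count of any tree rooted at ``root`` that contains all
    observed sequences with unit-edit edges (Dreyfus-Wagner over the
    sequence universe up to one base longer than the longest input)."""
    terminals = sorted(set([root] + list(observed)))
    max_len = max(len(s) for s in terminals) + 1
    nodes = _universe(max_len, alphabet)
    index = {s: i for i, s in enumerate(nodes)}
    adj = [sorted(index[n] for n in _neighbors(s, alphabet, max_len)) for s in nodes]
    t_ids = [index[t] for t in terminals]
    k = len(t_ids)
    INF = float("inf")

    # dp[mask][v]: min edges of a tree containing terminal set `mask` + node v
    dp = [[INF] * len(nodes) for _ in range(1 << k)]
    for i, t in enumerate(t_ids):
        dp[1 << i][t] = 0
    for mask in range(1, 1 << k):
        row = dp[mask]
        sub = (mask - 1) & mask
        while sub:
            other = mask ^ sub
            if sub < other:  # each split once
                a_row, b_row = dp[sub], dp[other]
                for v in range(len(nodes)):
                    s = a_row[v] + b_row[v]
                    if s < row[v]:
                        row[v] = s
            sub = (sub - 1) & mask
        # Dijkstra relaxation with unit edges
        heap = [(c, v) for v, c in enumerate(row) if c < INF]
        heapq.heapify(heap)
        while heap:
            c, v = heapq.heappop(heap)
            if c > row[v]:
                continue
            for w in adj[v]:
                if c + 1 < row[w]:
                    row[w] = c + 1
                    heapq.heappush(heap, (c + 1, w))
    edges = min(dp[(1 << k) - 1])
    return int(edges) + 1
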