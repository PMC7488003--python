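"""Compiled dynamic-programming kernels for edit-distance backtraces.

The growth heuristic needs, for a pair of sequences (a, b), the full set of
one-base operations on ``a`` that reduce the Levenshtein distance to ``b`` by
exactly one.  Testing each candidate operation with a fresh distance
computation is O(L^3 * |alphabet|); the kernel below does it in
O(L^2 * |alphabet|) using prefix and suffix distance matrices:

  D[i, j] = d(a[:i], b[:j])          (prefix distances)
  S[i, j] = d(a[i:], b[j:])          (suffix distances)

For any single edit of a at position p, the edited sequence splits at the
edit point, and its distance to b is a min over the split column j of
(prefix distance + suffix distance).  Editing the prefix a[:p-1] by appending
a candidate base c costs one extra row update of the Wagner-Fischer
recurrence seeded from row D[p-1].
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _lev_matrix(a, b):
    m = a.size
    n = b.size
    D = np.empty((m + 1, n + 1), np.int32)
    for j in range(n + 1):
        D[0, j] = j
    for i in range(1, m + 1):
        D[i, 0] = i
        ai = a[i - 1]
        for j in range(1, n + 1):
            best = D[i - 1, j - 1] + (0 if ai == b[j - 1] else 1)
            v = D[i - 1, j] + 1
            if v < best:
                best = v
            v = D[i, j - 1] + 1
            if v < best:
                best = v
            D[i, j] = best
    return D


@njit(cache=True)
def levenshtein(a, b):
    return _lev_matrix(a, b)[a.size, b.size]


@njit(cache=True)
def first_step_masks(a, b, k):
    """Masks of one-base operations on ``a`` that step toward ``b``.

    Parameters are integer code arrays (values in 0..k-1) and the alphabet
    size k.  Returns ``(del_mask, sub_mask, ins_mask)``:

    - ``del_mask[p-1]``     : deleting position p (1-based) reduces d by 1
    - ``sub_mask[p-1, c]``  : substituting position p with code c reduces d
    - ``ins_mask[p-1, c]``  : inserting code c so it becomes the p-th
                              character (p in 1..m+1) reduces d
    """
    m = a.size
    n = b.size
    D = _lev_matrix(a, b)
    # suffix distances by the reversed recurrence
    S = np.empty((m + 1, n + 1), np.int32)
    for j in range(n + 1):
        S[m, j] = n - j
    for i in range(m - 1, -1, -1):
        S[i, n] = m - i
        ai = a[i]
        for j in range(n - 1, -1, -1):
            best = S[i + 1, j + 1] + (0 if ai == b[j] else 1)
            v = S[i + 1, j] + 1
            if v < best:
                best = v
            v = S[i, j + 1] + 1
            if v < best:
                best = v
            S[i, j] = best

    target = D[m, n] - 1
    sentinel = m + n + 2

    del_mask = np.zeros(m, np.bool_)
    for p in range(1, m + 1):
        # deleted sequence splits into a[:p-1] and a[p:]
        best = sentinel
        for j in range(n + 1):
            v = D[p - 1, j] + S[p, j]
            if v < best:
                best = v
        if best == target:
            del_mask[p - 1] = True

    sub_mask = np.zeros((m, k), np.bool_)
    ins_mask = np.zeros((m + 1, k), np.bool_)
    R = np.empty(n + 1, np.int32)
    for p in range(1, m + 2):
        for c in range(k):
            # R[j] = d(a[:p-1] + c, b[:j]); one Wagner-Fischer row from D[p-1]
            R[0] = p
            for j in range(1, n + 1):
                best = D[p - 1, j - 1] + (0 if c == b[j - 1] else 1)
                v = D[p - 1, j] + 1
                if v < best:
                    best = v
                v = R[j - 1] + 1
                if v < best:
                    best = v
                R[j] = best
            # insertion at position p: suffix is a[p-1:]
            best = sentinel
            for j in range(n + 1):
                v = R[j] + S[p - 1, j]
                if v < best:
                    best = v
            if best == target:
                ins_mask[p - 1, c] = True
            # substitution at position p: suffix is a[p:]
            if p <= m and c != a[p - 1]:
                best = sentinel
                for j in range(n + 1):
                    v = R[j] + S[p, j]
                    if v < best:
                        best = v
                if best == target:
                    sub_mask[p - 1, c] = True
    return del_mask, sub_mask, ins_mask
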