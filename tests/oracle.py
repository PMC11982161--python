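"""Naive brute-force recomputation of every recurrence measure.

Deliberately slow and literal: build the full matrix cell by cell with
Python loops and count.  Used as the independent reference the fast
implementations are checked against; keep it free of any package
internals beyond the raw series values.
"""

from __future__ import annotations

import numpy as np


def naive_matrix(a, b) -> list[list[int]]:
    """matrix[j][i] = 1 iff a[i] != b[j]."""
    return [[1 if a[i] != b[j] else 0 for i in range(len(a))] for j in range(len(b))]


def naive_rr_global(a, b) -> float:
    mat = naive_matrix(a, b)
    return sum(sum(row) for row in mat) / (len(a) * len(b))


def naive_rr_los(a, b) -> float:
    return sum(1 for x, y in zip(a, b) if x != y) / len(a)


def naive_rr_at_lag(a, b, k: int) -> float:
    """Rate on the diagonal pairing a[t] with b[t + k], per-lag normalised."""
    n = len(a)
    cells = [(t, t + k) for t in range(n) if 0 <= t + k < n]
    return sum(1 for t, u in cells if a[t] != b[u]) / len(cells)


def naive_profile(a, b, max_lag: int) -> dict[int, float]:
    return {k: naive_rr_at_lag(a, b, k) for k in range(-max_lag, max_lag + 1)}


def naive_q_dcrp(a, b, max_lag: int) -> float:
    prof = naive_profile(a, b, max_lag)
    left = np.mean([prof[k] for k in range(-max_lag, 0)])
    right = np.mean([prof[k] for k in range(1, max_lag + 1)])
    return abs(right - left) / (right + left) if (right + left) > 0 else 0.0


def _naive_runs(cells: list[int]) -> list[int]:
    runs, cur = [], 0
    for c in cells:
        if c:
            cur += 1
        else:
            if cur:
                runs.append(cur)
            cur = 0
    if cur:
        runs.append(cur)
    return runs


def naive_lines(mat: list[list[int]], direction: str, l_min: int) -> list[int]:
    nrow, ncol = len(mat), len(mat[0])
    out: list[int] = []
    if direction == "vertical":
        for i in range(ncol):
            out += [r for r in _naive_runs([mat[j][i] for j in range(nrow)]) if r >= l_min]
    else:
        for j in range(nrow):
            out += [r for r in _naive_runs(mat[j]) if r >= l_min]
    return sorted(out)


def naive_line_stats(a, b, l_min: int) -> dict[str, float]:
    mat = naive_matrix(a, b)
    total = sum(sum(row) for row in mat)
    ver = naive_lines(mat, "vertical", l_min)
    hor = naive_lines(mat, "horizontal", l_min)
    return {
        "lam_ver": sum(ver) / total if total else 0.0,
        "lam_hor": sum(hor) / total if total else 0.0,
        "tt_ver": float(np.mean(ver)) if ver else 0.0,
        "tt_hor": float(np.mean(hor)) if hor else 0.0,
    }


def naive_bh(p: list[float]) -> list[float]:
    """Step-up BH by the textbook definition (independent of statsmodels)."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj
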