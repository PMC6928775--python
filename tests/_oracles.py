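"""Independent brute-force oracles used by the test suite.

These never touch the package's dynamic-programming code path: the DTW
oracle explicitly enumerates every admissible warping path of a grid and
takes the minimum of the summed local costs.
"""

from __future__ import annotations

import numpy as np


def _local(x_col: np.ndarray, y_col: np.ndarray) -> float:
    return float(np.linalg.norm(x_col - y_col))


def enumerate_paths(N: int, M: int):
    """All monotone step-(1,0)/(0,1)/(1,1) paths from (1,1) to (N,M)."""
    stack = [[(1, 1)]]
    while stack:
        path = stack.pop()
        i, j = path[-1]
        if i == N and j == M:
            yield path
            continue
        if i < N and j < M:
            stack.append(path + [(i + 1, j + 1)])
        if j < M:
            stack.append(path + [(i, j + 1)])
        if i < N:
            stack.append(path + [(i + 1, j)])


def dtw_brute(x: np.ndarray, y: np.ndarray) -> float:
    """Minimal path cost by explicit enumeration; x, y are (d, L) arrays."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    N, M = x.shape[1], y.shape[1]
    best = np.inf
    for path in enumerate_paths(N, M):
        cost = sum(_local(x[:, i - 1], y[:, j - 1]) for i, j in path)
        if cost < best:
            best = cost
    return best


def dtw_brute_with_path(x: np.ndarray, y: np.ndarray):
    """(min cost, list of optimal paths) by explicit enumeration."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    N, M = x.shape[1], y.shape[1]
    best, arg = np.inf, []
    for path in enumerate_paths(N, M):
        cost = sum(_local(x[:, i - 1], y[:, j - 1]) for i, j in path)
        if cost < best - 1e-12:
            best, arg = cost, [path]
        elif abs(cost - best) <= 1e-12:
            arg.append(path)
    return best, arg


def best_match_brute(x: np.ndarray, y: np.ndarray, dtw_fn):
    """Min over all 1 <= a <= b <= M of dtw_fn(x, y[:, a-1:b]).

    Returns (a, b, score) with the lexicographically smallest (b, a) among
    ties, mirroring the end-index-first tie rule.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    M = y.shape[1]
    best = None
    for b in range(1, M + 1):
        for a in range(1, b + 1):
            score = dtw_fn(x, y[:, a - 1 : b])
            if best is None or score < best[2] - 1e-12:
                best = (a, b, score)
    return best


def check_warping_path(pairs, N: int, M: int, full: bool = True) -> None:
    """Assert the boundary / monotonicity / step-size conditions."""
    assert len(pairs) >= 1
    if full:
        assert pairs[0] == (1, 1), f"path starts at {pairs[0]}"
    assert pairs[-1] == (N, M), f"path ends at {pairs[-1]}"
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        step = (i2 - i1, j2 - j1)
        assert step in ((1, 0), (0, 1), (1, 1)), f"illegal step {step}"
    assert len(set(pairs)) == len(pairs), "pairs not pairwise distinct"
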