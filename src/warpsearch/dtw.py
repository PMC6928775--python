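"""Exact dynamic time warping.

Provides the accumulated cost matrix (full and subsequence initialization),
the DTW distance, and optimal warping path recovery, for univariate and
multivariate series.  Indexing convention: series samples and matrix
interior cells are 1-based; the matrix carries a 0th border row/column
(``D[i,0] = inf`` for i >= 1, ``D[0,0] = 0``; in subsequence mode the whole
0th row is 0 so that ``D[1,j]`` reduces to the local cost).

A module-level counter tallies how many interior cost-matrix cells have
been evaluated, so that callers can compare the work done by exact search
against the kernel approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import DimensionMismatchError, InfeasibleSearchError, InputError

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    njit = None

__all__ = [
    "TimeSeries",
    "CostMatrix",
    "WarpingPath",
    "local_cost",
    "accumulated_cost_matrix",
    "optimal_warping_path",
    "dtw",
    "cell_count",
    "reset_cell_counter",
]

# ---------------------------------------------------------------------------
# instrumentation

_cells_evaluated = 0


def cell_count() -> int:
    """Total interior cost-matrix cells evaluated since the last reset."""
    return _cells_evaluated


def reset_cell_counter() -> None:
    global _cells_evaluated
    _cells_evaluated = 0


def _tally(n: int) -> None:
    global _cells_evaluated
    _cells_evaluated += n


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class TimeSeries:
    """A d-channel real-valued series of length L, stored as a (d, L) array.

    Univariate series are the ``d == 1`` case of the same type; 1-D input is
    promoted to a single-row matrix.  ``time`` is an optional vector of
    time-steps carried through I/O but never used by DTW.
    """

    values: np.ndarray
    label: str | None = None
    time: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.values, dtype=float))
        if v.ndim != 2:
            raise InputError(f"series values must be 1-D or 2-D, got ndim={v.ndim}")
        if v.shape[1] < 1:
            raise InputError("series must contain at least one sample")
        if not np.all(np.isfinite(v)):
            raise InputError("series values must all be finite")
        object.__setattr__(self, "values", v)
        if self.time is not None:
            t = np.asarray(self.time, dtype=float)
            if t.shape != (v.shape[1],):
                raise InputError(
                    f"time vector has length {t.shape[0]}, expected {v.shape[1]}"
                )
            object.__setattr__(self, "time", t)

    @property
    def dim(self) -> int:
        return self.values.shape[0]

    @property
    def length(self) -> int:
        return self.values.shape[1]

    def sample(self, i: int) -> np.ndarray:
        """The i-th sample vector (1-based)."""
        if not 1 <= i <= self.length:
            raise InputError(f"sample index {i} outside [1, {self.length}]")
        return self.values[:, i - 1]

    def window(self, a: int, b: int) -> "TimeSeries":
        """The subsequence on the 1-based inclusive interval [a, b]."""
        if not 1 <= a <= b <= self.length:
            raise InputError(f"window [{a}, {b}] outside [1, {self.length}]")
        t = None if self.time is None else self.time[a - 1 : b]
        return TimeSeries(self.values[:, a - 1 : b], label=self.label, time=t)


def as_timeseries(obj) -> TimeSeries:
    """Coerce an array-like or TimeSeries into a TimeSeries."""
    if isinstance(obj, TimeSeries):
        return obj
    return TimeSeries(np.asarray(obj, dtype=float))


@dataclass(frozen=True)
class CostMatrix:
    """Accumulated cost grid with its extended border row/column.

    ``D`` has shape (N+1, M+1); interior cells are 1-based.  ``mode`` is
    ``"full"`` (global alignment) or ``"subsequence"`` (free start in the
    longer series).
    """

    D: np.ndarray
    mode: str
    cost_name: str = "euclidean"
    band: int | None = None

    @property
    def N(self) -> int:
        return self.D.shape[0] - 1

    @property
    def M(self) -> int:
        return self.D.shape[1] - 1


@dataclass(frozen=True)
class WarpingPath:
    """An alignment as an ordered sequence of 1-based (i, j) index pairs."""

    pairs: tuple[tuple[int, int], ...]
    total_cost: float


# ---------------------------------------------------------------------------
# operations


def local_cost(x, y) -> float:
    """Euclidean distance between two equal-dimension sample vectors."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if x.shape != y.shape:
        raise DimensionMismatchError(
            f"sample dimensions differ: {x.shape} vs {y.shape}"
        )
    return float(np.linalg.norm(x - y))


def _fill_impl(C, D, band, slope):
    # band < 0 means unconstrained; otherwise the Sakoe-Chiba test is
    # |i * M/N - j| <= band (slope-normalized for unequal lengths).
    N, M = C.shape
    cells = 0
    for i in range(1, N + 1):
        for j in range(1, M + 1):
            if band >= 0.0 and abs(i * slope - j) > band:
                D[i, j] = np.inf
                continue
            best = D[i - 1, j - 1]
            if D[i - 1, j] < best:
                best = D[i - 1, j]
            if D[i, j - 1] < best:
                best = D[i, j - 1]
            D[i, j] = best + C[i - 1, j - 1]
            cells += 1
    return cells


if njit is not None:
    _fill = njit(cache=True)(_fill_impl)
else:  # pragma: no cover - numba is part of the supported environment
    _fill = _fill_impl


def accumulated_cost_matrix(
    X, Y, mode: str = "full", band: int | None = None
) -> CostMatrix:
    """Fill the accumulated cost matrix between ``X`` and ``Y``.

    Parameters
    ----------
    X, Y : TimeSeries or array-like
        Series of equal channel count.
    mode : {"full", "subsequence"}
        Initialization variant: "full" computes the global alignment grid;
        "subsequence" frees the start of the alignment in ``Y`` by setting
        the first interior row to local costs.
    band : int, optional
        Sakoe-Chiba half-width; cells with ``|i*M/N - j| > band`` are
        excluded (set to inf).  In full mode an infeasible band (no
        admissible path) raises :class:`InfeasibleSearchError`.
    """
    X = as_timeseries(X)
    Y = as_timeseries(Y)
    if X.dim != Y.dim:
        raise DimensionMismatchError(f"channel counts differ: {X.dim} vs {Y.dim}")
    if mode not in ("full", "subsequence"):
        raise InputError(f"unknown mode {mode!r}")
    if band is not None and band < 1:
        raise InputError("band half-width must be >= 1")
    N, M = X.length, Y.length

    C = cdist(X.values.T, Y.values.T)
    D = np.empty((N + 1, M + 1))
    D[1:, 0] = np.inf
    if mode == "full":
        D[0, 1:] = np.inf
        D[0, 0] = 0.0
    else:
        D[0, :] = 0.0  # makes D[1, j] = c(x1, y_j) for every j

    slope = M / N
    cells = _fill(C, D, -1.0 if band is None else float(band), slope)
    _tally(int(cells))

    if mode == "full" and not np.isfinite(D[N, M]):
        raise InfeasibleSearchError(
            f"band half-width {band} admits no warping path for lengths "
            f"N={N}, M={M}"
        )
    return CostMatrix(D=D, mode=mode, cost_name="euclidean", band=band)


def optimal_warping_path(cm: CostMatrix, start_col: int | None = None) -> WarpingPath:
    """Backtrack the optimal warping path from a filled cost matrix.

    Ties between predecessors fire both index decrements, so an equal-cost
    diagonal predecessor always wins.  ``start_col`` defaults to M; in
    subsequence mode the recovered path is trimmed to begin at the last
    pair lying in the first reference row, which identifies the match
    start ``a*``.
    """
    D = cm.D
    N, M = cm.N, cm.M
    if N < 1 or M < 1:
        raise InputError("cost matrix has no interior cells")
    b = M if start_col is None else int(start_col)
    if not 1 <= b <= M:
        raise InputError(f"start column {b} outside [1, {M}]")

    i, j = N, b
    pairs = [(i, j)]
    while i != 1 or j != 1:
        if i == 1:
            j -= 1
        elif j == 1:
            i -= 1
        else:
            diag = D[i - 1, j - 1]
            up = D[i - 1, j]
            left = D[i, j - 1]
            d_star = min(diag, up, left)
            step_i = d_star == up or d_star == diag
            step_j = d_star == left or d_star == diag
            if step_i:
                i -= 1
            if step_j:
                j -= 1
        pairs.append((i, j))
    pairs.reverse()

    if cm.mode == "subsequence":
        last_row1 = max(k for k, (pi, _) in enumerate(pairs) if pi == 1)
        pairs = pairs[last_row1:]

    return WarpingPath(pairs=tuple(pairs), total_cost=float(D[N, b]))


def dtw(X, Y, band: int | None = None) -> float:
    """DTW distance: minimal total cost over all admissible warping paths."""
    cm = accumulated_cost_matrix(X, Y, mode="full", band=band)
    return float(cm.D[cm.N, cm.M])
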