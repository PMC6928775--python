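"""Exact DTW-based subsequence search.

Finds the best-matching subsequence of a reference pattern inside a longer
stream (free start/end), and iterates that search to enumerate multiple
repetitions below a score threshold.  All reported intervals are 1-based
and inclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dtw import CostMatrix, accumulated_cost_matrix, as_timeseries, optimal_warping_path
from .errors import InputError

__all__ = [
    "DeltaFunction",
    "MatchInterval",
    "SearchConfig",
    "delta_function",
    "best_match",
    "search_repetitions",
]


@dataclass(frozen=True)
class MatchInterval:
    """A candidate repetition: stream interval [a, b] with its score."""

    a: int
    b: int
    score: float
    rank: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.a <= self.b:
            raise InputError(f"invalid interval [{self.a}, {self.b}]")
        if self.score < 0:
            raise InputError("score must be nonnegative")

    @property
    def length(self) -> int:
        return self.b - self.a + 1


@dataclass(frozen=True)
class SearchConfig:
    """Settings for iterated repetition search.

    ``tau`` is the acceptance threshold on the match score.  The exclusion
    radius (half-width of the neighborhood masked around each accepted end
    index) defaults to ceil(N/2) when left unset, which prevents the same
    event from being reported twice.
    """

    tau: float
    exclusion_radius: int | None = None
    max_matches: int | None = None

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise InputError("tau must be nonnegative")
        if self.exclusion_radius is not None and self.exclusion_radius < 1:
            raise InputError("exclusion_radius must be >= 1")
        if self.max_matches is not None and self.max_matches < 1:
            raise InputError("max_matches must be >= 1")

    def resolved_radius(self, n_reference: int) -> int:
        if self.exclusion_radius is not None:
            return self.exclusion_radius
        return math.ceil(n_reference / 2)


@dataclass
class DeltaFunction:
    """Last row of the subsequence cost matrix with exclusion masking.

    ``values[b-1]`` is the minimal DTW of the reference against any
    subsequence of the stream ending at b; excluded entries are inf.
    """

    values: np.ndarray
    excluded: set[int] = field(default_factory=set)

    def __call__(self, b: int) -> float:
        return float(self.values[b - 1])

    @property
    def M(self) -> int:
        return self.values.shape[0]

    def exclude(self, b: int, radius: int) -> None:
        """Mask every end index within ``radius`` of ``b`` (inclusive)."""
        lo = max(1, b - radius)
        hi = min(self.M, b + radius)
        self.values[lo - 1 : hi] = np.inf
        self.excluded.update(range(lo, hi + 1))

    def argmin(self) -> tuple[int, float] | None:
        """Smallest end index attaining the minimum, or None if all inf."""
        idx = int(np.argmin(self.values))
        val = float(self.values[idx])
        if not np.isfinite(val):
            return None
        return idx + 1, val


def delta_function(X, Y, band: int | None = None) -> tuple[DeltaFunction, CostMatrix]:
    """Compute the subsequence cost matrix and its (mutable) last row."""
    X = as_timeseries(X)
    Y = as_timeseries(Y)
    if X.length > Y.length:
        raise InputError(
            f"reference (N={X.length}) longer than stream (M={Y.length})"
        )
    cm = accumulated_cost_matrix(X, Y, mode="subsequence", band=band)
    return DeltaFunction(values=cm.D[cm.N, 1:].copy()), cm


def _recover_start(cm: CostMatrix, b: int) -> int:
    path = optimal_warping_path(cm, start_col=b)
    return path.pairs[0][1]


def best_match(X, Y, band: int | None = None) -> MatchInterval:
    """Best-fitting subsequence of ``Y`` against reference ``X``.

    The end index is the smallest minimizer of the last matrix row
    (lexicographic tie-break); the start index is recovered by trimmed
    path backtracking from that column.
    """
    delta, cm = delta_function(X, Y, band=band)
    located = delta.argmin()
    if located is None:
        raise InputError("no finite match score (over-constrained band?)")
    b, score = located
    a = _recover_start(cm, b)
    return MatchInterval(a=a, b=b, score=score)


def search_repetitions(X, Y, cfg: SearchConfig, band: int | None = None) -> list[MatchInterval]:
    """Ranked repetitions of ``X`` within ``Y`` scoring below ``cfg.tau``.

    The cost matrix is built once; each accepted match masks an exclusion
    neighborhood around its end index before the next minimum is taken, so
    returned end indices are pairwise separated by more than the radius.
    Matches come back sorted by score, best first.
    """
    X = as_timeseries(X)
    delta, cm = delta_function(X, Y, band=band)
    radius = cfg.resolved_radius(X.length)

    matches: list[MatchInterval] = []
    while cfg.max_matches is None or len(matches) < cfg.max_matches:
        located = delta.argmin()
        if located is None:
            break
        b, score = located
        if score > cfg.tau:
            break
        a = _recover_start(cm, b)
        matches.append(MatchInterval(a=a, b=b, score=score))
        delta.exclude(b, radius)

    matches.sort(key=lambda m: (m.score, m.a))
    return [
        MatchInterval(a=m.a, b=m.b, score=m.score, rank=r + 1)
        for r, m in enumerate(matches)
    ]
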