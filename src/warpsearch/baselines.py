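"""Fixed-window comparison searchers.

Sliding-window Euclidean search (the classic fast-similarity-search
output) and sliding fixed-window DTW: both score every offset of an
N-sample window over the stream, so all reported intervals have exactly
the reference's length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dtw import as_timeseries, dtw
from .errors import InputError
from .subsequence import MatchInterval

__all__ = ["SlidingProfile", "sliding_profile", "top_k_windows"]


@dataclass(frozen=True)
class SlidingProfile:
    """Distance of the reference to every length-N window of the stream.

    ``scores[j]`` (0-based) is the distance between X and Y[j+1 : j+N]
    (1-based inclusive).
    """

    scores: np.ndarray
    metric: str
    window: int


def sliding_profile(X, Y, metric: str = "euclidean") -> SlidingProfile:
    """Exhaustive window scores under the chosen metric.

    The Euclidean profile is the plain L2 distance between the reference
    and each window (all channels and samples); the DTW profile runs a full
    DTW per window.
    """
    X = as_timeseries(X)
    Y = as_timeseries(Y)
    if X.dim != Y.dim:
        raise InputError(f"channel counts differ: {X.dim} vs {Y.dim}")
    if X.length > Y.length:
        raise InputError(f"reference (N={X.length}) longer than stream (M={Y.length})")
    if metric not in ("euclidean", "dtw"):
        raise InputError(f"unknown metric {metric!r}")
    N, M = X.length, Y.length
    n_win = M - N + 1

    if metric == "euclidean":
        # windows overlap heavily: use a strided view, no copies
        from numpy.lib.stride_tricks import sliding_window_view

        wins = sliding_window_view(Y.values, N, axis=1)  # (d, n_win, N)
        diff = wins - X.values[:, None, :]
        scores = np.sqrt(np.einsum("dwn,dwn->w", diff, diff))
    else:
        scores = np.array([dtw(X, Y.window(j + 1, j + N)) for j in range(n_win)])
    return SlidingProfile(scores=scores, metric=metric, window=N)


def top_k_windows(
    profile: SlidingProfile, k: int, exclusion_radius: int = 0
) -> list[MatchInterval]:
    """Greedy selection of the k lowest-scoring windows.

    A window is admissible if its start offset differs by more than
    ``exclusion_radius`` from every already-selected start.  Score ties
    resolve by position (stable sort).  If fewer than k admissible windows
    exist, the shorter list is returned with a warning.
    """
    if k < 1:
        raise InputError("k must be >= 1")
    if exclusion_radius < 0:
        raise InputError("exclusion_radius must be >= 0")
    order = np.argsort(profile.scores, kind="stable")
    chosen: list[int] = []
    for j in order:
        if all(abs(int(j) - c) > exclusion_radius for c in chosen):
            chosen.append(int(j))
        if len(chosen) == k:
            break
    if len(chosen) < k:
        warnings.warn(
            f"only {len(chosen)} admissible windows for k={k} at "
            f"exclusion_radius={exclusion_radius}"
        )
    return [
        MatchInterval(
            a=j + 1,
            b=j + profile.window,
            score=float(profile.scores[j]),
            rank=r + 1,
        )
        for r, j in enumerate(chosen)
    ]
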