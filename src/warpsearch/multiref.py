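"""Multi-reference kernel learning and stream identification.

Given a library of reference patterns sharing one basis set, learns one RBF
length-scale per reference by matching the kernel distance between
reference embeddings to the (rescaled) pairwise DTW, then scores every
reference against every stream through the budgeted endpoint search and
assigns streams to references.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .bosearch import BOConfig, bo_best_match
from .dtw import TimeSeries, as_timeseries, dtw
from .embedding import BasisSet, KernelParams, embed
from .errors import InputError

__all__ = [
    "ReferenceLibrary",
    "RefDistanceMatrix",
    "GammaVector",
    "ScoreMatrix",
    "IdentificationResult",
    "pairwise_dtw",
    "learn_gammas",
    "score_matrix",
    "rescale_count_matrix",
    "identify",
]


@dataclass(frozen=True)
class ReferenceLibrary:
    refs: tuple[TimeSeries, ...]

    def __post_init__(self) -> None:
        refs = tuple(as_timeseries(r) for r in self.refs)
        if len(refs) < 1:
            raise InputError("library must contain at least one reference")
        d = refs[0].dim
        if any(r.dim != d for r in refs):
            raise InputError("all references must share the same channel count")
        object.__setattr__(self, "refs", refs)

    @property
    def n(self) -> int:
        return len(self.refs)


@dataclass(frozen=True)
class RefDistanceMatrix:
    """Pairwise DTW between references, raw and rescaled to [0, 1].

    Rescaling divides by the largest off-diagonal value; the lower end of
    the min-max range is the diagonal zero (two identical references attain
    it), so a single off-diagonal value maps to 1.
    """

    raw: np.ndarray
    normalized: np.ndarray


@dataclass(frozen=True)
class GammaVector:
    """Learned per-reference length-scales with the achieved objective."""

    gammas: np.ndarray
    objective_value: float

    def __post_init__(self) -> None:
        g = np.asarray(self.gammas, dtype=float)
        if np.any(g <= 0):
            raise InputError("all gammas must be positive")
        object.__setattr__(self, "gammas", g)


@dataclass(frozen=True)
class ScoreMatrix:
    """n x m matrix of best-match kernel distances (already in [0, 1])."""

    K: np.ndarray
    rescaled: np.ndarray | None = None


@dataclass(frozen=True)
class IdentificationResult:
    """Per-stream reference assignment (0-based indices) with tie flags."""

    assignment: tuple[int, ...]
    ties: tuple[int, ...]


def pairwise_dtw(refs: ReferenceLibrary, band: int | None = None) -> RefDistanceMatrix:
    """Symmetric pairwise DTW matrix with [0, 1] rescaling."""
    if refs.n < 2:
        raise InputError("pairwise distances require at least 2 references")
    n = refs.n
    raw = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            raw[i, j] = raw[j, i] = dtw(refs.refs[i], refs.refs[j], band=band)
    hi = raw.max()
    if hi == 0:
        raise InputError(
            "all references are DTW-identical; the rescaled matrix is "
            "degenerate - skip normalization or diversify the library"
        )
    return RefDistanceMatrix(raw=raw, normalized=raw / hi)


def _pair_error(gamma: float, gaps: np.ndarray, targets: np.ndarray) -> float:
    k = np.exp(-(gaps**2) / (2.0 * gamma * gamma))
    return float(np.mean(np.abs((1.0 - k) - targets)))


def _fit_scalar_gamma(
    gaps: np.ndarray, targets: np.ndarray, log_bounds: tuple[float, float]
) -> float:
    lo, hi = log_bounds
    grid = np.logspace(lo, hi, 400)
    errs = [_pair_error(g, gaps, targets) for g in grid]
    k = int(np.argmin(errs))
    g_lo = grid[max(0, k - 1)]
    g_hi = grid[min(len(grid) - 1, k + 1)]
    res = minimize_scalar(
        lambda lg: _pair_error(10.0**lg, gaps, targets),
        bounds=(math.log10(g_lo), math.log10(g_hi)),
        method="bounded",
    )
    best = 10.0**res.x
    if _pair_error(best, gaps, targets) <= errs[k]:
        return float(best)
    return float(grid[k])


def _upper_triangle_objective(
    gammas: np.ndarray, gap_matrix: np.ndarray, targets: np.ndarray
) -> float:
    """Mean absolute error over pairs i < j, the pair (i, j) using gamma_i."""
    n = gap_matrix.shape[0]
    total = 0.0
    count = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            k = math.exp(-(gap_matrix[i, j] ** 2) / (2.0 * gammas[i] ** 2))
            total += abs((1.0 - k) - targets[i, j])
            count += 1
    return total / count


def learn_gammas(
    refs: ReferenceLibrary,
    S: BasisSet,
    targets: np.ndarray | None = None,
    symmetric: bool = False,
    log_bounds: tuple[float, float] = (-6.0, 6.0),
) -> GammaVector:
    """Per-reference length-scales matching kernel distance to rescaled DTW.

    ``targets`` defaults to the rescaled pairwise DTW matrix of the
    library.  Under the default (asymmetric) reading, the pair (i, j) uses
    the row reference's gamma_i, and the per-reference problems decouple:
    each gamma_i is fitted against all partners j != i by bounded scalar
    search on log gamma.  ``symmetric=True`` instead averages the kernels
    with gamma_i and gamma_j per pair and refines jointly.  The reported
    objective is the upper-triangle mean absolute error.
    """
    if refs.n < 2:
        raise InputError("length-scale learning requires at least 2 references")
    n = refs.n
    phis = np.array([embed(r, S).vector for r in refs.refs])
    gap = np.linalg.norm(phis[:, None, :] - phis[None, :, :], axis=2)
    iu = np.triu_indices(n, k=1)
    if np.all(gap[iu] == 0):
        raise InputError("all reference embeddings are identical; cannot fit gamma")
    if targets is None:
        targets = pairwise_dtw(refs).normalized
    targets = np.asarray(targets, dtype=float)
    if targets.shape != (n, n):
        raise InputError(f"targets must have shape ({n}, {n})")

    gammas = np.empty(n)
    for i in range(n):
        others = [j for j in range(n) if j != i and gap[i, j] > 0]
        if not others:
            gammas[i] = 10.0 ** log_bounds[1]
            continue
        gammas[i] = _fit_scalar_gamma(
            gap[i, others], targets[i, others], log_bounds
        )

    if symmetric:

        def obj(log_g: np.ndarray) -> float:
            g = 10.0**log_g
            total = 0.0
            for i in range(n - 1):
                for j in range(i + 1, n):
                    ki = math.exp(-(gap[i, j] ** 2) / (2.0 * g[i] ** 2))
                    kj = math.exp(-(gap[i, j] ** 2) / (2.0 * g[j] ** 2))
                    total += abs((1.0 - 0.5 * (ki + kj)) - targets[i, j])
            return total / (n * (n - 1) / 2)

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = minimize(
                obj,
                np.log10(gammas),
                method="Nelder-Mead",
                options={"maxiter": 400 * n, "xatol": 1e-6, "fatol": 1e-10},
            )
        gammas = 10.0**res.x

    value = _upper_triangle_objective(gammas, gap, targets)
    return GammaVector(gammas=gammas, objective_value=value)


def _spawned_seed(seed: int, i: int, l: int) -> int:
    return int(np.random.SeedSequence([seed, i, l]).generate_state(1)[0])


def score_matrix(
    refs: ReferenceLibrary,
    streams: list[TimeSeries],
    S: BasisSet,
    g: GammaVector,
    cfg: BOConfig,
) -> ScoreMatrix:
    """Best-match kernel distance of every reference in every stream.

    Entry (i, l) runs the budgeted endpoint search of reference i inside
    stream l with the learned gamma_i; values are kernel distances in
    [0, 1] and need no further rescaling.  The search seed is derived
    deterministically from (cfg.seed, i, l).
    """
    if len(g.gammas) != refs.n:
        raise InputError("gamma vector length must match the library size")
    streams = [as_timeseries(y) for y in streams]
    K = np.empty((refs.n, len(streams)))
    for i, ref in enumerate(refs.refs):
        p = KernelParams(float(g.gammas[i]))
        for l, y in enumerate(streams):
            cfg_il = replace(cfg, seed=_spawned_seed(cfg.seed, i, l))
            K[i, l] = bo_best_match(ref, y, S, p, cfg_il).score
    return ScoreMatrix(K=K)


def rescale_count_matrix(counts: np.ndarray) -> np.ndarray:
    """Row-wise min-max rescaling to [0, 1] (confidence display of counts).

    A zero-range row cannot be rescaled; it becomes all zeros and raises a
    warning.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise InputError("counts must be a 2-D matrix")
    if np.any(counts < 0):
        raise InputError("counts must be nonnegative")
    out = np.zeros_like(counts)
    for i, row in enumerate(counts):
        rng = row.max() - row.min()
        if rng == 0:
            warnings.warn(f"row {i} has zero range; rescaled to zeros")
            continue
        out[i] = (row - row.min()) / rng
    return out


def identify(scores, mode: str = "distance") -> IdentificationResult:
    """Assign each stream (column) to a reference (row).

    ``mode="distance"`` takes the per-column argmin of kernel distances;
    ``mode="counts"`` the argmax of repetition counts.  Ties go to the
    lowest reference index and the column is flagged.
    """
    if isinstance(scores, ScoreMatrix):
        mat = scores.K
    else:
        mat = np.asarray(scores, dtype=float)
    if mat.ndim != 2:
        raise InputError("score matrix must be 2-D")
    if mode not in ("distance", "counts"):
        raise InputError(f"unknown mode {mode!r}")

    assignment = []
    ties = []
    for col in range(mat.shape[1]):
        vals = mat[:, col]
        best = vals.min() if mode == "distance" else vals.max()
        winners = np.flatnonzero(vals == best)
        assignment.append(int(winners[0]))
        if len(winners) > 1:
            ties.append(col)
    return IdentificationResult(assignment=tuple(assignment), ties=tuple(ties))
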