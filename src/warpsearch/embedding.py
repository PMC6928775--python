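"""Random-basis feature embedding and RBF kernel distance.

A set of R short random series maps any series (whatever its length) to a
fixed-length vector of DTW values; the RBF kernel on those vectors yields a
distance surrogate for DTW.  Also hosts the complexity-budget algebra that
ties the basis cardinality and the endpoint-search evaluation budget to the
target fraction of exact-DTW cost.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace

import numpy as np

from .dtw import TimeSeries, as_timeseries, dtw
from .errors import BasisMismatchError, DimensionMismatchError, InfeasibleSearchError, InputError

__all__ = [
    "BasisSet",
    "Embedding",
    "KernelParams",
    "ComplexityPlan",
    "generate_basis",
    "embed",
    "rbf_kernel",
    "kernel_distance",
    "max_basis_cardinality",
    "scaled_basis_cardinality",
    "bo_budget",
    "efficiency_satisfied",
    "save_basis",
    "load_basis",
]


@dataclass(frozen=True)
class BasisSet:
    """R short random series spanning the embedding space.

    Values are i.i.d. normal with mean 0 and variance ``sigma2``; lengths
    are uniform on {lmin, ..., lmax}.  ``basis_id`` fingerprints the
    generating parameters so embeddings from different basis sets cannot be
    mixed.
    """

    series: tuple[TimeSeries, ...]
    lmin: int
    lmax: int
    sigma2: float
    seed: int

    def __post_init__(self) -> None:
        if len(self.series) < 1:
            raise InputError("basis set must contain at least one series")
        for s in self.series:
            if not self.lmin <= s.length <= self.lmax:
                raise InputError(
                    f"basis series length {s.length} outside [{self.lmin}, {self.lmax}]"
                )

    @property
    def R(self) -> int:
        return len(self.series)

    @property
    def dim(self) -> int:
        return self.series[0].dim

    @property
    def basis_id(self) -> str:
        return (
            f"basis(R={self.R},lmin={self.lmin},lmax={self.lmax},"
            f"sigma2={self.sigma2},seed={self.seed},d={self.dim})"
        )


@dataclass(frozen=True)
class Embedding:
    """Fixed-length vector of DTW values against a basis set."""

    vector: np.ndarray
    basis_id: str

    def __post_init__(self) -> None:
        v = np.asarray(self.vector, dtype=float)
        object.__setattr__(self, "vector", v)

    @property
    def R(self) -> int:
        return self.vector.shape[0]


@dataclass(frozen=True)
class KernelParams:
    """RBF length-scale."""

    gamma: float

    def __post_init__(self) -> None:
        if not self.gamma > 0:
            raise InputError("gamma must be positive")


def generate_basis(
    R: int,
    lmin: int,
    lmax: int,
    d: int = 1,
    sigma2: float = 1.0,
    seed: int = 0,
) -> BasisSet:
    """Draw R basis series with uniform lengths and normal(0, sigma2) values."""
    if R < 1:
        raise InputError("R must be >= 1")
    if not 1 <= lmin <= lmax:
        raise InputError(f"invalid length bounds [{lmin}, {lmax}]")
    if d < 1:
        raise InputError("d must be >= 1")
    if sigma2 <= 0:
        raise InputError("sigma2 must be positive")
    rng = np.random.default_rng(seed)
    sd = math.sqrt(sigma2)
    series = []
    for i in range(R):
        L = int(rng.integers(lmin, lmax + 1))
        series.append(TimeSeries(rng.normal(0.0, sd, size=(d, L)), label=f"s{i + 1}"))
    return BasisSet(series=tuple(series), lmin=lmin, lmax=lmax, sigma2=sigma2, seed=seed)


def embed(X, S: BasisSet) -> Embedding:
    """DTW of ``X`` against every basis series, as an R-vector.

    Components are mutually independent, so any evaluation order (or a
    parallel map) produces the identical vector.
    """
    X = as_timeseries(X)
    if X.dim != S.dim:
        raise DimensionMismatchError(
            f"series has {X.dim} channels, basis has {S.dim}"
        )
    vec = np.array([dtw(X, s) for s in S.series])
    return Embedding(vector=vec, basis_id=S.basis_id)


def rbf_kernel(u: np.ndarray, v: np.ndarray, gamma: float) -> float:
    """exp(-||u - v||^2 / (2 gamma^2))."""
    gap2 = float(np.sum((np.asarray(u, float) - np.asarray(v, float)) ** 2))
    return math.exp(-gap2 / (2.0 * gamma * gamma))


def kernel_distance(u: Embedding, v: Embedding, p: KernelParams) -> float:
    """1 - RBF kernel of two embeddings; a pseudo-metric in [0, 1]."""
    if u.basis_id != v.basis_id:
        raise BasisMismatchError(
            f"embeddings use different basis sets: {u.basis_id} vs {v.basis_id}"
        )
    if u.R != v.R:
        raise BasisMismatchError("embedding lengths differ")
    return 1.0 - rbf_kernel(u.vector, v.vector, p.gamma)


# ---------------------------------------------------------------------------
# complexity-budget algebra


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def max_basis_cardinality(
    rho: float,
    alpha: float,
    N: int | None = None,
    M: int | None = None,
    regime: str = "exact",
    rounding: str = "nearest",
) -> int:
    """Largest basis cardinality meeting the target cost fraction ``rho``.

    ``regime="exact"`` evaluates R = rho*M / (alpha*(N+M));
    ``"similar_lengths"`` its N ~= M limit rho/(2*alpha); ``"subsequence"``
    its N << M limit rho/alpha.  Rounds half-up by default (the floor
    variant is available via ``rounding="floor"``); the result is clamped
    to at least 1.
    """
    if not 0 < rho < 1:
        raise InputError("rho must be in (0, 1)")
    if not 0 < alpha < 1:
        raise InputError("alpha must be in (0, 1)")
    if regime == "exact":
        if N is None or M is None:
            raise InputError("regime 'exact' requires N and M")
        if N < 1 or M < 1:
            raise InputError("N and M must be >= 1")
        r = rho * M / (alpha * (N + M))
    elif regime == "similar_lengths":
        r = rho / (2.0 * alpha)
    elif regime == "subsequence":
        r = rho / alpha
    else:
        raise InputError(f"unknown regime {regime!r}")
    if rounding == "nearest":
        out = _round_half_up(r)
    elif rounding == "floor":
        out = math.floor(r)
    else:
        raise InputError(f"unknown rounding {rounding!r}")
    return max(1, out)


def scaled_basis_cardinality(R: int, npp: int) -> int:
    """Basis cardinality scaled by the parallel-process count: npp * floor(R)."""
    if R < 1 or npp < 1:
        raise InputError("R and npp must be >= 1")
    return npp * math.floor(R)


def bo_budget(
    rho_bar: float, M: int, alpha: float, R: int, N: int, beta_plus: float
) -> int:
    """Endpoint-search evaluation budget eta = (rho_bar*M - alpha*R*N) / (alpha*R*N*beta_plus).

    Floored to an integer; raises if the configured cost fraction cannot
    support even one evaluation (the efficiency relation is violated).
    """
    if not 0 < rho_bar < 1:
        raise InputError("rho_bar must be in (0, 1)")
    if not 0 < alpha < 1:
        raise InputError("alpha must be in (0, 1)")
    if M < 1 or N < 1 or R < 1:
        raise InputError("M, N, R must be >= 1")
    if beta_plus < 1:
        raise InputError("beta_plus must be >= 1")
    base = alpha * R * N
    num = rho_bar * M - base
    eta = math.floor(num / (base * beta_plus)) if num > 0 else 0
    if eta < 1:
        raise InfeasibleSearchError(
            "evaluation budget infeasible: rho_bar*M must exceed "
            f"alpha*R*N*(1 + beta_plus) for one evaluation "
            f"(rho_bar*M={rho_bar * M:g}, alpha*R*N={base:g})"
        )
    return eta


def efficiency_satisfied(
    alpha: float, R: int, N: int, M: int, beta_plus: float, eta: int
) -> bool:
    """Whether the kernel pipeline is cheaper than one exact N-by-M matrix."""
    return alpha * R * N * N + alpha * R * N * beta_plus * N * eta < M * N


@dataclass(frozen=True)
class ComplexityPlan:
    """Budget parameters and their derived quantities.

    ``alpha`` sets the basis length cap (lmax = alpha*N); ``rho`` the
    target cost fraction for one embedding; ``rho_bar`` the target fraction
    for the whole endpoint search; ``beta_minus``/``beta_plus`` the match
    length bounds relative to N; ``npp`` the parallel-process count.
    """

    alpha: float
    rho: float
    rho_bar: float
    beta_plus: float = 1.5
    beta_minus: float = 0.8
    npp: int = 1
    R: int | None = None
    R_bar: int | None = None
    eta: int | None = None

    def __post_init__(self) -> None:
        for name in ("alpha", "rho", "rho_bar"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise InputError(f"{name} must be in (0, 1), got {v}")
        if not 1 <= self.beta_plus < 2:
            raise InputError("beta_plus must be in [1, 2)")
        if not 0 < self.beta_minus <= 1:
            raise InputError("beta_minus must be in (0, 1]")
        if self.beta_minus > self.beta_plus:
            raise InputError("beta_minus must not exceed beta_plus")
        if self.npp < 1:
            raise InputError("npp must be >= 1")

    def derive(self, N: int, M: int, regime: str = "exact") -> "ComplexityPlan":
        """Fill in R, R_bar and eta for a concrete problem size."""
        R = max_basis_cardinality(self.rho, self.alpha, N=N, M=M, regime=regime)
        R_bar = scaled_basis_cardinality(R, self.npp)
        eta = bo_budget(self.rho_bar, M, self.alpha, R, N, self.beta_plus)
        return replace(self, R=R, R_bar=R_bar, eta=eta)

    def basis_length_bounds(self, N: int) -> tuple[int, int]:
        """(lmin, lmax) with lmax = alpha*N rounded, lmin = half of that."""
        lmax = max(1, _round_half_up(self.alpha * N))
        lmin = max(1, lmax // 2)
        return lmin, lmax


# ---------------------------------------------------------------------------
# persistence


def save_basis(S: BasisSet, path) -> None:
    """Serialize a basis set (parameters + values) to a JSON text file."""
    payload = {
        "lmin": S.lmin,
        "lmax": S.lmax,
        "sigma2": S.sigma2,
        "seed": S.seed,
        "series": [s.values.tolist() for s in S.series],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_basis(path) -> BasisSet:
    with open(path) as fh:
        payload = json.load(fh)
    series = tuple(
        TimeSeries(np.asarray(v, dtype=float), label=f"s{i + 1}")
        for i, v in enumerate(payload["series"])
    )
    return BasisSet(
        series=series,
        lmin=int(payload["lmin"]),
        lmax=int(payload["lmax"]),
        sigma2=float(payload["sigma2"]),
        seed=int(payload["seed"]),
    )
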