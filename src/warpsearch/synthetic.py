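"""Synthetic accelerometer-like fixtures with planted, time-warped patterns.

Generates smooth pseudo-periodic reference patterns and long streams that
contain noisy, time-stretched copies of a reference at known locations, so
every search module can be validated against exact ground truth without
external data.  Also implements the delimited stream dialect (one row per
sample: time-step followed by the channel values) and the hit/overlap
scoring used against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dtw import TimeSeries, as_timeseries
from .errors import InputError
from .subsequence import MatchInterval

__all__ = [
    "PlantSpec",
    "GroundTruth",
    "make_reference",
    "warp_series",
    "plant_stream",
    "default_positions",
    "read_stream",
    "write_stream",
    "overlap_fraction",
    "hit_rate",
    "match_hits",
]


@dataclass(frozen=True)
class PlantSpec:
    """How copies of the reference are planted into a stream.

    ``positions`` are intended 1-based start indices.  Each copy is
    time-stretched by a factor drawn uniformly from ``warp_factor_range``
    and perturbed by additive Gaussian noise of ``noise_sd``.  Non-pattern
    regions follow the ``background`` model ("gaussian_noise" or
    "autoregressive"), scaled to ``background_scale`` times the
    reference's per-channel standard deviation.
    """

    positions: tuple[int, ...]
    warp_factor_range: tuple[float, float] = (0.8, 1.5)
    noise_sd: float = 0.0
    background: str = "gaussian_noise"
    background_scale: float = 1.0
    ar_coeff: float = 0.9
    warp_mode: str = "uniform"

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", tuple(int(p) for p in self.positions))
        lo, hi = self.warp_factor_range
        if not 0 < lo <= hi:
            raise InputError("warp_factor_range must satisfy 0 < lo <= hi")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be nonnegative")
        if self.background not in ("gaussian_noise", "autoregressive"):
            raise InputError(f"unknown background {self.background!r}")
        if self.warp_mode not in ("uniform", "monotone"):
            raise InputError(f"unknown warp_mode {self.warp_mode!r}")


@dataclass(frozen=True)
class GroundTruth:
    """Planted intervals (1-based inclusive) with their copy ids."""

    intervals: tuple[tuple[int, int, int], ...]
    reference_id: str | None = None


def make_reference(
    length: int,
    dim: int = 1,
    seed: int = 0,
    smoothness: float = 1.0,
    n_harmonics: int = 3,
) -> TimeSeries:
    """A smooth pseudo-periodic pattern: sum of low-frequency sinusoids.

    Each channel sums ``n_harmonics`` sinusoids with random amplitude,
    phase and 1-3 cycles over the pattern (divided by ``smoothness``, so
    larger values give slower patterns).  ``smoothness=0`` degenerates to
    white noise.  Channels are standardized to zero mean, unit variance.
    """
    if length < 2:
        raise InputError("length must be >= 2")
    if dim < 1:
        raise InputError("dim must be >= 1")
    rng = np.random.default_rng(seed)
    t = np.arange(length) / length
    values = np.empty((dim, length))
    for ch in range(dim):
        if smoothness <= 0:
            values[ch] = rng.normal(size=length)
        else:
            x = np.zeros(length)
            for _ in range(n_harmonics):
                cycles = rng.uniform(1.0, 3.0) / smoothness
                amp = rng.uniform(0.5, 1.5)
                phase = rng.uniform(0.0, 2.0 * math.pi)
                x += amp * np.sin(2.0 * math.pi * cycles * t + phase)
            values[ch] = x
        sd = values[ch].std()
        if sd > 0:
            values[ch] = (values[ch] - values[ch].mean()) / sd
    return TimeSeries(values, label=f"ref-{seed}")


def warp_series(X: TimeSeries, factor: float) -> TimeSeries:
    """Uniformly resample ``X`` in time by ``factor`` (linear interpolation)."""
    X = as_timeseries(X)
    if factor <= 0:
        raise InputError("warp factor must be positive")
    new_len = max(2, int(round(factor * X.length)))
    src = np.linspace(0.0, X.length - 1, new_len)
    grid = np.arange(X.length, dtype=float)
    values = np.vstack([np.interp(src, grid, row) for row in X.values])
    return TimeSeries(values, label=X.label)


def _monotone_warp(X: TimeSeries, factor: float, rng: np.random.Generator) -> TimeSeries:
    """Random monotone time map with overall stretch ``factor``."""
    X = as_timeseries(X)
    new_len = max(2, int(round(factor * X.length)))
    jumps = rng.uniform(0.25, 1.75, size=new_len)
    src = np.concatenate([[0.0], np.cumsum(jumps)])[:-1]
    src = src / src[-1] * (X.length - 1)
    grid = np.arange(X.length, dtype=float)
    values = np.vstack([np.interp(src, grid, row) for row in X.values])
    return TimeSeries(values, label=X.label)


def default_positions(
    M: int, n_copies: int, max_copy_len: int, margin: int = 10
) -> tuple[int, ...]:
    """Evenly spaced start positions leaving room for the longest copy."""
    if n_copies < 1:
        raise InputError("n_copies must be >= 1")
    slot = (M - 2 * margin) // n_copies
    if slot < max_copy_len:
        raise InputError(
            f"cannot fit {n_copies} copies of up to {max_copy_len} samples in M={M}"
        )
    return tuple(margin + 1 + k * slot for k in range(n_copies))


def plant_stream(
    X, M: int, spec: PlantSpec, seed: int = 0
) -> tuple[TimeSeries, GroundTruth]:
    """A length-M stream with warped noisy copies of ``X`` at known spots.

    Returns the stream and the exact planted intervals.  Raises if the
    warped copies would overlap each other or run off the stream end.
    """
    X = as_timeseries(X)
    rng = np.random.default_rng(seed)
    d = X.dim
    ref_sd = X.values.std(axis=1)
    ref_sd[ref_sd == 0] = 1.0

    scale = spec.background_scale * ref_sd[:, None]
    if spec.background == "gaussian_noise":
        stream = rng.normal(size=(d, M)) * scale
    else:
        innov = rng.normal(size=(d, M))
        stream = np.empty((d, M))
        stream[:, 0] = innov[:, 0]
        for t in range(1, M):
            stream[:, t] = spec.ar_coeff * stream[:, t - 1] + innov[:, t]
        stream *= scale * math.sqrt(1.0 - spec.ar_coeff**2)

    lo, hi = spec.warp_factor_range
    intervals: list[tuple[int, int, int]] = []
    last_end = 0
    for copy_id, pos in enumerate(sorted(spec.positions), start=1):
        factor = rng.uniform(lo, hi)
        if spec.warp_mode == "uniform":
            copy = warp_series(X, factor)
        else:
            copy = _monotone_warp(X, factor, rng)
        a, b = pos, pos + copy.length - 1
        if a <= last_end:
            raise InputError(
                f"planted copy {copy_id} at [{a}, {b}] overlaps the previous copy"
            )
        if b > M:
            raise InputError(f"planted copy {copy_id} at [{a}, {b}] exceeds M={M}")
        noisy = copy.values + rng.normal(size=copy.values.shape) * spec.noise_sd
        stream[:, a - 1 : b] = noisy
        intervals.append((a, b, copy_id))
        last_end = b

    truth = GroundTruth(intervals=tuple(intervals), reference_id=X.label)
    return TimeSeries(stream, label="stream"), truth


# ---------------------------------------------------------------------------
# stream I/O (delimited dialect: time-step, then one column per channel)


def write_stream(series: TimeSeries, path, delimiter: str = ",") -> None:
    """Write one row per sample: time-step then the d channel values."""
    series = as_timeseries(series)
    t = series.time if series.time is not None else np.arange(series.length, dtype=float)
    table = np.column_stack([t, series.values.T])
    with open(path, "w") as fh:
        for row in table:
            fh.write(delimiter.join(repr(float(v)) for v in row) + "\n")


def read_stream(path, label: str | None = None) -> TimeSeries:
    """Parse a delimited stream file; raises with the offending line number."""
    rows: list[list[float]] = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(",") if "," in line else line.split()
            try:
                vals = [float(p) for p in parts]
            except ValueError as exc:
                raise InputError(f"{path}: line {lineno}: non-numeric cell ({exc})")
            if len(vals) < 2:
                raise InputError(
                    f"{path}: line {lineno}: expected time-step plus >= 1 channel"
                )
            if width is None:
                width = len(vals)
            elif len(vals) != width:
                raise InputError(
                    f"{path}: line {lineno}: ragged row ({len(vals)} cells, "
                    f"expected {width})"
                )
            rows.append(vals)
    if not rows:
        raise InputError(f"{path}: empty stream file")
    table = np.asarray(rows)
    return TimeSeries(table[:, 1:].T, label=label, time=table[:, 0])


# ---------------------------------------------------------------------------
# ground-truth scoring


def overlap_fraction(first: tuple[int, int], second: tuple[int, int]) -> float:
    """Overlap of two 1-based inclusive intervals, relative to the shorter."""
    a1, b1 = first
    a2, b2 = second
    inter = min(b1, b2) - max(a1, a2) + 1
    if inter <= 0:
        return 0.0
    shorter = min(b1 - a1 + 1, b2 - a2 + 1)
    return inter / shorter


def match_hits(
    matches: Sequence[MatchInterval],
    truth: GroundTruth,
    min_overlap: float = 0.5,
) -> list[bool]:
    """Per-match flags: does the match cover some planted interval enough."""
    return [
        any(
            overlap_fraction((m.a, m.b), (a, b)) >= min_overlap
            for a, b, _ in truth.intervals
        )
        for m in matches
    ]


def hit_rate(
    matches: Sequence[MatchInterval],
    truth: GroundTruth,
    min_overlap: float = 0.5,
) -> float:
    """Fraction of planted intervals recovered by at least one match."""
    if not truth.intervals:
        raise InputError("ground truth contains no intervals")
    found = 0
    for a, b, _ in truth.intervals:
        if any(
            overlap_fraction((m.a, m.b), (a, b)) >= min_overlap for m in matches
        ):
            found += 1
    return found / len(truth.intervals)
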