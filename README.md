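# warpsearch

Subsequence search in long (possibly multivariate) sensor streams with
Dynamic Time Warping, plus a fast kernel-based approximation:

- **Exact DTW** — accumulated cost matrix (full and subsequence
  initialization), optimal warping path recovery, optional Sakoe–Chiba
  band, univariate and multivariate series.
- **Exact subsequence search** — best match endpoints with free start/end
  in the stream, and iterated multi-repetition search with exclusion
  neighborhoods and a score threshold.
- **Random-basis kernel approximation** — every series is embedded as its
  DTW to a set of short random basis series; an RBF kernel on those
  fixed-length vectors yields a distance surrogate, and closed-form
  complexity relations derive the basis cardinality `R` and the endpoint
  search budget `eta` from a target fraction of the exact DTW cost.
- **Budgeted endpoint search** — Gaussian-process Bayesian optimization
  (expected improvement) over integer `(start, length)` boxes, with a
  random-search fallback and a hard evaluation budget.
- **Multi-reference identification** — per-reference RBF length-scales
  learned against min-max rescaled pairwise DTW, reference-by-stream score
  matrices, and stream-to-reference assignment.
- **Baselines** — sliding-window Euclidean and fixed-window DTW profiles.
- **Synthetic data** — generators for smooth reference patterns and
  streams with planted, time-warped, noisy repetitions at known locations
  (exact ground truth), plus readers/writers for the delimited
  `time-step, ch1, ch2, ...` stream dialect.

Everything is seed-deterministic; an instrumented counter of evaluated
cost-matrix cells lets you compare the work done by exact and kernel
search directly.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end acceptance benchmarks
(oracle equivalence against explicit path enumeration, kernel contract,
planted-pattern recovery, identification); the rest are per-module unit
and property tests.

## Library quick start

```python
import numpy as np
import warpsearch as ws

# exact subsequence search
X = ws.make_reference(100, dim=1, seed=0)                 # reference pattern
spec = ws.PlantSpec(positions=ws.default_positions(5000, 5, 151),
                    warp_factor_range=(0.8, 1.5), noise_sd=0.2)
Y, truth = ws.plant_stream(X, 5000, spec, seed=1)          # stream + ground truth
matches = ws.search_repetitions(
    X, Y, ws.SearchConfig(tau=50.0, exclusion_radius=100))

# kernel-approximated search under an evaluation budget
R = ws.max_basis_cardinality(rho=0.5, alpha=0.2, N=100, M=5000)
eta = ws.bo_budget(rho_bar=0.95, M=5000, alpha=0.2, R=R, N=100, beta_plus=1.5)
S = ws.generate_basis(R=R, lmin=10, lmax=20, d=1, seed=2)
cfg = ws.BOConfig(eta=eta, seed=3, beta_minus=1.0, beta_plus=1.5)
fast = ws.bo_search_repetitions(
    X, Y, S, None, cfg,
    ws.SearchConfig(tau=np.inf, exclusion_radius=100, max_matches=5),
    budget_mode="total")
```

## CLI

```sh
# generate a synthetic fixture (reference + stream + ground truth)
warpsearch simulate --out fixture --seed 0 --m 5000 --n 100 --copies 5

# exact search
warpsearch search fixture/reference.csv fixture/stream.csv \
    --method dtw --tau 60 --radius 100 --out run-dtw

# kernel-approximated search (derives R and eta, logs them)
warpsearch search fixture/reference.csv fixture/stream.csv \
    --method kernel --tau 0.9 --rho 0.5 --alpha 0.1 --max-matches 5 \
    --out run-kernel

# fixed-window baselines
warpsearch search fixture/reference.csv fixture/stream.csv \
    --method euclidean-window --k 10 --out run-mass

# multi-reference identification
warpsearch simulate --out bench --preset identification --n-refs 8 \
    --m 1200 --n 100 --copies 4 --noise-sd 0.1
warpsearch identify --references bench/references --streams bench/streams \
    --out run-id --eta 18
```

Options may also come from a flat `key = value` config file via
`--config`; command-line flags override it. Every command writes a
`manifest.json` with the fully resolved configuration and derived seeds,
so reruns are byte-identical. Exit codes: 0 success, 2 configuration
error, 3 infeasible search.

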