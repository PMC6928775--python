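import numpy as np
import pytest

from warpsearch import (
    BOConfig,
    InfeasibleSearchError,
    InputError,
    KernelParams,
    KernelSubsequenceSearch,
    SearchConfig,
    bo_best_match,
    bo_search_repetitions,
    embed,
    generate_basis,
    kernel_distance,
    kernel_objective,
    make_reference,
    plant_stream,
)
from warpsearch.synthetic import PlantSpec, hit_rate, overlap_fraction


@pytest.fixture(scope="module")
def small_problem():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(1, 5))
    Y = rng.normal(size=(1, 20))
    S = generate_basis(R=3, lmin=2, lmax=3, seed=1)
    return X, Y, S


class TestBOConfig:
    def test_n_init_must_be_below_eta(self):
        with pytest.raises(InputError):
            BOConfig(eta=5, n_init=5)

    def test_default_n_init(self):
        assert BOConfig(eta=100).resolved_n_init() == 20
        assert BOConfig(eta=10).resolved_n_init() == 5
        assert BOConfig(eta=3).resolved_n_init() == 2

    def test_beta_bounds(self):
        with pytest.raises(InputError):
            BOConfig(eta=10, beta_plus=2.0)
        with pytest.raises(InputError):
            BOConfig(eta=10, beta_minus=0.0)


class TestKernelObjective:
    def test_exact_copy_zero(self):
        X = np.sin(np.arange(6.0)).reshape(1, -1)
        Y = np.concatenate([np.full((1, 4), 9.0), X, np.full((1, 4), 9.0)], axis=1)
        S = generate_basis(R=2, lmin=2, lmax=3, seed=0)
        val = kernel_objective(X, Y, a=5, length=5, S=S, p=KernelParams(1.0),
                               beta_minus=0.5, beta_plus=1.0)
        assert val == pytest.approx(0.0, abs=1e-12)

    def test_range(self, small_problem):
        X, Y, S = small_problem
        for a, ln in ((1, 5), (3, 6), (10, 4)):
            v = kernel_objective(X, Y, a=a, length=ln, S=S, p=KernelParams(1.0))
            assert 0.0 <= v <= 1.0

    def test_constraint_violations(self, small_problem):
        X, Y, S = small_problem
        with pytest.raises(InputError):
            kernel_objective(X, Y, a=1, length=50, S=S, p=KernelParams(1.0))
        with pytest.raises(InputError):
            kernel_objective(X, Y, a=18, length=5, S=S, p=KernelParams(1.0))

    def test_matches_exhaustive_table(self, small_problem):
        # oracle: build the full objective table with embed + kernel_distance
        X, Y, S = small_problem
        p = KernelParams(2.0)
        u = embed(X, S)
        M = Y.shape[1]
        from warpsearch.dtw import as_timeseries

        ts_y = as_timeseries(Y)
        for a in range(1, 12):
            for ln in (4, 5, 6, 7):
                if a + ln > M:
                    continue
                want = kernel_distance(embed(ts_y.window(a, a + ln), S), u, p)
                got = kernel_objective(X, Y, a=a, length=ln, S=S, p=p)
                assert got == pytest.approx(want, abs=1e-12)


class TestBOBestMatch:
    def test_small_grid_equals_exhaustive_minimum(self, small_problem):
        X, Y, S = small_problem
        p = KernelParams(2.0)
        cfg = BOConfig(eta=500, seed=3, beta_minus=0.8, beta_plus=1.4)
        m = bo_best_match(X, Y, S, p, cfg)
        # exhaustive oracle over the same box
        eng = KernelSubsequenceSearch(X, Y, S, p, cfg)
        best = np.inf
        for a in range(1, eng.a_max + 1):
            for ln in range(eng.lmin, min(eng.lmax, Y.shape[1] - a) + 1):
                best = min(best, kernel_objective(
                    X, Y, a=a, length=ln, S=S, p=p,
                    beta_minus=cfg.beta_minus, beta_plus=cfg.beta_plus))
        assert m.score == pytest.approx(best, abs=1e-12)

    def test_budget_respected(self, small_problem):
        X, Y, S = small_problem
        cfg = BOConfig(eta=8, n_init=4, seed=0)
        eng = KernelSubsequenceSearch(X, Y, S, KernelParams(1.0), cfg)
        eng.search(cfg.eta)
        assert eng.n_evaluations <= cfg.eta

    def test_score_never_beats_exhaustive(self, small_problem):
        X, Y, S = small_problem
        p = KernelParams(2.0)
        exhaustive = bo_best_match(X, Y, S, p, BOConfig(eta=500, seed=1)).score
        budgeted = bo_best_match(X, Y, S, p, BOConfig(eta=10, seed=1)).score
        assert budgeted >= exhaustive - 1e-12

    def test_reproducible(self, small_problem):
        X, Y, S = small_problem
        cfg = BOConfig(eta=12, seed=7)
        a = bo_best_match(X, Y, S, KernelParams(1.5), cfg)
        b = bo_best_match(X, Y, S, KernelParams(1.5), cfg)
        assert a == b

    def test_infeasible_region(self):
        X = np.zeros((1, 50))
        Y = np.zeros((1, 20))
        S = generate_basis(R=2, lmin=2, lmax=3, seed=0)
        with pytest.raises(InfeasibleSearchError):
            bo_best_match(X, Y, S, KernelParams(1.0), BOConfig(eta=5))

    def test_planted_copy_found_across_seeds(self):
        # planted low-noise copies; budgeted search overlaps a planted
        # interval (>= 50 % of shorter rule) in >= 90 % of 20 seeded runs
        hits = 0
        for seed in range(20):
            X = make_reference(60, seed=100 + seed)
            spec = PlantSpec(positions=(240,), warp_factor_range=(1.0, 1.0),
                             noise_sd=0.05)
            Y, truth = plant_stream(X, 600, spec, seed=200 + seed)
            S = generate_basis(R=3, lmin=8, lmax=16, seed=300 + seed)
            cfg = BOConfig(eta=40, n_init=30, seed=seed, beta_minus=1.0,
                           beta_plus=1.5)
            m = bo_best_match(X, Y, S, None, cfg)
            a0, b0, _ = truth.intervals[0]
            if overlap_fraction((m.a, m.b), (a0, b0)) >= 0.5:
                hits += 1
        assert hits >= 18

    def test_ambiguous_argmin_still_optimal_score(self):
        # two identical planted copies: argmin ambiguous, score must still
        # match the exhaustive-grid optimum
        pattern = np.sin(np.linspace(0, 2 * np.pi, 8)).reshape(1, -1)
        Y = np.full((1, 40), 5.0)
        Y[:, 4:12] = pattern
        Y[:, 24:32] = pattern
        S = generate_basis(R=2, lmin=2, lmax=4, seed=2)
        p = KernelParams(1.0)
        cfg = BOConfig(eta=600, seed=0, beta_minus=0.8, beta_plus=1.2)
        m = bo_best_match(pattern, Y, S, p, cfg)
        assert m.score == pytest.approx(0.0, abs=1e-12)


class TestBOSearchRepetitions:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_three_separated_copies(self, seed):
        X = make_reference(60, seed=1 + seed)
        spec = PlantSpec(positions=(100, 300, 500), warp_factor_range=(1.0, 1.0),
                         noise_sd=0.02)
        Y, truth = plant_stream(X, 700, spec, seed=2 + seed)
        S = generate_basis(R=3, lmin=8, lmax=16, seed=3 + seed)
        cfg = BOConfig(eta=100, n_init=70, seed=4 + seed, beta_minus=1.0,
                       beta_plus=1.5)
        matches = bo_search_repetitions(
            X, Y, S, None, cfg,
            SearchConfig(tau=np.inf, exclusion_radius=60, max_matches=3),
            budget_mode="total",
        )
        assert len(matches) == 3
        assert hit_rate(matches, truth) == 1.0

    def test_tau_zero_no_exact_copy_empty(self, small_problem):
        X, Y, S = small_problem
        cfg = BOConfig(eta=30, seed=0)
        matches = bo_search_repetitions(
            X, Y, S, KernelParams(1.0), cfg, SearchConfig(tau=0.0)
        )
        assert matches == []

    def test_huge_exclusion_radius_single_match(self, small_problem):
        X, Y, S = small_problem
        cfg = BOConfig(eta=30, seed=0)
        matches = bo_search_repetitions(
            X, Y, S, KernelParams(1.0), cfg,
            SearchConfig(tau=np.inf, exclusion_radius=10_000, max_matches=5),
        )
        assert len(matches) == 1

    def test_total_mode_requires_max_matches(self, small_problem):
        X, Y, S = small_problem
        with pytest.raises(InputError):
            bo_search_repetitions(
                X, Y, S, KernelParams(1.0), BOConfig(eta=10, seed=0),
                SearchConfig(tau=1.0), budget_mode="total",
            )

    def test_total_budget_respected(self):
        X = make_reference(20, seed=8)
        spec = PlantSpec(positions=(60, 160), warp_factor_range=(1.0, 1.2))
        Y, _ = plant_stream(X, 260, spec, seed=9)
        S = generate_basis(R=2, lmin=2, lmax=4, seed=10)
        cfg = BOConfig(eta=25, n_init=15, seed=11, beta_minus=1.0, beta_plus=1.5)
        eng = KernelSubsequenceSearch(X, Y, S, None, cfg)
        # replicate through public API then assert via a fresh engine count
        matches = bo_search_repetitions(
            X, Y, S, None, cfg,
            SearchConfig(tau=np.inf, exclusion_radius=20, max_matches=2),
            budget_mode="total",
        )
        assert len(matches) <= 2
        # the engine inside the call cannot exceed eta: verify the same
        # sequence manually
        eng.search(cfg.eta)
        assert eng.n_evaluations <= cfg.eta

    def test_ranked_by_score(self):
        X = make_reference(20, seed=20)
        spec = PlantSpec(positions=(50, 150, 250), warp_factor_range=(1.0, 1.0),
                         noise_sd=0.1)
        Y, _ = plant_stream(X, 350, spec, seed=21)
        S = generate_basis(R=2, lmin=2, lmax=4, seed=22)
        cfg = BOConfig(eta=60, n_init=45, seed=23, beta_minus=1.0, beta_plus=1.5)
        matches = bo_search_repetitions(
            X, Y, S, None, cfg,
            SearchConfig(tau=np.inf, exclusion_radius=20, max_matches=3),
            budget_mode="total",
        )
        scores = [m.score for m in matches]
        assert scores == sorted(scores)


class TestRandomFallback:
    def test_same_budget_contract(self, small_problem):
        X, Y, S = small_problem
        cfg = BOConfig(eta=15, n_init=5, seed=0, method="random")
        eng = KernelSubsequenceSearch(X, Y, S, KernelParams(1.0), cfg)
        eng.search(cfg.eta)
        assert eng.n_evaluations <= cfg.eta
        assert eng.incumbent() is not None

    def test_reproducible(self, small_problem):
        X, Y, S = small_problem
        cfg = BOConfig(eta=15, seed=5, method="random")
        a = bo_best_match(X, Y, S, KernelParams(1.0), cfg)
        b = bo_best_match(X, Y, S, KernelParams(1.0), cfg)
        assert a == b
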