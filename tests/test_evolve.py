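"""Variation/selection operators and the four non-rule-based steppers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nkbreed as nb
from nkbreed.errors import EmptyPoolError, InvalidParameterError
from nkbreed.evolve import (
    GLOBAL_F,
    RunState,
    _tournament_batch,
    grid_neighbourhoods,
    most_square_grid,
)
from nkbreed.rules import step_earl1, step_earl2

from _oracles import exhaustive_optimum


def make_state(n=20, lam=50, seed=3, k=2, fitness_fn=None, **params):
    L = None if fitness_fn else nb.generate_landscape(n, k, seed)
    p = nb.EvolutionParams(lam=lam, **params)
    pop = nb.init_population(n, lam, seed + 1)
    return RunState.create(L, None, p, pop, GLOBAL_F, seed + 2, fitness_fn=fitness_fn)


# ---------------------------------------------------------------------------
# initialization


def test_init_population_shape_determinism_and_allele_frequencies():
    pop = nb.init_population(100, 1000, 0)
    assert pop.shape == (1000, 100) and pop.dtype == np.uint8
    assert (nb.init_population(100, 1000, 0) == pop).all()
    big = nb.init_population(50, 10_000, 1)
    freq = big.mean(axis=0)
    assert (np.abs(freq - 0.5) < 0.02).all()
    with pytest.raises(InvalidParameterError):
        nb.init_population(0, 10, 0)
    with pytest.raises(InvalidParameterError):
        nb.init_population(10, 0, 0)


# ---------------------------------------------------------------------------
# mutation / crossover


def test_mutate_limits_and_expected_flip_count():
    rng = np.random.default_rng(0)
    g = nb.init_population(250, 1, 5)[0]
    assert (nb.mutate(g, 0.0, rng) == g).all()
    assert (nb.mutate(g, 1.0, rng) == 1 - g).all()
    # p_m = 1/N: mean Hamming distance to parent is N * p_m = 1
    batch = np.tile(g, (10_000, 1))
    mutants = nb.mutate(batch, 1 / 250, rng)
    dist = (mutants != g).sum(axis=1)
    assert abs(dist.mean() - 1.0) < 0.05
    with pytest.raises(InvalidParameterError):
        nb.mutate(g, 1.5, rng)


def test_mutate_leaves_input_unmodified():
    rng = np.random.default_rng(1)
    g = np.zeros(50, dtype=np.uint8)
    nb.mutate(g, 1.0, rng)
    assert (g == 0).all()


def test_uniform_crossover_contracts():
    rng = np.random.default_rng(2)
    a = nb.init_population(40, 1, 7)[0]
    assert (nb.uniform_crossover(a, a, rng) == a).all()
    b = nb.init_population(40, 1, 8)[0]
    child = nb.uniform_crossover(a, b, rng)
    assert ((child == a) | (child == b)).all()
    with pytest.raises(InvalidParameterError):
        nb.uniform_crossover(a, b[:20], rng)


def test_uniform_crossover_is_unbiased():
    rng = np.random.default_rng(3)
    zeros = np.zeros(100, dtype=np.uint8)
    ones = np.ones(100, dtype=np.uint8)
    counts = [nb.uniform_crossover(zeros, ones, rng).sum() for _ in range(10_000)]
    assert abs(np.mean(counts) - 50) < 1  # Binomial(100, 0.5)


@settings(max_examples=25, derandomize=True, deadline=None)
@given(seed=st.integers(0, 2 ** 16), n=st.integers(1, 64))
def test_crossover_alleles_always_come_from_a_parent(seed, n):
    rng = np.random.default_rng(seed)
    p1 = rng.integers(0, 2, n, dtype=np.uint8)
    p2 = rng.integers(0, 2, n, dtype=np.uint8)
    child = nb.uniform_crossover(p1, p2, rng)
    assert ((child == p1) | (child == p2)).all()


# ---------------------------------------------------------------------------
# tournament selection


def test_tournament_pool_of_one_and_empty_pool():
    rng = np.random.default_rng(4)
    f = np.array([0.1, 0.9, 0.5])
    assert nb.tournament_select(f, 5, rng, pool=[0]) == 0
    with pytest.raises(EmptyPoolError):
        nb.tournament_select(f, 5, rng, pool=np.array([], dtype=int))
    with pytest.raises(InvalidParameterError):
        nb.tournament_select(f, 0, rng)


def test_tournament_win_probability_matches_closed_form():
    # best of n=10 distinct fitnesses wins with prob 1 - ((n-1)/n)^t
    rng = np.random.default_rng(5)
    f = np.arange(10) / 10.0
    winners = _tournament_batch(f, 10, rng, 100_000)
    p_best = (winners == 9).mean()
    assert abs(p_best - (1 - 0.9 ** 10)) < 0.01


def test_tournament_size_one_is_uniform():
    rng = np.random.default_rng(6)
    f = np.arange(8) / 8.0
    winners = _tournament_batch(f, 1, rng, 100_000)
    freqs = np.bincount(winners, minlength=8) / 100_000
    assert (np.abs(freqs - 1 / 8) < 0.01).all()


# ---------------------------------------------------------------------------
# breeder (1+lambda)


def test_breeder_pm_zero_clones_champion():
    st_ = make_state(p_m=0.0)
    champ_before = st_.population[np.argmax(st_.fitness)].copy()
    f_before = st_.fitness.max()
    nb.step_breeder(st_)
    assert (st_.population == champ_before).all()
    assert st_.champion[1] == pytest.approx(f_before)


def test_breeder_champion_fitness_is_monotone():
    st_ = make_state(n=30, lam=40, seed=9)
    best = -np.inf
    for _ in range(25):
        nb.step_breeder(st_)
        assert st_.champion[1] >= best
        best = st_.champion[1]


def test_breeder_retains_a_global_optimum():
    L = nb.generate_landscape(8, 2, seed=13)
    best_g, best_f = exhaustive_optimum(L)
    pop = np.tile(best_g, (30, 1))
    st_ = RunState.create(L, None, nb.EvolutionParams(lam=30), pop, GLOBAL_F, 1)
    for _ in range(50):
        nb.step_breeder(st_)
        assert (st_.champion[0] == best_g).all()
        assert st_.champion[1] == pytest.approx(best_f)


# ---------------------------------------------------------------------------
# standard GA


def test_standard_ga_offspring_are_parent_copies_without_variation():
    st_ = make_state(p_m=0.0, p_c=0.0)
    parents = {bytes(row) for row in st_.population}
    nb.step_standard_ga(st_)
    assert st_.population.shape == (50, 20)
    assert all(bytes(row) in parents for row in st_.population)


def test_standard_ga_improves_mean_fitness_on_separable_landscape():
    improved = 0
    for s in range(100):
        L = nb.generate_landscape(10, 0, seed=9000 + s)
        pop = nb.init_population(10, 100, 9500 + s)
        st_ = RunState.create(L, None, nb.EvolutionParams(lam=100), pop, GLOBAL_F, 9700 + s)
        f0 = st_.fitness.mean()
        for _ in range(20):
            nb.step_standard_ga(st_)
        improved += st_.fitness.mean() > f0
    assert improved >= 95


# ---------------------------------------------------------------------------
# local mating


def test_grid_factorization_is_most_square():
    assert most_square_grid(1000) == (25, 40)
    assert most_square_grid(200) == (10, 20)
    assert most_square_grid(7) == (1, 7)


def test_neighbourhood_is_24_unique_surrounding_cells():
    nbrs = grid_neighbourhoods((5, 8))
    assert nbrs.shape == (40, 24)
    for i in range(40):
        assert len(set(nbrs[i].tolist())) == 24
        assert i not in nbrs[i]
    # toroidal brute-force check for one corner cell
    r0, c0 = 0, 0
    expect = {
        ((r0 + dr) % 5) * 8 + (c0 + dc) % 8
        for dr in range(-2, 3)
        for dc in range(-2, 3)
        if (dr, dc) != (0, 0)
    }
    assert set(nbrs[0].tolist()) == expect


def test_local_mating_offspring_descend_from_the_neighbourhood():
    st_ = make_state(n=15, lam=40, seed=31, p_m=0.0, grid_shape=(5, 8))
    nbrs = grid_neighbourhoods((5, 8))
    before = st_.population.copy()
    nb.step_local_mating(st_)
    for i in range(40):
        pool = np.concatenate(([i], nbrs[i]))
        alleles = before[pool]  # (25, n)
        # every offspring locus must occur in the focal cell's neighbourhood
        assert ((st_.population[i] == alleles).any(axis=0)).all()


def test_local_mating_rejects_mismatched_grid():
    with pytest.raises(InvalidParameterError):
        nb.EvolutionParams(lam=40, grid_shape=(3, 5))
    st_ = make_state(n=10, lam=40, seed=33)
    st_.params.grid_shape = (6, 7)  # bypass validation to hit the stepper check
    with pytest.raises(InvalidParameterError):
        nb.step_local_mating(st_)


# ---------------------------------------------------------------------------
# fitness sharing / niching


def test_shared_fitness_formula():
    assert nb.shared_fitness(0.7, 1) == pytest.approx(0.7)
    assert nb.shared_fitness(0.9, 11) == pytest.approx(0.45)
    values = [nb.shared_fitness(0.8, nc) for nc in range(1, 20)]
    assert all(a > b for a, b in zip(values, values[1:]))
    with pytest.raises(InvalidParameterError):
        nb.shared_fitness(0.5, 0)


def test_niche_counts_exact_and_sampled():
    pop = np.zeros((20, 30), dtype=np.uint8)
    pop[10:] = 1
    counts = nb.niche_counts(pop, n_r=5)
    assert (counts == 10).all()
    counts_all = nb.niche_counts(pop, n_r=30)
    assert (counts_all == 20).all()
    rng = np.random.default_rng(0)
    est = nb.niche_counts(pop, n_r=5, sample_size=10, rng=rng)
    assert est.shape == (20,) and (est >= 1).all()


def test_estimate_niche_count_clusters():
    rng = np.random.default_rng(1)
    identical = np.ones((50, 60), dtype=np.uint8)
    assert nb.estimate_niche_count(identical, 0, 50, rng) == 1
    two = np.zeros((40, 60), dtype=np.uint8)
    two[20:, :50] = 1  # mutual Hamming distance 50
    assert nb.estimate_niche_count(two, 5, 40, rng) == 2
    diverse = nb.init_population(60, 50, 2)
    assert nb.estimate_niche_count(diverse, 60, 50, rng) == 1  # radius covers space


def test_update_niche_radius_rules():
    ns = nb.NicheState(n_r=10, q_estimate=5)
    assert nb.update_niche_radius(ns, 5, 100).n_r == 10  # fixed point
    ns = nb.NicheState(n_r=10, q_estimate=20)
    assert nb.update_niche_radius(ns, 5, 100).n_r == 11  # merge niches
    ns = nb.NicheState(n_r=1, q_estimate=2)
    assert nb.update_niche_radius(ns, 5, 100).n_r == 1  # clamp at 1
    ns = nb.NicheState(n_r=100, q_estimate=50)
    assert nb.update_niche_radius(ns, 5, 100).n_r == 100  # clamp at N


def test_identical_population_shares_fitness_by_lambda():
    pop = np.ones((30, 12), dtype=np.uint8)
    counts = nb.niche_counts(pop, n_r=1)
    f_share = nb.shared_fitness(np.full(30, 0.6), counts)
    np.testing.assert_allclose(f_share, 10 * 0.6 / (9 + 30))


def _twin_peaks(genomes):
    # deep isolated peaks at all-0 and all-1; shallow slope elsewhere
    n = genomes.shape[1]
    d = np.minimum(genomes.sum(1), n - genomes.sum(1))
    return np.where(d == 0, 1.0, 0.05 * (1.0 - d / n))


def _peak_persistence(step, seed, cap=50):
    n, lam = 30, 100
    params = nb.EvolutionParams(lam=lam, p_m=1.0 / n)
    pop = np.zeros((lam, n), np.uint8)
    pop[lam // 2:] = 1
    st_ = RunState.create(None, None, params, pop, GLOBAL_F, seed, fitness_fn=_twin_peaks)
    for g in range(cap):
        s = st_.population.sum(1)
        if not ((s == 0).any() and (s == n).any()):
            return g
        step(st_)
    return cap


def test_niching_preserves_twin_peaks_longer_than_standard_ga():
    wins = sum(
        _peak_persistence(nb.step_niching, 1000 + s)
        > _peak_persistence(nb.step_standard_ga, 1000 + s)
        for s in range(40)
    )
    assert wins >= 32  # 80% of paired seeds


# ---------------------------------------------------------------------------
# cross-cutting stepper invariants

ALL_STEPPERS = {
    "breeder": nb.step_breeder,
    "standard_ga": nb.step_standard_ga,
    "local_mating": nb.step_local_mating,
    "niching": nb.step_niching,
    "earl1": step_earl1,
    "earl2": step_earl2,
}


@pytest.mark.parametrize("name", sorted(ALL_STEPPERS))
def test_steppers_preserve_shape_and_replay_deterministically(name):
    step = ALL_STEPPERS[name]
    runs = []
    for _ in range(2):
        st_ = make_state(n=16, lam=40, seed=77)
        gens = []
        for _ in range(3):
            step(st_)
            assert st_.population.shape == (40, 16)
            assert np.isin(st_.population, (0, 1)).all()
            gens.append(st_.population.copy())
        assert st_.generation == 3
        runs.append(gens)
    for a, b in zip(*runs):
        assert (a == b).all()


@pytest.mark.parametrize("name", sorted(ALL_STEPPERS))
def test_fitness_cache_matches_population(name):
    step = ALL_STEPPERS[name]
    st_ = make_state(n=16, lam=40, seed=78)
    step(st_)
    np.testing.assert_allclose(st_.fitness, st_.evaluate(st_.population))
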