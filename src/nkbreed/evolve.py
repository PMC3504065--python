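"""Variation, selection, and the four non-rule-based algorithm steppers.

Implements the operator toolbox (per-bit mutation, uniform crossover,
tournament selection) and generational steppers for:

* ``breeder`` — a (1+lambda) scheme: every offspring is a mutated clone of the
  single fittest individual, and the champion is retained (strong elitism).
* ``standard_ga`` — a non-elitist generational GA with tournament selection,
  uniform crossover with probability ``p_c``, cloning otherwise, and per-bit
  mutation everywhere.
* ``local_mating`` — a cellular GA on a toroidal grid: each cell mates only
  with the winner of a tournament over the 24 cells of the surrounding 5x5
  square, resisting rapid takeover.
* ``niching`` — genotypic fitness sharing: selection acts on
  ``f_share = 10 f / (9 + n_c)`` where ``n_c`` counts the individuals within
  Hamming radius ``n_r`` (self included); the radius adapts by +/-1 each
  generation toward a target niche count ``T_q``.

All steppers mutate the :class:`RunState` in place and return it; replaying
from the same seed reproduces bit-identical populations.  Randomness is split
into named child streams per operator category (selection, variation, niching,
rules) so algorithms sharing a starting population evolve on independent
streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np

from .errors import EmptyPoolError, InvalidParameterError
from .landscape import NKLandscape, TraitConfig

__all__ = [
    "EvolutionParams",
    "NicheState",
    "RunState",
    "init_population",
    "mutate",
    "uniform_crossover",
    "tournament_select",
    "shared_fitness",
    "niche_counts",
    "estimate_niche_count",
    "update_niche_radius",
    "step_breeder",
    "step_standard_ga",
    "step_local_mating",
    "step_niching",
    "most_square_grid",
]

GLOBAL_F = "global_F"
TRAIT_F_PRIME = "trait_F_prime"

_STREAM_NAMES = ("selection", "variation", "niching", "rules")


@dataclass
class EvolutionParams:
    """Algorithm parameters; defaults follow the standard tuned settings
    (lambda=1000, p_m=1/N, p_c=0.7, t_size=10, T_q=5).

    ``p_m=None`` resolves to ``1/N`` at run time.  ``grid_shape`` (local
    mating) defaults to the most-square factorization of lambda.
    ``sharing_sample_size=None`` computes niche counts exactly over the whole
    population; an integer switches to a sampled estimate for large lambda.
    """

    lam: int = 1000
    p_m: Optional[float] = None
    p_c: float = 0.7
    t_size: int = 10
    target_niches: int = 5
    niche_sample_size: int = 50
    sharing_sample_size: Optional[int] = None
    grid_shape: Optional[tuple[int, int]] = None
    # AQ-style rule learner (EARL) settings
    rule_beam_width: int = 5
    rule_max_conditions: int = 5
    rule_max_rules: int = 20
    rule_l_tolerance: int = 0
    top_fraction: float = 0.2
    bottom_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.lam < 1:
            raise InvalidParameterError(f"lam must be >= 1; got {self.lam}")
        if self.p_m is not None and not 0.0 <= self.p_m <= 1.0:
            raise InvalidParameterError(f"p_m must lie in [0, 1]; got {self.p_m}")
        if not 0.0 <= self.p_c <= 1.0:
            raise InvalidParameterError(f"p_c must lie in [0, 1]; got {self.p_c}")
        if self.t_size < 1:
            raise InvalidParameterError(f"t_size must be >= 1; got {self.t_size}")
        if self.target_niches < 1:
            raise InvalidParameterError("target_niches must be >= 1")
        if self.grid_shape is not None:
            r, c = self.grid_shape
            if r * c != self.lam:
                raise InvalidParameterError(
                    f"grid_shape {self.grid_shape} does not factor lam={self.lam}"
                )

    def resolve_p_m(self, n: int) -> float:
        return 1.0 / n if self.p_m is None else self.p_m


@dataclass(frozen=True)
class NicheState:
    """Dynamic niche-radius state for the niching GA."""

    n_r: int
    q_estimate: int = 1
    sample_size: int = 50

    def __post_init__(self) -> None:
        if self.n_r < 1:
            raise InvalidParameterError("niche radius must be >= 1")
        if self.q_estimate < 1:
            raise InvalidParameterError("niche count estimate must be >= 1")


@dataclass
class RunState:
    """Mutable state of one evolutionary run.

    ``fitness_mode`` selects the objective: the unmodified global fitness F
    during burn-in, the thresholded trait objective F' afterwards.
    ``fitness_fn`` may override the landscape-based objective (used for toy
    landscapes in tests and extensions).
    """

    landscape: Optional[NKLandscape]
    trait: Optional[TraitConfig]
    params: EvolutionParams
    population: np.ndarray
    fitness: np.ndarray
    fitness_mode: str
    generation: int = 0
    streams: dict = field(default_factory=dict)
    champion: Optional[tuple[np.ndarray, float]] = None
    niche: Optional[NicheState] = None
    fitness_fn: Optional[Callable[[np.ndarray], np.ndarray]] = None
    earl_audit: Optional[dict] = None
    _neighbourhood_cache: Optional[np.ndarray] = field(default=None, repr=False)

    @classmethod
    def create(
        cls,
        landscape: Optional[NKLandscape],
        trait: Optional[TraitConfig],
        params: EvolutionParams,
        population: np.ndarray,
        fitness_mode: str,
        seed,
        fitness_fn: Optional[Callable] = None,
    ) -> "RunState":
        if fitness_mode not in (GLOBAL_F, TRAIT_F_PRIME):
            raise InvalidParameterError(f"unknown fitness_mode {fitness_mode!r}")
        pop = np.ascontiguousarray(population, dtype=np.uint8)
        if pop.ndim != 2 or pop.shape[0] != params.lam:
            raise InvalidParameterError(
                f"population shape {pop.shape} does not match lam={params.lam}"
            )
        ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        children = ss.spawn(len(_STREAM_NAMES))
        streams = {
            name: np.random.default_rng(child)
            for name, child in zip(_STREAM_NAMES, children)
        }
        state = cls(
            landscape=landscape,
            trait=trait,
            params=params,
            population=pop,
            fitness=np.empty(params.lam),
            fitness_mode=fitness_mode,
            streams=streams,
            fitness_fn=fitness_fn,
        )
        state.fitness = state.evaluate(pop)
        return state

    def evaluate(self, genomes: np.ndarray) -> np.ndarray:
        """Active-mode fitness of a (M, N) genotype matrix."""
        if self.fitness_fn is not None:
            return np.asarray(self.fitness_fn(genomes), dtype=float)
        if self.landscape is None:
            raise InvalidParameterError("state has neither a landscape nor a fitness_fn")
        if self.fitness_mode == GLOBAL_F:
            return np.asarray(self.landscape.fitness(genomes))
        if self.trait is None:
            raise InvalidParameterError("trait_F_prime mode requires a TraitConfig")
        return np.asarray(self.landscape.modified_fitness(genomes, self.trait))


# ---------------------------------------------------------------------------
# operators


def init_population(n: int, lam: int, seed) -> np.ndarray:
    """lam genotypes of length n with independent uniform bits."""
    if n < 1 or lam < 1:
        raise InvalidParameterError(f"n and lam must be >= 1; got n={n}, lam={lam}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.integers(0, 2, size=(lam, n), dtype=np.uint8)


def mutate(genotype, p_m: float, rng: np.random.Generator) -> np.ndarray:
    """Flip each bit independently with probability ``p_m`` (input unmodified).

    Accepts a single genotype or a (M, N) matrix.
    """
    if not 0.0 <= p_m <= 1.0:
        raise InvalidParameterError(f"p_m must lie in [0, 1]; got {p_m}")
    arr = np.asarray(genotype, dtype=np.uint8)
    flips = rng.random(arr.shape) < p_m
    return arr ^ flips.astype(np.uint8)


def uniform_crossover(parent1, parent2, rng: np.random.Generator) -> np.ndarray:
    """Each offspring locus copied from either parent with probability 0.5."""
    p1 = np.asarray(parent1, dtype=np.uint8)
    p2 = np.asarray(parent2, dtype=np.uint8)
    if p1.shape != p2.shape:
        raise InvalidParameterError(
            f"parent length mismatch: {p1.shape} vs {p2.shape}"
        )
    mask = rng.random(p1.shape) < 0.5
    return np.where(mask, p1, p2).astype(np.uint8)


def _tournament_batch(
    fitnesses: np.ndarray,
    t_size: int,
    rng: np.random.Generator,
    m: int,
    pool: Optional[np.ndarray] = None,
) -> np.ndarray:
    """m independent tournaments; ties go to the first-sampled contender
    (deterministic replay; uniform among ties since draw order is random)."""
    f = np.asarray(fitnesses, dtype=float)
    if pool is None:
        idx = rng.integers(0, f.shape[0], size=(m, t_size))
    else:
        pool = np.asarray(pool)
        if pool.size == 0:
            raise EmptyPoolError("tournament pool is empty")
        idx = pool[rng.integers(0, pool.size, size=(m, t_size))]
    fv = f[idx]
    return idx[np.arange(m), fv.argmax(axis=1)]


def tournament_select(
    fitnesses,
    t_size: int,
    rng: np.random.Generator,
    pool=None,
) -> int:
    """Index of the fittest of ``t_size`` members sampled with replacement."""
    if t_size < 1:
        raise InvalidParameterError(f"t_size must be >= 1; got {t_size}")
    return int(_tournament_batch(fitnesses, t_size, rng, 1, pool)[0])


# ---------------------------------------------------------------------------
# fitness sharing


def shared_fitness(f, n_c):
    """Genotypic fitness sharing: ``f_share = 10 f / (9 + n_c)``.

    The niche count includes the individual itself, so an isolated individual
    (n_c = 1) keeps its raw fitness.
    """
    nc = np.asarray(n_c)
    if np.any(nc < 1):
        raise InvalidParameterError("niche count must be >= 1 (self counts)")
    out = 10.0 * np.asarray(f, dtype=float) / (9.0 + nc)
    return float(out) if out.ndim == 0 else out


def _hamming_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise Hamming distances between rows of binary matrices a and b."""
    af = a.astype(np.float64)
    bf = b.astype(np.float64)
    sa = af.sum(axis=1)
    sb = bf.sum(axis=1)
    return np.rint(sa[:, None] + sb[None, :] - 2.0 * (af @ bf.T)).astype(np.int64)


def niche_counts(
    population: np.ndarray,
    n_r: int,
    sample_size: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Per-member niche count: self plus all others within Hamming ``n_r``.

    Exact O(lambda^2) by default; with ``sample_size`` the count is estimated
    by comparing each member against a random subsample and rescaling.
    """
    pop = np.asarray(population, dtype=np.uint8)
    lam = pop.shape[0]
    if sample_size is None or sample_size >= lam:
        d = _hamming_matrix(pop, pop)
        return (d <= n_r).sum(axis=1)
    if rng is None:
        raise InvalidParameterError("sampled niche counting requires an rng")
    idx = rng.choice(lam, size=sample_size, replace=False)
    within = (_hamming_matrix(pop, pop[idx]) <= n_r).sum(axis=1)
    est = np.rint(within * (lam / sample_size)).astype(np.int64)
    return np.maximum(est, 1)


def estimate_niche_count(
    population: np.ndarray,
    n_r: int,
    sample_size: int,
    rng: np.random.Generator,
) -> int:
    """Estimate the number of niches q by greedy leader clustering of a sample.

    A sampled genotype joins the first existing leader within Hamming distance
    ``n_r``, otherwise founds a new leader; q is the number of leaders.
    """
    if sample_size < 1:
        raise InvalidParameterError("sample_size must be >= 1")
    pop = np.asarray(population, dtype=np.uint8)
    lam = pop.shape[0]
    m = min(sample_size, lam)
    idx = rng.choice(lam, size=m, replace=False)
    leaders: list[np.ndarray] = []
    for g in pop[idx]:
        for leader in leaders:
            if int((g != leader).sum()) <= n_r:
                break
        else:
            leaders.append(g)
    return len(leaders)


def update_niche_radius(ns: NicheState, t_q: int, n_loci: int) -> NicheState:
    """Move the radius one step toward the target niche count.

    Too many niches (q > T_q) widens the radius so niches merge; too few
    narrows it. Clamped to [1, N].
    """
    n_r = ns.n_r
    if ns.q_estimate > t_q:
        n_r += 1
    elif ns.q_estimate < t_q:
        n_r -= 1
    n_r = int(np.clip(n_r, 1, n_loci))
    return replace(ns, n_r=n_r)


def initial_niche_state(n_loci: int, sample_size: int = 50) -> NicheState:
    return NicheState(n_r=max(1, n_loci // 10), sample_size=sample_size)


# ---------------------------------------------------------------------------
# steppers


def _ga_offspring(state: RunState, selection_fitness: np.ndarray) -> np.ndarray:
    """One generational batch of offspring under standard-GA semantics.

    With probability p_c an offspring recombines two tournament-selected
    parents; otherwise it clones one tournament-selected parent. Per-bit
    mutation applies to every offspring.
    """
    p = state.params
    pop = state.population
    lam, n = pop.shape
    sel = state.streams["selection"]
    var = state.streams["variation"]
    recombine = sel.random(lam) < p.p_c
    p1 = _tournament_batch(selection_fitness, p.t_size, sel, lam)
    p2 = _tournament_batch(selection_fitness, p.t_size, sel, lam)
    offspring = pop[p1].copy()
    mask = var.random((lam, n)) < 0.5
    r = recombine
    offspring[r] = np.where(mask[r], pop[p1][r], pop[p2][r])
    flips = var.random((lam, n)) < p.resolve_p_m(n)
    offspring ^= flips.astype(np.uint8)
    return offspring


def step_standard_ga(state: RunState) -> RunState:
    """Non-elitist generational GA step; offspring fully replace parents."""
    offspring = _ga_offspring(state, state.fitness)
    state.population = offspring
    state.fitness = state.evaluate(offspring)
    state.generation += 1
    return state


def step_breeder(state: RunState) -> RunState:
    """(1+lambda) breeder step: all offspring are mutated clones of the
    champion; the champion survives unless an offspring beats it strictly."""
    var = state.streams["variation"]
    lam, n = state.population.shape
    if state.champion is None:
        i = int(np.argmax(state.fitness))
        state.champion = (state.population[i].copy(), float(state.fitness[i]))
    champ_g, champ_f = state.champion
    offspring = np.tile(champ_g, (lam, 1))
    flips = var.random((lam, n)) < state.params.resolve_p_m(n)
    offspring ^= flips.astype(np.uint8)
    f = state.evaluate(offspring)
    j = int(np.argmax(f))
    if f[j] > champ_f:
        state.champion = (offspring[j].copy(), float(f[j]))
    state.population = offspring
    state.fitness = f
    state.generation += 1
    return state


def most_square_grid(lam: int) -> tuple[int, int]:
    """Most-square factorization rows*cols = lam with rows <= cols."""
    best = (1, lam)
    for rows in range(1, int(np.sqrt(lam)) + 1):
        if lam % rows == 0:
            best = (rows, lam // rows)
    return best


def grid_neighbourhoods(grid_shape: tuple[int, int]) -> np.ndarray:
    """Population indices of the 24 cells in each cell's 5x5 toroidal square
    (focal cell excluded), row-major layout; shape (lam, 24)."""
    rows, cols = grid_shape
    offsets = [(dr, dc) for dr in range(-2, 3) for dc in range(-2, 3) if (dr, dc) != (0, 0)]
    rr, cc = np.divmod(np.arange(rows * cols), cols)
    nbrs = np.empty((rows * cols, len(offsets)), dtype=np.int64)
    for j, (dr, dc) in enumerate(offsets):
        nbrs[:, j] = ((rr + dr) % rows) * cols + (cc + dc) % cols
    return nbrs


def _state_neighbourhoods(state: RunState) -> np.ndarray:
    if state._neighbourhood_cache is None:
        lam = state.population.shape[0]
        shape = state.params.grid_shape or most_square_grid(lam)
        if shape[0] * shape[1] != lam:
            raise InvalidParameterError(
                f"grid {shape} does not factor population size {lam}"
            )
        state._neighbourhood_cache = grid_neighbourhoods(shape)
    return state._neighbourhood_cache


def step_local_mating(state: RunState) -> RunState:
    """Cellular GA step: each cell i recombines with (or is replaced by a
    clone of) the winner of a tournament over its 24-cell 5x5 neighbourhood;
    offspring replace their cells in place."""
    p = state.params
    pop = state.population
    lam, n = pop.shape
    nbrs = _state_neighbourhoods(state)
    sel = state.streams["selection"]
    var = state.streams["variation"]
    recombine = sel.random(lam) < p.p_c
    draws = sel.integers(0, nbrs.shape[1], size=(lam, p.t_size))
    cand = nbrs[np.arange(lam)[:, None], draws]
    fv = state.fitness[cand]
    winner = cand[np.arange(lam), fv.argmax(axis=1)]
    offspring = pop[winner].copy()
    mask = var.random((lam, n)) < 0.5
    r = recombine
    offspring[r] = np.where(mask[r], pop[r], pop[winner[r]])
    flips = var.random((lam, n)) < p.resolve_p_m(n)
    offspring ^= flips.astype(np.uint8)
    state.population = offspring
    state.fitness = state.evaluate(offspring)
    state.generation += 1
    return state


def step_niching(state: RunState) -> RunState:
    """Niching GA step: a standard generational step with tournament
    selection acting on shared fitness, followed by the dynamic niche-radius
    update toward the target niche count."""
    p = state.params
    lam, n = state.population.shape
    if state.niche is None:
        state.niche = initial_niche_state(n, p.niche_sample_size)
    nc = niche_counts(
        state.population,
        state.niche.n_r,
        sample_size=p.sharing_sample_size,
        rng=state.streams["niching"],
    )
    f_share = shared_fitness(state.fitness, nc)
    offspring = _ga_offspring(state, f_share)
    state.population = offspring
    state.fitness = state.evaluate(offspring)
    state.generation += 1
    q = estimate_niche_count(
        offspring, state.niche.n_r, state.niche.sample_size, state.streams["niching"]
    )
    state.niche = update_niche_radius(
        replace(state.niche, q_estimate=max(1, q)), p.target_niches, n
    )
    return state
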