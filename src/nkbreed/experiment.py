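"""Comparison harness: burn-in, matched replicates, and evaluation statistics.

The protocol mirrors a breeding trial: each replicate draws a fresh NK
landscape, runs a niching-GA burn-in on the *unmodified* global fitness F to
obtain a genetically diverse, moderately fit starting stock, then hands that
identical population to every algorithm, which evolves it for a fixed number
of further generations under the thresholded trait objective F'.  Evaluation
records per-generation mean/best fitness and mean per-locus Shannon entropy
(bits), the final-generation entropy profile across loci, and tie-adjusted
mean fitness ranks (1 = worst .. C = best) with +/-1 standard error
(stdev/sqrt(n)) across replicates.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from . import evolve
from .errors import InvalidParameterError
from .evolve import EvolutionParams, RunState, init_population
from .landscape import NKLandscape, TraitConfig
from .rules import step_earl1, step_earl2

logger = logging.getLogger(__name__)

__all__ = [
    "ALGORITHMS",
    "BurnInSpec",
    "ComparisonSpec",
    "Trace",
    "ComparisonResult",
    "run_burn_in",
    "run_replicate",
    "run_comparison",
    "locus_entropy",
    "mean_entropy",
    "rank_final_fitness",
    "standard_error",
    "search_space_report",
    "SearchSpaceReport",
]

#: Stepper registry: three phenotype-only (F) and three genotype-aware (G)
#: algorithms.
ALGORITHMS = {
    "breeder": evolve.step_breeder,
    "standard_ga": evolve.step_standard_ga,
    "local_mating": evolve.step_local_mating,
    "niching": evolve.step_niching,
    "earl1": step_earl1,
    "earl2": step_earl2,
}


@dataclass(frozen=True)
class BurnInSpec:
    """Burn-in protocol: the niching GA on the unmodified landscape."""

    generations: int = 20

    def __post_init__(self) -> None:
        if self.generations < 0:
            raise InvalidParameterError("burn-in generations must be >= 0")


@dataclass(frozen=True)
class ComparisonSpec:
    """Full experiment description; defaults give the standard protocol
    (all six algorithms, burn-in 20, 70 further generations, 100 matched
    replicates)."""

    n: int = 100
    k: int = 5
    r: int = 10
    f_th: float = 0.55
    algorithms: tuple[str, ...] = tuple(ALGORITHMS)
    replicates: int = 100
    burn_in: int = 20
    generations: int = 70
    params: EvolutionParams = field(default_factory=EvolutionParams)
    master_seed: int = 0

    def __post_init__(self) -> None:
        unknown = [a for a in self.algorithms if a not in ALGORITHMS]
        if unknown:
            raise InvalidParameterError(f"unknown algorithm id(s): {unknown}")
        if self.replicates < 1 or self.generations < 0 or self.burn_in < 0:
            raise InvalidParameterError("replicates >= 1 and generations, burn_in >= 0")

    def trait(self) -> TraitConfig:
        return TraitConfig.first_r(self.r, self.n, self.f_th)


@dataclass
class Trace:
    """Per-generation records of one algorithm arm (one replicate)."""

    generation: np.ndarray
    mean_fitness: np.ndarray
    best_fitness: np.ndarray
    mean_entropy: np.ndarray
    fitness_mode: str
    final_entropy_profile: np.ndarray
    start_hash: str


def locus_entropy(population: np.ndarray) -> np.ndarray:
    """Per-locus Shannon entropy in bits: H = -p0 log2 p0 - p1 log2 p1."""
    pop = np.asarray(population)
    if pop.ndim != 2 or pop.shape[0] == 0:
        raise InvalidParameterError("population must be a non-empty 2-D array")
    p1 = pop.mean(axis=0)
    out = np.zeros(pop.shape[1])
    for p in (p1, 1.0 - p1):
        nz = p > 0
        out[nz] -= p[nz] * np.log2(p[nz])
    return out


def mean_entropy(population: np.ndarray) -> float:
    """Mean per-locus Shannon entropy (bits)."""
    return float(locus_entropy(population).mean())


def standard_error(values: np.ndarray, axis: int = 0) -> np.ndarray:
    """+/-1 standard error band: stdev/sqrt(n) (sample stdev, ddof=1)."""
    return stats.sem(values, axis=axis, ddof=1)


def rank_final_fitness(fitness_table: np.ndarray) -> np.ndarray:
    """Mean tie-adjusted rank per algorithm over a (replicates, C) table.

    Within each replicate, rank 1 is the lowest fitness and C the highest;
    ties receive the mean rank. Returns the per-algorithm mean across
    replicates.
    """
    table = np.atleast_2d(np.asarray(fitness_table, dtype=float))
    if table.shape[1] < 2:
        raise InvalidParameterError("need at least 2 algorithms to rank")
    return stats.rankdata(table, axis=1).mean(axis=0)


def _population_hash(population: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(population, dtype=np.uint8).tobytes()).hexdigest()


def run_burn_in(
    landscape: NKLandscape,
    spec: BurnInSpec,
    params: EvolutionParams,
    seed,
    record: bool = False,
):
    """Initialize a uniform random population and burn it in with the niching
    GA on the unmodified global fitness F.

    Returns the resulting population, or ``(population, Trace)`` when
    ``record`` is true (the trace covers generations 0..burn-in under F).
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    init_ss, run_ss = ss.spawn(2)
    pop = init_population(landscape.n, params.lam, np.random.default_rng(init_ss))
    state = RunState.create(landscape, None, params, pop, evolve.GLOBAL_F, run_ss)
    records = [_snapshot(state)] if record else None
    for _ in range(spec.generations):
        evolve.step_niching(state)
        if record:
            records.append(_snapshot(state))
    if not record:
        return state.population
    trace = _records_to_trace(records, evolve.GLOBAL_F, state.population)
    return state.population, trace


def _snapshot(state: RunState) -> tuple[int, float, float, float]:
    return (
        state.generation,
        float(state.fitness.mean()),
        float(state.fitness.max()),
        mean_entropy(state.population),
    )


def _records_to_trace(records, mode: str, final_pop: np.ndarray, start_hash: str = "") -> Trace:
    arr = np.asarray(records, dtype=float)
    return Trace(
        generation=arr[:, 0].astype(int),
        mean_fitness=arr[:, 1],
        best_fitness=arr[:, 2],
        mean_entropy=arr[:, 3],
        fitness_mode=mode,
        final_entropy_profile=locus_entropy(final_pop),
        start_hash=start_hash,
    )


def run_replicate(
    landscape: NKLandscape,
    trait: TraitConfig,
    start_pop: np.ndarray,
    algorithm: str,
    params: EvolutionParams,
    generations: int,
    seed,
) -> Trace:
    """Run one algorithm arm for ``generations`` under the trait objective F'.

    The trace has ``generations + 1`` records: the matched starting population
    re-scored under F' (generation 0), then one per stepper call.
    """
    if algorithm not in ALGORITHMS:
        raise InvalidParameterError(
            f"unknown algorithm {algorithm!r}; choose from {sorted(ALGORITHMS)}"
        )
    step = ALGORITHMS[algorithm]
    state = RunState.create(
        landscape, trait, params, start_pop.copy(), evolve.TRAIT_F_PRIME, seed
    )
    start_hash = _population_hash(state.population)
    records = [_snapshot(state)]
    for _ in range(generations):
        step(state)
        records.append(_snapshot(state))
    return _records_to_trace(records, evolve.TRAIT_F_PRIME, state.population, start_hash)


@dataclass
class ComparisonResult:
    """Aggregated traces of a matched comparison.

    Trace arrays are indexed ``(algorithm, replicate, generation)``; entropy
    profiles ``(algorithm, replicate, locus)`` at the final generation.
    Burn-in arrays are shared across algorithms (matched starts) and indexed
    ``(replicate, burn_generation)``.
    """

    spec: ComparisonSpec
    algorithms: tuple[str, ...]
    mean_fitness: np.ndarray
    best_fitness: np.ndarray
    mean_entropy_trace: np.ndarray
    entropy_profiles: np.ndarray
    start_hashes: np.ndarray
    landscape_seeds: tuple[int, ...]
    burn_mean_fitness: np.ndarray
    burn_mean_entropy: np.ndarray

    # -- statistics ---------------------------------------------------------

    def final_entropy_profile(self) -> np.ndarray:
        """Per-locus entropy at the final generation, averaged over
        replicates; shape (C, N)."""
        return self.entropy_profiles.mean(axis=1)

    def rank_matrix(self, generation: int = -1) -> np.ndarray:
        """Tie-adjusted rank rows (replicates, C) at one generation."""
        table = self.mean_fitness[:, :, generation].T  # (R, C)
        return stats.rankdata(table, axis=1)

    def mean_ranks(self, generation: int = -1) -> tuple[np.ndarray, np.ndarray]:
        """Per-algorithm mean rank and standard error at one generation."""
        ranks = self.rank_matrix(generation)
        return ranks.mean(axis=0), standard_error(ranks, axis=0)

    def rank_trace(self) -> tuple[np.ndarray, np.ndarray]:
        """Mean rank and stderr per generation; shapes (C, G+1)."""
        ranks = stats.rankdata(self.mean_fitness, axis=0)  # over algorithms
        return ranks.mean(axis=1), standard_error(ranks, axis=1)

    # -- tidy exports -------------------------------------------------------

    def to_trace_frame(self) -> pd.DataFrame:
        """Tidy per-generation trace, including the shared burn-in rows
        (algorithm ``burn_in``, generations -burn..0, recorded under F)."""
        rows = []
        n_burn = self.burn_mean_fitness.shape[1]
        for rep in range(self.spec.replicates):
            for g in range(n_burn):
                rows.append(
                    (
                        "burn_in",
                        rep,
                        g - (n_burn - 1),
                        evolve.GLOBAL_F,
                        self.burn_mean_fitness[rep, g],
                        np.nan,
                        self.burn_mean_entropy[rep, g],
                    )
                )
        for a, alg in enumerate(self.algorithms):
            for rep in range(self.spec.replicates):
                for g in range(self.mean_fitness.shape[2]):
                    rows.append(
                        (
                            alg,
                            rep,
                            g,
                            evolve.TRAIT_F_PRIME,
                            self.mean_fitness[a, rep, g],
                            self.best_fitness[a, rep, g],
                            self.mean_entropy_trace[a, rep, g],
                        )
                    )
        return pd.DataFrame(
            rows,
            columns=[
                "algorithm",
                "replicate",
                "generation",
                "fitness_mode",
                "mean_fitness",
                "best_fitness",
                "mean_entropy",
            ],
        )

    def to_entropy_frame(self) -> pd.DataFrame:
        profile = self.final_entropy_profile()
        rows = [
            (alg, locus, profile[a, locus])
            for a, alg in enumerate(self.algorithms)
            for locus in range(profile.shape[1])
        ]
        return pd.DataFrame(rows, columns=["algorithm", "locus", "mean_entropy"])

    def to_rank_frame(self) -> pd.DataFrame:
        means, errs = self.rank_trace()
        rows = [
            (g, alg, means[a, g], errs[a, g])
            for g in range(means.shape[1])
            for a, alg in enumerate(self.algorithms)
        ]
        return pd.DataFrame(rows, columns=["generation", "algorithm", "mean_rank", "stderr"])

    def manifest(self) -> dict:
        from dataclasses import asdict

        spec = asdict(self.spec)
        spec["algorithms"] = list(self.spec.algorithms)
        spec["params"]["grid_shape"] = (
            list(self.spec.params.grid_shape) if self.spec.params.grid_shape else None
        )
        return {
            "spec": spec,
            "landscape_seeds": list(self.landscape_seeds),
        }


def run_comparison(spec: ComparisonSpec, progress: bool = False) -> ComparisonResult:
    """Run the full matched comparison.

    Per replicate: draw a fresh landscape from a child seed, burn in once with
    the niching GA under F, then hand the identical population to every
    algorithm arm (independent RNG streams) for the configured generations
    under F'.
    """
    trait = spec.trait()
    algs = spec.algorithms
    C, R, G1 = len(algs), spec.replicates, spec.generations + 1
    mean_f = np.empty((C, R, G1))
    best_f = np.empty((C, R, G1))
    mean_h = np.empty((C, R, G1))
    profiles = np.empty((C, R, spec.n))
    hashes = np.empty((C, R), dtype=object)
    burn_f = np.empty((R, spec.burn_in + 1))
    burn_h = np.empty((R, spec.burn_in + 1))
    land_seeds = []
    master = np.random.SeedSequence(spec.master_seed)
    rep_seeds = master.spawn(R)
    for rep in range(R):
        land_ss, burn_ss, arms_ss = rep_seeds[rep].spawn(3)
        seed = int(land_ss.generate_state(1)[0] % (2**31))
        land_seeds.append(seed)
        landscape = NKLandscape.generate(spec.n, spec.k, seed)
        pop, burn_trace = run_burn_in(
            landscape, BurnInSpec(spec.burn_in), spec.params, burn_ss, record=True
        )
        burn_f[rep] = burn_trace.mean_fitness
        burn_h[rep] = burn_trace.mean_entropy
        arm_seeds = arms_ss.spawn(C)
        for a, alg in enumerate(algs):
            trace = run_replicate(
                landscape, trait, pop, alg, spec.params, spec.generations, arm_seeds[a]
            )
            mean_f[a, rep] = trace.mean_fitness
            best_f[a, rep] = trace.best_fitness
            mean_h[a, rep] = trace.mean_entropy
            profiles[a, rep] = trace.final_entropy_profile
            hashes[a, rep] = trace.start_hash
        if progress:
            print(f"replicate {rep + 1}/{R} done", flush=True)
        logger.info("replicate %d/%d complete", rep + 1, R)
    return ComparisonResult(
        spec=spec,
        algorithms=algs,
        mean_fitness=mean_f,
        best_fitness=best_f,
        mean_entropy_trace=mean_h,
        entropy_profiles=profiles,
        start_hashes=hashes,
        landscape_seeds=tuple(land_seeds),
        burn_mean_fitness=burn_f,
        burn_mean_entropy=burn_h,
    )


# ---------------------------------------------------------------------------
# search-space bookkeeping


@dataclass(frozen=True)
class SearchSpaceReport:
    """Cardinality of a sequence space as mantissa x 10^exponent, plus the
    physical area a one-spot-per-sequence microarray would cover."""

    alphabet_size: int
    length: int
    mantissa: float
    exponent: int
    area_km2: Optional[float] = None


def search_space_report(
    alphabet_size: int,
    length: int,
    spot_side_um: Optional[float] = None,
) -> SearchSpaceReport:
    """Size of the space of all ``length``-mers over ``alphabet_size`` letters.

    Cardinality is computed through logarithms as an exact mantissa/decimal
    exponent decomposition.  With ``spot_side_um`` given, each sequence is
    assigned one square grid cell of that side and the total array area is
    reported in km^2 at two significant figures.
    """
    if alphabet_size < 2 or length < 1:
        raise InvalidParameterError("need alphabet_size >= 2 and length >= 1")
    log10_card = length * np.log10(alphabet_size)
    exponent = int(np.floor(log10_card))
    mantissa = float(10 ** (log10_card - exponent))
    area = None
    if spot_side_um is not None:
        spot_m = spot_side_um * 1e-6
        log10_area_m2 = log10_card + 2 * np.log10(spot_m)
        area_km2 = 10 ** (log10_area_m2 - 6)
        area = float(f"{area_km2:.2g}")
    return SearchSpaceReport(
        alphabet_size=alphabet_size,
        length=length,
        mantissa=mantissa,
        exponent=exponent,
        area_km2=area,
    )
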