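"""Modified NK fitness landscapes.

An NK landscape assigns each of ``N`` binary loci a fitness contribution drawn
from a random lookup table indexed by the locus's own allele together with the
alleles of ``K`` epistatic partner loci; total fitness ``F`` is the mean
contribution.  The "trait" modification weights a subset of ``r`` loci: their
mean realized contribution ``F_r`` is multiplied by ``F`` to give the breeding
objective ``F' = F_r * F``, and ``F'`` collapses to 0 whenever ``F`` falls
below a viability threshold ``F_th`` — modelling trait optimisation at the
expense of overall organismal fitness.

Conventions frozen for reproducibility:

* The epistasis table row for locus ``i`` lists ``i`` first, followed by its
  ``K`` partners drawn uniformly without replacement from the other loci.
* The ``(K+1)``-bit state indexing the fitness table reads the row in order
  with the focal locus as the most significant bit.
* One seed spawns two independent child streams (neighbour table, fitness
  table) so each can be regenerated separately.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import InvalidGenotypeError, InvalidParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "NKLandscape",
    "TraitConfig",
    "generate_landscape",
    "nk_fitness",
    "trait_fitness",
    "modified_fitness",
    "calibrate_threshold",
]


@dataclass(frozen=True)
class TraitConfig:
    """The ``r`` trait loci and the viability threshold ``F_th``.

    Parameters
    ----------
    trait_loci
        Ordered, distinct locus indices contributing to the trait. The default
        configuration uses the first ``r`` loci of the chromosome.
    f_th
        Viability threshold on the global fitness ``F``; genotypes with
        ``F < f_th`` have ``F' = 0``. Default 0.55.
    """

    trait_loci: tuple[int, ...]
    f_th: float = 0.55

    def __post_init__(self) -> None:
        loci = tuple(int(i) for i in self.trait_loci)
        object.__setattr__(self, "trait_loci", loci)
        if len(loci) < 1:
            raise InvalidParameterError("trait_loci must contain at least one locus")
        if len(set(loci)) != len(loci):
            raise InvalidParameterError("trait_loci must be distinct")
        if any(i < 0 for i in loci):
            raise InvalidParameterError("trait_loci must be non-negative")
        if not 0.0 <= self.f_th <= 1.0:
            raise InvalidParameterError("f_th must lie in [0, 1]")

    @classmethod
    def first_r(cls, r: int, n: int, f_th: float = 0.55) -> "TraitConfig":
        """Default trait: the first ``r`` of ``n`` loci."""
        if not 1 <= r <= n:
            raise InvalidParameterError(f"r must satisfy 1 <= r <= N; got r={r}, N={n}")
        return cls(trait_loci=tuple(range(r)), f_th=f_th)

    def validate_for(self, n: int) -> None:
        if max(self.trait_loci) >= n:
            raise InvalidParameterError(
                f"trait locus {max(self.trait_loci)} out of range for N={n}"
            )

    @property
    def r(self) -> int:
        return len(self.trait_loci)


@dataclass(frozen=True)
class NKLandscape:
    """A seeded NK landscape: epistasis map plus per-locus fitness tables.

    Attributes
    ----------
    n, k : int
        Chromosome length and epistasis order (each locus interacts with
        ``k`` others).
    seed : int
        Master seed; regeneration from ``(n, k, seed)`` is bit-identical.
    neighbours : ndarray of shape (n, k+1)
        Row ``i`` lists locus ``i`` first, then its ``k`` epistatic partners.
    tables : ndarray of shape (n, 2**(k+1))
        Uniform [0, 1) fitness contributions, one column per sub-vector state.
    """

    n: int
    k: int
    seed: int
    neighbours: np.ndarray
    tables: np.ndarray

    @classmethod
    def generate(cls, n: int, k: int, seed: int) -> "NKLandscape":
        if n < 1:
            raise InvalidParameterError(f"N must be >= 1; got {n}")
        if not 0 <= k <= n - 1:
            raise InvalidParameterError(f"K must satisfy 0 <= K <= N-1; got K={k}, N={n}")
        ss_nbr, ss_tab = np.random.SeedSequence(seed).spawn(2)
        rng = np.random.default_rng(ss_nbr)
        neighbours = np.empty((n, k + 1), dtype=np.int64)
        neighbours[:, 0] = np.arange(n)
        loci = np.arange(n)
        for i in range(n):
            pool = np.delete(loci, i)
            neighbours[i, 1:] = rng.choice(pool, size=k, replace=False)
        tables = np.random.default_rng(ss_tab).random((n, 2 ** (k + 1)))
        neighbours.setflags(write=False)
        tables.setflags(write=False)
        return cls(n=n, k=k, seed=int(seed), neighbours=neighbours, tables=tables)

    # -- evaluation ---------------------------------------------------------

    @property
    def _powers(self) -> np.ndarray:
        # focal locus = most significant bit
        return 2 ** np.arange(self.k, -1, -1)

    def _as_matrix(self, genotypes) -> tuple[np.ndarray, bool]:
        arr = np.asarray(genotypes)
        single = arr.ndim == 1
        if single:
            arr = arr[None, :]
        if arr.ndim != 2 or arr.shape[1] != self.n:
            raise InvalidGenotypeError(
                f"genotype length must equal N={self.n}; got shape {arr.shape}"
            )
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise InvalidGenotypeError("alleles must all be 0 or 1")
        return arr.astype(np.uint8, copy=False), single

    def contributions(self, genotypes) -> np.ndarray:
        """Realized per-locus contributions ``f_i``, shape (M, n)."""
        arr, single = self._as_matrix(genotypes)
        states = arr[:, self.neighbours] @ self._powers  # (M, n)
        out = self.tables[np.arange(self.n)[None, :], states]
        return out[0] if single else out

    def fitness(self, genotypes):
        """Global fitness ``F``: mean contribution over all loci."""
        arr, single = self._as_matrix(genotypes)
        f = self.contributions(arr).mean(axis=1)
        return float(f[0]) if single else f

    def trait_fitness(self, genotypes, trait: TraitConfig):
        """Trait fitness ``F_r``: mean contribution over the trait loci."""
        trait.validate_for(self.n)
        arr, single = self._as_matrix(genotypes)
        c = self.contributions(arr)
        f = c[:, list(trait.trait_loci)].mean(axis=1)
        return float(f[0]) if single else f

    def modified_fitness(self, genotypes, trait: TraitConfig):
        """Thresholded trait objective ``F' = F_r * F`` (0 when ``F < F_th``)."""
        trait.validate_for(self.n)
        arr, single = self._as_matrix(genotypes)
        c = self.contributions(arr)
        f = c.mean(axis=1)
        fr = c[:, list(trait.trait_loci)].mean(axis=1)
        fp = np.where(f >= trait.f_th, fr * f, 0.0)
        return float(fp[0]) if single else fp

    # -- serialization ------------------------------------------------------

    def to_manifest(self) -> dict:
        """Seed-based manifest; regeneration by seed is canonical."""
        return {"n": self.n, "k": self.k, "seed": self.seed}

    @classmethod
    def from_manifest(cls, manifest: dict) -> "NKLandscape":
        return cls.generate(int(manifest["n"]), int(manifest["k"]), int(manifest["seed"]))

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_manifest(), indent=2) + "\n")

    @classmethod
    def load(cls, path) -> "NKLandscape":
        return cls.from_manifest(json.loads(Path(path).read_text()))

    def dump_tables(self, neighbours_path, tables_path) -> None:
        """Optional CSV dump of the lookup tables for inspection."""
        np.savetxt(neighbours_path, self.neighbours, fmt="%d", delimiter=",")
        np.savetxt(tables_path, self.tables, delimiter=",")


def generate_landscape(n: int, k: int, seed: int) -> NKLandscape:
    """Generate a seeded NK landscape (see :meth:`NKLandscape.generate`)."""
    return NKLandscape.generate(n, k, seed)


def nk_fitness(landscape: NKLandscape, genotype) -> float:
    """Global fitness ``F`` of a single genotype."""
    return landscape.fitness(genotype)


def trait_fitness(landscape: NKLandscape, trait: TraitConfig, genotype) -> float:
    """Trait fitness ``F_r`` of a single genotype."""
    return landscape.trait_fitness(genotype, trait)


def modified_fitness(landscape: NKLandscape, trait: TraitConfig, genotype) -> float:
    """Thresholded trait objective ``F'`` of a single genotype."""
    return landscape.modified_fitness(genotype, trait)


def calibrate_threshold(
    landscape: NKLandscape,
    trait: TraitConfig,
    population,
    survivor_fraction: float = 0.01,
    grid_step: float = 0.05,
) -> float:
    """Largest grid threshold keeping at least ``survivor_fraction`` viable.

    Scans ``t in {0, grid_step, 2*grid_step, ...} <= 1`` and returns the largest
    ``t`` such that the fraction of the population with ``F >= t`` is at least
    ``survivor_fraction`` (the same ``>=`` survival rule the thresholded
    objective uses). Returns 0 with a warning when no positive grid value
    qualifies. Default runs use the fixed constant 0.55 instead; this is
    optional tooling.
    """
    arr, _ = landscape._as_matrix(population)
    if arr.shape[0] == 0:
        raise InvalidParameterError("population must be non-empty")
    if not 0.0 < survivor_fraction <= 1.0:
        raise InvalidParameterError("survivor_fraction must lie in (0, 1]")
    if not 0.0 < grid_step < 1.0:
        raise InvalidParameterError("grid_step must lie in (0, 1)")
    f = landscape.fitness(arr)
    n_steps = int(np.floor(1.0 / grid_step + 1e-9))
    grid = np.arange(n_steps + 1) * grid_step
    best = None
    for t in grid:
        if (f >= t).mean() >= survivor_fraction:
            best = float(t)
    if best is None or best == 0.0:
        logger.warning(
            "no positive threshold keeps a fraction %.3g of the population viable; "
            "returning 0",
            survivor_fraction,
        )
        return 0.0
    return best
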