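"""Run configuration (YAML/JSON), validation, and plain-text genotype I/O."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .errors import ConfigError, InvalidGenotypeError
from .evolve import EvolutionParams
from .experiment import ALGORITHMS, ComparisonSpec

__all__ = ["RunConfig", "load_config", "save_config", "save_genotypes", "load_genotypes"]


@dataclass
class RunConfig:
    """Validated experiment configuration with the standard defaults
    (lambda=1000, p_m=1/N, p_c=0.7, t_size=10, T_q=5; burn-in 20,
    70 generations, 100 replicates)."""

    n: int = 100
    k: int = 5
    r: int = 10
    f_th: float = 0.55
    lam: int = 1000
    p_m: Optional[float] = None  # None resolves to 1/N
    p_c: float = 0.7
    t_size: int = 10
    t_q: int = 5
    burn_in: int = 20
    generations: int = 70
    replicates: int = 100
    algorithms: tuple[str, ...] = tuple(ALGORITHMS)
    master_seed: int = 0
    outdir: str = "results"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        checks = [
            ("n", self.n >= 1),
            ("k", 0 <= self.k <= self.n - 1),
            ("r", 1 <= self.r <= self.n),
            ("f_th", 0.0 <= self.f_th <= 1.0),
            ("lam", self.lam >= 1),
            ("p_m", self.p_m is None or 0.0 <= self.p_m <= 1.0),
            ("p_c", 0.0 <= self.p_c <= 1.0),
            ("t_size", self.t_size >= 1),
            ("t_q", self.t_q >= 1),
            ("burn_in", self.burn_in >= 0),
            ("generations", self.generations >= 0),
            ("replicates", self.replicates >= 1),
            ("log_level", self.log_level in ("DEBUG", "INFO", "WARNING", "ERROR")),
        ]
        for name, ok in checks:
            if not ok:
                raise ConfigError(f"invalid value for '{name}': {getattr(self, name)!r}")
        self.algorithms = tuple(self.algorithms)
        unknown = [a for a in self.algorithms if a not in ALGORITHMS]
        if unknown:
            raise ConfigError(f"invalid value for 'algorithms': unknown {unknown}")

    @property
    def resolved_p_m(self) -> float:
        return 1.0 / self.n if self.p_m is None else self.p_m

    def to_params(self) -> EvolutionParams:
        return EvolutionParams(
            lam=self.lam,
            p_m=self.p_m,
            p_c=self.p_c,
            t_size=self.t_size,
            target_niches=self.t_q,
        )

    def to_comparison_spec(self, master_seed: Optional[int] = None) -> ComparisonSpec:
        return ComparisonSpec(
            n=self.n,
            k=self.k,
            r=self.r,
            f_th=self.f_th,
            algorithms=self.algorithms,
            replicates=self.replicates,
            burn_in=self.burn_in,
            generations=self.generations,
            params=self.to_params(),
            master_seed=self.master_seed if master_seed is None else master_seed,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["algorithms"] = list(self.algorithms)
        return d


def load_config(path) -> RunConfig:
    """Load and validate a YAML (or JSON-subset) run configuration.

    Unspecified fields fall back to the defaults; every validation failure
    names the offending field.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping; got {type(data).__name__}")
    known = {f.name for f in fields(RunConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigError(f"unknown config field(s): {unknown}")
    return RunConfig(**data)


def save_config(config: RunConfig, path) -> None:
    """Write a config that round-trips identically through :func:`load_config`."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def save_genotypes(path, population: np.ndarray) -> None:
    """Dump genotypes as '0'/'1' strings, one individual per line."""
    pop = np.asarray(population, dtype=np.uint8)
    lines = ["".join(str(int(b)) for b in row) for row in np.atleast_2d(pop)]
    Path(path).write_text("\n".join(lines) + "\n")


def load_genotypes(path) -> np.ndarray:
    """Read a plain-text genotype dump back into a (lambda, N) uint8 array."""
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise InvalidGenotypeError(f"no genotypes found in {path}")
    if len({len(ln) for ln in lines}) != 1:
        raise InvalidGenotypeError("genotype lines have unequal lengths")
    if set("".join(lines)) - {"0", "1"}:
        raise InvalidGenotypeError("genotype lines must contain only '0' and '1'")
    return np.array([[int(c) for c in ln] for ln in lines], dtype=np.uint8)
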