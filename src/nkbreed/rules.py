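"""AQ-style rule induction and the EARL rule-guided steppers.

Each generation the learner stratifies the population into the top and bottom
20% by fitness, then induces conjunctive ``locus = allele`` rules that hold in
the high stratum (H) but not the low stratum (L), via a transparent AQ-family
separate-and-conquer procedure: seed an uncovered H genotype, beam-search
conjunctions of the seed's alleles that minimise L-coverage and maximise
H-coverage, emit the first conjunction whose L-coverage is within tolerance,
mark its H matches covered, and repeat.  Rules may cover only part of H and
an empty rule set is a legal outcome.

EARL1 restricts both parents of each offspring to the sub-population ``s``
matching a selected rule (preserving discovered regularities); EARL2 draws
the second recombination parent from the complement of ``s`` (deliberately
disrupting them to probe epistatic interactions).  Rules are retrained every
generation and a rule is drawn independently per offspring, weighted by its
abundance in the top stratum.  Whenever no rules exist or a pool is empty,
selection degrades gracefully to plain tournament selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import EmptyRuleSetError, InvalidParameterError
from .evolve import RunState, _tournament_batch

__all__ = [
    "AttributionalRule",
    "RuleSet",
    "TrainingStrata",
    "extract_training_sets",
    "induce_rules",
    "rule_matches",
    "match_matrix",
    "select_rule",
    "step_earl",
    "step_earl1",
    "step_earl2",
]


@dataclass(frozen=True)
class AttributionalRule:
    """A conjunction of ``(locus, allele)`` conditions with coverage counts."""

    conditions: tuple[tuple[int, int], ...]
    h_coverage: int
    l_coverage: int
    top_abundance: int = 0

    def __post_init__(self) -> None:
        if len(self.conditions) == 0:
            raise InvalidParameterError("a rule must have at least one condition")
        loci = [c[0] for c in self.conditions]
        if len(set(loci)) != len(loci):
            raise InvalidParameterError("rule conditions must use distinct loci")
        if self.h_coverage < 1:
            raise InvalidParameterError("an emitted rule must cover >= 1 H member")


@dataclass
class RuleSet:
    """Ordered rules induced at one generation; may be empty."""

    rules: list[AttributionalRule] = field(default_factory=list)
    generation_trained: int = -1

    def __len__(self) -> int:
        return len(self.rules)

    def __bool__(self) -> bool:
        return bool(self.rules)

    def to_json(self) -> str:
        payload = {
            "generation_trained": self.generation_trained,
            "rules": [
                {
                    "conditions": [[int(l), int(a)] for l, a in r.conditions],
                    "h_coverage": r.h_coverage,
                    "l_coverage": r.l_coverage,
                    "top_abundance": r.top_abundance,
                }
                for r in self.rules
            ],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RuleSet":
        payload = json.loads(text)
        rules = [
            AttributionalRule(
                conditions=tuple((int(l), int(a)) for l, a in r["conditions"]),
                h_coverage=int(r["h_coverage"]),
                l_coverage=int(r["l_coverage"]),
                top_abundance=int(r.get("top_abundance", 0)),
            )
            for r in payload["rules"]
        ]
        return cls(rules=rules, generation_trained=int(payload["generation_trained"]))


@dataclass
class TrainingStrata:
    """Top (H) and bottom (L) fitness strata of one population."""

    h_set: np.ndarray
    l_set: np.ndarray


def extract_training_sets(
    population: np.ndarray,
    fitnesses: np.ndarray,
    top_fraction: float = 0.2,
    bottom_fraction: float = 0.2,
) -> TrainingStrata:
    """H = top and L = bottom fitness strata (floor(fraction * lambda) each).

    Ties at stratum boundaries are broken by index order: a stable descending
    sort puts lower indices first among equals, so with all fitnesses equal H
    is the first 20% and L the last 20% by index.
    """
    pop = np.asarray(population, dtype=np.uint8)
    f = np.asarray(fitnesses, dtype=float)
    lam = pop.shape[0]
    if lam < 10:
        raise InvalidParameterError(
            f"population size must be >= 10 for 20% strata; got {lam}"
        )
    m_top = int(np.floor(top_fraction * lam))
    m_bot = int(np.floor(bottom_fraction * lam))
    order = np.argsort(-f, kind="stable")
    return TrainingStrata(h_set=pop[order[:m_top]].copy(), l_set=pop[order[-m_bot:]].copy())


def rule_matches(rule: AttributionalRule, genotype) -> bool:
    """True iff every condition's allele equals the genotype at that locus."""
    g = np.asarray(genotype)
    for locus, allele in rule.conditions:
        if locus >= g.shape[-1]:
            raise InvalidParameterError(
                f"rule locus {locus} out of range for genotype of length {g.shape[-1]}"
            )
        if g[locus] != allele:
            return False
    return True


def match_matrix(ruleset: RuleSet, population: np.ndarray) -> np.ndarray:
    """Boolean (n_rules, lambda) matrix of rule satisfaction."""
    pop = np.asarray(population, dtype=np.uint8)
    out = np.ones((len(ruleset), pop.shape[0]), dtype=bool)
    for i, rule in enumerate(ruleset.rules):
        for locus, allele in rule.conditions:
            out[i] &= pop[:, locus] == allele
    return out


def induce_rules(
    strata: TrainingStrata,
    beam_width: int = 5,
    max_conditions: int = 5,
    max_rules: int = 20,
    l_tolerance: int = 0,
    generation: int = -1,
) -> RuleSet:
    """Separate-and-conquer induction of H-not-L rules.

    For each uncovered H seed, grows conjunctions of the seed's own alleles by
    beam search, scoring candidates lexicographically (fewest L matches, then
    most H matches, then lowest locus).  The first conjunction with L-coverage
    at most ``l_tolerance`` is emitted and its H matches marked covered; a
    seed from which no such conjunction exists within ``max_conditions`` is
    skipped.  Stops when H is covered, no seeds remain, or ``max_rules`` is
    reached.  An empty rule set is returned when no separating regularity
    exists (e.g. H identical to L).
    """
    H = np.asarray(strata.h_set, dtype=np.uint8)
    L = np.asarray(strata.l_set, dtype=np.uint8)
    if H.size == 0 or L.size == 0:
        raise InvalidParameterError("both strata must be non-empty")
    h, n = H.shape
    rules: list[AttributionalRule] = []
    covered = np.zeros(h, dtype=bool)
    while not covered.all() and len(rules) < max_rules:
        seed_row = int(np.argmin(covered))
        seed = H[seed_row]
        Hm = H == seed  # (h, n): which H members share the seed allele per locus
        Lm = L == seed
        # beam items: (ordered loci tuple, H match mask, L match mask)
        beam: list[tuple[tuple[int, ...], np.ndarray, np.ndarray]] = [
            ((), np.ones(h, dtype=bool), np.ones(L.shape[0], dtype=bool))
        ]
        emitted: Optional[tuple[tuple[int, ...], int, int]] = None
        for _depth in range(max_conditions):
            candidates: list[tuple[int, int, int, tuple[int, ...], int]] = []
            for loci, hm, lm in beam:
                h_cov = (hm[:, None] & Hm).sum(axis=0)  # (n,)
                l_cov = (lm[:, None] & Lm).sum(axis=0)
                for locus in range(n):
                    if locus in loci:
                        continue
                    if h_cov[locus] < 1:
                        continue
                    candidates.append(
                        (int(l_cov[locus]), -int(h_cov[locus]), locus, loci, seed_row)
                    )
            if not candidates:
                break
            candidates.sort()
            best_l, neg_h, locus, parent, _ = candidates[0]
            if best_l <= l_tolerance:
                emitted = (parent + (locus,), -neg_h, best_l)
                break
            seen: set[tuple[int, ...]] = set()
            new_beam = []
            for l_cov, neg_h_cov, locus, parent, _ in candidates:
                loci = parent + (locus,)
                key = tuple(sorted(loci))
                if key in seen:
                    continue
                seen.add(key)
                parent_item = next(b for b in beam if b[0] == parent)
                new_beam.append(
                    (loci, parent_item[1] & Hm[:, locus], parent_item[2] & Lm[:, locus])
                )
                if len(new_beam) >= beam_width:
                    break
            beam = new_beam
        if emitted is None:
            covered[seed_row] = True  # seed inseparable from L; skip it
            continue
        loci, h_cov, l_cov = emitted
        conditions = tuple((locus, int(seed[locus])) for locus in loci)
        rule = AttributionalRule(
            conditions=conditions,
            h_coverage=h_cov,
            l_coverage=l_cov,
            top_abundance=h_cov,
        )
        rules.append(rule)
        rule_mask = np.ones(h, dtype=bool)
        for locus, allele in conditions:
            rule_mask &= H[:, locus] == allele
        newly = rule_mask & ~covered
        if not newly.any():
            covered[seed_row] = True  # safeguard against stalling
        covered |= rule_mask
    return RuleSet(rules=rules, generation_trained=generation)


def select_rule(
    ruleset: RuleSet,
    top_members: np.ndarray,
    rng: np.random.Generator,
) -> AttributionalRule:
    """Draw a rule with probability proportional to its match count among the
    top stratum (uniform when all counts are zero)."""
    if not ruleset:
        raise EmptyRuleSetError("cannot select from an empty rule set")
    counts = match_matrix(ruleset, top_members).sum(axis=1).astype(float)
    total = counts.sum()
    p = None if total == 0 else counts / total
    i = rng.choice(len(ruleset), p=p)
    return ruleset.rules[int(i)]


def _rule_weights(ruleset: RuleSet, top_members: np.ndarray) -> np.ndarray:
    counts = match_matrix(ruleset, top_members).sum(axis=1).astype(float)
    total = counts.sum()
    if total == 0:
        return np.full(len(ruleset), 1.0 / len(ruleset))
    return counts / total


def step_earl(state: RunState, variant: int) -> RunState:
    """One EARL generation: retrain rules, then build lambda offspring with
    rule-restricted mating pools and generational replacement.

    variant 1: both parents from the rule-matching pool ``s``.
    variant 2: second recombination parent from the complement of ``s``
    (falling back to ``s`` when the complement is empty).
    """
    if variant not in (1, 2):
        raise InvalidParameterError(f"variant must be 1 or 2; got {variant}")
    p = state.params
    pop = state.population
    lam, n = pop.shape
    strata = extract_training_sets(
        pop, state.fitness, p.top_fraction, p.bottom_fraction
    )
    ruleset = induce_rules(
        strata,
        beam_width=p.rule_beam_width,
        max_conditions=p.rule_max_conditions,
        max_rules=p.rule_max_rules,
        l_tolerance=p.rule_l_tolerance,
        generation=state.generation,
    )
    audit: dict = {
        "generation": state.generation,
        "n_rules": len(ruleset),
        "empty_pool_fallbacks": 0,
        "complement_fallbacks": 0,
    }
    if not ruleset:
        # exact fallback: this generation is a plain standard-GA step
        from .evolve import _ga_offspring

        offspring = _ga_offspring(state, state.fitness)
        audit["rule_index"] = None
    else:
        matches = match_matrix(ruleset, pop)
        weights = _rule_weights(ruleset, strata.h_set)
        rules_rng = state.streams["rules"]
        sel = state.streams["selection"]
        var = state.streams["variation"]
        rule_idx = rules_rng.choice(len(ruleset), size=lam, p=weights)
        recombine = sel.random(lam) < p.p_c
        p1 = np.empty(lam, dtype=np.int64)
        p2 = np.empty(lam, dtype=np.int64)
        for k in np.unique(rule_idx):
            rows = np.flatnonzero(rule_idx == k)
            pool = np.flatnonzero(matches[k])
            if pool.size == 0:
                pool = None  # unrestricted tournament fallback
                audit["empty_pool_fallbacks"] += int(rows.size)
            p1[rows] = _tournament_batch(state.fitness, p.t_size, sel, rows.size, pool)
            if variant == 1:
                pool2 = pool
            else:
                complement = np.flatnonzero(~matches[k]) if pool is not None else None
                if complement is not None and complement.size > 0:
                    pool2 = complement
                else:
                    pool2 = pool  # degrade to variant-1 behaviour
                    audit["complement_fallbacks"] += int(rows.size)
            p2[rows] = _tournament_batch(state.fitness, p.t_size, sel, rows.size, pool2)
        offspring = pop[p1].copy()
        mask = var.random((lam, n)) < 0.5
        r = recombine
        offspring[r] = np.where(mask[r], pop[p1][r], pop[p2][r])
        flips = var.random((lam, n)) < p.resolve_p_m(n)
        offspring ^= flips.astype(np.uint8)
        audit.update(
            rule_index=rule_idx, recombine=recombine, parent1=p1, parent2=p2,
            ruleset=ruleset,
        )
    state.population = offspring
    state.fitness = state.evaluate(offspring)
    state.generation += 1
    state.earl_audit = audit
    return state


def step_earl1(state: RunState) -> RunState:
    return step_earl(state, 1)


def step_earl2(state: RunState) -> RunState:
    return step_earl(state, 2)
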