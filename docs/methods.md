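# Methods

`nkbreed` is an in silico testbed for asking a molecular-breeding question:
when every organism in a breeding population can be genotyped, do selection
algorithms that exploit genotype knowledge (G-algorithms) outperform
well-tuned algorithms that see only phenotypic fitness (F-algorithms)?  The
package provides the landscape model, six algorithms, and the comparison
protocol; this note records the model, its assumptions, and the design
choices made where the design was genuinely open.

## The modified NK landscape

Each individual is a binary chromosome of length `N`.  Locus `i` contributes
a fitness `f_i` read from a random lookup table indexed by the alleles of the
locus itself and `K` epistatic partners (drawn uniformly without replacement
per locus); the global fitness is the mean contribution,

    F(g) = (1/N) * sum_i f_i(g restricted to the neighbours of i),

with `f_i ~ Uniform[0, 1)` per state.  `K` tunes ruggedness: `K = 0` is a
separable landscape with a trivially locatable optimum; larger `K` couples
loci the way metabolic and regulatory networks couple genes.

Breeding targets a *trait*, not global fitness.  The trait is carried by `r`
designated loci (the first `r` by default), and the trait fitness is their
mean realized contribution,

    F_r(g) = (1/r) * sum_{i in trait loci} f_i(...)   in [0, 1].

The breeding objective is the product `F' = F_r * F`, and `F'` collapses to 0
whenever `F < F_th` (default 0.55): optimising a trait at the expense of
overall viability is fatal.  The `>=` side of the threshold survives.

Frozen conventions (any fixed choice works; these are documented so runs
reproduce): the `(K+1)`-bit table index reads the neighbour row in order with
the focal locus as the most significant bit; one landscape seed spawns two
child streams (neighbour table, fitness table) so either can be regenerated
alone.

`calibrate_threshold` is optional tooling that scans the grid
`t = i * grid_step` for the largest `t` keeping at least a `survivor_fraction`
of a population viable.  Note the grid points are literal floats, so e.g. the
12th point of a 0.05 grid is `0.6000000000000001` and a population fitness of
exactly 0.6 narrowly fails it; ties at grid points are measure-zero for real
landscapes.  Default runs use the fixed constant 0.55.

## The six algorithms

All use a constant population size `lambda`, per-bit mutation rate
`p_m = 1/N` by default, and generational replacement.  Defaults (tuned
settings): `lambda = 1000`, `p_c = 0.7`, `t_size = 10`, `T_q = 5`.

**Breeder (1+lambda)** (F): every offspring is a mutated clone of the single
fittest individual; the champion is retained unless strictly beaten.  Models
classical truncation breeding; expected to gain quickly and converge
prematurely.

**Standard GA** (F): non-elitist generational GA.  Each offspring recombines
two tournament-selected parents (uniform crossover, probability `p_c`) or
clones one (probability `1 - p_c`); mutation applies to all.

**Local mating** (F): the population sits on a toroidal grid (most-square
factorization of `lambda`, e.g. 1000 -> 25x40).  Cell `i` mates with the
winner of a `t_size`-tournament sampled with replacement from the 24 cells of
the surrounding 5x5 square (focal cell excluded; the clone path also draws
from that pool) and the offspring replaces `i` in place.  Spatial structure
slows takeover and preserves diversity.

**Niching GA** (G): genotypic fitness sharing.  The niche count `n_c` of an
individual is itself plus all others within Hamming distance `n_r`; selection
acts on `f_share = 10 f / (9 + n_c)`, so an isolated individual keeps its raw
fitness (`n_c = 1` implies `f_share = f` — this identity is why the count
includes self despite the looser "other individuals" phrasing in the
literature).  Sharing is computed exactly over the population (O(lambda^2)
Hamming via a matrix product); a sampled estimator is available for very
large `lambda`.  The radius is dynamic: each generation the niche number `q`
is estimated by greedy leader clustering of a 50-member sample (a sampled
genotype joins the first leader within `n_r`, else founds one), and `n_r`
moves by +/-1 toward the target `T_q = 5` (more niches than target -> widen
to merge, fewer -> narrow), clamped to `[1, N]`, starting from
`max(1, N/10)`.  The +/-1 rule and the initial radius are our choices; the
protocol fixes only "adjust toward a target niche count".

**EARL1 / EARL2** (G): rule-guided evolution in the spirit of learnable
evolution models.  Each generation the population is stratified into the top
and bottom 20% by fitness and an AQ-family separate-and-conquer learner
induces conjunctive `locus = allele` rules that hold in the top stratum but
not the bottom: seed an uncovered top genotype, beam-search (width 5)
conjunctions of the seed's alleles scored lexicographically (fewest
bottom-stratum matches, then most top-stratum matches), emit the first
conjunction with bottom-coverage within tolerance (default 0, at most 5
conditions, at most 20 rules), mark its matches covered, repeat.  Inseparable
seeds are skipped; an empty rule set is legal.  The learner is a transparent
reimplementation of the AQ *contract* (strong H-not-L regularities, possibly
incomplete), not of any particular AQ software's internals.

For each offspring a rule is drawn with probability proportional to its match
count in the top stratum (uniform when all counts are zero) and the matching
sub-population `s` forms the mating pool: EARL1 draws both parents from `s`
(preserving discovered regularities), EARL2 draws the second recombination
parent from the complement of `s` (deliberately disrupting them, on the
hypothesis that breaking cooperative loci reaches new basins).  Rules are
retrained every generation; selection is per offspring.  Fallbacks: no rules
-> the generation is exactly a standard-GA step; empty pool -> unrestricted
tournament; empty complement -> EARL2 degrades to EARL1 for that offspring.
Fallback counts are recorded in the per-generation audit.

### Tie-breaking

Tournament ties go to the first-sampled contender.  This is deterministic
under replay and uniform among tied members because the draw order is random.
(Breaking ties by lowest population index instead is subtly catastrophic: any
population containing two genotypes of exactly equal fitness systematically
routes every tied tournament to the lower-indexed cluster, which eliminates
the other cluster within a couple of generations.)

## The comparison protocol

Per replicate: draw a fresh landscape from a child seed; initialize `lambda`
uniform random genotypes; run the *niching GA on the unmodified global
fitness F* for the burn-in period (default 20 generations) — this "warm
start" yields a genetically diverse, moderately fit stock resembling a real
breeding trial (measured at the default scaled conditions: mean F rises
~0.50 -> ~0.55 while mean entropy stays ~0.9 bits); then hand the identical
population to every algorithm arm and run each for 70 further generations
under `F'`.  Arms share the starting population (verified by hashing) but
evolve on independent RNG streams, all derived from one master seed by
`SeedSequence` spawning; runs are byte-identical under replay.

Recorded per generation and arm: mean and best active-mode fitness and mean
per-locus Shannon entropy (base 2; 0 bits monomorphic, 1 bit at 50/50 — the
base is our choice).  At the final generation the full per-locus entropy
profile is kept and averaged locus-wise over replicates.  Algorithms are
ranked within each replicate by mean population fitness (1 = lowest .. C =
highest, mean rank for ties, via `scipy.stats.rankdata`); rank curves are
averaged over replicates with +/-1 standard error (`stdev/sqrt(n)`).  Ranks
are computed per generation; the final generation is the headline number.

Exports are tidy CSVs (trace, entropy profile, rank) plus a JSON manifest of
the full specification and all derived landscape seeds.  Burn-in rows appear
in the trace under the pseudo-algorithm `burn_in` with generations
`-burn..0` and mode `global_F`, making the fitness discontinuity at the
objective switch (F -> F') visible in plots.

## Problem sizes

The default specification is the full protocol (lambda = 1000, 100
replicates, burn-in 20, 70 generations).  The package's own acceptance runs
use a scaled-down profile — N = 100, K = 5, r = 10, lambda = 200, 20
replicates — chosen so the whole comparison completes in a few minutes on one
CPU while preserving every qualitative contrast between the algorithms; the
full profile is supported unchanged.

## What the testbed does and does not emulate

The generator produces haploid, single-chromosome, biallelic genomes with
uniform random epistasis and a uniform random initial gene pool.  It captures
epistatic ruggedness, trait/viability tension, and the population-genetic
dynamics of selection schemes.  It does not model diploidy, linkage or
recombination-rate maps, multi-allelic loci, structured epistasis from real
pathways, environmental variance, or multi-objective trait sets — so passing
tests demonstrate algorithmic behaviour on the model class, not predictions
for any particular crop.

## Numerical and degenerate-input notes

* Genotype matrices are `uint8`; fitness evaluation is a table gather after
  an integer matrix product (no floating-point accumulation issues at these
  sizes; the literal-evaluator oracle agrees to 1e-12).
* Early under `F'`, most individuals score exactly 0; tournaments among
  all-zero contenders resolve by the first-sampled rule above.
* `estimate_niche_count` samples without replacement (whole population when
  `lambda <= sample`); the sampled niche-count estimator rescales raw
  within-radius counts by `lambda/sample` and floors at 1.
* A (1+lambda) population of mutated champion clones has an irreducible
  entropy floor: each locus is binomially perturbed with rate `p_m`, giving
  `E[H] ≈ E[H(Bin(lambda, p_m)/lambda)]` — about 0.075 bits at
  `lambda = 200, p_m = 0.01`.  "Near-zero" breeder entropy means this floor,
  not 0.

## Known limitations

* The dynamic niche radius is a coarse integer controller; at small
  population sizes the niching GA holds diversity so well that it remains
  the lowest-ranked algorithm on mean `F'` through generation 70 (its mean
  entropy stays ~0.8 bits).  Larger populations and longer runs let it begin
  converging.
* The AQ-style learner is deliberately minimal (pure conjunctions over
  binary loci); it does not implement internal disjunctions, ranges, or
  exception handling.
* Exact sharing is O(lambda^2) per generation; use the sampled mode beyond
  lambda ~ 10^4.
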