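# nkbreed

An in silico testbed for molecular breeding programmes: when every organism
in a breeding population can be cheaply sequenced, does knowing the genotypes
buy you anything over well-tuned phenotype-only selection?

`nkbreed` answers this experimentally on synthetic genetics.  It implements a
trait-weighted, threshold-modified **NK fitness landscape** and six
evolutionary algorithms — three *F-algorithms* that see only fitness
(breeder (1+λ), standard GA, local mating) and three *G-algorithms* that also
exploit genotypes (niching GA with genotypic fitness sharing, and the
rule-learning EARL1/EARL2) — together with the burn-in protocol and the
fitness / rank / Shannon-entropy harness needed to compare them on matched
replicate landscapes.  It is aimed at quantitative geneticists and
evolutionary-computation researchers studying breeding-programme design.

## The model

A genome is a binary chromosome of length *N*.  Global fitness is the mean of
per-locus contributions, each read from a random lookup table indexed by the
locus and *K* epistatic partners:

    F(g) = (1/N) Σᵢ fᵢ(g restricted to the neighbours of i),  fᵢ ∈ [0, 1)

The breeder targets a trait carried by *r* designated loci with trait fitness
*F_r* = mean contribution of those loci.  The breeding objective is

    F′ = F_r · F     if F ≥ F_th     (else F′ = 0, default F_th = 0.55)

modelling trait optimisation at the expense of organismal viability.  Each
comparison replicate burns in a random population with the niching GA on the
unmodified *F* (a diverse, moderately fit "breeding stock"), then hands the
identical population to all six algorithms for 70 generations under *F′*.
Performance is summarised by mean fitness, tie-adjusted mean fitness ranks
(1 = worst … C = best, ±1 standard error = stdev/√n), and per-locus Shannon
entropy in bits.  See `docs/methods.md` for the full account.

## Worked example

```python
import nkbreed as nb

L  = nb.generate_landscape(n=100, k=5, seed=42)
tc = nb.TraitConfig.first_r(10, 100)          # trait = first 10 loci, F_th = 0.55
g  = nb.init_population(100, 1, seed=0)[0]
print(f"F   = {nb.nk_fitness(L, g):.4f}")
print(f"F_r = {nb.trait_fitness(L, tc, g):.4f}")
print(f"F'  = {nb.modified_fitness(L, tc, g):.4f}")

spec = nb.ComparisonSpec(n=100, k=5, r=10, replicates=5, burn_in=20,
                         generations=70, params=nb.EvolutionParams(lam=200),
                         master_seed=7)
res = nb.run_comparison(spec)
means, errs = res.mean_ranks()
for alg, m, e in sorted(zip(res.algorithms, means, errs), key=lambda t: -t[1]):
    h = res.mean_entropy_trace[res.algorithms.index(alg), :, -1].mean()
    print(f"{alg:>12s}  rank {m:4.2f} +/- {e:4.2f}   entropy {h:.3f} bits")
```

prints

```
F   = 0.5077
F_r = 0.5228
F'  = 0.0000
 standard_ga  rank 4.40 +/- 0.40   entropy 0.076 bits
       earl1  rank 4.20 +/- 0.58   entropy 0.085 bits
       earl2  rank 4.00 +/- 0.71   entropy 0.076 bits
local_mating  rank 3.80 +/- 0.66   entropy 0.151 bits
     breeder  rank 3.60 +/- 0.98   entropy 0.076 bits
     niching  rank 1.00 +/- 0.00   entropy 0.816 bits
```

The random genotype has near-average global fitness (F ≈ 0.51) but sits below
the viability threshold, so its breeding objective is zero.  After 70
generations the rule learners (EARL1/2) are statistically indistinguishable
from the standard GA; the greedy breeder trails them; and the two
diversity-preserving strategies pay a fitness price for their diversity —
most visibly the niching GA, which keeps the population near-maximally
diverse (0.82 bits/locus vs ≈ 0.08 for the converged algorithms) and
therefore ranks last on mean F′ at this population size.

## Command line

```bash
nkbreed generate-landscape --n 100 --k 5 --seed 1 --out landscape.json
nkbreed run --algorithm standard_ga --n 100 --k 5 --generations 70 --lam 200 --out trace.csv
nkbreed compare --config experiment.yaml --seed 7 --outdir results/
nkbreed report --traces results/traces.csv --plot curves.png
```

`compare` writes tidy `traces.csv`, `entropy_profile.csv`, `ranks.csv`, and a
`manifest.json` sufficient to reproduce the run exactly; outputs are
byte-identical for a given master seed.  Configs are YAML; unspecified fields
fall back to the standard defaults (λ = 1000, p_m = 1/N, p_c = 0.7,
t_size = 10, T_q = 5, burn-in 20, 70 generations, 100 replicates).  Genotype
dumps are plain-text '0'/'1' strings, one individual per line (alleles are
bits, not nucleotides).

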