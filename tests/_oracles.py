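"""Independent reference implementations used as test oracles.

These deliberately walk the definitions literally and slowly; they must stay
independent of the vectorized code paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np

from nkbreed.landscape import NKLandscape


def naive_nk_fitness(neighbours, tables, genotype) -> float:
    """Literal evaluation of the NK definition: for each locus, read its
    sub-vector in row order (focal locus first = most significant bit), index
    the lookup table, and average."""
    total = 0.0
    for i in range(len(genotype)):
        idx = 0
        for locus in neighbours[i]:
            idx = idx * 2 + int(genotype[locus])
        total += tables[i][idx]
    return total / len(genotype)


def exhaustive_optimum(landscape: NKLandscape):
    """Best genotype and fitness by enumerating all 2^N strings (N small)."""
    best_g, best_f = None, -1.0
    for bits in itertools.product((0, 1), repeat=landscape.n):
        g = np.array(bits, dtype=np.uint8)
        f = landscape.fitness(g)
        if f > best_f:
            best_g, best_f = g, f
    return best_g, best_f


def construct_landscape(neighbours, tables, seed: int = 0) -> NKLandscape:
    """Assemble a landscape from explicitly written tables (for hand toys)."""
    neighbours = np.asarray(neighbours, dtype=np.int64)
    tables = np.asarray(tables, dtype=float)
    n, kp1 = neighbours.shape
    assert tables.shape == (n, 2 ** kp1)
    return NKLandscape(n=n, k=kp1 - 1, seed=seed, neighbours=neighbours, tables=tables)
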