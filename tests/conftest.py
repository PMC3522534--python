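"""Shared fixtures: small hand-built datasets and builders."""

from __future__ import annotations

import numpy as np
import pytest

from msatpop.genotype_io import Dataset, Grouping, Individual


def build_dataset(pop_genotypes: dict, loci=None, sexes: dict | None = None,
                  coords: dict | None = None) -> Dataset:
    """Dataset from {population: [[(a, b) per locus], ...]} literals."""
    individuals = []
    rows = []
    n_loci = len(next(iter(pop_genotypes.values()))[0])
    loci = loci or [f"L{j}" for j in range(n_loci)]
    for pop, inds in pop_genotypes.items():
        for k, g in enumerate(inds):
            sex = "unknown"
            if sexes and pop in sexes:
                sex = sexes[pop][k]
            individuals.append(Individual(id=f"{pop}-{k}", population=pop,
                                          sex=sex))
            rows.append(g)
    return Dataset(individuals, loci, np.array(rows), coords or {})


def random_dataset(rng: np.random.Generator, pops: dict[str, int],
                   n_loci: int = 2, n_alleles: int = 4,
                   freqs: dict | None = None) -> Dataset:
    """Random HWE dataset; optionally per-population allele frequencies."""
    individuals, rows = [], []
    for pop, n in pops.items():
        p = (freqs or {}).get(pop)
        for k in range(n):
            individuals.append(Individual(id=f"{pop}-{k}", population=pop))
            g = []
            for _ in range(n_loci):
                if p is None:
                    g.append(rng.integers(1, n_alleles + 1, size=2))
                else:
                    g.append(rng.choice(np.arange(1, len(p) + 1), size=2, p=p))
            rows.append(g)
    return Dataset(individuals, [f"L{j}" for j in range(n_loci)],
                   np.array(rows))


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_901)


@pytest.fixture
def two_pop_toy():
    """10 vs 10 individuals, one biallelic locus, p = 0.6 vs 0.3."""
    rng = np.random.default_rng(42)
    return random_dataset(rng, {"P1": 10, "P2": 10}, n_loci=1,
                          freqs={"P1": [0.6, 0.4], "P2": [0.3, 0.7]})
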