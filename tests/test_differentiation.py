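"""Weir-Cockerham theta and hierarchical F-statistics.

Independent oracles: the per-allele WC84 component formulas coded
directly, and balanced nested-ANOVA mean squares on allele-indicator
variables.
"""

from __future__ import annotations

import numpy as np
import pytest

from msatpop.differentiation import (fst_permutation_test, hierarchical_fstats,
                                     hierf_permutation_test, pairwise_theta,
                                     wc_fst)
from msatpop.genotype_io import Dataset, Grouping, Individual
from conftest import build_dataset, random_dataset


def wc84_components(groups):
    """Direct WC84 per-locus variance components (a, b, c) summed over
    alleles; ``groups`` is a list of (n_i, 2) allele arrays."""
    r = len(groups)
    n = np.array([g.shape[0] for g in groups], dtype=float)
    N = n.sum()
    nbar = N / r
    nc = (N - (n ** 2).sum() / N) / (r - 1)
    alleles = np.unique(np.concatenate([g.ravel() for g in groups]))
    A = B = C = 0.0
    for al in alleles:
        p = np.array([np.mean(g == al) for g in groups])
        h = np.array([np.mean((g == al).sum(axis=1) == 1) for g in groups])
        pbar = (n * p).sum() / N
        s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n * h).sum() / N
        a = (nbar / nc) * (s2 - (1 / (nbar - 1))
                           * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2
                                   - ((2 * nbar - 1) / (4 * nbar)) * hbar)
        A, B, C = A + a, B + b, C + hbar / 2
    return A, B, C


def direct_theta(ds):
    num = den = 0.0
    for li in range(ds.n_loci):
        groups = [ds.population_genotypes(p)[:, li, :] for p in ds.populations]
        groups = [g[g[:, 0] > 0] for g in groups]
        a, b, c = wc84_components(groups)
        num += a
        den += a + b + c
    return num / den


class TestWcFst:
    def test_fixed_differences_give_theta_one(self):
        ds = build_dataset({"A": [[(1, 1)]] * 6, "B": [[(2, 2)]] * 6})
        _, theta = wc_fst(ds)
        assert theta == pytest.approx(1.0)

    def test_same_fixation_is_undefined(self):
        ds = build_dataset({"A": [[(1, 1)]] * 4, "B": [[(1, 1)]] * 4})
        pw, theta = wc_fst(ds)
        assert np.isnan(theta) and np.isnan(pw.theta[0, 1])

    def test_matches_direct_wc84_formulas(self, two_pop_toy):
        _, theta = wc_fst(two_pop_toy)
        assert theta == pytest.approx(direct_theta(two_pop_toy), abs=1e-12)

    def test_matches_direct_wc84_unbalanced_multiallelic(self, rng):
        for _ in range(10):
            sizes = {f"P{k}": int(rng.integers(3, 12))
                     for k in range(rng.integers(2, 5))}
            ds = random_dataset(rng, sizes, n_loci=3, n_alleles=5)
            _, theta = wc_fst(ds)
            assert theta == pytest.approx(direct_theta(ds), abs=1e-12)

    def test_random_split_of_panmictic_sample_near_zero(self, rng):
        vals = []
        for s in range(200):
            ds = random_dataset(np.random.default_rng(s), {"X": 40},
                                n_loci=4, n_alleles=4)
            half = np.zeros(40, dtype=bool)
            half[np.random.default_rng(1000 + s).choice(40, 20, replace=False)] = True
            vals.append(pairwise_theta(ds, np.nonzero(half)[0],
                                       np.nonzero(~half)[0]))
        assert abs(np.mean(vals)) < 0.01

    def test_invariant_under_allele_relabeling_and_pop_order(self, rng):
        ds = random_dataset(rng, {"A": 10, "B": 8}, n_loci=2, n_alleles=4)
        _, theta = wc_fst(ds)
        relabeled = Dataset(list(ds.individuals), list(ds.loci),
                            10 * ds.genotypes + 3)
        _, theta2 = wc_fst(relabeled)
        assert theta2 == pytest.approx(theta, abs=1e-12)
        reordered = ds.subset(np.argsort([-i for i in range(ds.n_individuals)]))
        _, theta3 = wc_fst(reordered)
        assert theta3 == pytest.approx(theta, abs=1e-12)


class TestFstPermutation:
    def test_identical_duplicated_samples_not_significant(self, rng):
        block = random_dataset(rng, {"A": 12}, n_loci=3, n_alleles=4)
        geno = np.concatenate([block.genotypes, block.genotypes])
        inds = ([Individual(id=f"A{k}", population="A") for k in range(12)]
                + [Individual(id=f"B{k}", population="B") for k in range(12)])
        ds = Dataset(inds, block.loci, geno)
        pw = fst_permutation_test(ds, n_perm=300, seed=3)
        assert pw.p_values[0, 1] > 0.5

    def test_separated_populations_significant(self, rng):
        ds = random_dataset(rng, {"A": 15, "B": 15}, n_loci=3,
                            freqs={"A": [0.9, 0.1], "B": [0.1, 0.9]})
        pw = fst_permutation_test(ds, n_perm=500, seed=4)
        assert pw.p_values[0, 1] <= 0.01

    def test_minimum_permutations_enforced(self, two_pop_toy):
        with pytest.raises(ValueError):
            fst_permutation_test(two_pop_toy, n_perm=50)


def balanced_nested_anova_components(ds, region_of):
    """Mean-squares nested ANOVA oracle for a balanced regions > pops >
    individuals > genes design (one locus)."""
    y_all = ds.genotypes[:, 0, :]
    regs = np.array([region_of[i.population] for i in ds.individuals])
    pops = np.array([i.population for i in ds.individuals])
    R = np.unique(regs).size
    P = np.unique(pops).size // R
    NI = np.sum(pops == pops[0])
    comp = np.zeros(4)
    for al in np.unique(y_all):
        y = (y_all == al).astype(float)
        grand = y.mean()
        ssg = ((y - y.mean(axis=1, keepdims=True)) ** 2).sum()
        ssi = ssp = ssr = 0.0
        for rname in np.unique(regs):
            ym_r = y[regs == rname].mean()
            ssr += 2 * P * NI * (ym_r - grand) ** 2
            for pname in np.unique(pops[regs == rname]):
                sel = pops == pname
                ym_p = y[sel].mean()
                ssp += 2 * NI * (ym_p - ym_r) ** 2
                ssi += (2 * (y[sel].mean(axis=1) - ym_p) ** 2).sum()
        msg = ssg / (R * P * NI)
        msi = ssi / (R * P * (NI - 1))
        msp = ssp / (R * (P - 1))
        msr = ssr / (R - 1)
        comp += [(msr - msp) / (2 * NI * P), (msp - msi) / (2 * NI),
                 (msi - msg) / 2, msg]
    return comp


class TestHierarchical:
    def test_two_level_case_collapses_to_theta(self, rng):
        ds = random_dataset(rng, {"A": 9, "B": 7, "C": 11}, n_loci=3,
                            n_alleles=4)
        res = hierarchical_fstats(ds, [])
        _, theta = wc_fst(ds)
        assert res.f("populations", "total") == pytest.approx(theta, abs=1e-10)

    def test_components_match_balanced_anova_oracle(self, rng):
        region_of = {}
        pops = {}
        for r in range(2):
            for p in range(3):
                name = f"P{r}{p}"
                region_of[name] = f"R{r}"
                pops[name] = 5
        ds = random_dataset(rng, pops, n_loci=1, n_alleles=4,
                            freqs={name: ([.5, .3, .15, .05] if name.startswith("P0")
                                          else [.05, .15, .3, .5])
                                   for name in pops})
        res = hierarchical_fstats(ds, [Grouping("regions", region_of)])
        oracle = balanced_nested_anova_components(ds, region_of)
        assert np.allclose(res.components.iloc[0].to_numpy(), oracle,
                           atol=1e-10)

    def test_fully_homozygous_individuals_drive_f_ind_pop_to_one(self):
        # polymorphic populations of homozygotes: every gene pair within an
        # individual identical, so all within-population variance sits
        # between individuals (F_IS boundary)
        ds = build_dataset({
            "A": [[(1, 1), (5, 5)]] * 4 + [[(2, 2), (6, 6)]] * 4,
            "B": [[(3, 3), (7, 7)]] * 4 + [[(4, 4), (8, 8)]] * 4,
        })
        res = hierarchical_fstats(ds, [])
        assert res.f("individuals", "populations") == pytest.approx(1.0, abs=1e-9)

    def test_non_nested_groupings_rejected(self, rng):
        ds = random_dataset(rng, {"A": 4, "B": 4, "C": 4, "D": 4}, n_loci=1)
        upper = Grouping("regions", {"A": "R1", "B": "R1", "C": "R2", "D": "R2"})
        lower = Grouping("clusters", {"A": "c1", "B": "c2", "C": "c2", "D": "c3"})
        with pytest.raises(ValueError, match="spans"):
            hierarchical_fstats(ds, [upper, lower])


class TestHierfPermutation:
    def test_strong_region_effect_detected(self):
        # 2 regions x 6 populations: enough whole-population permutation
        # granularity for p-values near 1/462
        hits = 0
        runs = 20
        for s in range(runs):
            rng = np.random.default_rng(s)
            freqs = {}
            region_of = {}
            for r, base in (("R1", [0.75, 0.15, 0.1]), ("R2", [0.1, 0.15, 0.75])):
                for p in range(6):
                    name = f"{r}p{p}"
                    freqs[name] = base
                    region_of[name] = r
            ds = random_dataset(rng, {n: 8 for n in freqs}, n_loci=3,
                                freqs=freqs)
            out = hierf_permutation_test(ds, [Grouping("regions", region_of)],
                                         "regions", n_perm=600, seed=100 + s)
            hits += out["p_value"] <= 0.01
        assert hits >= int(0.9 * runs)

    def test_single_region_not_testable(self, rng):
        ds = random_dataset(rng, {"A": 5, "B": 5}, n_loci=1)
        out = hierf_permutation_test(
            ds, [Grouping("regions", {"A": "R", "B": "R"})], "regions",
            n_perm=100, seed=0)
        assert out["p_value"] is None and out["note"] == "not testable"
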