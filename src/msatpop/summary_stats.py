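"""Per-population diversity statistics and exact tests.

Implements observed/expected heterozygosity, inbreeding coefficient,
hypergeometric rarefaction of allelic richness, exact Hardy-Weinberg
tests (full enumeration for few-allele loci, conditional Monte Carlo
otherwise), genotypic linkage-disequilibrium tests, exact population
differentiation tests with Fisher combination across loci, and
Benjamini-Hochberg false-discovery-rate control.

All Monte-Carlo tests sample tables *conditional on the observed allele
counts* (the exact-test null) and report p = (b + 1) / (B + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from .genotype_io import Dataset

logger = logging.getLogger(__name__)

__all__ = [
    "TestResult",
    "SummaryTable",
    "allele_frequencies",
    "summary_statistics",
    "allelic_richness",
    "hwe_exact_test",
    "global_het_test",
    "ld_genotypic_test",
    "exact_differentiation_test",
    "bh_fdr",
    "fisher_combine",
]

NOT_TESTABLE = "not testable"


@dataclass
class TestResult:
    statistic_name: str
    observed: float
    p_value: float | None
    mc_replicates: int = 0
    mc_standard_error: float = 0.0
    seed: int | None = None
    note: str = ""
    per_locus: dict = field(default_factory=dict)

    @property
    def testable(self) -> bool:
        return self.p_value is not None


@dataclass
class SummaryTable:
    """Per population x locus diversity statistics with across-locus means."""

    per_locus: pd.DataFrame  # rows (population, locus)
    means: pd.DataFrame      # rows population
    allele_freqs: dict       # (population, locus) -> {allele: freq}
    rarefaction_g: int

    def to_csv(self, path) -> None:
        self.means.to_csv(path)


# ---------------------------------------------------------------------------
# Frequencies and heterozygosity
# ---------------------------------------------------------------------------

def _typed_pairs(ds: Dataset, population: str, locus_idx: int) -> np.ndarray:
    g = ds.population_genotypes(population)[:, locus_idx, :]
    return g[g[:, 0] > 0]


def allele_frequencies(ds: Dataset, population: str, locus: str):
    """Allele frequencies among typed individuals; returns (freqs, n_typed)."""
    li = ds.loci.index(locus)
    pairs = _typed_pairs(ds, population, li)
    if pairs.shape[0] == 0:
        raise ValueError(f"locus {locus!r} untyped in population {population!r}")
    alleles, counts = np.unique(pairs.ravel(), return_counts=True)
    freqs = {int(a): c / pairs.size for a, c in zip(alleles, counts)}
    return freqs, int(pairs.shape[0])


def _cell_stats(pairs: np.ndarray) -> tuple[float, float, float, float | None, int]:
    """(H_O, H_E, uH_E, F_IS, n) for one population x locus complete-case block."""
    n = pairs.shape[0]
    ho = float(np.mean(pairs[:, 0] != pairs[:, 1]))
    _, counts = np.unique(pairs.ravel(), return_counts=True)
    p = counts / pairs.size
    he = float(1.0 - np.sum(p ** 2))
    uhe = he * (2 * n) / (2 * n - 1) if n > 1 else he
    fis = (he - ho) / he if he > 0 else None
    return ho, he, uhe, fis, n


def allelic_richness(ds: Dataset, g: int | None = None) -> pd.DataFrame:
    """Rarefied allele counts AR_g per population x locus.

    AR_g = sum over alleles of [1 - C(2n - N_i, g) / C(2n, g)]: the expected
    number of distinct alleles in a random subsample of ``g`` gene copies.
    Default ``g`` is the smallest 2 * n_typed over population x locus cells.
    """
    cells = {}
    min_genes = None
    for pop in ds.populations:
        for li, locus in enumerate(ds.loci):
            pairs = _typed_pairs(ds, pop, li)
            if pairs.shape[0] == 0:
                continue
            cells[(pop, locus)] = pairs
            min_genes = pairs.size if min_genes is None else min(min_genes, pairs.size)
    if g is None:
        g = min_genes
    if g is None or g < 2:
        raise ValueError("rarefaction size g must be >= 2")
    rows = []
    for (pop, locus), pairs in cells.items():
        total = pairs.size
        if g > total:
            rows.append((pop, locus, np.nan))
            continue
        _, counts = np.unique(pairs.ravel(), return_counts=True)
        # log C(2n - N_i, g) - log C(2n, g), with C = 0 when 2n - N_i < g
        keep = total - counts >= g
        logratio = np.full(counts.shape, -np.inf)
        m = total - counts[keep]
        logratio[keep] = (
            gammaln(m + 1) - gammaln(g + 1) - gammaln(m - g + 1)
            - (gammaln(total + 1) - gammaln(g + 1) - gammaln(total - g + 1))
        )
        ar = float(np.sum(1.0 - np.exp(logratio)))
        rows.append((pop, locus, ar))
    df = pd.DataFrame(rows, columns=["population", "locus", "AR"])
    return df.set_index(["population", "locus"])


def summary_statistics(ds: Dataset, rarefaction_g: int | None = None) -> SummaryTable:
    """Diversity summary per population x locus, plus across-locus means.

    H_E is the plain (biased) 1 - sum p^2 estimator; uH_E carries the
    2n/(2n-1) correction.  F_IS = (H_E - H_O)/H_E, undefined (NaN) at
    monomorphic cells and excluded from the across-locus means.
    """
    ar = allelic_richness(ds, rarefaction_g)
    g_used = rarefaction_g
    if g_used is None:
        g_used = min(
            _typed_pairs(ds, pop, li).size
            for pop in ds.populations for li in range(ds.n_loci)
            if _typed_pairs(ds, pop, li).size > 0
        )
    rows = []
    freqs = {}
    for pop in ds.populations:
        for li, locus in enumerate(ds.loci):
            pairs = _typed_pairs(ds, pop, li)
            if pairs.shape[0] == 0:
                logger.warning("untyped cell: %s x %s", pop, locus)
                rows.append((pop, locus, 0, np.nan, np.nan, np.nan, np.nan, np.nan))
                continue
            ho, he, uhe, fis, n = _cell_stats(pairs)
            freqs[(pop, locus)], _ = allele_frequencies(ds, pop, locus)
            arv = ar.loc[(pop, locus), "AR"] if (pop, locus) in ar.index else np.nan
            rows.append((pop, locus, n, ho, he, uhe,
                         np.nan if fis is None else fis, arv))
    per_locus = pd.DataFrame(
        rows,
        columns=["population", "locus", "n_typed", "H_O", "H_E", "uH_E", "F_IS", "AR"],
    ).set_index(["population", "locus"])
    means = per_locus.groupby(level="population", sort=False).mean()
    means["n"] = [
        len(ds.population_index(p)) for p in means.index
    ]
    return SummaryTable(per_locus=per_locus, means=means,
                        allele_freqs=freqs, rarefaction_g=int(g_used))


# ---------------------------------------------------------------------------
# Exact HWE test
# ---------------------------------------------------------------------------

def _log_table_prob(geno_counts: dict[tuple[int, int], int],
                    allele_counts: dict[int, int], n: int) -> float:
    """Levene's conditional probability of a genotype table given allele counts."""
    het = sum(c for (a, b), c in geno_counts.items() if a != b)
    two_n = 2 * n
    lp = (gammaln(n + 1)
          + sum(gammaln(c + 1) for c in allele_counts.values())
          + het * np.log(2.0)
          - gammaln(two_n + 1)
          - sum(gammaln(c + 1) for c in geno_counts.values()))
    return float(lp)


def _enumerate_tables(allele_counts: dict[int, int], n: int):
    """Yield (genotype_counts, log_prob, n_het) over all tables with the
    given allele counts — exact null support for the HWE test."""
    alleles = sorted(allele_counts)
    cells = [(alleles[i], alleles[j])
             for i in range(len(alleles)) for j in range(i, len(alleles))]

    results = []

    def rec(ci: int, remaining: dict[int, int], n_left: int, current: dict):
        if ci == len(cells):
            if n_left == 0 and all(v == 0 for v in remaining.values()):
                results.append(dict(current))
            return
        a, b = cells[ci]
        if a == b:
            max_c = min(remaining[a] // 2, n_left)
        else:
            max_c = min(remaining[a], remaining[b], n_left)
        # feasibility prune: remaining gene copies must be placeable
        for c in range(max_c + 1):
            remaining[a] -= c if a == b else c
            if a == b:
                remaining[a] -= c
            else:
                remaining[b] -= c
            if all(v >= 0 for v in remaining.values()):
                current[(a, b)] = c
                rec(ci + 1, remaining, n_left - c, current)
                del current[(a, b)]
            if a == b:
                remaining[a] += 2 * c
            else:
                remaining[a] += c
                remaining[b] += c

    rec(0, dict(allele_counts), n, {})
    out = []
    for table in results:
        lp = _log_table_prob(table, allele_counts, n)
        het = sum(c for (a, b), c in table.items() if a != b)
        out.append((table, lp, het))
    return out


def _pair_code(pairs: np.ndarray, k: int) -> np.ndarray:
    a = np.minimum(pairs[..., 0], pairs[..., 1])
    b = np.maximum(pairs[..., 0], pairs[..., 1])
    return a * k + b


def hwe_exact_test(ds: Dataset, population: str, locus: str,
                   mode: str = "auto", alternative: str = "two_sided",
                   B: int = 100_000, seed: int | None = None) -> TestResult:
    """Exact test of Hardy-Weinberg proportions conditional on allele counts.

    ``mode``: "enumeration" (complete enumeration, <= 4 alleles),
    "monte_carlo", or "auto" (enumeration when it applies).
    ``alternative``: "two_sided" (probability ordering), "deficit" or
    "excess" (heterozygote-count ordering).
    """
    li = ds.loci.index(locus)
    pairs = _typed_pairs(ds, population, li)
    if pairs.shape[0] == 0:
        raise ValueError(f"locus {locus!r} untyped in {population!r}")
    alleles, counts = np.unique(pairs.ravel(), return_counts=True)
    name = f"HWE[{population}:{locus}:{alternative}]"
    if alleles.size < 2:
        return TestResult(name, np.nan, None, note=NOT_TESTABLE)
    n = pairs.shape[0]
    allele_counts = {int(a): int(c) for a, c in zip(alleles, counts)}
    obs_het = int(np.sum(pairs[:, 0] != pairs[:, 1]))
    obs_table: dict[tuple[int, int], int] = {}
    for a, b in pairs:
        key = (int(min(a, b)), int(max(a, b)))
        obs_table[key] = obs_table.get(key, 0) + 1
    obs_lp = _log_table_prob(obs_table, allele_counts, n)

    if mode == "auto":
        mode = "enumeration" if alleles.size <= 4 and n <= 40 else "monte_carlo"
    if mode == "enumeration":
        if alleles.size > 4:
            raise ValueError("enumeration mode supports at most 4 alleles")
        tables = _enumerate_tables(allele_counts, n)
        lps = np.array([lp for _, lp, _ in tables])
        hets = np.array([h for _, _, h in tables])
        probs = np.exp(lps - lps.max())
        probs /= probs.sum()
        tol = 1e-12
        if alternative == "two_sided":
            p = float(probs[lps <= obs_lp + tol].sum())
        elif alternative == "deficit":
            p = float(probs[hets <= obs_het].sum())
        elif alternative == "excess":
            p = float(probs[hets >= obs_het].sum())
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        return TestResult(name, obs_lp if alternative == "two_sided" else obs_het,
                          min(p, 1.0), mc_replicates=0, seed=seed)

    if B < 1000:
        logger.warning("HWE Monte-Carlo with B=%d (<1000) is imprecise", B)
    rng = np.random.default_rng(seed)
    genes = pairs.ravel()
    k = int(alleles.max()) + 1
    const = (gammaln(n + 1) + sum(gammaln(c + 1) for c in allele_counts.values())
             - gammaln(2 * n + 1))
    perms = rng.permuted(np.tile(genes, (B, 1)), axis=1).reshape(B, n, 2)
    hets = np.sum(perms[:, :, 0] != perms[:, :, 1], axis=1)
    if alternative == "two_sided":
        codes = _pair_code(perms, k)
        counts_mat = np.zeros((B, k * k), dtype=np.int64)
        rows = np.repeat(np.arange(B), n)
        np.add.at(counts_mat, (rows, codes.ravel()), 1)
        lps = (const + hets * np.log(2.0)
               - gammaln(counts_mat + 1).sum(axis=1))
        extreme = lps <= obs_lp + 1e-9
    elif alternative == "deficit":
        extreme = hets <= obs_het
    elif alternative == "excess":
        extreme = hets >= obs_het
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    b = int(extreme.sum())
    p = (b + 1) / (B + 1)
    se = float(np.sqrt(p * (1 - p) / B))
    return TestResult(name, obs_lp if alternative == "two_sided" else obs_het,
                      p, mc_replicates=B, mc_standard_error=se, seed=seed)


def global_het_test(ds: Dataset, population: str, alternative: str,
                    B: int = 10_000, seed: int | None = None) -> TestResult:
    """Across-loci heterozygote deficiency/excess: Fisher combination of
    one-sided per-locus exact p-values."""
    pvals = []
    ss = np.random.SeedSequence(seed)
    for locus, child in zip(ds.loci, ss.spawn(ds.n_loci)):
        res = hwe_exact_test(ds, population, locus, mode="auto",
                             alternative=alternative, B=B,
                             seed=int(child.generate_state(1)[0] % 2**31))
        if res.testable:
            pvals.append(res.p_value)
    if not pvals:
        return TestResult(f"globalHWE[{population}:{alternative}]", np.nan, None,
                          note=NOT_TESTABLE)
    stat, p = fisher_combine(pvals)
    return TestResult(f"globalHWE[{population}:{alternative}]", stat, p, seed=seed)


# ---------------------------------------------------------------------------
# Contingency-table Monte-Carlo machinery (LD and differentiation tests)
# ---------------------------------------------------------------------------

def _mc_table_pvalue(codes_fixed: np.ndarray, codes_perm: np.ndarray,
                     B: int, rng: np.random.Generator) -> tuple[float, float, float]:
    """Monte-Carlo exact p for independence in the two-way table of
    (codes_fixed x codes_perm), permuting the second margin.

    The orderings use the conditional table probability (Fisher criterion):
    a table is as-or-more extreme when its probability is <= that of the
    observed table, i.e. when sum log(cell!) >= observed.
    """
    f_levels, f_idx = np.unique(codes_fixed, return_inverse=True)
    p_levels, p_idx = np.unique(codes_perm, return_inverse=True)
    nf, npv = f_levels.size, p_levels.size
    n = codes_fixed.size
    joint = f_idx * npv + p_idx
    obs_counts = np.bincount(joint, minlength=nf * npv)
    obs_stat = float(gammaln(obs_counts + 1).sum())

    perms = rng.permuted(np.tile(p_idx, (B, 1)), axis=1)
    joint_b = f_idx[None, :] * npv + perms
    counts = np.zeros((B, nf * npv), dtype=np.int64)
    rows = np.repeat(np.arange(B), n)
    np.add.at(counts, (rows, joint_b.ravel()), 1)
    stats = gammaln(counts + 1).sum(axis=1)
    b = int(np.sum(stats >= obs_stat - 1e-9))
    p = (b + 1) / (B + 1)
    se = float(np.sqrt(p * (1 - p) / B))
    return p, se, obs_stat


def ld_genotypic_test(ds: Dataset, population: str, locus_pair: tuple[str, str],
                      B: int = 10_000, seed: int | None = None) -> TestResult:
    """Monte-Carlo exact test of genotypic linkage disequilibrium.

    Builds the two-locus genotype contingency table over individuals typed
    at both loci and permutes one locus' genotypes among individuals.
    """
    la, lb = (ds.loci.index(l) for l in locus_pair)
    name = f"LD[{population}:{locus_pair[0]}x{locus_pair[1]}]"
    g = ds.population_genotypes(population)
    ok = (g[:, la, 0] > 0) & (g[:, lb, 0] > 0)
    ga, gb = g[ok][:, la, :], g[ok][:, lb, :]
    if ga.shape[0] < 2:
        return TestResult(name, np.nan, None, note=NOT_TESTABLE)
    k = int(max(ga.max(), gb.max())) + 1
    ca, cb = _pair_code(ga, k), _pair_code(gb, k)
    if np.unique(ca).size < 2 or np.unique(cb).size < 2:
        return TestResult(name, np.nan, None, note=NOT_TESTABLE)
    rng = np.random.default_rng(seed)
    p, se, stat = _mc_table_pvalue(ca, cb, B, rng)
    return TestResult(name, stat, p, mc_replicates=B, mc_standard_error=se,
                      seed=seed)


def exact_differentiation_test(ds: Dataset, populations: list[str] | None = None,
                               scope: str = "genic", B: int = 10_000,
                               seed: int | None = None) -> TestResult:
    """Exact test of population differentiation (Fisher-style).

    genic: allele x population table over gene copies; genotypic: genotype
    x population table over individuals.  Per-locus Monte-Carlo p-values
    are combined across loci by Fisher's method (-2 sum ln p vs chi^2 with
    2L degrees of freedom).
    """
    pops = populations if populations is not None else ds.populations
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    rng = np.random.default_rng(seed)
    per_locus: dict[str, float] = {}
    for li, locus in enumerate(ds.loci):
        pop_codes = []
        unit_codes = []
        skip = False
        for pi, pop in enumerate(pops):
            pairs = _typed_pairs(ds, pop, li)
            if pairs.shape[0] == 0:
                logger.warning("locus %s untyped in %s: skipped", locus, pop)
                skip = True
                break
            if scope == "genic":
                unit_codes.append(pairs.ravel())
                pop_codes.append(np.full(pairs.size, pi))
            elif scope == "genotypic":
                k = int(ds.genotypes.max()) + 1
                unit_codes.append(_pair_code(pairs, k))
                pop_codes.append(np.full(pairs.shape[0], pi))
            else:
                raise ValueError(f"unknown scope {scope!r}")
        if skip:
            continue
        units = np.concatenate(unit_codes)
        popc = np.concatenate(pop_codes)
        if np.unique(units).size < 2:
            continue  # monomorphic locus carries no information
        p, _, _ = _mc_table_pvalue(popc, units, B, rng)
        per_locus[locus] = p
    if not per_locus:
        return TestResult(f"differentiation[{scope}]", np.nan, None,
                          note=NOT_TESTABLE)
    floor = 1.0 / (B + 1)
    stat, p = fisher_combine([max(v, floor) for v in per_locus.values()])
    return TestResult(f"differentiation[{scope}]", stat, p, mc_replicates=B,
                      seed=seed, per_locus=per_locus)


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def fisher_combine(pvalues: list[float]) -> tuple[float, float]:
    """Fisher's combination: (-2 sum ln p, chi^2_{2L} upper tail p)."""
    pv = np.asarray(pvalues, dtype=float)
    stat = float(-2.0 * np.sum(np.log(pv)))
    return stat, float(chi2.sf(stat, 2 * pv.size))


def bh_fdr(pvalues, q: float = 0.05):
    """Benjamini-Hochberg step-up FDR control.

    Returns (reject boolean array, adjusted p-values), both in input order.
    """
    pv = np.asarray(pvalues, dtype=float)
    if pv.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    m = pv.size
    order = np.argsort(pv, kind="stable")
    ranked = pv[order]
    thresh = (np.arange(1, m + 1) / m) * q
    below = ranked <= thresh
    reject = np.zeros(m, dtype=bool)
    if below.any():
        kmax = int(np.max(np.nonzero(below)[0]))
        reject[order[: kmax + 1]] = True
    adj = ranked * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj
    return reject, adjusted
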