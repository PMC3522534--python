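"""Weir-Cockerham theta and hierarchical F-statistics.

Both are moment (ANOVA) estimators on allele-indicator variables: gene
copies nested in individuals, individuals in populations, populations in
optional higher groupings (clusters, regions, island/mainland).  Variance
components are estimated per locus and per allele from the classic
unbalanced nested ANOVA moment equations; multilocus F-statistics are
ratios of components summed over alleles and loci.  Negative components
are retained so that slightly negative theta values are representable.

Permutation tests re-estimate the statistic under shuffled membership.
Internals are batched over permutation replicates: membership only enters
through per-unit sufficient statistics (gene counts, allele-count sums,
summed squared within-individual dosages), so a replicate costs O(units),
not O(individuals).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import Dataset, Grouping

logger = logging.getLogger(__name__)

__all__ = [
    "PairwiseFst",
    "HierFResult",
    "wc_fst",
    "pairwise_theta",
    "fst_permutation_test",
    "hierarchical_fstats",
    "hierf_permutation_test",
]


@dataclass
class PairwiseFst:
    labels: list[str]
    theta: np.ndarray                 # (G, G), nan diagonal
    p_values: np.ndarray | None = None
    n_permutations: int = 0
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.theta, index=self.labels, columns=self.labels)

    def to_tsv(self, path, alpha: float = 0.05) -> None:
        """Lower triangle theta, upper triangle significance flags."""
        g = len(self.labels)
        out = pd.DataFrame("", index=self.labels, columns=self.labels)
        for i in range(g):
            for j in range(g):
                if i > j:
                    out.iloc[i, j] = f"{self.theta[i, j]:.4f}"
                elif i < j and self.p_values is not None:
                    out.iloc[i, j] = "+" if self.p_values[i, j] <= alpha else "-"
        out.to_csv(path, sep="\t")


@dataclass
class HierFResult:
    level_names: list[str]            # e.g. [total, regions, clusters, populations, individuals]
    f_matrix: dict                    # (lower, upper) -> F value
    components: pd.DataFrame          # per locus x level variance components
    p_values: dict = field(default_factory=dict)

    def f(self, lower: str, upper: str = "total") -> float:
        return self.f_matrix[(lower, upper)]

    def to_json_dict(self) -> dict:
        return {
            "levels": self.level_names,
            "F": {f"{lo}/{up}": v for (lo, up), v in self.f_matrix.items()},
            "p_values": {f"{lo}/{up}": v for (lo, up), v in self.p_values.items()},
        }


# ---------------------------------------------------------------------------
# Per-unit sufficient statistics
# ---------------------------------------------------------------------------

def _locus_alleles(genotypes: np.ndarray, locus: int) -> np.ndarray:
    g = genotypes[:, locus, :]
    return np.unique(g[g > 0])


def _unit_aggregates(genotypes: np.ndarray, unit_indices: list[np.ndarray],
                     locus: int, alleles: np.ndarray):
    """Per-unit gene count n, allele-count sums S and sum of squared
    per-individual dosages Q for one locus (complete-case)."""
    U, A = len(unit_indices), alleles.size
    n = np.zeros(U)
    S = np.zeros((U, A))
    Q = np.zeros((U, A))
    for u, idx in enumerate(unit_indices):
        g = genotypes[idx, locus, :]
        g = g[g[:, 0] > 0]
        if g.shape[0] == 0:
            continue
        dos = (g[:, 0, None] == alleles).astype(float) + (g[:, 1, None] == alleles)
        n[u] = 2 * g.shape[0]
        S[u] = dos.sum(axis=0)
        Q[u] = (dos ** 2).sum(axis=0)
    return n, S, Q


# ---------------------------------------------------------------------------
# Batched nested-ANOVA variance components
# ---------------------------------------------------------------------------

def _varcomp_locus(n, S, Q, assigns):
    """Variance components for one locus from unit-level aggregates.

    Parameters
    ----------
    n : (U,) gene counts per unit (population or group).
    S : (U, A) per-unit allele-count sums.
    Q : (U, A) per-unit sums of squared individual dosages.
    assigns : list of (B, U) integer category assignments for the upper
        levels, outermost first (may be empty).  B is the replicate axis.

    Returns
    -------
    sigma : (B, L, A) components for levels
        [upper levels..., units, individuals, genes].
    """
    assigns = [np.atleast_2d(a) for a in assigns]
    B = assigns[0].shape[0] if assigns else 1
    K = len(assigns)
    L = K + 3
    A = S.shape[1]
    active = n > 0
    nU = int(active.sum())
    if nU < 2:
        return np.full((B, L, A), np.nan)
    N = float(n.sum())
    Stot = S.sum(axis=0)                      # (A,)
    T0 = Stot ** 2 / N                        # (A,)
    with np.errstate(divide="ignore", invalid="ignore"):
        T_unit = np.where(active[:, None], S ** 2 / np.where(n[:, None] > 0, n[:, None], 1), 0.0).sum(axis=0)
    T_ind = Q.sum(axis=0) / 2.0
    T_gene = Stot.copy()

    # per-level category sizes / sums (batched)
    sizes = []     # list of (B, C_j)
    Tlev = []      # list of (B, A)
    cats = []      # list of (B, U) assignments
    for a in assigns:
        C = int(a.max()) + 1
        sz = np.zeros((B, C))
        rows = np.repeat(np.arange(B), n.size)
        np.add.at(sz, (rows, a.ravel()), np.tile(n, B))
        Sc = np.zeros((B, C, A))
        np.add.at(Sc, (rows, a.ravel()), np.tile(S, (B, 1)))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(sz[:, :, None] > 0, Sc ** 2 / np.where(sz[:, :, None] > 0, sz[:, :, None], 1), 0.0).sum(axis=1)
        sizes.append(sz)
        Tlev.append(t)
        cats.append(a)

    # T stack in level order: rows 1..L are [levels..., unit, ind, gene]
    T = np.empty((B, L + 1, A))
    T[:, 0] = T0
    for j in range(K):
        T[:, 1 + j] = Tlev[j]
    T[:, K + 1] = T_unit
    T[:, K + 2] = T_ind
    T[:, K + 3] = T_gene

    # coefficient matrix k (B, L+1, L): row 0 is the grand level
    k = np.full((B, L + 1, L), N)
    G_counts = [np.count_nonzero(sz > 0, axis=1) for sz in sizes]  # (B,) each

    def w2_within(row_level: int, col_level: int) -> np.ndarray:
        """sum over groups g at row_level of (sum of squared sizes of
        col_level categories inside g) / n_g ;  row < col (col finer)."""
        # sizes of col-level entities
        if col_level == K + 2:        # genes: W = n_g
            if row_level == 0:
                return np.full(B, 1.0)
            if row_level <= K:
                return G_counts[row_level - 1].astype(float)
            if row_level == K + 1:    # unit row
                return np.full(B, float(nU))
            return np.full(B, N / 2.0)  # individuals row: one group per individual
        if col_level == K + 1:        # individuals: W = 2 n_g
            if row_level == 0:
                return np.full(B, 2.0)
            if row_level <= K:
                return 2.0 * G_counts[row_level - 1]
            return np.full(B, 2.0 * nU)  # unit row (finer rows never request this)
        if col_level == K:            # units
            csz2 = n ** 2
            if row_level == 0:
                return np.full(B, float(csz2.sum() / N))
            j = row_level - 1
            sz = sizes[j]
            acc = np.zeros_like(sz)
            rows = np.repeat(np.arange(B), n.size)
            np.add.at(acc, (rows, cats[j].ravel()), np.tile(csz2, B))
            with np.errstate(divide="ignore", invalid="ignore"):
                return np.where(sz > 0, acc / np.where(sz > 0, sz, 1), 0.0).sum(axis=1)
        # col is an upper level j2 (0-based), row above it
        j2 = col_level
        sz2 = sizes[j2] ** 2          # (B, C2)
        if row_level == 0:
            return sz2.sum(axis=1) / N
        j = row_level - 1
        # parent category (at level j) of each level-j2 category
        C2 = sizes[j2].shape[1]
        parent = np.zeros((B, C2), dtype=np.intp)
        rows = np.repeat(np.arange(B), n.size)
        parent[rows, cats[j2].ravel()] = cats[j].ravel()
        acc = np.zeros_like(sizes[j])
        np.add.at(acc, (np.repeat(np.arange(B), C2), parent.ravel()), sz2.ravel())
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(sizes[j] > 0, acc / np.where(sizes[j] > 0, sizes[j], 1), 0.0).sum(axis=1)

    # fill k for columns finer than the row's level
    # column index m (0-based over L levels): 0..K-1 upper, K units, K+1 ind, K+2 genes
    for row in range(0, L + 1):       # row 0..L in T ordering
        # row's level in column coordinates: row-1 (row 1 ~ column 0)
        for m in range(L):
            if m > row - 1:           # finer than row level
                k[:, row, m] = w2_within(row, m)
    D = T[:, 1:, :] - T[:, :-1, :]    # (B, L, A)
    C = k[:, 1:, :] - k[:, :-1, :]    # (B, L, L) upper triangular
    sigma = np.zeros((B, L, A))
    for l in range(L - 1, -1, -1):
        resid = D[:, l, :].copy()
        for m in range(l + 1, L):
            resid -= C[:, l, m, None] * sigma[:, m, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            sigma[:, l, :] = resid / C[:, l, l, None]
    return sigma


def _multilocus_components(ds: Dataset, unit_indices, assigns, loci=None):
    """Sum variance components over alleles per locus; returns DataFrame
    (locus x level) for a single (non-batched) structure."""
    loci = range(ds.n_loci) if loci is None else loci
    K = len(assigns)
    L = K + 3
    rows = []
    for li in loci:
        alleles = _locus_alleles(ds.genotypes, li)
        if alleles.size < 2:
            rows.append(np.full(L, np.nan))
            continue
        n, S, Q = _unit_aggregates(ds.genotypes, unit_indices, li, alleles)
        sigma = _varcomp_locus(n, S, Q, [np.asarray(a)[None, :] for a in assigns])
        rows.append(np.nansum(sigma[0], axis=1) if not np.isnan(sigma[0]).all()
                    else np.full(L, np.nan))
    return np.array(rows)


def _theta_from_components(comp: np.ndarray) -> float:
    """Multilocus theta = sum(a) / sum(a+b+c) over loci (3-level layout)."""
    ok = ~np.isnan(comp).any(axis=1)
    if not ok.any():
        return float("nan")
    a = comp[ok, 0].sum()
    tot = comp[ok].sum()
    if tot == 0:
        return float("nan")
    return float(a / tot)


# ---------------------------------------------------------------------------
# Public theta API
# ---------------------------------------------------------------------------

def _group_indices(ds: Dataset, grouping: Grouping | None):
    if grouping is None:
        labels = ds.populations
        idx = [ds.population_index(p) for p in labels]
    else:
        grouping.validate(ds)
        labels = grouping.labels()
        idx = []
        for lab in labels:
            pops = set(grouping.members(lab))
            idx.append(np.array(
                [i for i, ind in enumerate(ds.individuals) if ind.population in pops],
                dtype=np.intp))
    return labels, idx


def wc_fst(ds: Dataset, grouping: Grouping | None = None):
    """Weir-Cockerham multilocus theta: global value and pairwise matrix.

    Returns (PairwiseFst, global_theta).  Pairwise values use only the two
    groups' data (computed for all pairs at once from per-group
    sufficient statistics).  Groups fixed for the same allele everywhere
    yield NaN.
    """
    labels, idx = _group_indices(ds, grouping)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    comp = _multilocus_components(ds, idx, [])
    global_theta = _theta_from_components(comp)
    G = len(labels)
    pi, pj = np.triu_indices(G, 1)
    num = np.zeros(pi.size)
    den = np.zeros(pi.size)
    for li in range(ds.n_loci):
        alleles = _locus_alleles(ds.genotypes, li)
        if alleles.size < 2:
            continue
        n, S, Q = _unit_aggregates(ds.genotypes, idx, li, alleles)
        ni, nj = n[pi], n[pj]                  # (P,)
        N = ni + nj
        ok = (ni >= 2) & (nj >= 2) & (N > 4)
        Ns = np.where(N > 0, N, 1.0)
        T0 = (S[pi] + S[pj]) ** 2 / Ns[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            T_grp = (S[pi] ** 2 / np.where(ni > 0, ni, 1)[:, None]
                     + S[pj] ** 2 / np.where(nj > 0, nj, 1)[:, None])
        T_ind = (Q[pi] + Q[pj]) / 2.0
        T_gene = S[pi] + S[pj]
        with np.errstate(divide="ignore", invalid="ignore"):
            sg = (T_gene - T_ind) / (Ns / 2.0)[:, None]
            si = ((T_ind - T_grp) - (Ns / 2.0 - 2.0)[:, None] * sg) \
                / (Ns - 4.0)[:, None]
            c11 = N - (ni ** 2 + nj ** 2) / Ns
            sp = ((T_grp - T0) - 2.0 * si - sg) / np.where(c11 > 0, c11, 1)[:, None]
        a = sp.sum(axis=1)
        tot = (sp + si + sg).sum(axis=1)
        num += np.where(ok, a, 0.0)
        den += np.where(ok, tot, 0.0)
    theta = np.full((G, G), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(den != 0, num / den, np.nan)
    theta[pi, pj] = vals
    theta[pj, pi] = vals
    return PairwiseFst(labels=labels, theta=theta), global_theta


def pairwise_theta(ds: Dataset, group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Multilocus theta between two explicit index sets of individuals."""
    comp = _multilocus_components(ds, [group_a, group_b], [])
    return _theta_from_components(comp)


def _two_group_theta_batched(genotypes: np.ndarray, pool: np.ndarray,
                             n1: int, perms: np.ndarray) -> np.ndarray:
    """theta for B permutations of pooled individuals into sizes (n1, rest).

    perms: (B, n) permuted index rows; first n1 columns form group 1.
    Closed-form back-substitution of the 3-level component system.
    """
    B, n = perms.shape
    member = np.zeros((B, n))
    rows = np.repeat(np.arange(B), n1)
    member[rows, perms[:, :n1].ravel()] = 1.0
    L = genotypes.shape[1]
    num = np.zeros(B)
    den = np.zeros(B)
    for li in range(L):
        g = genotypes[pool][:, li, :]
        typed = (g[:, 0] > 0).astype(float)
        alleles = np.unique(g[g > 0])
        if alleles.size < 2:
            continue
        dos = ((g[:, 0, None] == alleles).astype(float)
               + (g[:, 1, None] == alleles)) * typed[:, None]
        q = dos ** 2
        N = 2.0 * typed.sum()
        if N <= 4:
            continue
        Stot = dos.sum(axis=0)                    # (A,)
        T_ind = q.sum(axis=0) / 2.0               # (A,)
        T_gene = Stot
        T0 = Stot ** 2 / N
        n1g = 2.0 * (member @ typed)              # (B,)
        n2g = N - n1g
        S1 = member @ dos                         # (B, A)
        S2 = Stot[None, :] - S1
        bad = (n1g < 2) | (n2g < 2)
        n1s = np.where(n1g > 0, n1g, 1.0)
        n2s = np.where(n2g > 0, n2g, 1.0)
        T_grp = S1 ** 2 / n1s[:, None] + S2 ** 2 / n2s[:, None]
        # back-substitution (levels: group, individual, gene)
        c11 = N - (n1g ** 2 + n2g ** 2) / N       # (B,)
        sg = (T_gene - T_ind)[None, :] / (N / 2.0)            # (B_unused, A)
        si = ((T_ind[None, :] - T_grp) - (N / 2.0 - 2.0) * sg) / (N - 4.0)
        sp = ((T_grp - T0[None, :]) - 2.0 * si - 1.0 * sg) / c11[:, None]
        a = sp.sum(axis=1)
        tot = (sp + si + sg).sum(axis=1)
        a = np.where(bad, 0.0, a)
        tot = np.where(bad, 0.0, tot)
        num += a
        den += tot
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(den != 0, num / den, np.nan)


def fst_permutation_test(ds: Dataset, grouping: Grouping | None = None,
                         n_perm: int = 10_000, seed: int | None = None,
                         batch: int = 2000) -> PairwiseFst:
    """Pairwise theta with permutation p-values.

    Individuals (whole multilocus genotypes) are permuted between the two
    groups of each pair; p = (#{theta_perm >= theta_obs} + 1)/(n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    labels, idx = _group_indices(ds, grouping)
    G = len(labels)
    theta = np.full((G, G), np.nan)
    pvals = np.full((G, G), np.nan)
    rng = np.random.default_rng(seed)
    for i in range(G):
        for j in range(i + 1, G):
            pool = np.concatenate([idx[i], idx[j]])
            n1 = idx[i].size
            if n1 < 2 or idx[j].size < 2:
                logger.warning("pair (%s, %s) skipped: group too small",
                               labels[i], labels[j])
                continue
            obs = pairwise_theta(ds, idx[i], idx[j])
            theta[i, j] = theta[j, i] = obs
            if np.isnan(obs):
                continue
            count = 0
            done = 0
            while done < n_perm:
                b = min(batch, n_perm - done)
                perms = np.argsort(rng.random((b, pool.size)), axis=1)
                th = _two_group_theta_batched(ds.genotypes, pool, n1, perms)
                count += int(np.sum(th >= obs - 1e-15))
                done += b
            pvals[i, j] = pvals[j, i] = (count + 1) / (n_perm + 1)
    return PairwiseFst(labels=labels, theta=theta, p_values=pvals,
                       n_permutations=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# Hierarchical F-statistics
# ---------------------------------------------------------------------------

def _check_nested(ds: Dataset, levels: list[Grouping]) -> None:
    pops = ds.populations
    for upper, lower in zip(levels, levels[1:] + [None]):
        if lower is None:
            break
        for lab in lower.labels():
            members = lower.members(lab)
            uppers = {upper.assignment[p] for p in members}
            if len(uppers) > 1:
                raise ValueError(
                    f"level {lower.name!r} unit {lab!r} spans multiple "
                    f"{upper.name!r} categories: {sorted(uppers)}")
    for g in levels:
        g.validate(ds)
    _ = pops


def _level_assign_arrays(ds: Dataset, levels: list[Grouping]):
    pops = ds.populations
    arrays = []
    label_maps = []
    for g in levels:
        labs = g.labels()
        lmap = {lab: i for i, lab in enumerate(labs)}
        arrays.append(np.array([lmap[g.assignment[p]] for p in pops]))
        label_maps.append(labs)
    return pops, arrays, label_maps


def hierarchical_fstats(ds: Dataset, levels: list[Grouping]) -> HierFResult:
    """Hierarchical F-statistics over nested groupings of populations.

    ``levels`` lists groupings from outermost to innermost (populations,
    individuals and genes are appended implicitly).  F_{X/Y} is the sum of
    variance components from just below Y down to X, divided by the sum
    from just below Y to the bottom.
    """
    _check_nested(ds, levels)
    pops, assigns, _ = _level_assign_arrays(ds, levels)
    unit_idx = [ds.population_index(p) for p in pops]
    comp = _multilocus_components(ds, unit_idx, assigns)
    level_names = [g.name for g in levels] + ["populations", "individuals", "genes"]
    comp_df = pd.DataFrame(comp, index=ds.loci, columns=level_names)
    ok = ~np.isnan(comp).any(axis=1)
    total = comp[ok].sum(axis=0)          # (L,) summed over loci
    L = total.size
    f_matrix = {}
    # lower level X = component index xi (genes excluded as a named level);
    # upper level Y = "total" or any level above X; F = components from just
    # below Y through X over components from just below Y to the bottom.
    for xi in range(L - 1):
        uppers = ["total"] + level_names[:xi]
        for yi, up in enumerate(uppers):   # yi = 0 -> total, else level yi-1
            start = yi                     # first component below Y
            numer = total[start:xi + 1].sum()
            denom = total[start:].sum()
            f_matrix[(level_names[xi], up)] = (
                float(numer / denom) if denom != 0 else float("nan"))
    return HierFResult(level_names=["total"] + level_names,
                       f_matrix=f_matrix, components=comp_df)


def hierf_permutation_test(ds: Dataset, levels: list[Grouping],
                           tested_level: str, n_perm: int = 1000,
                           seed: int | None = None) -> dict:
    """Permutation p-value for the effect of one hierarchical level.

    Units of the level immediately below ``tested_level`` are permuted
    among the tested level's categories, within each enclosing category.
    The statistic is F_{tested/enclosing}; p = (b + 1)/(n_perm + 1) for
    permuted F >= observed.
    """
    _check_nested(ds, levels)
    names = [g.name for g in levels]
    if tested_level not in names:
        raise ValueError(f"unknown level {tested_level!r}")
    t = names.index(tested_level)
    pops, assigns, _ = _level_assign_arrays(ds, levels)
    unit_idx = [ds.population_index(p) for p in pops]
    npops = len(pops)

    # lower units: level t+1 groupings of populations (or populations)
    if t + 1 < len(levels):
        lower_assign = assigns[t + 1]
    else:
        lower_assign = np.arange(npops)
    lower_ids = np.unique(lower_assign)
    # tested/enclosing category per lower unit
    unit_tested = np.array([assigns[t][lower_assign == u][0] for u in lower_ids])
    if t > 0:
        unit_encl = np.array([assigns[t - 1][lower_assign == u][0] for u in lower_ids])
    else:
        unit_encl = np.zeros(lower_ids.size, dtype=int)
    # testability: some enclosing unit must hold >1 tested category
    testable = False
    for e in np.unique(unit_encl):
        if np.unique(unit_tested[unit_encl == e]).size > 1:
            testable = True
    if not testable:
        return {"p_value": None, "note": "not testable",
                "statistic": float("nan")}

    res = hierarchical_fstats(ds, levels)
    upper_name = "total" if t == 0 else names[t - 1]
    f_obs = res.f(tested_level, upper_name)

    rng = np.random.default_rng(seed)
    # permute tested labels of lower units within enclosing categories
    perm_unit_tested = np.tile(unit_tested, (n_perm, 1))
    for e in np.unique(unit_encl):
        cols = np.nonzero(unit_encl == e)[0]
        sub = perm_unit_tested[:, cols]
        idx = np.argsort(rng.random((n_perm, cols.size)), axis=1)
        perm_unit_tested[:, cols] = np.take_along_axis(sub, idx, axis=1)

    # expand to per-population tested assignment, batched
    pos = {u: i for i, u in enumerate(lower_ids)}
    unit_of_pop = np.array([pos[u] for u in lower_assign])
    assigns_b = []
    for j, a in enumerate(assigns):
        if j == t:
            assigns_b.append(perm_unit_tested[:, unit_of_pop])
        else:
            assigns_b.append(np.tile(a, (n_perm, 1)))

    K = len(assigns)
    Lc = K + 3
    comp_total = np.zeros((n_perm, Lc))
    for li in range(ds.n_loci):
        alleles = _locus_alleles(ds.genotypes, li)
        if alleles.size < 2:
            continue
        n, S, Q = _unit_aggregates(ds.genotypes, unit_idx, li, alleles)
        sigma = _varcomp_locus(n, S, Q, assigns_b)   # (B, Lc, A)
        locus_comp = sigma.sum(axis=2)               # (B, Lc)
        good = ~np.isnan(locus_comp).any(axis=1)
        comp_total[good] += locus_comp[good]
    # F_{tested/enclosing} per replicate (component index of tested level = t)
    start = t                # first component below the enclosing level
    with np.errstate(divide="ignore", invalid="ignore"):
        f_perm = comp_total[:, start:t + 1].sum(axis=1) / comp_total[:, start:].sum(axis=1)
    f_perm = f_perm[np.isfinite(f_perm)]
    b = int(np.sum(f_perm >= f_obs - 1e-15))
    p = (b + 1) / (n_perm + 1)
    return {"p_value": p, "statistic": f_obs, "n_perm": n_perm, "seed": seed}
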