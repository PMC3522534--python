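"""Sex-biased dispersal tests.

Under sex-biased dispersal the more dispersive sex carries more
immigrant-like multilocus genotypes: its corrected assignment index
(AIc) has a lower mean and higher variance, its among-group F_ST is
lower, and its within-group pairwise relatedness is lower.  This module
computes the four statistics per sex (F_ST, mAIc, vAIc, mPr) with
two-sided significance by permuting sex labels within groups, plus a
Welch t-test on within-group dyadic relatedness (flagged: dyads are not
independent, the permutation p is the safer reference).

Relatedness is the Queller-Goodnight symmetric estimator with reference
allele frequencies from the whole group and equal locus weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import Dataset, Grouping
from .structure_assignment import assignment_loglik

logger = logging.getLogger(__name__)

__all__ = [
    "SexBiasResult",
    "assignment_index",
    "pairwise_relatedness",
    "sex_bias_tests",
]


@dataclass
class SexBiasResult:
    per_sex: pd.DataFrame        # rows F/M, columns n, FST, mAIc, vAIc, mPr
    p_values: dict               # statistic -> two-sided permutation p
    t_test: dict                 # Welch t on dyadic relatedness (caveat flag)
    n_perm: int
    seed: int | None

    def to_csv(self, path) -> None:
        out = self.per_sex.copy()
        out.loc["P-value"] = [np.nan] + [
            self.p_values.get(c) for c in out.columns[1:]]
        out.to_csv(path)


def assignment_index(ds: Dataset, grouping: Grouping) -> pd.DataFrame:
    """AI and AIc per sexed individual.

    AI is the log10 expected frequency of the individual's multilocus
    genotype in its own group (Hardy-Weinberg, leave-one-out allele
    frequencies); AIc subtracts the group mean of AI, so within each
    group the AIc values of all its (sexed) individuals sum to zero.
    """
    grouping.validate(ds)
    sexed = np.array([ind.sex in ("F", "M") for ind in ds.individuals])
    sub = ds.subset(sexed)
    group_of = {p: grouping.assignment[p] for p in sub.populations}
    labels = np.array([group_of[ind.population] for ind in sub.individuals])
    keep_groups = [g for g in dict.fromkeys(labels)
                   if np.sum(labels == g) >= 2]
    dropped = set(labels) - set(keep_groups)
    if dropped:
        logger.warning("groups with <2 sexed individuals excluded: %s",
                       sorted(dropped))
    mask = np.isin(labels, keep_groups)
    sub = sub.subset(mask)
    labels = labels[mask]
    ll = assignment_loglik(sub, labels, leave_one_out=True)
    ai = np.array([ll.loc[ind.id, lab]
                   for ind, lab in zip(sub.individuals, labels)])
    aic = ai.copy()
    for g in keep_groups:
        sel = labels == g
        aic[sel] -= ai[sel].mean()
    return pd.DataFrame({
        "id": [ind.id for ind in sub.individuals],
        "group": labels,
        "sex": [ind.sex for ind in sub.individuals],
        "AI": ai,
        "AIc": aic,
    }).set_index("id")


def _relatedness_matrices(ds: Dataset, grouping: Grouping):
    """Per group: (ids, sexes, numerator-sum, denominator-sum matrices)."""
    grouping.validate(ds)
    out = {}
    for lab in grouping.labels():
        pops = set(grouping.members(lab))
        idx = np.array([i for i, ind in enumerate(ds.individuals)
                        if ind.population in pops], dtype=np.intp)
        if idx.size < 2:
            continue
        n = idx.size
        num = np.zeros((n, n))
        den = np.zeros((n, n))
        for li in range(ds.n_loci):
            g = ds.genotypes[idx, li, :]
            typed = g[:, 0] > 0
            nt = int(typed.sum())
            alleles = np.unique(g[g > 0])
            if alleles.size < 2 or nt < 3:
                continue
            dos = ((g[:, 0, None] == alleles).astype(float)
                   + (g[:, 1, None] == alleles)) * typed[:, None]
            # reference frequencies exclude the focal dyad (removes the
            # ~ -1/n bias of same-sample references)
            Stot = dos.sum(axis=0)            # (A,) allele counts
            T = dos @ Stot                    # (n,) dx . Stot
            q = (dos ** 2).sum(axis=1)        # (n,) dx . dx
            G = dos @ dos.T                   # (n, n) delta sums
            denom_genes = 2.0 * nt - 4.0
            upair = (T[:, None] + T[None, :] - q[:, None] - q[None, :]
                     - 2.0 * G) / denom_genes     # sum of p-terms for a dyad
            hom = (g[:, 0] == g[:, 1]) & typed
            tt = np.outer(typed, typed)
            num += (G - upair) * tt
            den += (2.0 + hom[:, None] + hom[None, :] - upair) * tt
        ids = [ds.individuals[i].id for i in idx]
        sexes = np.array([ds.individuals[i].sex for i in idx])
        out[lab] = (ids, sexes, num, den)
    return out


def pairwise_relatedness(ds: Dataset, grouping: Grouping) -> pd.DataFrame:
    """Queller-Goodnight relatedness for every within-group dyad.

    Symmetric ratio-of-sums form: numerators and denominators are summed
    over both orderings and all co-typed loci before dividing.  Dyads
    with no co-typed polymorphic locus are excluded.
    """
    rows = []
    for lab, (ids, sexes, num, den) in _relatedness_matrices(ds, grouping).items():
        n = len(ids)
        for i in range(n):
            for j in range(i + 1, n):
                if den[i, j] == 0:
                    continue
                rows.append({
                    "group": lab, "id1": ids[i], "id2": ids[j],
                    "sex1": sexes[i], "sex2": sexes[j],
                    "r": num[i, j] / den[i, j],
                })
    return pd.DataFrame(rows, columns=["group", "id1", "id2",
                                       "sex1", "sex2", "r"])


def _per_sex_theta_batched(ds, group_idx, sex_member, loci_data):
    """Multi-group WC theta for each replicate's sex membership.

    sex_member: (B, n) 0/1 indicator over ALL individuals for one sex.
    group_idx: list of index arrays.  Group sex counts are permutation-
    invariant (labels are shuffled within groups), so the coefficient
    matrix is constant and only allele sums vary.
    """
    B = sex_member.shape[0]
    num = np.zeros(B)
    den = np.zeros(B)
    for (dos_g, typed_g, q_g) in loci_data:
        # dos_g: list per group of (n_g, A); typed_g list of (n_g,)
        n_g = []
        A = dos_g[0].shape[1]
        Stot = np.zeros((B, A))
        T_grp = np.zeros((B, A))
        T_ind = np.zeros((B, A))
        sum_ng2 = np.zeros(B)
        for gi, idx in enumerate(group_idx):
            M = sex_member[:, idx]                      # (B, n_g)
            tg = typed_g[gi]
            ng = 2.0 * (M * tg[None, :]).sum(axis=1)    # (B,)
            Sg = M @ dos_g[gi]                          # (B, A)
            Qg = M @ q_g[gi]                            # (B, A)
            ok = ng >= 2
            ngs = np.where(ng > 0, ng, 1.0)
            T_grp += np.where(ok[:, None], Sg ** 2 / ngs[:, None], 0.0)
            T_ind += np.where(ok[:, None], Qg / 2.0, 0.0)
            Stot += np.where(ok[:, None], Sg, 0.0)
            sum_ng2 += np.where(ok, ng ** 2, 0.0)
            n_g.append(np.where(ok, ng, 0.0))
        ngm = np.stack(n_g)                             # (G, B)
        Ntot = ngm.sum(axis=0)                          # (B,)
        Gcnt = (ngm > 0).sum(axis=0).astype(float)      # (B,)
        T0 = (Stot ** 2) / np.where(Ntot > 0, Ntot, 1.0)[:, None]
        T_gene = Stot
        valid = (Gcnt >= 2) & (Ntot > 2 * Gcnt)
        with np.errstate(divide="ignore", invalid="ignore"):
            sg = (T_gene - T_ind) / (Ntot / 2.0)[:, None]
            si = ((T_ind - T_grp) - (Ntot / 2.0 - Gcnt)[:, None] * sg) \
                / (Ntot - 2.0 * Gcnt)[:, None]
            c11 = (Ntot - sum_ng2 / np.where(Ntot > 0, Ntot, 1.0))
            sp = ((T_grp - T0) - (2.0 * (Gcnt - 1.0))[:, None] * si
                  - (Gcnt - 1.0)[:, None] * sg) / c11[:, None]
        a = np.where(valid[:, None], sp, 0.0).sum(axis=1)
        tot = np.where(valid[:, None], sp + si + sg, 0.0).sum(axis=1)
        num += np.where(np.isfinite(a), a, 0.0)
        den += np.where(np.isfinite(tot), tot, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(den != 0, num / den, np.nan)


def sex_bias_tests(ds: Dataset, grouping: Grouping, n_perm: int = 1000,
                   seed: int | None = None) -> SexBiasResult:
    """Four sex-biased-dispersal statistics with permutation significance.

    Per sex: among-group F_ST, mean and variance of the corrected
    assignment index, and mean within-group pairwise relatedness.  The
    two-sided p-value of each statistic's F-M difference comes from
    permuting sex labels within groups (group sizes and sex ratios are
    preserved).  A Welch t-test on F-F vs M-M dyadic relatedness is
    reported alongside with a non-independence caveat.
    """
    ai = assignment_index(ds, grouping)
    ids_order = {ind.id: k for k, ind in enumerate(ds.individuals)}
    keep = np.array([ids_order[i] for i in ai.index], dtype=np.intp)
    sub = ds.subset(keep)
    labels = ai["group"].to_numpy()
    sexes = ai["sex"].to_numpy()
    aic = ai["AIc"].to_numpy()
    n = len(sub.individuals)
    groups = list(dict.fromkeys(labels))
    if len(groups) < 2:
        fst_testable = False
    else:
        fst_testable = True
    for g in groups:
        for s in ("F", "M"):
            if np.sum((labels == g) & (sexes == s)) == 0:
                logger.warning("sex %s absent from group %s "
                               "(dropped for that sex's F_ST)", s, g)

    group_idx = [np.nonzero(labels == g)[0] for g in groups]
    # per-locus per-group fixed data for batched theta
    loci_data = []
    for li in range(sub.n_loci):
        g_all = sub.genotypes[:, li, :]
        alleles = np.unique(g_all[g_all > 0])
        if alleles.size < 2:
            continue
        dos_g, typed_g, q_g = [], [], []
        for idx in group_idx:
            g = sub.genotypes[idx, li, :]
            typed = (g[:, 0] > 0).astype(float)
            dos = ((g[:, 0, None] == alleles).astype(float)
                   + (g[:, 1, None] == alleles)) * typed[:, None]
            dos_g.append(dos)
            typed_g.append(typed)
            q_g.append(dos ** 2)
        loci_data.append((dos_g, typed_g, q_g))

    rel = _relatedness_matrices(sub, grouping)
    # dyad matrices aligned to `sub` indexing, per group
    rel_mats = []
    for lab in groups:
        if lab not in rel:
            continue
        ids, _, num_m, den_m = rel[lab]
        pos = {iid: k for k, iid in enumerate(ai.index)}
        idx = np.array([pos[i] for i in ids], dtype=np.intp)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(den_m != 0, num_m / den_m, np.nan)
        np.fill_diagonal(r, np.nan)
        rel_mats.append((idx, r))

    def stats_for(member_f: np.ndarray, member_m: np.ndarray):
        """member_*: (B, n) indicators; returns dict of (B,) arrays."""
        out = {}
        for s, mem in (("F", member_f), ("M", member_m)):
            cnt = mem.sum(axis=1)
            out[(s, "mAIc")] = (mem @ aic) / cnt
            mean = out[(s, "mAIc")]
            out[(s, "vAIc")] = (mem @ aic ** 2) / cnt - mean ** 2
            out[(s, "vAIc")] *= cnt / np.maximum(cnt - 1, 1)
            if fst_testable:
                out[(s, "FST")] = _per_sex_theta_batched(
                    sub, group_idx, mem, loci_data)
            # mPr: mean within-group same-sex dyadic relatedness
            tot_r = np.zeros(mem.shape[0])
            tot_n = np.zeros(mem.shape[0])
            for idx, r in rel_mats:
                msub = mem[:, idx]
                rz = np.nan_to_num(r, nan=0.0)
                valid = (~np.isnan(r)).astype(float)
                tot_r += 0.5 * np.einsum("bi,ij,bj->b", msub, rz, msub)
                tot_n += 0.5 * np.einsum("bi,ij,bj->b", msub, valid, msub)
            out[(s, "mPr")] = np.where(tot_n > 0, tot_r / np.maximum(tot_n, 1), np.nan)
        return out

    obs_f = (sexes == "F").astype(float)[None, :]
    obs_m = (sexes == "M").astype(float)[None, :]
    obs = stats_for(obs_f, obs_m)

    rng = np.random.default_rng(seed)
    perm_sex = np.tile(sexes, (n_perm, 1))
    for g in groups:
        cols = np.nonzero(labels == g)[0]
        order = np.argsort(rng.random((n_perm, cols.size)), axis=1)
        perm_sex[:, cols] = np.take_along_axis(perm_sex[:, cols], order, axis=1)
    perm = stats_for((perm_sex == "F").astype(float),
                     (perm_sex == "M").astype(float))

    stat_names = ["FST", "mAIc", "vAIc", "mPr"] if fst_testable else \
        ["mAIc", "vAIc", "mPr"]
    p_values = {}
    for name in stat_names:
        d_obs = obs[("F", name)][0] - obs[("M", name)][0]
        d_perm = perm[("F", name)] - perm[("M", name)]
        d_perm = d_perm[np.isfinite(d_perm)]
        b = int(np.sum(np.abs(d_perm) >= abs(d_obs) - 1e-15))
        p_values[name] = (b + 1) / (d_perm.size + 1)
    if not fst_testable:
        p_values["FST"] = None

    # Welch t on dyadic relatedness (F-F vs M-M), non-independent dyads
    ff, mm = [], []
    for idx, r in rel_mats:
        sx = sexes[idx]
        iu = np.triu_indices_from(r, k=1)
        vals = r[iu]
        s1, s2 = sx[iu[0]], sx[iu[1]]
        good = ~np.isnan(vals)
        ff.extend(vals[good & (s1 == "F") & (s2 == "F")])
        mm.extend(vals[good & (s1 == "M") & (s2 == "M")])
    if len(ff) > 1 and len(mm) > 1:
        t, p = stats.ttest_ind(ff, mm, equal_var=False)
        df = len(ff) + len(mm) - 2
        t_test = {"t": float(t), "p": float(p), "n_FF": len(ff),
                  "n_MM": len(mm), "caveat": "dyads are non-independent"}
    else:
        t_test = {"t": None, "p": None, "caveat": "too few same-sex dyads"}

    table = pd.DataFrame(
        {
            "n": [int(obs_f.sum()), int(obs_m.sum())],
            "FST": [obs.get(("F", "FST"), [np.nan])[0],
                    obs.get(("M", "FST"), [np.nan])[0]],
            "mAIc": [obs[("F", "mAIc")][0], obs[("M", "mAIc")][0]],
            "vAIc": [obs[("F", "vAIc")][0], obs[("M", "vAIc")][0]],
            "mPr": [obs[("F", "mPr")][0], obs[("M", "mPr")][0]],
        },
        index=["F", "M"],
    )
    return SexBiasResult(per_sex=table, p_values=p_values, t_test=t_test,
                         n_perm=n_perm, seed=seed)
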