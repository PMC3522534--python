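"""Effective and census population size estimation.

Three N_E estimators:

* LD method: inter-locus Burrows composite disequilibrium r^2 in a single
  sample, corrected for the sampling expectation E[r^2 | S], inverted to
  N_E with the published small/large-sample constants.
* temporal moment method: standardized allele-frequency variance F_k
  between two samples t generations apart, corrected for sampling,
  N_E = t / (2 (F_k - 1/(2 S_0) - 1/(2 S_t))).
* temporal pseudo-likelihood: per-allele binomial likelihood of the later
  sample given a Beta-approximated drift transition from the first
  sample's posterior, profiled over an N_E grid.

Census size N_C uses a sequential Bayesian estimator adapted to sampling
*without replacement* (lethal trapping): catches deplete the population,
so occasion t's catch is Binomial(N - K_{t-1}, p) where K_{t-1} is the
cumulative removal.  A uniform grid prior over (N, p) is updated occasion
by occasion; the marginal posterior on N gives the mean N_C and a 95%
highest-posterior-density interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import betaln, gammaln, logsumexp
from scipy.stats import chi2, norm

from .genotype_io import Dataset

logger = logging.getLogger(__name__)

__all__ = [
    "NeEstimate",
    "RemovalSurvey",
    "CensusPosterior",
    "INFINITE",
    "ldne_estimate",
    "temporal_moment_ne",
    "temporal_likelihood_ne",
    "removal_census_posterior",
    "hpd_interval",
    "ne_nc_ratio",
    "generations_between",
]

INFINITE = float("inf")


@dataclass
class NeEstimate:
    method: str
    point: float                      # may be inf ("no signal")
    ci: tuple[float, float] | None
    ci_level: float = 0.95
    internals: dict = field(default_factory=dict)

    @property
    def is_infinite(self) -> bool:
        return not np.isfinite(self.point)


@dataclass
class RemovalSurvey:
    occasions: list[tuple[str, int]]  # (label, catch)

    def __post_init__(self) -> None:
        if any(c < 0 for _, c in self.occasions):
            raise ValueError("catches must be non-negative")

    @property
    def catches(self) -> np.ndarray:
        return np.array([c for _, c in self.occasions], dtype=int)

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.catches)

    @property
    def total(self) -> int:
        return int(self.catches.sum())

    @classmethod
    def from_csv(cls, path) -> "RemovalSurvey":
        import pandas as pd
        df = pd.read_csv(path)
        label_col = "label" if "label" in df.columns else "occasion"
        return cls([(str(r[label_col]), int(r["catch"])) for _, r in df.iterrows()])


@dataclass
class CensusPosterior:
    n_grid: np.ndarray
    p_grid: np.ndarray
    joint_log: np.ndarray             # (N, P) unnormalized log posterior
    marginal_n: np.ndarray            # normalized
    mean_n: float
    hpd: tuple[float, float]
    hpd_level: float = 0.95


# ---------------------------------------------------------------------------
# LD method
# ---------------------------------------------------------------------------

def _dosage_columns(ds: Dataset, idx: np.ndarray, pcrit: float):
    """Per locus: dosage matrix (complete-case aware) for alleles with
    frequency >= pcrit; returns list of (dosages, typed mask, n_alleles)."""
    out = []
    for li in range(ds.n_loci):
        g = ds.genotypes[idx][:, li, :]
        typed = g[:, 0] > 0
        vals = g[typed]
        if vals.shape[0] == 0:
            out.append(None)
            continue
        alleles, counts = np.unique(vals.ravel(), return_counts=True)
        freqs = counts / vals.size
        keep = alleles[freqs >= pcrit]
        if keep.size < 2:
            out.append(None)
            continue
        dos = (g[:, 0, None] == keep).astype(float) + (g[:, 1, None] == keep)
        out.append((dos, typed))
    return out


def _pair_r2(X: np.ndarray, Y: np.ndarray, S: int) -> np.ndarray:
    """Squared Burrows composite correlation for all allele pairs of one
    locus pair (small-sample factor S/(S-1) on the disequilibrium)."""
    pA = X.mean(axis=0) / 2.0
    pB = Y.mean(axis=0) / 2.0
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    delta = (Xc.T @ Yc) / S / 2.0 * (S / (S - 1.0))
    den = np.outer(pA * (1 - pA), pB * (1 - pB))
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = delta ** 2 / den
    return r2[np.isfinite(r2)]


def _pair_table(cols, expectation: str, n_null: int,
                rng: np.random.Generator | None):
    """Per locus-pair summaries: (i, j, S, k, mean r2, null mean r2).

    With ``expectation="empirical"`` the sampling expectation of r^2 for
    each locus pair is estimated by permuting one locus' genotypes among
    individuals (which destroys disequilibrium but preserves the allele
    frequencies and the estimator's exact small-sample behavior).
    """
    out = []
    L = len(cols)
    for i in range(L):
        if cols[i] is None:
            continue
        for j in range(i + 1, L):
            if cols[j] is None:
                continue
            di, ti = cols[i]
            dj, tj = cols[j]
            both = ti & tj
            S = int(both.sum())
            if S < 3:
                continue
            X = di[both]
            Y = dj[both]
            r2 = _pair_r2(X, Y, S)
            if r2.size == 0:
                continue
            null_mean = np.nan
            if expectation == "empirical":
                null_vals = []
                for _ in range(n_null):
                    null_vals.append(np.mean(_pair_r2(
                        X[rng.permutation(S)], Y, S)))
                null_mean = float(np.mean(null_vals))
            out.append((i, j, S, int(r2.size), float(np.mean(r2)), null_mean))
    if not out:
        raise ValueError("no usable locus pairs")
    return out


def _aggregate_r2(table) -> tuple[float, float, float, int]:
    """Comparison-weighted means: (r2_bar, null_bar, S_bar, n_comparisons)."""
    w = np.array([S * k for _, _, S, k, _, _ in table], dtype=float)
    r2bar = float(np.average([m for *_, m, _ in table], weights=w))
    nulls = [nm for *_, nm in table]
    null_bar = float(np.average(nulls, weights=w)) if np.isfinite(nulls).all() \
        else float("nan")
    Sbar = float(np.average([S for _, _, S, _, _, _ in table],
                            weights=[k for _, _, _, k, _, _ in table]))
    ncomp = int(sum(k for _, _, _, k, _, _ in table))
    return r2bar, null_bar, Sbar, ncomp


def _analytic_expectation(S: float) -> tuple[float, float, float]:
    """Published sampling expectation of r^2 and inversion constants."""
    if S >= 30:
        return 1.0 / S + 3.19 / S ** 2, 1.0 / 3.0, 2.76
    return 0.0018 + 0.907 / S + 4.44 / S ** 2, 0.308, 2.08


def _invert_r2prime(r2p: float, a: float = 1.0 / 3.0,
                    b: float = 2.76) -> float:
    """Drift relation r' = a/N - (a*b - ...)/N^2 inverted for N; the
    quadratic solution of r' = 1/(3N) - 0.69/N^2 in the default case."""
    if r2p <= 0:
        return INFINITE
    disc = max(a ** 2 - b * r2p, 0.0)
    return (a + np.sqrt(disc)) / (2.0 * r2p)


def ldne_estimate(ds: Dataset, populations: list[str] | str | None = None,
                  pcrit: float = 0.02, ci: str = "jackknife_loci",
                  ci_level: float = 0.95, expectation: str = "empirical",
                  n_null: int = 12, seed: int = 0) -> NeEstimate:
    """Linkage-disequilibrium effective size from a single sample.

    ``populations``: one label, a list pooled together, or None for the
    whole dataset.  Alleles rarer than ``pcrit`` are excluded.

    The drift signal is the mean squared Burrows composite correlation
    minus its sampling expectation.  With ``expectation="empirical"``
    (default) that expectation is estimated for this exact statistic by
    permuting genotypes among individuals within each locus pair
    (``n_null`` replicates, seeded); ``expectation="analytic"`` uses the
    published E[r^2|S] curves instead.  N_E then solves
    r2' = 1/(3 N_E) - 0.69/N_E^2; r2' <= 0 reports "infinite".  CI by
    jackknife over loci (default) or parametric chi-square.
    """
    if populations is None:
        idx = np.arange(ds.n_individuals)
    elif isinstance(populations, str):
        idx = ds.population_index(populations)
    else:
        idx = np.concatenate([ds.population_index(p) for p in populations])
    if idx.size < 10:
        logger.warning("LD method with S=%d (<10) is unreliable", idx.size)
    cols = _dosage_columns(ds, idx, pcrit)
    usable = [c for c in cols if c is not None]
    if len(usable) < 2:
        raise ValueError("need >= 2 polymorphic loci after pcrit screening")
    rng = np.random.default_rng(seed)
    table = _pair_table(cols, expectation, n_null, rng)
    r2bar, null_bar, S, ncomp = _aggregate_r2(table)
    if expectation == "empirical":
        exp = null_bar
        a, b = 1.0 / 3.0, 2.76
    elif expectation == "analytic":
        exp, a, b = _analytic_expectation(S)
    else:
        raise ValueError(f"unknown expectation mode {expectation!r}")
    r2p = r2bar - exp
    point = _invert_r2prime(r2p, a, b)
    internals = {"r2_mean": r2bar, "r2_expectation": exp, "r2_prime": r2p,
                 "S": S, "n_comparisons": ncomp, "pcrit": pcrit,
                 "expectation": expectation}
    z = float(norm.ppf(1 - (1 - ci_level) / 2))
    ci_tuple = None
    if ci == "jackknife_loci":
        drops = sorted({i for i, j, *_ in table} | {j for _, j, *_ in table})
        vals = []
        for drop in drops:
            sub = [row for row in table if drop not in row[:2]]
            if not sub:
                continue
            r2_i, null_i, _, _ = _aggregate_r2(sub)
            vals.append(r2_i - (null_i if expectation == "empirical" else exp))
        if len(vals) > 2:
            vals = np.array(vals)
            var = (len(vals) - 1) / len(vals) * np.sum((vals - vals.mean()) ** 2)
            sd = np.sqrt(var)
            ci_tuple = (_invert_r2prime(r2p + z * sd, a, b),
                        _invert_r2prime(r2p - z * sd, a, b))
    elif ci == "parametric":
        df = ncomp
        lo_r2 = r2bar * df / chi2.ppf(1 - (1 - ci_level) / 2, df)
        hi_r2 = r2bar * df / chi2.ppf((1 - ci_level) / 2, df)
        ci_tuple = (_invert_r2prime(hi_r2 - exp, a, b),
                    _invert_r2prime(lo_r2 - exp, a, b))
    return NeEstimate(method="LD", point=point, ci=ci_tuple,
                      ci_level=ci_level, internals=internals)


# ---------------------------------------------------------------------------
# Temporal methods
# ---------------------------------------------------------------------------

def _freq_vectors(ds: Dataset, population: str):
    """Per locus: (allele labels, freq vector, n diploid typed)."""
    out = []
    for li in range(ds.n_loci):
        g = ds.population_genotypes(population)[:, li, :]
        vals = g[g[:, 0] > 0]
        if vals.shape[0] == 0:
            out.append(None)
            continue
        alleles, counts = np.unique(vals.ravel(), return_counts=True)
        out.append((alleles, counts / vals.size, vals.shape[0], counts))
    return out


def temporal_moment_ne(sample_0: Dataset, sample_t: Dataset,
                       t_generations: float, population_0: str | None = None,
                       population_t: str | None = None,
                       ci_level: float = 0.95) -> NeEstimate:
    """Moment (F_k) temporal effective size, sample plan II.

    F_k per locus = (1/K) sum_i (x_i - y_i)^2 / ((x_i + y_i)/2 - x_i y_i)
    over the union of alleles seen in either sample; the across-locus
    mean is weighted by allele count.  N_E = t / (2 [F_k - 1/(2 S_0) -
    1/(2 S_t)]), infinite when the bracket is <= 0.
    """
    p0 = population_0 or sample_0.populations[0]
    pt = population_t or sample_t.populations[0]
    if sample_0.loci != sample_t.loci:
        raise ValueError("samples must share the same loci")
    f0 = _freq_vectors(sample_0, p0)
    ft = _freq_vectors(sample_t, pt)
    fks, ks = [], []
    S0s, Sts = [], []
    for a0, at in zip(f0, ft):
        if a0 is None or at is None:
            continue
        alleles = np.union1d(a0[0], at[0])
        x = np.array([a0[1][list(a0[0]).index(a)] if a in a0[0] else 0.0
                      for a in alleles])
        y = np.array([at[1][list(at[0]).index(a)] if a in at[0] else 0.0
                      for a in alleles])
        present = (x + y) > 0
        x, y = x[present], y[present]
        if x.size < 2:
            continue
        denom = (x + y) / 2.0 - x * y
        good = denom > 0
        if not good.any():
            continue
        fk = float(np.mean((x[good] - y[good]) ** 2 / denom[good]))
        fks.append(fk)
        ks.append(int(good.sum()))
        S0s.append(a0[2])
        Sts.append(at[2])
    if not fks:
        raise ValueError("no informative loci for temporal comparison")
    ks = np.array(ks, dtype=float)
    fk_bar = float(np.average(fks, weights=ks))
    S0 = float(np.mean(S0s))
    St = float(np.mean(Sts))
    bracket = fk_bar - 1.0 / (2 * S0) - 1.0 / (2 * St)
    point = t_generations / (2.0 * bracket) if bracket > 0 else INFINITE
    # chi-square CI on F_k with df = total independent alleles
    df = float((ks - 1).sum()) or 1.0
    lo_fk = fk_bar * df / chi2.ppf(1 - (1 - ci_level) / 2, df)
    hi_fk = fk_bar * df / chi2.ppf((1 - ci_level) / 2, df)
    ci = []
    for f in (hi_fk, lo_fk):
        br = f - 1.0 / (2 * S0) - 1.0 / (2 * St)
        ci.append(t_generations / (2.0 * br) if br > 0 else INFINITE)
    return NeEstimate(method="temporal_moment", point=point,
                      ci=(ci[0], ci[1]), ci_level=ci_level,
                      internals={"F_k": fk_bar, "t": t_generations,
                                 "S0": S0, "St": St, "df": df})


def temporal_likelihood_ne(sample_0: Dataset, sample_t: Dataset,
                           t_generations: float,
                           ne_grid: np.ndarray | None = None,
                           population_0: str | None = None,
                           population_t: str | None = None,
                           n_p0_grid: int = 128) -> NeEstimate:
    """Pseudo-likelihood temporal effective size on an N_E grid.

    Per locus and allele: the initial frequency has a Beta posterior from
    sample 0 (uniform prior); drift over t generations is approximated by
    a moment-matched Beta transition with variance p(1-p)(1-(1-1/(2N))^t);
    the later sample count is binomial.  The profile pseudo-likelihood is
    the product over alleles and loci; the CI is the 2-unit support drop.
    """
    if ne_grid is None:
        ne_grid = np.unique(np.round(np.geomspace(5, 1e5, 120)).astype(int))
    ne_grid = np.asarray(ne_grid, dtype=float)
    p0grid = (np.arange(n_p0_grid) + 0.5) / n_p0_grid       # open (0,1)
    pop0 = population_0 or sample_0.populations[0]
    popt = population_t or sample_t.populations[0]
    f0 = _freq_vectors(sample_0, pop0)
    ft = _freq_vectors(sample_t, popt)
    F = 1.0 - (1.0 - 1.0 / (2.0 * ne_grid)) ** t_generations  # (G,)
    c = (1.0 - F) / F                                          # (G,)
    loglik = np.zeros(ne_grid.size)
    for a0, at in zip(f0, ft):
        if a0 is None or at is None:
            continue
        alleles = np.union1d(a0[0], at[0])
        n0 = 2 * a0[2]
        nt = 2 * at[2]
        for al in alleles:
            x0 = int(a0[3][list(a0[0]).index(al)]) if al in a0[0] else 0
            xt = 0
            if al in at[0]:
                xt = int(round(at[1][list(at[0]).index(al)] * nt))
            # Beta posterior of p0 (uniform prior) on the grid
            lw = (x0 * np.log(p0grid) + (n0 - x0) * np.log1p(-p0grid))
            lw -= logsumexp(lw)
            # Beta-binomial of x_t given p0 and N_E
            aa = np.outer(c, p0grid)                  # (G, P)
            bb = np.outer(c, 1.0 - p0grid)
            lbb = (betaln(xt + aa, nt - xt + bb) - betaln(aa, bb)
                   + gammaln(nt + 1) - gammaln(xt + 1) - gammaln(nt - xt + 1))
            loglik += logsumexp(lbb + lw[None, :], axis=1)
    best = int(np.argmax(loglik))
    if best in (0, ne_grid.size - 1):
        logger.warning("temporal likelihood maximized at grid boundary; "
                       "consider widening ne_grid")
    support = loglik - loglik[best]
    inside = np.nonzero(support >= -2.0)[0]
    ci = (float(ne_grid[inside[0]]), float(ne_grid[inside[-1]]))
    point = float(ne_grid[best])
    if best == ne_grid.size - 1:
        point = INFINITE
    return NeEstimate(method="temporal_likelihood", point=point, ci=ci,
                      internals={"ne_grid": ne_grid, "loglik": loglik,
                                 "t": t_generations})


# ---------------------------------------------------------------------------
# Removal (without-replacement) census estimation
# ---------------------------------------------------------------------------

def removal_census_posterior(survey: RemovalSurvey, n_max: int | None = None,
                             n_step: int = 1, n_p: int = 512,
                             level: float = 0.95) -> CensusPosterior:
    """Grid posterior over census size N from a removal survey.

    Uniform priors on N in {K_T, ..., n_max} and capture probability p in
    (0, 1); occasion t contributes Binomial(n_t; N - K_{t-1}, p).  The
    update is sequential (each occasion's posterior is the next prior),
    which is identical to the joint product.  Returns the marginal
    posterior on N with its mean and HPD interval.
    """
    catches = survey.catches
    if catches.size < 2:
        raise ValueError("N not identifiable from a single occasion")
    if survey.total == 0:
        raise ValueError("need at least one positive catch")
    K = survey.total
    if n_max is None:
        n_max = max(10 * K, K + 100)
    if n_max <= K:
        raise ValueError("n_max must exceed the total catch")
    n_grid = np.arange(K, n_max + 1, n_step)
    p_grid = (np.arange(n_p) + 0.5) / n_p
    logp = np.log(p_grid)
    log1mp = np.log1p(-p_grid)
    joint = np.zeros((n_grid.size, p_grid.size))
    prev = 0
    for n_t in catches:
        avail = n_grid - prev                     # N - K_{t-1}
        ok = avail >= n_t
        lchoose = np.where(
            ok,
            gammaln(avail + 1) - gammaln(n_t + 1) - gammaln(np.maximum(avail - n_t, 0) + 1),
            -np.inf,
        )
        joint += lchoose[:, None] + n_t * logp[None, :] \
            + np.maximum(avail - n_t, 0)[:, None] * log1mp[None, :]
        joint[~ok, :] = -np.inf
        prev += n_t
    flat = joint - logsumexp(joint)
    marg = np.exp(logsumexp(flat, axis=1))
    marg /= marg.sum()
    mean_n = float(np.sum(n_grid * marg))
    hpd = hpd_interval(n_grid, marg, level)
    return CensusPosterior(n_grid=n_grid, p_grid=p_grid, joint_log=joint,
                           marginal_n=marg, mean_n=mean_n, hpd=hpd,
                           hpd_level=level)


def hpd_interval(grid: np.ndarray, weights: np.ndarray,
                 level: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous grid interval holding >= ``level`` mass."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    csum = np.concatenate([[0.0], np.cumsum(w)])
    n = w.size
    best = (0, n - 1)
    best_len = np.inf
    j = 0
    for i in range(n):
        j = max(j, i)
        while j < n and csum[j + 1] - csum[i] < level - 1e-12:
            j += 1
        if j == n:
            break
        length = grid[j] - grid[i]
        if length < best_len:
            best_len = length
            best = (i, j)
    return float(grid[best[0]]), float(grid[best[1]])


def ne_nc_ratio(ne: float | NeEstimate, nc: float | CensusPosterior,
                decimals: int = 3) -> float:
    """Point ratio N_E / N_C (sentinel NaN when N_E is infinite)."""
    ne_v = ne.point if isinstance(ne, NeEstimate) else float(ne)
    nc_v = nc.mean_n if isinstance(nc, CensusPosterior) else float(nc)
    if not np.isfinite(ne_v):
        return float("nan")
    if ne_v <= 0 or nc_v <= 0:
        raise ValueError("sizes must be positive")
    return round(ne_v / nc_v, decimals)


def generations_between(months: float, generations_per_year: float = 8.0) -> float:
    """Generations elapsed over a span of months (default 8 gen/year)."""
    return months / 12.0 * generations_per_year
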