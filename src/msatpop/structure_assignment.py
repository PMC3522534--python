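"""Model-free genetic clustering and frequency-likelihood assignment.

Clustering follows the discriminant-analysis-of-principal-components
recipe: individuals are coded as centered allele-dosage vectors, reduced
by PCA, clustered by k-means over a range of k with a BIC criterion, and
a linear discriminant analysis on the retained principal components gives
cluster memberships and posteriors.  Migrant detection compares each
individual's Hardy-Weinberg genotype likelihood (log10) under its home
cluster's allele frequencies — computed leave-one-out — with the best
other cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .genotype_io import Dataset

logger = logging.getLogger(__name__)

__all__ = [
    "DapcModel",
    "MigrantCall",
    "allele_dosage_matrix",
    "find_clusters",
    "dapc_fit",
    "assignment_loglik",
    "detect_migrants",
]


@dataclass
class DapcModel:
    n_pcs: int
    a_scores: dict                       # candidate n_pcs -> mean a-score
    k: int
    assignments: np.ndarray              # (n,) cluster index
    posteriors: np.ndarray               # (n, k)
    discriminant_scores: np.ndarray      # (n, k-1)
    bic: dict = field(default_factory=dict)

    def scatter_frame(self, ds: Dataset) -> pd.DataFrame:
        cols = {f"LD{i+1}": self.discriminant_scores[:, i]
                for i in range(self.discriminant_scores.shape[1])}
        cols["cluster"] = self.assignments
        cols["id"] = [ind.id for ind in ds.individuals]
        return pd.DataFrame(cols)


@dataclass
class MigrantCall:
    individual_id: str
    home: str
    loglik: dict                          # cluster -> log10 likelihood
    best_other: str
    lam: float                            # logL(home) - max logL(other)
    flagged_at: list


def allele_dosage_matrix(ds: Dataset, impute: str = "grand_mean"):
    """Individuals x alleles dosage matrix (0/1/2 copies).

    Missing genotypes are imputed by the grand mean dosage of each allele
    column (population means are avoided so the imputation cannot leak
    group labels into the ordination).
    Returns (X, column labels [(locus, allele), ...]).
    """
    cols = []
    mats = []
    for li, locus in enumerate(ds.loci):
        g = ds.genotypes[:, li, :]
        alleles = np.unique(g[g > 0])
        if alleles.size == 0:
            continue
        dos = (g[:, 0, None] == alleles).astype(float) + (g[:, 1, None] == alleles)
        missing = g[:, 0] == 0
        if missing.any():
            if impute == "grand_mean":
                mean = dos[~missing].mean(axis=0) if (~missing).any() else 0.0
                dos[missing] = mean
            else:
                raise ValueError(f"unknown imputation {impute!r}")
        mats.append(dos)
        cols.extend((locus, int(a)) for a in alleles)
    X = np.hstack(mats)
    return X, cols


def _pca_scores(X: np.ndarray, n_pcs: int) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    return (U * s)[:, :n_pcs]


def find_clusters(ds: Dataset, k_range=range(1, 9), n_pcs: int | None = None,
                  n_starts: int = 10, seed: int | None = None):
    """PCA + k-means clustering with BIC model choice.

    BIC(k) = n ln(WSS_k / n) + k ln(n); the returned k minimizes BIC.
    Returns dict with 'bic', 'k', 'assignments', 'scores'.
    """
    X, _ = allele_dosage_matrix(ds)
    n = X.shape[0]
    max_pcs = min(n - 1, X.shape[1])
    if n_pcs is None:
        n_pcs = max_pcs
    n_pcs = min(n_pcs, max_pcs)
    scores = _pca_scores(X, n_pcs)
    k_range = [k for k in k_range if k <= n - 1] or [1]
    if max(k_range) > n - 1:
        logger.warning("k_range truncated to n-1=%d", n - 1)
    rng = np.random.default_rng(seed)
    bic = {}
    labels = {}
    for k in k_range:
        if k == 1:
            wss = float(((scores - scores.mean(axis=0)) ** 2).sum())
            labels[k] = np.zeros(n, dtype=int)
        else:
            km = KMeans(n_clusters=k, n_init=n_starts,
                        random_state=int(rng.integers(2 ** 31)))
            labels[k] = km.fit_predict(scores)
            wss = float(km.inertia_)
        wss = max(wss, 1e-12)
        bic[k] = n * np.log(wss / n) + k * np.log(n)
    best = min(bic, key=bic.get)
    return {"bic": bic, "k": best, "assignments": labels[best],
            "scores": scores, "n_pcs": n_pcs}


def _reassignment_proportion(scores, labels, n_pcs, seed) -> float:
    lda = LinearDiscriminantAnalysis()
    lda.fit(scores[:, :n_pcs], labels)
    return float(np.mean(lda.predict(scores[:, :n_pcs]) == labels))


def dapc_fit(ds: Dataset, clusters: np.ndarray, n_pcs: int | str = "auto",
             seed: int | None = None, n_label_perms: int = 10) -> DapcModel:
    """Discriminant analysis of principal components.

    With ``n_pcs="auto"`` the retained PC count maximizes the mean
    a-score: observed correct-reassignment proportion minus the mean
    reassignment proportion after permuting cluster labels.
    """
    clusters = np.asarray(clusters)
    uniq, y = np.unique(clusters, return_inverse=True)
    k = uniq.size
    if k < 2 or np.min(np.bincount(y)) < 2:
        raise ValueError("need >= 2 clusters with >= 2 members each")
    X, _ = allele_dosage_matrix(ds)
    n = X.shape[0]
    hard_max = min(n - k - 1, X.shape[1])
    if hard_max < 1:
        raise ValueError("too few individuals for any retained PCs")
    scores_full = _pca_scores(X, hard_max)
    rng = np.random.default_rng(seed)
    a_scores: dict[int, float] = {}
    if n_pcs == "auto":
        candidates = sorted(set(np.unique(np.linspace(1, hard_max, num=min(hard_max, 12), dtype=int))))
        for c in candidates:
            obs = _reassignment_proportion(scores_full, y, c, seed)
            perm = []
            for _ in range(n_label_perms):
                perm.append(_reassignment_proportion(
                    scores_full, rng.permutation(y), c, seed))
            a_scores[c] = obs - float(np.mean(perm))
        n_pcs = max(a_scores, key=a_scores.get)
    else:
        n_pcs = int(n_pcs)
        if n_pcs >= n - k:
            raise ValueError(f"n_pcs={n_pcs} >= n - k = {n - k} (overfit guard)")
        n_pcs = min(n_pcs, hard_max)
    lda = LinearDiscriminantAnalysis(n_components=k - 1)
    Z = scores_full[:, :n_pcs]
    lda.fit(Z, y)
    post = lda.predict_proba(Z)
    ld_scores = lda.transform(Z)
    assign = np.argmax(post, axis=1)
    return DapcModel(n_pcs=int(n_pcs), a_scores=a_scores, k=k,
                     assignments=uniq[assign], posteriors=post,
                     discriminant_scores=ld_scores)


# ---------------------------------------------------------------------------
# Frequency-likelihood assignment / migrant detection
# ---------------------------------------------------------------------------

def assignment_loglik(ds: Dataset, clusters: dict[str, str] | np.ndarray,
                      leave_one_out: bool = True,
                      zero_freq: str = "1/(2n+1)") -> pd.DataFrame:
    """Per-individual log10 genotype likelihood under each cluster.

    logL(individual | cluster) = sum over typed loci of log10 P(genotype)
    under Hardy-Weinberg with the cluster's allele frequencies (2pq for
    heterozygotes, p^2 for homozygotes).  The focal individual's alleles
    are removed from its home cluster's counts before computing that
    cluster's frequencies (leave-one-out).  Alleles absent from a cluster
    get pseudo-frequency 1/(2n+1) (or epsilon 0.01 with zero_freq="eps").

    ``clusters`` maps population -> cluster label, or is a per-individual
    label array.  Returns a DataFrame indexed by individual id with one
    log-likelihood column per cluster plus 'home'.
    """
    if isinstance(clusters, dict):
        home = np.array([clusters[ind.population] for ind in ds.individuals])
    else:
        home = np.asarray(clusters)
    labels = list(dict.fromkeys(home))
    rows_out = np.zeros((ds.n_individuals, len(labels)))
    typed_any = np.zeros(ds.n_individuals, dtype=bool)
    for li in range(ds.n_loci):
        g = ds.genotypes[:, li, :]
        alleles = np.unique(g[g > 0])
        if alleles.size == 0:
            continue
        A = alleles.size
        aidx = {int(a): i for i, a in enumerate(alleles)}
        dos = (g[:, 0, None] == alleles).astype(float) + (g[:, 1, None] == alleles)
        typed = g[:, 0] > 0
        typed_any |= typed
        counts = np.zeros((len(labels), A))
        genes = np.zeros(len(labels))
        for ci, lab in enumerate(labels):
            sel = (home == lab) & typed
            counts[ci] = dos[sel].sum(axis=0)
            genes[ci] = 2 * sel.sum()
        for i in np.nonzero(typed)[0]:
            a, b = int(g[i, 0]), int(g[i, 1])
            ia, ib = aidx[a], aidx[b]
            hi = labels.index(home[i])
            for ci in range(len(labels)):
                c = counts[ci].copy()
                tot = genes[ci]
                if leave_one_out and ci == hi:
                    c[ia] -= 1
                    c[ib] -= 1
                    tot -= 2
                if tot <= 0:
                    continue
                pa, pb = c[ia] / tot, c[ib] / tot
                if zero_freq == "1/(2n+1)":
                    floor = 1.0 / (tot + 1)
                elif zero_freq == "eps":
                    floor = 0.01
                else:
                    raise ValueError(f"unknown zero_freq {zero_freq!r}")
                pa = max(pa, floor)
                pb = max(pb, floor)
                if a == b:
                    prob = pa * pa
                else:
                    prob = 2 * pa * pb
                rows_out[i, ci] += np.log10(prob)
    if (~typed_any).any():
        dropped = [ds.individuals[i].id for i in np.nonzero(~typed_any)[0]]
        logger.warning("individuals untyped at all loci excluded: %s", dropped)
    df = pd.DataFrame(rows_out, columns=labels,
                      index=[ind.id for ind in ds.individuals])
    df["home"] = home
    return df[typed_any]


def detect_migrants(loglik: pd.DataFrame, thresholds=(0.5, 1.0)):
    """Flag putative migrants by the assignment log-likelihood ratio.

    Lambda = log10 L(home) - max over other clusters of log10 L; an
    individual is flagged at threshold T when Lambda < T.  Returns the
    list of MigrantCall and a DataFrame of per-ordered-cluster-pair
    flagged counts at each threshold.
    """
    clusters = [c for c in loglik.columns if c != "home"]
    calls = []
    counts = {t: {} for t in thresholds}
    for ind_id, row in loglik.iterrows():
        home = row["home"]
        others = [c for c in clusters if c != home]
        ll = {c: float(row[c]) for c in clusters}
        best_other = max(others, key=lambda c: ll[c])
        lam = ll[home] - ll[best_other]
        flagged = [t for t in thresholds if lam < t]
        calls.append(MigrantCall(str(ind_id), home, ll, best_other, lam, flagged))
        for t in flagged:
            key = (home, best_other)
            counts[t][key] = counts[t].get(key, 0) + 1
    rows = []
    for t in thresholds:
        for (src, dst), c in sorted(counts[t].items()):
            rows.append({"threshold": t, "home": src, "best_other": dst,
                         "n_flagged": c})
    return calls, pd.DataFrame(rows, columns=["threshold", "home",
                                              "best_other", "n_flagged"])
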