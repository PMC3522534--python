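"""Isolation-by-distance regression and dispersal parameters.

Under a stepping-stone model at drift-migration equilibrium, linearized
F_ST between population pairs, y = F_ST / (1 - F_ST), increases with
geographic separation: linearly in distance d for movement along a line
(1D) and linearly in ln d for movement over a surface (2D).  The 2D
slope estimates 1/(4 pi D sigma^2), where D is the effective density of
breeders and sigma^2 the axial dispersal variance per generation, so a
fitted slope plus an independent N_E and habitat area yield sigma,
sigma^2, Wright's neighborhood size W_N = 4 pi D sigma^2 = 1/slope, and
a stepping-stone migration rate m = sigma^2 / epsilon^2 for inter-deme
distance epsilon.  Significance of the slope is assessed by a Mantel
permutation of population labels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .differentiation import PairwiseFst
from .genotype_io import haversine_km

logger = logging.getLogger(__name__)

__all__ = [
    "IBDFit",
    "DispersalEstimate",
    "linearized_fst_matrix",
    "ibd_regression",
    "mantel_test",
    "derive_dispersal",
]


@dataclass
class IBDFit:
    model: str                    # "1D" or "2D"
    pairs: pd.DataFrame           # columns pop1, pop2, theta, y, d_km, x
    slope: float
    intercept: float
    mantel_p: float | None
    n_perm: int
    seed: int | None
    subset: str = "all"


@dataclass
class DispersalEstimate:
    group: str
    model: str
    density: float                # breeders per km^2 (2D) or per km (1D)
    sigma: float                  # km per generation
    sigma2: float                 # km^2 (2D) or km (1D-scaled) per generation
    neighborhood: float | None    # W_N (2D only)
    m: float | None               # migration rate per generation
    ne_used: float
    habitat: float
    epsilon: float | None


def linearized_fst_matrix(pairwise: PairwiseFst,
                          coords: dict[str, tuple[float, float]]) -> pd.DataFrame:
    """Pair table of linearized F_ST and great-circle distance.

    y = theta/(1 - theta); theta = 1 pairs are undefined and excluded;
    duplicate coordinates give d = 0 (flagged, excluded from 2D fits).
    Negative theta values are retained.
    """
    labels = pairwise.labels
    missing = [l for l in labels if l not in coords]
    if missing:
        raise ValueError(f"no coordinates for populations: {missing}")
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            th = pairwise.theta[i, j]
            if np.isnan(th):
                logger.warning("pair (%s, %s): theta undefined, excluded",
                               labels[i], labels[j])
                continue
            if th >= 1.0:
                logger.warning("pair (%s, %s): theta = 1, y undefined",
                               labels[i], labels[j])
                continue
            d = haversine_km(*coords[labels[i]], *coords[labels[j]])
            if d == 0:
                logger.warning("pair (%s, %s): identical coordinates (d=0)",
                               labels[i], labels[j])
            rows.append({"pop1": labels[i], "pop2": labels[j],
                         "theta": th, "y": th / (1.0 - th), "d_km": d})
    return pd.DataFrame(rows, columns=["pop1", "pop2", "theta", "y", "d_km"])


def ibd_regression(pairs: pd.DataFrame, model: str = "2D",
                   n_perm: int = 10_000, seed: int | None = None,
                   subset: str = "all") -> IBDFit:
    """Least-squares y-on-x regression with Mantel significance.

    x = d for the 1D model, ln d for 2D (d = 0 pairs excluded from 2D).
    The Mantel test permutes population labels, which jointly permutes
    the y and d matrices' rows/columns; the p-value is one-sided for a
    positive slope.
    """
    pairs = pairs.copy()
    if model == "1D":
        pairs["x"] = pairs["d_km"]
    elif model == "2D":
        pairs = pairs[pairs["d_km"] > 0].copy()
        pairs["x"] = np.log(pairs["d_km"])
    else:
        raise ValueError("model must be '1D' or '2D'")
    if len(pairs) < 3:
        raise ValueError("need >= 3 population pairs")
    if pairs["x"].nunique() == 1:
        raise ValueError("no predictor variance: all distances equal")
    labels = sorted(set(pairs["pop1"]) | set(pairs["pop2"]))
    k = len(labels)
    pos = {l: i for i, l in enumerate(labels)}
    Y = np.full((k, k), np.nan)
    X = np.full((k, k), np.nan)
    for _, row in pairs.iterrows():
        i, j = pos[row["pop1"]], pos[row["pop2"]]
        Y[i, j] = Y[j, i] = row["y"]
        X[i, j] = X[j, i] = row["x"]

    def slope_of(Ym: np.ndarray) -> tuple[float, float]:
        iu = np.triu_indices(k, 1)
        y, x = Ym[iu], X[iu]
        good = ~np.isnan(y) & ~np.isnan(x)
        b, a = np.polyfit(x[good], y[good], 1)
        return float(b), float(a)

    b_obs, a_obs = slope_of(Y)
    p = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(k)
            b_p, _ = slope_of(Y[np.ix_(perm, perm)])
            if b_p >= b_obs - 1e-15:
                count += 1
        p = (count + 1) / (n_perm + 1)
    return IBDFit(model=model, pairs=pairs, slope=b_obs, intercept=a_obs,
                  mantel_p=p, n_perm=n_perm, seed=seed, subset=subset)


def mantel_test(matrix_a: np.ndarray, matrix_b: np.ndarray,
                n_perm: int = 10_000, seed: int | None = None):
    """Mantel correlation between two distance matrices.

    Rows/columns of the second matrix are permuted jointly;
    p = (b + 1)/(n_perm + 1), one-sided for positive correlation.
    Returns (correlation, p).
    """
    A = np.asarray(matrix_a, dtype=float)
    B = np.asarray(matrix_b, dtype=float)
    if A.shape != B.shape or A.shape[0] != A.shape[1]:
        raise ValueError("matrices must be square and of equal size")
    k = A.shape[0]
    iu = np.triu_indices(k, 1)

    def corr(Bm):
        a, b = A[iu], Bm[iu]
        return float(np.corrcoef(a, b)[0, 1])

    r_obs = corr(B)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(k)
        if corr(B[np.ix_(perm, perm)]) >= r_obs - 1e-15:
            count += 1
    return r_obs, (count + 1) / (n_perm + 1)


def derive_dispersal(fit: IBDFit, ne: float, habitat: float,
                     epsilon: float | None = None,
                     group: str = "") -> DispersalEstimate:
    """Dispersal parameters from an IBD slope and an effective size.

    2D: D = ne/area; sigma^2 = 1/(4 pi b D); W_N = 1/b; sigma = sqrt.
    1D: D = ne/length; sigma^2 = 1/(4 b D).
    m = sigma^2/epsilon^2 (stepping-stone relation) when epsilon given.
    """
    b = fit.slope
    if b <= 0:
        raise ValueError("no isolation-by-distance signal; dispersal not derivable")
    if ne <= 0 or habitat <= 0:
        raise ValueError("ne and habitat must be positive")
    D = ne / habitat
    if fit.model == "2D":
        sigma2 = 1.0 / (4.0 * math.pi * b * D)
        wn = 1.0 / b
    else:
        sigma2 = 1.0 / (4.0 * b * D)
        wn = None
    sigma = math.sqrt(sigma2)
    m = sigma2 / epsilon ** 2 if epsilon else None
    return DispersalEstimate(group=group, model=fit.model, density=D,
                             sigma=sigma, sigma2=sigma2, neighborhood=wn,
                             m=m, ne_used=ne, habitat=habitat, epsilon=epsilon)
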