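"""Ordination-based structure inference and constrained ordination.

PCA of mean-imputed dosages, discriminant analysis of principal components
(DAPC) with reassignment a-score, K-means BIC over a range of cluster
numbers, distance-based Moran's eigenvector maps (dbMEMs), redundancy
analysis (RDA) and partial RDA with permutation tests, variance partitioning,
and the conversion of constrained-variance fractions to "F_ST explained".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "OrdinationResult",
    "RdaResult",
    "pca_genotypes",
    "dapc",
    "kmeans_bic",
    "dbmem",
    "rda",
    "varpart",
    "varpart_fst",
]


@dataclass
class OrdinationResult:
    scores: np.ndarray              # individuals x retained axes
    eigenvalues: np.ndarray         # all axes, non-increasing
    n_retained: int
    retained_fraction: float
    group_centroids: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        ev = np.asarray(self.eigenvalues)
        if np.any(np.diff(ev) > 1e-8 * max(1.0, abs(ev[0]))):
            raise ValueError("eigenvalues must be non-increasing")
        if not 0 < self.retained_fraction <= 1 + 1e-12:
            raise ValueError("retained fraction must be in (0, 1]")


@dataclass
class RdaResult:
    constrained_fraction: float      # PTCV as a fraction of total variance
    partition: dict                  # pure/joint fractions per variable block
    p_values: dict                   # permutation p per term
    n_perm: int
    extras: dict = field(default_factory=dict)


def impute_dosages(g: GenotypeMatrix) -> np.ndarray:
    """Dosage matrix as float with missing cells mean-imputed per locus."""
    x = g.genotypes.astype(float)
    x[x == MISSING] = np.nan
    col_mean = np.nanmean(x, axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    idx = np.where(np.isnan(x))
    x[idx] = col_mean[idx[1]]
    return x


def pca_genotypes(
    g: GenotypeMatrix | np.ndarray,
    n_components: int | None = None,
    retention: str = "kaiser",
) -> OrdinationResult:
    """Centered (not scaled) PCA of the dosage matrix.

    ``retention`` "kaiser" keeps axes with eigenvalue above the mean
    eigenvalue (Kaiser-Guttman); "all" keeps every positive axis;
    ``n_components`` overrides both.
    """
    x = impute_dosages(g) if isinstance(g, GenotypeMatrix) else np.asarray(g, float)
    if x.shape[1] > 50_000:
        warnings.warn("more than 50k loci: dense eigendecomposition will be slow")
    xc = x - x.mean(axis=0)
    n = x.shape[0]
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    ev = s**2 / (n - 1)
    scores = u * s
    if n_components is not None:
        k = int(n_components)
    elif retention == "kaiser":
        k = int((ev > ev[ev > 1e-12].mean()).sum())
    else:
        k = int((ev > 1e-12).sum())
    k = max(1, min(k, len(ev)))
    total = ev.sum()
    groups = None
    if isinstance(g, GenotypeMatrix):
        groups = (
            pd.DataFrame(scores[:, :k])
            .assign(population=g.individuals["population"].to_numpy())
            .groupby("population")
            .mean()
        )
    return OrdinationResult(
        scores=scores[:, :k],
        eigenvalues=ev,
        n_retained=k,
        retained_fraction=float(ev[:k].sum() / total),
        group_centroids=groups,
        extras={"loadings": vt[:k].T},
    )


def dapc(
    g: GenotypeMatrix,
    groups: np.ndarray | None = None,
    n_pcs: int = 32,
    n_rand: int = 10,
    seed: int | None = None,
) -> OrdinationResult:
    """Discriminant analysis of principal components.

    LDA on the first ``n_pcs`` PC scores with ``groups`` (default: population
    labels) as priors. Returns discriminant scores, eigenvalues, the observed
    correct-reassignment rate and the a-score (observed rate minus its mean
    under ``n_rand`` random relabelings).
    """
    if groups is None:
        groups = g.individuals["population"].to_numpy()
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    n_groups = len(labels)
    if n_pcs >= g.n_individuals - n_groups:
        raise ValueError("n_pcs must be < n_individuals - n_groups")
    pca = pca_genotypes(g, n_components=n_pcs)
    X = pca.scores
    rng = np.random.default_rng(seed)

    def fit_rate(y, X=X):
        lda = LinearDiscriminantAnalysis(solver="eigen")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            while True:
                try:
                    lda.fit(X, y)
                    break
                except np.linalg.LinAlgError:
                    if X.shape[1] <= n_groups:
                        raise
                    X = X[:, : X.shape[1] - 1]
                    warnings.warn("singular within-group covariance; dropping a PC")
        return lda, float((lda.predict(X) == y).mean())

    lda, rate = fit_rate(groups)
    rand_rates = [fit_rate(rng.permutation(groups))[1] for _ in range(n_rand)]
    a_score = rate - float(np.mean(rand_rates))
    dscores = lda.transform(X)
    ev = np.sort(np.abs(lda.explained_variance_ratio_))[::-1]
    cent = (
        pd.DataFrame(dscores).assign(group=groups).groupby("group").mean()
    )
    return OrdinationResult(
        scores=dscores,
        eigenvalues=ev,
        n_retained=dscores.shape[1],
        retained_fraction=1.0,
        group_centroids=cent,
        extras={
            "reassignment_rate": rate,
            "a_score": a_score,
            "random_rates": rand_rates,
            "pc_retained_fraction": pca.retained_fraction,
            "posterior": lda.predict_proba(X),
        },
    )


def kmeans_bic(
    scores: np.ndarray,
    k_range=range(1, 13),
    n_init: int = 20,
    seed: int | None = None,
) -> pd.DataFrame:
    """BIC of K-means clustering per k: n ln(WSS/n) + k d ln(n)."""
    X = np.asarray(scores, dtype=float)
    n, d = X.shape
    rows = []
    for k in k_range:
        if k >= n:
            break
        if k == 1:
            wss = float(((X - X.mean(axis=0)) ** 2).sum())
        else:
            km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
            wss = float(km.inertia_)
        bic = n * np.log(wss / n) + k * d * np.log(n)
        rows.append((k, wss, bic))
    return pd.DataFrame(rows, columns=["k", "wss", "bic"])


def moran_i(values: np.ndarray, weights: np.ndarray) -> float:
    """Moran's I of a site-level variable under a spatial weight matrix."""
    z = np.asarray(values, float) - np.mean(values)
    w = np.asarray(weights, float)
    s0 = w.sum()
    n = len(z)
    return float(n / s0 * (z @ w @ z) / (z @ z))


def dbmem(distances_km: np.ndarray) -> pd.DataFrame:
    """Distance-based Moran's eigenvector maps for a set of sites.

    Truncates the distance matrix at the longest minimum-spanning-tree edge t
    (entries beyond t are set to 4t), performs PCoA of the Gower-centered
    squared distances, and keeps eigenvectors with positive eigenvalue whose
    Moran's I (connectivity weights: within truncation distance) exceeds the
    expectation -1/(n-1).
    """
    D = np.asarray(distances_km, dtype=float)
    n = D.shape[0]
    if n < 3:
        raise ValueError("need at least 3 sites")
    if np.all(D[np.triu_indices(n, 1)] == 0):
        raise ValueError("all sites coincident")
    mst = minimum_spanning_tree(D).toarray()
    t = mst.max()
    Dt = np.where(D > t + 1e-12, 4.0 * t, D)
    np.fill_diagonal(Dt, 0.0)
    A = -0.5 * Dt**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    ev, vec = np.linalg.eigh(G)
    order = np.argsort(ev)[::-1]
    ev, vec = ev[order], vec[:, order]
    W = ((D <= t + 1e-12) & (D > 0)).astype(float)
    e_i = -1.0 / (n - 1)
    keep, morans = [], []
    for j in range(n):
        if ev[j] <= 1e-10 * max(1.0, ev[0]):
            continue
        I = moran_i(vec[:, j], W)
        if I > e_i:
            keep.append(j)
            morans.append(I)
    if not keep:
        raise ValueError("no dbMEM with Moran's I above expectation")
    cols = vec[:, keep] * np.sqrt(ev[keep])
    out = pd.DataFrame(cols, columns=[f"dbMEM{i+1}" for i in range(len(keep))])
    out.attrs["eigenvalues"] = ev[keep]
    out.attrs["morans_i"] = np.array(morans)
    out.attrs["truncation_km"] = float(t)
    return out


def _fit_r2(Y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    """Fraction of total Y variance captured by the column space of X."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    q, r = np.linalg.qr(Xc)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())
    if not keep.all():
        warnings.warn("collinear explanatory columns dropped")
        q = q[:, keep]
    fitted = q @ (q.T @ Yc)
    tot = (Yc**2).sum()
    return float(min((fitted**2).sum() / tot, 1.0)), int(keep.sum())


def rda(
    Y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
    strata: np.ndarray | None = None,
) -> RdaResult:
    """(Partial) redundancy analysis with a permutation F-test.

    Y: response matrix (e.g. retained PC scores per individual); X:
    explanatory block; Z: optional conditioning block (pRDA residualizes
    both Y and X on Z first). The permutation test permutes rows of the
    (residualized) response; p uses the (1+k)/(1+B) convention, so its floor
    is 1/(B+1). ``strata`` restricts permutations to within groups (rows are
    shuffled only among rows sharing a stratum label), for designs where
    only units within a block are exchangeable.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.ndim == 1:
        X = X[:, None]
    n = Y.shape[0]
    rng = np.random.default_rng(seed)
    if Z is not None:
        Z = np.asarray(Z, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        Zc = Z - Z.mean(axis=0)
        qz, _ = np.linalg.qr(Zc)
        Yc = Y - Y.mean(axis=0)
        Y = Yc - qz @ (qz.T @ Yc)
        Xc = X - X.mean(axis=0)
        X = Xc - qz @ (qz.T @ Xc)
    r2, rank = _fit_r2(Y, X)
    resid_df = n - rank - 1 - (0 if Z is None else np.linalg.matrix_rank(Z - Z.mean(axis=0)))
    resid_df = max(resid_df, 1)
    def f_stat(r2v):
        if 1.0 - r2v < 1e-12:
            return np.inf
        return (r2v / rank) / ((1 - r2v) / resid_df)

    f_obs = f_stat(r2)
    if strata is not None:
        strata = np.asarray(strata)
        groups = [np.flatnonzero(strata == s) for s in np.unique(strata)]
    else:
        groups = None

    def count_ge(perms):
        k_ge = k_gt = 0
        for perm in perms:
            r2p, _ = _fit_r2(Y[perm], X)
            fp = f_stat(r2p)
            if fp >= f_obs * (1 - 1e-12) - 1e-12:
                k_ge += 1
                if fp > f_obs * (1 + 1e-12) + 1e-12:
                    k_gt += 1
        return k_ge, k_gt

    exhaustive = None
    if groups is not None:
        from itertools import permutations as iperm
        from itertools import product
        from math import factorial

        total = int(np.prod([factorial(len(g)) for g in groups]))
        if total <= n_perm:
            # enumerate the whole within-strata permutation group exactly
            per_group = [list(iperm(g)) for g in groups]
            exhaustive = []
            for combo in product(*per_group):
                perm = np.arange(n)
                for idx, arranged in zip(groups, combo):
                    perm[idx] = np.array(arranged)
                exhaustive.append(perm)
    if exhaustive is not None:
        # identity is part of the group: p = #{F_perm >= F_obs} / #perms
        k_ge, k_gt = count_ge(exhaustive)
        n_total = len(exhaustive)
        p = k_ge / n_total
        n_perm = n_total - 1
    else:
        def draw_perm():
            if groups is None:
                return rng.permutation(n)
            perm = np.arange(n)
            for idx in groups:
                perm[idx] = idx[rng.permutation(len(idx))]
            return perm

        k_ge, k_gt = count_ge(draw_perm() for _ in range(n_perm))
        n_total = n_perm + 1
        p = (1 + k_ge) / n_total
    return RdaResult(
        constrained_fraction=r2,
        partition={"full": r2},
        p_values={"full": p},
        n_perm=n_perm,
        extras={"F": f_obs, "rank": rank, "k_ge": k_ge, "k_gt": k_gt,
                "n_perm_total": n_total},
    )


def varpart(
    Y: np.ndarray, X1: np.ndarray, X2: np.ndarray,
    n_perm: int = 1000, seed: int | None = None,
) -> RdaResult:
    """Two-block variance partitioning with pRDA term tests.

    Fractions (unadjusted R^2): pure X1, pure X2 and joint sum exactly to the
    full-model constrained fraction. Term p-values come from pRDA of each
    block conditioned on the other.
    """
    X1 = np.atleast_2d(np.asarray(X1, float).T).T
    X2 = np.atleast_2d(np.asarray(X2, float).T).T
    full = rda(Y, np.hstack([X1, X2]), n_perm=n_perm, seed=seed)
    r2_1, _ = _fit_r2(np.asarray(Y, float), X1)
    r2_2, _ = _fit_r2(np.asarray(Y, float), X2)
    pure1 = full.constrained_fraction - r2_2
    pure2 = full.constrained_fraction - r2_1
    joint = r2_1 + r2_2 - full.constrained_fraction
    p1 = rda(Y, X1, Z=X2, n_perm=n_perm, seed=seed).p_values["full"]
    p2 = rda(Y, X2, Z=X1, n_perm=n_perm, seed=seed).p_values["full"]
    return RdaResult(
        constrained_fraction=full.constrained_fraction,
        partition={"pure_X1": pure1, "pure_X2": pure2, "joint": joint,
                   "marginal_X1": r2_1, "marginal_X2": r2_2},
        p_values={"full": full.p_values["full"], "X1": p1, "X2": p2},
        n_perm=n_perm,
        extras=full.extras,
    )


def varpart_fst(
    explained_fraction: float,
    pc_retained_fraction: float,
    fst_denominator: float,
) -> float:
    """Portion of among-population differentiation (F_ST) explained.

    (fraction of retained-PC variance explained) x (fraction of total
    variance retained in the PCs) / (F_ST denominator). Applied to the total
    constrained fraction or to any pure fraction.
    """
    if fst_denominator <= 0:
        raise ValueError("F_ST denominator must be positive")
    if not 0 < pc_retained_fraction <= 1:
        raise ValueError("pc_retained_fraction must be in (0, 1]")
    return explained_fraction * pc_retained_fraction / fst_denominator
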