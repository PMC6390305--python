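"""Per-locus and pairwise population statistics.

Weir-Cockerham F_ST, nucleotide diversity, Tajima's D, composite LD r^2,
hierarchical AMOVA on gene copies, Mantel tests, one-tailed rank-sum tests
and FDR control. These are the shared primitives of the outlier scan and the
downstream enrichment/decay analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "pairwise_fst",
    "wc_fst_components",
    "nucleotide_diversity",
    "prop_pairwise_differences",
    "tajimas_d",
    "tajima_constants",
    "ld_r2",
    "amova",
    "AmovaResult",
    "mantel_test",
    "wilcoxon_one_tailed",
    "fdr_adjust",
]


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) theta
# ---------------------------------------------------------------------------

def _pop_summaries(g: GenotypeMatrix, pops: list[str]):
    """Per population: called counts, minor-allele freqs, observed het rates."""
    ns, ps, hs = [], [], []
    for pop in pops:
        sub = g.genotypes[g.pop_indices(pop)]
        called = sub != MISSING
        n = called.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(called, sub, 0).sum(axis=0) / (2.0 * n)
            h = (sub == 1).sum(axis=0) / n
        ns.append(n)
        ps.append(p)
        hs.append(h)
    return np.array(ns), np.array(ps), np.array(hs)


def wc_fst_components(g: GenotypeMatrix, pops: list[str]):
    """Per-locus Weir-Cockerham variance components (a, b, c).

    Loci where any population has fewer than 2 called individuals are
    returned as NaN components and do not contribute to ratio-of-sums
    aggregates.
    """
    n, p, h = _pop_summaries(g, pops)
    r = len(pops)
    valid = (n >= 2).all(axis=0)
    n = np.where(n >= 2, n, np.nan)
    nbar = n.mean(axis=0)
    nc = (r * nbar - (n**2).sum(axis=0) / (r * nbar)) / (r - 1)
    pbar = (n * p).sum(axis=0) / (r * nbar)
    s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n * h).sum(axis=0) / (r * nbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
    c = hbar / 2.0
    a = np.where(valid, a, np.nan)
    b = np.where(valid, b, np.nan)
    c = np.where(valid, c, np.nan)
    return a, b, c


def pairwise_fst(g: GenotypeMatrix, popA: str, popB: str):
    """Weir-Cockerham theta per locus and genome-wide (ratio of sums).

    Returns (theta_per_locus, theta_genome_wide, components) where
    components is a DataFrame with columns a, den. Per-locus negative values
    are retained.
    """
    a, b, c = wc_fst_components(g, [popA, popB])
    den = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = a / den
    ok = np.isfinite(a) & np.isfinite(den)
    if not ok.any():
        raise ValueError("no locus with >= 2 called individuals in both populations")
    theta_gw = float(np.nansum(a[ok]) / np.nansum(den[ok]))
    comp = pd.DataFrame({"a": a, "den": den})
    return theta, theta_gw, comp


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

def nucleotide_diversity(g: GenotypeMatrix, population: str | None = None):
    """Per-SNP unbiased pairwise diversity pi and its mean over loci.

    pi per SNP = (n/(n-1)) * 2 p (1-p) over called gene copies, which equals
    the average proportion of pairwise allelic differences at the site.
    SNP-panel-conditional: inflated relative to genome-wide diversity.
    """
    if population is None:
        sub = g.genotypes
    else:
        sub = g.genotypes[g.pop_indices(population)]
    called = sub != MISSING
    n = 2.0 * called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, sub, 0).sum(axis=0) / n
        pi = np.where(n >= 2, 2.0 * p * (1 - p) * n / (n - 1), np.nan)
    return pi, float(np.nanmean(pi))


def prop_pairwise_differences(g: GenotypeMatrix, popA: str, popB: str):
    """Mean between-population proportion of pairwise differences per SNP:
    p_A (1 - p_B) + p_B (1 - p_A), averaged over loci."""
    pA = g.allele_freq(popA)
    pB = g.allele_freq(popB)
    d = pA * (1 - pB) + pB * (1 - pA)
    return d, float(np.nanmean(d))


def tajima_constants(n: int) -> dict[str, float]:
    """Tajima (1989) normalizing constants for sample size n gene copies."""
    if n < 4:
        raise ValueError("need at least 4 gene copies")
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": e1, "e2": e2}


def tajimas_d_from_summary(theta_pi: float, S: int, n: int) -> float:
    """Tajima's D from summed pairwise diversity, segregating sites, and n."""
    if S < 1:
        return np.nan
    k = tajima_constants(n)
    num = theta_pi - S / k["a1"]
    den = np.sqrt(k["e1"] * S + k["e2"] * S * (S - 1))
    return float(num / den) if den > 0 else np.nan


def tajimas_d(
    g: GenotypeMatrix,
    populations: list[str] | None = None,
    window_bp: int = 75,
) -> pd.DataFrame:
    """Tajima's D per window of SNPs grouped on the same scaffold.

    Windows are ``window_bp``-wide tiles (default 75, a sequence-tag length).
    n is taken as the rounded mean number of called gene copies over the
    window's loci; windows with S = 0 or n < 4 are returned as NaN and
    flagged. Returns a DataFrame (scaffold, window_start, S, n, theta_pi, D).
    """
    if populations is None:
        idx = np.arange(g.n_individuals)
    else:
        idx = np.concatenate([g.pop_indices(p) for p in populations])
    sub = g.genotypes[idx]
    called = sub != MISSING
    ncop = 2.0 * called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, sub, 0).sum(axis=0) / ncop
        pi = np.where(ncop >= 2, 2.0 * p * (1 - p) * ncop / (ncop - 1), np.nan)
    seg = (p > 0) & (p < 1)
    scaffold = g.loci["scaffold"].to_numpy()
    win = (g.loci["pos"].to_numpy() - 1) // window_bp * window_bp + 1
    rows = []
    key = pd.DataFrame({"scaffold": scaffold, "window_start": win})
    for (scaf, w0), sub_idx in key.groupby(["scaffold", "window_start"], sort=False).groups.items():
        j = np.asarray(sub_idx)
        S = int(seg[j].sum())
        n_mean = float(np.nanmean(ncop[j]))
        n_int = int(round(n_mean))
        theta_pi = float(np.nansum(pi[j][seg[j]]))
        if S >= 1 and n_int >= 4:
            D = tajimas_d_from_summary(theta_pi, S, n_int)
        else:
            D = np.nan
        rows.append((scaf, int(w0), S, n_int, theta_pi, D))
    return pd.DataFrame(rows, columns=["scaffold", "window_start", "S", "n", "theta_pi", "D"])


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

def ld_r2(dosA: np.ndarray, dosB: np.ndarray, min_shared: int = 20) -> float:
    """Composite-LD r^2: squared Pearson correlation of dosages.

    Computed across individuals with both loci called; NaN when fewer than
    ``min_shared`` shared calls or either locus is monomorphic among them.
    """
    shared = (dosA != MISSING) & (dosB != MISSING)
    if shared.sum() < min_shared:
        return np.nan
    x = dosA[shared].astype(float)
    y = dosB[shared].astype(float)
    if x.std() == 0 or y.std() == 0:
        return np.nan
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def pairwise_r2_matrix(dosages: np.ndarray, min_shared: int = 20) -> np.ndarray:
    """r^2 for all column pairs of a dosage matrix (missing pairwise-dropped)."""
    n_loci = dosages.shape[1]
    out = np.full((n_loci, n_loci), np.nan)
    for i in range(n_loci):
        for j in range(i + 1, n_loci):
            out[i, j] = out[j, i] = ld_r2(dosages[:, i], dosages[:, j], min_shared)
    return out


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclass
class AmovaResult:
    """Three-level AMOVA: among groups / among populations within groups /
    within populations, on gene copies with allelic-mismatch distance."""

    df: dict[str, int]
    sigma2: dict[str, float]
    pct_variation: dict[str, float]
    phi: dict[str, float]          # phi_CT, phi_SC, phi_ST
    p_values: dict[str, float]


def _copies_from_genotypes(g: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Expand genotypes to gene copies: (2N, L) 0/1 with -1 missing."""
    dos = g.genotypes
    c1 = np.where(dos == MISSING, MISSING, (dos >= 1).astype(np.int8))
    c2 = np.where(dos == MISSING, MISSING, (dos == 2).astype(np.int8))
    copies = np.empty((2 * dos.shape[0], dos.shape[1]), dtype=np.int8)
    copies[0::2] = c1
    copies[1::2] = c2
    ind_of_copy = np.repeat(np.arange(dos.shape[0]), 2)
    return copies, ind_of_copy


def _amova_ss(copies: np.ndarray, pop_of_copy: np.ndarray,
              group_of_pop: np.ndarray, n_pops: int, n_groups: int):
    """Sums of squared deviations per level, summed over loci.

    For 0/1 allelic data the within-set SS at a locus equals k(n-k)/n where
    k copies carry the allele among n called copies in the set.
    """
    L = copies.shape[1]
    calledm = (copies != MISSING)

    def ss_of_sets(set_of_copy, n_sets):
        k = np.zeros((n_sets, L))
        n = np.zeros((n_sets, L))
        for s in range(n_sets):
            rows = copies[set_of_copy == s]
            m = rows != MISSING
            k[s] = np.where(m, rows, 0).sum(axis=0)
            n[s] = m.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            ss = np.where(n > 0, k * (n - k) / n, 0.0)
        return ss.sum()

    ss_total = ss_of_sets(np.zeros(len(pop_of_copy), dtype=int), 1)
    ss_within_pops = ss_of_sets(pop_of_copy, n_pops)
    group_of_copy = group_of_pop[pop_of_copy]
    ss_within_groups = ss_of_sets(group_of_copy, n_groups)
    ss_among_pops_within_groups = ss_within_groups - ss_within_pops
    ss_among_groups = ss_total - ss_within_groups
    return ss_among_groups, ss_among_pops_within_groups, ss_within_pops


def _amova_components(ssa, ssb, ssw, pop_sizes, group_of_pop, n_groups):
    """Variance components from mean squares with unequal-size coefficients."""
    pop_sizes = np.asarray(pop_sizes, dtype=float)
    N = pop_sizes.sum()
    P = len(pop_sizes)
    G = n_groups
    df_a, df_b, df_w = G - 1, P - G, int(N) - P
    group_sizes = np.array([pop_sizes[group_of_pop == g].sum() for g in range(G)])
    sum_n2_over_group = sum(
        (pop_sizes[group_of_pop == g] ** 2).sum() / group_sizes[g] for g in range(G)
    )
    n1 = (N - sum_n2_over_group) / max(df_b, 1)
    n2 = (sum_n2_over_group - (pop_sizes**2).sum() / N) / max(df_a, 1)
    n3 = (N - (group_sizes**2).sum() / N) / max(df_a, 1)
    ms_a = ssa / df_a if df_a else np.nan
    ms_b = ssb / df_b if df_b else np.nan
    ms_w = ssw / df_w
    sig_c = ms_w
    sig_b = (ms_b - sig_c) / n1 if df_b else 0.0
    sig_a = (ms_a - sig_c - n2 * sig_b) / n3 if df_a else 0.0
    return (df_a, df_b, df_w), (sig_a, sig_b, sig_c)


def amova(
    g: GenotypeMatrix,
    groups: dict[str, str],
    n_perm: int = 999,
    seed: int | None = None,
) -> AmovaResult:
    """Hierarchical AMOVA on gene copies (allelic mismatch distance).

    ``groups`` maps population label -> group label. Permutation p-values:
    phi_ST permutes copies among populations, phi_SC permutes copies among
    populations within groups, phi_CT permutes whole populations among
    groups; all use the (1+k)/(1+B) convention.
    """
    pops = g.populations
    group_labels = sorted(set(groups[p] for p in pops))
    if len(group_labels) < 2:
        raise ValueError("need at least 2 groups")
    group_of_pop = np.array([group_labels.index(groups[p]) for p in pops])
    pop_index = {p: i for i, p in enumerate(pops)}
    copies, ind_of_copy = _copies_from_genotypes(g)
    pop_of_ind = np.array([pop_index[p] for p in g.individuals["population"]])
    pop_of_copy = pop_of_ind[ind_of_copy]
    n_pops, n_groups = len(pops), len(group_labels)
    pop_sizes = np.array([(pop_of_copy == i).sum() for i in range(n_pops)])

    ssa, ssb, ssw = _amova_ss(copies, pop_of_copy, group_of_pop, n_pops, n_groups)
    (df_a, df_b, df_w), (sig_a, sig_b, sig_c) = _amova_components(
        ssa, ssb, ssw, pop_sizes, group_of_pop, n_groups
    )
    total = sig_a + sig_b + sig_c
    phi_ct = sig_a / total
    phi_sc = sig_b / (sig_b + sig_c)
    phi_st = (sig_a + sig_b) / total

    rng = np.random.default_rng(seed)
    exceed = {"phi_CT": 0, "phi_SC": 0, "phi_ST": 0}
    for _ in range(n_perm):
        # phi_ST: copies among populations, ignoring groups
        perm = rng.permutation(pop_of_copy)
        pssa, pssb, pssw = _amova_ss(copies, perm, group_of_pop, n_pops, n_groups)
        _, (sa, sb, sc) = _amova_components(pssa, pssb, pssw, pop_sizes, group_of_pop, n_groups)
        if (sa + sb) / (sa + sb + sc) >= phi_st:
            exceed["phi_ST"] += 1
        # phi_SC: copies among populations within their group
        perm2 = pop_of_copy.copy()
        for grp in range(n_groups):
            mask = group_of_pop[pop_of_copy] == grp
            perm2[mask] = rng.permutation(pop_of_copy[mask])
        pssa, pssb, pssw = _amova_ss(copies, perm2, group_of_pop, n_pops, n_groups)
        _, (sa, sb, sc) = _amova_components(pssa, pssb, pssw, pop_sizes, group_of_pop, n_groups)
        if sb / (sb + sc) >= phi_sc:
            exceed["phi_SC"] += 1
        # phi_CT: whole populations among groups
        gperm = rng.permutation(group_of_pop)
        pssa, pssb, pssw = _amova_ss(copies, pop_of_copy, gperm, n_pops, n_groups)
        _, (sa, sb, sc) = _amova_components(pssa, pssb, pssw, pop_sizes, gperm, n_groups)
        if sa / (sa + sb + sc) >= phi_ct:
            exceed["phi_CT"] += 1
    p_values = {k: (1 + v) / (1 + n_perm) for k, v in exceed.items()}

    pct = {
        "among_groups": 100.0 * sig_a / total,
        "among_pops_within_groups": 100.0 * sig_b / total,
        "within_pops": 100.0 * sig_c / total,
    }
    return AmovaResult(
        df={"among_groups": df_a, "among_pops_within_groups": df_b,
            "within_pops": df_w, "total": df_a + df_b + df_w},
        sigma2={"among_groups": sig_a, "among_pops_within_groups": sig_b,
                "within_pops": sig_c},
        pct_variation=pct,
        phi={"phi_CT": phi_ct, "phi_SC": phi_sc, "phi_ST": phi_st},
        p_values=p_values,
    )


# ---------------------------------------------------------------------------
# Mantel, rank tests, FDR
# ---------------------------------------------------------------------------

def _offdiag(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def mantel_test(
    m1: np.ndarray,
    m2: np.ndarray,
    n_perm: int = 9999,
    tail: str = "greater",
    seed: int | None = None,
    exhaustive: bool = False,
) -> tuple[float, float]:
    """Mantel correlation between two symmetric distance matrices.

    Pearson r over upper-triangle entries; p by permuting the row/column
    order of m2 with the (1+k)/(1+B) convention. ``exhaustive`` enumerates
    all orderings (small matrices only).
    """
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    n = m1.shape[0]
    if n < 3 or m1.shape != m2.shape:
        raise ValueError("need matching square matrices with >= 3 populations")
    x = _offdiag(m1)
    if x.std() == 0 or _offdiag(m2).std() == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")

    def corr(perm):
        y = _offdiag(m2[np.ix_(perm, perm)])
        return np.corrcoef(x, y)[0, 1]

    obs = corr(np.arange(n))
    if exhaustive:
        from itertools import permutations

        rs = np.array([corr(np.array(p)) for p in permutations(range(n))])
        if tail == "greater":
            p = float((rs >= obs - 1e-12).mean())
        else:
            p = float((rs <= obs + 1e-12).mean())
        return float(obs), p
    rng = np.random.default_rng(seed)
    k = 0
    for _ in range(n_perm):
        r = corr(rng.permutation(n))
        if (tail == "greater" and r >= obs - 1e-12) or (
            tail == "less" and r <= obs + 1e-12
        ):
            k += 1
    return float(obs), (1 + k) / (1 + n_perm)


def wilcoxon_one_tailed(x, y, alternative: str = "less") -> float:
    """One-tailed Wilcoxon rank-sum (Mann-Whitney) p-value.

    Midrank ties; exact enumeration for small tie-free samples, normal
    approximation with continuity correction otherwise (scipy's auto rule).
    Degenerate all-tied inputs return 1.0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0
    return float(sps.mannwhitneyu(x, y, alternative=alternative, method="auto").pvalue)


def fdr_adjust(p_values, method: str = "BH", q: float = 0.05):
    """Step-up FDR adjustment. Returns (adjusted p-values, rejection flags).

    method "BH" (Benjamini-Hochberg) or "BY" (Benjamini-Yekutieli, with the
    harmonic-sum inflation).
    """
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    sm_method = {"BH": "fdr_bh", "BY": "fdr_by"}[method.upper()]
    reject, p_adj, _, _ = multipletests(p, alpha=q, method=sm_method)
    return p_adj, reject
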