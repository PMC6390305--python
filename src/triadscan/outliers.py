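"""Island-model F_ST outlier scan with heterozygosity-conditional p-values.

The null surface is the joint distribution of (H_e, F_ST) for two sampled
demes of a symmetric finite-island model at migration-drift equilibrium.
Each simulated locus draws an ancestral frequency x with density
proportional to 1/(x(1-x)) (the low-mutation infinite-alleles limit
collapsed to two alleles), starts all demes undifferentiated at x, and runs
a discrete Wright-Fisher island simulation: per generation, deterministic
mixing toward the metapopulation mean at a realized migrant fraction drawn
once per generation and deme (a genome-wide dataset experiences one shared
demographic history), then binomial resampling of the 2N gene copies. The
finite-population behaviour of rare variants — which a beta approximation
understates — is thereby represented. Diploid genotypes are sampled from
two demes without replacement at the user's sample sizes; optionally the
same GBS observation model as the data (overdispersed depths, per-allele
cap, sequencing error, binomial-likelihood calling, call-rate filter) is
applied before computing Weir-Cockerham theta and sample H_e.

The migration parameter Nm is solved by search so that the surface's
*trimmed* mean theta (loci within the conditional 5-95% envelope) matches
the target; the two-pass calibration culls provisional outliers from the
data the same way, making the comparison trim-for-trim under neutrality.
Two outlier definitions are emitted per locus: the operational envelope
call (conditional p outside [0.05, 0.95], the definition whose ~5% per-
comparison false-positive rate the triad intersection design absorbs) and
the far more stringent step-up FDR call on upper-tail p-values reported at
the surface's simulation resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .stats import fdr_adjust, pairwise_fst

__all__ = ["NullFstSurface", "ObservationModel", "simulate_null", "calibrate_mean",
           "outlier_scan"]

_X_EPS = 1e-3  # ancestral-frequency truncation


@dataclass(frozen=True)
class ObservationModel:
    """GBS depth-and-calling layer applied to simulated null genotypes."""

    depth_mean: float = 26.0
    depth_shape: float = 3.0
    depth_cap: int = 127
    min_call_reads: int = 5
    dropout: float = 0.03
    error_rate: float = 0.01
    # the data passed this filter, so simulated null loci must too
    min_locus_callrate: float = 0.85


@dataclass
class NullFstSurface:
    """Simulated (H_e, theta) pairs under the island-model null."""

    he: np.ndarray
    fst: np.ndarray
    a: np.ndarray                   # W-C numerator per simulated locus
    den: np.ndarray                 # W-C denominator per simulated locus
    target_mean_fst: float
    achieved_mean_fst: float        # trimmed (conditional 5-95% envelope)
    params: dict = field(default_factory=dict)

    # -- conditional machinery -------------------------------------------
    def _edges(self, n_bins: int, min_bin: int) -> np.ndarray:
        edges = np.unique(np.quantile(self.he, np.linspace(0, 1, n_bins + 1)))
        while len(edges) > 2:
            counts = np.histogram(self.he, bins=edges)[0]
            if counts.min() >= min_bin:
                break
            i = int(np.argmin(counts))
            edges = np.delete(edges, i + 1 if i < len(counts) - 1 else i)
        if (np.histogram(self.he, bins=edges)[0] == 0).any():
            raise ValueError("empty H_e bin after pooling")
        return edges

    def _bin_of(self, he, edges) -> np.ndarray:
        return np.clip(np.searchsorted(edges, np.asarray(he), side="right") - 1,
                       0, len(edges) - 2)

    def conditional_p(self, he_obs, fst_obs, n_bins: int = 50, min_bin: int = 500,
                      return_bin_sizes: bool = False, smooth_seed: int | None = None):
        """Lower-tail conditional empirical p: (1 + #{sim theta <= obs}) /
        (1 + n_bin) within the observed locus's equal-count H_e bin.

        With ``smooth_seed`` set, ties between the observed theta and
        simulated values are broken uniformly at random (randomized
        probability integral transform): under a perfectly matching null the
        result is exactly uniform, which the discrete rare-allele theta atoms
        otherwise prevent. Outlier decisions use the unsmoothed, conservative
        version.
        """
        he_obs = np.asarray(he_obs, dtype=float)
        fst_obs = np.asarray(fst_obs, dtype=float)
        edges = self._edges(n_bins, min_bin)
        bin_sim = self._bin_of(self.he, edges)
        bin_obs = self._bin_of(he_obs, edges)
        rng = None if smooth_seed is None else np.random.default_rng(smooth_seed)
        p = np.empty(len(he_obs))
        sizes = np.empty(len(he_obs), dtype=int)
        for b in range(len(edges) - 1):
            sel = bin_obs == b
            if not sel.any():
                continue
            sims = np.sort(self.fst[bin_sim == b])
            lo = np.searchsorted(sims, fst_obs[sel], side="left")
            hi = np.searchsorted(sims, fst_obs[sel], side="right")
            if rng is None:
                p[sel] = (1.0 + hi) / (1.0 + len(sims))
            else:
                u = rng.random(int(sel.sum()))
                p[sel] = (lo + u * (hi - lo + 1)) / (1.0 + len(sims))
            sizes[sel] = len(sims)
        if return_bin_sizes:
            return p, sizes
        return p

    def upper_tail_p(self, he_obs, fst_obs, n_bins: int = 20, min_bin: int = 500):
        """Upper-tail conditional p at the surface's simulation resolution.

        Loci with at least one simulated value above them in their H_e bin
        get the empirical (1 + #{sim >= obs})/(1 + n_bin) p-value. A locus
        exceeding every simulated value at its heterozygosity is below the
        resolution of its bin; it is reported at the resolution bound of the
        whole surface, 1/(1 + n_loci) — the "p-simulated < 1/n_sims"
        convention of simulation-based outlier scans.
        """
        he_obs = np.asarray(he_obs, dtype=float)
        fst_obs = np.asarray(fst_obs, dtype=float)
        edges = self._edges(n_bins, min_bin)
        bin_sim = self._bin_of(self.he, edges)
        bin_obs = self._bin_of(he_obs, edges)
        p = np.empty(len(he_obs))
        for b in range(len(edges) - 1):
            sel = bin_obs == b
            if not sel.any():
                continue
            sims = np.sort(self.fst[bin_sim == b])
            n = len(sims)
            cnt = n - np.searchsorted(sims, fst_obs[sel], side="left")
            p_emp = (1.0 + cnt) / (1.0 + n)
            p_emp[cnt == 0] = 1.0 / (1.0 + len(self.fst))
            p[sel] = p_emp
        return p

    def trimmed_mean(self, envelope=(0.05, 0.95), n_bins: int = 50,
                     min_bin: int = 500) -> float:
        """Ratio-of-sums theta over simulated loci inside the conditional
        envelope (per-H_e-bin theta quantiles)."""
        edges = self._edges(n_bins, min_bin)
        bins = self._bin_of(self.he, edges)
        keep = np.zeros(len(self.he), dtype=bool)
        for b in range(len(edges) - 1):
            m = bins == b
            if not m.any():
                continue
            lo, hi = np.quantile(self.fst[m], envelope)
            keep[m] = (self.fst[m] > lo) & (self.fst[m] < hi)
        return float(self.a[keep].sum() / self.den[keep].sum())


def island_equilibrium_F(Nm: float, n_demes: int) -> float:
    k = (n_demes / (n_demes - 1.0)) ** 2
    return 1.0 / (1.0 + 4.0 * Nm * k)


def _wc_two_samples(narr, parr, harr):
    """Weir-Cockerham components for r=2 vectorized over loci."""
    r = 2
    nbar = narr.mean(axis=0)
    nc = (r * nbar - (narr**2).sum(axis=0) / (r * nbar)) / (r - 1)
    pbar = (narr * parr).sum(axis=0) / (r * nbar)
    s2 = (narr * (parr - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (narr * harr).sum(axis=0) / (r * nbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
    c = hbar / 2.0
    return a, b, c, pbar


def _observe(dosage, obs: ObservationModel, rng):
    """Apply the GBS depth model and binomial-likelihood calling; returns
    called dosage with MISSING. Vectorized closed-form argmax of the three
    genotype log-likelihoods (shared binomial coefficient cancels)."""
    shape = dosage.shape
    p_nb = obs.depth_shape / (obs.depth_shape + obs.depth_mean)
    total = rng.negative_binomial(obs.depth_shape, p_nb, size=shape)
    total[rng.random(shape) < obs.dropout] = 0
    p_alt = np.array([obs.error_rate, 0.5, 1.0 - obs.error_rate])[dosage]
    alt = rng.binomial(total, p_alt)
    ref = np.minimum(total - alt, obs.depth_cap)
    alt = np.minimum(alt, obs.depth_cap)
    le, l1e, lh = np.log(obs.error_rate), np.log(1 - obs.error_rate), np.log(0.5)
    ll0 = ref * l1e + alt * le
    ll1 = (ref + alt) * lh
    ll2 = ref * le + alt * l1e
    called = np.argmax(np.stack([ll0, ll1, ll2]), axis=0).astype(np.int8)
    called[ref + alt < obs.min_call_reads] = MISSING
    return called


def _simulate_surface(
    Nm: float,
    sample_sizes,
    n_loci: int,
    rng: np.random.Generator,
    n_demes: int,
    deme_size: int,
    generations: int,
    obs: ObservationModel | None,
    min_maf: float = 0.025,
):
    """One surface draw at fixed island migration Nm."""
    n1, n2 = int(sample_sizes[0]), int(sample_sizes[1])
    d = n_demes
    N2 = 2 * deme_size
    m_tot = Nm / deme_size
    if m_tot >= 1:
        m_tot = 0.999
    he = np.empty(n_loci)
    out_a = np.empty(n_loci)
    out_den = np.empty(n_loci)
    filled = 0
    while filled < n_loci:
        # oversample: many rare-ancestral-frequency loci come back
        # monomorphic in the sample and are discarded (FDIST convention)
        m = int(1.5 * (n_loci - filled)) + 500
        aa = np.log((1 - _X_EPS) / _X_EPS)
        x = 1.0 / (1.0 + np.exp(-rng.uniform(-aa, aa, m)))
        # demes start undifferentiated; the Wright-Fisher run itself builds
        # the between-deme variance toward migration-drift equilibrium.
        # Realized migrant fractions are drawn once per generation and deme,
        # shared across loci: a genome-wide dataset experiences one
        # demographic history, which narrows the across-locus F distribution
        # relative to integrating over histories independently per locus.
        p = x[None, :].repeat(d, 0)
        for _ in range(generations):
            pbar = p.mean(axis=0)
            m_real = rng.binomial(deme_size, min(m_tot, 1.0), size=d) / deme_size
            p_next = (1 - m_real[:, None]) * p + m_real[:, None] * pbar[None, :]
            p = rng.binomial(N2, p_next) / N2
        # sample diploid genotypes from the first two demes: 2n gene copies
        # drawn without replacement from the deme's 2N copies (the demes are
        # finite, so binomial sampling would overstate the sampling variance)
        narr = np.array([[float(n1)], [float(n2)]]) * np.ones((1, m))
        ps, hs, ns = [], [], []
        for i, n in ((0, n1), (1, n2)):
            K = np.rint(p[i] * N2).astype(np.int64)
            k_sample = rng.hypergeometric(K, N2 - K, 2 * n)
            slots = np.arange(2 * n)[:, None] < k_sample[None, :]
            order = rng.random((2 * n, m)).argsort(axis=0)
            arranged = np.take_along_axis(slots, order, axis=0)
            dos = (arranged[0::2].astype(np.int8) + arranged[1::2])
            if obs is not None:
                dos = _observe(dos, obs, rng)
                calledm = dos != MISSING
                ncall = calledm.sum(axis=0).astype(float)
                with np.errstate(invalid="ignore", divide="ignore"):
                    freq = np.where(calledm, dos, 0).sum(axis=0) / (2 * ncall)
                    het = (dos == 1).sum(axis=0) / ncall
                ns.append(np.where(ncall >= 2, ncall, np.nan))
                ps.append(freq)
                hs.append(het)
            else:
                ns.append(np.full(m, float(n)))
                ps.append(dos.mean(axis=0) / 2.0)
                hs.append((dos == 1).mean(axis=0))
        narr = np.array(ns)
        a_c, b_c, c_c, pbar_s = _wc_two_samples(narr, np.array(ps), np.array(hs))
        he_new = 2.0 * pbar_s * (1.0 - pbar_s)
        maf = np.minimum(pbar_s, 1 - pbar_s)
        good = (he_new > 0) & np.isfinite(a_c) & np.isfinite(he_new)
        good &= maf >= min_maf
        if obs is not None:
            callrate = (narr[0] + narr[1]) / (n1 + n2)
            good &= callrate >= obs.min_locus_callrate
        keep = np.flatnonzero(good)
        keep = keep[: n_loci - filled]
        sl = slice(filled, filled + len(keep))
        he[sl] = he_new[keep]
        out_a[sl] = a_c[keep]
        out_den[sl] = (a_c + b_c + c_c)[keep]
        filled += len(keep)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(out_den != 0, out_a / out_den, 0.0)
    return he, theta, out_a, out_den


def simulate_null(
    target_mean_fst: float,
    sample_sizes=(40, 40),
    n_loci: int = 50_000,
    seed: int | None = None,
    n_demes: int = 3,
    deme_size: int = 150,
    generations: int = 90,
    obs: ObservationModel | None = None,
    min_maf: float = 0.025,
    tol: float = 1e-3,
    max_iter: int = 30,
) -> NullFstSurface:
    """Simulate the neutral (H_e, F_ST) surface at a requested mean F_ST.

    Bisects the island-model migration parameter Nm (common random numbers
    across iterations) until the surface's trimmed mean theta is within
    ``tol`` of the target. Deterministic for a fixed seed.
    """
    if not 0.0 < target_mean_fst < 0.99:
        raise ValueError("target mean F_ST must be in (0, 0.99)")
    if min(sample_sizes) < 2:
        raise ValueError("sample sizes must be >= 2")
    k = (n_demes / (n_demes - 1.0)) ** 2
    nm_lo, nm_hi = 1e-3, 1e6  # bracket on the migration parameter
    Nm = (1.0 / target_mean_fst - 1.0) / (4.0 * k)
    n_bisect = min(n_loci, 8_000)
    tol_eff = max(tol * target_mean_fst / 0.02, 0.04 * target_mean_fst)

    def draw(nm, n):
        rng = np.random.default_rng(seed)  # common random numbers
        he, fst, a, den = _simulate_surface(
            nm, sample_sizes, n, rng, n_demes, deme_size, generations, obs,
            min_maf=min_maf,
        )
        s = NullFstSurface(he=he, fst=fst, a=a, den=den,
                           target_mean_fst=target_mean_fst,
                           achieved_mean_fst=np.nan)
        s.achieved_mean_fst = s.trimmed_mean(min_bin=max(50, n // 100))
        return s

    for _ in range(max_iter):
        achieved = draw(Nm, n_bisect).achieved_mean_fst
        if abs(achieved - target_mean_fst) < tol_eff:
            break
        if achieved < target_mean_fst:
            nm_hi = Nm          # too little differentiation -> less migration
        else:
            nm_lo = Nm
        if nm_hi / nm_lo < 1.0 + 1e-9:
            raise ValueError(
                f"bisection bracket collapsed at Nm in [{nm_lo}, {nm_hi}] "
                f"without reaching target {target_mean_fst}"
            )
        # multiplicative update (trimmed mean ~ 1/Nm), bracket-safeguarded
        Nm = float(np.clip(Nm * max(achieved, 1e-6) / target_mean_fst,
                           nm_lo * 1.0001, nm_hi * 0.9999))
    surface = draw(Nm, n_loci)
    if abs(surface.achieved_mean_fst - target_mean_fst) > 2.5 * tol_eff:
        # one correction pass at full size
        Nm = float(np.clip(
            Nm * max(surface.achieved_mean_fst, 1e-6) / target_mean_fst,
            nm_lo * 1.0001, nm_hi * 0.9999))
        surface = draw(Nm, n_loci)
    surface.params = {
        "Nm": Nm,
        "F_equilibrium": island_equilibrium_F(Nm, n_demes),
        "n_demes": n_demes,
        "deme_size": deme_size,
        "generations": generations,
        "sample_sizes": tuple(int(s) for s in sample_sizes),
        "n_loci": n_loci,
        "seed": seed,
        "observation_model": obs is not None,
    }
    return surface


def calibrate_mean(
    theta_components: pd.DataFrame,
    he_obs: np.ndarray,
    sample_sizes,
    seed: int | None = None,
    n_calib_loci: int = 15_000,
    envelope=(0.05, 0.95),
    **null_kw,
) -> float:
    """Two-pass neutral-mean refinement of the target mean F_ST.

    Pass 1 builds a provisional surface at the raw trimmed mean and culls
    loci outside the conditional [0.05, 0.95] envelope; pass 2 returns the
    ratio-of-sums mean of the surviving loci. Because ``simulate_null``
    matches its own trimmed mean to this target, the comparison is
    trim-for-trim and unbiased when the data are neutral.
    """
    a = theta_components["a"].to_numpy()
    den = theta_components["den"].to_numpy()
    ok = np.isfinite(a) & np.isfinite(den)
    if ok.sum() < 50:
        raise ValueError("need >= 50 informative loci to calibrate")
    raw_mean = float(a[ok].sum() / den[ok].sum())
    raw_mean = min(max(raw_mean, 1e-4), 0.98)
    provisional = simulate_null(
        raw_mean, sample_sizes, n_loci=n_calib_loci, seed=seed, **null_kw
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(den != 0, a / den, 0.0)
    p = np.full(len(a), np.nan)
    p[ok] = provisional.conditional_p(np.asarray(he_obs)[ok], theta[ok],
                                      min_bin=max(50, n_calib_loci // 100))
    keep = ok & (p > envelope[0]) & (p < envelope[1])
    if keep.sum() < 50:
        keep = ok
    culled_mean = float(a[keep].sum() / den[keep].sum())
    return min(max(culled_mean, 1e-4), 0.98)


def _observed_he(g: GenotypeMatrix, popA: str, popB: str) -> np.ndarray:
    idx = np.concatenate([g.pop_indices(popA), g.pop_indices(popB)])
    sub = g.genotypes[idx]
    called = sub != MISSING
    n = 2.0 * called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, sub, 0).sum(axis=0) / n
    return 2.0 * p * (1.0 - p)


def outlier_scan(
    g: GenotypeMatrix,
    popA: str,
    popB: str,
    q: float = 0.05,
    n_sims: int = 50_000,
    fdr_method: str = "BH",
    seed: int | None = None,
    n_bins: int = 50,
    min_bin: int = 500,
    obs: ObservationModel | None = None,
    min_pair_maf: float = 0.025,
    **null_kw,
) -> pd.DataFrame:
    """F_ST outlier scan for one population pair.

    Returns a per-locus DataFrame with columns he, fst, p (lower-tail
    conditional empirical p), p_upper, p_adj (FDR-adjusted upper tail) and
    call in {"directional", "balancing", "neutral"}; loci without a valid
    theta get call "NA". Neutral-panel membership is 0.05 < p < 0.95. When
    the data's depth/calling parameters are known (e.g. synthetic GBS
    datasets), pass ``obs`` so the null carries the same observation noise.
    """
    theta, _, comp = pairwise_fst(g, popA, popB)
    he_obs = _observed_he(g, popA, popB)
    nA = np.median((g.genotypes[g.pop_indices(popA)] != MISSING).sum(axis=0))
    nB = np.median((g.genotypes[g.pop_indices(popB)] != MISSING).sum(axis=0))
    sample_sizes = (max(int(nA), 2), max(int(nB), 2))

    target = calibrate_mean(comp, he_obs, sample_sizes, seed=seed, obs=obs,
                            min_maf=min_pair_maf, **null_kw)
    surface = simulate_null(target, sample_sizes, n_loci=n_sims, seed=seed,
                            obs=obs, min_maf=min_pair_maf, **null_kw)

    a = comp["a"].to_numpy()
    den = comp["den"].to_numpy()
    # rare variants are excluded from the conditional test: their theta takes
    # only a handful of discrete values (an atom, not a usable p-value) and
    # they carry no outlier power; the null applies the same threshold
    pair_maf = 0.5 * (1.0 - np.sqrt(np.maximum(1.0 - 2.0 * he_obs, 0.0)))
    ok = np.isfinite(a) & np.isfinite(den) & (he_obs > 0) & (pair_maf >= min_pair_maf)
    p = np.full(g.n_loci, np.nan)
    p_upper = np.full(g.n_loci, np.nan)
    fst_ok = np.where(den[ok] != 0, a[ok] / den[ok], 0.0)
    p[ok] = surface.conditional_p(he_obs[ok], fst_ok,
                                  n_bins=n_bins, min_bin=min_bin)
    p_upper[ok] = surface.upper_tail_p(he_obs[ok], fst_ok,
                                       n_bins=min(n_bins, 20), min_bin=min_bin)

    p_adj = np.full(g.n_loci, np.nan)
    p_adj[ok], _ = fdr_adjust(p_upper[ok], method=fdr_method, q=q)
    call = np.array(["NA"] * g.n_loci, dtype=object)
    call[ok] = "neutral"
    call[ok & (p_adj <= q)] = "directional"
    p_adj_low = np.full(g.n_loci, np.nan)
    p_adj_low[ok], _ = fdr_adjust(p[ok], method=fdr_method, q=q)
    call[ok & (p_adj_low <= q) & (call != "directional")] = "balancing"

    out = pd.DataFrame(
        {
            "scaffold": g.loci["scaffold"].to_numpy(),
            "pos": g.loci["pos"].to_numpy(),
            "he": he_obs,
            "fst": theta,
            "p": p,
            "p_upper": p_upper,
            "p_adj": p_adj,
            "call": call,
            # envelope calls: the operational outlier definition of
            # simulation-based scans (p-simulated outside [0.05, 0.95]);
            # the FDR-adjusted "call" column is far more stringent
            "directional_envelope": ok & (p >= 0.95),
            "balancing_envelope": ok & (p <= 0.05),
            "neutral_panel": ok & (p > 0.05) & (p < 0.95),
        }
    )
    out.attrs["surface_params"] = surface.params
    out.attrs["target_mean_fst"] = target
    out.attrs["achieved_mean_fst"] = surface.achieved_mean_fst
    out.attrs["pair"] = (popA, popB)
    return out
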