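"""End-to-end validation experiments on synthetic triads.

Each function runs a complete, self-contained experiment — generate data with
the forward simulator, run the analysis chain, measure the outcome — and
returns a dictionary of summary numbers. They are shared by the test suite
and the reproduction script. Problem sizes are desk-scale: large enough for
the statistical properties to be measurable, small enough to run in minutes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, kstest, wilcoxon

from .candidates import call_candidates
from .decay import fst_decay
from .genotypes import filter_dataset
from .ordination import pca_genotypes, rda
from .outliers import ObservationModel, outlier_scan
from .pst import pst
from .simulate import POP_LABELS, SimConfig, simulate
from .stats import pairwise_fst

__all__ = [
    "triad_scans",
    "null_calibration",
    "selection_recovery",
    "regime_discrimination",
    "pst_recovery",
    "rda_calibration",
]


def _obs_from_config(cfg: SimConfig) -> ObservationModel:
    return ObservationModel(
        depth_mean=cfg.depth_mean, depth_shape=cfg.depth_shape,
        depth_cap=cfg.depth_cap, min_call_reads=cfg.min_call_reads,
        dropout=cfg.dropout, error_rate=cfg.error_rate,
    )


def triad_scans(g, design, cfg: SimConfig, seed: int, n_sims: int = 50_000):
    """The three within-triad outlier scans (TE-ref1, TE-ref2, ref-ref)."""
    obs = _obs_from_config(cfg)
    pairs = [(design.te, design.refs[0]), (design.te, design.refs[1]),
             (design.refs[0], design.refs[1])]
    return [
        outlier_scan(g, a, b, seed=seed + i, obs=obs, n_sims=n_sims,
                     deme_size=cfg.N, generations=cfg.burn_in + cfg.sel_generations)
        for i, (a, b) in enumerate(pairs)
    ]


def _match_truth(g, truth: pd.DataFrame, column: str) -> np.ndarray:
    key = g.loci["scaffold"].astype(str) + ":" + g.loci["pos"].astype(str)
    tkey = truth["scaffold"].astype(str) + ":" + truth["pos"].astype(str)
    return truth.set_index(tkey)[column].reindex(key).to_numpy()


def null_calibration(seed: int, n_loci: int = 5000, sample_size: int = 40,
                     n_sims: int = 50_000) -> dict:
    """Neutral-mode false-positive control of the outlier scan.

    Simulates a fully neutral triad dataset, filters it, scans the TE-vs-
    south-reference pair, and reports the FDR-adjusted directional-call
    rate, the envelope-outlier rate, and the KS uniformity p-value of the
    conditional empirical p-values.
    """
    cfg = SimConfig(seed=seed, n_loci=n_loci,
                    n_scaffolds=max(50, n_loci // 20),
                    sample_size=sample_size).neutral()
    sim = simulate(cfg)
    g, _ = filter_dataset(sim.genotypes)
    r = triad_scans(g, sim.designs[0], cfg, seed + 1000, n_sims=n_sims)[0]
    ok = r["p"].notna()
    p = r.loc[ok, "p"].to_numpy()
    n_tests = int(ok.sum())
    return {
        "n_tests": n_tests,
        "fdr_directional_rate": float((r["call"] == "directional").sum() / n_tests),
        "envelope_directional_rate": float(r["directional_envelope"].sum() / n_tests),
        "ks_p": float(kstest(p, "uniform").pvalue),
        "ks_D": float(kstest(p, "uniform").statistic),
    }


def selection_recovery(seed: int, n_reps: int = 10, n_sims: int = 12_000) -> dict:
    """Candidate-locus recovery under the default polygenic scenario.

    For each replicate: simulate the default selected-mode dataset, filter,
    run the three within-triad scans, call candidates, and test enrichment
    of true selected loci among candidates (hypergeometric). Also tracks the
    true allele-frequency change at selected loci.
    """
    hyper_p, medians, n_cand, n_true = [], [], [], []
    d_all = []
    for i in range(n_reps):
        cfg = SimConfig(seed=seed + i)
        sim = simulate(cfg)
        g, _ = filter_dataset(sim.genotypes)
        sel = _match_truth(g, sim.truth, "selected") == True  # noqa: E712
        tr = sim.truth
        te, rs_, rn = POP_LABELS[1], POP_LABELS[0], POP_LABELS[2]
        dp = np.abs(tr[f"freq_final_{te}"]
                    - 0.5 * (tr[f"freq_final_{rs_}"] + tr[f"freq_final_{rn}"]))
        d_sel = dp[tr["selected"]].to_numpy()
        medians.append(float(np.median(d_sel)))
        d_all.extend(d_sel.tolist())
        scans = triad_scans(g, sim.designs[0], cfg, seed + 100 * i + 7,
                            n_sims=n_sims)
        cands = call_candidates(*scans, sim.designs[0])
        c = cands["candidate"].to_numpy()
        M, n, k = len(c), int(sel.sum()), int((c & sel).sum())
        n_cand.append(int(c.sum()))
        n_true.append(k)
        hyper_p.append(
            float(hypergeom.sf(k - 1, M, n, int(c.sum()))) if c.sum() else 1.0
        )
    return {
        "n_reps": n_reps,
        "hypergeom_p": hyper_p,
        "frac_enriched": float(np.mean([p < 0.05 for p in hyper_p])),
        "n_candidates": n_cand,
        "n_true_candidates": n_true,
        "median_abs_dp_selected": float(np.median(d_all)),
        "per_rep_median_abs_dp": medians,
    }


def _decay_crossing(sim, max_dist: int = 2000) -> float:
    """F_ST-decay crossing distance around given focal loci (ground truth)."""
    g, _ = filter_dataset(sim.genotypes)
    focal = _match_truth(g, sim.truth, "selected") == True  # noqa: E712
    th1, gw1, _ = pairwise_fst(g, POP_LABELS[1], POP_LABELS[0])
    th2, gw2, _ = pairwise_fst(g, POP_LABELS[1], POP_LABELS[2])
    mean_theta = 0.5 * (th1 + th2)
    baseline = 0.5 * (gw1 + gw2)
    cand = pd.DataFrame({"candidate": focal})
    prof = fst_decay(cand, mean_theta, g.loci, baseline,
                     max_dist=max_dist, min_pairs=10)
    return prof.crossing_bp


def regime_discrimination(seed: int, n_reps: int = 20) -> dict:
    """Crossing distance of the F_ST decay: hard sweep vs polygenic default.

    Paired small-scale replicates; the focal loci are the true selected loci
    (ground truth), isolating the decay property from scan power. Reports
    the one-sided Wilcoxon signed-rank p that sweep crossings exceed
    polygenic crossings.
    """
    import warnings

    small = dict(N=120, n_loci=900, n_scaffolds=30, scaffold_length_bp=2000,
                 sample_size=30, burn_in=30, n_trait_loci=0)
    poly_x, sweep_x = [], []
    for i in range(n_reps):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sim_p = simulate(SimConfig(seed=seed + i, n_selected_loci=60, **small))
            sim_s = simulate(SimConfig(seed=seed + i, sweep_mode=True, **small))
            poly_x.append(_decay_crossing(sim_p))
            sweep_x.append(_decay_crossing(sim_s))
    poly = np.array(poly_x, dtype=float)
    swp = np.array(sweep_x, dtype=float)
    okpair = np.isfinite(poly) & np.isfinite(swp)
    stat = wilcoxon(swp[okpair], poly[okpair], alternative="greater",
                    zero_method="wilcox")
    return {
        "n_pairs": int(okpair.sum()),
        "polygenic_crossing_bp": poly.tolist(),
        "sweep_crossing_bp": swp.tolist(),
        "median_polygenic_bp": float(np.nanmedian(poly)),
        "median_sweep_bp": float(np.nanmedian(swp)),
        "wilcoxon_p": float(stat.pvalue),
    }


def pst_recovery(seed: int, n_reps: int = 100, n_per_pop: int = 50,
                 n_boot: int = 500) -> dict:
    """Coverage of the P_ST bootstrap CI at c/h^2 = 1 for a known truth.

    Two populations with fixed means (+-delta/2) and unit within-population
    variance; the generating P_ST at c/h^2 = 1 is sigma2_B/(sigma2_B +
    2 sigma2_W) with sigma2_B = delta^2/2 (the expected-mean-squares
    estimand for two fixed groups).
    """
    rng = np.random.default_rng(seed)
    delta, sigma_w = 1.2, 1.0
    s2b_true = delta**2 / 2.0
    pst_true = s2b_true / (s2b_true + 2 * sigma_w**2)
    hits = 0
    for _ in range(n_reps):
        vals = np.concatenate([
            rng.normal(-delta / 2, sigma_w, n_per_pop),
            rng.normal(+delta / 2, sigma_w, n_per_pop),
        ])
        traits = pd.DataFrame({
            "population": ["A"] * n_per_pop + ["B"] * n_per_pop,
            "value": vals,
        })
        res = pst(traits, ch2_grid=(1.0,), n_boot=n_boot,
                  seed=int(rng.integers(2**31 - 1)))
        if res.ci_low[0] <= pst_true <= res.ci_high[0]:
            hits += 1
    return {
        "n_reps": n_reps,
        "pst_true": pst_true,
        "coverage": hits / n_reps,
    }


def rda_calibration(seed: int, n_reps: int = 200, n_perm: int = 199) -> dict:
    """pRDA effluent-term p-values under neutral simulations, plus the
    permutation-p floor 1/(B+1) for a deterministic response at B = 1000.

    The calibration permutes at the deme level (response = deme-centroid PC
    scores): demes are the exchangeable units under drift — individual-level
    permutation would answer "is there any population structure", which is
    true even without selection.
    """
    import warnings

    small = dict(N=60, n_loci=200, n_scaffolds=40, scaffold_length_bp=1500,
                 sample_size=20, burn_in=25, n_trait_loci=0)
    pvals = []
    for i in range(n_reps):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sim = simulate(SimConfig(seed=seed + i, **small).neutral())
            g, _ = filter_dataset(sim.genotypes, min_maf=0.02)
            pca = pca_genotypes(g)
            pop_index = {p: j for j, p in enumerate(POP_LABELS)}
            rows = np.array([pop_index[p] for p in g.individuals["population"]])
            centroids = np.vstack([
                pca.scores[rows == j].mean(axis=0) for j in range(6)
            ])
            # condition on triad membership (the leading spatial eigenvector
            # for this geometry) and permute demes within triads: triad means
            # are invariant under the permutation, so residualized responses
            # stay orthogonal to the conditioning block and the test is exact
            triad = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])[:, None]
            effluent = np.array([0.0, 1.0, 0.0, 0.0, 1.0, 0.0])[:, None]
            res = rda(centroids, effluent, Z=triad, n_perm=n_perm,
                      seed=seed + 31 * i,
                      strata=np.array([0, 0, 0, 1, 1, 1]))
            # the within-triad group is small (and F is invariant to
            # swapping the two reference rows), so the exact p is discrete;
            # calibration is checked on the randomized PIT, which is
            # continuous-uniform when the discrete test is exact
            ex_ = res.extras
            ties = ex_["k_ge"] - ex_["k_gt"]
            p_less = ex_["n_perm_total"] - ex_["k_ge"]
            u = np.random.default_rng(seed + 977 * i).random()
            pvals.append((p_less + u * ties) / ex_["n_perm_total"])
    pvals = np.array(pvals)
    # attainable floor with a deterministic response
    rng = np.random.default_rng(seed)
    Xf = rng.normal(size=(30, 2))
    Yf = Xf @ rng.normal(size=(2, 3))
    floor = rda(Yf, Xf, n_perm=1000, seed=seed).p_values["full"]
    return {
        "n_reps": n_reps,
        "ks_p": float(kstest(pvals, "uniform").pvalue),
        "mean_p": float(pvals.mean()),
        "floor_p": float(floor),
        "floor_expected": 1.0 / 1001.0,
    }
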