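"""Forward simulator for triad datasets with ground-truth selected loci.

Six demes along a coastline form two triads (south reference, thermal-
effluent deme, north reference). Gene flow is unrestricted within a triad
and stepping-stone (weak, distance-limited) between triads, so isolation by
distance emerges among triads but not within them. Each triad starts from a
shared founder-haplotype pool (drawn around a triad-level frequency with
the configured between-triad F) whose mosaic copying plants short-range
linkage disequilibrium; within-triad differentiation is then built by the
neutral Wright-Fisher burn-in itself, reaching its own migration-drift
equilibrium. The selection phase applies ``sel_generations`` generations of
additive selection at the thermal-effluent demes only, acting on standing
variants. Sampling applies a GBS observation model: overdispersed read
depths (negative binomial around the mean depth), a per-allele read cap,
sequencing error, random dropout, and binomial-likelihood genotype calling
with a minimum read count.

A hard-sweep mode plants a single low-frequency allele on one haplotype
background and sweeps it with a large selection coefficient, for contrasting
the local F_ST/LD footprint of a sweep with the polygenic default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .candidates import TriadDesign
from .genotypes import DepthMatrix, GenotypeMatrix, call_genotypes
from .stats import ld_r2, pairwise_fst

__all__ = ["SimConfig", "SimResult", "simulate", "fit_regime_report"]

POP_LABELS = ("T1S", "T1TE", "T1N", "T2S", "T2TE", "T2N")


@dataclass(frozen=True)
class SimConfig:
    """Scenario parameters of the triad simulator.

    Defaults are desk-scale study conditions: two triads of three demes,
    recent (50-generation) polygenic selection with s = 0.05 per locus on
    100 standing variants at the effluent demes, GBS depths with mean 26 and
    a 127-reads-per-allele cap, and LD decaying over tens of bp.
    """

    # demography
    n_demes: int = 6
    deme_positions_km: tuple = (0.0, 30.0, 60.0, 460.0, 490.0, 520.0)
    te_demes: tuple = (1, 4)
    N: int = 150                        # diploids per deme
    m_within: float = 0.022             # per-gen migration to each other deme of the triad
    m_between: float = 1e-4             # between triads (demes 2 <-> 3)
    fst_between_init: float = 0.02      # triad-vs-global F at initialization
    burn_in: int = 40
    # genome
    n_loci: int = 2000
    n_scaffolds: int = 150
    scaffold_length_bp: int = 2000
    recomb_per_bp: float = 5e-5
    founder_switch_per_bp: float = 0.03  # ancestral-LD copying scale (~1/30 bp)
    n_founders: int = 8
    min_init_maf: float = 0.02
    # selection
    sel_generations: int = 50
    n_selected_loci: int = 100
    s: float = 0.05
    selected_min_maf: float = 0.02       # standing variants only
    sweep_mode: bool = False
    sweep_s: float = 0.5
    sweep_p0: float = 0.02
    # observation model
    sample_size: int = 40
    depth_mean: float = 26.0
    depth_shape: float = 3.0             # negative-binomial dispersion
    depth_cap: int = 127
    min_call_reads: int = 5
    dropout: float = 0.03
    error_rate: float = 0.01
    # trait model
    n_trait_loci: int = 30
    trait_effect: float = 0.5
    h2: float = 0.5
    seed: int = 0

    def neutral(self, **kw) -> "SimConfig":
        """Copy with selection switched off (null mode)."""
        return replace(self, n_selected_loci=0, sweep_mode=False, **kw)


@dataclass
class SimResult:
    genotypes: GenotypeMatrix
    depths: DepthMatrix
    popmap: pd.DataFrame
    designs: list
    truth: pd.DataFrame
    traits: pd.DataFrame
    config: SimConfig


# ---------------------------------------------------------------------------
# genome and initialization
# ---------------------------------------------------------------------------

def _locus_map(cfg: SimConfig, rng) -> pd.DataFrame:
    per = np.full(cfg.n_scaffolds, cfg.n_loci // cfg.n_scaffolds)
    per[: cfg.n_loci - per.sum()] += 1
    rows = []
    for s in range(cfg.n_scaffolds):
        pos = np.sort(rng.choice(cfg.scaffold_length_bp, size=per[s], replace=False)) + 1
        for p in pos:
            rows.append((f"scaf{s:04d}", int(p)))
    df = pd.DataFrame(rows, columns=["scaffold", "pos"])
    df["ref"], df["alt"] = "A", "C"
    return df


def _interval_probs(loci: pd.DataFrame, per_bp: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-interval event probability and scaffold-start marker (first locus
    of each scaffold gets probability handled by the caller)."""
    pos = loci["pos"].to_numpy()
    scaf = loci["scaffold"].to_numpy()
    d = np.empty(len(pos))
    start = np.empty(len(pos), dtype=bool)
    d[0], start[0] = 0.0, True
    same = scaf[1:] == scaf[:-1]
    d[1:] = np.where(same, np.abs(pos[1:] - pos[:-1]), 0.0)
    start[1:] = ~same
    prob = 0.5 * (1.0 - np.exp(-2.0 * per_bp * d))
    return prob, start


def _triad_freqs(cfg: SimConfig, rng) -> np.ndarray:
    """Per-triad initial allele frequencies (2, n_loci).

    Ancestral frequencies x have density ~ 1/(x(1-x)); triad means are drawn
    around x with the configured between-triad F. Demes within a triad start
    identical (mosaics of a shared founder pool) — the neutral burn-in builds
    within-triad differentiation to its own migration-drift equilibrium, so
    the within-triad F_ST distribution is generated, not imposed.
    """
    eps = cfg.min_init_maf
    a = np.log((1 - eps) / eps)
    x = 1.0 / (1.0 + np.exp(-rng.uniform(-a, a, cfg.n_loci)))
    lam_ct = (1 - cfg.fst_between_init) / cfg.fst_between_init
    p = np.empty((2, cfg.n_loci))
    for t in range(2):
        p[t] = rng.beta(np.maximum(x * lam_ct, 1e-8),
                        np.maximum((1 - x) * lam_ct, 1e-8))
    return np.clip(p, 0.0, 1.0)


def _founder_haplotypes(p_pool: np.ndarray, K: int, rng) -> np.ndarray:
    """(K, L) founder alleles whose pool frequency tracks the target
    frequency (stochastic rounding of K*p)."""
    L = p_pool.shape[0]
    target = K * p_pool
    count = np.floor(target).astype(int)
    count += rng.random(L) < (target - count)
    ranks = rng.random((K, L)).argsort(axis=0).argsort(axis=0)
    return (ranks < count[None, :]).astype(np.int8)


def _mosaic_haplotypes(founders: np.ndarray, n_hap: int,
                       switch_prob: np.ndarray, start: np.ndarray, rng) -> np.ndarray:
    """Li-Stephens-style mosaic copies of the founder pool: (n_hap, L)."""
    K, L = founders.shape
    sw = rng.random((n_hap, L)) < switch_prob[None, :]
    sw[:, start] = True  # new founder at every scaffold start
    seg = np.cumsum(sw, axis=1) - 1
    draw = rng.integers(0, K, size=(n_hap, L))
    founder_id = np.take_along_axis(draw, seg, axis=1)
    return founders[founder_id, np.arange(L)[None, :]]


# ---------------------------------------------------------------------------
# forward Wright-Fisher
# ---------------------------------------------------------------------------

def _migration_matrix(cfg: SimConfig) -> np.ndarray:
    """Row-stochastic parent-source probabilities.

    Gene flow is unrestricted (symmetric, all pairs) within a triad — the
    demes sit tens of km apart, well inside the dispersal scale, which is why
    no within-triad isolation by distance is expected — and stepping-stone
    between triads through the two inner demes, producing among-triad IBD.
    """
    M = np.zeros((cfg.n_demes, cfg.n_demes))
    within = {(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)}
    for i in range(cfg.n_demes):
        for j in range(cfg.n_demes):
            if i == j:
                continue
            if (min(i, j), max(i, j)) in within:
                M[i, j] = cfg.m_within
            elif (min(i, j), max(i, j)) == (2, 3):
                M[i, j] = cfg.m_between
    np.fill_diagonal(M, 1.0 - M.sum(axis=1))
    if (np.diag(M) <= 0).any():
        raise ValueError("migration rates too large: emigration exceeds 1")
    return M


def _advance(
    haps: np.ndarray,
    cfg: SimConfig,
    rec_prob: np.ndarray,
    rec_start: np.ndarray,
    sel_idx: np.ndarray,
    sel_s: np.ndarray,
    sel_demes: set,
    generations: int,
    rng,
) -> np.ndarray:
    """Run the diploid Wright-Fisher update for ``generations`` steps.

    ``haps`` is the stacked haplotype array (n_demes * 2N, L); individual i
    of deme d owns rows 2*(d*N+i) and 2*(d*N+i)+1. Fitness is multiplicative
    over selected loci, additive within locus (1, 1+s, 1+2s), applied only
    in the designated demes. Allele-count conservation holds trivially: each
    generation produces exactly 2N gametes per deme.
    """
    N, D = cfg.N, cfg.n_demes
    L = haps.shape[1]
    M = _migration_matrix(cfg)
    prob = rec_prob.copy()
    prob[rec_start] = 0.5  # independent scaffolds: ancestry re-randomized
    for _ in range(generations):
        # fitness per individual per deme (only selected demes deviate from 1)
        weights = []
        for d in range(D):
            if d in sel_demes and sel_idx.size:
                block = haps[2 * d * N: 2 * (d + 1) * N]
                dos = block[0::2][:, sel_idx] + block[1::2][:, sel_idx]
                w = np.exp(np.log1p(np.outer(np.ones(N), sel_s) * dos).sum(axis=1))
            else:
                w = np.ones(N)
            weights.append(w / w.sum())
        # two parents per offspring, migration then fitness-weighted choice
        parents = np.empty((2, D * N), dtype=np.int64)
        for which in range(2):
            for d in range(D):
                src_counts = rng.multinomial(N, M[d])
                rows = []
                for src, cnt in enumerate(src_counts):
                    if cnt == 0:
                        continue
                    idx = rng.choice(N, size=cnt, replace=True, p=weights[src])
                    rows.append(src * N + idx)
                got = np.concatenate(rows)
                rng.shuffle(got)
                parents[which, d * N: (d + 1) * N] = got
        # gametes with recombination
        new = np.empty_like(haps)
        for which in range(2):
            par = parents[which]
            anc = (np.cumsum(rng.random((D * N, L)) < prob[None, :], axis=1) & 1).astype(bool)
            hap_a = haps[2 * par]
            hap_b = haps[2 * par + 1]
            new[which::2] = np.where(anc, hap_b, hap_a)
        haps = new
    return haps


# ---------------------------------------------------------------------------
# observation model
# ---------------------------------------------------------------------------

def _gbs_depths(dosage: np.ndarray, cfg: SimConfig, rng) -> DepthMatrix:
    n_ind, L = dosage.shape
    p_nb = cfg.depth_shape / (cfg.depth_shape + cfg.depth_mean)
    total = rng.negative_binomial(cfg.depth_shape, p_nb, size=(n_ind, L))
    total[rng.random((n_ind, L)) < cfg.dropout] = 0
    p_alt = np.array([cfg.error_rate, 0.5, 1.0 - cfg.error_rate])[dosage]
    alt = rng.binomial(total, p_alt)
    ref = total - alt
    counts = np.stack([np.minimum(ref, cfg.depth_cap),
                       np.minimum(alt, cfg.depth_cap)], axis=2)
    return DepthMatrix(counts=counts.astype(np.int32), cap=cfg.depth_cap)


# ---------------------------------------------------------------------------
# top level
# ---------------------------------------------------------------------------

def _deme_freqs(haps: np.ndarray, N: int, D: int) -> np.ndarray:
    return np.stack([haps[2 * d * N: 2 * (d + 1) * N].mean(axis=0) for d in range(D)])


def simulate(cfg: SimConfig) -> SimResult:
    """Run the scenario and return called genotypes plus ground truth."""
    rng = np.random.default_rng(cfg.seed)
    loci = _locus_map(cfg, rng)
    L = cfg.n_loci
    rec_prob, rec_start = _interval_probs(loci, cfg.recomb_per_bp)
    copy_prob, _ = _interval_probs(loci, cfg.founder_switch_per_bp / 2.0)
    # founder copying uses the raw switch scale, not a meiotic map
    copy_prob = np.minimum(copy_prob * 2.0, 0.999)

    p0 = _triad_freqs(cfg, rng)
    # demes of a triad share one founder pool: within-triad divergence is
    # built by the burn-in, not the initialization
    pools = [_founder_haplotypes(p0[t], cfg.n_founders, rng) for t in range(2)]
    blocks = [
        _mosaic_haplotypes(pools[d // 3], 2 * cfg.N, copy_prob, rec_start, rng)
        for d in range(cfg.n_demes)
    ]
    haps = np.vstack(blocks)

    # neutral burn-in
    haps = _advance(haps, cfg, rec_prob, rec_start, np.array([], int),
                    np.array([]), set(), cfg.burn_in, rng)

    # choose selected loci among standing variants at selection onset
    freq_onset = _deme_freqs(haps, cfg.N, cfg.n_demes)
    meta = freq_onset.mean(axis=0)
    selected = np.zeros(L, dtype=bool)
    s_per_locus = np.zeros(L)
    sweep_locus = -1
    if cfg.sweep_mode:
        scaf_counts = loci.groupby("scaffold")["pos"].transform("size")
        dense = np.flatnonzero(scaf_counts == scaf_counts.max())
        sweep_locus = int(dense[len(dense) // 2])
        scaf_mask = (loci["scaffold"] == loci["scaffold"].iloc[sweep_locus]).to_numpy()
        te = cfg.te_demes[0]
        n0 = max(2, int(round(2 * cfg.N * cfg.sweep_p0)))
        haps[:, sweep_locus] = 0
        carriers = 2 * te * cfg.N + rng.choice(2 * cfg.N, size=n0, replace=False)
        donor = haps[carriers[0]].copy()
        for c in carriers:  # one shared haplotype background on the scaffold
            haps[c, scaf_mask] = donor[scaf_mask]
            haps[c, sweep_locus] = 1
        selected[sweep_locus] = True
        s_per_locus[sweep_locus] = cfg.sweep_s
        sel_demes = {te}
    else:
        sel_demes = set(cfg.te_demes)
        standing = np.flatnonzero(
            (np.minimum(meta, 1 - meta) >= cfg.selected_min_maf)
        )
        n_sel = min(cfg.n_selected_loci, standing.size)
        if n_sel:
            # the favored allele is allele 1 regardless of its frequency:
            # adaptation from standing variation can favor the major allele
            chosen = rng.choice(standing, size=n_sel, replace=False)
            selected[chosen] = True
            s_per_locus[chosen] = cfg.s
    sel_idx = np.flatnonzero(selected)
    freq_onset = _deme_freqs(haps, cfg.N, cfg.n_demes)

    haps = _advance(haps, cfg, rec_prob, rec_start, sel_idx,
                    s_per_locus[sel_idx], sel_demes, cfg.sel_generations, rng)
    freq_final = _deme_freqs(haps, cfg.N, cfg.n_demes)

    # sample individuals and apply the GBS observation model
    sample_rows, ids, pops = [], [], []
    for d in range(cfg.n_demes):
        take = np.sort(rng.choice(cfg.N, size=cfg.sample_size, replace=False))
        for i, t in enumerate(take):
            base = 2 * (d * cfg.N) + 2 * t
            sample_rows.append((base, base + 1))
            ids.append(f"{POP_LABELS[d]}_{i:03d}")
            pops.append(POP_LABELS[d])
    dosage = np.array([haps[a] + haps[b] for a, b in sample_rows], dtype=np.int8)
    depths = _gbs_depths(dosage, cfg, rng)
    individuals = pd.DataFrame({"id": ids, "population": pops})
    called = call_genotypes(
        depths, error_rate=cfg.error_rate, min_reads=cfg.min_call_reads,
        loci=loci, individuals=individuals,
    )

    popmap = individuals.copy()
    dists = {}
    for i in range(cfg.n_demes):
        for j in range(i + 1, cfg.n_demes):
            dists[(POP_LABELS[i], POP_LABELS[j])] = abs(
                cfg.deme_positions_km[i] - cfg.deme_positions_km[j]
            )
    designs = [
        TriadDesign(name="triad1", te=POP_LABELS[1],
                    refs=(POP_LABELS[0], POP_LABELS[2]), distances_km=dists),
        TriadDesign(name="triad2", te=POP_LABELS[4],
                    refs=(POP_LABELS[3], POP_LABELS[5]), distances_km=dists),
    ]

    truth = loci[["scaffold", "pos"]].copy()
    truth["selected"] = selected
    truth["s"] = s_per_locus
    for d in range(cfg.n_demes):
        truth[f"freq_onset_{POP_LABELS[d]}"] = freq_onset[d]
        truth[f"freq_final_{POP_LABELS[d]}"] = freq_final[d]

    # trait values: additive score over trait loci + environmental noise
    trait_idx = sel_idx[: cfg.n_trait_loci] if sel_idx.size else np.array([], int)
    truth["trait_locus"] = False
    if trait_idx.size:
        truth.loc[trait_idx, "trait_locus"] = True
    te_pop, ref_pop = POP_LABELS[cfg.te_demes[0]], POP_LABELS[cfg.te_demes[0] + 1]
    keep = [k for k, p in enumerate(pops) if p in (te_pop, ref_pop)]
    if trait_idx.size:
        gv = (dosage[np.ix_(keep, trait_idx)] * cfg.trait_effect).sum(axis=1).astype(float)
        pops_keep = np.array([pops[k] for k in keep])
        within_var = float(np.mean([gv[pops_keep == p].var() for p in (te_pop, ref_pop)]))
        var_g = within_var if within_var > 0 else 1.0
    else:
        gv = np.zeros(len(keep))
        var_g = 1.0
    noise_sd = np.sqrt(var_g * (1 - cfg.h2) / cfg.h2)
    traits = pd.DataFrame(
        {
            "id": [ids[k] for k in keep],
            "population": [pops[k] for k in keep],
            "value": gv + rng.normal(0, noise_sd, len(keep)),
        }
    )
    return SimResult(
        genotypes=called, depths=depths, popmap=popmap, designs=designs,
        truth=truth, traits=traits, config=cfg,
    )


def fit_regime_report(sim: SimResult, max_pairs: int = 4000, seed: int = 0) -> dict:
    """Non-binding diagnostics: realized depth, F_ST scales, LD decay, SFS."""
    g = sim.genotypes
    called = g.genotypes != -1
    depth_total = sim.depths.total
    mean_depth = float(depth_total.mean())
    within, among = [], []
    for a in range(6):
        for b in range(a + 1, 6):
            _, gw, _ = pairwise_fst(g, POP_LABELS[a], POP_LABELS[b])
            (within if a // 3 == b // 3 else among).append(gw)
    # LD half-decay from same-scaffold pairs within the first triad,
    # relative to the long-distance baseline
    rng = np.random.default_rng(seed)
    idx1 = np.concatenate([g.pop_indices(p) for p in POP_LABELS[:3]])
    dos1 = g.genotypes[idx1]
    scaf = g.loci["scaffold"].to_numpy()
    pos = g.loci["pos"].to_numpy()
    d_all, r_all = [], []
    for s in pd.unique(scaf):
        on = np.flatnonzero(scaf == s)
        for i in range(len(on)):
            for j in range(i + 1, len(on)):
                d = abs(pos[on[i]] - pos[on[j]])
                if d == 0:
                    continue
                d_all.append(d)
                r_all.append((on[i], on[j]))
    if len(d_all) > max_pairs:
        take = rng.choice(len(d_all), size=max_pairs, replace=False)
    else:
        take = np.arange(len(d_all))
    dist = np.array([d_all[k] for k in take], float)
    r2 = np.array([ld_r2(dos1[:, r_all[k][0]], dos1[:, r_all[k][1]])
                   for k in take])
    ok = np.isfinite(r2)
    dist, r2 = dist[ok], r2[ok]
    half_decay = np.nan
    if len(dist) > 50:
        edges = np.array([0, 15, 30, 60, 120, 250, 500, 1000, 2000, 1e9])
        bins = np.digitize(dist, edges) - 1
        means = np.array([r2[bins == b].mean() if (bins == b).any() else np.nan
                          for b in range(len(edges) - 1)])
        valid = np.flatnonzero(np.isfinite(means))
        top, floor = means[valid[0]], means[valid[-1]]
        if top > floor:
            under = valid[means[valid] <= floor + 0.5 * (top - floor)]
            if len(under):
                half_decay = float(edges[under[0]])
    maf = np.minimum(g.allele_freq(), 1 - g.allele_freq())
    return {
        "mean_depth": mean_depth,
        "mean_called_depth": float(depth_total[called].mean()),
        "call_rate": float(called.mean()),
        "fst_within_triad_mean": float(np.mean(within)),
        "fst_among_triad_mean": float(np.mean(among)),
        "ld_half_decay_bp": half_decay,
        "mean_maf": float(np.nanmean(maf)),
        "n_segregating": int(np.sum(np.nan_to_num(maf) > 0)),
    }
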