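"""Triad candidate-locus inference and diversity/SFS follow-up analyses.

A candidate locus is a SNP that is a directional outlier in both comparisons
of the putatively selected (thermal-effluent, TE) population against its two
flanking reference populations, but not in the reference-vs-reference
comparison. Follow-ups: enrichment of reduced diversity/Tajima's D at
candidates, allele-frequency-change summaries polarized on the global major
allele, and minor-allele-frequency-matched bootstrap resampling of the
neutral panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .genotypes import GenotypeMatrix
from .stats import wilcoxon_one_tailed

__all__ = [
    "TriadDesign",
    "call_candidates",
    "enrichment_tests",
    "af_change",
    "maf_matched_bootstrap",
]


@dataclass
class TriadDesign:
    """One TE population and its two flanking reference populations."""

    name: str
    te: str
    refs: tuple[str, str]  # (south, north) or any fixed order
    distances_km: dict = field(default_factory=dict)

    def __post_init__(self):
        labels = {self.te, *self.refs}
        if len(labels) != 3:
            raise ValueError("triad needs three distinct population labels")
        if self.distances_km:
            d_te_r = [self.distance(self.te, r) for r in self.refs]
            d_rr = self.distance(*self.refs)
            if not all(d < d_rr for d in d_te_r if d is not None):
                raise ValueError("TE population must be geographically intermediate")

    def distance(self, a: str, b: str):
        for key in ((a, b), (b, a), f"{a}-{b}", f"{b}-{a}"):
            if key in self.distances_km:
                return self.distances_km[key]
        return None

    @classmethod
    def from_yaml(cls, path) -> "TriadDesign":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        dist = {tuple(k.split("-")): v for k, v in d.get("distances_km", {}).items()}
        return cls(name=d["name"], te=d["te"], refs=tuple(d["refs"]), distances_km=dist)

    def to_yaml(self, path) -> None:
        dist = {f"{a}-{b}": float(v) for (a, b), v in self.distances_km.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"name": self.name, "te": self.te, "refs": list(self.refs),
                 "distances_km": dist},
                fh,
            )


def _check_same_loci(*results: pd.DataFrame) -> None:
    base = results[0][["scaffold", "pos"]]
    for r in results[1:]:
        if len(r) != len(base) or not (
            (r["scaffold"].to_numpy() == base["scaffold"].to_numpy()).all()
            and (r["pos"].to_numpy() == base["pos"].to_numpy()).all()
        ):
            raise ValueError("outlier results cover different locus sets")


def call_candidates(
    r_te_ref1: pd.DataFrame,
    r_te_ref2: pd.DataFrame,
    r_ref_ref: pd.DataFrame,
    design: TriadDesign,
    criterion: str = "envelope",
) -> pd.DataFrame:
    """Combine the three within-triad outlier scans into candidate calls.

    candidate = directional outlier in both TE comparisons AND not in the
    reference-vs-reference comparison. ``criterion`` selects the outlier
    definition: "envelope" (simulated p outside the 95% conditional
    envelope, the operational rule of simulation-based scans whose per-
    comparison false-positive rate the triad intersection is designed to
    absorb) or "fdr" (step-up-adjusted upper-tail p, far more stringent).
    A locus missing a verdict in any comparison is ineligible.
    ``neutral_panel`` requires 0.05 < p < 0.95 in all three comparisons.
    """
    _check_same_loci(r_te_ref1, r_te_ref2, r_ref_ref)
    if criterion == "envelope":
        o1 = r_te_ref1["directional_envelope"].to_numpy()
        o2 = r_te_ref2["directional_envelope"].to_numpy()
        o3 = r_ref_ref["directional_envelope"].to_numpy()
    elif criterion == "fdr":
        o1 = (r_te_ref1["call"] == "directional").to_numpy()
        o2 = (r_te_ref2["call"] == "directional").to_numpy()
        o3 = (r_ref_ref["call"] == "directional").to_numpy()
    else:
        raise ValueError("criterion must be 'envelope' or 'fdr'")
    eligible = (
        (r_te_ref1["call"] != "NA").to_numpy()
        & (r_te_ref2["call"] != "NA").to_numpy()
        & (r_ref_ref["call"] != "NA").to_numpy()
    )
    candidate = eligible & o1 & o2 & ~o3
    neutral = (
        r_te_ref1["neutral_panel"].to_numpy()
        & r_te_ref2["neutral_panel"].to_numpy()
        & r_ref_ref["neutral_panel"].to_numpy()
    )
    out = pd.DataFrame(
        {
            "scaffold": r_te_ref1["scaffold"].to_numpy(),
            "pos": r_te_ref1["pos"].to_numpy(),
            "outlier_te_ref1": o1,
            "outlier_te_ref2": o2,
            "outlier_ref_ref": o3,
            "candidate": candidate,
            "neutral_panel": neutral & ~candidate,
        }
    )
    out.attrs["triad"] = design.name
    out.attrs["counts"] = {
        "te_ref1": int(o1.sum()),
        "te_ref2": int(o2.sum()),
        "ref_ref": int(o3.sum()),
        "te_both": int((o1 & o2).sum()),
        "candidates": int(candidate.sum()),
        "any_outlier": int((o1 | o2 | o3).sum()),
    }
    return out


def enrichment_tests(
    candidates: pd.DataFrame,
    theta_pi: np.ndarray,
    tajimas_d_per_locus: np.ndarray,
    min_candidates: int = 5,
) -> pd.DataFrame:
    """Medians and one-tailed (less) rank-sum p: candidates vs all loci.

    ``theta_pi`` and ``tajimas_d_per_locus`` are per-locus values aligned with
    the candidate table (Tajima's D mapped from its window onto member loci).
    """
    cand = candidates["candidate"].to_numpy()
    if cand.sum() == 0:
        import warnings

        warnings.warn("no candidate loci; enrichment table empty")
        return pd.DataFrame(columns=["statistic", "median_candidates", "median_all", "p"])
    if cand.sum() < min_candidates:
        raise ValueError(f"need >= {min_candidates} candidates for enrichment tests")
    rows = []
    for name, vals in (("theta_pi", np.asarray(theta_pi, float)),
                       ("tajimas_d", np.asarray(tajimas_d_per_locus, float))):
        x = vals[cand]
        x = x[np.isfinite(x)]
        y = vals[np.isfinite(vals)]
        p = wilcoxon_one_tailed(x, y, alternative="less")
        rows.append((name, float(np.median(x)), float(np.median(y)), p))
    return pd.DataFrame(rows, columns=["statistic", "median_candidates", "median_all", "p"])


def af_change(
    candidates: pd.DataFrame,
    g: GenotypeMatrix,
    design: TriadDesign,
) -> pd.DataFrame:
    """Per-locus allele-frequency change of the TE population vs its references.

    Frequencies are polarized on the global major allele (across all
    populations in ``g``); delta_p = p_TE - unweighted mean of the two
    reference frequencies. Also flags private alleles (minor allele observed
    in exactly one population).
    """
    p_minor_global = g.allele_freq()
    freqs = {pop: g.allele_freq(pop) for pop in g.populations}
    # major-allele frequency = 1 - minor frequency under the fixed polarization
    maj = {pop: 1.0 - freqs[pop] for pop in g.populations}
    p_te = maj[design.te]
    p_r1 = maj[design.refs[0]]
    p_r2 = maj[design.refs[1]]
    delta = p_te - 0.5 * (p_r1 + p_r2)
    observed_in = np.zeros(g.n_loci, dtype=int)
    for pop in g.populations:
        observed_in += (np.nan_to_num(freqs[pop]) > 0).astype(int)
    uncalled = np.zeros(g.n_loci, dtype=bool)
    for pop in (design.te, *design.refs):
        uncalled |= ~np.isfinite(freqs[pop])
    out = pd.DataFrame(
        {
            "scaffold": g.loci["scaffold"].to_numpy(),
            "pos": g.loci["pos"].to_numpy(),
            "p_major_global": 1.0 - p_minor_global,
            "p_te": p_te,
            "p_ref_mean": 0.5 * (p_r1 + p_r2),
            "delta_p": delta,
            "abs_delta_p": np.abs(delta),
            "private": observed_in == 1,
            "excluded_uncalled": uncalled,
        }
    )
    cand = candidates["candidate"].to_numpy() if candidates is not None else None
    valid = ~uncalled

    def summarize(mask):
        d = out.loc[mask & valid, "abs_delta_p"]
        if len(d) == 0:
            return {"n": 0}
        return {
            "n": int(len(d)),
            "max": float(d.max()),
            "median": float(d.median()),
            "q90": float(d.quantile(0.9)),
            "frac_lt_0.10": float((d < 0.10).mean()),
        }

    out.attrs["summary_all"] = summarize(np.ones(len(out), dtype=bool))
    if cand is not None:
        out.attrs["summary_candidates"] = summarize(cand)
    out.attrs["n_excluded_uncalled"] = int(uncalled.sum())
    return out


def maf_matched_bootstrap(
    neutral_maf: np.ndarray,
    target_maf: np.ndarray,
    n_boot: int,
    seed: int | None = None,
    bin_width: float = 0.02,
) -> list[np.ndarray]:
    """Bootstrap index sets from the neutral panel matching the target's MAF
    histogram exactly (sampling with replacement within MAF bins).

    Returns ``n_boot`` arrays of indices into ``neutral_maf``, each the same
    size as ``target_maf``.
    """
    neutral_maf = np.asarray(neutral_maf, dtype=float)
    target_maf = np.asarray(target_maf, dtype=float)
    edges = np.arange(0.0, 0.5 + bin_width, bin_width)
    nb = np.clip(np.digitize(neutral_maf, edges) - 1, 0, len(edges) - 2)
    tb = np.clip(np.digitize(target_maf, edges) - 1, 0, len(edges) - 2)
    occupied, counts = np.unique(tb, return_counts=True)
    pools = {}
    missing = []
    for b in occupied:
        pool = np.flatnonzero(nb == b)
        if pool.size == 0:
            missing.append((float(edges[b]), float(edges[b + 1])))
        pools[b] = pool
    if missing:
        raise ValueError(f"neutral panel empty in occupied MAF bins: {missing}")
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n_boot):
        parts = [rng.choice(pools[b], size=c, replace=True)
                 for b, c in zip(occupied, counts)]
        draws.append(np.concatenate(parts))
    return draws
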