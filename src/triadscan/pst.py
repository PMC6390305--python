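"""P_ST: phenotypic analogue of Q_ST from one-way ANOVA variance components.

P_ST(c/h^2) = (c/h^2) sigma2_B / ((c/h^2) sigma2_B + 2 sigma2_W), where
sigma2_B and sigma2_W are the among- and within-population variance
components of a trait, c is the assumed proportion of among-population
variance that is additive and h^2 the narrow-sense heritability. Because
neither c nor h^2 is known for wild-caught phenotypes, P_ST is profiled over
a grid of c/h^2 with individual-level bootstrap confidence intervals, and
compared to genome-wide F_ST.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PstResult", "anova_components", "pst", "pst_exceeds_fst"]

DEFAULT_CH2_GRID = tuple(np.round(np.arange(0.1, 2.01, 0.1), 2))


@dataclass
class PstResult:
    sigma2_between: float
    sigma2_within: float
    truncated: bool                        # negative sigma2_B clipped to 0
    grid: np.ndarray                       # c/h^2 values
    pst: np.ndarray                        # point estimate per grid value
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_boot: int
    extras: dict = field(default_factory=dict)


def anova_components(values: np.ndarray, groups: np.ndarray) -> tuple[float, float, bool]:
    """One-way ANOVA variance components via expected mean squares.

    Uses the unbalanced-design coefficient n0 = (N - sum n_i^2 / N) / (k-1).
    Returns (sigma2_between, sigma2_within, truncated_flag).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels, inv = np.unique(groups, return_inverse=True)
    k = len(labels)
    if k < 2:
        raise ValueError("need >= 2 populations")
    n_i = np.bincount(inv).astype(float)
    if (n_i < 2).any():
        raise ValueError("each population needs >= 2 individuals")
    N = n_i.sum()
    grand = values.mean()
    means = np.bincount(inv, weights=values) / n_i
    ss_between = float((n_i * (means - grand) ** 2).sum())
    ss_within = float(((values - means[inv]) ** 2).sum())
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (N - k)
    n0 = (N - (n_i**2).sum() / N) / (k - 1)
    sigma2_w = ms_within
    sigma2_b = (ms_between - ms_within) / n0
    truncated = sigma2_b < 0
    if truncated:
        sigma2_b = 0.0
    return sigma2_b, sigma2_w, truncated


def _pst_curve(sigma2_b: float, sigma2_w: float, grid: np.ndarray) -> np.ndarray:
    num = grid * sigma2_b
    return num / (num + 2.0 * sigma2_w)


def pst(
    traits: pd.DataFrame,
    ch2_grid=DEFAULT_CH2_GRID,
    n_boot: int = 1000,
    seed: int | None = None,
    ci: float = 0.95,
) -> PstResult:
    """P_ST over a c/h^2 grid with stratified-bootstrap percentile CIs.

    ``traits`` has columns (population, value), one row per individual.
    Bootstrap resamples individuals within populations.
    """
    grid = np.asarray(ch2_grid, dtype=float)
    if grid.min() <= 0 or grid.max() > 2:
        raise ValueError("c/h^2 grid must lie in (0, 2]")
    values = traits["value"].to_numpy(dtype=float)
    groups = traits["population"].to_numpy()
    s2b, s2w, truncated = anova_components(values, groups)
    curve = _pst_curve(s2b, s2w, grid)

    rng = np.random.default_rng(seed)
    labels = pd.unique(groups)
    idx_by_pop = [np.flatnonzero(groups == lab) for lab in labels]
    boots = np.empty((n_boot, len(grid)))
    for b in range(n_boot):
        take = np.concatenate(
            [rng.choice(ix, size=len(ix), replace=True) for ix in idx_by_pop]
        )
        bs2b, bs2w, _ = anova_components(values[take], groups[take])
        boots[b] = _pst_curve(bs2b, bs2w, grid)
    alpha = (1.0 - ci) / 2.0
    return PstResult(
        sigma2_between=s2b,
        sigma2_within=s2w,
        truncated=truncated,
        grid=grid,
        pst=curve,
        ci_low=np.quantile(boots, alpha, axis=0),
        ci_high=np.quantile(boots, 1 - alpha, axis=0),
        n_boot=n_boot,
        extras={"populations": list(labels)},
    )


def pst_exceeds_fst(result: PstResult, fst: float) -> tuple[np.ndarray, float]:
    """Per-grid-point flag (bootstrap CI lower bound > F_ST) and its mean."""
    flags = result.ci_low > fst
    return flags, float(flags.mean())
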