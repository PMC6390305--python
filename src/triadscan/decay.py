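"""Decay of differentiation and LD with physical distance from candidates.

Local linear (tricube-weighted) regression with the span chosen by the
bias-corrected AIC, distance profiles of mean TE-vs-reference F_ST around
candidate SNPs against the genome-wide baseline, and r^2-vs-distance decay
with BY-controlled LD significance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genotypes import MISSING, GenotypeMatrix
from .stats import fdr_adjust, ld_r2

__all__ = ["LoessFit", "DecayProfile", "loess_aicc", "fst_decay", "ld_decay"]

DEFAULT_SPAN_GRID = (0.2, 0.3, 0.4, 0.5, 0.65, 0.8, 1.0)


@dataclass
class LoessFit:
    x: np.ndarray
    fitted: np.ndarray
    se: np.ndarray
    span: float
    aicc: float
    trace_hat: float


@dataclass
class DecayProfile:
    pairs: pd.DataFrame                 # distance, value (+ flags)
    fit: LoessFit | None
    baseline: float
    crossing_bp: float | None           # np.nan when undefined
    extras: dict = field(default_factory=dict)


def _loess_once(x, y, span):
    """Tricube local-linear fit at each x; returns fitted, hat-diag, l2norms."""
    n = len(x)
    k = max(3, int(np.ceil(span * n)))
    k = min(k, n)
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    fitted = np.empty(n)
    hat_diag = np.empty(n)
    l2 = np.empty(n)
    for ii in range(n):
        x0 = xs[ii]
        d = np.abs(xs - x0)
        idx = np.argpartition(d, k - 1)[:k]
        dmax = d[idx].max()
        if dmax == 0:
            w = np.ones(len(idx))
        else:
            w = (1 - (d[idx] / dmax) ** 3) ** 3
            w = np.maximum(w, 1e-9)
        X = np.column_stack([np.ones(len(idx)), xs[idx] - x0])
        XtW = X.T * w
        A = XtW @ X
        try:
            beta_row = np.linalg.solve(A, XtW)[0]  # row of the smoother matrix
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError("singular local fit")
        fitted[ii] = beta_row @ ys[idx]
        pos = np.where(idx == ii)[0]
        hat_diag[ii] = beta_row[pos[0]] if len(pos) else 0.0
        l2[ii] = beta_row @ beta_row
    inv = np.empty(n, dtype=int)
    inv[order] = np.arange(n)
    return fitted[inv], hat_diag[inv], l2[inv]


def loess_aicc(
    x: np.ndarray,
    y: np.ndarray,
    span_grid=DEFAULT_SPAN_GRID,
    ci_z: float = 1.96,
) -> LoessFit:
    """Local linear regression with the span minimizing the corrected AIC.

    AICc = n ln(sigma^2) + n (n + tr H) / (n - tr H - 2), with sigma^2 the
    mean squared residual and H the smoother (hat) matrix. Pointwise standard
    errors come from the smoother variance sigma * ||l_i||.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 points")
    best = None
    any_ok = False
    for span in span_grid:
        if not 0 < span <= 1:
            raise ValueError("spans must lie in (0, 1]")
        try:
            fitted, hat, l2 = _loess_once(x, y, span)
        except np.linalg.LinAlgError:
            continue
        any_ok = True
        n = len(x)
        resid = y - fitted
        sigma2 = max(float(resid @ resid) / n, 1e-300)
        tr = float(hat.sum())
        denom = n - tr - 2
        if denom <= 0:
            continue
        aicc = n * np.log(sigma2) + n * (n + tr) / denom
        if best is None or aicc < best[0]:
            best = (aicc, span, fitted, l2, tr, sigma2)
    if best is None:
        if not any_ok:
            raise np.linalg.LinAlgError("all spans produced singular fits")
        raise ValueError("no span with positive AICc degrees of freedom")
    aicc, span, fitted, l2, tr, sigma2 = best
    se = np.sqrt(sigma2 * l2)
    return LoessFit(x=x, fitted=fitted, se=se, span=span, aicc=aicc, trace_hat=tr)


def _neighbor_pairs(loci: pd.DataFrame, focal_mask: np.ndarray, max_dist: int):
    """(focal index, neighbor index, distance) for same-scaffold pairs."""
    scaf = loci["scaffold"].to_numpy()
    pos = loci["pos"].to_numpy()
    out_f, out_n, out_d = [], [], []
    for s in pd.unique(scaf[focal_mask]):
        on = np.flatnonzero(scaf == s)
        foc = on[focal_mask[on]]
        for f in foc:
            d = np.abs(pos[on] - pos[f])
            sel = (d > 0) & (d <= max_dist)
            out_f.extend([f] * sel.sum())
            out_n.extend(on[sel])
            out_d.extend(d[sel])
    return np.array(out_f, int), np.array(out_n, int), np.array(out_d, float)


def fst_decay(
    candidates: pd.DataFrame,
    per_locus_mean_te_fst: np.ndarray,
    loci: pd.DataFrame,
    baseline: float,
    max_dist: int = 1000,
    min_pairs: int = 30,
    span_grid=DEFAULT_SPAN_GRID,
) -> DecayProfile:
    """F_ST decay around candidate SNPs.

    For every non-candidate SNP within ``max_dist`` bp of a candidate on the
    same scaffold, records (distance, mean of the two TE-vs-reference
    per-locus theta values), loess-smooths the profile, and reports the
    distance at which the 95% CI of the smoothed curve first contains the
    genome-wide ``baseline``. Candidate-candidate pairs are recorded but
    excluded from the fit. Crossing is defined only when the curve starts
    above baseline (otherwise 0 when it starts at/below it by construction).
    """
    cand = candidates["candidate"].to_numpy()
    stat = np.asarray(per_locus_mean_te_fst, dtype=float)
    f, nb, d = _neighbor_pairs(loci, cand, max_dist)
    pairs = pd.DataFrame(
        {
            "focal": f,
            "neighbor": nb,
            "distance_bp": d,
            "value": stat[nb] if len(nb) else np.array([]),
            "neighbor_is_candidate": cand[nb] if len(nb) else np.array([], bool),
        }
    )
    fit_rows = pairs[~pairs["neighbor_is_candidate"] & np.isfinite(pairs["value"])]
    if len(fit_rows) < min_pairs:
        warnings.warn(f"only {len(fit_rows)} neighbor pairs; profile not smoothed")
        return DecayProfile(pairs=pairs, fit=None, baseline=baseline, crossing_bp=np.nan)
    fit = loess_aicc(fit_rows["distance_bp"].to_numpy(), fit_rows["value"].to_numpy(),
                     span_grid=span_grid)
    order = np.argsort(fit.x)
    xs = fit.x[order]
    fitted = fit.fitted[order]
    lo = (fit.fitted - 1.96 * fit.se)[order]
    if fitted[0] <= baseline:
        crossing = 0.0  # curve does not start above baseline
    else:
        # first distance at which the CI reaches down to the baseline, i.e.
        # the curve is no longer distinguishable from genome-wide F_ST
        hit = np.flatnonzero(lo <= baseline)
        crossing = float(xs[hit[0]]) if len(hit) else np.nan
    return DecayProfile(pairs=pairs, fit=fit, baseline=baseline, crossing_bp=crossing)


def ld_decay(
    g: GenotypeMatrix,
    candidates: pd.DataFrame,
    max_dist: int = 100_000,
    q: float = 0.1,
    min_shared: int = 20,
    populations: list[str] | None = None,
    span_grid=DEFAULT_SPAN_GRID,
) -> DecayProfile:
    """r^2 vs distance for candidate-containing and other same-scaffold pairs.

    Per-pair LD significance by Pearson correlation test, BY-adjusted at
    ``q``; reports the maximum distance of any significant candidate-
    containing pair and the distance at which the smoothed candidate-pair
    curve falls to half its maximum.
    """
    if populations is None:
        idx = np.arange(g.n_individuals)
    else:
        idx = np.concatenate([g.pop_indices(p) for p in populations])
    dos = g.genotypes[idx]
    cand = candidates["candidate"].to_numpy()
    scaf = g.loci["scaffold"].to_numpy()
    pos = g.loci["pos"].to_numpy()
    rows = []
    for s in pd.unique(scaf):
        on = np.flatnonzero(scaf == s)
        for ii in range(len(on)):
            for jj in range(ii + 1, len(on)):
                a, b = on[ii], on[jj]
                dist = abs(pos[a] - pos[b])
                if dist == 0 or dist > max_dist:
                    continue
                shared = (dos[:, a] != MISSING) & (dos[:, b] != MISSING)
                r2 = ld_r2(dos[:, a], dos[:, b], min_shared)
                if not np.isfinite(r2):
                    continue
                nsh = int(shared.sum())
                r = np.sqrt(r2)
                # two-sided correlation test p from t distribution
                if r2 >= 1.0 - 1e-12:
                    pval = 0.0
                else:
                    t = r * np.sqrt((nsh - 2) / (1 - r2))
                    pval = 2 * sps.t.sf(t, df=nsh - 2)
                rows.append((a, b, float(dist), r2, pval, bool(cand[a] or cand[b])))
    pairs = pd.DataFrame(
        rows, columns=["i", "j", "distance_bp", "r2", "p", "contains_candidate"]
    )
    max_sig = np.nan
    if len(pairs):
        p_adj, rej = fdr_adjust(pairs["p"].to_numpy(), method="BY", q=q)
        pairs["p_adj"] = p_adj
        pairs["significant"] = rej
        sig_cand = pairs[pairs["significant"] & pairs["contains_candidate"]]
        if len(sig_cand):
            max_sig = float(sig_cand["distance_bp"].max())
    fit = None
    half_decay = np.nan
    sub = pairs[pairs["contains_candidate"]]
    if len(sub) >= 10:
        fit = loess_aicc(sub["distance_bp"].to_numpy(), sub["r2"].to_numpy(),
                         span_grid=span_grid)
        order = np.argsort(fit.x)
        xs, ys = fit.x[order], fit.fitted[order]
        top = ys.max()
        under = np.flatnonzero(ys <= top / 2.0)
        if len(under):
            half_decay = float(xs[under[0]])
    return DecayProfile(
        pairs=pairs,
        fit=fit,
        baseline=float(pairs["r2"].median()) if len(pairs) else np.nan,
        crossing_bp=half_decay,
        extras={"max_significant_candidate_distance_bp": max_sig},
    )
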