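"""Vectorized statistical primitives for epigenome-wide association scans.

Methylation arrays carry 10^4-10^5 CpGs and every selection stage fits one
small model per CpG (logistic senescence status ~ scaled beta; OLS scaled
beta ~ scaled age; Cox survival ~ scaled beta + age). Fitting those one at a
time through a generic GLM interface is orders of magnitude too slow, so
this module implements the per-feature fits as batched Newton/IRLS
iterations over all CpGs simultaneously. Each fit is a 1- or 2-parameter
model, so the per-CpG Hessians are closed-form 2x2 solves.

The implementations are cross-checked against statsmodels (logistic) and
lifelines (Cox) in the test suite.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
from scipy import stats as sps

__all__ = [
    "logistic_by_feature",
    "firth_logistic_by_feature",
    "cox_by_feature",
    "standardized_slope",
    "bicor",
    "bicor_by_feature",
    "bicor_pvalue",
    "fixed_effect_meta",
    "adjust_pvalues",
]

_SEPARATION_CAP = 15.0  # |slope| beyond this on standardized data = separation


def _solve2x2(h00, h01, h11, g0, g1):
    """Solve per-row symmetric 2x2 systems H d = g."""
    det = h00 * h11 - h01 * h01
    det = np.where(np.abs(det) < 1e-300, np.nan, det)
    d0 = (h11 * g0 - h01 * g1) / det
    d1 = (h00 * g1 - h01 * g0) / det
    return d0, d1


def _sigmoid(eta):
    return 0.5 * (1.0 + np.tanh(0.5 * eta))


def logistic_by_feature(
    x: np.ndarray,
    y: np.ndarray,
    max_iter: int = 60,
    tol: float = 1e-10,
) -> dict:
    """Per-row logistic regression y ~ intercept + x[i] for every row of x.

    Parameters
    ----------
    x : (m, n) matrix of predictors (one row per CpG, typically z-scored betas)
    y : (n,) binary outcome shared by all rows

    Returns dict of (m,) arrays: effect, se, p, converged, separation.
    Rows with (quasi-)separation or failed convergence are refit with a
    Firth/Jeffreys penalty so they still receive a finite, flagged effect.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m, n = x.shape
    if y.shape != (n,):
        raise ValueError("y length must match x columns")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome is single-class; logistic model undefined")

    b0 = np.full(m, np.log(y.mean() / (1.0 - y.mean())))
    b1 = np.zeros(m)
    converged = np.zeros(m, dtype=bool)
    for _ in range(max_iter):
        eta = b0[:, None] + b1[:, None] * x
        p = _sigmoid(eta)
        w = p * (1.0 - p)
        resid = y[None, :] - p
        g0 = resid.sum(axis=1)
        g1 = (resid * x).sum(axis=1)
        h00 = w.sum(axis=1)
        h01 = (w * x).sum(axis=1)
        h11 = (w * x * x).sum(axis=1)
        d0, d1 = _solve2x2(h00, h01, h11, g0, g1)
        d0 = np.nan_to_num(d0)
        d1 = np.nan_to_num(d1)
        step = np.maximum(np.abs(d0), np.abs(d1))
        # freeze rows that already converged
        live = ~converged
        b0 = b0 + d0 * live
        b1 = b1 + d1 * live
        converged |= step < tol
        if converged.all():
            break
    # final information matrix for SEs
    eta = b0[:, None] + b1[:, None] * x
    p = _sigmoid(eta)
    w = p * (1.0 - p)
    h00 = w.sum(axis=1)
    h01 = (w * x).sum(axis=1)
    h11 = (w * x * x).sum(axis=1)
    det = h00 * h11 - h01 * h01
    with np.errstate(divide="ignore", invalid="ignore"):
        var1 = h00 / det
    se = np.sqrt(np.where(var1 > 0, var1, np.nan))

    separation = (~converged) | (np.abs(b1) > _SEPARATION_CAP) | ~np.isfinite(se)
    if separation.any():
        fb0, fb1, fse = firth_logistic_by_feature(x[separation], y)
        b0 = b0.copy()
        b1 = b1.copy()
        se = se.copy()
        b0[separation] = fb0
        b1[separation] = fb1
        se[separation] = fse
    with np.errstate(divide="ignore", invalid="ignore"):
        z = b1 / se
    pval = 2.0 * sps.norm.sf(np.abs(z))
    return {
        "effect": b1,
        "intercept": b0,
        "se": se,
        "p": pval,
        "converged": converged,
        "separation": separation,
    }


def firth_logistic_by_feature(
    x: np.ndarray, y: np.ndarray, max_iter: int = 120, tol: float = 1e-8
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Jeffreys-prior penalized logistic fits (per row of x).

    Firth's bias reduction keeps estimates finite under complete separation;
    used as the fallback for flagged CpGs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m, n = x.shape
    b0 = np.zeros(m)
    b1 = np.zeros(m)
    damp = 1.0
    for _ in range(max_iter):
        eta = np.clip(b0[:, None] + b1[:, None] * x, -30, 30)
        p = _sigmoid(eta)
        w = p * (1.0 - p)
        h00 = w.sum(axis=1)
        h01 = (w * x).sum(axis=1)
        h11 = (w * x * x).sum(axis=1)
        det = h00 * h11 - h01 * h01
        det = np.where(np.abs(det) < 1e-300, np.nan, det)
        a00 = h11 / det
        a01 = -h01 / det
        a11 = h00 / det
        # leverages of W^1/2 X with X = [1, x]
        hat = w * (a00[:, None] + 2.0 * a01[:, None] * x + a11[:, None] * x * x)
        adj = y[None, :] - p + hat * (0.5 - p)
        g0 = adj.sum(axis=1)
        g1 = (adj * x).sum(axis=1)
        d0, d1 = _solve2x2(h00, h01, h11, g0, g1)
        d0 = np.clip(np.nan_to_num(d0), -damp, damp)
        d1 = np.clip(np.nan_to_num(d1), -damp, damp)
        b0 = b0 + d0
        b1 = b1 + d1
        if max(np.abs(d0).max(initial=0.0), np.abs(d1).max(initial=0.0)) < tol:
            break
    eta = np.clip(b0[:, None] + b1[:, None] * x, -30, 30)
    p = _sigmoid(eta)
    w = p * (1.0 - p)
    h00 = w.sum(axis=1)
    h01 = (w * x).sum(axis=1)
    h11 = (w * x * x).sum(axis=1)
    det = h00 * h11 - h01 * h01
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(h00 / det)
    return b0, b1, se


# ---------------------------------------------------------------------------
# Cox proportional hazards, one CpG at a time (vectorized), Breslow ties
# ---------------------------------------------------------------------------

def cox_by_feature(
    z: np.ndarray,
    covariate: Optional[np.ndarray],
    time: np.ndarray,
    event: np.ndarray,
    max_iter: int = 40,
    tol: float = 1e-9,
    chunk_elements: int = 20_000_000,
) -> dict:
    """Per-row Cox PH fit: hazard ~ z[i] (+ shared covariate, e.g. age).

    Breslow partial likelihood, Newton-Raphson, vectorized over rows of
    ``z`` in memory-bounded chunks. Returns per-row log HR ('effect'), SE,
    Wald p, and flags for non-convergence/divergence.
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    n = time.shape[0]
    if event.sum() < 1:
        raise ValueError("no events; Cox model undefined")
    order = np.argsort(time, kind="stable")
    t_s = time[order]
    e_s = event[order].astype(bool)
    # for tied times the risk set starts at the first index of that time
    first_idx = np.searchsorted(t_s, t_s, side="left")
    has_cov = covariate is not None
    a = np.asarray(covariate, dtype=float)[order] if has_cov else None

    m = z.shape[0]
    effect = np.empty(m)
    se = np.empty(m)
    flagged = np.zeros(m, dtype=bool)
    chunk = max(1, int(chunk_elements // max(n, 1)))
    for start in range(0, m, chunk):
        Z = z[start:start + chunk][:, order]
        c = Z.shape[0]
        bz = np.zeros(c)
        ba = np.zeros(c)
        conv = np.zeros(c, dtype=bool)
        for _ in range(max_iter):
            eta = bz[:, None] * Z
            if has_cov:
                eta = eta + ba[:, None] * a[None, :]
            theta = np.exp(np.clip(eta, -60, 60))
            # suffix (reverse cumulative) sums over the risk set
            def rsum(v):
                return np.cumsum(v[:, ::-1], axis=1)[:, ::-1][:, first_idx]

            s0 = rsum(theta)
            s1z = rsum(theta * Z)
            mz = s1z / s0
            gz = (Z[:, e_s] - mz[:, e_s]).sum(axis=1)
            s2zz = rsum(theta * Z * Z)
            hzz = (s2zz[:, e_s] / s0[:, e_s] - mz[:, e_s] ** 2).sum(axis=1)
            if has_cov:
                s1a = rsum(theta * a[None, :])
                ma = s1a / s0
                ga = (a[None, e_s] - ma[:, e_s]).sum(axis=1)
                s2za = rsum(theta * Z * a[None, :])
                s2aa = rsum(theta * (a * a)[None, :])
                hza = (s2za[:, e_s] / s0[:, e_s] - mz[:, e_s] * ma[:, e_s]).sum(axis=1)
                haa = (s2aa[:, e_s] / s0[:, e_s] - ma[:, e_s] ** 2).sum(axis=1)
                dz, da = _solve2x2(hzz, hza, haa, gz, ga)
            else:
                with np.errstate(divide="ignore", invalid="ignore"):
                    dz = gz / hzz
                da = np.zeros_like(dz)
            dz = np.clip(np.nan_to_num(dz), -2.0, 2.0)
            da = np.clip(np.nan_to_num(da), -2.0, 2.0)
            live = ~conv
            bz = bz + dz * live
            ba = ba + da * live
            conv |= np.maximum(np.abs(dz), np.abs(da)) < tol
            if conv.all():
                break
        # variance from the final information matrix
        eta = bz[:, None] * Z
        if has_cov:
            eta = eta + ba[:, None] * a[None, :]
        theta = np.exp(np.clip(eta, -60, 60))
        rs = np.cumsum(theta[:, ::-1], axis=1)[:, ::-1][:, first_idx]
        s1z = np.cumsum((theta * Z)[:, ::-1], axis=1)[:, ::-1][:, first_idx]
        s2zz = np.cumsum((theta * Z * Z)[:, ::-1], axis=1)[:, ::-1][:, first_idx]
        mzv = s1z / rs
        hzz = (s2zz[:, e_s] / rs[:, e_s] - mzv[:, e_s] ** 2).sum(axis=1)
        if has_cov:
            s1a = np.cumsum((theta * a[None, :])[:, ::-1], axis=1)[:, ::-1][:, first_idx]
            s2za = np.cumsum((theta * Z * a[None, :])[:, ::-1], axis=1)[:, ::-1][:, first_idx]
            s2aa = np.cumsum((theta * (a * a)[None, :])[:, ::-1], axis=1)[:, ::-1][:, first_idx]
            mav = s1a / rs
            hza = (s2za[:, e_s] / rs[:, e_s] - mzv[:, e_s] * mav[:, e_s]).sum(axis=1)
            haa = (s2aa[:, e_s] / rs[:, e_s] - mav[:, e_s] ** 2).sum(axis=1)
            det = hzz * haa - hza * hza
            with np.errstate(divide="ignore", invalid="ignore"):
                var_z = haa / det
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                var_z = 1.0 / hzz
        sez = np.sqrt(np.where(var_z > 0, var_z, np.nan))
        bad = (~conv) | ~np.isfinite(sez) | (np.abs(bz) > 10.0)
        effect[start:start + chunk] = bz
        se[start:start + chunk] = sez
        flagged[start:start + chunk] = bad
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = effect / se
    p = 2.0 * sps.norm.sf(np.abs(zstat))
    return {"effect": effect, "se": se, "p": p, "flagged": flagged}


# ---------------------------------------------------------------------------
# standardized OLS slope (equals Pearson r on z-scored data)
# ---------------------------------------------------------------------------

def standardized_slope(x: np.ndarray, y: np.ndarray) -> dict:
    """Slope of z-scored x[i] regressed on z-scored y, per row.

    On standardized variables the slope equals the Pearson correlation; SE
    and two-sided p come from the usual t distribution with n-2 df.
    Constant rows are flagged (NaN slope).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.std(y) == 0:
        raise ValueError("degenerate (constant) regressor")
    yc = y - y.mean()
    yz = yc / y.std(ddof=1)
    xc = x - x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1)
    flagged = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        xz = xc / sd[:, None]
    r = (xz * yz[None, :]).sum(axis=1) / (n - 1)
    r = np.where(flagged, np.nan, np.clip(r, -1.0, 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt((1.0 - r**2) / (n - 2))
        t = r / se
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isfinite(t), p, 0.0)
    p = np.where(flagged, np.nan, p)
    return {"effect": r, "se": se, "p": p, "flagged": flagged}


# ---------------------------------------------------------------------------
# biweight midcorrelation
# ---------------------------------------------------------------------------

def _biweight_transform(x: np.ndarray):
    """Median-centered, (1-u^2)^2-weighted deviations; u = dev / (9 MAD)."""
    med = np.median(x, axis=-1, keepdims=True)
    dev = x - med
    mad = np.median(np.abs(dev), axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        u = dev / (9.0 * mad)
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    tx = dev * w
    norm = np.sqrt((tx**2).sum(axis=-1, keepdims=True))
    zero_mad = (mad == 0).squeeze(-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tx = tx / norm
    return tx, zero_mad


def bicor_by_feature(x: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Biweight midcorrelation of each row of x with y.

    Returns (r, flagged); flagged rows have zero median absolute deviation
    (constant or near-constant vectors) and r = NaN.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float)
    if x.shape[-1] < 3:
        raise ValueError("bicor needs at least 3 paired values")
    tx, flag_x = _biweight_transform(x)
    ty, flag_y = _biweight_transform(y[None, :])
    flagged = flag_x | flag_y[0]
    r = (tx * ty).sum(axis=-1)
    r = np.where(flagged, np.nan, np.clip(r, -1.0, 1.0))
    return r, flagged


def bicor(x: np.ndarray, y: np.ndarray) -> float:
    """Scalar biweight midcorrelation of two vectors (NaN if MAD is zero)."""
    r, flagged = bicor_by_feature(np.asarray(x, dtype=float)[None, :], y)
    return float(r[0])


def bicor_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Student-t approximation for bicor p-values (as in WGCNA)."""
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return np.where(np.isnan(r), np.nan, p)


# ---------------------------------------------------------------------------
# fixed-effects inverse-variance meta-analysis
# ---------------------------------------------------------------------------

def fixed_effect_meta(
    effects: np.ndarray, ses: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pool per-stratum effects with weights 1/SE^2.

    ``effects``/``ses`` are (k, m): k strata by m CpGs (or 1-D for a single
    CpG). Strata with non-finite effect or SE are skipped per CpG; CpGs with
    no usable stratum come back NaN. Returns (pooled effect, pooled SE,
    two-sided normal p).
    """
    effects = np.atleast_2d(np.asarray(effects, dtype=float))
    ses = np.atleast_2d(np.asarray(ses, dtype=float))
    if effects.shape != ses.shape:
        raise ValueError("effects and ses must have the same shape")
    usable = np.isfinite(effects) & np.isfinite(ses) & (ses > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(usable, 1.0 / ses**2, 0.0)
    wsum = w.sum(axis=0)
    none = wsum == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        pooled = (w * np.where(usable, effects, 0.0)).sum(axis=0) / wsum
        pooled_se = 1.0 / np.sqrt(wsum)
    pooled = np.where(none, np.nan, pooled)
    pooled_se = np.where(none, np.nan, pooled_se)
    z = pooled / pooled_se
    p = 2.0 * sps.norm.sf(np.abs(z))
    return pooled, pooled_se, p


# ---------------------------------------------------------------------------
# multiple-testing adjustment
# ---------------------------------------------------------------------------

def adjust_pvalues(p: np.ndarray, method: str = "bonferroni",
                   m: Optional[int] = None) -> np.ndarray:
    """Bonferroni (min(1, m*p), m defaults to len(p)) or Benjamini-Hochberg
    step-up adjusted p-values. NaNs pass through untouched and do not count
    toward m."""
    p = np.asarray(p, dtype=float)
    ok = np.isfinite(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bonferroni":
        m_eff = int(m) if m is not None else int(ok.sum())
        out = np.minimum(p * m_eff, 1.0)
        return np.where(ok, out, np.nan)
    if method == "bh":
        from statsmodels.stats.multitest import multipletests

        out = np.full_like(p, np.nan)
        if ok.sum():
            out[ok] = multipletests(p[ok], method="fdr_bh")[1]
        return out
    raise ValueError(f"unknown adjustment method {method!r}")
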