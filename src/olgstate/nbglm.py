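"""Negative-binomial GLM machinery shared by the pseudobulk and bulk
differential modules.

Implements median-of-ratios size factors, TMM normalization factors,
within-group method-of-moments dispersions shrunk toward a parametric
mean-dispersion trend, and a batched IRLS fitter (log link, fixed
per-feature dispersion) with Wald and likelihood-ratio tests. The fitter
handles all features simultaneously: per-feature weighted normal equations
are assembled with einsum and solved with batched linear algebra, so a few
thousand features by a few dozen samples fit in well under a second.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

_LN2 = np.log(2.0)
_DISP_MIN = 1e-8
_DISP_MAX = 10.0


# ---------------------------------------------------------------------------
# normalization factors
# ---------------------------------------------------------------------------

def size_factors_median_ratio(counts: np.ndarray) -> np.ndarray:
    """DESeq-style median-of-ratios size factors (geometric-mean reference).

    Falls back to library-size factors when no feature is positive in all
    samples.
    """
    counts = np.asarray(counts, dtype=float)
    with np.errstate(divide="ignore"):
        logc = np.log(counts)
    finite = np.isfinite(logc).all(axis=1)
    if finite.sum() == 0:
        lib = counts.sum(axis=0)
        return lib / np.exp(np.mean(np.log(lib)))
    ref = logc[finite].mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logc[finite] - ref, axis=0))
    return sf


def tmm_norm_factors(
    counts: np.ndarray,
    logratio_trim: float = 0.30,
    abs_trim: float = 0.05,
) -> np.ndarray:
    """Trimmed-mean-of-M-values normalization factors (geomean-centered).

    The reference sample is the one whose upper-quartile fraction is
    closest to the mean; M values are trimmed by 30% on each tail and A
    values by 5%, and the trimmed mean is weighted by asymptotic inverse
    variances.
    """
    counts = np.asarray(counts, dtype=float)
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("sample with zero total counts")
    uq = np.array([np.quantile(counts[:, j][counts[:, j] > 0], 0.75) / lib[j] for j in range(counts.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(counts.shape[1])
    yr, nr = counts[:, ref], lib[ref]
    for j in range(counts.shape[1]):
        if j == ref:
            continue
        yk, nk = counts[:, j], lib[j]
        keep = (yk > 0) & (yr > 0)
        if keep.sum() < 10:
            continue
        m = np.log2((yk[keep] / nk) / (yr[keep] / nr))
        a = 0.5 * np.log2((yk[keep] / nk) * (yr[keep] / nr))
        w = (nk - yk[keep]) / (nk * yk[keep]) + (nr - yr[keep]) / (nr * yr[keep])
        lo_m, hi_m = np.quantile(m, [logratio_trim, 1 - logratio_trim])
        lo_a, hi_a = np.quantile(a, [abs_trim, 1 - abs_trim])
        sel = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if sel.sum() == 0 or np.sum(1.0 / w[sel]) == 0:
            continue
        factors[j] = 2 ** (np.sum(m[sel] / w[sel]) / np.sum(1.0 / w[sel]))
    return factors / np.exp(np.mean(np.log(factors)))


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------

def dispersion_mom(
    counts: np.ndarray, size_factors: np.ndarray, groups: np.ndarray
) -> np.ndarray:
    """Within-group method-of-moments dispersion per feature.

    Uses size-factor-normalized counts; pooled within-group variance keeps
    genuine condition effects out of the dispersion estimate.
    """
    norm = np.asarray(counts, dtype=float) / size_factors
    xi = np.mean(1.0 / size_factors)
    levels = pd.unique(groups)
    ss = np.zeros(counts.shape[0])
    dof = 0
    for lv in levels:
        cols = np.flatnonzero(groups == lv)
        if len(cols) < 2:
            continue
        sub = norm[:, cols]
        ss += sub.var(axis=1, ddof=1) * (len(cols) - 1)
        dof += len(cols) - 1
    if dof == 0:
        raise ValueError("dispersion not estimable: no group has >= 2 replicates")
    pooled_var = ss / dof
    mean = norm.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (pooled_var - xi * mean) / mean**2
    d[~np.isfinite(d)] = 0.0
    return np.clip(d, 0.0, _DISP_MAX)


def dispersion_trend(mean: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Parametric trend d(mu) = a1 + a0/mu fit to positive raw estimates."""
    ok = (mean > 0) & (disp > 1e-6)
    if ok.sum() < 10:
        med = max(float(np.median(disp[disp > 0])) if (disp > 0).any() else 0.01, 1e-4)
        return np.full_like(mean, med)
    x = 1.0 / mean[ok]
    y = disp[ok]
    keep = np.ones(ok.sum(), dtype=bool)
    a0, a1 = 0.0, float(np.median(y))
    for _ in range(10):  # iteratively drop far-outlying genes from the fit
        A = np.c_[x[keep], np.ones(keep.sum())]
        coef, *_ = np.linalg.lstsq(A, y[keep], rcond=None)
        a0, a1 = float(coef[0]), float(coef[1])
        pred = a0 * x + a1
        ratio = y / np.maximum(pred, 1e-8)
        new_keep = (ratio < 10) & (ratio > 1e-3)
        if (new_keep == keep).all():
            break
        keep = new_keep
    a0 = max(a0, 0.0)
    a1 = max(a1, 1e-6)
    return a0 / np.maximum(mean, 1e-8) + a1


def shrink_dispersions(
    disp: np.ndarray, trend: np.ndarray, weight: float = 0.25
) -> np.ndarray:
    """Geometric shrinkage of gene-wise estimates toward the trend."""
    d = np.maximum(disp, _DISP_MIN)
    out = np.exp(weight * np.log(d) + (1 - weight) * np.log(np.maximum(trend, _DISP_MIN)))
    return np.clip(out, _DISP_MIN, _DISP_MAX)


def estimate_dispersions(
    counts: np.ndarray,
    size_factors: np.ndarray,
    groups: np.ndarray,
    weight: float = 0.25,
) -> np.ndarray:
    raw = dispersion_mom(counts, size_factors, groups)
    mean = (np.asarray(counts, float) / size_factors).mean(axis=1)
    trend = dispersion_trend(mean, raw)
    return shrink_dispersions(raw, trend, weight=weight)


# ---------------------------------------------------------------------------
# batched IRLS fitting
# ---------------------------------------------------------------------------

def nb_loglik(y: np.ndarray, mu: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Per-feature NB log-likelihood (summed over samples)."""
    a = np.maximum(disp, _DISP_MIN)[:, None]
    mu = np.maximum(mu, 1e-10)
    inv = 1.0 / a
    ll = (
        special.gammaln(y + inv)
        - special.gammaln(inv)
        - special.gammaln(y + 1.0)
        + y * np.log(a * mu / (1.0 + a * mu))
        - inv * np.log1p(a * mu)
    )
    return ll.sum(axis=1)


def fit_nb_glm(
    counts: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    disp: np.ndarray,
    n_iter: int = 50,
    ridge: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit log-link NB GLMs for every feature against a common design.

    counts : (F, S) integers; X : (S, P); offset : (S,) log-scale;
    disp : (F,) fixed per-feature dispersions.
    Returns (beta (F, P), cov (F, P, P), mu (F, S)).
    """
    Y = np.asarray(counts, dtype=float)
    F, S = Y.shape
    P = X.shape[1]
    disp_col = np.maximum(disp, _DISP_MIN)[:, None]

    # start from a working log-linear fit
    z0 = np.log((Y + 0.5)) - offset[None, :]
    beta, *_ = np.linalg.lstsq(X, z0.T, rcond=None)
    beta = beta.T  # (F, P)

    eye = ridge * np.eye(P)
    for _ in range(n_iter):
        eta = np.clip(beta @ X.T + offset[None, :], -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + disp_col * mu)  # (F, S)
        z = eta - offset[None, :] + (Y - mu) / np.maximum(mu, 1e-10)
        A = np.einsum("sp,fs,sq->fpq", X, w, X) + eye[None, :, :]
        b = np.einsum("sp,fs,fs->fp", X, w, z)
        new_beta = np.linalg.solve(A, b[..., None])[..., 0]
        delta = np.max(np.abs(new_beta - beta))
        beta = new_beta
        if delta < 1e-10:
            break
    eta = np.clip(beta @ X.T + offset[None, :], -30.0, 30.0)
    mu = np.exp(eta)
    w = mu / (1.0 + disp_col * mu)
    A = np.einsum("sp,fs,sq->fpq", X, w, X) + eye[None, :, :]
    cov = np.linalg.inv(A)
    return beta, cov, mu


def build_design(
    meta: pd.DataFrame,
    condition_col: str,
    reference: str,
    covariate_cols: list[str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Intercept + treatment-coded condition dummies + covariate dummies."""
    levels = [lv for lv in pd.unique(meta[condition_col]) if lv != reference]
    cols = [np.ones(len(meta))]
    names = ["intercept"]
    for lv in levels:
        cols.append((meta[condition_col] == lv).to_numpy(dtype=float))
        names.append(f"{condition_col}_{lv}")
    for cov in covariate_cols or []:
        cl = [x for x in pd.unique(meta[cov])][1:]
        for lv in cl:
            cols.append((meta[cov] == lv).to_numpy(dtype=float))
            names.append(f"{cov}_{lv}")
    return np.column_stack(cols), names


def wald_contrast(
    beta: np.ndarray,
    cov: np.ndarray,
    names: list[str],
    numerator: str,
    denominator: str,
    condition_col: str,
    reference: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """log2FC, Wald z and two-sided p for numerator vs denominator."""
    c = np.zeros(beta.shape[1])
    if numerator != reference:
        c[names.index(f"{condition_col}_{numerator}")] += 1.0
    if denominator != reference:
        c[names.index(f"{condition_col}_{denominator}")] -= 1.0
    est = beta @ c
    var = np.einsum("p,fpq,q->f", c, cov, c)
    se = np.sqrt(np.maximum(var, 1e-300))
    z = est / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return est / _LN2, z, p


def bh_adjust(p: np.ndarray) -> np.ndarray:
    mask = np.isfinite(p)
    out = np.full_like(p, np.nan, dtype=float)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# edgeR-style common/tagwise dispersion + LRT
# ---------------------------------------------------------------------------

def common_dispersion(
    counts: np.ndarray, X: np.ndarray, offset: np.ndarray
) -> float:
    """Common NB dispersion maximizing the summed Cox-Reid adjusted profile
    likelihood (the adjustment avoids the downward bias from estimating the
    design coefficients)."""
    Y = np.asarray(counts, float)

    def neg_ll(log_d: float) -> float:
        d = float(np.exp(log_d))
        disp = np.full(Y.shape[0], d)
        beta, _, mu = fit_nb_glm(Y, X, offset, disp, n_iter=25)
        ll = nb_loglik(Y, mu, disp)
        w = mu / (1.0 + d * mu)
        A = np.einsum("sp,fs,sq->fpq", X, w, X)
        sign, logdet = np.linalg.slogdet(A + 1e-10 * np.eye(X.shape[1]))
        return -float((ll - 0.5 * logdet).sum())

    res = optimize.minimize_scalar(neg_ll, bounds=(np.log(1e-5), np.log(5.0)), method="bounded",
                                   options={"xatol": 1e-3})
    return float(np.exp(res.x))


def tagwise_dispersion(
    counts: np.ndarray,
    size_factors: np.ndarray,
    groups: np.ndarray,
    common: float,
    prior_weight: float = 0.75,
) -> np.ndarray:
    raw = dispersion_mom(counts, size_factors, groups)
    raw = np.maximum(raw, _DISP_MIN)
    out = np.exp((1 - prior_weight) * np.log(raw) + prior_weight * np.log(max(common, _DISP_MIN)))
    return np.clip(out, _DISP_MIN, _DISP_MAX)


def nb_lrt_contrast(
    counts: np.ndarray,
    X_full: np.ndarray,
    X_reduced: np.ndarray,
    offset: np.ndarray,
    disp: np.ndarray,
    lfc_vector: np.ndarray,
) -> pd.DataFrame:
    """Likelihood-ratio test of the coefficients dropped in the reduced
    design; ``lfc_vector`` extracts the reported contrast from the full fit."""
    Y = np.asarray(counts, float)
    beta_f, _, mu_f = fit_nb_glm(Y, X_full, offset, disp)
    _, _, mu_r = fit_nb_glm(Y, X_reduced, offset, disp)
    ll_f = nb_loglik(Y, mu_f, disp)
    ll_r = nb_loglik(Y, mu_r, disp)
    lr = np.maximum(2.0 * (ll_f - ll_r), 0.0)
    df = X_full.shape[1] - X_reduced.shape[1]
    p = stats.chi2.sf(lr, df)
    logfc = (beta_f @ lfc_vector) / _LN2
    return pd.DataFrame({"logFC": logfc, "LR": lr, "p": p, "fdr": bh_adjust(p)})
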