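"""Along-tract functional statistics.

A varying-coefficient model over arclength: for subject i with design row
x_i and diffusion property y_i(s),

    y_i(s) = x_i^T beta(s) + e_i(s),

estimated by pointwise weighted least squares combined with local-linear
(Epanechnikov-kernel) smoothing of the coefficient functions. Residual
curves feed a functional PCA (components retained to 95% variance) and a
pointwise Wald statistic; global covariate significance uses the integrated
Wald statistic with a wild-bootstrap (Rademacher) null; local significance
is Benjamini-Hochberg FDR corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core import StructuralError
from .formats.tables import ARCLENGTH_COLUMN


@dataclass
class VCModelSpec:
    """Model definition and testing parameters."""

    covariates: Sequence[str] = ()        # design = intercept + these columns
    bandwidth: Optional[float] = None     # mm; default 2 x grid step
    n_resamples: int = 1000
    fdr_q: float = 0.05
    fpca_var: float = 0.95
    seed: int = 0

    def __post_init__(self):
        if self.bandwidth is not None and self.bandwidth <= 0:
            raise StructuralError("bandwidth must be positive")


@dataclass
class VCMFit:
    """Fitted varying-coefficient model."""

    grid: np.ndarray                      # (m,) arclength
    covariate_names: List[str]            # includes 'intercept'
    betas: np.ndarray                     # (p, m) smoothed coefficients
    se: np.ndarray                        # (p, m) pointwise standard errors
    residuals: np.ndarray                 # (n, m) residual curves
    valid: np.ndarray                     # (m,) bins with enough subjects
    X: np.ndarray                         # (n, p) design
    Y: np.ndarray                         # (n, m) responses (NaN = missing)
    smoother: np.ndarray                  # (m, m) local-linear matrix
    spec: VCModelSpec = dc_field(default_factory=VCModelSpec)
    fpca_values: Optional[np.ndarray] = None
    fpca_components: Optional[np.ndarray] = None
    fpca_var_explained: Optional[float] = None


@dataclass
class StatResult:
    """Per-covariate test output for one property."""

    grid: np.ndarray
    covariate: str
    beta: np.ndarray
    se: np.ndarray
    p_raw: np.ndarray
    p_fdr: np.ndarray
    significant: np.ndarray
    p_global: float


def _epanechnikov(u: np.ndarray) -> np.ndarray:
    return np.where(np.abs(u) <= 1, 0.75 * (1 - u ** 2), 0.0)


def local_linear_smoother(grid: np.ndarray, h: float) -> np.ndarray:
    """(m, m) matrix applying a local-linear Epanechnikov smooth on the grid."""
    ds = grid[np.newaxis, :] - grid[:, np.newaxis]       # (s0, s_j)
    w = _epanechnikov(ds / h)
    s0 = w.sum(axis=1)
    s1 = (w * ds).sum(axis=1)
    s2 = (w * ds ** 2).sum(axis=1)
    den = s0 * s2 - s1 ** 2
    # fall back to Nadaraya-Watson where the local line is degenerate
    L = np.where(den[:, np.newaxis] > 1e-12,
                 w * (s2[:, np.newaxis] - s1[:, np.newaxis] * ds)
                 / np.where(den[:, np.newaxis] > 1e-12, den[:, np.newaxis], 1),
                 w / np.where(s0[:, np.newaxis] > 0, s0[:, np.newaxis], 1))
    return L


def _design(covariates: pd.DataFrame, labels: Sequence[str],
            names: Sequence[str]) -> np.ndarray:
    X = np.ones((len(labels), 1 + len(names)))
    for k, name in enumerate(names):
        if name not in covariates.columns:
            raise StructuralError(f"covariate {name!r} not in table")
        X[:, k + 1] = covariates.loc[list(labels), name].to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X)
        bad = [(["intercept"] + list(names))[j]
               for j in range(X.shape[1]) if abs(R[j, j]) < 1e-10]
        raise StructuralError(f"design matrix is rank deficient; collinear "
                              f"columns: {bad}")
    return X


def fit_vcm(profiles: pd.DataFrame, covariates: pd.DataFrame,
            spec: VCModelSpec) -> VCMFit:
    """Fit the varying-coefficient model to an arclength-first profile table.

    Profile columns are matched to covariate rows by label (an ``atlas``
    reference column is ignored). Bins where a subject is missing drop that
    subject from the local fit; bins with fewer than p + 2 subjects are
    flagged invalid and excluded from smoothing and global integration.
    """
    grid = profiles[ARCLENGTH_COLUMN].to_numpy(dtype=float)
    labels = [c for c in profiles.columns
              if c not in (ARCLENGTH_COLUMN, "atlas")]
    if len(labels) < len(spec.covariates) + 3:
        raise StructuralError("need at least covariates + 3 subjects")
    Y = profiles[labels].to_numpy(dtype=float).T          # (n, m)
    X = _design(covariates, labels, spec.covariates)
    n, p = X.shape
    m = len(grid)
    step = float(np.median(np.diff(grid)))
    h = spec.bandwidth if spec.bandwidth is not None else 2.0 * step

    # pointwise WLS (per-bin OLS with missing subjects dropped)
    b_raw = np.full((p, m), np.nan)
    valid = np.zeros(m, dtype=bool)
    complete = ~np.isnan(Y).any(axis=0)
    if complete.all():
        pinv = np.linalg.pinv(X)
        b_raw[:, :] = pinv @ Y
        valid[:] = True
    else:
        for j in range(m):
            ok = ~np.isnan(Y[:, j])
            if ok.sum() < p + 2:
                continue
            b_raw[:, j] = np.linalg.pinv(X[ok]) @ Y[ok, j]
            valid[j] = True
    if valid.sum() < 3:
        raise StructuralError("fewer than 3 valid arclength bins")

    # local-linear smoothing of the coefficient functions over valid bins
    L = local_linear_smoother(grid[valid], h)
    betas = np.full((p, m), np.nan)
    betas[:, valid] = b_raw[:, valid] @ L.T

    # residual curves and variance from the RAW per-bin fit: smoothing bias
    # of the coefficient curves must not inflate the noise estimate
    resid = Y - X @ np.nan_to_num(b_raw)
    resid[:, ~valid] = np.nan

    nv = (~np.isnan(Y)).sum(axis=0)
    v = np.nansum(resid ** 2, axis=0) / np.maximum(nv - p, 1)
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.clip(np.outer(np.diag(xtx_inv), v), 0, None))
    se[:, ~valid] = np.nan

    fit = VCMFit(grid=grid, covariate_names=["intercept"]
                 + list(spec.covariates), betas=betas, se=se,
                 residuals=resid, valid=valid, X=X, Y=Y,
                 smoother=L, spec=spec)
    _fpca(fit)
    return fit


def _fpca(fit: VCMFit) -> None:
    """Functional PCA of the residual curves (valid, complete bins)."""
    R = fit.residuals[:, fit.valid]
    R = np.nan_to_num(R)
    R = R - R.mean(axis=0, keepdims=True)
    if R.shape[0] < 2:
        return
    U, svals, Vt = np.linalg.svd(R, full_matrices=False)
    lam = svals ** 2 / max(R.shape[0] - 1, 1)
    if lam.sum() <= 0:
        fit.fpca_values = lam
        fit.fpca_components = Vt
        fit.fpca_var_explained = 1.0
        return
    frac = np.cumsum(lam) / lam.sum()
    k = int(np.searchsorted(frac, fit.spec.fpca_var) + 1)
    fit.fpca_values = lam[:k]
    fit.fpca_components = Vt[:k]
    fit.fpca_var_explained = float(frac[k - 1])


def _cov_index(fit: VCMFit, covariate: str) -> int:
    try:
        return fit.covariate_names.index(covariate)
    except ValueError:
        raise StructuralError(
            f"covariate {covariate!r} not in model "
            f"({fit.covariate_names})") from None


def _wald_curve(betas: np.ndarray, v: np.ndarray, xtx_inv_kk: float,
                k: int) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        return betas[k] ** 2 / (xtx_inv_kk * v)


def global_test(fit: VCMFit, covariate: str,
                spec: Optional[VCModelSpec] = None) -> float:
    """Wild-bootstrap p-value for the integrated Wald statistic.

    The null resamples residual curves from the reduced model (covariate
    removed) with subject-level Rademacher signs; p = (1 + #{resample >=
    observed}) / (1 + n_resamples).
    """
    spec = spec or fit.spec
    k = _cov_index(fit, covariate)
    X, Y, grid, valid, L = fit.X, fit.Y, fit.grid, fit.valid, fit.smoother
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    step = float(np.median(np.diff(grid)))

    def stat_for(Ymat: np.ndarray) -> np.ndarray:
        """Integrated Wald statistic; Ymat (..., n, m_valid)."""
        pinv = np.linalg.pinv(X)
        b_raw = pinv @ Ymat                        # (..., p, m_valid)
        b = b_raw @ L.T
        resid = Ymat - X @ b_raw
        v = (resid ** 2).sum(axis=-2) / max(n - p, 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            w = b[..., k, :] ** 2 / (xtx_inv[k, k] * v)
        return np.nan_to_num(w).sum(axis=-1) * step

    Yv = fit.Y[:, valid].copy()
    if np.isnan(Yv).any():
        # impute rare missing cells with the per-bin mean so the resampling
        # algebra stays dense
        col_mean = np.nanmean(Yv, axis=0)
        nan_r, nan_c = np.where(np.isnan(Yv))
        Yv[nan_r, nan_c] = col_mean[nan_c]
    observed = float(stat_for(Yv))

    # reduced (null) model fit
    keep = [j for j in range(p) if j != k]
    X0 = X[:, keep]
    b0 = np.linalg.pinv(X0) @ Yv @ L.T
    null_fit = X0 @ b0
    e0 = Yv - null_fit

    rng = np.random.default_rng(spec.seed)
    signs = rng.choice([-1.0, 1.0], size=(spec.n_resamples, n))
    Ystar = null_fit[np.newaxis] + signs[:, :, np.newaxis] * e0[np.newaxis]
    stats_star = stat_for(Ystar)
    p_val = (1.0 + float((stats_star >= observed).sum())) \
        / (1.0 + spec.n_resamples)
    return p_val


def local_test_fdr(fit: VCMFit, covariate: str,
                   spec: Optional[VCModelSpec] = None) -> StatResult:
    """Pointwise Wald tests with Benjamini-Hochberg correction.

    ``p_global`` in the result is NaN; run :func:`global_test` for it.
    """
    spec = spec or fit.spec
    k = _cov_index(fit, covariate)
    valid = fit.valid
    with np.errstate(invalid="ignore", divide="ignore"):
        z = fit.betas[k] / fit.se[k]
    # exact fit (zero residual variance): no evidence against zero unless
    # the coefficient itself is nonzero
    degenerate = fit.se[k] < 1e-12
    z = np.where(degenerate,
                 np.where(np.abs(fit.betas[k]) < 1e-10, 0.0, np.inf), z)
    p_raw = np.full(len(fit.grid), np.nan)
    p_raw[valid] = sps.chi2.sf(z[valid] ** 2, df=1)
    p_fdr = np.full_like(p_raw, np.nan)
    rej = np.zeros(len(p_raw), dtype=bool)
    if valid.any():
        rej_v, p_corr, _, _ = multipletests(p_raw[valid], alpha=spec.fdr_q,
                                            method="fdr_bh")
        p_fdr[valid] = p_corr
        rej[valid] = rej_v
    return StatResult(grid=fit.grid, covariate=covariate, beta=fit.betas[k],
                      se=fit.se[k], p_raw=p_raw, p_fdr=p_fdr,
                      significant=rej, p_global=np.nan)


def run_stats(profiles: pd.DataFrame, covariates: pd.DataFrame,
              spec: VCModelSpec) -> Dict[str, StatResult]:
    """Fit, then local + global tests for every named covariate."""
    fit = fit_vcm(profiles, covariates, spec)
    out = {}
    for name in spec.covariates:
        res = local_test_fdr(fit, name, spec)
        res.p_global = global_test(fit, name, spec)
        out[name] = res
    return out


def export_stats_csv(results: Dict[str, StatResult]) -> pd.DataFrame:
    """Arclength-first table: beta_<cov>, p_<cov>, pFDR_<cov> per covariate."""
    if not results:
        raise StructuralError("no results to export")
    first = next(iter(results.values()))
    data = {ARCLENGTH_COLUMN: first.grid}
    for name, res in results.items():
        data[f"beta_{name}"] = res.beta
        data[f"p_{name}"] = res.p_raw
        data[f"pFDR_{name}"] = res.p_fdr
    return pd.DataFrame(data)
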