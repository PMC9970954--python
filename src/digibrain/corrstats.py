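"""Confounder-adjusted Spearman correlation with FDR control.

Digital and clinical measures may be confounded by age, sex, and body mass
index.  Each variable is therefore residualized on the three confounders
with a robust linear model (iteratively reweighted least squares, Huber
weighting, c = 1.345) before rank correlation, and Benjamini–Hochberg
false-discovery-rate control is applied either separately per measure
(36 tests per family, the primary configuration) or globally over the full
36 × 21 grid (the conservative configuration).  Significance is q < 0.05.

The supporting analytic power calculation uses the Fisher z-transform
normal approximation for a correlation test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

Q_SIGNIFICANT = 0.05


@dataclass(frozen=True)
class FdrFamilySpec:
    """How the measure × region grid is partitioned into BH families."""

    mode: str = "per_measure"  # "per_measure" | "global_36x21"

    def __post_init__(self):
        if self.mode not in ("per_measure", "global_36x21"):
            raise ValueError(f"unknown FDR family mode {self.mode!r}")


def residualize(y: np.ndarray, covariates: pd.DataFrame | np.ndarray | None,
                max_iter: int = 50, tol: float = 1e-8) -> np.ndarray:
    """Residuals of ``y`` after a robust linear fit on the covariates.

    Fits an intercept plus the covariate columns by IRLS with Huber
    weighting (tuning constant 1.345) and returns ``y`` minus the fit.
    With no covariates this is simply centering on the robust location
    estimate.  Raises on rank-deficient designs, naming a collinear column.
    """
    y = np.asarray(y, float)
    if covariates is None or (hasattr(covariates, "shape")
                              and np.size(covariates) == 0):
        X = np.ones((len(y), 1))
        names = ["const"]
    else:
        C = pd.DataFrame(covariates)
        names = ["const"] + [str(c) for c in C.columns]
        X = np.column_stack([np.ones(len(y)), C.to_numpy(float)])
    if len(y) < X.shape[1] + 2:
        raise ValueError("too few observations for residualization")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        for j in range(X.shape[1] - 1, 0, -1):
            keep = [k for k in range(X.shape[1]) if k != j]
            if np.linalg.matrix_rank(X[:, keep]) == np.linalg.matrix_rank(X):
                raise ValueError(f"collinear covariate column: {names[j]}")
        raise ValueError("rank-deficient covariate design")
    model = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=1.345))
    fit = model.fit(maxiter=max_iter, tol=tol, conv="coefs")
    return y - fit.fittedvalues


def _spearman_t_p(r: float, n: int, k: int) -> float:
    """Two-sided p for Spearman's r via the t-approximation.

    The degrees of freedom are reduced by the ``k`` covariates consumed by
    residualization (df = n - 2 - k), as in standard partial-correlation
    inference; with k = 0 this is the usual Spearman t-approximation.
    """
    df = n - 2 - k
    if df <= 0 or abs(r) >= 1:
        return 0.0 if abs(r) >= 1 else np.nan
    t = r * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df))


def adjusted_spearman(x, y, covariates=None) -> tuple[float, float, int]:
    """Spearman correlation of confounder-residualized x and y.

    Both vectors are residualized on the covariates with the robust linear
    model, then rank-correlated (average ranks for ties); the two-sided p
    comes from the t-approximation for Spearman's coefficient with the
    degrees of freedom reduced by the number of covariates.  Pairs with
    a missing value in x, y, or any covariate are dropped first
    (pairwise-complete).  Returns ``(r, p, n)``; r and p are NaN (with a
    warning) when a residual vector is constant.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    C = None if covariates is None else pd.DataFrame(covariates)
    mask = np.isfinite(x) & np.isfinite(y)
    if C is not None:
        mask &= np.isfinite(C.to_numpy(float)).all(axis=1)
    n = int(mask.sum())
    if n < 10:
        raise ValueError(f"pairwise-complete n = {n} < 10")
    Cm = None if C is None else C.loc[mask]
    rx = residualize(x[mask], Cm)
    ry = residualize(y[mask], Cm)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        warnings.warn("constant residual vector; correlation undefined")
        return np.nan, np.nan, n
    r = float(stats.spearmanr(rx, ry).statistic)
    k = 0 if C is None else C.shape[1]
    return r, _spearman_t_p(r, n, k), n


def fdr_adjust(pvalues, method: str = "fdr_bh") -> np.ndarray:
    """Benjamini–Hochberg step-up q-values for one family of tests."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) & np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method=method)[1]
    return q


def correlation_grid(measures: pd.DataFrame, regions: pd.DataFrame,
                     covariates: pd.DataFrame | None = None,
                     family: FdrFamilySpec | None = None) -> pd.DataFrame:
    """Adjusted Spearman correlation of every measure against every region.

    Parameters
    ----------
    measures, regions : DataFrame indexed by subject_id
        Aggregated measure and regional MRI tables.
    covariates : DataFrame indexed by subject_id, optional
        age / sex (0=F, 1=M) / BMI confounders.
    family : FdrFamilySpec
        BH family layout; default per-measure (36 tests each).

    Returns
    -------
    DataFrame with one row per measure × region pair: columns
    measure, region, r, p, q, n, significant (q < 0.05).
    """
    family = family or FdrFamilySpec()
    shared = measures.index.intersection(regions.index)
    if covariates is not None:
        shared = shared.intersection(covariates.index)
    if len(shared) == 0:
        raise ValueError("no overlapping subjects between tables")
    M = measures.loc[shared]
    R = regions.loc[shared]
    C = None if covariates is None else covariates.loc[shared]

    complete = not (M.isna().to_numpy().any() or R.isna().to_numpy().any()
                    or (C is not None and C.isna().to_numpy().any()))
    rows = []
    if complete and len(shared) >= 10:
        # no missing cells: per-pair pairwise-complete residualization is
        # identical to residualizing each column once
        resM = {m: residualize(M[m].to_numpy(float), C) for m in M.columns}
        resR = {g: residualize(R[g].to_numpy(float), C) for g in R.columns}
        n = len(shared)
        k = 0 if C is None else C.shape[1]
        for m in M.columns:
            for g in R.columns:
                if np.ptp(resM[m]) == 0 or np.ptp(resR[g]) == 0:
                    r = p = np.nan
                else:
                    r = float(stats.spearmanr(resM[m], resR[g]).statistic)
                    p = _spearman_t_p(r, n, k)
                rows.append({"measure": m, "region": g, "r": r,
                             "p": p, "n": n})
    else:
        for m in M.columns:
            for g in R.columns:
                try:
                    r, p, n = adjusted_spearman(M[m], R[g], C)
                except ValueError:
                    r, p, n = np.nan, np.nan, 0
                rows.append({"measure": m, "region": g, "r": r, "p": p, "n": n})
    grid = pd.DataFrame(rows)
    grid["q"] = np.nan
    if family.mode == "per_measure":
        for m in M.columns:
            sel = grid["measure"] == m
            grid.loc[sel, "q"] = fdr_adjust(grid.loc[sel, "p"].to_numpy())
    else:
        grid["q"] = fdr_adjust(grid["p"].to_numpy())
    grid["significant"] = grid["q"] < Q_SIGNIFICANT
    return grid


def power_for_correlation(rho: float, n: int, alpha: float = 0.05) -> float:
    """Analytic power to detect a correlation ``rho`` at sample size ``n``.

    Uses the Fisher z-transform normal approximation for a two-sided test:
    with δ = √(n−3)·atanh(ρ) and z = Φ⁻¹(1−α/2), power = Φ(δ−z) + Φ(−δ−z)
    (both rejection tails).  At ρ = 0 this returns α.
    """
    if abs(rho) >= 1:
        raise ValueError("|rho| must be < 1")
    if n < 4:
        raise ValueError("n must be >= 4")
    delta = np.sqrt(n - 3) * np.arctanh(rho)
    z = stats.norm.ppf(1 - alpha / 2)
    return float(stats.norm.cdf(delta - z) + stats.norm.cdf(-delta - z))
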