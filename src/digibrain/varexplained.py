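"""Variance in each measure explainable from volumetric MRI.

Two Bayesian ridge regression models predict each (digital or clinical)
measure, and their leave-one-out cross-validated R² scores are contrasted:

* **Whole Brain** — normalized total brain volume plus age, sex, and BMI;
* **Parcellation** — all 36 regional MRI outcomes plus age, sex, and BMI.

A measure driven by a localized anatomical signal gains R² when moving
from the Whole Brain to the Parcellation model; a globally driven measure
does not.  The Bayesian ridge places a zero-mean isotropic Gaussian prior
on the weights with the weight and noise precisions estimated by evidence
(marginal-likelihood) maximization; predictors are standardized internally
and coefficients are reported on the standardized scale.  Negative LOO R²
values are floored at 0 by default (``signed=True`` disables the floor).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import BayesianRidge

from .regions import REGION_NAMES, TOTAL_BRAIN_VOLUME

_COVARIATE_COLS = ("age", "sex", "bmi")


@dataclass
class RidgeFit:
    """A fitted Bayesian ridge: standardized weights and precisions."""

    weights: pd.Series          # per (retained) predictor, standardized scale
    intercept: float
    noise_precision: float      # β: 1/σ² of the Gaussian likelihood
    weight_precision: float     # α of the isotropic Gaussian weight prior
    n_iter: int
    converged: bool
    dropped: list[str] = field(default_factory=list)
    _scale: tuple[np.ndarray, np.ndarray] | None = None
    _model: BayesianRidge | None = None

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        X = pd.DataFrame(X)
        X = X[[c for c in X.columns if str(c) not in self.dropped]]
        mu, sd = self._scale
        return self._model.predict((X.to_numpy(float) - mu) / sd)


def fit_bayesian_ridge(X: pd.DataFrame | np.ndarray, y,
                       max_iter: int = 300, tol: float = 1e-6) -> RidgeFit:
    """Fit a Bayesian ridge regression with evidence maximization.

    Precisions are estimated by fixed-point iteration until the relative
    coefficient change falls below ``tol`` or ``max_iter`` is reached.
    Constant predictor columns are dropped with a warning; a constant
    response is an error.  Requires complete data and n ≥ 5.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, float)
    if len(y) < 5:
        raise ValueError("need n >= 5 observations")
    if np.isnan(y).any() or X.isna().to_numpy().any():
        raise ValueError("missing cells are not supported; complete cases only")
    if np.ptp(y) == 0:
        raise ValueError("constant response")
    sd_all = X.to_numpy(float).std(axis=0)
    dropped = [str(c) for c, s in zip(X.columns, sd_all) if s == 0]
    if dropped:
        warnings.warn(f"dropping constant predictor column(s): {dropped}")
        X = X[[c for c in X.columns if str(c) not in dropped]]
    Xv = X.to_numpy(float)
    mu, sd = Xv.mean(axis=0), Xv.std(axis=0)
    Z = (Xv - mu) / sd
    model = BayesianRidge(max_iter=max_iter, tol=tol, fit_intercept=True)
    model.fit(Z, y)
    return RidgeFit(
        weights=pd.Series(model.coef_, index=[str(c) for c in X.columns]),
        intercept=float(model.intercept_),
        noise_precision=float(model.alpha_),
        weight_precision=float(model.lambda_),
        n_iter=int(model.n_iter_),
        converged=bool(model.n_iter_ < max_iter),
        dropped=dropped, _scale=(mu, sd), _model=model)


def loo_r2(X: pd.DataFrame | np.ndarray, y, signed: bool = False,
           max_iter: int = 300, tol: float = 1e-6) -> float:
    """Leave-one-out cross-validated R² of a Bayesian ridge model.

    For each subject i the model is refit on the remaining n−1 (with
    predictor standardization recomputed inside the fold) and yᵢ is
    predicted; R² = 1 − Σ(yᵢ−ŷ₋ᵢ)² / Σ(yᵢ−ȳ)².  Negative values are
    reported as 0 unless ``signed`` is set.
    """
    X = pd.DataFrame(X).reset_index(drop=True)
    y = np.asarray(y, float)
    n = len(y)
    if n < 10:
        raise ValueError("need n >= 10 for leave-one-out estimation")
    if np.ptp(y) == 0:
        raise ValueError("constant response")
    preds = np.empty(n)
    idx = np.arange(n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n):
            train = idx != i
            fit = fit_bayesian_ridge(X.loc[train], y[train],
                                     max_iter=max_iter, tol=tol)
            preds[i] = fit.predict(X.loc[[i]])[0]
    r2 = 1.0 - np.sum((y - preds) ** 2) / np.sum((y - y.mean()) ** 2)
    return float(r2) if signed else float(max(r2, 0.0))


@dataclass
class VarianceReport:
    measure: str
    r2_whole_brain: float
    r2_parcellation: float
    coefficients: pd.Series   # Parcellation-model standardized weights
    n: int


def whole_brain_vs_parcellation(measures: pd.DataFrame, regions: pd.DataFrame,
                                covariates: pd.DataFrame,
                                signed: bool = False) -> list[VarianceReport]:
    """Per-measure LOO R² under the Whole Brain and Parcellation models.

    ``regions`` must contain the 36 regional columns and the normalized
    total brain volume column; demographics (age, sex, BMI) enter both
    models.  Complete-case analysis per measure; requires ≥ 20 subjects.
    """
    missing = [c for c in (*REGION_NAMES, TOTAL_BRAIN_VOLUME)
               if c not in regions.columns]
    if missing:
        raise ValueError(f"missing region columns: {missing}")
    shared = measures.index.intersection(regions.index).intersection(covariates.index)
    base = regions.loc[shared].join(covariates.loc[shared][list(_COVARIATE_COLS)])

    reports = []
    for m in measures.columns:
        y_all = measures.loc[shared, m]
        cc = y_all.notna() & base.notna().all(axis=1)
        if cc.sum() < 20:
            raise ValueError(f"fewer than 20 complete cases for {m}")
        y = y_all[cc].to_numpy(float)
        Xwb = base.loc[cc, [TOTAL_BRAIN_VOLUME, *_COVARIATE_COLS]]
        Xparc = base.loc[cc, [*REGION_NAMES, *_COVARIATE_COLS]]
        r2_wb = loo_r2(Xwb, y, signed=signed)
        r2_parc = loo_r2(Xparc, y, signed=signed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coef = fit_bayesian_ridge(Xparc, y).weights.loc[list(REGION_NAMES)]
        reports.append(VarianceReport(str(m), r2_wb, r2_parc, coef, int(cc.sum())))
    return reports


def variance_report_frame(reports: list[VarianceReport]) -> pd.DataFrame:
    """Tabulate a list of per-measure variance reports."""
    return pd.DataFrame([{"measure": r.measure,
                          "r2_whole_brain": r.r2_whole_brain,
                          "r2_parcellation": r.r2_parcellation,
                          "n": r.n} for r in reports])
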