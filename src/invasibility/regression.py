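"""OLS and logistic regressions of invasion outcomes, with AIC model search.

Fits are delegated to statsmodels (closed-form least squares; IRLS for the
binomial family) behind a small ``RegressionResult`` container. Model
comparison ranks every non-empty subset of {SR, MPD, ND, RFD} plus the
intercept-only model by AIC, with predictors z-scored by default so
coefficient magnitudes are comparable across variables; the best univariate
model is reported alongside the best overall. Complete separation in
logistic fits is detected and flagged instead of reporting divergent
coefficients. No multiple-testing correction is applied.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

__all__ = [
    "RegressionResult",
    "ModelComparison",
    "fit_ols",
    "fit_logistic",
    "compare_models",
    "simulate_predictor_response",
]

_IRLS_TOL = 1e-8


@dataclass
class RegressionResult:
    """Estimates and diagnostics of one fitted regression."""

    family: str  # "gaussian" | "binomial"
    response: str
    predictors: list[str]
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    llf: float
    aic: float
    df_resid: float
    nobs: int
    rsquared: float | None = None
    f_pvalue: float | None = None
    separation: bool = False
    converged: bool = True

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.params, "se": self.bse, "p": self.pvalues}
        )


def _design_matrix(X: pd.DataFrame | np.ndarray, predictors: Sequence[str] | None):
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        mat = X.to_numpy(dtype=float)
    else:
        mat = np.asarray(X, dtype=float)
        if mat.ndim == 1:
            mat = mat[:, None]
        names = list(predictors) if predictors else [f"x{i+1}" for i in range(mat.shape[1])]
    exog = sm.add_constant(mat, has_constant="add")
    return exog, ["const"] + names


def _check_rank(exog: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        # identify columns that are linearly dependent on the preceding ones
        bad = []
        for j in range(1, exog.shape[1]):
            if np.linalg.matrix_rank(exog[:, : j + 1]) <= np.linalg.matrix_rank(exog[:, :j]):
                bad.append(names[j])
        raise ValueError(f"rank-deficient design matrix; collinear columns: {bad}")


def fit_ols(
    y: Sequence[float],
    X: pd.DataFrame | np.ndarray,
    predictors: Sequence[str] | None = None,
    response: str = "y",
) -> RegressionResult:
    """Ordinary least squares with an intercept added automatically."""
    y = np.asarray(y, dtype=float)
    exog, names = _design_matrix(X, predictors)
    if len(y) <= exog.shape[1]:
        raise ValueError("need more observations than coefficients")
    _check_rank(exog, names)
    res = sm.OLS(y, exog).fit()
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rsq = float(res.rsquared)
    if not np.isfinite(rsq):  # constant response: zero explained, zero total
        rsq = 0.0
    return RegressionResult(
        family="gaussian",
        response=response,
        predictors=names[1:],
        params=pd.Series(res.params, index=names),
        bse=pd.Series(res.bse, index=names),
        pvalues=pd.Series(res.pvalues, index=names),
        llf=float(res.llf),
        aic=float(res.aic),
        df_resid=float(res.df_resid),
        nobs=int(res.nobs),
        rsquared=rsq,
        f_pvalue=float(res.f_pvalue) if exog.shape[1] > 1 else None,
    )


def _looks_separated(y: np.ndarray, fitted: np.ndarray, params: np.ndarray) -> bool:
    eps = 1e-6
    perfect = np.all((fitted > 1 - eps) == (y == 1)) and np.all(
        (fitted < eps) == (y == 0)
    )
    return perfect or bool(np.any(np.abs(params) > 1e2))


def fit_logistic(
    y: Sequence[int],
    X: pd.DataFrame | np.ndarray | None = None,
    predictors: Sequence[str] | None = None,
    response: str = "y",
) -> RegressionResult:
    """Binomial GLM (logit link) fitted by IRLS; flags complete separation.

    ``X=None`` fits the intercept-only model. Complete separation yields a
    result with ``separation=True`` and NaN coefficients rather than the
    divergent estimates.
    """
    y = np.asarray(y, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("response must be binary (0/1)")
    if len(np.unique(y)) < 2:
        raise ValueError("response has a single class; logistic fit undefined")
    if X is None:
        exog = np.ones((len(y), 1))
        names = ["const"]
    else:
        exog, names = _design_matrix(X, predictors)
        _check_rank(exog, names)

    model = sm.GLM(y, exog, family=sm.families.Binomial())
    separated = False
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            res = model.fit(tol=_IRLS_TOL, maxiter=200)
        except (PerfectSeparationError, PerfectSeparationWarning):
            separated = True
            res = None
    if res is not None and _looks_separated(y, res.fittedvalues, res.params):
        separated = True
    if separated:
        nan = pd.Series(np.nan, index=names)
        return RegressionResult(
            family="binomial",
            response=response,
            predictors=names[1:],
            params=nan,
            bse=nan.copy(),
            pvalues=nan.copy(),
            llf=float("nan"),
            aic=float("nan"),
            df_resid=float(len(y) - len(names)),
            nobs=int(len(y)),
            separation=True,
            converged=False,
        )
    return RegressionResult(
        family="binomial",
        response=response,
        predictors=names[1:],
        params=pd.Series(res.params, index=names),
        bse=pd.Series(res.bse, index=names),
        pvalues=pd.Series(res.pvalues, index=names),
        llf=float(res.llf),
        aic=float(res.aic),
        df_resid=float(res.df_resid),
        nobs=int(res.nobs),
        converged=bool(res.converged),
    )


@dataclass
class ModelComparison:
    """AIC ranking of all predictor subsets for one response."""

    response: str
    family: str
    table: pd.DataFrame  # columns: predictors, k, aic, delta_aic, failed
    results: dict[tuple[str, ...], RegressionResult] = field(default_factory=dict)

    @property
    def best(self) -> tuple[str, ...]:
        ok = self.table[~self.table["failed"]]
        return tuple(ok.iloc[0]["predictors"])

    @property
    def best_univariate(self) -> str:
        uni = self.table[(self.table["k"] == 1) & (~self.table["failed"])]
        if uni.empty:
            raise ValueError("no successful univariate fit")
        return uni.sort_values("aic").iloc[0]["predictors"][0]


def compare_models(
    data: pd.DataFrame,
    response: str,
    predictors: Sequence[str] = ("SR", "MPD", "ND", "RFD"),
    family: str = "gaussian",
    zscore: bool = True,
) -> ModelComparison:
    """Fit every non-empty predictor subset plus intercept-only, rank by AIC.

    Rows with missing values in the response or any candidate predictor are
    dropped once, so all models see the same observations. Individual fit
    failures (including flagged separation) are recorded per row, not fatal.
    """
    if family not in ("gaussian", "binomial"):
        raise ValueError("family must be 'gaussian' or 'binomial'")
    cols = [response, *predictors]
    df = data[cols].dropna().reset_index(drop=True)
    if df.empty:
        raise ValueError("no complete observations")
    Xall = df[list(predictors)].astype(float)
    if zscore:
        sd = Xall.std(ddof=0).replace(0, 1.0)
        Xall = (Xall - Xall.mean()) / sd
    y = df[response].to_numpy(dtype=float)

    subsets: list[tuple[str, ...]] = [()]
    for k in range(1, len(predictors) + 1):
        subsets.extend(itertools.combinations(predictors, k))

    rows, results = [], {}
    for subset in subsets:
        try:
            if family == "gaussian":
                res = fit_ols(
                    y,
                    Xall[list(subset)] if subset else np.empty((len(y), 0)),
                    response=response,
                ) if subset else _intercept_only_ols(y, response)
            else:
                res = fit_logistic(
                    y, Xall[list(subset)] if subset else None, response=response
                )
            failed = bool(res.separation) or not np.isfinite(res.aic)
            results[subset] = res
            rows.append((subset, len(subset), res.aic, failed, ""))
        except Exception as exc:  # recorded, not fatal
            rows.append((subset, len(subset), float("nan"), True, str(exc)))
    table = pd.DataFrame(rows, columns=["predictors", "k", "aic", "failed", "error"])
    best_aic = table.loc[~table["failed"], "aic"].min()
    table["delta_aic"] = table["aic"] - best_aic
    table = table.sort_values("aic", na_position="last").reset_index(drop=True)
    return ModelComparison(response=response, family=family, table=table, results=results)


def _intercept_only_ols(y: np.ndarray, response: str) -> RegressionResult:
    res = sm.OLS(y, np.ones((len(y), 1))).fit()
    return RegressionResult(
        family="gaussian",
        response=response,
        predictors=[],
        params=pd.Series(res.params, index=["const"]),
        bse=pd.Series(res.bse, index=["const"]),
        pvalues=pd.Series(res.pvalues, index=["const"]),
        llf=float(res.llf),
        aic=float(res.aic),
        df_resid=float(res.df_resid),
        nobs=int(res.nobs),
        rsquared=float(res.rsquared),
    )


def simulate_predictor_response(
    n: int,
    effect_on: str,
    family: str,
    beta: float = 3.0,
    intercept: float = -0.5,
    noise_sd: float = 1.0,
    predictor_corr: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic outcome table driven by a single predictor.

    Generates SR (binary 1/2), and jointly normal MPD/ND/RFD with pairwise
    correlation ``predictor_corr``, then draws the response from ``effect_on``
    alone: Bernoulli(logit^-1(intercept + beta*z)) for the binomial family,
    intercept + beta*z + N(0, noise_sd) for the gaussian. Used for the
    model-selection recovery checks.
    """
    if effect_on not in ("SR", "MPD", "ND", "RFD"):
        raise ValueError("effect_on must be one of SR, MPD, ND, RFD")
    rng = np.random.default_rng(seed)
    cov = np.full((3, 3), predictor_corr)
    np.fill_diagonal(cov, 1.0)
    mpd_nd_rfd = rng.multivariate_normal(np.zeros(3), cov, size=n)
    df = pd.DataFrame(mpd_nd_rfd, columns=["MPD", "ND", "RFD"])
    df.insert(0, "SR", rng.integers(1, 3, size=n))
    z = df[effect_on].to_numpy(dtype=float)
    z = (z - z.mean()) / z.std()
    eta = intercept + beta * z
    if family == "binomial":
        df["y"] = rng.binomial(1, 1.0 / (1.0 + np.exp(-eta)))
    elif family == "gaussian":
        df["y"] = eta + rng.normal(0.0, noise_sd, size=n)
    else:
        raise ValueError("family must be 'gaussian' or 'binomial'")
    return df
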