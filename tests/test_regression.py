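"""Regression fits against closed-form oracles, and AIC model comparison."""

import numpy as np
import pandas as pd
import pytest

from invasibility.regression import (
    compare_models,
    fit_logistic,
    fit_ols,
    simulate_predictor_response,
)


def test_ols_exact_line():
    x = np.arange(10, dtype=float)
    res = fit_ols(2.0 * x, x[:, None], predictors=["x"])
    assert res.params["x"] == pytest.approx(2.0)
    assert res.params["const"] == pytest.approx(0.0, abs=1e-12)
    assert res.rsquared == pytest.approx(1.0)


def test_ols_constant_response():
    x = np.arange(10, dtype=float)
    res = fit_ols(np.full(10, 3.0), x[:, None], predictors=["x"])
    assert res.params["x"] == pytest.approx(0.0, abs=1e-12)
    assert res.rsquared == pytest.approx(0.0, abs=1e-12)


def test_ols_matches_normal_equations_oracle():
    # independent oracle: beta = (X'X)^-1 X'y assembled by hand
    rng = np.random.default_rng(50)
    X = rng.normal(size=(50, 3))
    y = rng.normal(size=50)
    res = fit_ols(y, X, predictors=["a", "b", "c"])
    Xc = np.column_stack([np.ones(50), X])
    beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ y)
    assert np.allclose(res.params.to_numpy(), beta, atol=1e-10)
    resid = y - Xc @ beta
    sigma2 = resid @ resid / (50 - 4)
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(Xc.T @ Xc)))
    assert np.allclose(res.bse.to_numpy(), se, atol=1e-10)


def test_ols_rank_deficiency_names_columns():
    X = pd.DataFrame({"a": np.arange(10.0), "b": 2.0 * np.arange(10.0)})
    with pytest.raises(ValueError, match="b"):
        fit_ols(np.random.default_rng(0).normal(size=10), X)


def test_logistic_intercept_only_closed_form():
    # MLE of a proportion: intercept = logit(37/108) = ln(37/71)
    y = np.array([1] * 37 + [0] * 71)
    res = fit_logistic(y)
    assert res.params["const"] == pytest.approx(np.log(37 / 71), abs=1e-6)


def test_logistic_separation_flagged():
    x = np.arange(10, dtype=float)
    y = (x >= 5).astype(float)
    res = fit_logistic(y, x[:, None], predictors=["x"])
    assert res.separation
    assert res.params.isna().all()


def test_logistic_rejects_degenerate_response():
    with pytest.raises(ValueError):
        fit_logistic(np.ones(10), np.arange(10.0)[:, None])
    with pytest.raises(ValueError):
        fit_logistic(np.array([0, 1, 2]), np.arange(3.0)[:, None])


def test_logistic_null_calibration():
    # y independent of x: the Wald p-value exceeds 0.05 in >= 90% of seeds
    calm = 0
    n_seeds = 100
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=200)
        y = rng.binomial(1, 0.4, size=200)
        res = fit_logistic(y, x[:, None], predictors=["x"])
        if res.separation or res.pvalues["x"] >= 0.05:
            calm += 1
    assert calm >= 90


def test_noise_predictor_raises_aic_on_average():
    rng = np.random.default_rng(77)
    deltas = []
    for _ in range(50):
        x = rng.normal(size=(80, 2))
        y = 1.5 * x[:, 0] + rng.normal(size=80)
        full = fit_ols(y, x, predictors=["signal", "noise"])
        base = fit_ols(y, x[:, :1], predictors=["signal"])
        deltas.append(full.aic - base.aic)
    assert np.mean(deltas) > 0


@pytest.mark.parametrize("family,effect", [("binomial", "ND"), ("gaussian", "RFD")])
def test_compare_models_recovers_generating_predictor(family, effect):
    df = simulate_predictor_response(324, effect_on=effect, family=family, seed=4)
    comp = compare_models(df, "y", ("SR", "MPD", "ND", "RFD"), family=family)
    assert comp.best_univariate == effect
    # structure contract: intercept-only plus all 15 subsets, best delta = 0
    assert len(comp.table) == 16
    ok = comp.table[~comp.table["failed"]]
    assert ok.iloc[0]["delta_aic"] == pytest.approx(0.0)


def test_compare_models_null_prefers_small_models():
    wins = 0
    n_seeds = 30
    for seed in range(n_seeds):
        rng = np.random.default_rng(1000 + seed)
        df = pd.DataFrame(rng.normal(size=(60, 4)), columns=["SR", "MPD", "ND", "RFD"])
        df["y"] = rng.normal(size=60)
        comp = compare_models(df, "y", ("SR", "MPD", "ND", "RFD"), family="gaussian")
        row = comp.table[comp.table["k"] == 0]
        if float(row["delta_aic"].iloc[0]) <= 2.0:
            wins += 1
    assert wins > n_seeds / 2
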