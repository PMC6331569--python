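"""ND/RFD formulas, community aggregation, and the analytic LV oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from invasibility.coexistence import (
    analytic_nd_rfd_lv,
    community_predictors,
    niche_difference,
    pairwise_coexistence_table,
    relative_fitness_difference,
)
from invasibility.lv import InoculationEvent, simulate_lv


@pytest.mark.parametrize(
    "s1,s2,expected",
    [((0.25, 0.25), None, 0.75), ((1.0, 1.0), None, 0.0), ((0.04, 0.09), None, 0.94)],
)
def test_niche_difference_examples(s1, s2, expected):
    (a, b) = s1
    nd, flag = niche_difference(a, b)
    assert flag == ""
    assert nd == pytest.approx(expected)


@pytest.mark.parametrize(
    "s1,s2,expected", [((0.5, 0.5), None, 1.0), ((0.25, 1.0), None, 2.0), ((1.0, 0.25), None, 0.5)]
)
def test_rfd_examples(s1, s2, expected):
    a, b = s1
    rfd, flag = relative_fitness_difference(a, b)
    assert flag == ""
    assert rfd == pytest.approx(expected)


@given(s1=st.floats(1e-3, 3.0), s2=st.floats(1e-3, 3.0))
@settings(max_examples=200, derandomize=True)
def test_symmetry_properties(s1, s2):
    # ND symmetric under swapping the pair; RFD inverts; ND never exceeds 1
    nd_a, _ = niche_difference(s1, s2)
    nd_b, _ = niche_difference(s2, s1)
    assert nd_a == pytest.approx(nd_b)
    assert nd_a <= 1.0
    rfd_a, _ = relative_fitness_difference(s1, s2)
    rfd_b, _ = relative_fitness_difference(s2, s1)
    assert rfd_a * rfd_b == pytest.approx(1.0, rel=1e-9)
    assert rfd_a > 0


def test_nonpositive_sensitivities_flagged():
    nd, flag = niche_difference(-0.1, 0.5)
    assert np.isnan(nd) and flag == "nonpositive_sensitivity"
    table = pairwise_coexistence_table(
        pd.DataFrame({"invader": ["I"], "native": ["N"], "S1": [-0.1], "S2": [0.5]})
    )
    assert not table.loc[0, "valid"]


def test_analytic_oracle_examples(pair_params):
    p = pair_params(a_in=0.5, a_ni=0.5)
    o = analytic_nd_rfd_lv(p, "I", "N")
    assert o["ND"] == pytest.approx(0.5)
    assert o["RFD"] == pytest.approx(1.0)

    p = pair_params(a_in=0.2, a_ni=0.8)
    o = analytic_nd_rfd_lv(p, "I", "N")
    assert o["ND"] == pytest.approx(0.6)
    assert o["RFD"] == pytest.approx(2.0)

    p = pair_params(a_in=0.0, a_ni=0.0)
    o = analytic_nd_rfd_lv(p, "I", "N")
    assert o["ND"] == pytest.approx(1.0)
    assert np.isnan(o["RFD"])


def test_analytic_oracle_matches_numerical_invasion_rate(pair_params):
    # The oracle's S1 = alpha_IN K_N / K_I is checked against the growth rate
    # of a vanishing invader introduced into the resident's ODE equilibrium.
    p = pair_params(a_in=0.35, a_ni=0.7, K_I=1e9, K_N=1.6e9, r=0.45)
    o = analytic_nd_rfd_lv(p, "I", "N")
    tiny = 1.0  # CFU/mL, far below K so feedback is negligible
    traj = simulate_lv(
        p, {"N": 1e4}, [0.0, 200.0, 200.5],
        events=[InoculationEvent(200.0, "I", tiny)],
    )
    mu_num = (np.log(traj[2, 0]) - np.log(tiny)) / 0.5
    mu_lin = p.r[0] * (1 - o["S1"])
    assert mu_num == pytest.approx(mu_lin, abs=1e-3)


def test_nd_monotone_in_alpha_product(pair_params):
    products, nds = [], []
    for a in np.linspace(0.1, 0.9, 9):
        o = analytic_nd_rfd_lv(pair_params(a_in=a, a_ni=a), "I", "N")
        products.append(a * a)
        nds.append(o["ND"])
    assert all(np.diff(nds) < 0)  # ND strictly decreases as overlap grows


def _pairwise_table():
    return pd.DataFrame(
        {
            "invader": ["I", "I"],
            "native": ["A", "B"],
            "S1": [0.5, 0.5],
            "S2": [0.5, 0.5],
            "ND": [0.2, 0.6],
            "RFD": [1.0, 2.0],
            "valid": [True, True],
            "flag": ["", ""],
        }
    )


def test_community_aggregation_mean():
    out = community_predictors(_pairwise_table(), "I", ["A"])
    assert out["mean_ND"] == pytest.approx(0.2)
    out = community_predictors(_pairwise_table(), "I", ["A", "B"])
    assert out["mean_ND"] == pytest.approx(0.4)
    assert out["mean_RFD"] == pytest.approx(1.5)


def test_community_aggregation_most_abundant_and_closest():
    table = _pairwise_table()
    out = community_predictors(
        table, "I", ["A", "B"], aggregation="most_abundant",
        abundances={"A": 1e5, "B": 1e7},
    )
    assert out["mean_ND"] == pytest.approx(0.6)
    pdm = pd.DataFrame(
        [[0, 3, 1], [3, 0, 2], [1, 2, 0]],
        index=["I", "A", "B"], columns=["I", "A", "B"], dtype=float,
    )
    out = community_predictors(table, "I", ["A", "B"], aggregation="closest", pd_matrix=pdm)
    assert out["mean_ND"] == pytest.approx(0.6)  # B is the closer native
    assert out["MPD"] == pytest.approx(1.0)  # PD to the chosen native only


def test_community_aggregation_errors():
    with pytest.raises(KeyError):
        community_predictors(_pairwise_table(), "I", ["A", "C"])
    with pytest.raises(ValueError):
        community_predictors(_pairwise_table(), "I", ["A"], aggregation="median")
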