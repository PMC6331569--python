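"""Growth rates and mutual-invasion sensitivities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from invasibility.growth import (
    GrowthRate,
    pairwise_sensitivities,
    per_capita_growth_rate,
    sensitivities_from_assays,
    sensitivity,
)
from invasibility.plating import DensityEstimate
from invasibility.simulate import simulate_mutual_invasion_assays


def dens(density, time, species="A", below=False):
    return DensityEstimate("M1", species, time, density, 1, below)


@pytest.mark.parametrize(
    "d6,d14,expected",
    [
        (1e4, 1e5, np.log(10) / 8),
        (1e5, 1e5, 0.0),
        (1e5, 1e4, -np.log(10) / 8),
    ],
)
def test_two_point_log_slope(d6, d14, expected):
    g = per_capita_growth_rate(dens(d6, 6.0), dens(d14, 14.0))
    assert g.valid
    assert g.mu == pytest.approx(expected)


def test_growth_rate_flags_below_detection():
    g = per_capita_growth_rate(dens(0.0, 6.0, below=True), dens(1e4, 14.0))
    assert not g.valid and np.isnan(g.mu)
    with pytest.raises(ValueError):
        per_capita_growth_rate(dens(1e4, 14.0), dens(1e5, 6.0))


@pytest.mark.parametrize(
    "mu_alone,mu_inv,expected",
    [(0.4, 0.1, 0.75), (0.4, 0.4, 0.0), (0.4, 0.0, 1.0), (0.4, -0.2, 1.5)],
)
def test_sensitivity_examples(mu_alone, mu_inv, expected):
    s, flag = sensitivity(
        GrowthRate("A", "alone", None, mu_alone),
        GrowthRate("A", "invading", "B", mu_inv),
    )
    assert flag == ""
    assert s == pytest.approx(expected)


def test_sensitivity_flags_nonpositive_alone_rate():
    s, flag = sensitivity(
        GrowthRate("A", "alone", None, -0.1),
        GrowthRate("A", "invading", "B", 0.1),
    )
    assert np.isnan(s) and flag == "nonpositive_mu_alone"


@given(
    mu_alone=st.floats(0.05, 2.0),
    mu_inv=st.floats(-1.0, 2.0),
    scale=st.floats(0.1, 10.0),
)
@settings(max_examples=100, derandomize=True)
def test_sensitivity_scale_invariant(mu_alone, mu_inv, scale):
    # rescaling both rates by the same positive constant leaves S unchanged
    s1, _ = sensitivity(
        GrowthRate("A", "alone", None, mu_alone),
        GrowthRate("A", "invading", "B", mu_inv),
    )
    s2, _ = sensitivity(
        GrowthRate("A", "alone", None, scale * mu_alone),
        GrowthRate("A", "invading", "B", scale * mu_inv),
    )
    assert s2 == pytest.approx(s1, rel=1e-9, abs=1e-12)


def _rates(invader, native, alone1, inv1, alone2, inv2):
    return {
        (invader, "alone"): [GrowthRate(invader, "alone", None, m) for m in alone1],
        (invader, "invading"): [GrowthRate(invader, "invading", native, m) for m in inv1],
        (native, "alone"): [GrowthRate(native, "alone", None, m) for m in alone2],
        (native, "invading"): [GrowthRate(native, "invading", invader, m) for m in inv2],
    }


def test_average_then_ratio_order_of_operations():
    # replicate rates are averaged per context before taking the ratio:
    # mean(0.3, 0.5) = 0.4, mean(0.1, 0.1) = 0.1 -> S1 = 0.75, which differs
    # from the ratio-then-average value mean(2/3, 0.8) ≈ 0.733
    pair = pairwise_sensitivities(
        "I", "N", _rates("I", "N", [0.3, 0.5], [0.1, 0.1], [0.4], [0.2])
    )
    assert pair.S1 == pytest.approx(0.75)
    assert pair.S2 == pytest.approx(0.5)
    assert pair.S1 != pytest.approx(np.mean([(0.3 - 0.1) / 0.3, (0.5 - 0.1) / 0.5]))


def test_missing_context_rejected():
    rates = _rates("I", "N", [0.3], [0.1], [0.4], [0.2])
    del rates[("N", "invading")]
    with pytest.raises(ValueError):
        pairwise_sensitivities("I", "N", rates)


def test_no_interaction_round_trip(pair_params):
    # alpha = 0 both ways: invading and alone trajectories coincide, S1=S2=0
    params = pair_params(a_in=0.0, a_ni=0.0)
    assay = simulate_mutual_invasion_assays(params, [("I", "N")], n_replicates=1)
    alone = assay[assay["context"] == "alone"].set_index(["focal", "time"])["density"]
    invading = assay[assay["context"] == "invading"].set_index(["focal", "time"])["density"]
    assert np.allclose(alone.sort_index(), invading.sort_index(), rtol=1e-6)
    sens = sensitivities_from_assays(assay)
    assert abs(sens.loc[0, "S1"]) < 0.02
    assert abs(sens.loc[0, "S2"]) < 0.02


def test_sensitivity_matches_linearization_on_grid(pair_params):
    # noise-free simulator: S1 ≈ alpha_IN * K_N / K_I within 0.05
    for a in (0.1, 0.5, 0.9):
        for kr in (0.5, 1.0, 2.0):
            params = pair_params(a_in=a, a_ni=0.4, K_I=1e9, K_N=kr * 1e9)
            assay = simulate_mutual_invasion_assays(params, [("I", "N")], n_replicates=1)
            sens = sensitivities_from_assays(assay)
            assert sens.loc[0, "S1"] == pytest.approx(a * kr, abs=0.05)


def test_full_niche_overlap_stops_invader_growth(pair_params):
    # alpha = 1 both ways, equal K: the resident fills the shared niche and
    # the invading growth rate is ~0, i.e. sensitivity ~1
    params = pair_params(a_in=1.0, a_ni=1.0)
    assay = simulate_mutual_invasion_assays(params, [("I", "N")], n_replicates=1)
    sens = sensitivities_from_assays(assay)
    assert sens.loc[0, "S1"] == pytest.approx(1.0, abs=0.02)
    assert sens.loc[0, "S2"] == pytest.approx(1.0, abs=0.02)
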