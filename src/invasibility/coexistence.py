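"""Niche differences and relative fitness differences from sensitivities.

From the mutual-invasion sensitivities S1 (invader to native) and S2 (native
to invader):

    ND  = 1 - sqrt(S1 * S2)      (one minus the geometric mean)
    RFD = sqrt(S2 / S1)          (geometric standard deviation)

ND measures how much more strongly each species limits itself than its
partner (ND = 1: independent niches; ND = 0: complete overlap; ND < 0:
priority effects). RFD measures the competitive-ability asymmetry; RFD > 1
means the invader has the fitness advantage, and RFD(S1,S2)·RFD(S2,S1) = 1.
Both require S1, S2 > 0; facilitation (negative sensitivity) renders them
undefined and such pairs are flagged and excluded downstream.

The module also carries the closed-form Lotka-Volterra oracle used to
validate the whole estimation pipeline: linearising the invasion growth rate
of species I at the resident N's single-species equilibrium K_N gives
mu_invading = r_I (1 - alpha_IN K_N / K_I), hence S1 = alpha_IN K_N / K_I,
S2 = alpha_NI K_I / K_N, ND = 1 - sqrt(alpha_IN alpha_NI) and
RFD = (K_I/K_N) sqrt(alpha_NI/alpha_IN).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .lv import LVParams

__all__ = [
    "PairwiseCoexistence",
    "niche_difference",
    "relative_fitness_difference",
    "pairwise_coexistence_table",
    "community_predictors",
    "analytic_nd_rfd_lv",
]

AGGREGATIONS = ("mean", "closest", "most_abundant")


@dataclass(frozen=True)
class PairwiseCoexistence:
    invader: str
    native: str
    ND: float
    RFD: float
    valid: bool
    flag: str = ""


def niche_difference(S1: float, S2: float) -> tuple[float, str]:
    """ND = 1 - sqrt(S1*S2); (value, flag). Undefined unless S1, S2 > 0."""
    if not (np.isfinite(S1) and np.isfinite(S2)):
        return float("nan"), "undefined_sensitivity"
    if S1 <= 0 or S2 <= 0:
        return float("nan"), "nonpositive_sensitivity"
    return float(1.0 - np.sqrt(S1 * S2)), ""


def relative_fitness_difference(S1: float, S2: float) -> tuple[float, str]:
    """RFD = sqrt(S2/S1); (value, flag). Undefined unless S1, S2 > 0."""
    if not (np.isfinite(S1) and np.isfinite(S2)):
        return float("nan"), "undefined_sensitivity"
    if S1 <= 0 or S2 <= 0:
        return float("nan"), "nonpositive_sensitivity"
    return float(np.sqrt(S2 / S1)), ""


def pairwise_coexistence_table(sensitivities: pd.DataFrame) -> pd.DataFrame:
    """ND/RFD per pair from a sensitivities table (invader, native, S1, S2).

    Pairs with flagged or non-positive sensitivities get ``valid = False``
    and NaN metrics; they are excluded from regressions downstream.
    """
    rows = []
    for row in sensitivities.itertuples(index=False):
        upstream = "" if getattr(row, "valid", True) else (getattr(row, "flag", "") or "invalid_sensitivity")
        nd, f1 = niche_difference(row.S1, row.S2)
        rfd, f2 = relative_fitness_difference(row.S1, row.S2)
        flags = ";".join(dict.fromkeys(x for x in (upstream, f1, f2) if x))
        rows.append(
            (row.invader, row.native, row.S1, row.S2, nd, rfd, not flags, flags)
        )
    return pd.DataFrame(
        rows, columns=["invader", "native", "S1", "S2", "ND", "RFD", "valid", "flag"]
    )


def community_predictors(
    pairwise: pd.DataFrame,
    invader: str,
    composition: Sequence[str],
    aggregation: str = "mean",
    abundances: dict[str, float] | None = None,
    pd_matrix: pd.DataFrame | None = None,
) -> dict:
    """Aggregate pairwise ND/RFD (and PD, if given) to the recipient community.

    ``mean`` (default) averages over the natives present; ``closest`` takes
    the native at minimal patristic distance from the invader (requires
    ``pd_matrix``); ``most_abundant`` takes the dominant native (requires
    ``abundances``). An invalid pair under ``mean`` propagates invalidity.
    """
    if aggregation not in AGGREGATIONS:
        raise ValueError(f"unknown aggregation {aggregation!r}; use {AGGREGATIONS}")
    composition = sorted(composition)
    sub = pairwise[
        (pairwise["invader"] == invader) & (pairwise["native"].isin(composition))
    ].set_index("native")
    missing = set(composition) - set(sub.index)
    if missing:
        raise KeyError(f"missing pairs for natives {sorted(missing)}")

    if aggregation == "closest":
        if pd_matrix is None:
            raise ValueError("closest aggregation requires a patristic distance matrix")
        chosen = [min(composition, key=lambda n: pd_matrix.loc[invader, n])]
    elif aggregation == "most_abundant":
        if abundances is None:
            raise ValueError("most_abundant aggregation requires native abundances")
        chosen = [max(composition, key=lambda n: abundances[n])]
    else:
        chosen = composition

    block = sub.loc[chosen]
    valid = bool(block["valid"].all())
    out = {
        "invader": invader,
        "native_composition": "+".join(composition),
        "richness": len(composition),
        "aggregation": aggregation,
        "mean_ND": float(block["ND"].mean()) if valid else float("nan"),
        "mean_RFD": float(block["RFD"].mean()) if valid else float("nan"),
        "valid": valid,
    }
    if pd_matrix is not None:
        out["MPD"] = float(
            np.mean([pd_matrix.loc[invader, n] for n in chosen])
        )
    return out


def analytic_nd_rfd_lv(
    params: LVParams, invader: str, native: str
) -> dict[str, float]:
    """Closed-form S1, S2, ND, RFD for a Lotka-Volterra pair.

    Derived by linearising each species' invasion growth rate at the other's
    single-species equilibrium. With zero competition both ways ND = 1 and
    RFD is undefined (returned as NaN).
    """
    i, n = params.index(invader), params.index(native)
    if i == n:
        raise ValueError("invader and native must differ")
    a_in = params.alpha[i, n]
    a_ni = params.alpha[n, i]
    ki, kn = params.K[i], params.K[n]
    s1 = a_in * kn / ki
    s2 = a_ni * ki / kn
    nd = 1.0 - np.sqrt(a_in * a_ni)
    rfd = (ki / kn) * np.sqrt(a_ni / a_in) if a_in > 0 else float("nan")
    return {"S1": float(s1), "S2": float(s2), "ND": float(nd), "RFD": float(rfd)}
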