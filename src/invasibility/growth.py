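"""Per-capita growth rates and mutual-invasion sensitivities.

With both assay samples taken in exponential phase, the per-capita growth
rate is the two-point log slope mu = (ln d2 - ln d1) / (t2 - t1). A species'
*sensitivity* to a resident is the proportional reduction of its growth rate
when invading the resident's steady-state culture relative to growing alone:

    S = (mu_alone - mu_invading) / mu_alone.

S = 0 means the resident does not affect the focal species, S = 1 means the
focal species stops growing entirely, S > 1 means it declines. Replicate
growth rates are averaged per context *before* the ratio is taken
(average-then-ratio, not ratio-then-average).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plating import DensityEstimate

__all__ = [
    "GrowthRate",
    "SensitivityPair",
    "per_capita_growth_rate",
    "sensitivity",
    "pairwise_sensitivities",
    "sensitivities_from_assays",
]


@dataclass(frozen=True)
class GrowthRate:
    species: str
    context: str  # "alone" | "invading"
    partner: str | None
    mu: float  # 1/h; nan when undefined
    valid: bool = True
    flag: str = ""


@dataclass(frozen=True)
class SensitivityPair:
    invader: str
    native: str
    S1: float  # invader's sensitivity to the native
    S2: float  # native's sensitivity to the invader
    valid: bool = True
    flag: str = ""


def per_capita_growth_rate(
    d_early: DensityEstimate, d_late: DensityEstimate, context: str = "alone",
    partner: str | None = None,
) -> GrowthRate:
    """Two-point log-slope growth rate between two density estimates."""
    if d_late.time <= d_early.time:
        raise ValueError("d_late must be sampled after d_early")
    if d_early.species != d_late.species:
        raise ValueError("density estimates are for different species")
    sp = d_early.species
    if (
        d_early.density <= 0
        or d_late.density <= 0
        or d_early.below_detection
        or d_late.below_detection
    ):
        return GrowthRate(sp, context, partner, float("nan"), False, "below_detection")
    mu = (np.log(d_late.density) - np.log(d_early.density)) / (
        d_late.time - d_early.time
    )
    return GrowthRate(sp, context, partner, float(mu))


def sensitivity(mu_alone: GrowthRate, mu_invading: GrowthRate) -> tuple[float, str]:
    """Sensitivity S = (mu_alone - mu_invading)/mu_alone; (value, flag)."""
    if mu_alone.species != mu_invading.species:
        raise ValueError("growth rates are for different focal species")
    if not (mu_alone.valid and mu_invading.valid):
        return float("nan"), "undefined_rate"
    if mu_alone.mu <= 0:
        return float("nan"), "nonpositive_mu_alone"
    return float((mu_alone.mu - mu_invading.mu) / mu_alone.mu), ""


def _mean_rate(rates: list[GrowthRate]) -> GrowthRate:
    valid = [g for g in rates if g.valid]
    if not valid:
        g = rates[0]
        return GrowthRate(g.species, g.context, g.partner, float("nan"), False,
                          "no_valid_replicates")
    g = valid[0]
    return GrowthRate(
        g.species, g.context, g.partner, float(np.mean([x.mu for x in valid]))
    )


def pairwise_sensitivities(
    invader: str,
    native: str,
    rates: dict[tuple[str, str], list[GrowthRate]],
) -> SensitivityPair:
    """Combine replicate growth rates into the pair's (S1, S2).

    ``rates`` maps (focal species, context) to replicate growth rates; all
    four contexts — each species alone and invading — must be present.
    Replicates are arithmetically averaged per context first, then S1 (the
    invader's sensitivity to the native) and S2 (the native's to the invader)
    are computed from the averaged rates.
    """
    needed = [(invader, "alone"), (invader, "invading"),
              (native, "alone"), (native, "invading")]
    for key in needed:
        if not rates.get(key):
            raise ValueError(f"no replicates for focal/context {key}")
    means = {key: _mean_rate(rates[key]) for key in needed}
    s1, f1 = sensitivity(means[(invader, "alone")], means[(invader, "invading")])
    s2, f2 = sensitivity(means[(native, "alone")], means[(native, "invading")])
    flags = ";".join(x for x in (f1, f2) if x)
    return SensitivityPair(invader, native, s1, s2, valid=not flags, flag=flags)


def sensitivities_from_assays(densities: pd.DataFrame) -> pd.DataFrame:
    """Sensitivities for every pair in a mutual-invasion density table.

    ``densities`` is the per-sample density table of the assays (true or
    plate-count-estimated), with columns ``invader, native, focal, context,
    replicate, time, density`` and exactly two times per replicate culture.

    Returns one row per (invader, native) pair with S1, S2 and flags.
    """
    out = []
    for (invader, native), grp in densities.groupby(["invader", "native"], sort=True):
        rates: dict[tuple[str, str], list[GrowthRate]] = {}
        for (focal, context, rep), g in grp.groupby(
            ["focal", "context", "replicate"], sort=True
        ):
            g = g.sort_values("time")
            if len(g) != 2:
                raise ValueError(
                    f"expected two assay times for {(invader, native, focal, context, rep)}, "
                    f"got {len(g)}"
                )
            pair_partner = native if focal == invader else invader
            early, late = (
                DensityEstimate(
                    microcosm_id=str(row.microcosm_id)
                    if "microcosm_id" in g.columns
                    else "",
                    species=focal,
                    time=float(row.time),
                    density=float(row.density),
                    n_dilutions_used=0,
                    below_detection=bool(getattr(row, "below_detection", False)),
                )
                for row in g.itertuples(index=False)
            )
            rates.setdefault((focal, context), []).append(
                per_capita_growth_rate(early, late, context, pair_partner)
            )
        pair = pairwise_sensitivities(invader, native, rates)
        out.append(
            (pair.invader, pair.native, pair.S1, pair.S2, pair.valid, pair.flag)
        )
    return pd.DataFrame(
        out, columns=["invader", "native", "S1", "S2", "valid", "flag"]
    )
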