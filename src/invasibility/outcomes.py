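"""Invasion success (establishment, abundance) and impact per microcosm.

Success at the final sampling is coded two ways: establishment (1 if the
invader's density is at or above the detection limit, else 0) and abundance
(ln(density + 1), evaluated only for established microcosms in the primary
analysis). Impact on the native community is the Euclidean distance between
the native species' density vectors in invaded versus control microcosms —
for a single native this is the absolute density difference. Control
densities are summarised as the mean over the control replicates of the same
composition.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .design import split_composition

__all__ = [
    "DEFAULT_DETECTION_LIMIT",
    "establishment",
    "invader_abundance",
    "impact",
    "aggregate_outcomes",
]

#: CFU/mL; the nominal floor of the lowest (1e2) dilution level.
DEFAULT_DETECTION_LIMIT = 1e2


def establishment(final_invader_density: float, detection_limit: float = DEFAULT_DETECTION_LIMIT) -> int:
    """1 if the invader persists at or above the detection limit, else 0."""
    if final_invader_density < 0:
        raise ValueError("density must be >= 0")
    return int(final_invader_density >= detection_limit)


def invader_abundance(final_invader_density: float) -> float:
    """ln(density + 1), density in CFU/mL."""
    if final_invader_density < 0:
        raise ValueError("density must be >= 0")
    return float(np.log(final_invader_density + 1.0))


def impact(
    invaded_native_densities: Sequence[float],
    control_native_densities: Sequence[float],
    log_scale: bool = False,
) -> float:
    """Euclidean norm of per-species native density changes under invasion.

    Vectors must list the same native species in the same order. With
    ``log_scale`` the differences are taken on ln(density + 1) instead of raw
    CFU/mL (the raw scale is the primary definition).
    """
    a = np.asarray(invaded_native_densities, dtype=float)
    b = np.asarray(control_native_densities, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("density vectors must be 1-D and the same length")
    if log_scale:
        a, b = np.log1p(a), np.log1p(b)
    return float(np.sqrt(np.sum((a - b) ** 2)))


def aggregate_outcomes(
    densities: pd.DataFrame,
    design: pd.DataFrame,
    detection_limit: float = DEFAULT_DETECTION_LIMIT,
    control_rule: str = "mean",
    log_scale_impact: bool = False,
) -> pd.DataFrame:
    """One outcome row per invaded microcosm from a final-density table.

    ``densities`` holds columns ``microcosm_id, species, time, density``
    (true or estimated); only each microcosm's final sample time is used.
    Control densities are averaged over the control replicates of the same
    composition (``control_rule='mean'``); ``'paired'`` matches invaded
    replicate k with control replicate k.

    Returns columns ``microcosm_id, invader, native_composition, richness,
    invader_density, established, abundance, impact``. Abundance is NaN for
    unestablished microcosms (the abundance analysis covers established
    invaders only).
    """
    if control_rule not in ("mean", "paired"):
        raise ValueError("control_rule must be 'mean' or 'paired'")
    dens = densities.set_index(["microcosm_id", "species", "time"])["density"]

    def final_density(mid: str, species: str, t: float) -> float:
        try:
            return float(dens.loc[(mid, species, t)])
        except KeyError:
            raise KeyError(
                f"no density for microcosm {mid}, species {species}, hour {t:g}"
            ) from None

    controls = design[design["treatment"] == "control"]
    invaded = design[design["treatment"] == "invaded"]

    # per-composition control density vectors at the final time
    control_vecs: dict[str, dict] = {}
    for comp, grp in controls.groupby("native_composition"):
        natives = split_composition(comp)
        per_rep = {}
        for row in grp.itertuples(index=False):
            t = float(str(row.sample_times).split(";")[-1])
            per_rep[row.replicate] = np.array(
                [final_density(row.microcosm_id, n, t) for n in natives]
            )
        control_vecs[comp] = {
            "natives": natives,
            "per_rep": per_rep,
            "mean": np.mean(list(per_rep.values()), axis=0),
        }

    rows = []
    for row in invaded.itertuples(index=False):
        comp = row.native_composition
        if comp not in control_vecs:
            raise ValueError(f"composition {comp!r} has no control microcosms")
        ctrl = control_vecs[comp]
        natives = ctrl["natives"]
        t = float(str(row.sample_times).split(";")[-1])
        inv_density = final_density(row.microcosm_id, row.invader, t)
        native_vec = [final_density(row.microcosm_id, n, t) for n in natives]
        if control_rule == "paired":
            if row.replicate not in ctrl["per_rep"]:
                raise ValueError(
                    f"no control replicate {row.replicate} for composition {comp!r}"
                )
            ref = ctrl["per_rep"][row.replicate]
        else:
            ref = ctrl["mean"]
        est = establishment(inv_density, detection_limit)
        rows.append(
            {
                "microcosm_id": row.microcosm_id,
                "invader": row.invader,
                "native_composition": comp,
                "richness": len(natives),
                "invader_density": inv_density,
                "established": est,
                "abundance": invader_abundance(inv_density) if est else float("nan"),
                "impact": impact(native_vec, ref, log_scale=log_scale_impact),
            }
        )
    return pd.DataFrame(rows)
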