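"""Simulated microcosm experiments on a Lotka-Volterra ground truth.

Two experiments are simulated on the same community model:

* the **main invasion experiment** — native communities are inoculated at
  hour 0, equilibrate for 48 h, a single invader is introduced into the
  invaded microcosms at hour 48, and microcosms are sampled per the design
  (destructive pre-invasion samples at hour 48, invaded and control
  microcosms at hour 96);
* the **mutual-invasion assays** — for each invader-native pair, each species
  is grown from a low-density inoculum both alone in fresh medium and
  invading the partner's 48 h steady-state culture, with the focal density
  recorded 6 h and 14 h after introduction (exponential-phase window).

Dynamics are deterministic; replicate microcosms share the same truth and
differ only through plate-count observation noise, which is applied
separately by :mod:`invasibility.plating`.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import Schedule, split_composition
from .lv import InoculationEvent, LVParams, simulate_lv

__all__ = [
    "DEFAULT_INTRO_DENSITY",
    "simulate_invasion_experiment",
    "simulate_mutual_invasion_assays",
]

#: Default introduction density, CFU/mL in the 6 mL culture: a 10 uL transfer
#: of a 1e6 CFU/mL stock (~1e4 cells) into 6 mL.
DEFAULT_INTRO_DENSITY = 10.0 / 6000.0 * 1e6

#: Introductions must stay below this fraction of the focal carrying capacity
#: for the low-density invasion-growth-rate reading to be meaningful.
MAX_INTRO_FRACTION_OF_K = 0.02


def _intro_density(
    species: str, intro_density: float | Mapping[str, float] | None
) -> float:
    if intro_density is None:
        return DEFAULT_INTRO_DENSITY
    if isinstance(intro_density, Mapping):
        return float(intro_density.get(species, DEFAULT_INTRO_DENSITY))
    return float(intro_density)


def _check_intro(params: LVParams, species: str, density: float) -> None:
    k = params.K[params.index(species)]
    if density > MAX_INTRO_FRACTION_OF_K * k:
        raise ValueError(
            f"introduction density {density:g} for {species} exceeds 2% of its "
            f"carrying capacity {k:g}; the invasion-rate estimate assumes a "
            "low-density introduction"
        )


def simulate_invasion_experiment(
    params: LVParams,
    design: pd.DataFrame,
    intro_density: float | Mapping[str, float] | None = None,
    schedule: Schedule | None = None,
) -> pd.DataFrame:
    """True densities at every (microcosm, species, sample time) of a design.

    Natives start at their introduction density at hour 0; the invader of an
    invaded row is added as an inoculation event at the establishment time.
    Replicates of the same (composition, invader, treatment) share identical
    deterministic trajectories, so each unique scenario is integrated once.

    Returns a long DataFrame ``microcosm_id, species, time, density``
    covering every species present in each microcosm (invader density is 0
    in controls and pre-invasion samples).
    """
    schedule = schedule or Schedule()
    known = set(params.species_ids)
    cache: dict[tuple, pd.DataFrame] = {}
    out = []
    for row in design.itertuples(index=False):
        natives = split_composition(row.native_composition)
        invader = row.invader or None
        missing = (set(natives) | ({invader} if invader else set())) - known
        if missing:
            raise KeyError(f"design references unknown species {sorted(missing)}")
        times = tuple(float(t) for t in str(row.sample_times).split(";"))
        key = (row.native_composition, invader, times)
        if key not in cache:
            members = list(natives) + ([invader] if invader else [])
            sub = params.subset(members)
            init = {n: _intro_density(n, intro_density) for n in natives}
            events = []
            if invader:
                d = _intro_density(invader, intro_density)
                events.append(
                    InoculationEvent(schedule.establishment_time, invader, d)
                )
            grid = sorted(set(times) | {0.0})
            traj = simulate_lv(sub, [init.get(s, 0.0) for s in members], grid, events)
            frames = []
            for t in times:
                ti = grid.index(t)
                frames.append(
                    pd.DataFrame(
                        {"species": members, "time": t, "density": traj[ti]}
                    )
                )
            cache[key] = pd.concat(frames, ignore_index=True)
        block = cache[key].copy()
        block.insert(0, "microcosm_id", row.microcosm_id)
        out.append(block)
    return pd.concat(out, ignore_index=True)


def simulate_mutual_invasion_assays(
    params: LVParams,
    pairs: Sequence[tuple[str, str]],
    intro_density: float | Mapping[str, float] | None = None,
    schedule: Schedule | None = None,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Reciprocal invasion-assay densities for each (invader, native) pair.

    For each pair, each member is the focal species in two contexts:
    ``alone`` (low-density inoculum into fresh medium) and ``invading``
    (the same inoculum into the partner's culture established alone for the
    schedule's establishment time). The focal density is reported at the
    assay times measured from its introduction.

    The truth is deterministic; rows are repeated for ``n_replicates``
    replicate microcosms so observation noise can be layered per replicate.
    Columns: ``invader, native, focal, context, replicate, time, density``
    plus ``microcosm_id`` (unique per assay culture).
    """
    schedule = schedule or Schedule()
    t1, t2 = schedule.assay_times
    rows = []
    counter = 0
    for invader, native in pairs:
        if invader == native:
            raise ValueError(f"pair with identical species {invader!r}")
        for sp in (invader, native):
            params.index(sp)
            _check_intro(params, sp, _intro_density(sp, intro_density))
        sub = params.subset([invader, native])
        for focal, resident in ((invader, native), (native, invader)):
            fi = sub.species_ids.index(focal)
            d_focal = _intro_density(focal, intro_density)
            d_res = _intro_density(resident, intro_density)
            # alone: focal from its inoculum in fresh medium
            alone = simulate_lv(
                sub,
                {focal: d_focal},
                [0.0, t1, t2],
            )[:, fi]
            # invading: resident establishes, focal added at establishment
            t0 = schedule.establishment_time
            inv = simulate_lv(
                sub,
                {resident: d_res},
                [0.0, t0 + t1, t0 + t2],
                events=[InoculationEvent(t0, focal, d_focal)],
            )[:, fi]
            for context, dens in (("alone", alone[1:]), ("invading", inv[1:])):
                for rep in range(1, n_replicates + 1):
                    counter += 1
                    mid = f"A{counter:05d}"
                    for t, d in zip((t1, t2), dens):
                        rows.append(
                            (mid, invader, native, focal, context, rep, t, d)
                        )
    return pd.DataFrame(
        rows,
        columns=[
            "microcosm_id",
            "invader",
            "native",
            "focal",
            "context",
            "replicate",
            "time",
            "density",
        ],
    )
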