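"""Serial-dilution plate-count observation and density back-calculation.

True densities are observed by plating a fixed volume of each of several
serial dilutions and counting colonies; colony counts are Poisson with mean
``density * plated_volume / dilution_factor``, independent across dilutions.
Densities are recovered from the dilution(s) whose counts fall in the
countable range (30-300 colonies by microbiological convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PlateCountRecord",
    "DensityEstimate",
    "DEFAULT_DILUTION_LADDER",
    "DEFAULT_PLATED_VOLUME",
    "COUNTABLE_RANGE",
    "observe_plate_counts",
    "observe_counts_table",
    "estimate_density",
    "estimate_density_table",
]

#: Five dilution levels from 1e2 to 1e6.
DEFAULT_DILUTION_LADDER: tuple[float, ...] = (1e2, 1e3, 1e4, 1e5, 1e6)
DEFAULT_PLATED_VOLUME = 0.1  # mL spread per plate
COUNTABLE_RANGE: tuple[float, float] = (30, 300)


@dataclass(frozen=True)
class PlateCountRecord:
    microcosm_id: str
    species: str
    time: float
    dilution_factor: float
    plated_volume: float
    colonies: int

    def __post_init__(self) -> None:
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")
        if self.colonies < 0:
            raise ValueError("colonies must be >= 0")


@dataclass(frozen=True)
class DensityEstimate:
    microcosm_id: str
    species: str
    time: float
    density: float  # CFU/mL
    n_dilutions_used: int
    below_detection: bool = False


def observe_plate_counts(
    true_density: float,
    dilution_ladder: Sequence[float] = DEFAULT_DILUTION_LADDER,
    plated_volume: float = DEFAULT_PLATED_VOLUME,
    seed: int | np.random.Generator = 0,
    microcosm_id: str = "",
    species: str = "",
    time: float = 0.0,
) -> list[PlateCountRecord]:
    """Poisson colony counts for one sample across the dilution ladder."""
    if true_density < 0 or not np.isfinite(true_density):
        raise ValueError("true_density must be finite and >= 0")
    if len(dilution_ladder) == 0:
        raise ValueError("dilution ladder must be non-empty")
    if plated_volume <= 0:
        raise ValueError("plated_volume must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    records = []
    for d in dilution_ladder:
        mean = true_density * plated_volume / d
        records.append(
            PlateCountRecord(
                microcosm_id=microcosm_id,
                species=species,
                time=time,
                dilution_factor=float(d),
                plated_volume=float(plated_volume),
                colonies=int(rng.poisson(mean)),
            )
        )
    return records


def observe_counts_table(
    densities: pd.DataFrame,
    dilution_ladder: Sequence[float] = DEFAULT_DILUTION_LADDER,
    plated_volume: float = DEFAULT_PLATED_VOLUME,
    seed: int = 0,
) -> pd.DataFrame:
    """Vectorised plate-count observation of a true-density table.

    ``densities`` needs a ``density`` column; all other columns (sample
    identifiers such as microcosm, species, time, assay context, replicate)
    are preserved, and the result repeats each row once per dilution with a
    ``colonies`` draw.
    """
    if "density" not in densities.columns:
        raise ValueError("density table must have a 'density' column")
    if (densities["density"] < 0).any():
        raise ValueError("densities must be >= 0")
    if plated_volume <= 0:
        raise ValueError("plated_volume must be > 0")
    rng = np.random.default_rng(seed)
    ladder = np.asarray(dilution_ladder, dtype=float)
    base = densities.loc[densities.index.repeat(len(ladder))].reset_index(drop=True)
    base["dilution_factor"] = np.tile(ladder, len(densities))
    base["plated_volume"] = plated_volume
    means = base["density"].to_numpy() * plated_volume / base["dilution_factor"].to_numpy()
    base["colonies"] = rng.poisson(means)
    return base.drop(columns="density")


def _estimate_one(
    dilutions: np.ndarray,
    volumes: np.ndarray,
    colonies: np.ndarray,
    countable_range: tuple[float, float],
) -> tuple[float, int, bool]:
    lo, hi = countable_range
    per_plate = colonies * dilutions / volumes
    countable = (colonies >= lo) & (colonies <= hi)
    if countable.any():
        return float(per_plate[countable].mean()), int(countable.sum()), False
    if (colonies == 0).all():
        return 0.0, 0, True
    # nearest-to-range fallback; ties broken toward the smallest dilution
    dist = np.where(colonies < lo, lo - colonies, np.where(colonies > hi, colonies - hi, 0))
    order = np.lexsort((dilutions, dist))
    best = order[0]
    return float(per_plate[best]), 1, False


def estimate_density(
    records: Iterable[PlateCountRecord],
    countable_range: tuple[float, float] = COUNTABLE_RANGE,
) -> DensityEstimate:
    """Back-calculate CFU/mL for one (microcosm, species, time) sample.

    Uses ``colonies * dilution_factor / plated_volume`` at every countable
    dilution and averages the qualifying estimates; with no countable plate
    the count nearest the range is used; all-zero counts give density 0 with
    the below-detection flag set.
    """
    records = list(records)
    if not records:
        raise ValueError("need at least one plate-count record")
    keys = {(r.microcosm_id, r.species, r.time) for r in records}
    if len(keys) > 1:
        raise ValueError("records span multiple samples")
    density, n_used, below = _estimate_one(
        np.array([r.dilution_factor for r in records], dtype=float),
        np.array([r.plated_volume for r in records], dtype=float),
        np.array([r.colonies for r in records], dtype=float),
        countable_range,
    )
    r0 = records[0]
    return DensityEstimate(
        microcosm_id=r0.microcosm_id,
        species=r0.species,
        time=r0.time,
        density=density,
        n_dilutions_used=n_used,
        below_detection=below,
    )


def estimate_density_table(
    counts: pd.DataFrame,
    countable_range: tuple[float, float] = COUNTABLE_RANGE,
    group_cols: Sequence[str] = ("microcosm_id", "species", "time"),
) -> pd.DataFrame:
    """Apply the density back-calculation to every sample in a count table.

    Extra grouping columns (e.g. replicate, assay context) are preserved by
    passing them in ``group_cols``.
    """
    rows = []
    for key, grp in counts.groupby(list(group_cols), sort=True):
        density, n_used, below = _estimate_one(
            grp["dilution_factor"].to_numpy(dtype=float),
            grp["plated_volume"].to_numpy(dtype=float),
            grp["colonies"].to_numpy(dtype=float),
            countable_range,
        )
        rows.append((*key, density, n_used, below))
    return pd.DataFrame(
        rows, columns=[*group_cols, "density", "n_dilutions_used", "below_detection"]
    )
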