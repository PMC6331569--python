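"""Factorial design tables for microcosm invasion experiments.

The layout mirrors a mutual-invasibility study on freshwater bacteria: every
native monoculture and every two-species native polyculture is assembled, each
composition is replicated across three fates — destructive pre-invasion
sampling at the establishment time, challenge with a single invader, or
uninvaded control — and invaded/control microcosms are sampled at the final
hour.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = [
    "Schedule",
    "generate_design",
    "design_summary",
    "invader_native_pairs",
    "COMPOSITION_SEP",
]

#: Separator used to serialise a native composition into a single CSV field.
COMPOSITION_SEP = "+"

TREATMENTS = ("preinvasion_sample", "invaded", "control")


@dataclass(frozen=True)
class Schedule:
    """Timing of the experiment, in hours since native inoculation."""

    establishment_time: float = 48.0
    final_time: float = 96.0
    assay_times: tuple[float, float] = (6.0, 14.0)  # post-introduction

    def __post_init__(self) -> None:
        if not 0 < self.establishment_time < self.final_time:
            raise ValueError("need 0 < establishment_time < final_time")
        t1, t2 = self.assay_times
        if not 0 < t1 < t2:
            raise ValueError("assay_times must be increasing and positive")


def _species_labels(spec: int | Sequence[str], prefix: str) -> list[str]:
    if isinstance(spec, int):
        if spec < 0:
            raise ValueError("species count must be >= 0")
        return [f"{prefix}{i + 1}" for i in range(spec)]
    labels = [str(s) for s in spec]
    if len(set(labels)) != len(labels):
        raise ValueError("species labels must be unique")
    return labels


def composition_label(species: Sequence[str]) -> str:
    return COMPOSITION_SEP.join(sorted(species))


def split_composition(label: str) -> list[str]:
    return label.split(COMPOSITION_SEP)


def generate_design(
    natives: int | Sequence[str],
    invaders: int | Sequence[str],
    max_richness: int = 2,
    reps_preinvasion: int = 3,
    reps_invaded_per_invader: int = 3,
    reps_control: int = 3,
    schedule: Schedule | None = None,
) -> pd.DataFrame:
    """Enumerate every microcosm of the factorial design as one table row.

    ``natives``/``invaders`` may be species-label sequences or plain counts
    (labelled ``N1..`` / ``I1..``). Native compositions are all subsets of the
    natives of size 1..``max_richness`` (at most 2, the pairwise design).

    Returns a DataFrame with columns ``microcosm_id, native_composition,
    richness, invader, treatment, replicate, sample_times`` (semicolon-joined
    hours).
    """
    schedule = schedule or Schedule()
    native_ids = _species_labels(natives, "N")
    invader_ids = _species_labels(invaders, "I")
    if set(native_ids) & set(invader_ids):
        raise ValueError("native and invader labels overlap")
    if max_richness > 2:
        raise ValueError("max_richness > 2 is not supported by this design")
    if not 1 <= max_richness <= len(native_ids):
        raise ValueError("need n_natives >= max_richness >= 1")
    for name, reps in (
        ("reps_preinvasion", reps_preinvasion),
        ("reps_invaded_per_invader", reps_invaded_per_invader),
        ("reps_control", reps_control),
    ):
        if reps < 0:
            raise ValueError(f"{name} must be >= 0")
    if not invader_ids and reps_invaded_per_invader > 0:
        raise ValueError("invaded replicates requested but no invaders given")

    compositions = [
        composition_label(combo)
        for k in range(1, max_richness + 1)
        for combo in itertools.combinations(native_ids, k)
    ]

    pre_times = f"{schedule.establishment_time:g}"
    final_times = f"{schedule.final_time:g}"
    rows = []
    for comp in compositions:
        richness = len(split_composition(comp))
        for rep in range(1, reps_preinvasion + 1):
            rows.append((comp, richness, "", "preinvasion_sample", rep, pre_times))
        for inv in invader_ids:
            for rep in range(1, reps_invaded_per_invader + 1):
                rows.append((comp, richness, inv, "invaded", rep, final_times))
        for rep in range(1, reps_control + 1):
            rows.append((comp, richness, "", "control", rep, final_times))

    df = pd.DataFrame(
        rows,
        columns=[
            "native_composition",
            "richness",
            "invader",
            "treatment",
            "replicate",
            "sample_times",
        ],
    )
    df.insert(0, "microcosm_id", [f"M{i + 1:04d}" for i in range(len(df))])
    return df


def design_summary(design: pd.DataFrame) -> dict[str, int]:
    """Headline counts of a design table (compositions, microcosms, treatments)."""
    invaders = sorted(x for x in design["invader"].unique() if x)
    natives = sorted(
        {s for comp in design["native_composition"] for s in split_composition(comp)}
    )
    counts = design["treatment"].value_counts()
    return {
        "n_compositions": design["native_composition"].nunique(),
        "n_microcosms": len(design),
        "n_preinvasion": int(counts.get("preinvasion_sample", 0)),
        "n_invaded": int(counts.get("invaded", 0)),
        "n_control": int(counts.get("control", 0)),
        "n_invader_native_pairs": len(invaders) * len(natives),
    }


def invader_native_pairs(
    natives: int | Sequence[str], invaders: int | Sequence[str]
) -> list[tuple[str, str]]:
    """All (invader, native) pairs for the mutual-invasion assays."""
    return [
        (i, n)
        for i in _species_labels(invaders, "I")
        for n in _species_labels(natives, "N")
    ]
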