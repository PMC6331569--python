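"""End-to-end orchestration: simulate, analyze, report.

A single YAML/JSON config drives everything. Its ``simulation`` block states
the synthetic world (community size, trait model, observation noise); an
``inputs`` block can instead point at real tables in the same schema. Every
stage writes its table as CSV under the output directory, and the report is
plain Markdown. All randomness flows from one integer seed, so a pipeline
run is byte-for-byte reproducible.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import Schedule, design_summary, generate_design, invader_native_pairs
from .model import InvasionAnalysis
from .phylosim import map_traits_to_lv, simulate_phylogeny_and_traits
from .plating import (
    DEFAULT_DILUTION_LADDER,
    DEFAULT_PLATED_VOLUME,
    observe_counts_table,
)
from .simulate import simulate_invasion_experiment, simulate_mutual_invasion_assays

__all__ = ["DEFAULT_CONFIG", "load_config", "simulate_experiment", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "simulation": {
        "n_natives": 8,
        "n_invaders": 3,
        "max_richness": 2,
        "reps_preinvasion": 3,
        "reps_invaded_per_invader": 3,
        "reps_control": 3,
        "trait_model": "brownian",
        "trait_rate": 1.0,
        "niche_width": 1.0,
        "K_base": 1e9,
        "K_sensitivity": 0.3,
        "r_range": [0.3, 0.7],
        "assay_replicates": 3,
        "observe_noise": True,
        "dilution_ladder": list(DEFAULT_DILUTION_LADDER),
        "plated_volume": DEFAULT_PLATED_VOLUME,
    },
    "metrics": {
        "detection_limit": 1e2,
        "aggregation": "mean",
        "control_rule": "mean",
    },
}


def load_config(path: str | Path | None) -> dict:
    """Read a YAML/JSON config, filling unset keys from the defaults."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for block, values in user.items():
            if isinstance(values, dict):
                cfg.setdefault(block, {}).update(values)
            else:
                cfg[block] = values
    return cfg


def simulate_experiment(config: dict, seed: int) -> dict:
    """Generate the full synthetic experiment described by the config.

    Returns a dict of artifacts: ``design``, ``phylogeny`` (newick string),
    ``params`` (LVParams), ``truth`` / ``assay_truth`` (true densities) and
    ``counts`` / ``assay_counts`` (plate-count tables, or the truth tables
    when observation noise is disabled).
    """
    sim = config["simulation"]
    rng = np.random.default_rng(seed)
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, size=6)]

    n_total = sim["n_natives"] + sim["n_invaders"]
    phylogeny = simulate_phylogeny_and_traits(
        n_total,
        seed=sub[0],
        trait_model=sim["trait_model"],
        trait_rate=sim["trait_rate"],
    )
    params = map_traits_to_lv(
        phylogeny,
        niche_width=sim["niche_width"],
        K_base=sim["K_base"],
        K_sensitivity=sim["K_sensitivity"],
        r_range=tuple(sim["r_range"]),
        seed=sub[1],
    )
    species = params.species_ids
    natives = species[: sim["n_natives"]]
    invaders = species[sim["n_natives"] : sim["n_natives"] + sim["n_invaders"]]

    design = generate_design(
        natives,
        invaders,
        max_richness=sim["max_richness"],
        reps_preinvasion=sim["reps_preinvasion"],
        reps_invaded_per_invader=sim["reps_invaded_per_invader"],
        reps_control=sim["reps_control"],
    )
    truth = simulate_invasion_experiment(params, design)
    pairs = invader_native_pairs(natives, invaders)
    assay_truth = simulate_mutual_invasion_assays(
        params, pairs, n_replicates=sim["assay_replicates"]
    )

    if sim["observe_noise"]:
        counts = observe_counts_table(
            truth,
            dilution_ladder=sim["dilution_ladder"],
            plated_volume=sim["plated_volume"],
            seed=sub[2],
        )
        assay_for_counts = assay_truth.rename(columns={"focal": "species"})
        assay_counts = observe_counts_table(
            assay_for_counts,
            dilution_ladder=sim["dilution_ladder"],
            plated_volume=sim["plated_volume"],
            seed=sub[3],
        ).rename(columns={"species": "focal"})
    else:
        counts = truth
        assay_counts = assay_truth

    return {
        "design": design,
        "phylogeny": phylogeny,
        "params": params,
        "truth": truth,
        "assay_truth": assay_truth,
        "counts": counts,
        "assay_counts": assay_counts,
        "natives": natives,
        "invaders": invaders,
    }


def _write_params(params, path: Path) -> None:
    payload = {
        "species_ids": params.species_ids,
        "r": params.r.tolist(),
        "K": params.K.tolist(),
        "alpha": params.alpha.tolist(),
    }
    path.write_text(json.dumps(payload, indent=2) + "\n")


def run_pipeline(
    config: dict | str | Path | None,
    seed: int,
    outdir: str | Path,
) -> Path:
    """Simulate (or load), analyze, and report; returns the report path."""
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    inputs = config.get("inputs")
    if inputs:
        design = pd.read_csv(inputs["design"], keep_default_na=False)
        counts = pd.read_csv(inputs["counts"])
        assay_counts = pd.read_csv(inputs["assay_counts"])
        newick = Path(inputs["tree"]).read_text() if inputs.get("tree") else None
        if config.get("metrics", {}).get("use_mpd", True) and inputs.get("tree") is None:
            if config.get("metrics", {}).get("require_tree", False):
                raise ValueError(
                    "configuration error: MPD requested but no tree provided "
                    "in the inputs block"
                )
    else:
        artifacts = simulate_experiment(config, seed)
        design = artifacts["design"]
        counts = artifacts["counts"]
        assay_counts = artifacts["assay_counts"]
        newick = artifacts["phylogeny"].newick
        design.to_csv(outdir / "design.csv", index=False)
        artifacts["truth"].to_csv(outdir / "true_densities.csv", index=False)
        artifacts["assay_truth"].to_csv(outdir / "assay_true_densities.csv", index=False)
        counts.to_csv(outdir / "plate_counts.csv", index=False)
        assay_counts.to_csv(outdir / "assay_plate_counts.csv", index=False)
        (outdir / "phylogeny.nwk").write_text(newick + "\n")
        _write_params(artifacts["params"], outdir / "lv_params.json")

    metrics = config.get("metrics", {})
    model = InvasionAnalysis(
        assay_counts=assay_counts,
        experiment_counts=counts,
        design=design,
        tree=newick,
        detection_limit=metrics.get("detection_limit", 1e2),
        aggregation=metrics.get("aggregation", "mean"),
        control_rule=metrics.get("control_rule", "mean"),
    )
    results = model.fit()

    results.sensitivities.to_csv(outdir / "sensitivities.csv", index=False)
    results.pairwise.to_csv(outdir / "pairwise_coexistence.csv", index=False)
    results.outcomes.to_csv(outdir / "outcomes.csv", index=False)
    results.analysis_table.to_csv(outdir / "analysis_table.csv", index=False)
    if results.pd_matrix is not None:
        results.pd_matrix.to_csv(outdir / "pd_matrix.csv")
    for response, comp in results.comparisons.items():
        tab = comp.table.copy()
        tab["predictors"] = tab["predictors"].map(lambda t: "+".join(t) or "(intercept)")
        tab.to_csv(outdir / f"model_comparison_{response}.csv", index=False)

    report = outdir / "report.md"
    counts_summary = design_summary(design)
    lines = [
        "# Invasion pipeline report",
        "",
        f"- package version: {__version__}",
        f"- seed: {seed}",
        "",
        "## Design",
        "",
    ]
    lines += [f"- {k}: {v}" for k, v in counts_summary.items()]
    lines += ["", "## Analysis", "", "```", results.summary().rstrip(), "```", ""]
    lines.append(
        "No multiple-testing correction is applied to the reported p-values."
    )
    report.write_text("\n".join(lines) + "\n")
    return report
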