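"""The top-level Model/Results pair tying the pipeline stages together.

``InvasionAnalysis`` is built from the data of one experiment — the
mutual-invasion assay plate counts, the main-experiment plate counts, the
design table, and (optionally) a phylogeny — and ``fit()`` runs the whole
estimation chain: density back-calculation, growth rates and sensitivities,
ND/RFD, patristic distances and MPD, per-microcosm outcomes, and the
regressions/model comparisons of establishment, abundance and impact on
{SR, MPD, ND, RFD}. The returned ``InvasionAnalysisResults`` carries every
intermediate table plus the fitted comparisons and renders a text summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from . import coexistence, growth, outcomes as outcomes_mod, phylo, plating
from .design import split_composition

__all__ = ["InvasionAnalysis", "InvasionAnalysisResults"]


class InvasionAnalysis:
    """Full invasion analysis of a microcosm experiment.

    Parameters
    ----------
    assay_counts
        Plate counts (or already-estimated densities) of the mutual-invasion
        assays: columns ``invader, native, focal, context, replicate, time``
        plus either plate-count columns (``microcosm_id, dilution_factor,
        plated_volume, colonies``) or a ``density`` column.
    experiment_counts
        Plate counts or densities of the main experiment: ``microcosm_id,
        species, time`` plus count columns or ``density``.
    design
        The design table (see :func:`invasibility.design.generate_design`).
    tree
        Optional Newick string or dendropy tree; enables MPD predictors.
    """

    def __init__(
        self,
        assay_counts: pd.DataFrame,
        experiment_counts: pd.DataFrame,
        design: pd.DataFrame,
        tree: str | dendropy.Tree | None = None,
        detection_limit: float = outcomes_mod.DEFAULT_DETECTION_LIMIT,
        countable_range: tuple[float, float] = plating.COUNTABLE_RANGE,
        aggregation: str = "mean",
        control_rule: str = "mean",
    ) -> None:
        self.assay_counts = assay_counts
        self.experiment_counts = experiment_counts
        self.design = design
        if isinstance(tree, str):
            tree = phylo.read_tree(tree)
        self.tree = tree
        self.detection_limit = detection_limit
        self.countable_range = countable_range
        self.aggregation = aggregation
        self.control_rule = control_rule

    # -- helpers -----------------------------------------------------------

    def _densities(self, counts: pd.DataFrame, group_cols: list[str]) -> pd.DataFrame:
        if "density" in counts.columns:
            return counts
        est = plating.estimate_density_table(
            counts, countable_range=self.countable_range, group_cols=group_cols
        )
        return est

    # -- fitting -----------------------------------------------------------

    def fit(self) -> "InvasionAnalysisResults":
        assay_dens = self._densities(
            self.assay_counts,
            ["invader", "native", "focal", "context", "replicate", "time"],
        )
        sens = growth.sensitivities_from_assays(assay_dens)
        pairwise = coexistence.pairwise_coexistence_table(sens)

        pdm = None
        if self.tree is not None:
            species = sorted(
                set(pairwise["invader"]) | set(pairwise["native"])
            )
            pdm = phylo.pd_matrix(self.tree, order=species)

        exp_dens = self._densities(
            self.experiment_counts, ["microcosm_id", "species", "time"]
        )
        outcome_table = outcomes_mod.aggregate_outcomes(
            exp_dens,
            self.design,
            detection_limit=self.detection_limit,
            control_rule=self.control_rule,
        )

        # community-level predictors for every invaded microcosm
        pred_cache: dict[tuple[str, str], dict] = {}
        pred_rows = []
        for row in outcome_table.itertuples(index=False):
            key = (row.invader, row.native_composition)
            if key not in pred_cache:
                pred_cache[key] = coexistence.community_predictors(
                    pairwise,
                    row.invader,
                    split_composition(row.native_composition),
                    aggregation=self.aggregation,
                    pd_matrix=pdm,
                )
            pred_rows.append(pred_cache[key])
        predictors = pd.DataFrame(pred_rows)
        analysis = pd.concat(
            [outcome_table.reset_index(drop=True), predictors.drop(
                columns=["invader", "native_composition", "richness"]
            )],
            axis=1,
        )
        analysis = analysis.rename(
            columns={"mean_ND": "ND", "mean_RFD": "RFD"}
        )
        analysis["SR"] = analysis["richness"].astype(float)

        from .regression import compare_models  # local import avoids cycles

        predictor_names = ["SR", "ND", "RFD"] + (["MPD"] if pdm is not None else [])
        usable = analysis[analysis["valid"]]
        comparisons = {}
        if usable["established"].nunique() > 1:
            comparisons["establishment"] = compare_models(
                usable, "established", predictor_names, family="binomial"
            )
        established = usable[usable["established"] == 1]
        if len(established) > len(predictor_names) + 2:
            comparisons["abundance"] = compare_models(
                established, "abundance", predictor_names, family="gaussian"
            )
        comparisons["impact"] = compare_models(
            usable, "impact", predictor_names, family="gaussian"
        )

        return InvasionAnalysisResults(
            model=self,
            sensitivities=sens,
            pairwise=pairwise,
            pd_matrix=pdm,
            outcomes=outcome_table,
            analysis_table=analysis,
            comparisons=comparisons,
        )


@dataclass
class InvasionAnalysisResults:
    """Tables and fitted comparisons produced by :meth:`InvasionAnalysis.fit`."""

    model: InvasionAnalysis
    sensitivities: pd.DataFrame
    pairwise: pd.DataFrame
    pd_matrix: pd.DataFrame | None
    outcomes: pd.DataFrame
    analysis_table: pd.DataFrame
    comparisons: dict

    def summary(self) -> str:
        lines = ["Invasion analysis summary", "=" * 26, ""]
        n_pairs = len(self.pairwise)
        n_valid = int(self.pairwise["valid"].sum())
        lines.append(f"invader-native pairs: {n_pairs} ({n_valid} with valid ND/RFD)")
        lines.append(f"invaded microcosms:   {len(self.outcomes)}")
        est = self.outcomes.groupby("invader")["established"].sum()
        tot = self.outcomes.groupby("invader")["established"].size()
        for inv in est.index:
            lines.append(
                f"  {inv}: established in {int(est[inv])}/{int(tot[inv])} microcosms"
            )
        lines.append("")
        for response, comp in self.comparisons.items():
            best = comp.best
            lines.append(
                f"{response} ({comp.family}): best AIC model "
                f"{{{', '.join(best) if best else 'intercept only'}}}; "
                f"best univariate: {comp.best_univariate}"
            )
            res = comp.results[best]
            for name, coef in res.params.items():
                if name == "const":
                    continue
                lines.append(
                    f"    {name}: coef={coef:+.3f} (se {res.bse[name]:.3f}, "
                    f"p={res.pvalues[name]:.3g})"
                )
        return "\n".join(lines) + "\n"

    def plot_predictors(self, response: str = "abundance", ax=None):
        """Scatter plots of a response against ND and RFD, one color per invader."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
        else:
            axes = ax
        data = self.analysis_table.dropna(subset=[response])
        for i, pred in enumerate(("ND", "RFD")):
            for inv, grp in data.groupby("invader"):
                axes[i].scatter(grp[pred], grp[response], s=12, label=str(inv))
            axes[i].set_xlabel(pred)
        axes[0].set_ylabel(response)
        axes[0].legend(frameon=False, fontsize=8)
        return axes
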