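"""Simulated phylogenies with evolving niche and fitness traits.

A pure-birth (Yule) tree is simulated with dendropy and rescaled to unit root
depth, then two quantitative traits evolve on it: a *niche* trait (positions
on a resource axis; its distances set competition coefficients) and a
*fitness* trait (modulates carrying capacity). Under ``brownian`` evolution
trait distance accumulates along branches, so patristic distance is
informative about ecology; under ``white`` evolution traits are i.i.d. at the
tips and the phylogeny carries no ecological signal. Toggling the trait model
therefore controls how strongly phylogenetic distance predicts niche and
fitness differences in the synthetic experiment.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import dendropy
import numpy as np
from dendropy.simulate import treesim

from .lv import LVParams

__all__ = ["SimulatedPhylogeny", "simulate_phylogeny_and_traits", "map_traits_to_lv"]

TRAIT_MODELS = ("brownian", "white")


@dataclass
class SimulatedPhylogeny:
    """A rooted ultrametric tree plus one niche and one fitness value per tip."""

    tree: dendropy.Tree
    newick: str
    niche_trait: dict[str, float]
    fitness_trait: dict[str, float]
    trait_model: str

    @property
    def species_ids(self) -> list[str]:
        return sorted(self.niche_trait)


def _yule_tree(n_species: int, rng: random.Random) -> dendropy.Tree:
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_species,
        rng=rng,
    )
    # The simulation stops exactly at the n-th speciation, leaving the newest
    # pair of tips with zero-length pendant edges (and PD 0). Extend every tip
    # by the waiting time to the next would-be speciation, Exp(n * birth rate),
    # the standard convention for Yule trees conditioned on tip count.
    extra = rng.expovariate(n_species * 1.0)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    # deterministic tip labels in traversal order
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"S{i + 1:02d}"
    depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    if depth > 0:
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length /= depth
    return tree


def _evolve_trait(
    tree: dendropy.Tree, model: str, rate: float, rng: np.random.Generator
) -> dict[str, float]:
    if model == "white":
        return {
            leaf.taxon.label: float(rng.normal(0.0, np.sqrt(rate)))
            for leaf in tree.leaf_node_iter()
        }
    # Brownian motion: root value 0, Gaussian increments with variance
    # rate * branch length down every edge.
    values: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[id(node)] = 0.0
        else:
            bl = node.edge.length or 0.0
            values[id(node)] = values[id(node.parent_node)] + float(
                rng.normal(0.0, np.sqrt(rate * bl))
            )
    return {
        leaf.taxon.label: values[id(leaf)] for leaf in tree.leaf_node_iter()
    }


def simulate_phylogeny_and_traits(
    n_species: int,
    seed: int,
    trait_model: str = "brownian",
    trait_rate: float = 1.0,
    tree_model: str = "yule",
) -> SimulatedPhylogeny:
    """Simulate a Yule tree (unit root depth) with niche and fitness traits.

    Deterministic given ``seed``: the tree topology, branch lengths and both
    trait draws are reproduced exactly on repeated calls.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    if trait_model not in TRAIT_MODELS:
        raise ValueError(f"unknown trait_model {trait_model!r}; use {TRAIT_MODELS}")
    if tree_model != "yule":
        raise ValueError(f"unknown tree_model {tree_model!r}; only 'yule' supported")
    if trait_rate <= 0:
        raise ValueError("trait_rate must be > 0")

    tree = _yule_tree(n_species, random.Random(seed))
    rng = np.random.default_rng(seed)
    niche = _evolve_trait(tree, trait_model, trait_rate, rng)
    fitness = _evolve_trait(tree, trait_model, trait_rate, rng)
    newick = tree.as_string(schema="newick", suppress_rooting=True).strip()
    return SimulatedPhylogeny(
        tree=tree,
        newick=newick,
        niche_trait=niche,
        fitness_trait=fitness,
        trait_model=trait_model,
    )


def map_traits_to_lv(
    phylo: SimulatedPhylogeny,
    niche_width: float = 1.0,
    K_base: float = 1e9,
    K_sensitivity: float = 0.3,
    r_range: tuple[float, float] = (0.3, 0.7),
    seed: int = 0,
) -> LVParams:
    """Turn tip traits into Lotka-Volterra parameters.

    Competition decays with niche-trait distance through a Gaussian kernel,
    ``alpha_ij = exp(-(z_i - z_j)^2 / (2 niche_width^2))`` (unit diagonal), so
    ecologically similar species compete strongly. Carrying capacity scales
    log-linearly with the fitness trait, ``K_i = K_base exp(K_sensitivity *
    f_i)``, and growth rates are drawn uniformly from ``r_range`` (1/h).
    """
    if niche_width <= 0:
        raise ValueError("niche_width must be > 0")
    species = phylo.species_ids
    z = np.array([phylo.niche_trait[s] for s in species])
    f = np.array([phylo.fitness_trait[s] for s in species])
    dz = z[:, None] - z[None, :]
    alpha = np.exp(-(dz**2) / (2.0 * niche_width**2))
    np.fill_diagonal(alpha, 1.0)
    K = K_base * np.exp(K_sensitivity * f)
    rng = np.random.default_rng(seed)
    r = rng.uniform(r_range[0], r_range[1], size=len(species))
    return LVParams(species_ids=species, r=r, K=K, alpha=alpha)
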