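"""Patristic distances, invader-to-community MPD, and the Mantel test.

Trees are consumed as Newick with branch lengths (never inferred here);
out-group taxa can be pruned on read. The patristic distance between two
leaves is the sum of branch lengths on the unique path between them — it is
invariant to the root position, so unrooted input is safe. MPD is the
arithmetic mean patristic distance from an invader to the members of the
recipient community. Distance matrices (e.g. from two alternative tree
reconstructions) are compared with a one-sided Mantel permutation test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "read_tree",
    "patristic_distance",
    "pd_matrix",
    "mpd",
    "MantelResult",
    "mantel",
]


def read_tree(
    newick: str, prune_labels: Sequence[str] | None = None
) -> dendropy.Tree:
    """Parse a Newick tree, validate it, and optionally prune out-groups.

    Requires unique leaf labels and a branch length on every non-root edge.
    Prune labels absent from the tree raise a warning, not an error.
    """
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several parse-error types
        raise ValueError(f"could not parse Newick tree: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
    if len(labels) != len(tree.leaf_nodes()):
        raise ValueError("tree has unlabeled leaves")
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise ValueError(f"duplicate leaf labels: {sorted(dupes)}")
    if prune_labels:
        present = set(labels)
        absent = [l for l in prune_labels if l not in present]
        if absent:
            warnings.warn(f"prune labels not in tree: {absent}", stacklevel=2)
        to_drop = [l for l in prune_labels if l in present]
        if to_drop:
            tree.prune_taxa_with_labels(to_drop)
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if node.edge.length is None:
            raise ValueError("tree has edges with missing branch lengths")
        if node.edge.length < 0:
            raise ValueError("negative branch length")
    return tree


def _leaf(tree: dendropy.Tree, label: str) -> dendropy.Node:
    for leaf in tree.leaf_node_iter():
        if leaf.taxon and leaf.taxon.label == label:
            return leaf
    raise KeyError(f"unknown leaf {label!r}")


def patristic_distance(tree: dendropy.Tree, a: str, b: str) -> float:
    """Sum of branch lengths on the path between leaves ``a`` and ``b``."""
    if a == b:
        _leaf(tree, a)
        return 0.0
    pdm = tree.phylogenetic_distance_matrix()
    return float(pdm.patristic_distance(_leaf(tree, a).taxon, _leaf(tree, b).taxon))


def pd_matrix(tree: dendropy.Tree, order: Sequence[str] | None = None) -> pd.DataFrame:
    """Square symmetric patristic-distance matrix over the tree's leaves."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {leaf.taxon.label: leaf.taxon for leaf in tree.leaf_node_iter()}
    labels = list(order) if order is not None else sorted(taxa)
    missing = [l for l in labels if l not in taxa]
    if missing:
        raise KeyError(f"labels not in tree: {missing}")
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = float(pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]]))
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=labels, columns=labels)


def mpd(
    distances: pd.DataFrame, invader: str, natives: Sequence[str]
) -> float:
    """Mean patristic distance from ``invader`` to the ``natives``."""
    natives = list(natives)
    if not natives:
        raise ValueError("natives must be non-empty")
    if invader in natives:
        raise ValueError("invader cannot be a member of the native community")
    return float(np.mean([distances.loc[invader, n] for n in natives]))


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_permutations: int


def _as_square(m) -> np.ndarray:
    a = m.to_numpy(dtype=float) if isinstance(m, pd.DataFrame) else np.asarray(m, float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(a, a.T):
        raise ValueError("matrix must be symmetric")
    return a


def mantel(
    matrix1,
    matrix2,
    n_permutations: int = 999,
    seed: int | np.random.Generator | None = None,
) -> MantelResult:
    """One-sided Mantel permutation test between two distance matrices.

    r is the Pearson correlation of the upper-triangle entries; the p-value is
    (1 + #{permuted r >= observed r}) / (1 + n_permutations), permuting rows
    and columns of the second matrix jointly. If matrices are DataFrames the
    species orders must match. Constant matrices (zero variance) are rejected.
    """
    if isinstance(matrix1, pd.DataFrame) and isinstance(matrix2, pd.DataFrame):
        if list(matrix1.index) != list(matrix2.index):
            raise ValueError("matrices must share the same species order")
    m1, m2 = _as_square(matrix1), _as_square(matrix2)
    if m1.shape != m2.shape:
        raise ValueError("matrices must have the same shape")
    n = m1.shape[0]
    iu = np.triu_indices(n, k=1)
    x = m1[iu]
    if x.std() == 0 or m2[iu].std() == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")

    def corr(m) -> float:
        return float(np.corrcoef(x, m[iu])[0, 1])

    r_obs = corr(m2)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if corr(m2[np.ix_(perm, perm)]) >= r_obs:
            count += 1
    return MantelResult(
        r=r_obs, p=(count + 1) / (n_permutations + 1), n_permutations=n_permutations
    )
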