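"""Newick reading, patristic distances, MPD, and the Mantel test."""

import numpy as np
import pytest

from invasibility.phylo import mantel, mpd, patristic_distance, pd_matrix, read_tree
from invasibility.phylosim import simulate_phylogeny_and_traits


def test_read_toy_tree(toy_newick):
    tree = read_tree(toy_newick)
    assert sorted(l.taxon.label for l in tree.leaf_node_iter()) == ["A", "B", "C"]


def test_prune_outgroup(toy_newick):
    tree = read_tree(toy_newick, prune_labels=["C"])
    assert sorted(l.taxon.label for l in tree.leaf_node_iter()) == ["A", "B"]


def test_prune_missing_label_warns(toy_newick):
    with pytest.warns(UserWarning):
        read_tree(toy_newick, prune_labels=["Z"])


def test_duplicate_labels_rejected():
    with pytest.raises(ValueError):
        read_tree("((A:1,A:1):1,C:2);")


def test_missing_branch_lengths_rejected():
    with pytest.raises(ValueError):
        read_tree("((A:1,B):1,C:2);")


def test_unparsable_rejected():
    with pytest.raises(ValueError):
        read_tree("((A:1,B:1;")


def test_patristic_distances_on_toy_tree(toy_newick):
    tree = read_tree(toy_newick)
    assert patristic_distance(tree, "A", "B") == pytest.approx(2.0)
    assert patristic_distance(tree, "A", "C") == pytest.approx(4.0)
    assert patristic_distance(tree, "A", "A") == 0.0
    with pytest.raises(KeyError):
        patristic_distance(tree, "A", "Z")


def test_pd_matrix_metric_axioms():
    ph = simulate_phylogeny_and_traits(10, seed=11)
    m = pd_matrix(ph.tree).to_numpy()
    assert np.allclose(np.diag(m), 0.0)
    assert np.allclose(m, m.T)
    assert (m[~np.eye(10, dtype=bool)] > 0).all()
    # triangle inequality over all triples
    for i in range(10):
        for j in range(10):
            for k in range(10):
                assert m[i, j] <= m[i, k] + m[k, j] + 1e-12


def test_mpd(toy_newick):
    m = pd_matrix(read_tree(toy_newick))
    assert mpd(m, "B", ["A"]) == pytest.approx(2.0)
    assert mpd(m, "B", ["A", "C"]) == pytest.approx(3.0)
    assert min(m.loc["B", "A"], m.loc["B", "C"]) <= mpd(m, "B", ["A", "C"]) <= max(
        m.loc["B", "A"], m.loc["B", "C"]
    )
    with pytest.raises(ValueError):
        mpd(m, "B", ["A", "B"])
    with pytest.raises(ValueError):
        mpd(m, "B", [])


def _random_pd(seed, n=8):
    return pd_matrix(simulate_phylogeny_and_traits(n, seed=seed).tree).to_numpy()


def test_mantel_self_and_scale():
    m = _random_pd(3)
    res = mantel(m, m, n_permutations=99, seed=0)
    assert res.r == pytest.approx(1.0)
    assert mantel(m, 2.0 * m, n_permutations=99, seed=0).r == pytest.approx(1.0)


def test_mantel_constant_matrix_rejected():
    m = np.ones((4, 4)) - np.eye(4)
    with pytest.raises(ValueError):
        mantel(m, m, n_permutations=9)


def test_mantel_relabeling_invariance():
    # jointly permuting both matrices leaves r (and the null law) unchanged
    m1, m2 = _random_pd(5), _random_pd(6)
    perm = np.random.default_rng(0).permutation(8)
    a = mantel(m1, m2, n_permutations=199, seed=7)
    b = mantel(m1[np.ix_(perm, perm)], m2[np.ix_(perm, perm)], n_permutations=199, seed=7)
    assert a.r == pytest.approx(b.r)


def test_mantel_matches_skbio():
    # independent oracle: scikit-bio's mantel on the same matrices
    skbio_distance = pytest.importorskip("skbio.stats.distance")
    m1, m2 = _random_pd(8), _random_pd(9)
    ours = mantel(m1, m2, n_permutations=999, seed=1)
    r_skbio, p_skbio, _ = skbio_distance.mantel(
        skbio_distance.DistanceMatrix(m1),
        skbio_distance.DistanceMatrix(m2),
        method="pearson",
        permutations=999,
        alternative="greater",
    )
    assert ours.r == pytest.approx(float(r_skbio), abs=1e-12)
    assert ours.p == pytest.approx(float(p_skbio), abs=0.08)


def test_mantel_null_calibration():
    # two independently simulated trees: p-values ~ Uniform(0,1); the
    # rejection rate at 0.05 over 200 seed pairs stays near nominal.
    # One matrix is randomly relabeled so the shared traversal-order tip
    # numbering cannot induce an association between the matrices.
    hits = 0
    n_runs = 200
    for seed in range(n_runs):
        m1 = _random_pd(10_000 + seed)
        m2 = _random_pd(20_000 + seed)
        perm = np.random.default_rng(30_000 + seed).permutation(m2.shape[0])
        if mantel(m1, m2[np.ix_(perm, perm)], n_permutations=999, seed=seed).p < 0.05:
            hits += 1
    assert abs(hits / n_runs - 0.05) <= 0.03
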