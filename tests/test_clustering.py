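"""Ward linkage, tree operations and comparison metrics.

The Lance–Williams implementation is checked against two independent routes:
a naive O(n^3) agglomerator that recomputes every candidate merge's
within-cluster variance increase directly from the coordinates, and scipy's
ward linkage.  The legacy unsquared variant is checked via its algebraic
relation to the squared variant and against R's hclust.
"""

import shutil
import subprocess
from itertools import combinations

import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

from karyoclust.aberrations import build_frequency_table
from karyoclust.cluster import (DistanceMatrix, WardClustering, adjusted_rand,
                                cophenetic, cut_tree, euclidean_distance,
                                to_newick, ward_linkage)

# ---------------------------------------------------------------------------
# naive oracle: recompute all cluster variances at every step


def naive_ward(X, labels):
    """Exhaustive minimum-variance agglomeration from coordinates.

    Merge cost of (A, B) is ESS(A+B) - ESS(A) - ESS(B); reported height is
    sqrt(2 * cost) (distance scale: two singletons at distance d merge at d).
    Same lexicographic tie-break as the production implementation.
    """
    X = np.asarray(X, dtype=float)

    def ess(idx):
        pts = X[list(idx)]
        return float(((pts - pts.mean(axis=0)) ** 2).sum())

    clusters = [frozenset([i]) for i in range(len(X))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in combinations(clusters, 2):
            cost = ess(a | b) - ess(a) - ess(b)
            la, lb = sorted((min(labels[i] for i in a), min(labels[i] for i in b)))
            key = (cost, la, lb)
            if best is None or key < best[0]:
                best = (key, a, b)
        (cost, _, _), a, b = best
        merges.append((a, b, np.sqrt(2.0 * cost)))
        clusters = [c for c in clusters if c not in (a, b)] + [a | b]
    return merges


def test_euclidean_distance_basics():
    d = euclidean_distance(np.array([[0, 1, 1], [1, 1, 0], [0, 1, 1]]))
    assert d.matrix[0, 2] == 0.0  # identical rows
    assert d.matrix[0, 1] == pytest.approx(np.sqrt(2))
    d1 = euclidean_distance(np.array([[0, 0], [0, 1]]))
    assert d1.matrix[0, 1] == 1.0  # one differing binary coordinate
    with pytest.raises(ValueError):
        euclidean_distance(np.array([[1.0, 2.0]]))
    with pytest.raises(ValueError):
        euclidean_distance(np.array([[1.0], [np.nan]]))


def test_columns_axis_transposes(table1):
    table = build_frequency_table(table1.values())
    d = euclidean_distance(table, axis="columns")
    assert set(d.labels) == set(table.lines)
    assert d.matrix.shape == (4, 4)


def test_two_points_merge_at_their_distance():
    d = DistanceMatrix(("A", "B"), np.array([[0.0, 1.0], [1.0, 0.0]]))
    tree = ward_linkage(d)
    assert len(tree.merges) == 1 and tree.merges[0].height == pytest.approx(1.0)


def test_identical_points_merge_at_height_zero():
    X = np.ones((5, 3))
    tree = ward_linkage(euclidean_distance(X))
    assert all(m.height == 0 for m in tree.merges)


@pytest.mark.parametrize("seed", range(12))
def test_ward_equals_naive_oracle_on_random_instances(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 9))
    X = rng.normal(size=(n, int(rng.integers(1, 4))))
    labels = [f"L{i}" for i in range(n)]
    tree = ward_linkage(DistanceMatrix(tuple(labels), squareform(pdist(X))))
    expected = naive_ward(X, labels)
    for merge, (a, b, h) in zip(tree.merges, expected):
        assert {merge.a, merge.b} == {a, b}
        assert merge.height == pytest.approx(h)


def test_planted_two_cluster_configuration_matches_oracle():
    X = np.array([[0.0, 0], [0.1, 0], [0, 0.1], [5, 5], [5.1, 5], [5, 5.1]])
    labels = list("ABCDEF")
    tree = ward_linkage(DistanceMatrix(tuple(labels), squareform(pdist(X))))
    expected = naive_ward(X, labels)
    assert [{m.a, m.b} for m in tree.merges] == [{a, b} for a, b, _ in expected]
    assert cut_tree(tree, 2) == {"A": 1, "B": 1, "C": 1, "D": 2, "E": 2, "F": 2}


def test_ward_heights_match_scipy():
    rng = np.random.default_rng(42)
    X = rng.normal(size=(15, 4))
    tree = ward_linkage(euclidean_distance(X))
    Z = linkage(pdist(X), method="ward")
    assert np.allclose(sorted(m.height for m in tree.merges), sorted(Z[:, 2]))


def test_legacy_variant_relates_to_squared_input():
    # the unsquared recurrence run on squared distances reproduces the
    # squared heights of the minimum-variance variant
    rng = np.random.default_rng(1)
    X = rng.normal(size=(8, 3))
    d = euclidean_distance(X)
    d2 = DistanceMatrix(d.labels, d.matrix ** 2)
    legacy = ward_linkage(d2, variant="ward.D")
    proper = ward_linkage(d, variant="ward")
    assert np.allclose([m.height for m in legacy.merges],
                       [m.height ** 2 for m in proper.merges])
    assert [{m.a, m.b} for m in legacy.merges] == \
        [{m.a, m.b} for m in proper.merges]


def test_both_variants_match_r_hclust(tmp_path):
    """Merge heights agree with R's hclust ward.D / ward.D2 on a random matrix."""
    rng = np.random.default_rng(7)
    X = rng.normal(size=(9, 3))
    np.savetxt(tmp_path / "x.tsv", X, delimiter="\t")
    script = tmp_path / "ward.R"
    script.write_text(
        'x <- as.matrix(read.table("%s"))\n'
        'd <- dist(x)\n'
        'cat(hclust(d, method="ward.D")$height, "\\n")\n'
        'cat(hclust(d, method="ward.D2")$height, "\\n")\n' % (tmp_path / "x.tsv"))
    rscript = shutil.which("Rscript")
    assert rscript is not None, "Rscript expected on PATH"
    out = subprocess.run([rscript, str(script)], capture_output=True, text=True,
                         check=True).stdout.strip().splitlines()
    r_wardD = [float(v) for v in out[0].split()]
    r_wardD2 = [float(v) for v in out[1].split()]
    d = euclidean_distance(X)
    assert np.allclose([m.height for m in ward_linkage(d, "ward.D").merges], r_wardD)
    assert np.allclose([m.height for m in ward_linkage(d, "ward").merges], r_wardD2)


@pytest.mark.parametrize("variant", ["ward", "ward.D"])
def test_heights_monotone_and_cophenetic_ultrametric(variant):
    rng = np.random.default_rng(11)
    X = rng.normal(size=(10, 3))
    tree = ward_linkage(euclidean_distance(X), variant=variant)
    heights = [m.height for m in tree.merges]
    assert all(h2 >= h1 for h1, h2 in zip(heights, heights[1:]))
    c = cophenetic(tree).matrix
    n = len(c)
    for i in range(n):
        for j in range(n):
            for k in range(n):
                assert c[i, j] <= max(c[i, k], c[j, k]) + 1e-9


def test_permutation_invariance_up_to_isomorphism():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(8, 3))
    labels = [f"L{i}" for i in range(8)]
    perm = rng.permutation(8)
    t1 = ward_linkage(DistanceMatrix(tuple(labels), squareform(pdist(X))))
    t2 = ward_linkage(DistanceMatrix(tuple(labels[i] for i in perm),
                                     squareform(pdist(X[perm]))))
    c1, c2 = t1.cophenetic(), t2.cophenetic()
    for a in labels:
        for b in labels:
            if a != b:
                assert c1.value(a, b) == pytest.approx(c2.value(a, b))


def test_cut_tree_extremes_and_nesting():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(7, 2))
    tree = ward_linkage(euclidean_distance(X))
    assert len(set(cut_tree(tree, 1).values())) == 1
    assert len(set(cut_tree(tree, 7).values())) == 7
    for k in range(1, 7):
        coarse, fine = cut_tree(tree, k), cut_tree(tree, k + 1)
        # refinement: leaves together at k+1 stay together at k
        for a in tree.labels:
            for b in tree.labels:
                if fine[a] == fine[b]:
                    assert coarse[a] == coarse[b]
    with pytest.raises(ValueError):
        cut_tree(tree, 0)
    with pytest.raises(ValueError):
        cut_tree(tree, 8)


def test_cophenetic_basics():
    d = DistanceMatrix(("A", "B"), np.array([[0.0, 2.0], [2.0, 0.0]]))
    tree = ward_linkage(d)
    assert cophenetic(tree).value("A", "B") == pytest.approx(2.0)
    rng = np.random.default_rng(9)
    t = ward_linkage(euclidean_distance(rng.normal(size=(6, 2))))
    assert cophenetic(t).matrix.max() == pytest.approx(t.merges[-1].height)


@pytest.mark.parametrize("variant", ["ward", "ward.D"])
def test_cell_line_tree_isolates_mcf7(table1, variant):
    """T47D and BT474 join first; MCF7 is farther from every line than they
    are from each other, and is the last line to join the tree."""
    table = build_frequency_table(table1.values())
    tree = ward_linkage(euclidean_distance(table, axis="columns"), variant=variant)
    c = cophenetic(tree)
    for other in ("T47D", "BT474", "SKBR3"):
        assert c.value("T47D", "BT474") < c.value("MCF7", other)
    last = tree.merges[-1]
    assert frozenset([tree.labels.index("MCF7")]) in (last.a, last.b)


def test_adjusted_rand_identity_and_relabeling():
    a = {"w": 1, "x": 1, "y": 2, "z": 2}
    assert adjusted_rand(a, a) == 1.0
    assert adjusted_rand(a, {"w": 5, "x": 5, "y": 3, "z": 3}) == 1.0
    with pytest.raises(ValueError):
        adjusted_rand(a, {"w": 1, "x": 1, "y": 2, "q": 2})


def test_adjusted_rand_against_pair_counting():
    # brute force over the 6 leaf pairs of (1,1,2,2) vs (1,2,1,2)
    a = {"p": 1, "q": 1, "r": 2, "s": 2}
    b = {"p": 1, "q": 2, "r": 1, "s": 2}
    keys = sorted(a)
    together_a = {(i, j) for i, j in combinations(keys, 2) if a[i] == a[j]}
    together_b = {(i, j) for i, j in combinations(keys, 2) if b[i] == b[j]}
    n_pairs = 6
    n11 = len(together_a & together_b)
    n00 = len([p for p in combinations(keys, 2)
               if p not in together_a and p not in together_b])
    ri = (n11 + n00) / n_pairs
    expected_ri = (len(together_a) * len(together_b)
                   + (n_pairs - len(together_a)) * (n_pairs - len(together_b))) / n_pairs ** 2
    expected_ari = (ri - expected_ri) / (1 - expected_ri)
    assert adjusted_rand(a, b) == pytest.approx(expected_ari)


def test_newick_two_leaves_midpoint_split():
    d = DistanceMatrix(("A", "B"), np.array([[0.0, 2.0], [2.0, 0.0]]))
    assert to_newick(ward_linkage(d)) == "(A:1,B:1);"


def test_newick_singleton_and_quoting():
    d = DistanceMatrix(("only leaf",), np.zeros((1, 1)))
    tree = ward_linkage(d)
    assert to_newick(tree) == "'only leaf';"


def test_newick_round_trip_recovers_cophenetic():
    import dendropy
    rng = np.random.default_rng(21)
    X = rng.normal(size=(7, 3))
    labels = [f"M_{i}" for i in range(7)]
    tree = ward_linkage(DistanceMatrix(tuple(labels), squareform(pdist(X))))
    parsed = dendropy.Tree.get(data=to_newick(tree), schema="newick",
                               preserve_underscores=True)
    pdm = parsed.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in parsed.taxon_namespace}
    c = cophenetic(tree)
    for a in labels:
        for b in labels:
            if a != b:
                assert pdm.patristic_distance(taxa[a], taxa[b]) == \
                    pytest.approx(c.value(a, b), abs=1e-6)


def test_ward_estimator_sklearn_contract(table1):
    from sklearn.utils.estimator_checks import check_estimator  # noqa: F401
    est = WardClustering(n_clusters=3)
    assert est.get_params() == {"n_clusters": 3, "variant": "ward"}
    X = np.vstack([np.zeros((4, 3)), np.ones((4, 3))])
    labels = est.set_params(n_clusters=2).fit_predict(X)
    assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
    assert est.tree_.n_leaves == 8 and est.n_features_in_ == 3
    with pytest.raises(ValueError):
        WardClustering(n_clusters=9).fit(X)
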