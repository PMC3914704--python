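"""Agglomerative Ward clustering over binary and frequency matrices.

Implements the two analyses this package exists for: clustering metaphases of
one cell line on their binary aberration profiles, and clustering cell lines
on their aberration-frequency vectors — Euclidean distances, Ward's
minimum-variance linkage, tree cutting, cophenetic distances, Newick export.

Ward linkage is implemented directly via the Lance–Williams recurrence so
that tie-breaking is deterministic (lexicographically smallest member label)
and both conventions are available:

- ``variant="ward"``: minimum-variance Ward on *squared* Euclidean
  distances, heights reported on the distance scale (the behavior of
  ``scipy`` ward and R ``hclust(method="ward.D2")``);
- ``variant="ward.D"``: the legacy recurrence applied to unsquared
  distances (old R ``hclust(method="ward")``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import adjusted_rand_score
from sklearn.utils.validation import check_array

__all__ = [
    "DistanceMatrix",
    "LinkageTree",
    "euclidean_distance",
    "ward_linkage",
    "cut_tree",
    "cophenetic",
    "adjusted_rand",
    "to_newick",
    "WardClustering",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Labelled symmetric nonnegative distance matrix with zero diagonal."""

    labels: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(self.labels):
            raise ValueError("distance matrix shape does not match labels")
        if not np.all(np.isfinite(m)):
            raise ValueError("non-finite distances")
        if np.any(m < 0) or not np.allclose(m, m.T) or np.any(np.diag(m) != 0):
            raise ValueError("matrix is not a distance matrix")
        object.__setattr__(self, "matrix", m)

    def __len__(self) -> int:
        return len(self.labels)

    def value(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.matrix[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.labels),
                            columns=list(self.labels))


def euclidean_distance(matrix, axis: str = "rows") -> DistanceMatrix:
    """Pairwise Euclidean distances between rows or columns of ``matrix``.

    ``matrix`` may be a numpy array, a pandas DataFrame, or any object with a
    ``frame`` DataFrame attribute (MetaphaseMatrix, FrequencyTable).
    """
    frame = getattr(matrix, "frame", matrix)
    if isinstance(frame, pd.DataFrame):
        data = frame.to_numpy(dtype=float)
        labels = list(frame.index), list(frame.columns)
    else:
        data = np.asarray(frame, dtype=float)
        labels = ([f"R{i}" for i in range(data.shape[0])],
                  [f"C{i}" for i in range(data.shape[1])])
    if axis == "columns":
        data, names = data.T, labels[1]
    elif axis == "rows":
        names = labels[0]
    else:
        raise ValueError(f"axis must be 'rows' or 'columns', got {axis!r}")
    if data.shape[0] < 2:
        raise ValueError("need at least 2 items to compute distances")
    if not np.all(np.isfinite(data)):
        raise ValueError("missing or non-finite values in input")
    return DistanceMatrix(tuple(str(n) for n in names),
                          squareform(pdist(data, metric="euclidean")))


@dataclass(frozen=True)
class Merge:
    a: frozenset
    b: frozenset
    height: float

    @property
    def members(self) -> frozenset:
        return self.a | self.b


class LinkageTree:
    """Sequence of agglomerative merges with heights over labelled leaves."""

    def __init__(self, labels, merges):
        self.labels = tuple(str(l) for l in labels)
        self.merges = list(merges)
        if len(self.merges) != max(len(self.labels) - 1, 0):
            raise ValueError("a tree over n leaves needs n-1 merges")
        heights = [m.height for m in self.merges]
        if any(h2 < h1 - 1e-9 for h1, h2 in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def cut(self, k: int) -> dict[str, int]:
        """Cluster labels from removing the ``k - 1`` last (highest) merges.

        Cluster ids are 1..k in order of first leaf appearance, so results are
        deterministic and nested as ``k`` grows.
        """
        n = self.n_leaves
        if not 1 <= k <= n:
            raise ValueError(f"k={k} out of range 1..{n}")
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for m in self.merges[: n - k]:
            ra, rb = find(min(m.a)), find(min(m.b))
            parent[rb] = ra
        ids: dict[int, int] = {}
        out: dict[str, int] = {}
        for i, label in enumerate(self.labels):
            root = find(i)
            if root not in ids:
                ids[root] = len(ids) + 1
            out[label] = ids[root]
        return out

    def cophenetic(self) -> DistanceMatrix:
        """Ultrametric matrix: entry (i, j) is the height of the merge joining them."""
        n = self.n_leaves
        m = np.zeros((n, n))
        for merge in self.merges:
            for i in merge.a:
                for j in merge.b:
                    m[i, j] = m[j, i] = merge.height
        return DistanceMatrix(self.labels, m)

    def to_scipy(self) -> np.ndarray:
        """Standard (n-1, 4) linkage matrix for scipy/matplotlib dendrograms."""
        n = self.n_leaves
        ids: dict[frozenset, int] = {frozenset([i]): i for i in range(n)}
        Z = np.zeros((n - 1, 4))
        for step, m in enumerate(self.merges):
            ia, ib = ids[m.a], ids[m.b]
            Z[step] = [min(ia, ib), max(ia, ib), m.height, len(m.members)]
            ids[m.members] = n + step
        return Z


def ward_linkage(d: DistanceMatrix, variant: str = "ward") -> LinkageTree:
    """Ward's method by the Lance–Williams recurrence.

    At each step the pair of clusters with the smallest working distance is
    merged; ties are broken by the lexicographically smallest pair of member
    labels, making runs reproducible.  See the module docstring for the two
    variants.
    """
    if variant not in ("ward", "ward.D"):
        raise ValueError(f"unknown ward variant {variant!r}")
    n = len(d)
    if n < 1:
        raise ValueError("empty distance matrix")
    squared = variant == "ward"
    w = d.matrix ** 2 if squared else d.matrix.copy()
    active: dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
    # smallest member label per cluster, for tie-breaking
    minlab = {i: d.labels[i] for i in range(n)}
    alive = np.ones(n, dtype=bool)
    merges: list[Merge] = []
    for _ in range(n - 1):
        cand = np.where(np.triu(np.outer(alive, alive), 1), w, np.inf)
        wmin = cand.min()
        ties = np.argwhere(cand == wmin)
        i, j = min(map(tuple, ties),
                   key=lambda p: tuple(sorted((minlab[p[0]], minlab[p[1]]))))
        wij = float(wmin)
        height = float(np.sqrt(max(wij, 0.0))) if squared else wij
        if merges and height < merges[-1].height:
            height = merges[-1].height  # guard against ulp-level non-monotonicity
        merges.append(Merge(active[i], active[j], height))
        ni, nj = len(active[i]), len(active[j])
        for k in active:
            if k in (i, j):
                continue
            nk = len(active[k])
            w[i, k] = w[k, i] = ((ni + nk) * w[i, k] + (nj + nk) * w[j, k]
                                 - nk * wij) / (ni + nj + nk)
        active[i] = active[i] | active[j]
        minlab[i] = min(minlab[i], minlab[j])
        del active[j]
        alive[j] = False
    return LinkageTree(d.labels, merges)


def cut_tree(tree: LinkageTree, k: int) -> dict[str, int]:
    return tree.cut(k)


def cophenetic(tree: LinkageTree) -> DistanceMatrix:
    return tree.cophenetic()


def adjusted_rand(a: dict[str, int], b: dict[str, int]) -> float:
    """Permutation-model adjusted Rand index between two leaf labelings."""
    if set(a) != set(b):
        raise ValueError("labelings cover different leaf sets")
    keys = sorted(a)
    return float(adjusted_rand_score([a[k] for k in keys], [b[k] for k in keys]))


_NEWICK_UNSAFE = re.compile(r"[\s()\[\]{}:;,']")


def _quote(label: str) -> str:
    if _NEWICK_UNSAFE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree: LinkageTree) -> str:
    """Newick string with branch lengths encoding merge heights.

    Each internal node sits at half its merge height (midpoint split), so the
    path length between two leaves equals their cophenetic distance.
    """
    if tree.n_leaves == 1:
        return f"{_quote(tree.labels[0])};"
    node_height: dict[frozenset, float] = {frozenset([i]): 0.0
                                           for i in range(tree.n_leaves)}
    newick: dict[frozenset, str] = {frozenset([i]): _quote(lab)
                                    for i, lab in enumerate(tree.labels)}
    for m in tree.merges:
        h = m.height / 2.0
        parts = [f"{newick[c]}:{h - node_height[c]:.10g}" for c in (m.a, m.b)]
        key = m.members
        newick[key] = "(" + ",".join(parts) + ")"
        node_height[key] = h
    return newick[frozenset(range(tree.n_leaves))] + ";"


class WardClustering(ClusterMixin, BaseEstimator):
    """Hierarchical Ward clustering as a scikit-learn estimator.

    Clusters the rows of ``X`` (metaphases on binary profiles, or cell lines
    on frequency vectors) with Euclidean distances and Ward linkage, exposing
    the fitted dendrogram.

    Parameters
    ----------
    n_clusters : int, default 2
        Number of flat clusters returned in ``labels_``.
    variant : {"ward", "ward.D"}, default "ward"
        Linkage convention, see :func:`ward_linkage`.

    Attributes
    ----------
    tree_ : LinkageTree
        The fitted dendrogram.
    labels_ : ndarray of shape (n_samples,)
        Flat cluster ids (0-based) from cutting the tree at ``n_clusters``.
    """

    def __init__(self, n_clusters: int = 2, variant: str = "ward"):
        self.n_clusters = n_clusters
        self.variant = variant

    def fit(self, X, y=None):
        frame = getattr(X, "frame", X)
        if isinstance(frame, pd.DataFrame):
            labels = [str(i) for i in frame.index]
            data = check_array(frame.to_numpy(dtype=float))
        else:
            data = check_array(X)
            labels = [f"R{i}" for i in range(data.shape[0])]
        if not 1 <= self.n_clusters <= data.shape[0]:
            raise ValueError(f"n_clusters={self.n_clusters} out of range")
        d = DistanceMatrix(tuple(labels), squareform(pdist(data)))
        self.tree_ = ward_linkage(d, variant=self.variant)
        cut = self.tree_.cut(self.n_clusters)
        self.labels_ = np.asarray([cut[l] - 1 for l in labels])
        self.n_features_in_ = data.shape[1]
        return self
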