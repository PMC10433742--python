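"""Hierarchical co-expression clustering and cluster-level collective tests.

Genes (or samples) are clustered by average linkage (UPGMA) on the uncentered
Pearson distance d = 1 − Σxy/√(Σx²Σy²) — the Cluster 3.0 similarity metric.
Gene clusters are delimited by a fractional cut of the tree, and each cluster
is scored per group contrast with a "collective p-value": a two-sample Student
t-test on the per-sample means of the cluster's genes. Because each cluster
yields a single test, no multiple-testing correction is applied at this stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform
from scipy import stats

from .matrix import ExpressionMatrix


@dataclass
class LinkageTree:
    """A dendrogram: scipy linkage matrix plus the leaf identifiers.

    ``Z`` rows are (left, right, height, size) merges in scipy convention;
    heights are uncentered-Pearson distances in [0, 2] and non-decreasing
    (average linkage is monotone).
    """

    Z: np.ndarray
    leaf_ids: list[str]
    axis: str = "genes"

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    @property
    def root_height(self) -> float:
        return float(self.Z[-1, 2])

    def leaf_order(self) -> list[str]:
        return [self.leaf_ids[i] for i in leaves_list(self.Z)]


@dataclass
class CollectiveResult:
    """Cluster-level two-group comparison on per-sample cluster means."""

    contrast: tuple[str, str]
    sample_means: pd.Series
    t: float
    p: float
    direction: str  # "up" / "down" in the first group of the contrast


@dataclass
class GeneCluster:
    id: int
    members: list[str]
    collective: dict[tuple[str, str], CollectiveResult] = field(default_factory=dict)
    direction_pattern: dict[tuple[str, str], str] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# distances and linkage
# ---------------------------------------------------------------------------


def uncentered_pearson_distance(x, y) -> float:
    """d = 1 − Σxy/√(Σx²·Σy²); scale-invariant, NOT shift-invariant.

    An all-zero vector has undefined similarity; by convention its similarity
    with anything is 0, hence d = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size == 0:
        raise ValueError("x and y must be 1-D arrays of equal nonzero length")
    nx = np.sqrt((x * x).sum())
    ny = np.sqrt((y * y).sum())
    if nx == 0 or ny == 0:
        return 1.0
    return float(1.0 - (x @ y) / (nx * ny))


def uncentered_distance_matrix(values: np.ndarray) -> np.ndarray:
    """Condensed uncentered-Pearson distance matrix over rows of ``values``."""
    X = np.asarray(values, dtype=float)
    norms = np.sqrt((X * X).sum(axis=1))
    safe = np.where(norms > 0, norms, 1.0)
    U = X / safe[:, None]
    U[norms == 0] = 0.0  # zero rows: similarity 0 with everything
    S = U @ U.T
    np.clip(S, -1.0, 1.0, out=S)
    D = 1.0 - S
    np.fill_diagonal(D, 0.0)
    # exact symmetry for squareform
    D = (D + D.T) / 2.0
    np.clip(D, 0.0, 2.0, out=D)
    return squareform(D, checks=False)


def average_linkage(matrix: ExpressionMatrix, axis: str = "genes") -> LinkageTree:
    """UPGMA dendrogram of genes or samples on the uncentered-Pearson distance."""
    if axis == "genes":
        values, leaf_ids = matrix.values.to_numpy(), matrix.gene_ids
    elif axis == "samples":
        values, leaf_ids = matrix.values.to_numpy().T, matrix.sample_ids
    else:
        raise ValueError(f"axis must be 'genes' or 'samples', got {axis!r}")
    if len(leaf_ids) < 2:
        raise ValueError(f"need at least 2 {axis} to cluster")
    condensed = uncentered_distance_matrix(values)
    if not np.isfinite(condensed).all():
        raise ValueError("non-finite distances; check input for pathological rows")
    Z = linkage(condensed, method="average")
    return LinkageTree(Z, list(leaf_ids), axis)


# ---------------------------------------------------------------------------
# tree cut
# ---------------------------------------------------------------------------


def cut_tree(
    tree: LinkageTree,
    fraction: float = 0.2,
    min_size: int = 10,
    absolute: float | None = None,
) -> list[GeneCluster]:
    """Cut the dendrogram into co-expression clusters.

    The cut height is ``fraction × root merge height`` (relative, the default)
    or the explicit distance ``absolute``. Clusters are the maximal subtrees
    whose internal merges all sit at or below the cut; clusters smaller than
    ``min_size`` are discarded. Cluster ids are numbered 1.. in dendrogram
    leaf order of their first member.
    """
    if absolute is not None:
        h_star = float(absolute)
    else:
        if not 0 <= fraction <= 1:
            raise ValueError("fraction must be in [0, 1]")
        h_star = fraction * tree.root_height
    labels = fcluster(tree.Z, t=h_star, criterion="distance")
    order = leaves_list(tree.Z)
    clusters: list[GeneCluster] = []
    seen: set[int] = set()
    for leaf in order:
        lab = labels[leaf]
        if lab in seen:
            continue
        seen.add(lab)
        members = [tree.leaf_ids[i] for i in np.flatnonzero(labels == lab)]
        if len(members) >= min_size:
            clusters.append(GeneCluster(id=len(clusters) + 1, members=members))
    return clusters


# ---------------------------------------------------------------------------
# collective tests
# ---------------------------------------------------------------------------


def collective_test(
    matrix: ExpressionMatrix,
    cluster: GeneCluster | list[str],
    groupA: str,
    groupB: str,
    welch: bool = False,
) -> CollectiveResult:
    """Student t-test comparing the per-sample cluster-mean between two groups.

    For a singleton cluster this reduces to a per-gene t-test on that gene.
    If both groups have zero within-group variance and equal means, p = 1.
    """
    members = cluster.members if isinstance(cluster, GeneCluster) else list(cluster)
    if not members:
        raise ValueError("empty cluster")
    sub = matrix.values.loc[members]
    means = sub.mean(axis=0)
    a = means[matrix.samples_in_group(groupA)].to_numpy()
    b = means[matrix.samples_in_group(groupB)].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 samples")
    if np.var(a) == 0 and np.var(b) == 0:
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t = np.inf if a.mean() > b.mean() else -np.inf
            p = 0.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=not welch)
        t, p = float(t), float(p)
    direction = "up" if a.mean() > b.mean() else "down"
    return CollectiveResult((groupA, groupB), means, t, p, direction)


def extract_differential_clusters(
    matrix: ExpressionMatrix,
    clusters: list[GeneCluster],
    contrasts: list[tuple[str, str]],
    alpha: float = 0.05,
    welch: bool = False,
) -> list[GeneCluster]:
    """Keep clusters whose collective test separates at least one contrast.

    Each retained cluster is annotated with its direction pattern across the
    contrasts — up/down where the collective p < alpha, "unchanged" otherwise —
    which is how shift patterns such as "down in mimic A, unchanged in mimic B"
    are read off.
    """
    retained: list[GeneCluster] = []
    for cluster in clusters:
        any_sig = False
        for contrast in contrasts:
            result = collective_test(matrix, cluster, *contrast, welch=welch)
            cluster.collective[contrast] = result
            if result.p < alpha:
                cluster.direction_pattern[contrast] = result.direction
                any_sig = True
            else:
                cluster.direction_pattern[contrast] = "unchanged"
        if any_sig:
            retained.append(cluster)
    return retained
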