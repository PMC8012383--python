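"""Agglomerative (AGNES) clustering of LD scores and its evaluation.

Each howl starts as its own cluster; at every step the two closest clusters
are merged, with inter-cluster dissimilarity given by the chosen linkage
(average by default) over Manhattan (L1) point distances.  Cutting the merge
tree at a fixed height — the "clustering scale" — yields the flat clusters
that are read as putative individuals, so the number of distinct clusters is
the estimated number of wolves in the batch.

The agglomeration is implemented here with Lance-Williams updates and fully
declared tie-breaking (lowest merge height first, then the lexicographically
smallest leaf id in each candidate cluster), so dendrograms are reproducible
bit-for-bit regardless of input row order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .exceptions import HowlIdError

logger = logging.getLogger(__name__)

LINKAGES = ("average", "single", "complete")
METRICS = {"manhattan": "cityblock", "euclidean": "euclidean"}


@dataclass
class Dendrogram:
    """AGNES merge tree.

    Leaves are numbered ``0..n-1`` in ``leaf_ids`` order; internal nodes
    continue ``n, n+1, ...`` in merge order (the scipy convention).  Each
    merge records ``(node_a, node_b, height)`` with ``node_a < node_b``.
    """

    leaf_ids: tuple[str, ...]
    merges: tuple[tuple[int, int, float], ...]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    @property
    def heights(self) -> np.ndarray:
        return np.array([h for _, _, h in self.merges])

    def to_linkage(self) -> np.ndarray:
        """Linkage matrix in scipy's ``(n-1) x 4`` format."""
        n = self.n_leaves
        sizes = {i: 1 for i in range(n)}
        Z = np.zeros((n - 1, 4))
        for k, (a, b, h) in enumerate(self.merges):
            size = sizes[a] + sizes[b]
            sizes[n + k] = size
            Z[k] = [a, b, h, size]
        return Z

    def to_newick(self) -> str:
        """Newick string with merge-height differences as branch lengths."""
        n = self.n_leaves
        height = {i: 0.0 for i in range(n)}
        children: dict[int, tuple[int, int]] = {}
        for k, (a, b, h) in enumerate(self.merges):
            node = n + k
            height[node] = h
            children[node] = (a, b)

        def fmt(node: int, parent_h: float) -> str:
            bl = parent_h - height[node]
            if node < n:
                name = self.leaf_ids[node].replace(" ", "_")
                if any(ch in name for ch in "():,;'"):
                    name = "'" + name.replace("'", "''") + "'"
                return f"{name}:{bl:.10g}"
            a, b = children[node]
            h = height[node]
            return f"({fmt(a, h)},{fmt(b, h)}):{bl:.10g}"

        root = n + len(self.merges) - 1
        a, b = children[root]
        h = height[root]
        return f"({fmt(a, h)},{fmt(b, h)});"


@dataclass
class ClusterAssignment:
    """A flat cut of the dendrogram: howl -> cluster index (1-based),
    clusters numbered by first leaf appearance."""

    howl_ids: tuple[str, ...]
    clusters: np.ndarray
    cut_height: float | None = None

    @property
    def n_clusters(self) -> int:
        return len(set(self.clusters.tolist()))

    def as_series(self) -> pd.Series:
        return pd.Series(
            self.clusters, index=pd.Index(self.howl_ids, name="howl_id"),
            name="cluster",
        )


HEIGHT_SCALES = ("raw", "mad", "nn")


def agnes_cluster(
    ld: pd.DataFrame,
    metric: str = "manhattan",
    linkage: str = "average",
    height_scale: str = "raw",
) -> Dendrogram:
    """Build the AGNES dendrogram over LD scores.

    ``ld`` is a DataFrame of coordinates indexed by howl_id.  Duplicate
    coordinates are allowed (they merge at height zero).

    ``height_scale`` sets the units of the dendrogram heights, and hence
    the meaning of a fixed clustering-scale cut:

    - ``"raw"``: heights are plain metric distances in LD units.
    - ``"mad"``: coordinates are first centred and divided by their mean
      absolute deviation within the batch (the AGNES ``stand``
      convention); heights depend on the batch's overall spread.
    - ``"nn"``: distances are divided by the batch's median
      nearest-neighbour distance.  Because each howl's nearest neighbour
      is almost always another howl of the same individual, this scales
      heights by the within-individual spread, so a fixed cut transfers
      across batches regardless of how far apart the individuals happen
      to lie.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(METRICS)}")
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    if height_scale not in HEIGHT_SCALES:
        raise ValueError(
            f"unknown height_scale {height_scale!r}; choose from {HEIGHT_SCALES}"
        )
    X = ld.to_numpy(dtype=float)
    n = len(X)
    if n < 2:
        raise HowlIdError(f"clustering needs at least 2 howls, got {n}")
    if height_scale == "mad":
        center = X.mean(axis=0)
        mad = np.abs(X - center).mean(axis=0)
        mad[mad < 1e-12] = 1.0  # constant coordinate: leave as zeros
        X = (X - center) / mad
    leaf_ids = tuple(str(i) for i in ld.index)

    D = cdist(X, X, METRICS[metric])
    if height_scale == "nn":
        off = D + np.diag(np.full(n, np.inf))
        nn = np.median(off.min(axis=1))
        if nn > 1e-12:
            D = D / nn
    # grow the distance matrix as clusters are created
    dist = np.full((2 * n - 1, 2 * n - 1), np.inf)
    dist[:n, :n] = D
    np.fill_diagonal(dist, np.inf)
    sizes = {i: 1 for i in range(n)}
    # lexicographically smallest leaf id in each cluster, for tie-breaks
    min_leaf = {i: leaf_ids[i] for i in range(n)}
    active: list[int] = list(range(n))
    merges: list[tuple[int, int, float]] = []

    for step in range(n - 1):
        best: tuple[float, str, str, int, int] | None = None
        for ii in range(len(active)):
            a = active[ii]
            for jj in range(ii + 1, len(active)):
                b = active[jj]
                d = dist[a, b]
                lo, hi = sorted((min_leaf[a], min_leaf[b]))
                key = (d, lo, hi, min(a, b), max(a, b))
                if best is None or key < best:
                    best = key
        assert best is not None
        d, _, _, a, b = best
        node = n + step
        merges.append((a, b, float(d)))
        na, nb = sizes[a], sizes[b]
        for c in active:
            if c in (a, b):
                continue
            if linkage == "average":
                dnew = (na * dist[a, c] + nb * dist[b, c]) / (na + nb)
            elif linkage == "single":
                dnew = min(dist[a, c], dist[b, c])
            else:  # complete
                dnew = max(dist[a, c], dist[b, c])
            dist[node, c] = dist[c, node] = dnew
        sizes[node] = na + nb
        min_leaf[node] = min(min_leaf[a], min_leaf[b])
        active.remove(a)
        active.remove(b)
        active.append(node)

    return Dendrogram(leaf_ids=leaf_ids, merges=tuple(merges))


def cut_dendrogram(
    dendrogram: Dendrogram, height: float = 2.2
) -> ClusterAssignment:
    """Cut the merge tree at a clustering scale.

    Merges with height strictly above the cut are removed; the remaining
    connected components are the flat clusters, numbered 1, 2, ... by first
    leaf appearance.
    """
    if height < 0:
        raise HowlIdError(f"cut height must be non-negative, got {height}")
    return _cut(dendrogram, keep=lambda h, k: h <= height, cut_height=height)


def cut_to_k(dendrogram: Dendrogram, n_clusters: int) -> ClusterAssignment:
    """Alternative cut criterion: apply merges in order until exactly
    ``n_clusters`` clusters remain."""
    n = dendrogram.n_leaves
    if not 1 <= n_clusters <= n:
        raise HowlIdError(f"n_clusters must be in 1..{n}, got {n_clusters}")
    n_merges = n - n_clusters
    return _cut(dendrogram, keep=lambda h, k: k < n_merges, cut_height=None)


def _cut(dendrogram: Dendrogram, keep, cut_height) -> ClusterAssignment:
    n = dendrogram.n_leaves
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for k, (a, b, h) in enumerate(dendrogram.merges):
        node = n + k
        if keep(h, k):
            parent[find(a)] = node
            parent[find(b)] = node

    labels = np.empty(n, dtype=int)
    seen: dict[int, int] = {}
    for i in range(n):
        root = find(i)
        if root not in seen:
            seen[root] = len(seen) + 1
        labels[i] = seen[root]
    return ClusterAssignment(
        howl_ids=dendrogram.leaf_ids, clusters=labels, cut_height=cut_height
    )


def count_individuals(assignment: ClusterAssignment) -> int:
    """Estimated number of individuals = number of distinct clusters."""
    return assignment.n_clusters


def calibrate_cut_height(
    dendrogram: Dendrogram,
    true_labels: Mapping[str, str] | pd.Series,
) -> float:
    """Choose the clustering scale from a labelled (training) dendrogram.

    Dendrogram heights depend on the scale of the discriminant scores, so
    a transferable cut must be read off a dendrogram whose identities are
    known: the returned height maximises cluster-to-individual
    identification accuracy on the given labels, preferring (on ties) the
    fewest clusters, and returning the midpoint of the winning height
    interval so the cut has headroom on both sides when reused on a novel
    batch.
    """
    heights = sorted(set(float(h) for h in dendrogram.heights))
    edges = [0.0] + heights + [heights[-1] * 1.1 + 1e-9]

    # score each constant-clustering interval between consecutive merge
    # heights with the one-to-one assignment accuracy: unlike the
    # plurality score it penalises over-splitting (surplus clusters stay
    # unmapped), so the optimum sits where each individual forms one
    # cluster
    best_key: tuple[float, int] | None = None
    best_interval: tuple[float, float] | None = None
    for lo, hi in zip(edges[:-1], edges[1:]):
        cand = 0.5 * (lo + hi)
        assignment = cut_dendrogram(dendrogram, cand)
        acc = evaluate_identification(
            assignment, true_labels, one_to_one=True
        ).accuracy
        key = (-acc, assignment.n_clusters)
        if best_key is None or key < best_key:
            best_key = key
            best_interval = (lo, hi)
    assert best_interval is not None
    lo, hi = best_interval
    # The interval's lower edge (the largest merge height kept, i.e. the
    # within-individual scale) transfers to new batches up to a modest
    # out-of-sample inflation; its upper edge (the nearest between-
    # individual merge) is specific to this batch's individuals.  Anchor
    # the cut just above the within edge rather than mid-interval.
    return float(min(1.75 * lo, 0.5 * (lo + hi))) if lo > 0 else 0.5 * (lo + hi)


@dataclass
class ConfusionMatrix:
    """Cluster-based identification accuracy against known identities.

    ``counts`` is a true-individual x assigned-individual table;
    ``cluster_map`` records which individual each cluster was read as.
    """

    counts: pd.DataFrame
    row_percent: pd.DataFrame
    accuracy: float
    cluster_map: dict[int, str | None]

    @property
    def n_correct(self) -> int:
        shared = [c for c in self.counts.index if c in self.counts.columns]
        return int(sum(self.counts.loc[c, c] for c in shared))

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


def evaluate_identification(
    assignment: ClusterAssignment,
    true_labels: Mapping[str, str] | pd.Series,
    one_to_one: bool = False,
) -> ConfusionMatrix:
    """Map clusters to individuals and score the identification.

    Each cluster is read as the individual holding the plurality of its
    members; ties go to the individual with more howls overall, then to the
    lexicographically first (ties are logged).  With ``one_to_one=True`` an
    optimal one-to-one cluster-to-individual assignment maximising the
    number of correct howls is used instead (clusters beyond the number of
    individuals stay unmapped).
    """
    if isinstance(true_labels, pd.Series):
        true_labels = true_labels.to_dict()
    missing = [h for h in assignment.howl_ids if h not in true_labels or true_labels[h] is None]
    if missing:
        raise HowlIdError(f"howl(s) without a true label: {missing}")

    truth = [str(true_labels[h]) for h in assignment.howl_ids]
    individuals = sorted(set(truth))
    total_per_ind = {c: truth.count(c) for c in individuals}
    cluster_ids = sorted(set(assignment.clusters.tolist()))

    # cluster x individual membership counts
    comp = pd.DataFrame(0, index=cluster_ids, columns=individuals, dtype=int)
    for h, k, lab in zip(assignment.howl_ids, assignment.clusters, truth):
        comp.loc[k, lab] += 1

    cluster_map: dict[int, str | None] = {}
    if one_to_one:
        cost = -comp.to_numpy(dtype=float)
        rows, cols = linear_sum_assignment(cost)
        for r, c in zip(rows, cols):
            cluster_map[cluster_ids[r]] = individuals[c]
        for k in cluster_ids:
            cluster_map.setdefault(k, None)
    else:
        for k in cluster_ids:
            row = comp.loc[k]
            best = row.max()
            tied = sorted(row.index[row == best])
            if len(tied) > 1:
                tied.sort(key=lambda c: (-total_per_ind[c], c))
                logger.warning(
                    "cluster %s plurality tie between %s; mapped to %s",
                    k,
                    tied,
                    tied[0],
                )
            cluster_map[k] = tied[0]

    assigned = [cluster_map[k] for k in assignment.clusters]
    col_names = sorted(
        set(individuals) | {a for a in assigned if a is not None}
    )
    counts = pd.DataFrame(0, index=individuals, columns=col_names + ["unassigned"], dtype=int)
    for lab, a in zip(truth, assigned):
        counts.loc[lab, a if a is not None else "unassigned"] += 1
    if counts["unassigned"].sum() == 0:
        counts = counts.drop(columns="unassigned")

    correct = sum(1 for lab, a in zip(truth, assigned) if a == lab)
    accuracy = correct / len(truth)
    row_percent = counts.div(counts.sum(axis=1), axis=0) * 100.0
    return ConfusionMatrix(
        counts=counts,
        row_percent=row_percent,
        accuracy=accuracy,
        cluster_map=cluster_map,
    )
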