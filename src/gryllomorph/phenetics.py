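"""Procrustes distance matrices and UPGMA phenograms.

A phenogram summarizes overall phenetic similarity (not an explicit
phylogeny): pairwise partial Procrustes distances among genus consensus
shapes are clustered by UPGMA — unweighted pair-group method with arithmetic
averages, i.e. agglomerative average linkage with size-weighted updates.
Merge heights are half the inter-cluster distance, so the root-to-leaf path
equals half the cophenetic distance (the molecular-phenetics convention) and
the cophenetic matrix is ultrametric.

Ties in the minimum inter-cluster distance are broken by the lexicographically
smallest pair of cluster indices (leaves numbered in input order, merged
clusters in creation order), which makes the procedure deterministic.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
from scipy.stats import pearsonr

from .procrustes import partial_procrustes_distance
from .tps_io import Configuration

__all__ = [
    "DistanceMatrix",
    "distance_matrix",
    "UltrametricTree",
    "upgma",
    "cophenetic_correlation",
]


@dataclasses.dataclass
class DistanceMatrix:
    """Square symmetric nonnegative matrix with a zero diagonal, plus labels."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if d.shape != (n, n):
            raise ValueError(f"matrix shape {d.shape} does not match {n} labels")
        if not np.allclose(d, d.T, atol=1e-8):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(d) != 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(d < 0.0):
            raise ValueError("distances must be nonnegative")
        self.d = 0.5 * (d + d.T)

    def __len__(self) -> int:
        return len(self.labels)

    def reordered(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(lab) for lab in labels]
        return DistanceMatrix(labels=list(labels), d=self.d[np.ix_(idx, idx)])


def distance_matrix(
    consensuses: Mapping[str, Configuration], allow_reflection: bool = False
) -> DistanceMatrix:
    """Pairwise partial Procrustes distances among consensus configurations."""
    labels = list(consensuses.keys())
    if len(labels) < 2:
        raise ValueError("need at least 2 configurations")
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dij = partial_procrustes_distance(
                consensuses[labels[i]], consensuses[labels[j]], allow_reflection
            )
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(labels=labels, d=d)


@dataclasses.dataclass
class UltrametricTree:
    """UPGMA merge history.

    Cluster ids: leaves are 0..n-1 in ``leaves`` order; the i-th merge
    creates cluster n+i.  ``merges`` holds (cluster_a, cluster_b, height)
    with nondecreasing heights.
    """

    leaves: list[str]
    merges: list[tuple[int, int, float]]

    def __post_init__(self) -> None:
        n = len(self.leaves)
        if n >= 2 and len(self.merges) != n - 1:
            raise ValueError(f"{n} leaves require {n - 1} merges")
        heights = [h for _, _, h in self.merges]
        if any(b < a - 1e-12 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be nondecreasing")

    @property
    def height(self) -> float:
        return self.merges[-1][2] if self.merges else 0.0

    def clades(self) -> list[frozenset[str]]:
        """Leaf-label sets of every internal node, in merge order."""
        n = len(self.leaves)
        members: dict[int, frozenset[str]] = {
            i: frozenset([lab]) for i, lab in enumerate(self.leaves)
        }
        out = []
        nid = n
        for a, b, _ in self.merges:
            members[nid] = members[a] | members[b]
            out.append(members[nid])
            nid += 1
        return out

    def cophenetic_matrix(self) -> DistanceMatrix:
        """Pairwise cophenetic distances (twice the merge height joining each pair)."""
        n = len(self.leaves)
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        coph = np.zeros((n, n))
        nid = n
        for a, b, h in self.merges:
            ma, mb = members.pop(a), members.pop(b)
            for i in ma:
                for j in mb:
                    coph[i, j] = coph[j, i] = 2.0 * h
            members[nid] = ma + mb
            nid += 1
        return DistanceMatrix(labels=list(self.leaves), d=coph)


def upgma(distmat: DistanceMatrix) -> UltrametricTree:
    """Average-linkage (UPGMA proper, size-weighted) clustering of a distance matrix.

    Repeatedly merges the cluster pair with minimal average inter-cluster
    distance at height d/2; after a merge, distances to the new cluster are
    size-weighted arithmetic averages of the distances to its parts.
    """
    n = len(distmat)
    if n < 2:
        raise ValueError("UPGMA needs at least 2 taxa")
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(distmat.d[i, j])
    sizes: dict[int, int] = {i: 1 for i in range(n)}
    active: list[int] = list(range(n))
    merges: list[tuple[int, int, float]] = []
    nid = n
    while len(active) > 1:
        best: tuple[int, int] | None = None
        best_d = np.inf
        for ia, a in enumerate(active):
            for b in active[ia + 1 :]:
                dab = dist[(a, b)]
                # strict < keeps the lexicographically smallest pair on ties
                if dab < best_d:
                    best_d, best = dab, (a, b)
        assert best is not None
        a, b = best
        na, nb = sizes[a], sizes[b]
        for c in active:
            if c in (a, b):
                continue
            key = lambda u, v: (u, v) if u < v else (v, u)  # noqa: E731
            dac = dist.pop(key(a, c))
            dbc = dist.pop(key(b, c))
            dist[(c, nid)] = (na * dac + nb * dbc) / (na + nb)
        del dist[(a, b)]
        merges.append((a, b, best_d / 2.0))
        sizes[nid] = na + nb
        active = [c for c in active if c not in (a, b)] + [nid]
        nid += 1
    return UltrametricTree(leaves=list(distmat.labels), merges=merges)


def cophenetic_correlation(tree: UltrametricTree, distmat: DistanceMatrix) -> float:
    """Pearson correlation between original and cophenetic distances over all pairs."""
    if set(tree.leaves) != set(distmat.labels):
        raise ValueError("tree and distance matrix label sets differ")
    if len(tree.leaves) < 3:
        raise ValueError("cophenetic correlation undefined for fewer than 3 leaves")
    dm = distmat.reordered(tree.leaves)
    coph = tree.cophenetic_matrix()
    iu = np.triu_indices(len(tree.leaves), k=1)
    return float(pearsonr(dm.d[iu], coph.d[iu]).statistic)
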