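"""PCA of state-level profiles and minimum-spanning-tree trajectories.

Disease-state profiles (aggregated gene expression or predicted fluxes) are
projected onto principal components; an MST over Euclidean distances in the
retained PC space links each state to its nearest neighbours, and a
depth-first walk from a chosen root reads off a pseudo-temporal ordering,
with tree nodes of degree >= 3 reported as branch points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "StateMatrix",
    "TrajectoryResult",
    "pca",
    "minimum_spanning_tree",
    "extract_trajectory",
    "pc_variance_cutoff",
]

#: retain the leading PCs covering this fraction of variance for MST distances
PC_VARIANCE_TARGET = 0.9


@dataclass
class StateMatrix:
    """Observations (states) x features (genes or reactions) matrix."""

    values: pd.DataFrame
    feature_kind: str = "genes"   # genes | non_metabolic_genes | metabolic_genes | slc_genes | fluxes

    @property
    def observations(self) -> list[str]:
        return list(self.values.index)


@dataclass
class TrajectoryResult:
    pc_coordinates: pd.DataFrame = field(default_factory=pd.DataFrame)
    loadings: pd.DataFrame = field(default_factory=pd.DataFrame)   # components x features
    variance_explained: np.ndarray = field(default_factory=lambda: np.array([]))
    mst_edges: list[tuple[str, str, float]] = field(default_factory=list)
    orderings: dict[str, list[str]] = field(default_factory=dict)
    branch_points: list[str] = field(default_factory=list)


def pca(
    matrix: StateMatrix | pd.DataFrame,
    n_components: int | None = None,
    scale: bool | None = None,
) -> TrajectoryResult:
    """Principal component analysis of state profiles.

    Features are always centered; unit scaling defaults on for gene
    matrices and off for flux matrices (fluxes share units).  Component
    signs are fixed so the largest-magnitude loading of each axis is
    positive, making outputs reproducible.  A matrix with no variance at
    all is an error.
    """
    if isinstance(matrix, StateMatrix):
        df = matrix.values
        if scale is None:
            scale = matrix.feature_kind != "fluxes"
    else:
        df = matrix
        if scale is None:
            scale = True
    X = df.values.astype(float)
    n_obs, n_feat = X.shape
    Xc = X - X.mean(axis=0, keepdims=True)
    if not np.any(np.abs(Xc) > 0):
        raise ValueError("constant matrix: no variance to decompose")
    if scale:
        sd = Xc.std(axis=0, ddof=0, keepdims=True)
        Xc = np.where(sd > 0, Xc / np.where(sd == 0, 1, sd), 0.0)
    max_comp = min(n_obs - 1, n_feat) if n_obs > 1 else 1
    if n_components is None:
        n_components = max_comp
    if n_components > min(n_obs, n_feat):
        raise ValueError("n_components exceeds matrix dimensions")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    s = s[:max_comp]
    U = U[:, :max_comp]
    Vt = Vt[:max_comp]
    # sign convention: largest-|loading| positive per component
    for i in range(len(s)):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    var = s**2
    total = var.sum()
    ratios = var / total if total > 0 else var
    k = min(n_components, len(s))
    coords = pd.DataFrame(
        U[:, :k] * s[:k],
        index=df.index,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    loadings = pd.DataFrame(
        Vt[:k], index=[f"PC{i + 1}" for i in range(k)], columns=df.columns
    )
    return TrajectoryResult(
        pc_coordinates=coords, loadings=loadings, variance_explained=ratios[:k]
    )


def pc_variance_cutoff(ratios: np.ndarray, target: float = PC_VARIANCE_TARGET) -> int:
    """Smallest number of leading PCs whose variance share reaches target."""
    csum = np.cumsum(ratios)
    idx = int(np.searchsorted(csum, target - 1e-12)) + 1
    return min(idx, len(ratios))


def minimum_spanning_tree(
    points: pd.DataFrame | None = None,
    distances: pd.DataFrame | None = None,
) -> list[tuple[str, str, float]]:
    """MST over states from PC coordinates (Euclidean) or a distance matrix.

    Kruskal with edges sorted by (weight, label pair) so equal-weight ties
    always break to the lexicographically smallest edge.  Returns n-1
    edges (u, v, weight) with u < v.
    """
    if (points is None) == (distances is None):
        raise ValueError("provide exactly one of points or distances")
    if distances is None:
        X = points.values.astype(float)
        labels = list(points.index)
        diff = X[:, None, :] - X[None, :, :]
        D = np.sqrt((diff**2).sum(axis=2))
    else:
        labels = list(distances.index)
        D = distances.values.astype(float)
        if list(distances.columns) != labels or not np.allclose(D, D.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric with matching labels")
        if (D < 0).any():
            raise ValueError("distances must be non-negative")
    n = len(labels)
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            u, v = sorted((labels[i], labels[j]))
            edges.append((float(D[i, j]), u, v))
    edges.sort()
    uf = nx.utils.UnionFind(labels)
    mst = []
    for w, u, v in edges:
        if uf[u] != uf[v]:
            uf.union(u, v)
            mst.append((u, v, w))
        if len(mst) == n - 1:
            break
    return mst


def extract_trajectory(
    mst_edges: list[tuple[str, str, float]],
    root: str,
) -> tuple[list[str], list[str]]:
    """Depth-first pseudo-temporal ordering of states from a root.

    Neighbours are visited in lexicographic order for determinism; nodes of
    tree degree >= 3 are reported as branch points.  A path-graph tree
    rooted at an end yields a total order.
    """
    G = nx.Graph()
    for u, v, w in mst_edges:
        G.add_edge(u, v, weight=w)
    if root not in G:
        raise ValueError(f"root {root!r} is not a node of the tree")
    ordering = []
    visited = set()
    stack = [root]
    while stack:
        node = stack.pop()
        if node in visited:
            continue
        visited.add(node)
        ordering.append(node)
        stack.extend(sorted((n for n in G.neighbors(node) if n not in visited),
                            reverse=True))
    branch_points = sorted(n for n in G.nodes if G.degree(n) >= 3)
    return ordering, branch_points
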