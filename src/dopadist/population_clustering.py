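"""Hierarchical clustering of PSTHs on their first two principal components.

PSTH matrices (units x bins of smoothed z scores) are column-centered and
decomposed by SVD; the two leading component scores feed agglomerative
clustering with average linkage on Euclidean distances.  Cluster/population
enrichment tables summarize how projection-defined populations distribute
over clusters.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree

__all__ = [
    "PSTHMatrix",
    "Dendrogram",
    "ClusterAssignment",
    "extract_pcs",
    "hcluster_average_euclidean",
    "cut_dendrogram",
    "population_enrichment",
    "dendrogram_to_newick",
]


@dataclass
class PSTHMatrix:
    values: np.ndarray                   # units x bins, smoothed z
    unit_ids: list[str]
    labels: list[str] | None = None      # optional population labels

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 2:
            raise ValueError("PSTH matrix must be 2-D (units x bins)")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("PSTH matrix contains missing values")
        if len(self.unit_ids) != self.values.shape[0]:
            raise ValueError("unit_ids length mismatch")


@dataclass
class Dendrogram:
    merges: np.ndarray                   # scipy linkage matrix (n-1 x 4)
    unit_ids: list[str]

    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


@dataclass
class ClusterAssignment:
    assignment: dict[str, int]
    k: int


def extract_pcs(matrix: PSTHMatrix, n_components: int = 2) -> np.ndarray:
    """Scores on the leading principal components of the column-centered
    matrix (SVD), with a deterministic sign convention: each component's
    largest-magnitude loading is positive."""
    X = matrix.values
    if X.shape[0] < 3:
        raise ValueError("need at least 3 units")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    if np.sum(S > 1e-12 * S[0]) < n_components:
        raise ValueError(f"matrix rank below {n_components}")
    scores = U[:, :n_components] * S[:n_components]
    for j in range(n_components):
        lead = np.argmax(np.abs(Vt[j]))
        if Vt[j, lead] < 0:
            scores[:, j] = -scores[:, j]
    return scores


def explained_variance_ratio(matrix: PSTHMatrix) -> np.ndarray:
    Xc = matrix.values - matrix.values.mean(axis=0, keepdims=True)
    s = np.linalg.svd(Xc, compute_uv=False)
    return s**2 / np.sum(s**2)


def hcluster_average_euclidean(scores: np.ndarray,
                               unit_ids: list[str] | None = None) -> Dendrogram:
    """Agglomerative clustering, average linkage, Euclidean distances."""
    scores = np.asarray(scores, float)
    if scores.shape[0] < 2:
        raise ValueError("need at least 2 points")
    if unit_ids is None:
        unit_ids = [f"u{i}" for i in range(scores.shape[0])]
    Z = linkage(scores, method="average", metric="euclidean")
    return Dendrogram(Z, list(unit_ids))


def cut_dendrogram(d: Dendrogram, k: int) -> ClusterAssignment:
    """Cut into exactly k clusters (at the (n-k)-th merge)."""
    n = len(d.unit_ids)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    flat = fcluster(d.merges, t=k, criterion="maxclust")
    return ClusterAssignment({u: int(c) for u, c in zip(d.unit_ids, flat)}, k)


def population_enrichment(assignment: ClusterAssignment,
                          labels: dict[str, str]) -> pd.DataFrame:
    """Long-form enrichment table: per (cluster, population) the fraction of
    the cluster made of that population, plus per-population modal cluster
    and the fraction of the population it captures."""
    units = list(assignment.assignment)
    if set(units) != set(labels):
        raise ValueError("assignment and labels cover different units")
    df = pd.DataFrame({
        "unit_id": units,
        "cluster": [assignment.assignment[u] for u in units],
        "population": [labels[u] for u in units],
    })
    frac_in_cluster = (df.groupby(["cluster", "population"]).size()
                       / df.groupby("cluster").size()).rename("fraction_of_cluster")
    frac_of_pop = (df.groupby(["cluster", "population"]).size()
                   / df.groupby("population").size()).rename("fraction_of_population")
    out = pd.concat([frac_in_cluster, frac_of_pop], axis=1).reset_index()
    modal = (out.sort_values("fraction_of_population", ascending=False)
             .groupby("population").first()["cluster"].rename("modal_cluster"))
    return out.merge(modal, on="population")


def modal_cluster_fractions(assignment: ClusterAssignment,
                            labels: dict[str, str]) -> dict[str, float]:
    """Per population, the fraction of its units in its modal cluster."""
    table = population_enrichment(assignment, labels)
    best = table.groupby("population")["fraction_of_population"].max()
    return {str(k): float(v) for k, v in best.items()}


def dendrogram_to_newick(d: Dendrogram) -> str:
    """Serialize the merge tree to Newick (branch lengths from merge heights)."""
    tree = to_tree(d.merges)

    def render(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{d.unit_ids[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return render(tree, tree.dist) + ";"
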