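"""Contact-based cell-cell communication scoring.

Physical contacts are read off the element clouds: a k-nearest-neighbor
(k = 8) graph over all elements pooled, with two cells in contact whenever
any cross-cell element neighbor relation exists (in either direction).  A
directed per-contact score s_ij = g_i^L * g_j^R is computed for every
ligand-receptor pair, aggregated to directed cluster pairs as
S_IJ = sum_{i in I, j in J} s_ij / (N_I N_J) (non-contact pairs contribute
zero), and tested against a label-permutation null with the add-one
p-value estimator (r + 1)/(n + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .io import ExpressionMatrix, LRDatabase
from .shapes import CellShapes

__all__ = [
    "ContactGraph",
    "CommResult",
    "contact_graph",
    "communication_scores",
    "cluster_communication",
    "permutation_test",
]


@dataclass
class ContactGraph:
    """Undirected cell-cell contact edges."""

    edges: set[tuple[int, int]]
    n_cells: int

    def __post_init__(self) -> None:
        cleaned = set()
        for i, j in self.edges:
            if i == j:
                raise ValueError("self-contacts are not allowed")
            cleaned.add((min(i, j), max(i, j)))
        self.edges = cleaned

    def has_edge(self, i: int, j: int) -> bool:
        return (min(i, j), max(i, j)) in self.edges

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class CommResult:
    """Edge-level and cluster-level communication scores."""

    # directed: (cell_i, cell_j, ligand, receptor) -> score
    edge_scores: dict[tuple[int, int, str, str], float] = field(default_factory=dict)
    # directed: (cluster_I, cluster_J, ligand, receptor) -> mean score
    cluster_scores: dict[tuple[str, str, str, str], float] = field(default_factory=dict)
    p_values: dict[tuple[str, str, str, str], float] = field(default_factory=dict)
    significant: dict[tuple[str, str, str, str], bool] = field(default_factory=dict)
    labels: list[str] | None = None


def contact_graph(shapes: CellShapes, k: int = 8) -> ContactGraph:
    """kNN contact graph over the pooled element set."""
    N, n_e, _ = shapes.elements.shape
    if N < 2:
        raise ValueError("need at least two cells for a contact graph")
    pooled = shapes.elements.reshape(N * n_e, 2)
    owner = np.repeat(np.arange(N), n_e)
    total = pooled.shape[0]
    if total <= k:
        warnings.warn(f"only {total} elements; reducing k from {k} to {total - 1}")
        k = total - 1
    tree = cKDTree(pooled)
    _, idx = tree.query(pooled, k=k + 1)   # first neighbor is the element itself
    edges: set[tuple[int, int]] = set()
    src = owner.repeat(k)
    dst = owner[idx[:, 1:].ravel()]
    cross = src != dst
    for i, j in zip(src[cross], dst[cross]):
        edges.add((min(int(i), int(j)), max(int(i), int(j))))
    return ContactGraph(edges, N)


def communication_scores(
    E_cells: ExpressionMatrix, db: LRDatabase, graph: ContactGraph
) -> CommResult:
    """Directed per-contact scores s_ij^LR = g_i^L * g_j^R for both edge
    orientations; zero-score entries are recorded only implicitly."""
    gidx = {g: i for i, g in enumerate(E_cells.gene_ids)}
    result = CommResult(labels=E_cells.labels)
    for lig, rec, _path in db.pairs:
        li, ri = gidx.get(lig), gidx.get(rec)
        if li is None or ri is None:
            continue
        L = E_cells.values[:, li]
        R = E_cells.values[:, ri]
        for i, j in graph.edges:
            s_ij = float(L[i] * R[j])
            s_ji = float(L[j] * R[i])
            if s_ij > 0:
                result.edge_scores[(i, j, lig, rec)] = s_ij
            if s_ji > 0:
                result.edge_scores[(j, i, lig, rec)] = s_ji
    return result


def _cluster_matrix(
    edge_scores: dict[tuple[int, int, str, str], float],
    labels: np.ndarray,
    clusters: list[str],
) -> dict[tuple[str, str, str, str], float]:
    counts = {c: int((labels == c).sum()) for c in clusters}
    for c, n in counts.items():
        if n == 0:
            raise ValueError(f"cluster {c!r} has zero cells")
    sums: dict[tuple[str, str, str, str], float] = {}
    for (i, j, lig, rec), s in edge_scores.items():
        key = (str(labels[i]), str(labels[j]), lig, rec)
        sums[key] = sums.get(key, 0.0) + s
    return {
        (I, J, lig, rec): s / (counts[I] * counts[J])
        for (I, J, lig, rec), s in sums.items()
    }


def cluster_communication(result: CommResult, labels: list[str] | None = None) -> CommResult:
    """Directed cluster-pair means over ALL cell pairs (denominator N_I N_J;
    non-contact pairs contribute zero)."""
    if labels is None:
        labels = result.labels
    if labels is None:
        raise ValueError("cluster labels are required")
    lab = np.asarray([str(x) for x in labels])
    clusters = sorted(set(lab))
    out = CommResult(edge_scores=dict(result.edge_scores), labels=list(lab))
    out.cluster_scores = _cluster_matrix(result.edge_scores, lab, clusters)
    return out


def permutation_test(
    result: CommResult,
    labels: list[str] | None = None,
    n_perm: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
) -> CommResult:
    """Label-permutation null for every observed cluster-pair/LR combination.

    p = (1 + #{S_perm >= S_obs}) / (n_perm + 1); significant iff p < alpha.
    """
    if labels is None:
        labels = result.labels
    if labels is None:
        raise ValueError("cluster labels are required")
    lab = np.asarray([str(x) for x in labels])
    clusters = sorted(set(lab))
    if len(clusters) < 2:
        raise ValueError("need at least two clusters")
    out = cluster_communication(result, list(lab))
    observed = out.cluster_scores
    exceed = {key: 0 for key in observed}
    rng = np.random.default_rng(seed)
    for _ in range(n_perm):
        perm = rng.permutation(lab)
        perm_scores = _cluster_matrix(result.edge_scores, perm, clusters)
        for key, obs in observed.items():
            if perm_scores.get(key, 0.0) >= obs:
                exceed[key] += 1
    out.p_values = {
        key: (1 + r) / (n_perm + 1) for key, r in exceed.items()
    }
    out.significant = {key: p < alpha for key, p in out.p_values.items()}
    return out
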