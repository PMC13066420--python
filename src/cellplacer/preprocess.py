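"""Standard expression preprocessing.

Cells expressing two or fewer genes are dropped, then genes detected in two
or fewer cells; each remaining cell is scaled to the median pre-scaling
total count and log1p-transformed.  Marker genes are picked by a one-vs-rest
Welch t-test (top 100 per type), the low-dimensional embedding is a 50-PC
PCA with a fixed sign convention, and ligand/receptor genes must be detected
in at least 1% of cells to survive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .io import ExpressionMatrix, LRDatabase

__all__ = [
    "EmbeddingMatrix",
    "filter_and_normalize",
    "shared_genes",
    "select_marker_genes",
    "pca_embed",
    "filter_lr_genes",
    "leiden_labels",
]

MIN_GENES_PER_CELL = 3   # ">2 detected genes"
MIN_CELLS_PER_GENE = 3   # ">2 cells"
N_MARKERS = 100
N_PCS = 50
LR_MIN_FRAC = 0.01


@dataclass
class EmbeddingMatrix:
    """Observations x d real embedding (default d = 50)."""

    vectors: np.ndarray
    method: str = "pca"

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2:
            raise ValueError("embedding must be 2-D")
        if not np.isfinite(self.vectors).all():
            raise ValueError("embedding contains non-finite values")

    @property
    def n_obs(self) -> int:
        return self.vectors.shape[0]


def filter_and_normalize(
    E: ExpressionMatrix,
    min_genes_per_cell: int = MIN_GENES_PER_CELL,
    min_cells_per_gene: int = MIN_CELLS_PER_GENE,
) -> ExpressionMatrix:
    """Filter low-coverage cells then genes, median-count normalize, log1p.

    The step order is fixed: cell filter, gene filter, per-cell scaling to
    the median pre-scaling total, log1p.
    """
    detected = E.values > 0
    keep_cells = detected.sum(axis=1) >= min_genes_per_cell
    if not keep_cells.any():
        raise ValueError("all cells removed by the cell filter")
    vals = E.values[keep_cells]
    keep_genes = (vals > 0).sum(axis=0) >= min_cells_per_gene
    vals = vals[:, keep_genes]
    if vals.shape[1] == 0:
        raise ValueError("all genes removed by the gene filter")

    totals = vals.sum(axis=1)
    target = float(np.median(totals))
    scale = np.where(totals > 0, target / np.maximum(totals, 1e-300), 0.0)
    vals = np.log1p(vals * scale[:, None])

    obs_idx = np.flatnonzero(keep_cells)
    return ExpressionMatrix(
        vals,
        [E.obs_ids[i] for i in obs_idx],
        [g for g, k in zip(E.gene_ids, keep_genes) if k],
        None if E.labels is None else [E.labels[i] for i in obs_idx],
    )


def shared_genes(
    E_sc: ExpressionMatrix, E_st: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Reduce both matrices to their shared genes, in a common order."""
    common = [g for g in E_sc.gene_ids if g in set(E_st.gene_ids)]
    if not common:
        raise ValueError("no shared genes between the two datasets")
    return E_sc.subset_genes(common), E_st.subset_genes(common)


def _welch_t(group: np.ndarray, rest: np.ndarray) -> np.ndarray:
    """Vectorized one-vs-rest Welch t-statistic per gene (column)."""
    n1, n2 = group.shape[0], rest.shape[0]
    m1, m2 = group.mean(axis=0), rest.mean(axis=0)
    v1 = group.var(axis=0, ddof=1)
    v2 = rest.var(axis=0, ddof=1)
    denom = np.sqrt(v1 / n1 + v2 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / denom
    # zero-variance genes with equal means carry no signal
    t[~np.isfinite(t)] = 0.0
    return t


def select_marker_genes(
    E: ExpressionMatrix,
    labels: list[str] | None = None,
    n_markers: int = N_MARKERS,
    seed: int = 0,
) -> list[str]:
    """Union of the top ``n_markers`` one-vs-rest t-statistic genes per type.

    If no labels are supplied, Leiden clustering on the kNN graph of the
    50-PC embedding provides them.  Ties are broken by gene id and the
    returned list is sorted by gene id for determinism.
    """
    if labels is None:
        labels = E.labels
    if labels is None:
        labels = leiden_labels(E, seed=seed)
    labels = list(labels)
    if len(labels) != E.n_obs:
        raise ValueError("labels length must match number of cells")
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValueError("need at least two cell types for marker selection")
    lab_arr = np.asarray(labels)
    selected: set[str] = set()
    genes = np.asarray(E.gene_ids)
    for lab in uniq:
        mask = lab_arr == lab
        if mask.sum() < 2 or (~mask).sum() < 2:
            raise ValueError(f"cell type {lab!r} has fewer than 2 cells")
        t = _welch_t(E.values[mask], E.values[~mask])
        # sort by descending t, then gene id for deterministic ties
        order = np.lexsort((genes, -t))
        selected.update(genes[order[:n_markers]])
    return sorted(selected)


def leiden_labels(
    E: ExpressionMatrix, n_neighbors: int = 15, resolution: float = 1.0, seed: int = 0
) -> list[str]:
    """Leiden clustering on the kNN graph of the PCA embedding (fallback
    when no cell-type annotation is available)."""
    import igraph
    import leidenalg
    from sklearn.neighbors import NearestNeighbors

    emb = pca_embed(E).vectors
    k = min(n_neighbors, E.n_obs - 1)
    nn = NearestNeighbors(n_neighbors=k).fit(emb)
    _, idx = nn.kneighbors(emb)
    edges = {(min(i, j), max(i, j)) for i in range(E.n_obs) for j in idx[i] if i != j}
    graph = igraph.Graph(n=E.n_obs, edges=sorted(edges))
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
    )
    return [str(m) for m in part.membership]


def pca_embed(E: ExpressionMatrix | np.ndarray, d: int = N_PCS) -> EmbeddingMatrix:
    """Centered PCA retaining ``min(d, rank)`` components.

    Sign convention: each component's largest-magnitude loading is positive,
    so the embedding is deterministic across runs and LAPACK builds.
    """
    X = E.values if isinstance(E, ExpressionMatrix) else np.asarray(E, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA requires at least two observations")
    d_eff = int(min(d, X.shape[0] - 1, X.shape[1]))
    pca = PCA(n_components=d_eff, svd_solver="full")
    Z = pca.fit_transform(X)
    # fix signs via the dominant loading of each component
    comp = pca.components_
    flip = np.sign(comp[np.arange(d_eff), np.abs(comp).argmax(axis=1)])
    flip[flip == 0] = 1.0
    return EmbeddingMatrix(Z * flip, method="pca")


def filter_lr_genes(
    E: ExpressionMatrix, db: LRDatabase, min_frac: float = LR_MIN_FRAC
) -> LRDatabase:
    """Keep LR pairs whose genes are both present and detected in >= ``min_frac``
    of cells ("less than 1%" is a strict cut, so exactly 1% survives)."""
    frac = {
        g: float((E.values[:, i] > 0).mean()) for i, g in enumerate(E.gene_ids)
    }
    kept = [
        (lig, rec, path)
        for lig, rec, path in db.pairs
        if frac.get(lig, 0.0) >= min_frac and frac.get(rec, 0.0) >= min_frac
    ]
    return LRDatabase(kept)
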