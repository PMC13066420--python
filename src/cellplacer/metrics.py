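"""Spatial benchmarking metrics.

KL divergence between 100x100 histogram densities of two point clouds,
exact earth-mover's distance with uniform weights, an uncorrected Ripley's
K/L on 20 radius bins (max radius = a quarter of the shorter bounding-box
side), Delaunay-graph neighborhood enrichment z-scores, and same-type
nearest-neighbor distances.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import Delaunay, cKDTree
from scipy.spatial.distance import cdist, pdist
from scipy.optimize import linear_sum_assignment

from ._ot import linear_ot

__all__ = [
    "kl_divergence_density",
    "wasserstein_points",
    "ripley_l",
    "ripley_l_mse",
    "neighborhood_enrichment",
    "same_type_nn_distance",
    "per_type_kl",
]

DEFAULT_EPS = 1e-10


def _histogram_density(points: np.ndarray, lo: np.ndarray, hi: np.ndarray,
                       grid: int, smooth_sigma: float | None = None) -> np.ndarray:
    H, _, _ = np.histogram2d(
        points[:, 0], points[:, 1], bins=grid,
        range=[[lo[0], hi[0]], [lo[1], hi[1]]],
    )
    if smooth_sigma is not None and smooth_sigma > 0:
        from scipy.ndimage import gaussian_filter

        H = gaussian_filter(H, smooth_sigma)
    total = H.sum()
    return H / total if total > 0 else H


def kl_divergence_density(
    points_a: np.ndarray,
    points_b: np.ndarray,
    grid: int = 100,
    eps: float = DEFAULT_EPS,
    smooth_sigma: float | None = None,
) -> float:
    """KL(p, q) = sum p log((p + eps)/(q + eps)) on a shared 100x100 grid
    spanning the joint bounding box of the two point clouds.

    ``smooth_sigma`` (in bins) optionally Gaussian-smooths both histograms
    before normalization (kernel-density variant).
    """
    a = np.asarray(points_a, dtype=float)
    b = np.asarray(points_b, dtype=float)
    if a.shape[0] < 5 or b.shape[0] < 5:
        raise ValueError("each point set needs at least 5 points")
    both = np.vstack([a, b])
    lo, hi = both.min(axis=0), both.max(axis=0)
    hi = np.where(hi > lo, hi, lo + 1.0)  # degenerate axis guard
    p = _histogram_density(a, lo, hi, grid, smooth_sigma)
    q = _histogram_density(b, lo, hi, grid, smooth_sigma)
    return float(np.sum(p * np.log((p + eps) / (q + eps))))


def wasserstein_points(points_a: np.ndarray, points_b: np.ndarray) -> float:
    """Exact EMD between two point clouds with uniform weights and Euclidean
    ground cost.  Equal-size clouds reduce to an optimal matching; the
    general case solves the transportation LP."""
    a = np.atleast_2d(np.asarray(points_a, dtype=float))
    b = np.atleast_2d(np.asarray(points_b, dtype=float))
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("point sets must be non-empty")
    M = cdist(a, b)
    if a.shape[0] == b.shape[0]:
        rows, cols = linear_sum_assignment(M)
        return float(M[rows, cols].mean())
    p = np.full(a.shape[0], 1 / a.shape[0])
    q = np.full(b.shape[0], 1 / b.shape[0])
    T = linear_ot(M, p, q)
    return float((T * M).sum())


def ripley_l(
    points: np.ndarray,
    area: float | None = None,
    r_grid: np.ndarray | None = None,
    n_bins: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Uncorrected Ripley's K transformed to L on a radius grid.

    K(r) = a / (n (n - 1)) * sum_{i != j} I(d_ij <= r); L = sqrt(K / pi).
    Default radii: ``n_bins`` evenly spaced values up to a quarter of the
    shorter bounding-box side.  Returns (r_grid, L).
    """
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    if n < 2:
        raise ValueError("need at least two points")
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    extent = hi - lo
    if area is None:
        if (extent <= 0).any():
            raise ValueError("degenerate bounding box; provide area explicitly")
        area = float(extent.prod())
    if r_grid is None:
        if (extent <= 0).any():
            raise ValueError("degenerate bounding box; provide r_grid explicitly")
        r_max = extent.min() / 4
        r_grid = np.linspace(r_max / n_bins, r_max, n_bins)
    r_grid = np.asarray(r_grid, dtype=float)
    d = pdist(pts)
    counts = np.searchsorted(np.sort(d), r_grid, side="right") * 2  # i != j ordered pairs
    K = area / (n * (n - 1)) * counts
    return r_grid, np.sqrt(K / np.pi)


def ripley_l_mse(curve_a: np.ndarray, curve_b: np.ndarray) -> float:
    """Mean squared error between two L curves evaluated on the same grid."""
    a = np.asarray(curve_a, dtype=float)
    b = np.asarray(curve_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("curves must share the radius grid")
    return float(np.mean((a - b) ** 2))


def _delaunay_edges(points: np.ndarray) -> np.ndarray:
    tri = Delaunay(points)
    edges = set()
    for simplex in tri.simplices:
        for a in range(3):
            for b in range(a + 1, 3):
                edges.add((min(simplex[a], simplex[b]), max(simplex[a], simplex[b])))
    return np.array(sorted(edges), dtype=int)


def neighborhood_enrichment(
    positions: np.ndarray,
    labels: list[str],
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[list[str], np.ndarray]:
    """Permutation z-scores for inter-cluster edge counts on the Delaunay graph.

    Returns (cluster names, z-matrix); z[I, J] compares the observed number
    of Delaunay edges joining clusters I and J with its label-permutation
    null (n_perm shuffles).
    """
    pos = np.asarray(positions, dtype=float)
    lab = np.asarray([str(x) for x in labels])
    clusters = sorted(set(lab))
    if len(clusters) < 2:
        raise ValueError("need at least two clusters")
    edges = _delaunay_edges(pos)
    codes = np.searchsorted(clusters, lab)
    k = len(clusters)

    def edge_counts(c: np.ndarray) -> np.ndarray:
        a, b = c[edges[:, 0]], c[edges[:, 1]]
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        flat = np.bincount(lo * k + hi, minlength=k * k).reshape(k, k)
        return flat + np.triu(flat, 1).T

    obs = edge_counts(codes)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, k, k))
    for p in range(n_perm):
        null[p] = edge_counts(rng.permutation(codes))
    mean = null.mean(axis=0)
    std = null.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (obs - mean) / std
    z[~np.isfinite(z)] = 0.0
    return clusters, z


def same_type_nn_distance(
    positions: np.ndarray, labels: list[str]
) -> tuple[np.ndarray, dict[str, float]]:
    """Per-cell distance to the nearest same-label cell, plus per-type means.

    Singleton types are skipped (their cells get NaN).
    """
    pos = np.asarray(positions, dtype=float)
    lab = np.asarray([str(x) for x in labels])
    out = np.full(pos.shape[0], np.nan)
    means: dict[str, float] = {}
    for c in sorted(set(lab)):
        idx = np.flatnonzero(lab == c)
        if idx.size < 2:
            continue
        tree = cKDTree(pos[idx])
        d, _ = tree.query(pos[idx], k=2)
        out[idx] = d[:, 1]
        means[c] = float(d[:, 1].mean())
    return out, means


def per_type_kl(
    positions: np.ndarray,
    labels: list[str],
    reference_positions: np.ndarray,
    reference_labels: list[str],
    min_cells: int = 5,
    **kwargs,
) -> dict[str, float]:
    """KL divergence of each cell type's predicted spatial density against the
    reference, over every type with >= ``min_cells`` cells in both sets."""
    lab = np.asarray([str(x) for x in labels])
    ref_lab = np.asarray([str(x) for x in reference_labels])
    out: dict[str, float] = {}
    for c in sorted(set(ref_lab)):
        a = np.asarray(reference_positions)[ref_lab == c]
        b = np.asarray(positions)[lab == c]
        if a.shape[0] >= min_cells and b.shape[0] >= min_cells:
            out[str(c)] = kl_divergence_density(a, b, **kwargs)
    return out
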