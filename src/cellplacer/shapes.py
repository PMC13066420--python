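"""Subcellular-element cell shape simulation.

Each refined cell centroid is expanded into ``n_e`` point elements evolving
under an overdamped Langevin equation: a 12-6 intercellular potential
between elements of different cells (weighted by the expression-similarity
matrix alpha), a 12-6 plus cubic-stretch intracellular potential between
elements of the same cell, and annealed Gaussian noise whose strength
decays as sqrt((T_max - t)/T_max).

The steady-state radius of an isolated cell is approximately
sqrt(n_e) * r_intra / 2; centroids are pre-scaled via the median Delaunay
edge length so neighboring cells neither overlap heavily nor drift apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np
from scipy.spatial import Delaunay, cKDTree

__all__ = [
    "ShapeParams",
    "CellShapes",
    "alpha_matrix",
    "init_elements",
    "inter_potential",
    "intra_potential",
    "simulate_shapes",
    "cell_radius",
    "median_delaunay_distance",
]

logger = logging.getLogger(__name__)


@dataclass
class ShapeParams:
    """Defaults follow the reference parameterization of the element model."""

    n_e: int = 20
    r_inter: float = 2.4
    r_intra: float = 2.0
    beta: float = 0.25
    gamma: float = 0.001
    dt: float = 0.04
    t_max: int = 2000
    radius_scaling: float = 2.5   # per-dataset presentation scaling (2.5 or 3.0)
    init_scale_coef: float = 1.25  # centroid rescale: coef * sqrt(n_e) * r_intra / d_m
    noise: bool = True
    cutoff_factor: float = 3.0    # inter-cell interactions within this x cell diameter
    # numerical safety: per-element force norm clamp (keeps the first Euler
    # steps stable while overlapping 12-6 cores relax)
    f_max: float = 50.0
    # inner Euler substeps per dt: the stiff 12-6 core is unstable at the
    # nominal dt in compact clusters (artificial swelling); substepping
    # integrates the same dynamics at dt/n_substeps
    n_substeps: int = 5

    def __post_init__(self) -> None:
        if self.n_e < 3:
            raise ValueError("n_e must be >= 3")
        for name in ("r_inter", "r_intra", "beta", "gamma", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CellShapes:
    """Per-cell element clouds (cells x n_e x 2) plus the alpha matrix."""

    elements: np.ndarray
    cell_ids: list[str]
    alpha: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.elements = np.asarray(self.elements, dtype=float)
        if self.elements.ndim != 3 or self.elements.shape[2] != 2:
            raise ValueError("elements must be cells x n_e x 2")
        if len(self.cell_ids) != self.elements.shape[0]:
            raise ValueError("cell_ids length must match number of cells")

    @property
    def n_cells(self) -> int:
        return self.elements.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[1]

    def centroids(self) -> np.ndarray:
        return self.elements.mean(axis=1)


def alpha_matrix(embeddings: np.ndarray) -> np.ndarray:
    """Interaction strengths: max(PCC, 0.05) mapped linearly [0.05, 1] -> [0.04, 1]."""
    X = np.asarray(embeddings, dtype=float)
    X = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(X, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    pcc = (X / safe[:, None]) @ (X / safe[:, None]).T
    clipped = np.maximum(pcc, 0.05)
    return 0.04 + (clipped - 0.05) * (1.0 - 0.04) / (1.0 - 0.05)


def median_delaunay_distance(centroids: np.ndarray) -> float:
    """Median edge length of the Delaunay triangulation of the centroids
    (pairwise median fallback for < 3 or degenerate inputs)."""
    pts = np.asarray(centroids, dtype=float)
    if pts.shape[0] >= 3:
        try:
            tri = Delaunay(pts)
            edges = set()
            for simplex in tri.simplices:
                for a in range(3):
                    for b_ in range(a + 1, 3):
                        e = (min(simplex[a], simplex[b_]), max(simplex[a], simplex[b_]))
                        edges.add(e)
            idx = np.array(sorted(edges))
            lengths = np.linalg.norm(pts[idx[:, 0]] - pts[idx[:, 1]], axis=1)
            return float(np.median(lengths))
        except Exception:  # collinear and similar degeneracies
            pass
    from scipy.spatial.distance import pdist

    d = pdist(pts)
    if d.size == 0:
        raise ValueError("need at least two centroids")
    return float(np.median(d))


def init_elements(
    centroids: np.ndarray,
    params: ShapeParams | None = None,
    seed: int = 0,
    embeddings: np.ndarray | None = None,
    cell_ids: list[str] | None = None,
) -> CellShapes:
    """Rescale centroids to element units and scatter ``n_e`` elements per cell.

    Centroid coordinates are multiplied by
    ``init_scale_coef * sqrt(n_e) * r_intra / d_m`` (d_m = median Delaunay
    intercellular distance) and elements are sampled isotropic-normal with
    sigma = r_intra / 2 around each scaled centroid.  Coincident centroids
    are jittered.
    """
    params = params or ShapeParams()
    rng = np.random.default_rng(seed)
    pts = np.array(centroids, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("centroids must be cells x 2")
    n = pts.shape[0]
    if n > 1:
        from scipy.spatial.distance import pdist

        if pdist(pts).min() == 0:
            pts = pts + rng.normal(scale=1e-9 * (1 + np.abs(pts).max()), size=pts.shape)
        d_m = median_delaunay_distance(pts)
        scale = params.init_scale_coef * np.sqrt(params.n_e) * params.r_intra / d_m
        pts = pts * scale
    elems = pts[:, None, :] + rng.normal(
        scale=params.r_intra / 2, size=(n, params.n_e, 2)
    )
    ids = cell_ids if cell_ids is not None else [str(i) for i in range(n)]
    alpha = alpha_matrix(embeddings) if embeddings is not None else None
    return CellShapes(elems, list(ids), alpha)


def inter_potential(r, r_inter: float = 2.4):
    """12-6 potential (r_inter/r)^12 - 2 (r_inter/r)^6, minimum -1 at r_inter."""
    r = np.asarray(r, dtype=float)
    if (r <= 0).any():
        raise ValueError("r must be positive")
    x = r_inter / r
    return x ** 12 - 2 * x ** 6


def intra_potential(r, params: ShapeParams | None = None):
    """beta * [(r_intra/r)^12 - 2 (r_intra/r)^6] + gamma r^3."""
    params = params or ShapeParams()
    r = np.asarray(r, dtype=float)
    if (r <= 0).any():
        raise ValueError("r must be positive")
    x = params.r_intra / r
    return params.beta * (x ** 12 - 2 * x ** 6) + params.gamma * r ** 3


def _pair_force_12_6(diff: np.ndarray, r2: np.ndarray, r_eq: float) -> np.ndarray:
    """Force on the first element of each pair from d/dr[(a/r)^12 - 2(a/r)^6].

    dV/dr = -12/r * (x^12 - x^6) with x = a/r; force = -dV/dr * rhat.
    """
    x2 = (r_eq ** 2) / r2
    x6 = x2 ** 3
    coeff = 12.0 * (x6 * x6 - x6) / r2   # (-dV/dr)/r
    return coeff[..., None] * diff


def simulate_shapes(
    shapes: CellShapes,
    params: ShapeParams | None = None,
    seed: int = 0,
) -> CellShapes:
    """Forward-Euler integration of the element Langevin dynamics.

    Inter-cell forces act only between cell pairs whose centroids lie within
    ``cutoff_factor * sqrt(n_e) * r_intra`` (sparse element pair list,
    refreshed every 5 steps); intra forces act between all element pairs of a
    cell.  Per-step
    noise std is sigma(t) * sqrt(dt) with sigma(t) = sqrt((T_max - t)/T_max),
    reaching zero at the final step.  On numerical blow-up the step is
    rejected and dt halved (logged).
    """
    params = params or ShapeParams()
    rng = np.random.default_rng(seed)
    E = shapes.elements.copy()          # N x n_e x 2
    N, n_e, _ = E.shape
    alpha = shapes.alpha if shapes.alpha is not None else np.ones((N, N))
    cutoff = params.cutoff_factor * np.sqrt(params.n_e) * params.r_intra
    # the 12-6 kernel is numerically negligible beyond a few r_inter; pair
    # lists carry a margin so they stay valid between refreshes
    elem_cutoff = 4.0 * params.r_inter
    dt = params.dt
    owner = np.repeat(np.arange(N), n_e)

    def refresh_pairs(E: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Cross-cell element pairs within range, pruned by centroid distance."""
        empty = (np.empty(0, int), np.empty(0, int), np.empty(0))
        if N < 2:
            return empty
        cents = E.mean(axis=1)
        ctree = cKDTree(cents)
        allowed = np.zeros((N, N), dtype=bool)
        cp = ctree.query_pairs(cutoff, output_type="ndarray")
        allowed[cp[:, 0], cp[:, 1]] = allowed[cp[:, 1], cp[:, 0]] = True
        tree = cKDTree(E.reshape(-1, 2))
        ep = tree.query_pairs(elem_cutoff, output_type="ndarray")
        if ep.size == 0:
            return empty
        oa, ob = owner[ep[:, 0]], owner[ep[:, 1]]
        keep = (oa != ob) & allowed[oa, ob]
        a, b = ep[keep, 0], ep[keep, 1]
        return a, b, alpha[owner[a], owner[b]]

    def total_force(E: np.ndarray, pairs) -> np.ndarray:
        F = np.zeros_like(E)
        # intra: all element pairs within each cell
        diff = E[:, :, None, :] - E[:, None, :, :]          # N x n_e x n_e x 2
        r2 = (diff ** 2).sum(axis=-1)
        r2_safe = np.where(r2 > 0, r2, 1.0)
        f = params.beta * _pair_force_12_6(diff, r2_safe, params.r_intra)
        # cubic stretch penalty: dV/dr = 3 gamma r^2 => force -3 gamma r^2 rhat
        r = np.sqrt(r2_safe)
        f -= 3.0 * params.gamma * r[..., None] * diff
        mask = (r2 > 0)[..., None]
        F += np.where(mask, f, 0.0).sum(axis=2)
        # inter: sparse cross-cell element pairs, alpha-weighted
        a, b, w = pairs
        if a.size:
            flat = E.reshape(-1, 2)
            d = flat[a] - flat[b]
            rr2 = np.maximum((d ** 2).sum(axis=-1), 1e-12)
            x6 = ((params.r_inter ** 2) / rr2) ** 3
            coeff = w * 12.0 * (x6 * x6 - x6) / rr2
            fab = coeff[:, None] * d
            Fflat = F.reshape(-1, 2)
            np.add.at(Fflat, a, fab)
            np.add.at(Fflat, b, -fab)
        # numerical clamp on per-element force norm
        norms = np.linalg.norm(F, axis=-1, keepdims=True)
        with np.errstate(invalid="ignore"):
            F = np.where(norms > params.f_max, F * (params.f_max / norms), F)
        return F

    pairs = refresh_pairs(E)
    t = 0
    while t < params.t_max:
        if t % 5 == 0:
            pairs = refresh_pairs(E)
        sigma_t = np.sqrt(max(params.t_max - t, 0) / params.t_max) if params.noise else 0.0
        dt_sub = dt / params.n_substeps
        E_new = E
        for _ in range(params.n_substeps):
            F = total_force(E_new, pairs)
            noise = rng.normal(scale=1.0, size=E.shape) * sigma_t * np.sqrt(dt_sub)
            E_new = E_new + dt_sub * F + noise
        if not np.isfinite(E_new).all():
            dt *= 0.5
            logger.warning("element step rejected at t=%d; dt halved to %g", t, dt)
            if dt < params.dt * 2 ** -20:
                raise FloatingPointError("element dynamics diverged")
            continue
        E = E_new
        t += 1
    return CellShapes(E, list(shapes.cell_ids), shapes.alpha)


def cell_radius(shapes: CellShapes) -> np.ndarray:
    """Per-cell radius: sqrt(2) x RMS element distance from the element centroid."""
    cents = shapes.centroids()
    d2 = ((shapes.elements - cents[:, None, :]) ** 2).sum(axis=-1)
    return np.sqrt(2.0 * d2.mean(axis=1))
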