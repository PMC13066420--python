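"""Synthetic tissue generator and pseudo-Visium aggregation.

The generator emits a spatial single-cell ground truth (positions, types,
negative-binomial counts with type markers) and the aggregator collapses it
onto a uniform spot grid: cells are assigned to their nearest grid point by
global distance order, capped at ``n_max`` cells per grid point and at half
the grid spacing; empty grid points are dropped and spot expression is the
sum over assigned cells.

Coordinates default to a micrometre-like scale (2000 x 2000 units for 1000
cells, i.e. Visium-like cell spacing of ~60 um) so that the refinement
defaults (time step h = 20) are dimensionally sensible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .io import ExpressionMatrix, SpotTable

__all__ = [
    "GroundTruthTissue",
    "PseudoSpotData",
    "generate_tissue",
    "make_pseudo_visium",
    "perturb_positions",
]

DEFAULT_EXTENT = 2000.0  # tissue side length for n_cells=1000 (length units, um-like)


@dataclass
class GroundTruthTissue:
    """Single-cell-resolution spatial ground truth."""

    positions: np.ndarray        # cells x 2
    types: list[str]             # per-cell label
    expression: ExpressionMatrix
    seed: int

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if not np.isfinite(self.positions).all():
            raise ValueError("positions must be finite")
        if len(set(self.types)) < 1:
            raise ValueError("every tissue needs at least one cell type")


@dataclass
class PseudoSpotData:
    """Aggregated spot data with the ground-truth cell-to-spot assignment."""

    spots: SpotTable
    expression: ExpressionMatrix
    assignment: dict[int, list[int]]  # surviving spot index -> cell indices

    def __post_init__(self) -> None:
        for j, cells in self.assignment.items():
            if len(cells) == 0:
                raise ValueError(f"spot {j} has no assigned cells")


def _layout_positions(
    n_cells: int, n_types: int, layout: str, extent: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample positions uniformly within per-type regions; return (pos, type idx)."""
    pos = rng.uniform(0.0, extent, size=(n_cells, 2))
    if layout == "layers":
        # horizontal bands: type is a monotone function of the y band
        band = np.floor(pos[:, 1] / extent * n_types).astype(int)
        t = np.clip(band, 0, n_types - 1)
    elif layout == "rings":
        center = np.array([extent / 2, extent / 2])
        r = np.linalg.norm(pos - center, axis=1)
        r_max = extent / 2 * np.sqrt(2)
        t = np.clip((r / r_max * n_types).astype(int), 0, n_types - 1)
    elif layout == "blobs":
        centers = rng.uniform(0.2 * extent, 0.8 * extent, size=(n_types, 2))
        t = rng.integers(0, n_types, size=n_cells)
        pos = centers[t] + rng.normal(scale=extent / 10, size=(n_cells, 2))
    else:
        raise ValueError(f"unknown layout {layout!r}")
    return pos, t


def generate_tissue(
    n_cells: int = 1000,
    n_types: int = 4,
    n_genes: int = 200,
    layout: str = "layers",
    noise: float = 0.5,
    seed: int = 0,
    extent: float | None = None,
    marker_fold: float = 8.0,
    base_mean: float = 1.0,
    n_markers_per_type: int | None = None,
    lr_programs: bool = False,
) -> GroundTruthTissue:
    """Generate a spatial tissue with typed cells and NB counts.

    ``noise`` is the negative-binomial dispersion (variance = mu + noise*mu^2);
    ``noise=0`` gives the per-type means exactly.  Each type gets an equal
    block of marker genes whose mean is ``marker_fold`` times the baseline.
    With ``lr_programs``, the first two marker genes of adjacent types act as
    a ligand-receptor program (ligand up in type t, receptor up in type t+1).
    """
    if n_types < 2:
        raise ValueError("need at least two cell types")
    if n_genes < n_types:
        raise ValueError("need at least one gene per type")
    rng = np.random.default_rng(seed)
    if extent is None:
        extent = DEFAULT_EXTENT * np.sqrt(n_cells / 1000.0)
    pos, t_idx = _layout_positions(n_cells, n_types, layout, extent, rng)

    block = n_genes // n_types if n_markers_per_type is None else n_markers_per_type
    block = max(1, min(block, n_genes // n_types))
    means = np.full((n_types, n_genes), base_mean)
    for t in range(n_types):
        means[t, t * block:(t + 1) * block] = base_mean * marker_fold
    if lr_programs and block >= 2:
        # adjacent-type signaling program: the first gene of type t's block is
        # its ligand (up in t), the second gene of type t+1's block the
        # matching receptor (up in t+1)
        for t in range(n_types - 1):
            means[t, t * block] = base_mean * marker_fold * 2
            means[t + 1, (t + 1) * block + 1] = base_mean * marker_fold * 2

    mu = means[t_idx]
    if noise > 0:
        # NB with mean mu and dispersion `noise`: n = 1/noise, p = n/(n+mu)
        n_param = 1.0 / noise
        counts = rng.negative_binomial(n_param, n_param / (n_param + mu)).astype(float)
    else:
        counts = mu.copy()

    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    types = [f"type{t}" for t in t_idx]
    expr = ExpressionMatrix(
        counts, [f"cell{i:05d}" for i in range(n_cells)], gene_ids, labels=types
    )
    return GroundTruthTissue(pos, types, expr, seed)


def make_pseudo_visium(
    gt: GroundTruthTissue,
    grid_rows: int = 14,
    grid_cols: int = 14,
    radius: float | None = None,
    n_max: int = 5,
) -> PseudoSpotData:
    """Aggregate a ground-truth tissue onto a uniform spot grid.

    Cells are sorted globally by distance to their nearest grid point and
    assigned greedily (stable tie-break by cell index); a cell is assignable
    only within half the neighbouring-grid-point spacing, each grid point
    takes at most ``n_max`` cells, and empty grid points are removed.
    """
    pos = gt.positions
    lo, hi = pos.min(axis=0), pos.max(axis=0)
    xs = np.linspace(lo[0], hi[0], grid_cols)
    ys = np.linspace(lo[1], hi[1], grid_rows)
    grid = np.array([(x, y) for y in ys for x in xs])
    spacing = min(
        (hi[0] - lo[0]) / max(grid_cols - 1, 1),
        (hi[1] - lo[1]) / max(grid_rows - 1, 1),
    )
    if spacing <= 0:
        raise ValueError("degenerate tissue bounding box")
    if radius is None:
        radius = spacing / 2

    tree = cKDTree(grid)
    dist, nearest = tree.query(pos)
    order = np.lexsort((np.arange(len(pos)), dist))  # by distance, then cell index
    capacity = np.full(len(grid), n_max, dtype=int)
    assignment: dict[int, list[int]] = {}
    half = spacing / 2 + 1e-9
    for i in order:
        j = int(nearest[i])
        if dist[i] <= half and capacity[j] > 0:
            assignment.setdefault(j, []).append(int(i))
            capacity[j] -= 1

    surviving = sorted(assignment)
    if not surviving:
        raise ValueError("no grid point received any cell")
    coords = grid[surviving]
    expr_vals = np.stack([
        gt.expression.values[assignment[j]].sum(axis=0) for j in surviving
    ])
    spot_ids = [f"spot{j:04d}" for j in surviving]
    expression = ExpressionMatrix(expr_vals, spot_ids, list(gt.expression.gene_ids))
    remapped = {new: assignment[j] for new, j in enumerate(surviving)}
    return PseudoSpotData(SpotTable(coords, float(radius)), expression, remapped)


def perturb_positions(
    positions: np.ndarray, sigma: float, seed: int = 0
) -> np.ndarray:
    """Add independent isotropic Gaussian noise to each position."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    positions = np.asarray(positions, dtype=float)
    if sigma == 0:
        return positions.copy()
    rng = np.random.default_rng(seed)
    return positions + rng.normal(scale=sigma, size=positions.shape)
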