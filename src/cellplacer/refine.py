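"""Particle-based position refinement.

Each mapped cell is a particle obeying dx_i/dt = F_m + F_s + F_g + F_LR:
a pairwise Morse force with an annealed amplitude, a capped quadratic
spot-constraint force, an annealed attraction proportional to the clipped
Pearson correlation of PCA embeddings (restricted to cells in the same or
adjacent spots), and an optional ligand-receptor affinity force on the same
neighborhoods.  The ODE is integrated with forward Euler (default h = 20,
10 iterations, simultaneous updates) and a hard Gaussian-mixture level-set
tissue boundary is enforced after every step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import pdist, squareform

from .io import ExpressionMatrix, LRDatabase, SpotTable
from .mapping import Assignment
from .preprocess import EmbeddingMatrix

__all__ = [
    "MorseParams",
    "ParticleState",
    "LRAffinity",
    "TissueBoundary",
    "RefineConfig",
    "choose_morse_params",
    "morse_potential",
    "morse_force",
    "spot_force",
    "gene_force",
    "lr_affinity",
    "lr_force",
    "fit_boundary",
    "enforce_boundary",
    "build_neighborhoods",
    "refine",
    "anneal_gene",
]

# Shape of the Morse family, taken as fixed amplitude/width ratios; only the
# overall length scale is fit to the target equilibrium distance.
_SHAPE_V0_C1 = 0.90931  # V0 / c1
_SHAPE_U0_C1 = 0.08267  # U0 / c1
_SHAPE_C2_C1 = 1.57064  # c2 / c1


@dataclass
class MorseParams:
    """Parameters of V(r) = V0 exp(-r^2/c1^2) - U0 exp(-r^2/c2^2)."""

    U0: float
    V0: float
    c1: float
    c2: float

    def __post_init__(self) -> None:
        if min(self.U0, self.V0, self.c1, self.c2) <= 0:
            raise ValueError("all Morse parameters must be positive")
        r_eq = self.equilibrium_radius()
        if not (0 < r_eq < np.inf):
            raise ValueError("Morse potential has no interior minimum")

    def equilibrium_radius(self) -> float:
        """Distance at which V attains its minimum (numeric 1-D search)."""
        res = minimize_scalar(
            lambda r: morse_potential(r, self),
            bounds=(1e-9 * self.c2, 20 * self.c2),
            method="bounded",
            options={"xatol": 1e-12 * self.c2},
        )
        return float(res.x)


def morse_potential(r, params: MorseParams):
    r2 = np.square(r)
    return params.V0 * np.exp(-r2 / params.c1 ** 2) \
        - params.U0 * np.exp(-r2 / params.c2 ** 2)


def choose_morse_params(d_min: float, shape_ratios: tuple[float, float, float] | None = None) -> MorseParams:
    """Morse parameters whose potential well sits at 0.35 x ``d_min``.

    A fixed-shape family (amplitudes and widths proportional to c1) is
    rescaled so that the numeric argmin of V lands on the target distance;
    by homogeneity the equilibrium scales linearly with d_min.
    """
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    v0c1, u0c1, c2c1 = shape_ratios if shape_ratios is not None else (
        _SHAPE_V0_C1, _SHAPE_U0_C1, _SHAPE_C2_C1)
    target = 0.35 * d_min
    ref = MorseParams(U0=u0c1, V0=v0c1, c1=1.0, c2=c2c1)
    r_hat = ref.equilibrium_radius()
    c1 = target / r_hat
    return MorseParams(U0=u0c1 * c1, V0=v0c1 * c1, c1=c1, c2=c2c1 * c1)


@dataclass
class ParticleState:
    """Per-cell positions plus everything the forces need."""

    positions: np.ndarray                  # cells x 2
    spot_index: np.ndarray                 # per-cell spot index
    embeddings: np.ndarray | None = None   # cells x d (PCA)
    t: int = 0
    t_f: int = 10
    h: float = 20.0
    cell_ids: list[str] | None = None
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.spot_index = np.asarray(self.spot_index, dtype=int)
        if not np.isfinite(self.positions).all():
            raise ValueError("positions must be finite")
        if self.positions.shape[0] != self.spot_index.shape[0]:
            raise ValueError("positions and spot_index disagree on cell count")

    @property
    def n_cells(self) -> int:
        return self.positions.shape[0]


@dataclass
class LRAffinity:
    """Symmetric cell-cell ligand-receptor affinity, raw (W0) and sparsified (W)."""

    W0: np.ndarray
    W: np.ndarray
    threshold: float = 0.4

    def __post_init__(self) -> None:
        self.W0 = np.asarray(self.W0, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        if not np.allclose(self.W0, self.W0.T):
            raise ValueError("W0 must be symmetric")
        if (self.W < 0).any():
            raise ValueError("W entries must be non-negative")
        if ((self.W > 0) & (self.W0 == 0)).any():
            raise ValueError("W support must be contained in W0 support")


@dataclass
class TissueBoundary:
    """Level set of an equal-weight Gaussian mixture over the initial positions."""

    centers: np.ndarray
    variance: float = 1e4
    level_frac: float = 0.4
    level: float = field(init=False)

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        if self.centers.ndim != 2 or self.centers.shape[0] < 1:
            raise ValueError("need at least one center")
        # the mixture maximum is attained (to excellent approximation for
        # overlapping kernels) at one of the component centers
        self.level = self.level_frac * float(self.density(self.centers).max())

    def density(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        d2 = ((x[:, None, :] - self.centers[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-d2 / (2 * self.variance)).sum(axis=1) / (2 * np.pi * self.variance)

    def density_grad(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        diff = self.centers[None, :, :] - x[:, None, :]
        d2 = (diff ** 2).sum(axis=2)
        w = np.exp(-d2 / (2 * self.variance)) / (2 * np.pi * self.variance ** 2)
        return (w[:, :, None] * diff).sum(axis=1)


def fit_boundary(initial_positions: np.ndarray, variance: float = 1e4,
                 level_frac: float = 0.4) -> TissueBoundary:
    return TissueBoundary(np.asarray(initial_positions, dtype=float), variance, level_frac)


def enforce_boundary(positions: np.ndarray, boundary: TissueBoundary,
                     rtol: float = 1e-4, max_steps: int = 100) -> np.ndarray:
    """Relocate cells with Z(x) < level to the nearest point with Z = level.

    The crossing is bracketed along the (ascending) density gradient and
    solved by bisection; if the gradient vanishes the cell walks toward the
    densest mixture center instead.
    """
    pos = np.array(positions, dtype=float)
    z = boundary.density(pos)
    outside = np.flatnonzero(z < boundary.level)
    if outside.size == 0:
        return pos
    peak = boundary.centers[int(np.argmax(boundary.density(boundary.centers)))]
    sigma = np.sqrt(boundary.variance)
    for i in outside:
        x = pos[i]
        for _ in range(max_steps):
            g = boundary.density_grad(x[None])[0]
            gn = np.linalg.norm(g)
            d = g / gn if gn > 0 else _unit(peak - x)
            # bracket the level crossing along d
            step = sigma / 4
            lo, hi = 0.0, step
            while boundary.density((x + hi * d)[None])[0] < boundary.level:
                lo, hi = hi, hi + step
                if hi > 100 * sigma:  # pathological; jump to the peak side
                    break
            else:
                # bisection on t in [lo, hi]
                for _ in range(80):
                    mid = 0.5 * (lo + hi)
                    if boundary.density((x + mid * d)[None])[0] < boundary.level:
                        lo = mid
                    else:
                        hi = mid
                x = x + hi * d
                break
            x = x + (hi / 2) * d  # retry from closer in
        pos[i] = x
    return pos


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def anneal_morse(t: int, t_f: int) -> float:
    """Linear amplitude decay for the Morse force: s(t) = (t_f - t)/t_f."""
    return max(0.0, (t_f - t) / t_f)


def anneal_gene(t: int, t_f: int) -> float:
    """a(t) = (t - t_f)^2 / (20 t_f^2): strictly decreasing on [0, t_f], a(t_f) = 0."""
    return (t - t_f) ** 2 / (20.0 * t_f ** 2)


def morse_force(state: ParticleState, params: MorseParams,
                schedule: bool = True) -> np.ndarray:
    """Pairwise Morse force F_m(x_i) = -sum_j grad V, with annealed amplitude.

    Coincident cells contribute zero force (the Gaussian gradients vanish at
    r = 0).  Pairwise contributions are antisymmetric, so the total summed
    force is the zero vector.
    """
    pos = state.positions
    n = pos.shape[0]
    if n < 2:
        return np.zeros_like(pos)
    diff = pos[:, None, :] - pos[None, :, :]              # x_i - x_j
    r2 = (diff ** 2).sum(axis=2)
    # dV/d(r^2); gradient wrt x_i is 2 * dV/d(r^2) * (x_i - x_j)
    dV = -params.V0 / params.c1 ** 2 * np.exp(-r2 / params.c1 ** 2) \
        + params.U0 / params.c2 ** 2 * np.exp(-r2 / params.c2 ** 2)
    np.fill_diagonal(dV, 0.0)
    F = -2.0 * (dV[:, :, None] * diff).sum(axis=1)
    if schedule:
        F = F * anneal_morse(state.t, state.t_f)
    return F


def spot_force(state: ParticleState, spots: SpotTable,
               b: float = 0.05, cap: float = 1.5) -> np.ndarray:
    """Quadratic restoring force toward the assigned spot, zero inside r_s,
    magnitude capped at ``cap``."""
    centers = spots.coords[state.spot_index]
    diff = state.positions - centers
    d = np.linalg.norm(diff, axis=1)
    mag = np.minimum(b * np.square(np.maximum(d - spots.radius, 0.0)), cap)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(d[:, None] > 0, diff / np.maximum(d, 1e-300)[:, None], 0.0)
    return -mag[:, None] * unit


def build_neighborhoods(assignment: Assignment, spots: SpotTable,
                        adjacency_factor: float = 1.5) -> list[np.ndarray]:
    """Per-cell arrays of neighbor cells: those in the same or adjacent spots.

    Adjacent means spot centers within ``adjacency_factor`` x the minimum
    center spacing (covers square and hexagonal grids).  Built once at
    initialization.
    """
    coords = spots.coords
    if spots.n_spots > 1:
        dmat = squareform(pdist(coords))
        d_min = dmat[dmat > 0].min()
        adj = dmat <= adjacency_factor * d_min + 1e-12
    else:
        adj = np.ones((1, 1), dtype=bool)
    spot_members: dict[int, list[int]] = {j: list(c) for j, c in assignment.spot_cells.items()}
    occupied = sorted(spot_members)
    neighborhoods: list[np.ndarray] = []
    cell_spot = assignment.cell_spot
    n_cells = max(cell_spot) + 1 if cell_spot else 0
    for i in range(n_cells):
        j = cell_spot.get(i)
        if j is None:
            neighborhoods.append(np.empty(0, dtype=int))
            continue
        cells = [c for jj in occupied if adj[j, jj] for c in spot_members[jj] if c != i]
        neighborhoods.append(np.asarray(sorted(cells), dtype=int))
    return neighborhoods


def _clipped_pcc(emb: np.ndarray, clip: float = 0.0) -> np.ndarray:
    """Pairwise Pearson correlation of embedding rows, clipped from below."""
    X = emb - emb.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(X, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    C = (X / safe[:, None]) @ (X / safe[:, None]).T
    return np.maximum(C, clip)


def _neighborhood_attraction(positions: np.ndarray, weights: np.ndarray,
                             neighborhoods: list[np.ndarray], scale: float) -> np.ndarray:
    """Shared kernel of F_g and F_LR: -sum_j scale * w_ij * (x_i - x_j)/||.||."""
    F = np.zeros_like(positions)
    for i, nbrs in enumerate(neighborhoods):
        if nbrs.size == 0:
            continue
        diff = positions[i] - positions[nbrs]
        d = np.linalg.norm(diff, axis=1)
        ok = d > 0
        if not ok.any():
            continue
        unit = diff[ok] / d[ok][:, None]
        F[i] -= scale * (weights[i, nbrs[ok]][:, None] * unit).sum(axis=0)
    return F


def gene_force(state: ParticleState, neighborhoods: list[np.ndarray],
               pcc: np.ndarray | None = None) -> np.ndarray:
    """Attraction toward same-neighborhood cells with similar embeddings,
    weighted by max(PCC, 0) and the a(t) schedule."""
    if pcc is None:
        if state.embeddings is None:
            raise ValueError("gene force requires embeddings")
        pcc = _clipped_pcc(state.embeddings)
    return _neighborhood_attraction(
        state.positions, pcc, neighborhoods, anneal_gene(state.t, state.t_f)
    )


# ---------------------------------------------------------------------------
# Ligand-receptor affinity
# ---------------------------------------------------------------------------

def lr_affinity(
    E_cells: ExpressionMatrix,
    db: LRDatabase,
    threshold: float = 0.4,
    method: str = "effective-resistance",
    seed: int = 0,
    n_projections: int = 8,
) -> LRAffinity:
    """Cell-cell affinity W0 = T_L T_R' + T_R T_L' and its sparsification W.

    ``effective-resistance`` scores each edge by weight x approximate
    effective resistance (random-projection estimate of the graph
    resistance, in the spirit of spectral sparsification) and keeps the
    top-scoring edges until the retained fraction of total edge weight
    reaches ``threshold``; ``quantile`` simply keeps edges at or above the
    ``threshold`` weight quantile.
    """
    n = E_cells.n_obs
    present = set(E_cells.gene_ids)
    pairs = [p for p in db.pairs if p[0] in present and p[1] in present]
    if not pairs:
        Z = np.zeros((n, n))
        return LRAffinity(Z, Z.copy(), threshold)
    gidx = {g: i for i, g in enumerate(E_cells.gene_ids)}
    TL = E_cells.values[:, [gidx[p[0]] for p in pairs]]
    TR = E_cells.values[:, [gidx[p[1]] for p in pairs]]
    W0 = TL @ TR.T + TR @ TL.T
    np.fill_diagonal(W0, 0.0)
    W0 = np.maximum(W0, 0.0)
    if W0.max() == 0:
        return LRAffinity(W0, W0.copy(), threshold)

    iu = np.triu_indices(n, k=1)
    w = W0[iu]
    nz = w > 0
    if method == "quantile":
        cut = np.quantile(w[nz], threshold)
        keep = w >= cut
    elif method == "effective-resistance":
        r_eff = _approx_effective_resistance(W0, iu, seed=seed, k=n_projections)
        score = w * r_eff
        order = np.argsort(-score, kind="stable")
        cum = np.cumsum(w[order])
        budget = threshold * w.sum()
        n_keep = int(np.searchsorted(cum, budget) + 1)
        keep = np.zeros_like(w, dtype=bool)
        keep[order[:n_keep]] = True
        keep &= nz
    else:
        raise ValueError(f"unknown sparsification method {method!r}")
    W = np.zeros_like(W0)
    W[iu[0][keep], iu[1][keep]] = w[keep]
    W = W + W.T
    return LRAffinity(W0, W, threshold)


def _approx_effective_resistance(W: np.ndarray, iu, seed: int = 0, k: int = 8) -> np.ndarray:
    """Random-projection estimate of pairwise effective resistances for the
    edges indexed by ``iu`` on the weighted graph W."""
    n = W.shape[0]
    L = np.diag(W.sum(axis=1)) - W
    # pseudo-solve via regularized Cholesky-free least squares
    L_reg = L + 1e-8 * np.trace(L) / n * np.eye(n)
    rng = np.random.default_rng(seed)
    # signed edge incidence applied to random vectors: R_uv ~ ||Z_u - Z_v||^2
    # with Z = L^+ B' W^{1/2} Q, estimated through k random projections
    ii, jj = iu
    m = ii.size
    proj = np.zeros((n, k))
    q = rng.choice([-1.0, 1.0], size=(m, k)) / np.sqrt(k)
    sw = np.sqrt(W[iu])
    for col in range(k):
        y = np.zeros(n)
        np.add.at(y, ii, sw * q[:, col])
        np.add.at(y, jj, -sw * q[:, col])
        proj[:, col] = np.linalg.solve(L_reg, y)
    return ((proj[ii] - proj[jj]) ** 2).sum(axis=1)


def lr_force(state: ParticleState, affinity: LRAffinity,
             neighborhoods: list[np.ndarray]) -> np.ndarray:
    """F_LR: attraction along unit vectors weighted by w_ij and a(t),
    restricted to the same neighborhoods as the gene force."""
    return _neighborhood_attraction(
        state.positions, affinity.W, neighborhoods, anneal_gene(state.t, state.t_f)
    )


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

@dataclass
class RefineConfig:
    h: float = 20.0
    t_f: int = 10
    b: float = 0.05
    cap: float = 1.5
    use_morse: bool = True
    use_spot: bool = True
    use_gene: bool = True
    use_lr: bool = False          # LR term is optional; off by default
    init_sigma_frac: float = 1 / 3  # initial spread = r_s * this
    boundary_variance: float = 1e4
    boundary_scale_auto: bool = False
    adjacency_factor: float = 1.5
    morse_params: MorseParams | None = None
    # printed but undefined in the model equations; kept as an inert stub
    m: float = 0.025


def refine(
    assignment: Assignment,
    spots: SpotTable,
    embeddings: EmbeddingMatrix | np.ndarray | None = None,
    affinity: LRAffinity | None = None,
    config: RefineConfig | None = None,
    seed: int = 0,
    initial_positions: np.ndarray | None = None,
    cell_ids: list[str] | None = None,
    labels: list[str] | None = None,
) -> list[ParticleState]:
    """Integrate the force model; returns the trajectory of states.

    Initial positions are sampled isotropic-normal around each cell's
    assigned spot center (sigma = r_s * init_sigma_frac) unless given.  All
    positions update simultaneously by h x total force each iteration, then
    the tissue boundary is enforced.
    """
    config = config or RefineConfig()
    cells = assignment.assigned_cells
    if not cells:
        raise ValueError("assignment is empty")
    cell_spot = assignment.cell_spot
    spot_idx = np.asarray([cell_spot[i] for i in cells], dtype=int)

    rng = np.random.default_rng(seed)
    if initial_positions is None:
        centers = spots.coords[spot_idx]
        positions = centers + rng.normal(
            scale=spots.radius * config.init_sigma_frac, size=centers.shape
        )
    else:
        positions = np.asarray(initial_positions, dtype=float).copy()
        if positions.shape[0] != len(cells):
            raise ValueError("initial_positions rows must match assigned cells")

    emb = None
    if embeddings is not None:
        vecs = embeddings.vectors if isinstance(embeddings, EmbeddingMatrix) else np.asarray(embeddings)
        emb = vecs[cells]

    params = config.morse_params
    if params is None and config.use_morse:
        if spots.n_spots > 1:
            params = choose_morse_params(spots.min_center_distance())
        else:
            params = choose_morse_params(2 * spots.radius)

    variance = config.boundary_variance
    if config.boundary_scale_auto:
        extent = positions.max(axis=0) - positions.min(axis=0)
        diameter = float(np.linalg.norm(extent))
        variance = config.boundary_variance * (diameter / 100.0) ** 2

    # remap assignment to the compact cell order used in the state
    compact = {c: idx for idx, c in enumerate(cells)}
    compact_assign = Assignment(
        {j: [compact[c] for c in cc] for j, cc in assignment.spot_cells.items()},
        n_cells=len(cells), n_spots=assignment.n_spots,
    )
    neighborhoods = build_neighborhoods(compact_assign, spots, config.adjacency_factor)
    boundary = fit_boundary(positions, variance=variance)
    pcc = _clipped_pcc(emb) if (emb is not None and config.use_gene) else None
    aff = None
    if affinity is not None and config.use_lr:
        ix = np.ix_(cells, cells)
        aff = LRAffinity(affinity.W0[ix], affinity.W[ix], affinity.threshold)

    state = ParticleState(
        positions, spot_idx, embeddings=emb, t=0, t_f=config.t_f, h=config.h,
        cell_ids=None if cell_ids is None else [cell_ids[i] for i in cells],
        labels=None if labels is None else [labels[i] for i in cells],
    )
    trajectory = [state]
    for t in range(config.t_f):
        state = ParticleState(
            state.positions.copy(), spot_idx, embeddings=emb, t=t,
            t_f=config.t_f, h=config.h, cell_ids=state.cell_ids, labels=state.labels,
        )
        F = np.zeros_like(state.positions)
        if config.use_morse:
            F += morse_force(state, params)
        if config.use_spot:
            F += spot_force(state, spots, b=config.b, cap=config.cap)
        if config.use_gene and pcc is not None:
            F += gene_force(state, neighborhoods, pcc=pcc)
        if config.use_lr and aff is not None:
            F += lr_force(state, aff, neighborhoods)
        new_pos = state.positions + config.h * F
        new_pos = enforce_boundary(new_pos, boundary)
        state = ParticleState(
            new_pos, spot_idx, embeddings=emb, t=t + 1, t_f=config.t_f,
            h=config.h, cell_ids=state.cell_ids, labels=state.labels,
        )
        trajectory.append(state)
    return trajectory
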