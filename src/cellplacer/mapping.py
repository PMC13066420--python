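"""Initial cell-to-spot mapping by fused Gromov-Wasserstein transport.

The linear cost M is the cosine dissimilarity between cell and spot marker
expression; the structure costs are C1 (cell-cell expression dissimilarity)
and C2 = A1 * A2, the elementwise product of normalized spot-center
distances and the cosine dissimilarity of a spatially consistent spot
embedding.  The default embedding provider is a spatially smoothed PCA; an
externally computed embedding (e.g. a graph neural embedding) can be
injected via file or array.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from ._ot import fused_gromov_wasserstein, linear_ot
from .io import ExpressionMatrix, SpotTable
from .preprocess import EmbeddingMatrix, pca_embed

__all__ = [
    "FGWProblem",
    "CouplingMatrix",
    "Assignment",
    "spot_embedding",
    "build_costs",
    "fgw_map",
    "assign_top_k",
    "map_rare_types",
    "cosine_dissimilarity",
]


def cosine_dissimilarity(A: np.ndarray, B: np.ndarray | None = None) -> np.ndarray:
    """1 - cosine similarity between rows of A and rows of B (or A with itself).

    Zero-norm rows get dissimilarity 1 by convention (their similarity to
    anything, including themselves, is treated as 0).
    """
    A = np.asarray(A, dtype=float)
    B = A if B is None else np.asarray(B, dtype=float)

    def _unit(X: np.ndarray) -> np.ndarray:
        n = np.linalg.norm(X, axis=1)
        safe = np.where(n > 0, n, 1.0)
        return X / safe[:, None]

    sim = _unit(A) @ _unit(B).T
    return 1.0 - np.clip(sim, -1.0, 1.0)


@dataclass
class FGWProblem:
    """Costs and marginals of the fused transport problem."""

    M: np.ndarray    # c x s linear cost
    C1: np.ndarray   # c x c structure cost (cells)
    C2: np.ndarray   # s x s structure cost (spots)
    p: np.ndarray    # length-c weights
    q: np.ndarray    # length-s weights
    eta: float = 0.5

    def __post_init__(self) -> None:
        for name in ("M", "C1", "C2", "p", "q"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (0.0 <= self.eta <= 1.0):
            raise ValueError("eta must lie in [0, 1]")
        for name in ("M", "C1", "C2"):
            X = getattr(self, name)
            if X.min() < -1e-12 or X.max() > 2 + 1e-12:
                raise ValueError(f"{name} entries must lie in [0, 2]")
        for name in ("p", "q"):
            w = getattr(self, name)
            if (w < 0).any() or abs(w.sum() - 1) > 1e-9:
                raise ValueError(f"{name} must be a probability vector")


@dataclass
class CouplingMatrix:
    """Transport plan T (cells x spots) with conserved marginals."""

    T: np.ndarray
    log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        if (self.T < -1e-12).any():
            raise ValueError("coupling must be non-negative")


@dataclass
class Assignment:
    """Per-spot ordered cell lists (length <= k); each cell in at most one list."""

    spot_cells: dict[int, list[int]]
    n_cells: int
    n_spots: int

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for cells in self.spot_cells.values():
            for c in cells:
                if c in seen:
                    raise ValueError(f"cell {c} assigned to multiple spots")
                seen.add(c)

    @property
    def cell_spot(self) -> dict[int, int]:
        return {c: j for j, cells in self.spot_cells.items() for c in cells}

    @property
    def assigned_cells(self) -> list[int]:
        return sorted(self.cell_spot)


def spot_embedding(
    G: ExpressionMatrix,
    spots: SpotTable,
    provider: str | np.ndarray = "smoothed-pca",
    d: int = 50,
    k_smooth: int = 6,
    n_rounds: int = 2,
) -> EmbeddingMatrix:
    """Spatially consistent low-dimensional spot embedding.

    Default provider: PCA of spot expression followed by ``n_rounds`` rounds
    of averaging each spot's vector with its ``k_smooth`` spatially nearest
    spots.  A precomputed (spots x d) array or a CSV path passes through
    unchanged.
    """
    if isinstance(provider, np.ndarray):
        emb = np.asarray(provider, dtype=float)
        if emb.shape[0] != spots.n_spots:
            raise ValueError("external embedding row count does not match spots")
        return EmbeddingMatrix(emb, method="external")
    if isinstance(provider, str) and provider not in ("smoothed-pca", "pca"):
        import pandas as pd

        emb = pd.read_csv(provider, index_col=0).to_numpy(dtype=float)
        if emb.shape[0] != spots.n_spots:
            raise ValueError("external embedding row count does not match spots")
        return EmbeddingMatrix(emb, method="external")

    Z = pca_embed(G, d=d).vectors
    if provider == "smoothed-pca" and k_smooth > 0 and spots.n_spots > 1:
        from scipy.spatial import cKDTree

        k = min(k_smooth, spots.n_spots - 1)
        tree = cKDTree(spots.coords)
        _, idx = tree.query(spots.coords, k=k + 1)  # includes self
        for _ in range(n_rounds):
            Z = Z[idx].mean(axis=1)
    return EmbeddingMatrix(Z, method=str(provider))


def build_costs(
    S: ExpressionMatrix,
    G: ExpressionMatrix,
    spots: SpotTable,
    embedding: EmbeddingMatrix,
    eta: float = 0.5,
) -> FGWProblem:
    """Assemble the FGW costs from marker expression, spot geometry, and the
    spot embedding.  S and G must share an identical gene set."""
    if S.gene_ids != G.gene_ids:
        raise ValueError("S and G must be reduced to the same gene set")
    if len(S.gene_ids) == 0:
        raise ValueError("zero shared genes")
    if embedding.n_obs != spots.n_spots:
        raise ValueError("embedding rows must match number of spots")
    M = cosine_dissimilarity(S.values, G.values)
    C1 = cosine_dissimilarity(S.values)
    A1 = squareform(pdist(spots.coords))
    if A1.max() > 0:
        A1 = A1 / A1.max()
    A2 = cosine_dissimilarity(embedding.vectors)
    C2 = A1 * A2
    c, s = S.n_obs, G.n_obs
    return FGWProblem(M, C1, C2, np.full(c, 1 / c), np.full(s, 1 / s), eta)


def fgw_map(problem: FGWProblem, max_iter: int = 10000, tol: float = 1e-9) -> CouplingMatrix:
    """Solve the fused transport problem by conditional gradient."""
    if problem.eta == 0.0:
        T = linear_ot(problem.M, problem.p, problem.q)
        return CouplingMatrix(T, {"objective": [float((problem.M * T).sum())],
                                  "converged": True, "n_iter": 1})
    T, log = fused_gromov_wasserstein(
        problem.M, problem.C1, problem.C2, problem.p, problem.q,
        eta=problem.eta, max_iter=max_iter, tol=tol,
    )
    return CouplingMatrix(T, log)


def assign_top_k(T: CouplingMatrix | np.ndarray, k: int = 5) -> Assignment:
    """Top-k cells per spot, resolving cell conflicts greedily by mass.

    Candidates are each spot's k largest coupling entries; they are granted
    in descending T order (ties broken by spot index then cell index), a
    cell is placed at most once, and a spot holds at most k cells.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    mat = T.T if isinstance(T, CouplingMatrix) else np.asarray(T, dtype=float)
    c, s = mat.shape
    candidates: list[tuple[float, int, int]] = []
    for j in range(s):
        col = mat[:, j]
        top = np.argsort(-col, kind="stable")[: min(k, c)]
        candidates.extend((float(col[i]), j, int(i)) for i in top)
    candidates.sort(key=lambda x: (-x[0], x[1], x[2]))
    taken: set[int] = set()
    spot_cells: dict[int, list[int]] = {}
    for val, j, i in candidates:
        if i in taken or len(spot_cells.get(j, [])) >= k:
            continue
        spot_cells.setdefault(j, []).append(i)
        taken.add(i)
    return Assignment(spot_cells, n_cells=c, n_spots=s)


def map_rare_types(
    S: ExpressionMatrix,
    G: ExpressionMatrix,
    assignment: Assignment,
    rare_type_labels: list[str],
) -> Assignment:
    """Append unmapped cells of the listed types to their cosine-argmax spot.

    Cells already present in the assignment are untouched; spot capacity is
    not enforced for the rescued cells.
    """
    if not rare_type_labels:
        return assignment
    if S.labels is None:
        raise ValueError("cell labels are required for rare-type mapping")
    known = set(S.labels)
    unknown = set(rare_type_labels) - known
    if unknown:
        raise ValueError(f"unknown cell type labels: {sorted(unknown)}")
    sim = 1.0 - cosine_dissimilarity(S.values, G.values)
    assigned = set(assignment.cell_spot)
    spot_cells = {j: list(cells) for j, cells in assignment.spot_cells.items()}
    for i, lab in enumerate(S.labels):
        if lab in rare_type_labels and i not in assigned:
            j_star = int(np.argmax(sim[i]))
            spot_cells.setdefault(j_star, []).append(i)
    return Assignment(spot_cells, assignment.n_cells, assignment.n_spots)
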