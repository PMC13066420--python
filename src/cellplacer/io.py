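"""Readers/writers for the tabular and sparse formats the pipeline touches.

Canonical on-disk formats are dense CSV/TSV (header row = gene ids, first
column = observation id) and Matrix Market triplets with ``*_obs_ids.txt`` /
``*_gene_ids.txt`` sidecar files.  An HDF5 container mirroring the same
arrays is provided for convenience.  All coordinates are 2-D and inherit the
units of the input spatial data.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "ExpressionMatrix",
    "SpotTable",
    "LRDatabase",
    "read_expression",
    "write_expression",
    "read_lr_database",
    "write_positions",
    "read_positions",
    "write_shapes",
    "read_shapes",
    "write_scores",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Observations x genes matrix of non-negative expression values.

    Used for both single cells and spatial spots.  ``labels`` optionally
    carries a per-observation cell-type / cluster annotation.
    """

    values: np.ndarray
    obs_ids: list[str]
    gene_ids: list[str]
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if np.isnan(self.values).any():
            raise ValueError("expression values contain NaN")
        if (self.values < 0).any():
            raise ValueError("expression values contain negative entries")
        if len(self.obs_ids) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.obs_ids)} obs ids for {self.values.shape[0]} rows"
            )
        if len(self.gene_ids) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {self.values.shape[1]} columns"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids are not unique")
        if self.labels is not None and len(self.labels) != self.values.shape[0]:
            raise ValueError("labels length does not match number of observations")

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        """Return a copy restricted to ``genes`` in the given order."""
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in idx]
        if missing:
            raise KeyError(f"genes not present: {missing[:5]}")
        cols = [idx[g] for g in genes]
        return ExpressionMatrix(
            self.values[:, cols], list(self.obs_ids), list(genes),
            None if self.labels is None else list(self.labels),
        )

    def subset_obs(self, rows: np.ndarray) -> "ExpressionMatrix":
        rows = np.asarray(rows)
        return ExpressionMatrix(
            self.values[rows],
            [self.obs_ids[i] for i in rows],
            list(self.gene_ids),
            None if self.labels is None else [self.labels[i] for i in rows],
        )


@dataclass
class SpotTable:
    """Spot coordinates (spots x 2) plus the common capture radius ``r_s``."""

    coords: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("spot coords must be an s x 2 matrix")
        if self.coords.shape[0] < 1:
            raise ValueError("at least one spot is required")
        if not np.isfinite(self.coords).all():
            raise ValueError("spot coords must be finite")
        if not self.radius > 0:
            raise ValueError("spot radius must be positive")

    @property
    def n_spots(self) -> int:
        return self.coords.shape[0]

    def min_center_distance(self) -> float:
        """Minimum pairwise distance between spot centers."""
        from scipy.spatial.distance import pdist

        if self.n_spots < 2:
            raise ValueError("need >= 2 spots for a center distance")
        return float(pdist(self.coords).min())


@dataclass
class LRDatabase:
    """Ligand-receptor pair table, CellChatDB-style.

    Multi-subunit complexes are expected to be pre-flattened to per-gene
    pairs; duplicate (ligand, receptor) rows are collapsed on construction.
    """

    pairs: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str], tuple[str, str, str]] = {}
        for lig, rec, path in self.pairs:
            if not str(lig).strip() or not str(rec).strip():
                raise ValueError("ligand/receptor gene names must be non-empty")
            seen.setdefault((lig, rec), (lig, rec, path))
        self.pairs = list(seen.values())

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def ligands(self) -> list[str]:
        return [p[0] for p in self.pairs]

    @property
    def receptors(self) -> list[str]:
        return [p[1] for p in self.pairs]


# ---------------------------------------------------------------------------
# Expression readers / writers
# ---------------------------------------------------------------------------

def _dedup_genes(values: np.ndarray, gene_ids: list[str]) -> tuple[np.ndarray, list[str]]:
    """Sum duplicate gene columns (conserves counts, deterministic)."""
    if len(set(gene_ids)) == len(gene_ids):
        return values, gene_ids
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, g in enumerate(gene_ids):
        if g not in groups:
            groups[g] = []
            order.append(g)
        groups[g].append(i)
    out = np.column_stack([values[:, groups[g]].sum(axis=1) for g in order])
    return out, order


def _read_id_file(path: str) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_expression(path: str, format: str | None = None) -> ExpressionMatrix:
    """Read an expression matrix from dense CSV/TSV, MTX triplet, or HDF5.

    For ``.mtx`` input the observation and gene ids are taken from sidecar
    files ``<stem>_obs_ids.txt`` and ``<stem>_gene_ids.txt`` next to the
    matrix (rows = observations, columns = genes).  Duplicate gene columns
    are summed.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format is None:
        ext = os.path.splitext(path)[1].lower()
        format = {".csv": "csv", ".tsv": "tsv", ".mtx": "mtx",
                  ".h5": "h5", ".hdf5": "h5"}.get(ext)
        if format is None:
            raise ValueError(f"cannot infer format from extension of {path!r}")

    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        # read the header ourselves: pandas mangles duplicate gene columns
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)
        df = pd.read_csv(path, sep=sep, header=None, skiprows=1, index_col=0)
        values = df.to_numpy(dtype=float)
        obs_ids = [str(i) for i in df.index]
        gene_ids = [str(c) for c in header[1:]]
    elif format == "mtx":
        mat = spio.mmread(path)
        values = np.asarray(mat.todense() if sparse.issparse(mat) else mat, dtype=float)
        stem = os.path.splitext(path)[0]
        obs_ids = _read_id_file(stem + "_obs_ids.txt")
        gene_ids = _read_id_file(stem + "_gene_ids.txt")
        if len(obs_ids) != values.shape[0] or len(gene_ids) != values.shape[1]:
            raise ValueError(
                "id files do not match matrix dimensions: "
                f"matrix {values.shape}, {len(obs_ids)} obs ids, {len(gene_ids)} gene ids"
            )
    elif format == "h5":
        import h5py

        with h5py.File(path, "r") as fh:
            values = np.asarray(fh["values"], dtype=float)
            obs_ids = [s.decode() for s in fh["obs_ids"][...]]
            gene_ids = [s.decode() for s in fh["gene_ids"][...]]
        if len(obs_ids) != values.shape[0] or len(gene_ids) != values.shape[1]:
            raise ValueError("HDF5 id arrays do not match matrix dimensions")
    else:
        raise ValueError(f"unknown format {format!r}")

    values, gene_ids = _dedup_genes(values, gene_ids)
    return ExpressionMatrix(values, obs_ids, gene_ids)


def write_expression(E: ExpressionMatrix, path: str, format: str | None = None) -> None:
    """Write an expression matrix in any of the formats `read_expression` accepts."""
    if format is None:
        ext = os.path.splitext(path)[1].lower()
        format = {".csv": "csv", ".tsv": "tsv", ".mtx": "mtx",
                  ".h5": "h5", ".hdf5": "h5"}.get(ext, "csv")
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        pd.DataFrame(E.values, index=E.obs_ids, columns=E.gene_ids).to_csv(path, sep=sep)
    elif format == "mtx":
        spio.mmwrite(path, sparse.coo_matrix(E.values))
        stem = os.path.splitext(path)[0]
        for name, ids in (("_obs_ids.txt", E.obs_ids), ("_gene_ids.txt", E.gene_ids)):
            with open(stem + name, "w") as fh:
                fh.write("\n".join(ids) + "\n")
    elif format == "h5":
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("values", data=E.values)
            fh.create_dataset("obs_ids", data=np.array(E.obs_ids, dtype="S"))
            fh.create_dataset("gene_ids", data=np.array(E.gene_ids, dtype="S"))
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Ligand-receptor table
# ---------------------------------------------------------------------------

def read_lr_database(path: str) -> LRDatabase:
    """Read a ligand/receptor/pathway CSV into an `LRDatabase`."""
    df = pd.read_csv(path)
    required = {"ligand", "receptor", "pathway"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"LR table missing required columns: {sorted(missing)}")
    pairs = [
        (str(r.ligand), str(r.receptor), str(r.pathway))
        for r in df.itertuples(index=False)
    ]
    return LRDatabase(pairs)


# ---------------------------------------------------------------------------
# Result writers
# ---------------------------------------------------------------------------

def write_positions(state, path: str) -> None:
    """Write per-cell positions: columns id, x, y, spot_id, label."""
    n = state.positions.shape[0]
    ids = state.cell_ids if state.cell_ids is not None else [str(i) for i in range(n)]
    labels = state.labels if state.labels is not None else [""] * n
    df = pd.DataFrame({
        "id": ids,
        "x": state.positions[:, 0],
        "y": state.positions[:, 1],
        "spot_id": state.spot_index,
        "label": labels,
    })
    df.to_csv(path, index=False, float_format="%.17g")


def read_positions(path: str) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"id": str})


def write_shapes(shapes, path: str) -> None:
    """Write element clouds in long format: cell_id, element_index, x, y."""
    rows = []
    for i, cid in enumerate(shapes.cell_ids):
        for k in range(shapes.elements.shape[1]):
            rows.append((cid, k, shapes.elements[i, k, 0], shapes.elements[i, k, 1]))
    pd.DataFrame(rows, columns=["cell_id", "element_index", "x", "y"]).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_shapes(path: str) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"cell_id": str})


def write_scores(result, path: str) -> None:
    """Write cluster-level communication scores with permutation p-values."""
    rows = []
    for (src, dst, lig, rec), score in result.cluster_scores.items():
        pval = result.p_values.get((src, dst, lig, rec), np.nan)
        sig = result.significant.get((src, dst, lig, rec), False)
        rows.append((src, dst, lig, rec, score, pval, sig))
    pd.DataFrame(
        rows,
        columns=["cluster_src", "cluster_dst", "ligand", "receptor",
                 "score", "p_value", "significant"],
    ).to_csv(path, index=False, float_format="%.17g")
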