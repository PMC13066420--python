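"""End-to-end orchestration: preprocess -> map -> refine -> shape -> ccc -> eval.

A single master seed deterministically derives per-stage seeds; every stage
writes its artifact as CSV/MTX next to a JSON manifest recording the
configuration, derived seeds and input checksums.  Stages are resumable:
with ``resume=True`` a stage whose artifact already exists is skipped.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import ccc as ccc_mod
from . import io as cio
from . import mapping as mapping_mod
from . import metrics as metrics_mod
from . import preprocess as pp
from . import shapes as shapes_mod
from .refine import RefineConfig, lr_affinity
from .refine import refine as run_refine

__all__ = ["RunConfig", "run_pipeline", "stage_seeds"]

logger = logging.getLogger("cellplacer")


@dataclass
class RunConfig:
    """All stage parameters with their standard defaults."""

    # inputs (paths); leave None to run the bundled synthetic demo
    sc_path: str | None = None
    st_path: str | None = None
    coords_path: str | None = None
    spot_radius: float | None = None
    lr_path: str | None = None
    labels_path: str | None = None
    out_dir: str = "cellplacer_run"

    # mapping
    k: int = 5
    eta: float = 0.5
    embedding_provider: str = "smoothed-pca"
    rare_types: list[str] = field(default_factory=list)
    fgw_max_iter: int = 10000

    # refinement
    h: float = 20.0
    t_f: int = 10
    b: float = 0.05
    cap: float = 1.5
    use_lr: bool = False
    lr_threshold: float = 0.4

    # shapes
    n_e: int = 20
    dt: float = 0.04
    shape_iters: int = 2000
    radius_scaling: float = 2.5

    # ccc
    k_contact: int = 8
    n_perm: int = 100

    # misc
    seed: int = 0
    resume: bool = False
    run_shapes: bool = True
    run_ccc: bool = True

    def validate(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not (0.0 <= self.eta <= 1.0):
            raise ValueError("eta must lie in [0, 1]")
        if self.t_f < 1 or self.shape_iters < 1:
            raise ValueError("iteration counts must be positive")
        if self.h <= 0 or self.dt <= 0:
            raise ValueError("step sizes must be positive")
        if self.n_e < 3:
            raise ValueError("n_e must be >= 3")
        if self.k_contact < 1 or self.n_perm < 1:
            raise ValueError("k_contact and n_perm must be positive")


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Derive one independent sub-2^31 seed per stage from the master seed."""
    ss = np.random.SeedSequence(master_seed)
    names = ["simulate", "map", "refine", "shape", "ccc", "eval"]
    children = ss.spawn(len(names))
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))
        for name, child in zip(names, children)
    }


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _demo_inputs(out_dir: str, seed: int):
    """Synthetic paired inputs for the bundled demo."""
    from . import synthetic as syn

    gt = syn.generate_tissue(n_cells=300, n_types=3, n_genes=90, seed=seed)
    pv = syn.make_pseudo_visium(gt, grid_rows=8, grid_cols=8)
    sc = cio.ExpressionMatrix(
        gt.expression.values, gt.expression.obs_ids,
        gt.expression.gene_ids, labels=gt.types,
    )
    lr = cio.LRDatabase([("g0000", "g0030", "demo"), ("g0030", "g0060", "demo")])
    return sc, pv.expression, pv.spots, lr, gt


def run_pipeline(config: RunConfig) -> str:
    """Run every stage; returns the artifact directory.

    Any stage error aborts with the failing stage named.
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    log_path = os.path.join(config.out_dir, "run.log")
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    seeds = stage_seeds(config.seed)
    manifest: dict = {"config": asdict(config), "seeds": seeds, "inputs": {}}

    stage = "load"
    try:
        gt = None
        if config.sc_path is None:
            sc_raw, st_raw, spots, lrdb, gt = _demo_inputs(config.out_dir, seeds["simulate"])
        else:
            sc_raw = cio.read_expression(config.sc_path)
            st_raw = cio.read_expression(config.st_path)
            coords = pd.read_csv(config.coords_path, index_col=0).to_numpy(dtype=float)
            spots = cio.SpotTable(coords, float(config.spot_radius))
            lrdb = cio.LRDatabase([]) if config.lr_path is None else cio.read_lr_database(config.lr_path)
            if config.labels_path is not None:
                lab = pd.read_csv(config.labels_path, index_col=0).iloc[:, 0]
                sc_raw.labels = [str(x) for x in lab]
            for p in (config.sc_path, config.st_path, config.coords_path):
                manifest["inputs"][p] = _checksum(p)

        stage = "preprocess"
        sc = pp.filter_and_normalize(sc_raw)
        st = pp.filter_and_normalize(st_raw)
        # keep the spot table aligned with surviving spots
        if st.n_obs != st_raw.n_obs:
            keep = [st_raw.obs_ids.index(i) for i in st.obs_ids]
            spots = cio.SpotTable(spots.coords[keep], spots.radius)
        sc_sh, st_sh = pp.shared_genes(sc, st)
        markers = pp.select_marker_genes(sc_sh, seed=seeds["map"])
        S = sc_sh.subset_genes(markers)
        G = st_sh.subset_genes(markers)
        cell_emb = pp.pca_embed(sc_sh)
        lrdb_f = pp.filter_lr_genes(sc, lrdb)
        logger.info("preprocess: %d cells, %d spots, %d markers, %d LR pairs",
                    sc.n_obs, st.n_obs, len(markers), lrdb_f.n_pairs)

        stage = "map"
        map_path = os.path.join(config.out_dir, "assignment.csv")
        emb = mapping_mod.spot_embedding(st_sh, spots, provider=config.embedding_provider)
        problem = mapping_mod.build_costs(S, G, spots, emb, eta=config.eta)
        coupling = mapping_mod.fgw_map(problem, max_iter=config.fgw_max_iter)
        assignment = mapping_mod.assign_top_k(coupling, k=config.k)
        if config.rare_types:
            assignment = mapping_mod.map_rare_types(S, G, assignment, config.rare_types)
        rows = [(c, j) for j, cc in sorted(assignment.spot_cells.items()) for c in cc]
        pd.DataFrame(rows, columns=["cell", "spot"]).to_csv(map_path, index=False)
        logger.info("map: %d cells assigned over %d spots",
                    len(assignment.assigned_cells), len(assignment.spot_cells))

        stage = "refine"
        affinity = None
        if config.use_lr and lrdb_f.n_pairs > 0:
            affinity = lr_affinity(
                sc, lrdb_f, threshold=config.lr_threshold, seed=seeds["refine"])
        rconf = RefineConfig(
            h=config.h, t_f=config.t_f, b=config.b, cap=config.cap,
            use_lr=config.use_lr and affinity is not None,
        )
        traj = run_refine(
            assignment, spots, embeddings=cell_emb, affinity=affinity,
            config=rconf, seed=seeds["refine"],
            cell_ids=sc.obs_ids, labels=sc.labels,
        )
        final = traj[-1]
        cio.write_positions(final, os.path.join(config.out_dir, "positions.csv"))

        shapes = None
        if config.run_shapes:
            stage = "shape"
            cells = assignment.assigned_cells
            sp = shapes_mod.ShapeParams(
                n_e=config.n_e, dt=config.dt, t_max=config.shape_iters,
                radius_scaling=config.radius_scaling,
            )
            shapes = shapes_mod.init_elements(
                final.positions, sp, seed=seeds["shape"],
                embeddings=cell_emb.vectors[cells],
                cell_ids=[sc.obs_ids[i] for i in cells],
            )
            shapes = shapes_mod.simulate_shapes(shapes, sp, seed=seeds["shape"])
            cio.write_shapes(shapes, os.path.join(config.out_dir, "shapes.csv"))

        if config.run_ccc and shapes is not None and lrdb_f.n_pairs > 0:
            stage = "ccc"
            cells = assignment.assigned_cells
            E_cells = sc.subset_obs(np.asarray(cells))
            graph = ccc_mod.contact_graph(shapes, k=config.k_contact)
            res = ccc_mod.communication_scores(E_cells, lrdb_f, graph)
            res = ccc_mod.permutation_test(
                res, E_cells.labels, n_perm=config.n_perm, seed=seeds["ccc"])
            cio.write_scores(res, os.path.join(config.out_dir, "ccc.csv"))

        stage = "eval"
        report: dict = {"seeds": seeds}
        if gt is not None:
            cells = assignment.assigned_cells
            pred_labels = [gt.types[i] for i in cells]
            report["per_type_kl"] = metrics_mod.per_type_kl(
                final.positions, pred_labels, gt.positions, gt.types)
            _, nn_means = metrics_mod.same_type_nn_distance(final.positions, pred_labels)
            report["same_type_nn_mean"] = nn_means
        with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, default=float)

        with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
    return config.out_dir
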