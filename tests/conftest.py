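import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def small_expression():
    """Tiny deterministic cell x gene count matrix with labels."""
    from cellplacer.io import ExpressionMatrix

    rng = np.random.default_rng(42)
    n_cells, n_genes = 30, 12
    base = rng.poisson(3.0, size=(n_cells, n_genes)).astype(float)
    labels = ["A"] * 15 + ["B"] * 15
    base[:15, 0] += 20    # gene g00 marks type A
    base[15:, 1] += 20    # gene g01 marks type B
    return ExpressionMatrix(
        base,
        [f"c{i}" for i in range(n_cells)],
        [f"g{j:02d}" for j in range(n_genes)],
        labels=labels,
    )


@pytest.fixture
def layered_tissue():
    """Small layered ground-truth tissue shared by mapping/refinement tests."""
    from cellplacer.synthetic import generate_tissue

    return generate_tissue(n_cells=300, n_types=3, n_genes=90, seed=7)


def preprocess_pair(gt, grid=8):
    """Ground truth -> (S, G, spots, sc_shared, st_shared, pseudo) on markers."""
    from cellplacer import preprocess as pp
    from cellplacer.io import ExpressionMatrix, SpotTable
    from cellplacer.synthetic import make_pseudo_visium

    pv = make_pseudo_visium(gt, grid, grid, n_max=5)
    sc = ExpressionMatrix(
        gt.expression.values, gt.expression.obs_ids, gt.expression.gene_ids,
        labels=gt.types,
    )
    sc_n = pp.filter_and_normalize(sc)
    st_n = pp.filter_and_normalize(pv.expression)
    keep = [pv.expression.obs_ids.index(i) for i in st_n.obs_ids]
    spots = SpotTable(pv.spots.coords[keep], pv.spots.radius)
    sc_sh, st_sh = pp.shared_genes(sc_n, st_n)
    markers = pp.select_marker_genes(sc_sh)
    return sc_sh.subset_genes(markers), st_sh.subset_genes(markers), spots, sc_sh, st_sh, pv
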