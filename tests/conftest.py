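import numpy as np
import pytest
import scipy.sparse as sp

from cardimap.core_io import CellMeta, ExpressionMatrix
from cardimap.syndata import default_config, simulate_two_species


def make_matrix(counts, gene_ids=None, cell_ids=None, species="other"):
    counts = np.asarray(counts)
    g, c = counts.shape
    if gene_ids is None:
        gene_ids = [f"G{i}" for i in range(g)]
    if cell_ids is None:
        cell_ids = [f"C{i}" for i in range(c)]
    return ExpressionMatrix(sp.csr_matrix(counts), np.array(gene_ids, dtype=object),
                            np.array(cell_ids, dtype=object), species)


def make_meta(cell_ids, stages, stage_order, batch="b0", **extra):
    import pandas as pd

    table = pd.DataFrame({"stage": stages, "batch": batch, **extra},
                         index=pd.Index(cell_ids, name="cell_id"))
    return CellMeta(table, list(stage_order))


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition two-species simulation shared across tests."""
    cfg = default_config(seed=11)
    mat_h, mat_m, meta_h, meta_m, omap, truth = simulate_two_species(cfg)
    return {"config": cfg, "mat_h": mat_h, "mat_m": mat_m, "meta_h": meta_h,
            "meta_m": meta_m, "omap": omap, "truth": truth}


@pytest.fixture(scope="session")
def small_sim():
    """A scaled-down simulation for fast unit tests."""
    cfg = default_config(
        seed=5, n_genes=800, n_types=3, markers_per_type=20,
        n_dynamic_genes=90,
        human_stages=[("5W", 0.1, 80), ("9W", 0.5, 80), ("25W", 0.9, 80)],
        mouse_stages=[("e8.5", 0.15, 80), ("e10.5", 0.55, 80),
                      ("e14.5", 0.85, 120)],
        human_batches=["strt"] * 3,
        mouse_batches=["smartseq", "smartseq", "droplet"],
    )
    mat_h, mat_m, meta_h, meta_m, omap, truth = simulate_two_species(cfg)
    return {"config": cfg, "mat_h": mat_h, "mat_m": mat_m, "meta_h": meta_h,
            "meta_m": meta_m, "omap": omap, "truth": truth}
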