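"""Per-cell quality control and artificial-nearest-neighbor doublet detection.

Species/platform presets carry the published filter settings: human UMI data
keeps cells with at least 1,000 detected genes and at least 5,000 transcripts;
deep full-length mouse data keeps cells with strictly more than 1,800 detected
genes and at least 1e6 transcripts; all presets drop cells whose mitochondrial
fraction exceeds 30% (the heart tolerates unusually high mitochondrial
content, so the cutoff is generous). "Transcripts" means column sums of the
count matrix for both UMI and read-count chemistries.

Doublet calling is a pANN (proportion of artificial nearest neighbors)
scheme: artificial doublets are averaged random cell pairs, real and
artificial cells are embedded together by PCA of log-normalized highly
variable genes, each real cell is scored by the fraction of artificial
points among its k nearest neighbors, and the top ``round(expected_rate x
n_cells)`` scores are flagged. It deliberately omits the parameter sweeps
and homotypic adjustments of heavier doublet callers; only the contract
(likely doublets removed before clustering) matters downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .core_io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["QCThresholds", "PRESETS", "compute_cell_qc", "filter_cells",
           "detect_doublets"]


@dataclass(frozen=True)
class QCThresholds:
    """Cell-filter settings.

    ``genes_strict`` selects strictly-greater-than semantics for the
    detected-gene threshold (the deep full-length preset); the default is
    at-least semantics.
    """

    min_genes: int = 0
    min_transcripts: float = 0
    max_mito_frac: float = 1.0
    mito_prefix: str = "MT-"
    genes_strict: bool = False

    def __post_init__(self) -> None:
        if self.min_genes < 0:
            raise ValueError("min_genes must be >= 0")
        if not 0.0 <= self.max_mito_frac <= 1.0:
            raise ValueError("max_mito_frac must be in [0, 1]")


PRESETS: dict[str, QCThresholds] = {
    "human": QCThresholds(min_genes=1000, min_transcripts=5000,
                          max_mito_frac=0.30, mito_prefix="MT-"),
    "mouse_smartseq": QCThresholds(min_genes=1800, min_transcripts=1e6,
                                   max_mito_frac=0.30, mito_prefix="mt-",
                                   genes_strict=True),
    # droplet data cannot reach full-length read depths; thresholds follow
    # the UMI preset with the mouse mito naming convention
    "mouse_droplet": QCThresholds(min_genes=1000, min_transcripts=5000,
                                  max_mito_frac=0.30, mito_prefix="mt-"),
}


def compute_cell_qc(matrix: ExpressionMatrix, mito_prefix: str = "MT-") -> pd.DataFrame:
    """Per-cell QC metrics: detected genes, total transcripts, mito fraction.

    Cells with zero total counts get ``mito_frac = 0`` and are flagged
    ``degenerate``.
    """
    m = matrix.values.tocsc()
    n_genes_detected = np.asarray((m > 0).sum(axis=0)).ravel()
    n_transcripts = np.asarray(m.sum(axis=0)).ravel().astype(float)
    mito_mask = np.array([str(g).startswith(mito_prefix) for g in matrix.gene_ids])
    mito_counts = (np.asarray(m[mito_mask].sum(axis=0)).ravel().astype(float)
                   if mito_mask.any() else np.zeros(matrix.n_cells))
    degenerate = n_transcripts == 0
    mito_frac = np.zeros(matrix.n_cells)
    nz = ~degenerate
    mito_frac[nz] = mito_counts[nz] / n_transcripts[nz]
    return pd.DataFrame({
        "n_genes_detected": n_genes_detected,
        "n_transcripts": n_transcripts,
        "mito_frac": mito_frac,
        "degenerate": degenerate,
    }, index=pd.Index(matrix.cell_ids, name="cell_id"))


def qc_pass_mask(qc: pd.DataFrame, thr: QCThresholds) -> np.ndarray:
    genes_ok = (qc["n_genes_detected"] > thr.min_genes if thr.genes_strict
                else qc["n_genes_detected"] >= thr.min_genes)
    keep = (genes_ok
            & (qc["n_transcripts"] >= thr.min_transcripts)
            & (qc["mito_frac"] <= thr.max_mito_frac))
    return keep.to_numpy()


def filter_cells(matrix: ExpressionMatrix, qc: pd.DataFrame,
                 thr: QCThresholds) -> ExpressionMatrix:
    """Keep cells passing all three thresholds; order and genes unchanged."""
    missing = [c for c in matrix.cell_ids if c not in qc.index]
    if missing:
        raise ValueError(f"QC table missing cells: {missing[:5]}")
    qc = qc.loc[list(matrix.cell_ids)]
    keep = qc_pass_mask(qc, thr)
    if not keep.any():
        raise ValueError(
            "all cells removed by QC thresholds; review min_genes/"
            "min_transcripts/max_mito_frac against the data's depth"
        )
    return matrix.subset_cells(keep)


def detect_doublets(matrix: ExpressionMatrix, n_artificial: int | None = None,
                    k_neighbors: int = 20, expected_rate: float = 0.075,
                    seed: int = 0, n_hvg: int = 2000, n_pcs: int = 20) -> pd.DataFrame:
    """pANN doublet scores and calls.

    Returns a per-cell table with ``pann_score`` in [0, 1] and ``is_doublet``;
    exactly ``round(expected_rate * n_cells)`` cells are flagged (the
    rank-threshold rule). Deterministic given ``seed``.
    """
    from .embed import lognormalize, run_pca, select_hvg

    if expected_rate >= 0.5:
        raise ValueError(f"expected_rate={expected_rate} is implausibly high (>= 0.5)")
    if expected_rate < 0:
        raise ValueError("expected_rate must be nonnegative")
    n = matrix.n_cells
    if n < k_neighbors + 1:
        raise ValueError(f"need at least k_neighbors+1={k_neighbors + 1} cells, got {n}")
    if n_artificial is None:
        n_artificial = max(1, int(round(0.25 * n)))
    rng = np.random.default_rng(seed)

    n_flag = int(round(expected_rate * n))
    index = pd.Index(matrix.cell_ids, name="cell_id")
    if n_flag == 0 and expected_rate == 0:
        return pd.DataFrame({"pann_score": np.zeros(n),
                             "is_doublet": np.zeros(n, bool)}, index=index)

    pairs = rng.integers(0, n, size=(n_artificial, 2))
    counts = matrix.values.tocsc()
    art = counts[:, pairs[:, 0]] + counts[:, pairs[:, 1]]
    combined = ExpressionMatrix(
        sp.hstack([counts, art]).tocsr(),
        matrix.gene_ids,
        np.concatenate([matrix.cell_ids,
                        np.array([f"__art{i}" for i in range(n_artificial)], object)]),
        matrix.species,
    )
    norm = lognormalize(combined, allow_zero_cells=True)
    hvg = select_hvg(norm, n=min(n_hvg, matrix.n_genes))
    emb = run_pca(norm, hvg, d=min(n_pcs, len(hvg), combined.n_cells - 1), seed=seed)

    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(emb.scores)
    _, idx = nn.kneighbors(emb.scores[:n])
    neigh = idx[:, 1:]  # drop self
    pann = (neigh >= n).mean(axis=1)

    # rank-threshold: flag the top n_flag scores; ties broken by cell order
    order = np.lexsort((np.arange(n), -pann))
    is_doublet = np.zeros(n, bool)
    is_doublet[order[:n_flag]] = True
    return pd.DataFrame({"pann_score": pann, "is_doublet": is_doublet}, index=index)
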