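"""Cross-species developmental-stage projection via an oriented PC1 axis.

For one cell type, the human cells' core genes (detected in at least 75% of
the cells) are z-scored and decomposed by PCA; PC1 separates developmental
stages as overlapping, stepwise clusters ordered by age, so it serves as a
maturation axis. The axis is oriented so PC1 increases with stage rank, and
a Gaussian kernel density of the oriented PC1 scores is estimated per human
stage on a shared grid.

Mouse cells of the homologous type are then projected *onto the human axis*:
loadings are restricted to core genes with orthologs detected in the mouse
matrix, renormalized to unit norm (compensating ortholog dropout), and the
mouse expression is standardized with the HUMAN gene statistics -- the only
choice that keeps the dot product on the human axis geometrically coherent.
Each mouse stage is assigned the human stage whose density is highest at the
mouse stage's mean PC1; ties break toward the earlier human stage.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .core_io import CellMeta, NormMatrix, OrthologMap
from .embed import CLIP, run_pca

logger = logging.getLogger(__name__)

__all__ = ["select_core_genes", "StageAxisModel", "fit_stage_axis",
           "project_other_species", "map_stages", "stage_posteriors"]

GRID_SIZE = 512
BW_FLOOR_FRAC = 0.01  # bandwidth floor as a fraction of the PC1 range


def select_core_genes(norm: NormMatrix, min_fraction: float = 0.75) -> list[str]:
    """Genes detected (count > 0) in at least ``min_fraction`` of the cells."""
    if not 0.0 < min_fraction <= 1.0:
        raise ValueError("min_fraction must be in (0, 1]")
    frac = np.asarray((norm.values > 0).mean(axis=1)).ravel()
    genes = [str(g) for g, f in zip(norm.gene_ids, frac) if f >= min_fraction]
    if not genes:
        raise ValueError(
            f"no gene detected in >= {min_fraction:.0%} of cells; "
            "lower min_fraction"
        )
    return genes


@dataclass
class StageAxisModel:
    """Oriented PC1 axis with per-stage kernel density estimates.

    ``pc1_loadings`` has unit Euclidean norm; ``orientation`` is +/-1 and is
    already folded into the stored loadings' usage via :meth:`score`.
    ``stage_densities`` maps each human stage label to ``(grid, density,
    bandwidth)`` where the 512-point grid spans the observed PC1 range padded
    by three bandwidths.
    """

    core_genes: list[str]
    gene_means: np.ndarray
    gene_sds: np.ndarray
    pc1_loadings: np.ndarray
    orientation: int
    stage_densities: dict[str, tuple[np.ndarray, np.ndarray, float]]
    stage_order: list[str]
    train_scores: np.ndarray | None = None
    train_stages: np.ndarray | None = None

    def score(self, z: np.ndarray) -> np.ndarray:
        """Oriented PC1 score of z-scored rows (cells x core genes)."""
        return self.orientation * (z @ self.pc1_loadings)

    def to_json(self) -> str:
        payload = {
            "core_genes": list(self.core_genes),
            "gene_means": self.gene_means.tolist(),
            "gene_sds": self.gene_sds.tolist(),
            "pc1_loadings": self.pc1_loadings.tolist(),
            "orientation": int(self.orientation),
            "stage_order": list(self.stage_order),
            "stage_densities": {
                s: {"grid": g.tolist(), "density": d.tolist(), "bandwidth": bw}
                for s, (g, d, bw) in self.stage_densities.items()
            },
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "StageAxisModel":
        p = json.loads(text)
        return cls(
            core_genes=p["core_genes"],
            gene_means=np.asarray(p["gene_means"]),
            gene_sds=np.asarray(p["gene_sds"]),
            pc1_loadings=np.asarray(p["pc1_loadings"]),
            orientation=int(p["orientation"]),
            stage_densities={
                s: (np.asarray(v["grid"]), np.asarray(v["density"]),
                    float(v["bandwidth"]))
                for s, v in p["stage_densities"].items()
            },
            stage_order=p["stage_order"],
        )


def _stage_kde(scores: np.ndarray, grid: np.ndarray, bw: float) -> np.ndarray:
    return scipy.stats.norm.pdf(grid[:, None], scores[None, :], bw).mean(axis=1)


def fit_stage_axis(norm_h: NormMatrix, meta: CellMeta, core_genes,
                   seed: int = 0) -> StageAxisModel:
    """Fit the oriented PC1 stage axis on one cell type's human cells.

    Requires at least two stages with five or more cells each. The axis sign
    is chosen so the Spearman correlation between PC1 score and stage rank is
    nonnegative.
    """
    stages = meta.stages(norm_h.cell_ids)
    counts = stages.value_counts()
    usable = [s for s in meta.stage_order if counts.get(s, 0) >= 5]
    if len(usable) < 2:
        raise ValueError("need >= 2 stages with >= 5 cells each")

    emb = run_pca(norm_h, list(core_genes), d=1, seed=seed)
    pc1 = emb.scores[:, 0]
    rank = meta.stage_rank(norm_h.cell_ids)
    rho = scipy.stats.spearmanr(pc1, rank).statistic
    orientation = 1 if (np.isnan(rho) or rho >= 0) else -1
    pc1 = orientation * pc1

    stage_arr = stages.astype(str).to_numpy()
    rng_lo, rng_hi = float(pc1.min()), float(pc1.max())
    span = max(rng_hi - rng_lo, 1e-12)
    densities: dict[str, tuple[np.ndarray, np.ndarray, float]] = {}
    for s in usable:
        scores = pc1[stage_arr == s]
        # Scott's rule with a floor so tiny stages do not degenerate
        bw = scores.std(ddof=1) * len(scores) ** (-1 / 5) if len(scores) > 1 else 0.0
        bw = max(bw, BW_FLOOR_FRAC * span)
        grid = np.linspace(rng_lo - 3 * bw, rng_hi + 3 * bw, GRID_SIZE)
        densities[s] = (grid, _stage_kde(scores, grid, bw), bw)

    return StageAxisModel(
        core_genes=[str(g) for g in core_genes],
        gene_means=emb.gene_means,
        gene_sds=emb.gene_sds,
        pc1_loadings=emb.loadings[:, 0],
        orientation=orientation,
        stage_densities=densities,
        stage_order=[s for s in meta.stage_order if s in densities],
        train_scores=pc1,
        train_stages=stage_arr,
    )


def project_other_species(model: StageAxisModel, norm_m: NormMatrix,
                          omap: OrthologMap, min_coverage: float = 0.5,
                          ) -> np.ndarray:
    """Project another species' cells onto the human PC1 axis.

    Core-gene loadings are restricted to ortholog pairs detected in the query
    matrix and renormalized to unit norm; query expression is standardized
    with the stored (human) gene statistics. Raises if fewer than
    ``min_coverage`` of the core genes are covered.
    """
    h2m = omap.a_to_b()
    present = {str(g): i for i, g in enumerate(norm_m.gene_ids)}
    detected = np.asarray((norm_m.values > 0).sum(axis=1)).ravel() > 0
    shared_pos = []   # index into core_genes
    query_rows = []   # row index in the query matrix
    for i, g in enumerate(model.core_genes):
        partner = h2m.get(g)
        if partner is not None and partner in present and detected[present[partner]]:
            shared_pos.append(i)
            query_rows.append(present[partner])
    coverage = len(shared_pos) / len(model.core_genes)
    if coverage < min_coverage:
        raise ValueError(
            f"ortholog coverage of core genes is {coverage:.1%}, below "
            f"the required {min_coverage:.0%}"
        )
    shared_pos = np.asarray(shared_pos, dtype=int)
    loadings = model.pc1_loadings[shared_pos]
    nrm = np.linalg.norm(loadings)
    if nrm == 0:
        raise ValueError("restricted loading vector has zero norm")
    loadings = loadings / nrm

    x = np.asarray(norm_m.values[np.asarray(query_rows, dtype=int)].todense()).T
    z = np.clip((x - model.gene_means[shared_pos]) / model.gene_sds[shared_pos],
                -CLIP, CLIP)
    return model.orientation * (z @ loadings)


def _density_at(model: StageAxisModel, stage: str, value: float) -> tuple[float, bool]:
    grid, dens, _ = model.stage_densities[stage]
    out_of_range = value < grid[0] or value > grid[-1]
    return float(np.interp(value, grid, dens)), out_of_range


def map_stages(model: StageAxisModel, query_pc1, query_stage_labels) -> pd.DataFrame:
    """Assign each query stage to the human stage of maximal density.

    For every query (mouse) stage, its mean PC1 is evaluated against every
    human stage's KDE by linear interpolation on the stored grid; the best
    and runner-up human stages are reported. Ties break toward the earlier
    human stage and are flagged; a mean outside all grids is evaluated at the
    nearest grid endpoint and flagged ``out_of_range``.
    """
    pc1 = np.asarray(query_pc1, dtype=float)
    labels = np.asarray(query_stage_labels, dtype=object)
    if len(pc1) != len(labels):
        raise ValueError("every query cell needs a stage label")
    rows = []
    for s in pd.unique(labels):
        mean_pc1 = float(pc1[labels == s].mean())
        evals = {}
        any_in_range = False
        for hs in model.stage_order:
            d, oor = _density_at(model, hs, mean_pc1)
            evals[hs] = d
            any_in_range = any_in_range or not oor
        ranked = sorted(model.stage_order,
                        key=lambda hs: (-evals[hs], model.stage_order.index(hs)))
        best = ranked[0]
        runner = ranked[1] if len(ranked) > 1 else ""
        tie = runner != "" and np.isclose(evals[best], evals[runner], rtol=0,
                                          atol=1e-300 + 1e-9 * abs(evals[best]))
        rows.append({
            "query_stage": s,
            "mean_pc1": mean_pc1,
            "best_human_stage": best,
            "best_density": evals[best],
            "runner_up_stage": runner,
            "runner_up_density": evals[runner] if runner else np.nan,
            "tie": bool(tie),
            "out_of_range": not any_in_range,
        })
    return pd.DataFrame(rows)


def stage_posteriors(model: StageAxisModel, query_pc1) -> pd.DataFrame:
    """Per-cell soft stage assignment: normalized density over human stages."""
    pc1 = np.asarray(query_pc1, dtype=float)
    cols = {}
    for hs in model.stage_order:
        grid, dens, _ = model.stage_densities[hs]
        cols[hs] = np.interp(pc1, grid, dens)
    out = pd.DataFrame(cols)
    total = out.sum(axis=1)
    total[total == 0] = 1.0
    return out.div(total, axis=0)
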