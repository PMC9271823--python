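"""Pseudotime trajectories, pseudotime differential expression, gene phases.

The trajectory is a centroid-MST scheme (Monocle-1/TSCAN family): PCA of the
ordering genes, k-means centroids, a minimum spanning tree over centroids,
cells assigned to their nearest centroid, and pseudotime measured as
geodesic tree distance from a root centroid (the one most enriched for
earliest-stage cells) plus the cell's signed projection onto its incident
edge, min-max scaled to [0, 1].

Pseudotime-dependent genes are found by a likelihood-ratio test of a
negative-binomial regression (log link, library-size offset) with a natural
cubic spline in pseudotime (3 df) against an intercept-only model, chi-square
with 3 df, BH-corrected. Significant genes are partitioned into three phases
-- initial, transitional, terminal -- by where their smoothed, z-scored
profile peaks over the pseudotime tertiles; in the heart-development setting
these correspond to genes highly expressed at the beginning of the
trajectory (proliferative, immature programs) and at its end (sarcomere and
contraction programs).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
import statsmodels.api as sm
from scipy.sparse.csgraph import minimum_spanning_tree, shortest_path
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .core_io import CellMeta, ExpressionMatrix, NormMatrix
from .embed import run_pca

logger = logging.getLogger(__name__)

__all__ = ["filter_trajectory_genes", "select_ordering_genes", "fit_trajectory",
           "test_pseudotime_dependence", "assign_trajectory_phases",
           "subpopulation_density", "Trajectory", "natural_spline_basis"]


def natural_spline_basis(x: np.ndarray, df: int = 3,
                         knots: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Natural cubic spline basis (no intercept column) and its knots.

    Boundary knots at min/max of ``x``; ``df - 1`` interior knots at
    quantiles. Returns ``(basis, knots)`` with ``basis.shape == (len(x), df)``.
    """
    x = np.asarray(x, dtype=float)
    if knots is None:
        qs = np.linspace(0, 1, df + 1)
        knots = np.quantile(x, qs)
        knots = np.unique(knots)
        if len(knots) < 2:  # degenerate (constant x): linear fallback
            knots = np.array([knots[0], knots[0] + 1.0])
    k = knots
    K = len(k)

    def dk(j: int, t: np.ndarray) -> np.ndarray:
        num = np.maximum(t - k[j], 0) ** 3 - np.maximum(t - k[K - 1], 0) ** 3
        return num / (k[K - 1] - k[j])

    cols = [x]
    for j in range(K - 2):
        cols.append(dk(j, x) - dk(K - 2, x))
    basis = np.column_stack(cols)
    return basis[:, :df], k


def filter_trajectory_genes(matrix: ExpressionMatrix) -> list[str]:
    """Genes detected in at least max(10, ceil(5% of cells)) cells."""
    n_cells = matrix.n_cells
    threshold = max(10, int(np.ceil(0.05 * n_cells)))
    detected = np.asarray((matrix.values > 0).sum(axis=1)).ravel()
    genes = [str(g) for g, d in zip(matrix.gene_ids, detected) if d >= threshold]
    if not genes:
        raise ValueError("no gene passes the trajectory detection filter")
    return genes


def select_ordering_genes(norm: NormMatrix, stages, q_cut: float = 0.01,
                          top_n: int = 1000) -> list[str]:
    """Stage-differential genes (Kruskal-Wallis, BH) ranked by statistic."""
    stages = np.asarray(stages, dtype=object)
    groups = []
    for s in pd.unique(stages):
        mask = stages == s
        if mask.sum() < 3:
            warnings.warn(f"stage {s!r} has fewer than 3 cells; excluded from test")
            continue
        groups.append(np.flatnonzero(mask))
    if len(groups) < 2:
        raise ValueError("need at least 2 stages with >= 3 cells")
    x = np.asarray(norm.values.todense())
    stats = np.zeros(norm.n_genes)
    pvals = np.ones(norm.n_genes)
    for gi in range(norm.n_genes):
        samples = [x[gi, g] for g in groups]
        if all(np.all(s == samples[0][0]) for s in samples):
            continue  # constant gene
        try:
            h, p = scipy.stats.kruskal(*samples)
        except ValueError:  # all identical values
            continue
        stats[gi], pvals[gi] = h, p
    qvals = multipletests(pvals, method="fdr_bh")[1]
    hits = np.flatnonzero(qvals < q_cut)
    hits = hits[np.argsort(-stats[hits], kind="stable")][:top_n]
    return [str(norm.gene_ids[i]) for i in hits]


class Trajectory:
    """Centroid-MST trajectory with per-cell pseudotime in [0, 1]."""

    def __init__(self, centroids, edges, cell_assignment, pseudotime, root_node,
                 cell_ids):
        self.centroids = centroids          # n_nodes x d
        self.edges = edges                  # list of (i, j)
        self.cell_assignment = cell_assignment
        self.pseudotime = pseudotime
        self.root_node = int(root_node)
        self.cell_ids = cell_ids


def fit_trajectory(norm: NormMatrix, genes, meta: CellMeta, n_nodes: int = 15,
                   d: int = 2, seed: int = 0) -> Trajectory:
    """Fit the centroid-MST trajectory and root it at the earliest stage.

    The root centroid is the one whose assigned cells have the largest
    fraction belonging to the earliest observed stage (ties to the smaller
    node id); stage order comes from ``meta``, never from label sorting.
    """
    genes = list(genes)
    if len(genes) < d:
        raise ValueError(f"need at least d={d} ordering genes, got {len(genes)}")
    n_cells = norm.n_cells
    if n_nodes > n_cells:
        raise ValueError(f"n_nodes={n_nodes} exceeds n_cells={n_cells}")
    emb = run_pca(norm, genes, d=d, seed=seed)
    x = emb.scores

    km = KMeans(n_clusters=n_nodes, n_init=5, random_state=seed).fit(x)
    centroids = km.cluster_centers_
    assignment = km.labels_

    dist = np.linalg.norm(centroids[:, None, :] - centroids[None, :, :], axis=2)
    mst = minimum_spanning_tree(dist)
    mst = mst + mst.T  # symmetric adjacency of the tree
    edges = [(int(i), int(j)) for i, j in zip(*sp.triu(mst).nonzero())]

    stage_rank = meta.stage_rank(norm.cell_ids)
    earliest = stage_rank.min()
    frac_early = np.zeros(n_nodes)
    for v in range(n_nodes):
        cells_v = assignment == v
        if cells_v.any():
            frac_early[v] = (stage_rank[cells_v] == earliest).mean()
    # ties (several purely-earliest nodes) break toward the most peripheral
    # node of the tree: a trajectory starts at an extreme, not mid-path
    all_dist = shortest_path(mst, directed=False)
    candidates = np.flatnonzero(frac_early >= frac_early.max() - 1e-9)
    root = int(candidates[np.argmax(all_dist[candidates].sum(axis=1))])

    node_dist = shortest_path(mst, directed=False, indices=root)
    # predecessor direction for the signed within-node offset
    _, predecessors = shortest_path(mst, directed=False, indices=root,
                                    return_predecessors=True)
    directions = np.zeros_like(centroids)
    for v in range(n_nodes):
        if v == root:
            # point from the root toward its nearest tree neighbor
            nbrs = [j for i, j in edges if i == root] + \
                   [i for i, j in edges if j == root]
            ref = centroids[nbrs[0]] - centroids[root] if nbrs else None
        else:
            ref = centroids[v] - centroids[predecessors[v]]
        if ref is not None and np.linalg.norm(ref) > 0:
            directions[v] = ref / np.linalg.norm(ref)

    offset = np.einsum("ij,ij->i", x - centroids[assignment],
                       directions[assignment])
    pt = node_dist[assignment] + offset
    lo, hi = pt.min(), pt.max()
    pt = (pt - lo) / (hi - lo) if hi > lo else np.zeros_like(pt)
    return Trajectory(centroids, edges, assignment, pt, root,
                      np.asarray(norm.cell_ids, dtype=object))


def _fit_nb_glm(y, design, offset, alpha):
    fam = (sm.families.Poisson() if alpha < 1e-8
           else sm.families.NegativeBinomial(alpha=alpha))
    model = sm.GLM(y, design, family=fam, offset=offset)
    return model.fit(maxiter=100, tol=1e-8)


def test_pseudotime_dependence(counts: ExpressionMatrix, pseudotime,
                               df: int = 3) -> pd.DataFrame:
    """Negative-binomial spline LRT of pseudotime dependence per gene.

    The gene-wise dispersion is estimated by moments under the intercept-only
    model and held fixed in both fits, so the chi-square reference for the
    likelihood ratio is well calibrated under the null. Genes whose fits fail
    get ``p_value = 1`` and ``converged = False``.
    """
    pt = np.asarray(pseudotime, dtype=float)
    if not np.all(np.isfinite(pt)):
        raise ValueError("pseudotime must be finite")
    lib = np.asarray(counts.values.sum(axis=0)).ravel().astype(float)
    if (lib == 0).any():
        raise ValueError("cells with zero library size")
    offset = np.log(lib)
    basis, _ = natural_spline_basis(pt, df=df)
    x_full = sm.add_constant(basis, has_constant="add")
    x_null = np.ones((len(pt), 1))
    dense = np.asarray(counts.values.todense())

    records = []
    for gi in range(counts.n_genes):
        y = dense[gi].astype(float)
        gene = str(counts.gene_ids[gi])
        if y.max() == 0:
            records.append({"gene": gene, "lrt_stat": 0.0, "p_value": 1.0,
                            "converged": False})
            continue
        try:
            # moment dispersion under the null: mu = L * (sum y / sum L)
            mu0 = lib * y.sum() / lib.sum()
            alpha = float(((y - mu0) ** 2 - mu0).sum() / (mu0**2).sum())
            alpha = min(max(alpha, 0.0), 100.0)
            fit_null = _fit_nb_glm(y, x_null, offset, alpha)
            fit_full = _fit_nb_glm(y, x_full, offset, alpha)
            lrt = max(2.0 * (fit_full.llf - fit_null.llf), 0.0)
            p = float(scipy.stats.chi2.sf(lrt, df))
            converged = bool(getattr(fit_full, "converged", True))
            if not np.isfinite(lrt) or not np.isfinite(p):
                raise FloatingPointError
        except Exception:
            lrt, p, converged = 0.0, 1.0, False
        records.append({"gene": gene, "lrt_stat": lrt, "p_value": p,
                        "converged": converged})
    out = pd.DataFrame(records)
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def assign_trajectory_phases(norm: NormMatrix, pseudotime, significant_genes,
                             df: int = 3, n_grid: int = 100) -> pd.Series:
    """Phase (initial / transitional / terminal) per significant gene.

    Each gene's log-normalized expression is spline-smoothed on a pseudotime
    grid, z-scored, and averaged within the three tertiles of [0, 1]; the
    argmax tertile names the phase, ties go to ``transitional``.
    """
    genes = list(significant_genes)
    if not genes:
        raise ValueError("significant_genes is empty")
    pt = np.asarray(pseudotime, dtype=float)
    basis, knots = natural_spline_basis(pt, df=df)
    design = sm.add_constant(basis, has_constant="add")
    grid = np.linspace(0.0, 1.0, n_grid)
    gb, _ = natural_spline_basis(grid, df=df, knots=knots)
    grid_design = sm.add_constant(gb, has_constant="add")

    idx = norm.gene_index(genes)
    x = np.asarray(norm.values[idx].todense())
    coef, *_ = np.linalg.lstsq(design, x.T, rcond=None)
    smooth = grid_design @ coef  # grid x genes
    mu = smooth.mean(axis=0)
    sd = smooth.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z = (smooth - mu) / sd

    tertile = np.minimum((grid * 3).astype(int), 2)
    means = np.stack([z[tertile == t].mean(axis=0) for t in range(3)])
    names = np.array(["initial", "transitional", "terminal"], dtype=object)
    top = means.max(axis=0)
    phases = []
    for j in range(len(genes)):
        winners = np.flatnonzero(np.isclose(means[:, j], top[j], atol=1e-12))
        phases.append("transitional" if len(winners) > 1 else names[winners[0]])
    return pd.Series(phases, index=pd.Index(genes, name="gene"), name="phase")


def subpopulation_density(pseudotime, subpop_labels, n_grid: int = 200,
                          min_bandwidth: float = 0.05) -> pd.DataFrame:
    """Gaussian KDE of each subpopulation over a shared [0, 1] grid.

    Scott's rule bandwidth with a fixed minimum for degenerate (size-1 or
    constant) subpopulations; each curve is renormalized to unit trapezoid
    integral over the grid.
    """
    pt = np.asarray(pseudotime, dtype=float)
    labels = np.asarray(subpop_labels, dtype=object)
    if len(labels) != len(pt):
        raise ValueError("one label per cell required")
    if len(labels) == 0:
        raise ValueError("at least one labeled cell required")
    grid = np.linspace(0.0, 1.0, n_grid)
    curves = {}
    for s in sorted(set(labels)):
        pts = pt[labels == s]
        if len(pts) < 2 or pts.std() == 0:
            bw = min_bandwidth
            dens = scipy.stats.norm.pdf(grid[:, None], pts[None, :], bw).mean(axis=1)
        else:
            kde = scipy.stats.gaussian_kde(pts, bw_method="scott")
            dens = kde(grid)
        integral = np.trapezoid(dens, grid)
        curves[s] = dens / integral if integral > 0 else dens
    out = pd.DataFrame(curves, index=pd.Index(grid, name="pseudotime"))
    return out
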