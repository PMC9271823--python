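"""Normalization, HVG selection, PCA, geometric sketching, batch alignment.

The preprocessing chain mirrors standard single-cell practice: library-size
log-normalization with a scale factor of 10,000; top-2,000 highly variable
genes ranked by a variance-stabilized dispersion (per-gene variance of the
log values divided by the median variance of its 20-quantile mean bin);
per-gene z-scoring clipped at +/-10 before PCA.

Geometric sketching balances platforms of very different cell counts by
covering the embedding's bounding box with equal-sided hypercubes and
sampling one cell per occupied box, so rare populations that occupy their
own corner of expression space survive subsampling.

Batch alignment is an iterative centroid-matching scheme: soft k-means on
the current scores, then for each cluster each batch's cells are shifted by
the responsibility-weighted difference between the batch-conditional
centroid and the overall cluster centroid, until displacements vanish. It
carries the two published knobs (at most 50 clusters, at most 100
iterations) and returns the top ``d_out`` corrected dimensions, each
rescaled to unit variance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp
from sklearn.cluster import KMeans

from .core_io import ExpressionMatrix, NormMatrix

logger = logging.getLogger(__name__)

__all__ = ["Embedding", "lognormalize", "select_hvg", "run_pca",
           "geometric_sketch", "align_batches"]

SD_FLOOR = 1e-8
CLIP = 10.0


@dataclass
class Embedding:
    """PCA-style embedding with everything needed for out-of-sample projection.

    ``scores`` is cells x d; ``loadings`` is genes x d with orthonormal
    columns; ``gene_means``/``gene_sds`` are the centering/scaling statistics
    on the genes in ``gene_ids``. New data is projected by z-scoring with
    these statistics (clipped at +/-10) and multiplying by the loadings.
    """

    scores: np.ndarray
    loadings: np.ndarray
    gene_ids: np.ndarray
    gene_means: np.ndarray
    gene_sds: np.ndarray
    explained_variance: np.ndarray
    cell_ids: np.ndarray

    @property
    def d(self) -> int:
        return self.scores.shape[1]

    def project(self, norm: NormMatrix) -> np.ndarray:
        """Project cells of ``norm`` (must contain all embedding genes)."""
        idx = norm.gene_index(self.gene_ids)
        x = np.asarray(norm.values[idx].todense()).T
        z = np.clip((x - self.gene_means) / self.gene_sds, -CLIP, CLIP)
        return z @ self.loadings


def lognormalize(matrix: ExpressionMatrix, scale_factor: float = 10_000.0,
                 allow_zero_cells: bool = False) -> NormMatrix:
    """``log(1 + count / cell_total * scale_factor)``, sparsity preserved."""
    totals = np.asarray(matrix.values.sum(axis=0)).ravel().astype(float)
    zero = totals == 0
    if zero.any():
        if not allow_zero_cells:
            bad = list(matrix.cell_ids[zero][:5])
            raise ValueError(f"cells with zero total counts: {bad}")
        totals[zero] = 1.0
    values = matrix.values.tocsc().astype(float)
    # scale each column (cell) by scale_factor / total, then log1p the data
    values = values @ sp.diags(scale_factor / totals)
    values.data = np.log1p(values.data)
    return NormMatrix(values.tocsr(), matrix.gene_ids, matrix.cell_ids,
                      matrix.species, scale_factor)


def _gene_mean_var(values: sp.csr_matrix) -> tuple[np.ndarray, np.ndarray]:
    n = values.shape[1]
    mean = np.asarray(values.mean(axis=1)).ravel()
    sq = np.asarray(values.multiply(values).mean(axis=1)).ravel()
    var = np.maximum(sq - mean**2, 0.0) * (n / max(n - 1, 1))
    return mean, var


def select_hvg(norm: NormMatrix, n: int = 2000, n_bins: int = 20) -> list[str]:
    """Top-``n`` highly variable genes by binned variance-stabilized dispersion.

    Genes are binned into ``n_bins`` quantile bins of mean log expression;
    the statistic is the gene's variance divided by its bin's median
    variance. Constant genes are excluded; ties break by gene id.
    """
    if n > norm.n_genes:
        n = norm.n_genes
    mean, var = _gene_mean_var(norm.values)
    # constant genes can carry ~1e-16 residual variance from sparse arithmetic
    ok = var > 1e-10 * (1.0 + mean**2)
    if not ok.any():
        return []
    # quantile bins over genes with variance
    order = np.argsort(mean[ok], kind="stable")
    ranks = np.empty(ok.sum(), dtype=int)
    ranks[order] = np.arange(ok.sum())
    bins = np.minimum((ranks * n_bins) // max(ok.sum(), 1), n_bins - 1)
    disp = np.full(norm.n_genes, -np.inf)
    v = var[ok]
    stat = np.empty_like(v)
    for b in range(n_bins):
        in_bin = bins == b
        if in_bin.any():
            med = np.median(v[in_bin])
            stat[in_bin] = v[in_bin] / max(med, SD_FLOOR)
    disp[ok] = stat
    gene_ids = np.asarray(norm.gene_ids, dtype=object)
    # rank by statistic descending, ties by gene id ascending
    candidates = sorted(
        (i for i in range(norm.n_genes) if ok[i]),
        key=lambda i: (-disp[i], str(gene_ids[i])),
    )
    return [str(gene_ids[i]) for i in candidates[:n]]


def run_pca(norm: NormMatrix, genes, d: int, seed: int = 0) -> Embedding:
    """PCA of the z-scored (clipped at +/-10) log-normalized gene subset.

    Component signs are fixed so each loading vector's largest-magnitude
    entry is positive, making runs reproducible across solvers.
    """
    genes = list(genes)
    if d > len(genes):
        raise ValueError(f"d={d} exceeds number of genes {len(genes)}")
    if d < 1:
        raise ValueError("d must be >= 1")
    idx = norm.gene_index(genes)
    x = np.asarray(norm.values[idx].todense()).T  # cells x genes
    gene_means = x.mean(axis=0)
    gene_sds = np.maximum(x.std(axis=0, ddof=0), SD_FLOOR)
    z = np.clip((x - gene_means) / gene_sds, -CLIP, CLIP)

    n = z.shape[0]
    rank = min(n - 1 if n > 1 else 1, z.shape[1])
    if d > rank:
        warnings.warn(f"d={d} exceeds data rank {rank}; trailing components "
                      "have zero variance")
    # decompose the clipped z-matrix itself (no re-centering after clipping)
    # so that out-of-sample projection through (loadings, means, sds) exactly
    # reproduces training scores; clipping rarely moves the mean off zero
    if min(z.shape) > 300 and d <= min(z.shape) // 5:
        from sklearn.utils.extmath import randomized_svd
        u, s, vt = randomized_svd(z, n_components=d, n_iter=7,
                                  random_state=seed)
    else:
        u, s, vt = np.linalg.svd(z, full_matrices=False)
    k = min(d, len(s))
    loadings = vt[:k].T.copy()
    scores = u[:, :k] * s[:k]
    expl = (s[:k] ** 2) / max(n - 1, 1)
    if d > k:  # pad zero-variance trailing components
        pad = d - k
        loadings = np.hstack([loadings, np.zeros((loadings.shape[0], pad))])
        scores = np.hstack([scores, np.zeros((n, pad))])
        expl = np.concatenate([expl, np.zeros(pad)])
    # sign convention
    for j in range(d):
        col = loadings[:, j]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            loadings[:, j] = -col
            scores[:, j] = -scores[:, j]
    return Embedding(
        scores=scores,
        loadings=loadings,
        gene_ids=np.asarray(genes, dtype=object),
        gene_means=gene_means,
        gene_sds=gene_sds,
        explained_variance=expl,
        cell_ids=np.asarray(norm.cell_ids, dtype=object),
    )


def geometric_sketch(embedding: Embedding, k_target: int, seed: int = 0) -> np.ndarray:
    """Geometry-covering subsample of exactly ``k_target`` cell indices.

    The embedding's bounding box is covered with equal-sided hypercubes; the
    side length is binary-searched until the number of occupied boxes lies in
    ``[k_target, 2*k_target]`` (or the grid cannot be refined further, e.g.
    with duplicated points). One random cell is drawn per sampled box; the
    sketch is topped up uniformly from unsampled cells if boxes run out.
    """
    x = embedding.scores
    n = x.shape[0]
    if not 1 <= k_target <= n:
        raise ValueError(f"k_target={k_target} outside [1, {n}]")
    if k_target == n:
        return np.arange(n)
    rng = np.random.default_rng(seed)
    lo_pt = x.min(axis=0)
    span = float(np.max(x.max(axis=0) - lo_pt))
    if span == 0:  # all points identical: boxes cannot separate anything
        return rng.choice(n, size=k_target, replace=False)

    def occupancy(side: float) -> dict:
        keys = np.floor((x - lo_pt) / side).astype(np.int64)
        boxes: dict = {}
        for i, key in enumerate(map(tuple, keys)):
            boxes.setdefault(key, []).append(i)
        return boxes

    lo, hi = span * 1e-6, span * (1 + 1e-9)
    boxes = occupancy(hi)
    for _ in range(60):
        mid = (lo + hi) / 2
        b = occupancy(mid)
        if len(b) < k_target:
            hi = mid
        else:
            lo, boxes = mid, b
            if len(b) <= 2 * k_target:
                break
    if len(boxes) < k_target:
        boxes = occupancy(lo)

    keys = sorted(boxes)  # deterministic box order
    chosen = rng.choice(len(keys), size=min(k_target, len(keys)), replace=False)
    picked = [boxes[keys[j]][rng.integers(len(boxes[keys[j]]))] for j in chosen]
    if len(picked) < k_target:  # top up from cells not yet in the sketch
        rest = np.setdiff1d(np.arange(n), picked)
        extra = rng.choice(rest, size=k_target - len(picked), replace=False)
        picked = list(picked) + list(extra)
    return np.sort(np.asarray(picked, dtype=int))


def align_batches(embedding: Embedding, batch_labels, n_clusters: int = 50,
                  max_iter: int = 100, d_out: int = 20, seed: int = 0,
                  tol: float = 1e-4) -> Embedding:
    """Iterative centroid-matching batch correction in embedding space.

    Returns an embedding whose scores are the first ``d_out`` corrected
    dimensions, each rescaled to unit variance; loadings and gene statistics
    are carried through unchanged for provenance (they describe the
    uncorrected axes). Cell count and order never change.
    """
    batches = np.asarray(batch_labels)
    if len(batches) != embedding.scores.shape[0]:
        raise ValueError("one batch label per cell required")
    d_out = min(d_out, embedding.d)
    uniq = np.unique(batches)
    x = embedding.scores.copy()
    n = x.shape[0]
    if len(uniq) < 2 or len(uniq) == n:
        msg = ("single batch" if len(uniq) < 2 else
               "every cell its own batch")
        warnings.warn(f"align_batches: {msg}; returning identity transform")
        return replace(embedding)

    k = min(n_clusters, n)
    for _ in range(max_iter):
        km = KMeans(n_clusters=k, n_init=1, random_state=seed).fit(x)
        centers = km.cluster_centers_
        d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        sigma2 = max(np.mean(np.min(d2, axis=1)), 1e-12)
        logr = -d2 / (2 * sigma2)
        logr -= logr.max(axis=1, keepdims=True)
        r = np.exp(logr)
        r /= r.sum(axis=1, keepdims=True)

        w_c = r.sum(axis=0)  # cluster mass
        mu_c = (r.T @ x) / np.maximum(w_c[:, None], 1e-12)
        shift = np.zeros_like(x)
        for b in uniq:
            in_b = batches == b
            w_cb = r[in_b].sum(axis=0)
            present = w_cb > 1e-8
            mu_cb = np.zeros_like(mu_c)
            mu_cb[present] = (r[in_b].T @ x[in_b])[present] / w_cb[present, None]
            delta = np.zeros_like(mu_c)
            delta[present] = mu_cb[present] - mu_c[present]
            shift[in_b] = r[in_b] @ delta
        x = x - shift
        if np.abs(shift).max() < tol:
            break

    out = x[:, :d_out]
    sds = out.std(axis=0, ddof=0)
    sds[sds < SD_FLOOR] = 1.0
    out = out / sds
    return Embedding(
        scores=out,
        loadings=embedding.loadings[:, :d_out],
        gene_ids=embedding.gene_ids,
        gene_means=embedding.gene_means,
        gene_sds=embedding.gene_sds,
        explained_variance=embedding.explained_variance[:d_out],
        cell_ids=embedding.cell_ids,
    )
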