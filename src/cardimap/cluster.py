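"""kNN-graph community detection, marker genes, and cell-type annotation.

Clustering follows the standard single-cell recipe: a k-nearest-neighbor
graph in embedding space with shared-neighbor Jaccard edge weights, then
modularity-maximizing (Louvain-family) community detection. Marker genes are
one-vs-rest two-sided Wilcoxon rank-sum tests on log-normalized values with
a Benjamini-Hochberg correction within each cluster.

Annotation scores each cluster against a marker dictionary: the per-gene
mean expression profile is z-scored across clusters and averaged over each
cell type's genes; the top-scoring type wins, and a composite label (e.g.
"ECs/FBs", a cluster co-expressing endothelial and fibroblast programs) is
called when the top two scores are within a margin and their union is a
declared composite.
"""

from __future__ import annotations

import logging
import warnings

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .core_io import NormMatrix
from .embed import Embedding

logger = logging.getLogger(__name__)

__all__ = ["build_knn_graph", "cluster_graph", "find_markers",
           "annotate_clusters", "DEFAULT_MARKERS", "DEFAULT_COMPOSITES"]

# Known embryonic-heart marker genes per major cell type (human symbols;
# mouse data is matched case-insensitively via title-casing). NKX2-5 is
# deliberately absent from the EC list despite occasionally being grouped
# with endothelial markers: canonically it is a cardiomyocyte transcription
# factor and listing it under ECs would misdirect annotation.
DEFAULT_MARKERS: dict[str, list[str]] = {
    "CMs": ["TTN", "MYH6", "TNNT2", "TNNC1", "ACTN2"],
    "FBs": ["COL3A1", "COL1A2", "FN1"],
    "ECs": ["CDH5", "EMCN", "PECAM1", "CD93", "TEK", "KDR", "ESAM"],
    "EPs": ["UPK3B", "MSLN", "WT1"],
    "MACs": ["MS4A4A", "SEPP1", "CD68"],
    "MONOs": ["LYZ", "S100A8", "S100A6"],
    "NKTs": ["NKG7", "GNLY"],
    "Blood": ["HBB", "HBA1", "ALAS2"],
}

# composite labels assignable when two programs are co-expressed
DEFAULT_COMPOSITES: dict[str, tuple[str, str]] = {
    "ECs/FBs": ("ECs", "FBs"),
    "MACs/MONOs": ("MACs", "MONOs"),
    "EPs/FBs": ("EPs", "FBs"),
}


def build_knn_graph(embedding: Embedding, k: int = 20) -> ig.Graph:
    """Undirected kNN graph with shared-neighbor Jaccard weights.

    Nodes are cells in embedding order; an edge links each cell to its k
    Euclidean nearest neighbors (self excluded); the weight of edge (i, j)
    is the Jaccard overlap of the two cells' neighbor sets.
    """
    n = embedding.scores.shape[0]
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n_cells={n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding.scores)
    _, idx = nn.kneighbors(embedding.scores)
    neigh = idx[:, 1:]

    rows = np.repeat(np.arange(n), k)
    cols = neigh.ravel()
    adj = sp.csr_matrix((np.ones(n * k), (rows, cols)), shape=(n, n))
    adj = ((adj + adj.T) > 0).astype(float)  # union of directed edges
    # shared-neighbor counts via the directed adjacency (rows = neighbor sets)
    directed = sp.csr_matrix((np.ones(n * k), (rows, cols)), shape=(n, n))
    shared = directed @ directed.T

    src, dst = sp.triu(adj, k=1).nonzero()
    inter = np.asarray(shared[src, dst]).ravel()
    union = 2 * k - inter
    weights = inter / union
    g = ig.Graph(n=n, edges=list(zip(src.tolist(), dst.tolist())), directed=False)
    g.es["weight"] = weights.tolist()
    return g


def cluster_graph(graph: ig.Graph, resolution: float = 1.0, seed: int = 0) -> np.ndarray:
    """Modularity community detection; labels relabeled by decreasing size."""
    if graph.vcount() == 0:
        raise ValueError("empty graph")
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight" if "weight" in graph.es.attributes() else None,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    labels = np.asarray(part.membership)
    sizes = pd.Series(labels).value_counts()
    # stable relabel: by decreasing size, ties by old label
    order = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[c] for c in labels])


def _rank_sum_exact_pvalues(x: np.ndarray, in_cluster: np.ndarray) -> np.ndarray:
    """Permutation-exact two-sided rank-sum p-values (tiny samples only)."""
    from itertools import combinations

    n = x.shape[1]
    n1 = int(in_cluster.sum())
    ranks = scipy.stats.rankdata(x, axis=1)
    mu = n1 * (n + 1) / 2.0
    obs = np.abs(ranks[:, in_cluster].sum(axis=1) - mu)
    combos = np.array(list(combinations(range(n), n1)))
    # all possible rank sums for each gene under label permutation
    all_sums = ranks[:, combos].sum(axis=2)  # genes x n_combos
    return (np.abs(all_sums - mu) >= obs[:, None] - 1e-12).mean(axis=1)


def _rank_sum_pvalues(x: np.ndarray, in_cluster: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p-values per gene (rows of ``x``).

    Normal approximation with tie correction, vectorized over genes; on tiny
    fixtures (<= 10 cells) the exact permutation distribution is enumerated
    instead.
    """
    if x.shape[1] <= 10:
        return _rank_sum_exact_pvalues(x, in_cluster)
    n1 = int(in_cluster.sum())
    n2 = x.shape[1] - n1
    ranks = scipy.stats.rankdata(x, axis=1)
    r1 = ranks[:, in_cluster].sum(axis=1)
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    # tie correction per gene
    n = n1 + n2
    tie_term = np.zeros(x.shape[0])
    for g in range(x.shape[0]):
        _, counts = np.unique(x[g], return_counts=True)
        tie_term[g] = (counts**3 - counts).sum()
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sigma = np.sqrt(np.maximum(sigma2, 0))
    z = np.zeros_like(u)
    nz = sigma > 0
    z[nz] = (u[nz] - mu) / sigma[nz]
    p = 2 * scipy.stats.norm.sf(np.abs(z))
    p[~nz] = 1.0
    return np.minimum(p, 1.0)


def find_markers(norm: NormMatrix, labels, min_pct: float = 0.1,
                 min_logfc: float = 0.25) -> pd.DataFrame:
    """One-vs-rest Wilcoxon marker table.

    Per cluster, genes with detection fraction >= ``min_pct`` in the cluster
    or in the rest, and absolute average natural-log fold change (on
    ``mean(expm1(.)) + 1`` scale) >= ``min_logfc``, are tested; BH correction
    is applied within each cluster. Clusters with fewer than 3 cells are
    skipped with a warning.
    """
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    x = np.asarray(norm.values.todense())
    expm1 = np.expm1(x)
    records = []
    for c in clusters:
        in_c = labels == c
        if in_c.sum() < 3:
            warnings.warn(f"cluster {c} has fewer than 3 cells; skipped")
            continue
        out_c = ~in_c
        pct_in = (x[:, in_c] > 0).mean(axis=1)
        pct_out = (x[:, out_c] > 0).mean(axis=1)
        logfc = np.log(expm1[:, in_c].mean(axis=1) + 1) - \
            np.log(expm1[:, out_c].mean(axis=1) + 1)
        tested = ((pct_in >= min_pct) | (pct_out >= min_pct)) & \
            (np.abs(logfc) >= min_logfc)
        if not tested.any():
            continue
        idx = np.flatnonzero(tested)
        p = _rank_sum_pvalues(x[idx], in_c)
        p_adj = multipletests(p, method="fdr_bh")[1]
        for j, gi in enumerate(idx):
            records.append({
                "gene": norm.gene_ids[gi], "cluster": c,
                "avg_logFC": logfc[gi], "p_value": p[j], "p_adj": p_adj[j],
                "pct_in": pct_in[gi], "pct_out": pct_out[gi],
            })
    return pd.DataFrame(records, columns=[
        "gene", "cluster", "avg_logFC", "p_value", "p_adj", "pct_in", "pct_out"])


def annotate_clusters(norm: NormMatrix, labels, marker_dict: dict | None = None,
                      composites: dict | None = None, margin: float = 0.25,
                      ) -> dict[int, str]:
    """Assign a cell-type name to every cluster from a marker dictionary.

    Scores are means (over each type's genes) of cluster-mean expression
    z-scored per gene across clusters. Mouse-cased symbols are matched by
    title-casing dictionary entries. The argmax type wins; if the runner-up
    is within ``margin`` and the pair is a declared composite, the composite
    label is assigned. Ties break alphabetically.
    """
    if marker_dict is None:
        marker_dict = DEFAULT_MARKERS
    if composites is None:
        composites = DEFAULT_COMPOSITES
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    present = {str(g) for g in norm.gene_ids}

    def resolve(g: str) -> str | None:
        if g in present:
            return g
        alt = g.capitalize()
        return alt if alt in present else None

    used = {t: [resolve(g) for g in genes if resolve(g)]
            for t, genes in marker_dict.items()}
    used = {t: gs for t, gs in used.items() if gs}
    if not used:
        raise ValueError("no marker-dictionary gene present in the matrix")

    all_genes = sorted({g for gs in used.values() for g in gs})
    gidx = norm.gene_index(all_genes)
    x = np.asarray(norm.values[gidx].todense())
    means = np.stack([x[:, labels == c].mean(axis=1) for c in clusters], axis=1)
    mu = means.mean(axis=1, keepdims=True)
    sd = means.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    zmat = (means - mu) / sd  # gene x cluster
    row = {g: i for i, g in enumerate(all_genes)}

    result: dict[int, str] = {}
    for ci, c in enumerate(clusters):
        scores = {t: float(np.mean([zmat[row[g], ci] for g in gs]))
                  for t, gs in used.items()}
        ranked = sorted(scores, key=lambda t: (-scores[t], t))
        best = ranked[0]
        if len(ranked) > 1:
            second = ranked[1]
            if scores[best] - scores[second] <= margin:
                pair = frozenset((best, second))
                for comp, (a, b) in composites.items():
                    if frozenset((a, b)) == pair:
                        best = comp
                        break
        result[int(c)] = best
    return result
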