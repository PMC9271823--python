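"""Hypergeometric over-representation analysis against GMT gene sets.

The test is the classic urn model: with a universe of N genes, a set of K,
and a query of n, the p-value is the exact upper tail P(X >= k) of the
hypergeometric distribution for the observed overlap k, BH-corrected across
all sets reaching the minimum overlap.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .core_io import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = ["run_ora", "build_deg_query", "synthetic_gmt"]


def run_ora(query, universe, sets: GeneSetCollection,
            min_overlap: int = 2) -> pd.DataFrame:
    """Over-representation of ``query`` within each gene set.

    Genes outside the universe are dropped from the query with a warning;
    each set is intersected with the universe before testing. Only sets with
    overlap >= ``min_overlap`` are tested (and BH-corrected); results are
    sorted by p-value.
    """
    universe = set(map(str, universe))
    if not universe:
        raise ValueError("empty universe")
    query = set(map(str, query))
    outside = query - universe
    if outside:
        warnings.warn(f"{len(outside)} query genes outside the universe dropped")
        query &= universe
    n = len(query)
    N = len(universe)

    rows = []
    for name, genes in sets.sets.items():
        genes_u = set(map(str, genes)) & universe
        K = len(genes_u)
        k = len(query & genes_u)
        if k < min_overlap or K == 0:
            continue
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"set": name, "overlap": k, "set_size": K,
                     "query_size": n, "universe_size": N, "p_value": p})
    out = pd.DataFrame(rows, columns=["set", "overlap", "set_size",
                                      "query_size", "universe_size", "p_value"])
    if len(out):
        out["p_adj"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out = out.sort_values("p_value", kind="stable").reset_index(drop=True)
    else:
        out["p_adj"] = pd.Series(dtype=float)
    return out


def build_deg_query(markers: pd.DataFrame, cluster, p_cut: float = 0.01) -> list[str]:
    """Upregulated significant genes of one cluster: logFC > 0, p_adj < p_cut."""
    if markers.empty:
        raise ValueError("empty marker table")
    sel = markers[(markers["cluster"] == cluster)
                  & (markers["avg_logFC"] > 0.0)
                  & (markers["p_adj"] < p_cut)]
    genes = sel["gene"].astype(str).tolist()
    if not genes:
        warnings.warn(f"no significant upregulated gene for cluster {cluster!r}")
    return genes


def synthetic_gmt(universe, enriched_genes, n_random_sets: int = 20,
                  set_size: int = 25, seed: int = 0) -> GeneSetCollection:
    """A toy GMT for tests: random sets plus one enriched in the given genes."""
    rng = np.random.default_rng(seed)
    universe = sorted(map(str, universe))
    sets = {}
    descriptions = {}
    for i in range(n_random_sets):
        sets[f"RANDOM_{i}"] = set(rng.choice(universe, size=set_size, replace=False))
        descriptions[f"RANDOM_{i}"] = "random background set"
    enriched = [g for g in map(str, enriched_genes) if g in set(universe)]
    take = enriched[:set_size]
    filler = [g for g in universe if g not in take][: max(0, set_size - len(take))]
    sets["ENRICHED"] = set(take) | set(filler)
    descriptions["ENRICHED"] = "set planted around the query program"
    return GeneSetCollection(sets, descriptions)
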