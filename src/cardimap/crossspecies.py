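"""Ortholog-restricted cross-species comparison of annotated cell types.

Both species' matrices are collapsed to one-to-one ortholog pairs, average
log-normalized expression per cell type is computed, and human x mouse
cell-type similarity is the Pearson correlation over shared ortholog rows.
Marker conservation classifies each (ortholog pair, cell type) as shared,
human-specific, mouse-specific, or neither: shared means a significant
positive marker of the homologous type in both species; species-specific
means significant in one species while, in the other, the gene is barely
detected in that type or clearly non-significant.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .core_io import NormMatrix, OrthologMap

logger = logging.getLogger(__name__)

__all__ = ["collapse_to_orthologs", "type_profiles", "correlate_types",
           "detection_by_type", "classify_marker_conservation"]


def collapse_to_orthologs(norm_h: NormMatrix, norm_m: NormMatrix,
                          omap: OrthologMap) -> tuple[NormMatrix, NormMatrix]:
    """Restrict both matrices to ortholog pairs present in both; align rows.

    Row order follows the ortholog table; pairs missing from either matrix
    are dropped.
    """
    genes_h = {g: i for i, g in enumerate(norm_h.gene_ids)}
    genes_m = {g: i for i, g in enumerate(norm_m.gene_ids)}
    keep = [(a, b) for a, b in zip(omap.pairs["gene_a"], omap.pairs["gene_b"])
            if a in genes_h and b in genes_m]
    if not keep:
        raise ValueError("no ortholog pair present in both matrices")
    idx_h = np.array([genes_h[a] for a, _ in keep])
    idx_m = np.array([genes_m[b] for _, b in keep])
    return norm_h.subset_genes(idx_h), norm_m.subset_genes(idx_m)


def type_profiles(norm: NormMatrix, type_labels) -> pd.DataFrame:
    """Mean log-normalized expression per cell type (genes x types)."""
    labels = np.asarray(type_labels, dtype=object)
    types = sorted(set(labels))
    x = np.asarray(norm.values.todense())
    data = {t: x[:, labels == t].mean(axis=1) for t in types}
    return pd.DataFrame(data, index=pd.Index(norm.gene_ids, name="gene"))


def correlate_types(prof_h: pd.DataFrame, prof_m: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of human x mouse type profiles over aligned rows."""
    if prof_h.shape[0] != prof_m.shape[0]:
        raise ValueError("profiles must be row-aligned over the same ortholog pairs")
    out = pd.DataFrame(index=prof_h.columns, columns=prof_m.columns, dtype=float)
    for th in prof_h.columns:
        a = prof_h[th].to_numpy()
        for tm in prof_m.columns:
            b = prof_m[tm].to_numpy()
            if a.std() == 0 or b.std() == 0:
                warnings.warn(f"zero-variance profile for {th!r} or {tm!r}")
                out.loc[th, tm] = np.nan
            else:
                out.loc[th, tm] = float(np.corrcoef(a, b)[0, 1])
    return out


def detection_by_type(norm: NormMatrix, type_labels) -> pd.DataFrame:
    """Fraction of cells with nonzero expression, per gene and cell type."""
    labels = np.asarray(type_labels, dtype=object)
    types = sorted(set(labels))
    x = norm.values
    data = {t: np.asarray((x[:, labels == t] > 0).mean(axis=1)).ravel()
            for t in types}
    return pd.DataFrame(data, index=pd.Index(norm.gene_ids, name="gene"))


def classify_marker_conservation(markers_h: pd.DataFrame, markers_m: pd.DataFrame,
                                 omap: OrthologMap,
                                 detect_h: pd.DataFrame, detect_m: pd.DataFrame,
                                 p_cut: float = 0.01, fc_cut: float = 0.25,
                                 min_detect: float = 0.1,
                                 nonsig_p: float = 0.05) -> pd.DataFrame:
    """Shared/specific status per ortholog pair and homologous cell type.

    ``markers_*`` are marker tables whose ``cluster`` column holds annotated
    cell-type names (the homology link); ``detect_*`` are detection-fraction
    tables from :func:`detection_by_type`. A gene is a *marker* when
    ``p_adj < p_cut`` and ``avg_logFC > fc_cut``; it clearly *fails* in the
    other species when its detection in the type is below ``min_detect`` or
    its test is non-significant (``p_adj >= nonsig_p`` or untested).
    """
    def marker_lookup(markers: pd.DataFrame) -> dict:
        return {(r.gene, r.cluster): r for r in markers.itertuples()}

    lut_h, lut_m = marker_lookup(markers_h), marker_lookup(markers_m)
    types_h = set(markers_h["cluster"]) | set(detect_h.columns)
    types_m = set(markers_m["cluster"]) | set(detect_m.columns)
    shared_types = sorted(types_h & types_m)
    for t in sorted((types_h | types_m) - set(shared_types)):
        warnings.warn(f"cell type {t!r} absent in one species; skipped")

    rows = []
    for gh, gm in zip(omap.pairs["gene_a"], omap.pairs["gene_b"]):
        if gh not in detect_h.index or gm not in detect_m.index:
            continue
        for t in shared_types:
            rec_h = lut_h.get((gh, t))
            rec_m = lut_m.get((gm, t))
            sig_h = rec_h is not None and rec_h.p_adj < p_cut and rec_h.avg_logFC > fc_cut
            sig_m = rec_m is not None and rec_m.p_adj < p_cut and rec_m.avg_logFC > fc_cut
            fail_m = (detect_m.loc[gm, t] < min_detect
                      or rec_m is None or rec_m.p_adj >= nonsig_p)
            fail_h = (detect_h.loc[gh, t] < min_detect
                      or rec_h is None or rec_h.p_adj >= nonsig_p)
            if sig_h and sig_m:
                status = "shared"
            elif sig_h and fail_m:
                status = "human_specific"
            elif sig_m and fail_h:
                status = "mouse_specific"
            else:
                status = "neither"
            rows.append({"gene_h": gh, "gene_m": gm, "cell_type": t,
                         "status": status})
    out = pd.DataFrame(rows, columns=["gene_h", "gene_m", "cell_type", "status"])
    # partition check: exactly one status per (pair, type) by construction
    assert not out.duplicated(["gene_h", "cell_type"]).any()
    return out
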