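"""Config-driven orchestration of the full cross-species pipeline.

``run_pipeline`` executes qc -> sketch -> integrate -> cluster -> annotate ->
markers -> cross-species correlation -> trajectory -> stage mapping ->
enrichment on two species bundles and writes every stage artifact plus a
``report.json``. ``stage_correspondence_pipeline`` is the core path
(qc -> integrate -> annotate -> stagemap) reused by the orchestrator.

One global seed deterministically derives per-stage seeds by hashing the
stage name, so any stage can be re-run in isolation with the same stream.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as cl
from . import crossspecies as xs
from . import embed, enrich, qc, stagemap, trajectory
from .core_io import (CellMeta, ExpressionMatrix, OrthologMap, read_counts,
                      read_gmt, read_ortholog_table)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "stage_correspondence_pipeline",
           "stage_seed", "SYNTHETIC_QC"]

# QC thresholds matched to the synthetic platforms' sequencing depths
# (the published presets in qc.PRESETS are for the real datasets' depths)
SYNTHETIC_QC: dict[str, qc.QCThresholds] = {
    "strt": qc.QCThresholds(min_genes=500, min_transcripts=1500,
                            max_mito_frac=0.30, mito_prefix="MT-"),
    "smartseq": qc.QCThresholds(min_genes=800, min_transcripts=5000,
                                max_mito_frac=0.30, mito_prefix="mt-",
                                genes_strict=True),
    "droplet": qc.QCThresholds(min_genes=250, min_transcripts=600,
                               max_mito_frac=0.30, mito_prefix="mt-"),
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed derived from the global seed and the stage name."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class PipelineConfig:
    """Paths and per-stage parameters of one pipeline run."""

    human_dir: str = ""
    mouse_dir: str = ""
    ortholog_table: str = ""
    gmt: str = ""
    out_dir: str = "run"
    qc_thresholds: dict = field(default_factory=lambda: dict(SYNTHETIC_QC))
    doublet_rate: float = 0.075
    doublet_k: int = 20
    scale_factor: float = 10_000.0
    n_hvg: int = 2000
    n_pcs: int = 50
    d_out: int = 20
    align_clusters: int = 50
    align_max_iter: int = 100
    knn: int = 20
    resolution: float = 1.0
    marker_min_pct: float = 0.1
    marker_min_logfc: float = 0.25
    trajectory_type: str = "CMs"
    trajectory_nodes: int = 15
    trajectory_dims: int = 2
    core_min_fraction: float = 0.75
    seed: int = 0
    do_markers: bool = True
    do_trajectory: bool = True
    do_enrich: bool = True


def _qc_species(matrix: ExpressionMatrix, meta: CellMeta,
                thresholds: dict, doublet_rate: float, doublet_k: int,
                seed: int) -> tuple[ExpressionMatrix, CellMeta, dict]:
    """Per-platform QC filters, then pANN doublet removal; returns counts."""
    meta = meta.aligned_to(matrix.cell_ids)
    platforms = meta.table["batch"].to_numpy()
    keep = np.zeros(matrix.n_cells, dtype=bool)
    for b in np.unique(platforms):
        thr = thresholds[b] if b in thresholds else qc.QCThresholds()
        in_b = platforms == b
        sub = matrix.subset_cells(in_b)
        table = qc.compute_cell_qc(sub, thr.mito_prefix)
        keep[np.flatnonzero(in_b)[qc.qc_pass_mask(table, thr)]] = True
    filtered = matrix.subset_cells(keep)
    n_post_qc = filtered.n_cells

    calls = qc.detect_doublets(filtered, expected_rate=doublet_rate,
                               k_neighbors=doublet_k, seed=seed)
    singlet = ~calls["is_doublet"].to_numpy()
    filtered = filtered.subset_cells(singlet)
    counts = {
        "n_input": int(matrix.n_cells),
        "n_post_qc": int(n_post_qc),
        "n_post_doublet_removal": int(filtered.n_cells),
    }
    return filtered, meta.aligned_to(filtered.cell_ids), counts


def _sketch_to_balance(matrix: ExpressionMatrix, meta: CellMeta,
                       n_hvg: int, n_pcs: int, seed: int
                       ) -> tuple[ExpressionMatrix, CellMeta, dict]:
    """Downsample the largest platform to the size of the smallest.

    Mirrors balancing a deep plate-based dataset against a much larger
    droplet dataset before integration; smaller platforms pass unchanged.
    """
    batches = meta.table["batch"].to_numpy()
    uniq, sizes = np.unique(batches, return_counts=True)
    if len(uniq) < 2 or sizes.max() == sizes.min():
        return matrix, meta, {"sketched": {}}
    target = int(sizes.min())
    keep = np.zeros(matrix.n_cells, dtype=bool)
    info = {}
    for b, size in zip(uniq, sizes):
        in_b = np.flatnonzero(batches == b)
        if size <= target:
            keep[in_b] = True
            continue
        sub = matrix.subset_cells(in_b)
        norm = embed.lognormalize(sub)
        hvg = embed.select_hvg(norm, n=min(n_hvg, sub.n_genes))
        emb = embed.run_pca(norm, hvg, d=min(n_pcs, len(hvg), sub.n_cells - 1),
                            seed=seed)
        picked = embed.geometric_sketch(emb, target, seed=seed)
        keep[in_b[picked]] = True
        info[str(b)] = {"from": int(size), "to": target}
    sk = matrix.subset_cells(keep)
    return sk, meta.aligned_to(sk.cell_ids), {"sketched": info}


def _embed_and_cluster(matrix: ExpressionMatrix, meta: CellMeta,
                       cfg: PipelineConfig, seed: int):
    norm = embed.lognormalize(matrix, cfg.scale_factor)
    hvg = embed.select_hvg(norm, n=min(cfg.n_hvg, matrix.n_genes))
    d = min(cfg.n_pcs, len(hvg), matrix.n_cells - 1)
    emb = embed.run_pca(norm, hvg, d=d, seed=seed)
    batches = meta.table["batch"].to_numpy()
    if len(np.unique(batches)) > 1:
        emb = embed.align_batches(emb, batches, n_clusters=cfg.align_clusters,
                                  max_iter=cfg.align_max_iter,
                                  d_out=min(cfg.d_out, d), seed=seed)
    else:
        from dataclasses import replace
        emb = replace(emb, scores=emb.scores[:, :cfg.d_out],
                      loadings=emb.loadings[:, :cfg.d_out],
                      explained_variance=emb.explained_variance[:cfg.d_out])
    graph = cl.build_knn_graph(emb, k=min(cfg.knn, matrix.n_cells - 1))
    labels = cl.cluster_graph(graph, resolution=cfg.resolution, seed=seed)
    annotation = cl.annotate_clusters(norm, labels)
    cell_types = np.array([annotation[int(c)] for c in labels], dtype=object)
    return norm, emb, labels, annotation, cell_types


def _cells_of_type(cell_types: np.ndarray, wanted: str) -> np.ndarray:
    """Cells annotated as ``wanted``, including composite labels covering it."""
    hits = np.array([t == wanted or wanted in str(t).split("/")
                     for t in cell_types])
    return hits


def stage_correspondence_pipeline(mat_h: ExpressionMatrix, meta_h: CellMeta,
                                  mat_m: ExpressionMatrix, meta_m: CellMeta,
                                  omap: OrthologMap,
                                  cfg: PipelineConfig | None = None,
                                  seed: int | None = None) -> dict:
    """QC -> integrate -> annotate -> stage mapping for one cell type.

    Returns a dict with the correspondence table, per-species QC counts,
    annotations, and the fitted axis model.
    """
    cfg = cfg or PipelineConfig()
    seed = cfg.seed if seed is None else seed

    mat_h, meta_h, counts_h = _qc_species(
        mat_h, meta_h, cfg.qc_thresholds, cfg.doublet_rate, cfg.doublet_k,
        stage_seed(seed, "qc_human"))
    mat_m, meta_m, counts_m = _qc_species(
        mat_m, meta_m, cfg.qc_thresholds, cfg.doublet_rate, cfg.doublet_k,
        stage_seed(seed, "qc_mouse"))
    mat_m, meta_m, sketch_info = _sketch_to_balance(
        mat_m, meta_m, cfg.n_hvg, cfg.n_pcs, stage_seed(seed, "sketch"))

    norm_h, emb_h, labels_h, ann_h, types_h = _embed_and_cluster(
        mat_h, meta_h, cfg, stage_seed(seed, "cluster_human"))
    norm_m, emb_m, labels_m, ann_m, types_m = _embed_and_cluster(
        mat_m, meta_m, cfg, stage_seed(seed, "cluster_mouse"))

    wanted = cfg.trajectory_type
    mask_h = _cells_of_type(types_h, wanted)
    mask_m = _cells_of_type(types_m, wanted)
    if mask_h.sum() < 10 or mask_m.sum() < 10:
        raise ValueError(f"too few cells annotated {wanted!r} "
                         f"(human {int(mask_h.sum())}, mouse {int(mask_m.sum())})")
    norm_h_t = norm_h.subset_cells(mask_h)
    norm_m_t = norm_m.subset_cells(mask_m)
    meta_h_t = meta_h.aligned_to(norm_h_t.cell_ids)
    meta_m_t = meta_m.aligned_to(norm_m_t.cell_ids)

    core = stagemap.select_core_genes(norm_h_t, cfg.core_min_fraction)
    axis = stagemap.fit_stage_axis(norm_h_t, meta_h_t, core,
                                   seed=stage_seed(seed, "stage_axis"))
    pc1_m = stagemap.project_other_species(axis, norm_m_t, omap)
    corr = stagemap.map_stages(axis, pc1_m,
                               meta_m_t.stages(norm_m_t.cell_ids).astype(str))
    return {
        "correspondence": corr,
        "qc_counts": {"human": counts_h, "mouse": counts_m},
        "sketch": sketch_info,
        "annotation": {"human": ann_h, "mouse": ann_m},
        "cell_types": {"human": types_h, "mouse": types_m},
        "cluster_labels": {"human": labels_h, "mouse": labels_m},
        "norm": {"human": norm_h, "mouse": norm_m},
        "meta": {"human": meta_h, "mouse": meta_m},
        "embedding": {"human": emb_h, "mouse": emb_m},
        "axis_model": axis,
        "mouse_pc1": pc1_m,
        "type_masks": {"human": mask_h, "mouse": mask_m},
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline from on-disk bundles and write artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    report: dict = {"seed": config.seed, "stage_seeds": {}}

    def tick(stage: str, t0: float) -> None:
        timings[stage] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s finished in %.2fs", stage, timings[stage])

    for p, what in ((config.human_dir, "human bundle"),
                    (config.mouse_dir, "mouse bundle"),
                    (config.ortholog_table, "ortholog table")):
        if not p or not Path(p).exists():
            raise FileNotFoundError(f"{what} not found at {p!r}")

    t0 = time.perf_counter()
    mat_h, meta_h = read_counts(config.human_dir)
    mat_m, meta_m = read_counts(config.mouse_dir)
    omap = read_ortholog_table(config.ortholog_table)
    tick("load", t0)

    t0 = time.perf_counter()
    res = stage_correspondence_pipeline(mat_h, meta_h, mat_m, meta_m, omap,
                                        cfg=config, seed=config.seed)
    tick("core", t0)
    report["qc_counts"] = res["qc_counts"]
    report["sketch"] = res["sketch"]
    report["stage_seeds"] = {s: stage_seed(config.seed, s) for s in
                             ("qc_human", "qc_mouse", "sketch", "cluster_human",
                              "cluster_mouse", "stage_axis", "markers",
                              "trajectory")}
    report["annotation"] = {sp: {int(k): v for k, v in res["annotation"][sp].items()}
                            for sp in ("human", "mouse")}
    report["cluster_sizes"] = {
        sp: pd.Series(res["cluster_labels"][sp]).value_counts().sort_index()
           .to_dict() for sp in ("human", "mouse")}
    res["correspondence"].to_csv(out / "correspondence.tsv", sep="\t", index=False)
    (out / "stage_axis.json").write_text(res["axis_model"].to_json())
    report["correspondence"] = res["correspondence"][
        ["query_stage", "best_human_stage"]].to_dict("records")

    norm_h, norm_m = res["norm"]["human"], res["norm"]["mouse"]
    types_h, types_m = res["cell_types"]["human"], res["cell_types"]["mouse"]
    for sp in ("human", "mouse"):
        pd.DataFrame({
            "cell_id": res["norm"][sp].cell_ids,
            "cluster": res["cluster_labels"][sp],
            "cell_type": res["cell_types"][sp],
        }).to_csv(out / f"clusters_{sp}.tsv", sep="\t", index=False)

    # cross-species correlation over orthologs
    t0 = time.perf_counter()
    orth_h, orth_m = xs.collapse_to_orthologs(norm_h, norm_m, omap)
    prof_h = xs.type_profiles(orth_h, types_h)
    prof_m = xs.type_profiles(orth_m, types_m)
    corr = xs.correlate_types(prof_h, prof_m)
    corr.to_csv(out / "correlation.tsv", sep="\t")
    report["type_correlation"] = corr.round(4).to_dict()
    tick("crossspecies", t0)

    markers_h = markers_m = None
    if config.do_markers:
        t0 = time.perf_counter()
        markers_h = cl.find_markers(norm_h, types_h, config.marker_min_pct,
                                    config.marker_min_logfc)
        markers_m = cl.find_markers(norm_m, types_m, config.marker_min_pct,
                                    config.marker_min_logfc)
        markers_h.to_csv(out / "markers_human.tsv", sep="\t", index=False)
        markers_m.to_csv(out / "markers_mouse.tsv", sep="\t", index=False)
        conservation = xs.classify_marker_conservation(
            markers_h, markers_m, omap,
            xs.detection_by_type(norm_h, types_h),
            xs.detection_by_type(norm_m, types_m))
        conservation.to_csv(out / "conservation.tsv", sep="\t", index=False)
        report["n_markers"] = {"human": int(len(markers_h)),
                               "mouse": int(len(markers_m))}
        report["conservation_counts"] = (
            conservation["status"].value_counts().to_dict())
        tick("markers", t0)

    phase_counts = {}
    if config.do_trajectory:
        t0 = time.perf_counter()
        mask = res["type_masks"]["human"]
        wanted_ids = list(norm_h.cell_ids[mask])
        pos = {c: i for i, c in enumerate(mat_h.cell_ids)}
        counts_t = mat_h.subset_cells([pos[c] for c in wanted_ids])
        norm_t = norm_h.subset_cells(mask)
        meta_t = res["meta"]["human"].aligned_to(norm_t.cell_ids)
        traj_genes = trajectory.filter_trajectory_genes(counts_t)
        norm_tg = norm_t.subset_genes(norm_t.gene_index(traj_genes))
        ordering = trajectory.select_ordering_genes(
            norm_tg, meta_t.stages(norm_tg.cell_ids).astype(str))
        traj = trajectory.fit_trajectory(
            norm_tg, ordering, meta_t, n_nodes=config.trajectory_nodes,
            d=config.trajectory_dims, seed=stage_seed(config.seed, "trajectory"))
        counts_og = counts_t.subset_genes(counts_t.gene_index(ordering))
        ptde = trajectory.test_pseudotime_dependence(counts_og, traj.pseudotime)
        sig = ptde.loc[ptde["q_value"] < 0.01, "gene"].tolist()
        pd.DataFrame({"cell_id": traj.cell_ids, "node": traj.cell_assignment,
                      "pseudotime": traj.pseudotime}).to_csv(
            out / "trajectory.tsv", sep="\t", index=False)
        ptde.to_csv(out / "pt_de.tsv", sep="\t", index=False)
        if sig:
            phases = trajectory.assign_trajectory_phases(
                norm_tg, traj.pseudotime, sig)
            phases.to_frame().to_csv(out / "phases.tsv", sep="\t")
            phase_counts = phases.value_counts().to_dict()
            report["trajectory_phases"] = {str(k): int(v)
                                           for k, v in phase_counts.items()}
        report["n_pt_de_significant"] = int(len(sig))
        tick("trajectory", t0)

        if config.do_enrich and config.gmt and sig:
            t0 = time.perf_counter()
            sets = read_gmt(config.gmt)
            universe = [str(g) for g in norm_tg.gene_ids]
            ora = enrich.run_ora(sig, universe, sets)
            ora.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            report["n_enriched_sets"] = int((ora["p_adj"] < 0.05).sum()) \
                if len(ora) else 0
            tick("enrich", t0)

    report["timings_s"] = timings
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
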