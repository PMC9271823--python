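"""Two-species synthetic single-cell count generator with ground truth.

The generator emulates the statistical structure the cross-species pipeline
assumes: two species whose cells share a latent maturation axis in [0, 1]
expressed through orthologous gene programs; cell-type marker programs with
conserved and species-specific members; ordered developmental-stage labels
that sample the axis at species-specific points; two sequencing platforms
with different depth (a deep full-length plate chemistry vs a shallow
droplet chemistry); mitochondrial genes carrying a fixed share of each
cell's expected mass; and a controlled doublet fraction.

Counts are negative binomial (gamma-Poisson) with a single dispersion
scalar: mean = depth x capture x cell-size factor x relative expression,
where relative expression is exp(gene baseline + type effect +
archetype(maturation)), renormalized so mitochondrial genes receive
``mito_frac_mean`` of the mass. Doublets are sums of two randomly chosen
same-species expected profiles.

Dynamic archetypes over maturation m:

* ``early``: decreasing logistic (high at m=0, low at m=1),
* ``late``:  increasing logistic,
* ``mid``:   Gaussian bump centered at m=0.5,
* ``flat``:  constant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_io import CellMeta, ExpressionMatrix, OrthologMap, write_counts

__all__ = ["SimConfig", "SyntheticTruth", "simulate_two_species", "write_bundle",
           "default_config", "CANONICAL_TYPES"]

# Default type names and their conserved, canonically named markers; these
# match the marker dictionary shipped with the annotation module so that
# synthetic bundles can be annotated with the same dictionary used for real
# heart data.
CANONICAL_TYPES: dict[str, list[str]] = {
    "CMs": ["TTN", "MYH6", "TNNT2", "TNNC1", "ACTN2"],
    "FBs": ["COL3A1", "COL1A2", "FN1"],
    "ECs": ["CDH5", "EMCN", "PECAM1", "CD93", "TEK", "KDR", "ESAM"],
    "EPs": ["UPK3B", "MSLN", "WT1"],
    "MACs": ["MS4A4A", "SEPP1", "CD68"],
    "NKTs": ["NKG7", "GNLY"],
    "MONOs": ["LYZ", "S100A8", "S100A6"],
    "Blood": ["HBB", "HBA1", "ALAS2"],
}

N_MITO = 13  # mitochondrial protein-coding gene count in mammals


@dataclass
class SimConfig:
    """Parameters of the two-species simulation.

    Stage tuples are ``(label, maturation in [0,1], n_cells)`` with strictly
    increasing maturation within a species. ``platform_params`` maps a batch
    name to ``(depth multiplier, capture efficiency in (0,1])``; batches are
    assigned per stage via ``human_batches`` / ``mouse_batches``.
    """

    n_genes: int = 3000
    frac_ortholog: float = 0.8
    n_types: int = 6
    markers_per_type: int = 40
    frac_specific_markers: float = 0.2
    n_dynamic_genes: int = 300
    human_stages: list[tuple[str, float, int]] = field(default_factory=lambda: [
        ("5W", 0.10, 400), ("7W", 0.32, 400), ("9W", 0.57, 400),
        ("13W", 0.73, 400), ("25W", 0.90, 400),
    ])
    mouse_stages: list[tuple[str, float, int]] = field(default_factory=lambda: [
        ("e8.5", 0.15, 400), ("e9.5", 0.35, 400),
        ("e10.5", 0.60, 400), ("e14.5", 0.85, 800),
    ])
    platform_params: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "strt": (1.0, 0.6),        # human: UMI 5' chemistry, moderate depth
        "smartseq": (2.0, 0.9),    # mouse dataset1: full-length plate, deep
        "droplet": (0.6, 0.5),     # mouse dataset2: droplet, shallow
    })
    human_batches: list[str] = field(default_factory=lambda: ["strt"] * 5)
    mouse_batches: list[str] = field(default_factory=lambda: [
        "smartseq", "smartseq", "smartseq", "droplet"])
    mito_frac_mean: float = 0.08
    doublet_rate: float = 0.05
    dispersion: float = 0.3
    base_depth: float = 8000.0      # expected total counts at depth x capture = 1
    marker_effect: float = 2.0      # log-scale boost of a marker in its type
    dynamic_amplitude: float = 2.0  # log-scale range of archetype curves
    # maturation programs run through abundant structural/metabolic genes
    # (the kind detected in most cells), so dynamic genes get a baseline boost
    dynamic_baseline_boost: float = 1.0
    marker_baseline_boost: float = 0.5
    maturation_jitter: float = 0.05 # per-cell sd around the stage's maturation
    seed: int = 0

    def validate(self) -> None:
        for name, frac in (("frac_ortholog", self.frac_ortholog),
                           ("frac_specific_markers", self.frac_specific_markers),
                           ("mito_frac_mean", self.mito_frac_mean),
                           ("doublet_rate", self.doublet_rate)):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name}={frac} outside [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.markers_per_type * self.n_types > self.n_genes:
            raise ValueError(
                f"markers_per_type x n_types = "
                f"{self.markers_per_type * self.n_types} exceeds n_genes={self.n_genes}"
            )
        for species, stages in (("human", self.human_stages), ("mouse", self.mouse_stages)):
            mats = [m for _, m, _ in stages]
            if any(b <= a for a, b in zip(mats, mats[1:])):
                raise ValueError(f"{species} stage maturations must be strictly increasing")
            if any(n < 1 for _, _, n in stages):
                raise ValueError(f"{species} stage with n_cells < 1")
            if any(not 0.0 <= m <= 1.0 for m in mats):
                raise ValueError(f"{species} maturation outside [0, 1]")
        for batches, stages, sp_ in ((self.human_batches, self.human_stages, "human"),
                                     (self.mouse_batches, self.mouse_stages, "mouse")):
            if len(batches) != len(stages):
                raise ValueError(f"{sp_}: one batch per stage required")
            for b in batches:
                if b not in self.platform_params:
                    raise ValueError(f"unknown batch {b!r}")
        for b, (depth, capture) in self.platform_params.items():
            if depth <= 0 or not 0 < capture <= 1:
                raise ValueError(f"platform {b!r}: depth>0 and capture in (0,1] required")


def default_config(**overrides) -> SimConfig:
    """The default study conditions; keyword overrides applied on top."""
    cfg = SimConfig(**overrides)
    cfg.validate()
    return cfg


@dataclass
class SyntheticTruth:
    """Ground-truth tables for downstream recovery tests.

    ``cell_table``: per cell -- species, stage, maturation, true type, doublet
    flag, batch. ``gene_table``: per gene -- species, ortholog partner (or
    empty), marker-of type (or empty), conserved/specific flag, dynamic
    archetype. ``correspondence``: per mouse stage, the nearest human stage by
    absolute maturation difference (ties to the earlier human stage).
    """

    cell_table: pd.DataFrame
    gene_table: pd.DataFrame
    correspondence: pd.DataFrame
    seed: int = 0


def _archetype_curve(archetype: str, m: np.ndarray, amplitude: float) -> np.ndarray:
    if archetype == "early":
        return amplitude / (1.0 + np.exp(6.0 * (m - 0.5)))
    if archetype == "late":
        return amplitude / (1.0 + np.exp(-6.0 * (m - 0.5)))
    if archetype == "mid":
        return amplitude * np.exp(-((m - 0.5) ** 2) / (2 * 0.15**2))
    return np.zeros_like(m)


def _nearest_human_stage(m_mouse: float, human_stages) -> str:
    # ties broken toward the earlier human stage (list order is stage order)
    best, best_d = None, np.inf
    for label, m, _ in human_stages:
        d = abs(m_mouse - m)
        if d < best_d - 1e-12:
            best, best_d = label, d
    return best


def _gene_names(cfg: SimConfig, rng: np.random.Generator):
    """Gene identifiers, ortholog pairing, and structural gene roles.

    Layout of gene indices (identical in both species so that orthologous
    structure is positional; names differ by species convention -- human
    upper-case, mouse title-case of the same symbol for orthologs,
    species-unique names otherwise):

    ``[0, N_MITO)`` mito genes, then markers per type, then dynamic genes,
    then background. Orthologs are the first ``round(frac_ortholog*n_genes)``
    positions (mito genes are always orthologous).
    """
    n = cfg.n_genes
    n_orth = int(round(cfg.frac_ortholog * n))
    n_orth = max(n_orth, N_MITO)
    mito_h = [f"MT-G{i}" for i in range(N_MITO)]
    mito_m = [f"mt-g{i}" for i in range(N_MITO)]

    type_names = (list(CANONICAL_TYPES)[: cfg.n_types]
                  if cfg.n_types <= len(CANONICAL_TYPES)
                  else [f"T{t}" for t in range(cfg.n_types)])

    human = list(mito_h)
    mouse = list(mito_m)
    roles = [{"marker_of": "", "conservation": "", "archetype": "flat", "mito": True}
             for _ in range(N_MITO)]

    def add(sym_h: str, sym_m: str, marker_of="", conservation="", archetype="flat"):
        human.append(sym_h)
        mouse.append(sym_m)
        roles.append({"marker_of": marker_of, "conservation": conservation,
                      "archetype": archetype, "mito": False})

    counter = 0
    for t, tname in enumerate(type_names):
        canon = CANONICAL_TYPES.get(tname, [])
        n_specific = int(round(cfg.frac_specific_markers * cfg.markers_per_type))
        n_conserved = cfg.markers_per_type - n_specific
        for j in range(n_conserved):
            if j < len(canon):
                sym = canon[j]
            else:
                sym = f"MK{t}C{j}"
            add(sym, sym.capitalize(), marker_of=tname, conservation="conserved")
        for j in range(n_specific):
            sym = f"MK{t}S{j}"
            add(sym, sym.capitalize(), marker_of=tname, conservation="specific")
            counter += 1

    archetypes = ["early", "mid", "late"]
    for j in range(cfg.n_dynamic_genes):
        sym = f"DYN{j}"
        add(sym, sym.capitalize(), archetype=archetypes[j % 3])

    while len(human) < n:
        j = len(human)
        add(f"BG{j}", f"Bg{j}")
    if len(human) > n:
        raise ValueError("structural genes exceed n_genes; increase n_genes")

    # positions >= n_orth are species-unique (no ortholog partner)
    for i in range(n_orth, n):
        human[i] = f"HS-{human[i]}"
        mouse[i] = f"Ms-{mouse[i]}"
    is_ortholog = np.arange(n) < n_orth

    # specific markers: decide which species keeps the effect
    specific_species = {}
    for i, r in enumerate(roles):
        if r["conservation"] == "specific":
            specific_species[i] = "human" if rng.random() < 0.5 else "mouse"
    return (np.array(human, dtype=object), np.array(mouse, dtype=object),
            is_ortholog, roles, type_names, specific_species)


def _simulate_species(cfg, rng, species, gene_syms, roles, type_names,
                      specific_species, baseline, type_effects, stages, batches):
    """NB counts + per-cell truth for one species."""
    n_genes = cfg.n_genes
    mito_mask = np.array([r["mito"] for r in roles])
    arche = np.array([r["archetype"] for r in roles], dtype=object)

    stage_label, stage_m, batch_of, n_cells = [], [], [], 0
    for (label, m, n), b in zip(stages, batches):
        stage_label += [label] * n
        stage_m += [m] * n
        batch_of += [b] * n
        n_cells += n
    stage_label = np.array(stage_label, dtype=object)
    stage_m = np.array(stage_m, dtype=float)
    batch_of = np.array(batch_of, dtype=object)

    maturation = np.clip(
        stage_m + rng.normal(0.0, cfg.maturation_jitter, n_cells), 0.0, 1.0)
    cell_type = rng.integers(0, cfg.n_types, n_cells)

    # log relative expression: baseline + type effect + archetype(maturation)
    log_rel = np.tile(baseline, (n_cells, 1))
    for i, r in enumerate(roles):
        if r["marker_of"]:
            if r["conservation"] == "specific" and specific_species[i] != species:
                continue
            t = type_names.index(r["marker_of"])
            log_rel[cell_type == t, i] += cfg.marker_effect
    for a in ("early", "mid", "late"):
        cols = np.flatnonzero(arche == a)
        if len(cols):
            log_rel[:, cols] += _archetype_curve(a, maturation, cfg.dynamic_amplitude)[:, None]
    # per-type background wobble so types differ beyond markers a little
    log_rel += type_effects[cell_type]

    w = np.exp(log_rel)
    w_mito = w[:, mito_mask]
    w_rest = w[:, ~mito_mask]
    w_mito *= cfg.mito_frac_mean / np.maximum(w_mito.sum(1, keepdims=True), 1e-300)
    w_rest *= (1 - cfg.mito_frac_mean) / np.maximum(w_rest.sum(1, keepdims=True), 1e-300)
    w[:, mito_mask] = w_mito
    w[:, ~mito_mask] = w_rest

    depth = np.array([cfg.platform_params[b][0] for b in batch_of])
    capture = np.array([cfg.platform_params[b][1] for b in batch_of])
    size_factor = np.exp(rng.normal(0.0, 0.25, n_cells))
    totals = cfg.base_depth * depth * capture * size_factor
    mu = w * totals[:, None]

    is_doublet = rng.random(n_cells) < cfg.doublet_rate
    if is_doublet.any():
        partners = rng.integers(0, n_cells, int(is_doublet.sum()))
        mu[is_doublet] = mu[is_doublet] + mu[partners]

    shape = 1.0 / cfg.dispersion
    lam = rng.gamma(shape, mu * cfg.dispersion)
    counts = rng.poisson(lam).astype(np.int32)

    cell_ids = np.array([f"{species[0].upper()}C{i:05d}" for i in range(n_cells)],
                        dtype=object)
    matrix = ExpressionMatrix(sp.csr_matrix(counts.T), gene_syms, cell_ids, species)
    cell_table = pd.DataFrame({
        "cell_id": cell_ids, "species": species, "stage": stage_label,
        "maturation": maturation, "cell_type": [type_names[t] for t in cell_type],
        "is_doublet": is_doublet, "batch": batch_of,
    })
    meta = CellMeta(
        cell_table.set_index("cell_id")[["stage", "batch"]].assign(
            species=species, platform=batch_of),
        stage_order=[label for label, _, _ in stages],
    )
    return matrix, meta, cell_table


def simulate_two_species(config: SimConfig):
    """Simulate paired human/mouse single-cell counts with ground truth.

    Returns ``(matrix_h, matrix_m, meta_h, meta_m, ortholog_map, truth)``.
    Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    human_syms, mouse_syms, is_orth, roles, type_names, specific_species = \
        _gene_names(config, rng)

    baseline = rng.normal(0.0, 1.0, config.n_genes)
    for i, r in enumerate(roles):
        if r["archetype"] != "flat":
            baseline[i] += config.dynamic_baseline_boost
        if r["marker_of"]:
            baseline[i] += config.marker_baseline_boost
    # mild per-type background shifts on non-structural genes
    type_effects = rng.normal(0.0, 0.05, (config.n_types, config.n_genes))

    rng_h = np.random.default_rng(rng.integers(2**31))
    rng_m = np.random.default_rng(rng.integers(2**31))
    mat_h, meta_h, cells_h = _simulate_species(
        config, rng_h, "human", human_syms, roles, type_names, specific_species,
        baseline, type_effects, config.human_stages, config.human_batches)
    mat_m, meta_m, cells_m = _simulate_species(
        config, rng_m, "mouse", mouse_syms, roles, type_names, specific_species,
        baseline, type_effects, config.mouse_stages, config.mouse_batches)

    omap = OrthologMap(pd.DataFrame({
        "gene_a": human_syms[is_orth], "gene_b": mouse_syms[is_orth]}))

    gene_rows = []
    for i, r in enumerate(roles):
        for species, syms, partner_syms in (("human", human_syms, mouse_syms),
                                            ("mouse", mouse_syms, human_syms)):
            conservation = r["conservation"]
            if conservation == "specific":
                conservation = f"{specific_species[i]}_specific"
            gene_rows.append({
                "gene": syms[i], "species": species,
                "ortholog_partner": partner_syms[i] if is_orth[i] else "",
                "marker_of": r["marker_of"], "conservation": conservation,
                "archetype": r["archetype"], "mito": r["mito"],
            })
    gene_table = pd.DataFrame(gene_rows)

    correspondence = pd.DataFrame({
        "mouse_stage": [label for label, _, _ in config.mouse_stages],
        "human_stage": [_nearest_human_stage(m, config.human_stages)
                        for _, m, _ in config.mouse_stages],
    })
    truth = SyntheticTruth(pd.concat([cells_h, cells_m], ignore_index=True),
                           gene_table, correspondence, seed=config.seed)
    return mat_h, mat_m, meta_h, meta_m, omap, truth


def write_bundle(outputs, directory, force: bool = False) -> list[str]:
    """Write a simulation to disk as MTX/TSV files plus a manifest.

    ``outputs`` is the tuple returned by :func:`simulate_two_species`. Refuses
    a non-empty target directory unless ``force`` is set.
    """
    mat_h, mat_m, meta_h, meta_m, omap, truth = outputs
    d = Path(directory)
    if d.exists() and any(d.iterdir()) and not force:
        raise FileExistsError(f"{d} is not empty; pass force=True to overwrite")
    d.mkdir(parents=True, exist_ok=True)

    files: list[str] = []
    for species, mat, meta in (("human", mat_h, meta_h), ("mouse", mat_m, meta_m)):
        sub = d / species
        sub.mkdir(exist_ok=True)
        files += [f"{species}/{f}" for f in write_counts(mat, meta, sub)]
    omap.pairs.to_csv(d / "orthologs.tsv", sep="\t", index=False)
    truth.cell_table.to_csv(d / "truth_cells.tsv", sep="\t", index=False)
    truth.gene_table.to_csv(d / "truth_genes.tsv", sep="\t", index=False)
    truth.correspondence.to_csv(d / "truth_correspondence.tsv", sep="\t", index=False)
    files += ["orthologs.tsv", "truth_cells.tsv", "truth_genes.tsv",
              "truth_correspondence.tsv"]
    manifest = {
        "seed": int(truth.seed),
        "files": files,
        "n_genes": int(mat_h.n_genes),
        "n_cells_human": int(mat_h.n_cells),
        "n_cells_mouse": int(mat_m.n_cells),
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2))
    files.append("manifest.json")
    return files
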