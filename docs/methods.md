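# Methods

`cardimap` re-implements, as a tested and reusable pipeline, a cross-species
comparison of human and mouse embryonic-heart single-cell transcriptomes:
quality control, platform balancing, integration, clustering and marker-based
annotation, ortholog-restricted cell-type correlation, pseudotime trajectory
analysis with three-phase gene clustering, gene-set over-representation, and
a PC1-density procedure that maps mouse developmental stages onto human
stages. This note documents the models, the default parameters and why they
hold their values, what the synthetic data generator does and does not
emulate, and the numerical choices made where the design was open.

## Quality control

Per-cell metrics are the detected gene count (genes with count > 0), the
transcript total (column sum of the raw count matrix, for both UMI and
read-count chemistries), and the mitochondrial fraction (genes recognized by
the `MT-`/`mt-` prefix). Shipped presets carry published-style filter
settings: human UMI data keeps cells with >= 1,000 genes and >= 5,000
transcripts; deep full-length mouse data keeps cells with > 1,800 genes
(strictly greater) and >= 1e6 transcripts; all presets drop cells above 30%
mitochondrial content — a deliberately generous cutoff because roughly a
third of cardiac mRNA is mitochondrial. Zero-count cells are flagged
degenerate; they fail any preset with `min_genes >= 1` and are retained but
flagged when all thresholds are zero. A second threshold set
(`pipeline.SYNTHETIC_QC`) carries the same structure scaled to the synthetic
platforms' depths.

Doublet detection is a pANN (proportion of artificial nearest neighbors)
scheme: artificial doublets are sums of random cell pairs; real and
artificial cells are embedded jointly by PCA (20 components) of the top
2,000 highly variable genes of the log-normalized combined matrix; a cell's
score is the fraction of artificial points among its k = 20 nearest
neighbors; the top `round(expected_rate * n_cells)` scores are flagged
(default expected rate 7.5%, default artificial fraction 25%). This omits
parameter sweeps and homotypic-rate adjustment of heavier doublet callers on
purpose — downstream stages only require that likely doublets are removed
before clustering. On the default synthetic conditions with 10% planted
doublets the scheme recovers ~80% of them; same-type doublets are
intrinsically harder and account for most misses.

## Normalization, HVGs, PCA, sketching, integration

Counts are log-normalized as `log(1 + count / cell_total * 10,000)`.
Highly variable genes are ranked by a variance-stabilized dispersion: the
per-gene variance of log values divided by the median variance of the gene's
20-quantile mean-expression bin; the top 2,000 are kept, ties broken by gene
identifier so results are reproducible. Before PCA genes are z-scored with
values clipped at +/-10 (rare-cell blowup protection); the decomposition is
applied to the clipped z-matrix directly, without re-centering, so that
out-of-sample projection through the stored means, standard deviations, and
loadings exactly reproduces training scores. Component signs are fixed so
each loading vector's largest-magnitude entry is positive. For large inputs
a seeded randomized SVD computes the leading components; small inputs use a
full SVD.

Geometric sketching balances platforms of very different sizes: the
embedding's bounding box is covered with equal-sided hypercubes, the side
length binary-searched until the occupied-box count falls in
`[k_target, 2 k_target]`, one random cell is drawn per sampled box, and the
sketch is topped up uniformly if boxes run out. Box coverage is what
preserves rare populations that occupy their own region of expression space.

Batch alignment is an iterative centroid-matching scheme carrying the two
conventional knobs (at most 50 clusters, at most 100 iterations): soft
k-means responsibilities on current scores; per cluster, each batch's cells
are shifted by the responsibility-weighted difference between the
batch-conditional centroid and the overall cluster centroid; iteration stops
when the maximum displacement drops below 1e-4. The first 20 corrected
dimensions, rescaled to unit variance, feed clustering. This is a simplified
stand-in for published diversity-penalized integration objectives; it
satisfies the same testable contract (batches mix, cell types stay apart)
and its limitations are noted below.

## Clustering and annotation

Cells are clustered by Leiden modularity optimization (resolution 1.0,
seeded) on a k = 20 nearest-neighbor graph with shared-neighbor Jaccard edge
weights. Markers are one-vs-rest two-sided Wilcoxon rank-sum tests on
log-normalized values — normal approximation with tie correction at scale,
exact permutation enumeration on fixtures of <= 10 cells — restricted to
genes detected in >= 10% of either side with |avg log fold change| >= 0.25
(natural log of `mean(expm1) + 1` ratios), BH-corrected within each cluster.

Annotation scores each cluster against a marker dictionary (cluster-mean
expression z-scored per gene across clusters, averaged over each type's
genes). The dictionary ships the canonical embryonic-heart markers: CMs
(TTN, MYH6, TNNT2, TNNC1, ACTN2), FBs (COL3A1, COL1A2, FN1), ECs (CDH5,
EMCN, PECAM1, CD93, TEK, KDR, ESAM), EPs (UPK3B, MSLN, WT1), MACs (MS4A4A,
SEPP1, CD68), MONOs (LYZ, S100A8, S100A6), NKTs (NKG7, GNLY), and blood
(HBB, HBA1, ALAS2 — standard erythroid markers chosen here). NKX2-5 is
excluded from the EC list despite sometimes being grouped with endothelial
markers: it is canonically a cardiomyocyte transcription factor. Composite
labels (`ECs/FBs`, `MACs/MONOs`, `EPs/FBs`) are assigned when the top two
type scores lie within a margin delta = 0.25 (configurable; there is no
canonical rule for mixed clusters) and the pair is a declared composite.

A consequence worth stating: with a realistic maturation program the graph
clustering subdivides each cell type along the developmental axis — exactly
as real embryonic-heart analyses report more clusters than types. Type
recovery is therefore evaluated on annotated (dictionary-merged) labels, not
raw cluster ids; on the default synthetic conditions the merged labels reach
ARI > 0.95 against planted types.

## Cross-species comparison

Both species' matrices are collapsed to one-to-one ortholog pairs present in
both (rows aligned in ortholog-table order), cell-type profiles are mean
log-normalized expression, and similarity is the Pearson correlation of
profiles over shared rows — no further scaling, the simplest reading of
"average expression levels". Marker conservation classifies each (pair,
type): *shared* if a significant positive marker (p_adj < 0.01, logFC >
0.25) of the homologous type in both species; *species-specific* if
significant in one while in the other the gene is detected in < 10% of the
type's cells or clearly non-significant (p_adj >= 0.05 or untested);
*neither* otherwise. The specificity rule quantifies "only expressed in one
species", which has no canonical formalization.

## Trajectories, pseudotime DE, phases

Trajectory genes must be detected in `max(10, ceil(5% of cells))` cells.
Ordering genes are stage-differential genes (Kruskal-Wallis across stages,
BH q < 0.01, top 1,000 by statistic). The trajectory itself is a
centroid-MST scheme in the Monocle-1/TSCAN family: PCA to 2 dimensions on
ordering genes, k-means with 15 nodes, minimum spanning tree over centroids,
cells assigned to the nearest centroid. The root is the centroid whose cells
are most enriched for the earliest stage (explicit stage order, never string
sorting), with ties broken toward the most peripheral tree node — a
trajectory starts at an extreme, not mid-path. Pseudotime is geodesic tree
distance from the root plus the cell's signed projection onto its incident
edge, min-max scaled to [0, 1]. A faithful re-implementation of
graph-embedding trajectory methods (DDRTree and kin) would be out of
proportion to their role here; the testable contract — cells ordered from
early to late stages — is identical.

Pseudotime-dependent genes are tested per gene by a likelihood-ratio test of
negative-binomial regression (log link, library-size offset) with a natural
cubic spline in pseudotime (3 df, hand-built basis with boundary knots at
the range and interior knots at quantiles) against an intercept-only model,
chi-square with 3 df, BH-corrected. The NB dispersion is estimated by
moments under the null model and held fixed in both fits: estimating it
per-model inflates the LRT under the null, while the shared-dispersion form
is well calibrated (KS test of null p-values against uniform passes
comfortably) at the cost of mild conservatism under strong alternatives —
acceptable, since planted dynamic genes are still detected with q < 0.01 at
n = 400 cells. Counts, not normalized values, are modeled; genes whose fits
fail get p = 1 and a flag.

Significant genes (q < 0.01, matching the DEG cut used elsewhere) are
smoothed by the same spline basis on a 100-point pseudotime grid, z-scored,
and assigned the tertile — initial, transitional, terminal — where their
smoothed profile peaks; exact ties go to transitional. Subpopulation density
curves are per-label Gaussian KDEs (Scott bandwidth, floor 0.05 for
degenerate groups) on a shared 200-point grid over [0, 1], renormalized to
unit trapezoid integral because boundary truncation otherwise leaks mass.

## Stage mapping (the PC1-density procedure)

For one cell type: core genes are those detected in >= 75% of the human
cells of that type. The human cells' core genes are z-scored and decomposed;
PC1 separates stages as overlapping, stepwise clusters ordered by age, so it
serves as the maturation axis. The axis is oriented so Spearman correlation
of PC1 with stage rank is nonnegative, and a Gaussian KDE of oriented PC1 is
fit per human stage (Scott's rule with a floor of 1% of the PC1 range so
small stages do not degenerate; 512-point grid spanning the observed range
plus three bandwidths).

Mouse cells of the homologous type are projected onto this axis: loadings
restricted to core genes whose orthologs are detected in the mouse matrix
(>= 50% coverage required), renormalized to unit norm — zero-imputation was
rejected because it systematically shrinks projections toward the center —
and mouse expression standardized with the **human** gene statistics, the
only choice that keeps the dot product on the human axis geometrically
coherent. Each mouse stage is assigned the human stage whose density is
highest at the mouse stage's mean PC1 (linear interpolation on the stored
grid); ties break toward the earlier human stage and are flagged, and
queries outside all grids are evaluated at the nearest endpoint and flagged.
Per-cell soft assignments (normalized densities) are also available.

## The synthetic data generator

The generator is first-class, tested code and defines the study conditions
for every recovery test. Two species share a latent maturation axis in
[0, 1]; counts are negative binomial (gamma-Poisson, one dispersion scalar,
default 0.3) with mean = depth x capture x cell-size factor x relative
expression, where log relative expression = gene baseline + cell-type marker
effect + archetype(maturation), renormalized so mitochondrial genes (13 of
them, `MT-`/`mt-` prefixed) carry 8% of each cell's expected mass. Doublets
(default 5%) are sums of two random same-species expected profiles.

Default conditions: 3,000 genes per species, 80% one-to-one orthologs
(human upper-case symbols, mouse title-case of the same string; species-
unique genes prefixed `HS-`/`Ms-`); 6 cell types named and marked like the
major embryonic-heart populations so the shipped annotation dictionary
applies; 40 markers per type with a 2.0 natural-log effect, 20% of them
species-specific (effect in one species only); 300 maturation-program genes
split evenly into early (decreasing logistic, slope 6), mid (Gaussian bump
at 0.5, sd 0.15), and late (increasing logistic) archetypes with a 2.0
natural-log amplitude. Two parameter choices deserve justification:

* **Dynamic genes get a +1.0 baseline boost** (markers +0.5). Maturation
  programs in the heart run through abundant structural and metabolic genes
  — which is also the premise of the 75%-detection core-gene filter. Without
  the boost most dynamic genes fall below the detection level the stage-axis
  procedure requires, and the within-stage PC1 noise swamps the
  between-stage signal.
* **Amplitude 2.0** corresponds to a ~7-fold expression change across the
  full developmental window, typical of strongly dynamic maturation genes.

Stages sample the axis at species-specific points: human 5W/7W/9W/13W/25W
at maturations 0.10/0.32/0.57/0.73/0.90 (400 cells each); mouse
e8.5/e9.5/e10.5/e14.5 at 0.15/0.35/0.60/0.85 (400/400/400/800). The human
anchors are deliberately unevenly spaced: with evenly spaced anchors the
third mouse stage would be exactly equidistant from two human stages and the
ground-truth correspondence undefined. Per-cell maturation jitters around
the stage value (sd 0.05) — embryos within a nominal stage vary. Platforms:
human `strt` (depth x capture = 0.6, ~5k counts/cell), mouse `smartseq`
(1.8, ~14k) for the three early stages and `droplet` (0.3, ~2.4k) for
e14.5, against a base depth of 8,000; the large droplet stage is the one
the pipeline sketches down, mirroring the usual deep-plate vs
large-droplet design. Ground truth records every cell's type, maturation,
doublet flag and batch, every gene's role, and the nearest-maturation stage
correspondence (ties to the earlier human stage).

What the generator does **not** emulate: gene-gene correlation beyond the
shared programs, ambient RNA, empty droplets, batch-specific gene-length or
GC biases, spatial structure, cell-cycle phase, or realistic gene-level
parameters of any particular dataset. Passing recovery tests therefore shows
the pipeline's internal consistency under its stated assumptions, not
performance on any real dataset.

## Known limitations

* **Cross-platform projection bias.** Log-normalization does not remove the
  depth dependence of log1p means: deeply sequenced query data looks
  systematically "older" (and shallow data at the immature end does too,
  because weakly expressed genes at each end carry the distortion). At the
  default depth contrasts the residual bias is a fraction of the
  within-stage spread; at more extreme contrasts it can shift stage calls
  toward later stages. The projection deliberately follows the stated
  contract (query standardized with human statistics) rather than adding an
  uncontracted correction.
* The centroid-matching integrator corrects location shifts per cluster, not
  covariance or nonlinear distortions.
* The stage call is the density argmax at the stage-mean PC1; with heavily
  overlapping stage densities the call degrades to a nearest-mean rule and
  should be read together with the reported runner-up and the per-cell
  posteriors.
* The NB dispersion is per-gene-by-moments, not shrunk across genes; very
  low-count genes have noisy dispersion estimates and conservative tests.
* Problem sizes in tests and in `scripts/acceptance.py` (≈2,000–2,400 cells
  per species, 3,000 genes, 10–20 seeds per check) were chosen as the
  smallest sizes at which every recovery statistic is stable; they are the
  package's own study conditions.
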