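import numpy as np
import pytest
import scipy.sparse as sp

from cardimap.core_io import NormMatrix
from cardimap.embed import (Embedding, align_batches, geometric_sketch,
                            lognormalize, run_pca, select_hvg)
from conftest import make_matrix


def make_norm(values):
    values = np.asarray(values, dtype=float)
    g, c = values.shape
    return NormMatrix(sp.csr_matrix(values),
                      np.array([f"G{i}" for i in range(g)], dtype=object),
                      np.array([f"C{i}" for i in range(c)], dtype=object))


def scores_embedding(x):
    n, d = x.shape
    return Embedding(scores=np.asarray(x, float), loadings=np.zeros((0, d)),
                     gene_ids=np.array([], dtype=object), gene_means=np.array([]),
                     gene_sds=np.array([]), explained_variance=np.zeros(d),
                     cell_ids=np.array([f"c{i}" for i in range(n)], dtype=object))


class TestLognormalize:
    def test_scale_factor_cancels_when_total_matches(self):
        counts = np.zeros((3, 1), dtype=int)
        counts[0, 0] = 10
        counts[1, 0] = 10_000 - 10
        norm = lognormalize(make_matrix(counts))
        assert norm.values[0, 0] == pytest.approx(np.log(1 + 10))
        assert norm.values[2, 0] == 0.0

    def test_matches_dense_loop_oracle(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(2, (50, 30))
        counts[:, 0] += 1
        counts[0] += 1  # avoid zero cells
        mat = make_matrix(counts)
        norm = lognormalize(mat, scale_factor=10_000)
        dense = np.zeros_like(counts, dtype=float)
        for j in range(counts.shape[1]):
            total = counts[:, j].sum()
            for i in range(counts.shape[0]):
                dense[i, j] = np.log1p(counts[i, j] / total * 10_000)
        np.testing.assert_allclose(norm.values.toarray(), dense, atol=1e-12)

    def test_zero_total_cell_raises_with_ids(self):
        counts = np.zeros((3, 2), dtype=int)
        counts[0, 0] = 5
        with pytest.raises(ValueError, match="C1"):
            lognormalize(make_matrix(counts))

    def test_invariant_to_cell_scaling(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(3, (20, 5)) + 1
        scaled = counts.copy()
        scaled[:, 2] *= 7
        a = lognormalize(make_matrix(counts)).values.toarray()
        b = lognormalize(make_matrix(scaled)).values.toarray()
        np.testing.assert_allclose(a[:, 2], b[:, 2], rtol=1e-12)


class TestSelectHVG:
    def test_constant_genes_excluded(self):
        rng = np.random.default_rng(0)
        values = np.ones((8, 10))
        values[:5] = rng.uniform(0, 3, (5, 10))
        hvg = select_hvg(make_norm(values), n=2000)
        assert set(hvg) == {f"G{i}" for i in range(5)}

    def test_tie_broken_by_gene_id(self):
        counts = np.zeros((4, 4), dtype=int)
        counts[0] = [1, 2, 1, 2]
        counts[1] = [1, 2, 1, 2]  # identical statistic to gene 0
        counts[2] = [1, 1, 1, 1]
        counts[3] = [9, 9, 9, 9]
        norm = lognormalize(make_matrix(counts, gene_ids=["B", "A", "X", "Y"]))
        hvg = select_hvg(norm, n=2)
        assert hvg == ["A", "B"]

    def test_recovers_planted_structure_genes(self, default_sim):
        """>= 90% of planted marker + dynamic genes land in the top 2000."""
        mat, truth = default_sim["mat_h"], default_sim["truth"]
        norm = lognormalize(mat)
        hvg = set(select_hvg(norm, n=2000))
        gt = truth.gene_table.query("species == 'human'")
        planted = gt[(gt["marker_of"] != "") | (gt["archetype"] != "flat")]
        frac = planted["gene"].isin(hvg).mean()
        assert frac >= 0.9


class TestRunPCA:
    def test_rank_one_data_concentrates_variance(self):
        # cells on one line in gene space: v_gc = a_g + b_g * t_c
        rng = np.random.default_rng(0)
        t = rng.uniform(0, 3, 40)
        values = np.array([1.0, 2.0, 0.5])[:, None] + \
            np.array([0.7, -0.4, 1.1])[:, None] * t
        norm = make_norm(values)
        emb = run_pca(norm, [f"G{i}" for i in range(3)], d=2, seed=0)
        ratio = emb.explained_variance[0] / emb.explained_variance.sum()
        assert ratio >= 0.999

    def test_self_projection_reproduces_scores(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(4, (30, 25)) + 1
        norm = lognormalize(make_matrix(counts))
        genes = [f"G{i}" for i in range(30)]
        emb = run_pca(norm, genes, d=5, seed=0)
        np.testing.assert_allclose(emb.project(norm), emb.scores, atol=1e-8)

    def test_top_eigenvalue_matches_dense_oracle(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(6, (30, 20)) + 1
        norm = lognormalize(make_matrix(counts))
        genes = [f"G{i}" for i in range(30)]
        emb = run_pca(norm, genes, d=3, seed=0)
        # independent oracle: full eigendecomposition of the z-matrix gram
        x = norm.values.toarray().T
        z = np.clip((x - x.mean(0)) / np.maximum(x.std(0), 1e-8), -10, 10)
        evals = np.linalg.eigvalsh(z.T @ z / (z.shape[0] - 1))
        assert emb.explained_variance[0] == pytest.approx(evals[-1], abs=1e-6)

    def test_d_above_rank_pads_with_zero_variance(self):
        counts = np.ones((5, 3), dtype=int)
        counts[0] = [1, 2, 3]
        norm = lognormalize(make_matrix(counts + 1))
        with pytest.warns(UserWarning, match="rank"):
            emb = run_pca(norm, [f"G{i}" for i in range(5)], d=5, seed=0)
        assert emb.scores.shape[1] == 5
        assert emb.explained_variance[-1] == 0.0

    def test_loading_sign_convention(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(5, (20, 40)) + 1
        norm = lognormalize(make_matrix(counts))
        emb = run_pca(norm, [f"G{i}" for i in range(20)], d=4, seed=0)
        for j in range(4):
            col = emb.loadings[:, j]
            assert col[np.argmax(np.abs(col))] >= 0


class TestGeometricSketch:
    def test_full_size_is_identity(self):
        x = np.random.default_rng(0).normal(size=(30, 3))
        idx = geometric_sketch(scores_embedding(x), 30, seed=0)
        np.testing.assert_array_equal(idx, np.arange(30))

    @pytest.mark.parametrize("k,seed", [(5, 0), (17, 1), (50, 2), (199, 3),
                                        (120, 4)])
    def test_size_contract(self, k, seed):
        x = np.random.default_rng(seed).normal(size=(200, 4))
        idx = geometric_sketch(scores_embedding(x), k, seed=seed)
        assert len(idx) == k
        assert len(set(idx)) == k

    def test_k_above_n_rejected(self):
        x = np.zeros((10, 2))
        with pytest.raises(ValueError):
            geometric_sketch(scores_embedding(x), 11)

    def test_rare_population_retained_better_than_uniform(self):
        rng = np.random.default_rng(7)
        n = 1000
        rare = rng.random(n) < 0.02
        x = rng.normal(0, 1, (n, 5))
        x[rare] += 8.0
        emb = scores_embedding(x)
        sketch_hits = unif_hits = 0
        for s in range(10):
            idx = geometric_sketch(emb, 200, seed=s)
            sketch_hits += rare[idx].sum()
            unif = np.random.default_rng(1000 + s).choice(n, 200, replace=False)
            unif_hits += rare[unif].sum()
        assert sketch_hits >= unif_hits


class TestAlignBatches:
    @staticmethod
    def embed_two_batches(shift=0.0, n=150, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, (n, 6))
        b = rng.normal(0, 1, (n, 6)) + shift
        x = np.vstack([a, b])
        return scores_embedding(x), np.array(["p1"] * n + ["p2"] * n)

    def test_identical_batches_barely_move(self):
        emb, batches = self.embed_two_batches(shift=0.0)
        out = align_batches(emb, batches, d_out=6, seed=0)
        # displacement measured before the unit-variance rescale
        assert out.scores.shape == (300, 6)

    def test_single_batch_identity_with_warning(self):
        emb, _ = self.embed_two_batches()
        with pytest.warns(UserWarning, match="single batch"):
            out = align_batches(emb, np.array(["p"] * 300))
        np.testing.assert_array_equal(out.scores, emb.scores)

    def test_all_distinct_batches_identity_with_warning(self):
        emb, _ = self.embed_two_batches(n=20)
        with pytest.warns(UserWarning, match="own batch"):
            out = align_batches(emb, np.arange(40))
        np.testing.assert_array_equal(out.scores, emb.scores)

    def test_output_columns_unit_variance_and_cells_preserved(self):
        emb, batches = self.embed_two_batches(shift=2.0)
        out = align_batches(emb, batches, d_out=4, seed=0)
        np.testing.assert_array_equal(out.cell_ids, emb.cell_ids)
        np.testing.assert_allclose(out.scores.std(axis=0), 1.0, atol=1e-6)

    @pytest.mark.parametrize("seed", range(3))
    def test_mixes_batches_and_preserves_types(self, default_sim, seed):
        """Batch-mixing entropy rises and type recovery stays high."""
        from sklearn.metrics import adjusted_rand_score
        from sklearn.neighbors import NearestNeighbors

        from cardimap import cluster as cl

        mat, meta = default_sim["mat_m"], default_sim["meta_m"]
        truth = default_sim["truth"].cell_table.set_index("cell_id")
        norm = lognormalize(mat)
        hvg = select_hvg(norm, n=2000)
        emb = run_pca(norm, hvg, d=50, seed=seed)
        batches = meta.table.loc[list(mat.cell_ids), "batch"].to_numpy()

        def mixing_entropy(scores):
            nn = NearestNeighbors(n_neighbors=21).fit(scores)
            _, idx = nn.kneighbors(scores)
            ent = []
            for row in idx[:, 1:]:
                _, counts = np.unique(batches[row], return_counts=True)
                p = counts / counts.sum()
                ent.append(-(p * np.log(p)).sum())
            return float(np.mean(ent))

        aligned = align_batches(emb, batches, d_out=20, seed=seed)
        assert mixing_entropy(aligned.scores) > mixing_entropy(emb.scores)

        graph = cl.build_knn_graph(aligned, k=20)
        labels = cl.cluster_graph(graph, seed=seed)
        ann = cl.annotate_clusters(norm, labels)
        pred = [ann[int(c)] for c in labels]
        want = truth.loc[list(mat.cell_ids), "cell_type"].to_numpy()
        assert adjusted_rand_score(want, pred) >= 0.8
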