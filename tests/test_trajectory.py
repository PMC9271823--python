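import numpy as np
import pandas as pd
import pytest
import scipy.stats

from cardimap.trajectory import (assign_trajectory_phases,
                                 filter_trajectory_genes, fit_trajectory,
                                 natural_spline_basis, select_ordering_genes,
                                 subpopulation_density)
from cardimap.trajectory import test_pseudotime_dependence as pt_dependence
from conftest import make_matrix, make_meta
from test_embed import make_norm


class TestFilterTrajectoryGenes:
    def test_detection_thresholds(self):
        counts = np.zeros((3, 1000), dtype=int)
        counts[0, :9] = 1    # 9 cells < 10 -> excluded
        counts[1, :49] = 1   # 49 cells = 4.9% -> excluded
        counts[2, :50] = 1   # 50 cells = 5.0% -> included
        genes = filter_trajectory_genes(make_matrix(counts))
        assert genes == ["G2"]

    def test_thresholds_coincide_at_hundred_cells(self):
        counts = np.zeros((2, 100), dtype=int)
        counts[0, :10] = 1
        counts[1, :9] = 1
        assert filter_trajectory_genes(make_matrix(counts)) == ["G0"]

    def test_empty_result_raises(self):
        counts = np.zeros((2, 100), dtype=int)
        counts[0, 0] = 1
        with pytest.raises(ValueError):
            filter_trajectory_genes(make_matrix(counts))


class TestOrderingGenes:
    def test_constant_gene_not_selected(self):
        rng = np.random.default_rng(0)
        values = np.vstack([np.ones(60),
                            rng.normal(np.repeat([1, 3, 5], 20), 0.3).clip(0)])
        stages = np.repeat(["a", "b", "c"], 20)
        genes = select_ordering_genes(make_norm(values), stages)
        assert genes == ["G1"]

    def test_recovers_planted_dynamic_genes(self, default_sim):
        """>= 90% of planted early/late archetype genes are selected."""
        from cardimap.embed import lognormalize

        tc = default_sim["truth"].cell_table.set_index("cell_id")
        mat = default_sim["mat_h"]
        cms = tc.loc[list(mat.cell_ids)].query(
            "cell_type == 'CMs' and ~is_doublet").index
        sub = mat.subset_cells(np.isin(mat.cell_ids, cms))
        norm = lognormalize(sub)
        stages = default_sim["meta_h"].stages(sub.cell_ids).astype(str)
        genes = set(select_ordering_genes(norm, stages))
        gt = default_sim["truth"].gene_table.query(
            "species == 'human' and archetype in ('early', 'late')")
        assert gt["gene"].isin(genes).mean() >= 0.9

    def test_permuted_labels_control_false_discoveries(self, small_sim):
        from cardimap.embed import lognormalize

        norm = lognormalize(small_sim["mat_h"])
        n_sel = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            stages = rng.permutation(
                small_sim["meta_h"].stages(norm.cell_ids).astype(str).to_numpy())
            genes = select_ordering_genes(norm, stages, q_cut=0.01)
            n_sel.append(len(genes))
        assert max(n_sel) <= 0.01 * norm.n_genes * 2

    def test_small_stage_excluded_with_warning(self):
        rng = np.random.default_rng(1)
        values = rng.uniform(0, 2, size=(5, 23))
        stages = np.array(["a"] * 10 + ["b"] * 11 + ["tiny"] * 2)
        with pytest.warns(UserWarning, match="tiny"):
            select_ordering_genes(make_norm(values), stages)


def line_fixture(n=120, noise=0.0, seed=0):
    """Cells along a 1-D expression gradient with stage labels."""
    rng = np.random.default_rng(seed)
    t = np.sort(rng.uniform(0, 1, n))
    genes = [f"G{i}" for i in range(6)]
    slopes = np.array([2.0, -1.5, 1.0, -0.5, 0.8, 1.2])
    values = 2 + slopes[:, None] * t + rng.normal(0, noise, (6, n))
    norm = make_norm(values)
    stages = np.where(t < 0.5, "early", "late")
    meta = make_meta(norm.cell_ids, stages, ["early", "late"])
    return norm, genes, meta, t


class TestFitTrajectory:
    def test_recovers_noiseless_gradient(self):
        norm, genes, meta, t = line_fixture()
        traj = fit_trajectory(norm, genes, meta, n_nodes=10, d=2, seed=0)
        rho = scipy.stats.spearmanr(traj.pseudotime, t).statistic
        assert abs(rho) >= 0.99
        # rooted at the earliest stage, so early cells have small pseudotime
        assert rho > 0

    def test_stage_means_ordered_along_pseudotime(self):
        norm, genes, meta, t = line_fixture(noise=0.1, seed=1)
        traj = fit_trajectory(norm, genes, meta, n_nodes=8, d=2, seed=1)
        early = traj.pseudotime[t < 0.5].mean()
        late = traj.pseudotime[t >= 0.5].mean()
        assert early < late

    def test_pseudotime_invariant_to_cell_order(self):
        norm, genes, meta, t = line_fixture(noise=0.05, seed=2)
        traj = fit_trajectory(norm, genes, meta, n_nodes=8, d=2, seed=2)
        perm = np.random.default_rng(0).permutation(norm.n_cells)
        norm_p = norm.subset_cells(perm)
        meta_p = meta.aligned_to(norm_p.cell_ids)
        traj_p = fit_trajectory(norm_p, genes, meta_p, n_nodes=8, d=2, seed=2)
        rho = scipy.stats.spearmanr(traj.pseudotime[perm],
                                    traj_p.pseudotime).statistic
        assert abs(rho) >= 0.99

    def test_pseudotime_in_unit_interval_and_tree_connected(self):
        norm, genes, meta, _ = line_fixture(noise=0.2, seed=3)
        traj = fit_trajectory(norm, genes, meta, n_nodes=12, d=2, seed=3)
        assert traj.pseudotime.min() == 0.0
        assert traj.pseudotime.max() == 1.0
        assert len(traj.edges) == len(traj.centroids) - 1  # spanning tree

    def test_too_many_nodes_rejected(self):
        norm, genes, meta, _ = line_fixture(n=10)
        with pytest.raises(ValueError):
            fit_trajectory(norm, genes, meta, n_nodes=11, d=2, seed=0)


def nb_counts(mu, disp, rng):
    return rng.poisson(rng.gamma(1.0 / disp, mu * disp))


class TestPseudotimeDependence:
    def test_constant_zero_gene_flagged(self):
        rng = np.random.default_rng(0)
        counts = np.vstack([np.zeros(50, dtype=int),
                            rng.poisson(5, 50)])
        res = pt_dependence(make_matrix(counts),
                                         rng.uniform(0, 1, 50))
        rec = res.set_index("gene").loc["G0"]
        assert rec["p_value"] == 1.0 and not rec["converged"]

    def test_lrt_statistic_nonnegative(self):
        rng = np.random.default_rng(1)
        counts = nb_counts(np.full((30, 80), 3.0), 0.3, rng)
        res = pt_dependence(make_matrix(counts),
                                         rng.uniform(0, 1, 80))
        assert (res["lrt_stat"] >= 0).all()
        assert (res["q_value"] >= res["p_value"] - 1e-12).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_planted_late_gene_detected(self, seed):
        """A maturation-driven gene reaches q < 0.01 at n = 400 cells."""
        rng = np.random.default_rng(100 + seed)
        n = 400
        pt = rng.uniform(0, 1, n)
        lib = np.exp(rng.normal(0, 0.3, n))
        mu_null = np.outer(np.exp(rng.normal(0, 1, 40)) * 4, lib)
        mu_late = 2.0 * np.exp(2.0 / (1 + np.exp(-6 * (pt - 0.5)))) * lib
        mu = np.vstack([mu_late, mu_null])
        counts = nb_counts(mu, 0.3, rng)
        res = pt_dependence(make_matrix(counts), pt)
        assert res.set_index("gene").loc["G0", "q_value"] < 0.01

    def test_spline_basis_shape_and_knots(self):
        x = np.linspace(0, 1, 50)
        basis, knots = natural_spline_basis(x, df=3)
        assert basis.shape == (50, 3)
        assert len(knots) == 4
        # linear tails: second differences vanish outside the boundary knots
        xs = np.array([-1.0, -0.9, -0.8])
        b, _ = natural_spline_basis(xs, df=3, knots=knots)
        d2 = b[2] - 2 * b[1] + b[0]
        np.testing.assert_allclose(d2, 0.0, atol=1e-9)


class TestPhases:
    def test_symmetric_bump_is_transitional(self):
        rng = np.random.default_rng(0)
        pt = rng.uniform(0, 1, 300)
        bump = np.exp(-((pt - 0.5) ** 2) / 0.02)
        values = np.vstack([bump, 1 - pt, pt]) + \
            np.abs(rng.normal(0, 0.01, (3, 300)))
        norm = make_norm(values)
        phases = assign_trajectory_phases(norm, pt, ["G0", "G1", "G2"])
        assert phases["G0"] == "transitional"
        assert phases["G1"] == "initial"
        assert phases["G2"] == "terminal"

    def test_partition_covers_all_significant_genes(self):
        rng = np.random.default_rng(1)
        pt = rng.uniform(0, 1, 100)
        values = rng.uniform(0, 2, (8, 100))
        genes = [f"G{i}" for i in range(8)]
        phases = assign_trajectory_phases(make_norm(values), pt, genes)
        assert len(phases) == 8
        assert set(phases) <= {"initial", "transitional", "terminal"}

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ValueError):
            assign_trajectory_phases(make_norm(np.ones((2, 5))),
                                     np.linspace(0, 1, 5), [])


class TestSubpopulationDensity:
    def test_point_mass_peaks_at_location(self):
        pt = np.full(20, 0.5)
        dens = subpopulation_density(pt, ["s"] * 20)
        assert dens["s"].idxmax() == pytest.approx(0.5, abs=0.01)

    def test_curves_integrate_to_one(self):
        rng = np.random.default_rng(0)
        pt = rng.uniform(0, 1, 200)
        labels = rng.choice(["a", "b", "c"], 200)
        dens = subpopulation_density(pt, labels)
        for c in dens.columns:
            integral = np.trapezoid(dens[c], dens.index)
            assert integral == pytest.approx(1.0, abs=0.01)

    def test_early_subpop_peaks_before_late_subpop(self):
        rng = np.random.default_rng(1)
        early = rng.beta(2, 8, 100)
        late = rng.beta(8, 2, 100)
        pt = np.concatenate([early, late])
        labels = ["early"] * 100 + ["late"] * 100
        dens = subpopulation_density(pt, labels)
        assert dens["early"].idxmax() < dens["late"].idxmax()

    def test_singleton_subpop_uses_floor_bandwidth(self):
        dens = subpopulation_density(np.array([0.3, 0.9]), ["solo", "other"])
        assert np.isfinite(dens["solo"]).all()
        assert dens["solo"].idxmax() == pytest.approx(0.3, abs=0.01)
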