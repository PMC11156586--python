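"""Projection onto single cells, external cohorts and developmental data."""
import numpy as np
import pandas as pd
import pytest

from ctxprog import (
    consistency_by_age_window,
    coupling_correlation,
    decile_curves,
    dme,
    external_consistency,
    fit_trajectories,
    generate_development,
    generate_single_cells,
    preprocess_cohort,
    score_cells,
)


@pytest.fixture(scope="module")
def weighted_world(clean_cohort):
    donors, truth = clean_cohort
    comps = ["C1", "C2", "C3"]
    weights = pd.DataFrame(
        truth.loadings / np.abs(truth.loadings).max(),  # scale into [-1, 1]
        index=list(truth.gene_ids), columns=comps,
    )
    return truth, weights


class TestScoreCells:
    def test_single_gene_positive_set(self, weighted_world):
        truth, _ = weighted_world
        genes = list(truth.gene_ids)[:60]
        cells = pd.DataFrame(
            np.random.default_rng(0).random((5, 60)), columns=genes
        )
        w = pd.DataFrame(0.0, index=genes, columns=["C1"])
        w.iloc[0, 0] = 1.0
        w.iloc[1, 0] = -0.4
        sc = score_cells(cells, w, min_shared_genes=10)
        np.testing.assert_allclose(sc.scores["C1+"], cells.iloc[:, 0])
        np.testing.assert_allclose(sc.scores["C1-"], cells.iloc[:, 1])

    def test_zero_expression_cell_scores_zero(self, weighted_world):
        truth, weights = weighted_world
        cells = pd.DataFrame(
            np.zeros((3, len(truth.gene_ids))), columns=list(truth.gene_ids)
        )
        sc = score_cells(cells, weights)
        assert (sc.scores.to_numpy() == 0).all()

    def test_hand_weighted_average(self):
        genes = [f"g{i}" for i in range(60)]
        cells = pd.DataFrame([np.r_[[1.0, 2.0, 3.0], np.zeros(57)]], columns=genes)
        w = pd.DataFrame(0.0, index=genes, columns=["C1"])
        w.loc["g0", "C1"] = 0.5
        w.loc["g1", "C1"] = 0.5
        w.loc["g3", "C1"] = -0.5
        sc = score_cells(cells, w, min_shared_genes=10)
        assert sc.scores["C1+"].iloc[0] == pytest.approx(1.5)

    def test_linearity(self, weighted_world):
        truth, weights = weighted_world
        rng = np.random.default_rng(1)
        a = pd.DataFrame(rng.random((4, len(truth.gene_ids))), columns=list(truth.gene_ids))
        b = pd.DataFrame(rng.random((4, len(truth.gene_ids))), columns=list(truth.gene_ids))
        sa = score_cells(a, weights).scores
        sb = score_cells(b, weights).scores
        sab = score_cells(a + b, weights).scores
        np.testing.assert_allclose(sab.to_numpy(), (sa + sb).to_numpy(), atol=1e-10)

    def test_empty_negative_set_rejected(self):
        genes = [f"g{i}" for i in range(60)]
        cells = pd.DataFrame(np.ones((2, 60)), columns=genes)
        w = pd.DataFrame(0.1, index=genes, columns=["C1"])  # all positive
        with pytest.raises(ValueError):
            score_cells(cells, w, min_shared_genes=10)


class TestCoupling:
    def test_latent_coupling_detected_within_types(self, weighted_world):
        truth, weights = weighted_world
        cells, types = generate_single_cells(
            truth, 1200, {"neuron": 0.5, "glia": 0.5}, seed=2
        )
        sc = score_cells(cells, weights, cell_types=types)
        table = coupling_correlation(sc, n_boot=100, seed=3)
        assert (table["r"] <= -0.5).all()
        assert (table["ci_high"] < 0).all()

    def test_independent_genes_uncorrelated(self, weighted_world):
        truth, weights = weighted_world
        cells, types = generate_single_cells(
            truth, 1000, {"a": 1.0}, seed=4, coupling_sd=0.0
        )
        sc = score_cells(cells, weights, cell_types=types)
        table = coupling_correlation(sc, n_boot=50, seed=5)
        assert (table["r"].abs() < 0.1).all()

    def test_tiny_group_skipped(self, weighted_world):
        truth, weights = weighted_world
        cells, _ = generate_single_cells(truth, 10, {"a": 1.0}, seed=6)
        types = pd.Series(["a"] * 8 + ["b"] * 2, index=cells.index)
        sc = score_cells(cells, weights, cell_types=types)
        with pytest.warns(UserWarning):
            table = coupling_correlation(sc, n_boot=20, seed=7)
        assert set(table["group"]) == {"a"}


class TestExternalConsistency:
    def test_self_consistency(self, clean_cohort):
        donors, _ = clean_cohort
        mat, _ = preprocess_cohort(donors, min_donors=3)
        comps = dme(mat, 3)
        r = external_consistency(mat.values, comps.weights, comps.scores)
        assert (r > 0.95).all()  # projection smooths slightly; near-identity

    def test_affine_invariance(self, clean_cohort):
        donors, _ = clean_cohort
        mat, _ = preprocess_cohort(donors, min_donors=3)
        comps = dme(mat, 3)
        rng = np.random.default_rng(8)
        scale = rng.uniform(0.5, 3, mat.values.shape[1])
        shift = rng.uniform(-5, 5, mat.values.shape[1])
        transformed = mat.values * scale + shift
        r0 = external_consistency(mat.values, comps.weights, comps.scores)
        r1 = external_consistency(transformed, comps.weights, comps.scores)
        np.testing.assert_allclose(r0, r1, atol=1e-10)

    def test_fetal_c3_suppressed(self, weighted_world):
        truth, weights = weighted_world
        ref = pd.DataFrame(
            truth.latent_scores, index=list(truth.parcel_ids),
            columns=["C1", "C2", "C3"],
        )
        ages_fetal = list(np.linspace(-0.5, -0.1, 8))
        ages_adult = list(np.linspace(20, 40, 8))
        dev = generate_development(truth, ages_fetal + ages_adult, seed=9)
        cons = consistency_by_age_window(
            dev, weights, ref, windows={"fetal": (-0.75, 0.0), "adult": (18.0, 40.0)}
        )
        assert abs(cons.loc["fetal", "C3"]) < 0.35
        assert cons.loc["fetal", "C1"] > 0.8
        assert (cons.loc["adult"] > 0.8).all()


class TestTrajectories:
    def _dev_table(self, rng, slope=1.0, n_donors=30, noise=0.1):
        ages = np.linspace(0.0, 40.0, n_donors)
        rows = []
        from ctxprog import years_to_log10_pcd

        for j, age in enumerate(ages):
            x = years_to_log10_pcd(age)
            for region in ["R1", "R2"]:
                rows.append(
                    {
                        "donor": f"B{j}", "age_years": age,
                        "sex": "F" if j % 2 else "M", "region": region,
                        "gene": "g1", "value": slope * x + rng.normal(0, noise),
                    }
                )
        return pd.DataFrame(rows)

    def test_linear_gene_recovered(self, rng):
        dev = self._dev_table(rng)
        fit = fit_trajectories(dev)["g1"]
        assert (np.diff(fit.curve) > -1e-3).all()  # monotone up to noise
        from ctxprog import years_to_log10_pcd

        truth_diff = years_to_log10_pcd(fit.age_grid_years[-1]) - years_to_log10_pcd(
            fit.age_grid_years[0]
        )
        got = fit.curve[-1] - fit.curve[0]
        assert got == pytest.approx(truth_diff, rel=0.1)

    def test_constant_gene_flat(self, rng):
        dev = self._dev_table(rng, slope=0.0, noise=0.05)
        fit = fit_trajectories(dev)["g1"]
        assert fit.curve.max() - fit.curve.min() < 0.15

    def test_degenerate_design_rejected(self, rng):
        dev = self._dev_table(rng)
        dev["age_years"] = 10.0
        with pytest.raises(ValueError):
            fit_trajectories(dev)

    def test_decile_binning(self):
        genes = [f"g{i:02d}" for i in range(50)]
        grid = np.linspace(1, 30, 10)
        from ctxprog import TrajectoryFit

        fits = {
            g: TrajectoryFit(g, grid, np.full(10, float(i)), 40)
            for i, g in enumerate(genes)
        }
        w = pd.Series(np.arange(50, dtype=float), index=genes)
        dc = decile_curves(fits, w)
        assert dc.shape == (10, 10)
        # decile d averages genes 5d-5..5d-1 -> constant curve at their mean
        np.testing.assert_allclose(dc[1], np.full(10, 2.0))
        np.testing.assert_allclose(dc[10], np.full(10, 47.0))

    def test_equal_weights_fall_back_to_id_order(self):
        genes = [f"g{i:02d}" for i in range(20)]
        grid = np.linspace(1, 30, 5)
        from ctxprog import TrajectoryFit

        fits = {g: TrajectoryFit(g, grid, np.ones(5), 40) for g in genes}
        w = pd.Series(1.0, index=genes)
        dc = decile_curves(fits, w)
        np.testing.assert_allclose(dc.to_numpy(), 1.0)
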