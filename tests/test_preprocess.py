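"""Filtering and normalization: SRS, DS, probe handling, donor aggregation."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctxprog import (
    DonorExpression,
    aggregate_probes_to_genes,
    assemble_group_matrix,
    differential_stability,
    filter_genes_by_ds,
    filter_probes_by_intensity,
    filter_regions_by_coverage,
    preprocess_cohort,
    srs_normalize,
)


def donor(donor_id, values, regions=None, genes=None, **kw):
    values = np.asarray(values, float)
    regions = regions or [f"R{i}" for i in range(values.shape[0])]
    genes = genes or [f"G{j}" for j in range(values.shape[1])]
    return DonorExpression(donor_id, pd.DataFrame(values, index=regions, columns=genes), **kw)


class TestSRS:
    def test_hand_values(self):
        np.testing.assert_allclose(srs_normalize(np.array([2.0, 2, 2])), [0.5, 0.5, 0.5])
        np.testing.assert_allclose(srs_normalize(np.array([0.0, 1, 2])), [0, 0.5, 1])

    def test_rank_order_preserved(self):
        out = srs_normalize(np.array([5.0, -1.0, 3.0]))
        assert out[1] < out[2] < out[0]

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            srs_normalize(np.array([1.0]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(-50, 50), min_size=4, max_size=30, unique=True),
        st.floats(0.1, 10),
        st.floats(-5, 5),
    )
    def test_positive_affine_invariance(self, xs, a, b):
        x = np.array(xs)
        np.testing.assert_allclose(
            srs_normalize(a * x + b), srs_normalize(x), atol=1e-7
        )


class TestIntensityFilter:
    def _probe_donors(self):
        # 10 pooled samples across two donors; probe p1 above background in
        # 6/10, p2 in 4/10
        vals = np.ones((5, 2))
        bg1 = pd.DataFrame({"p1": [1, 1, 1, 0, 0], "p2": [1, 1, 0, 0, 0]}, dtype=bool)
        bg2 = pd.DataFrame({"p1": [1, 1, 1, 0, 0], "p2": [1, 1, 0, 0, 0]}, dtype=bool)
        pg = pd.Series(["G0", "G1"], index=["p1", "p2"])
        mk = lambda i, bg: DonorExpression(
            f"D{i}",
            pd.DataFrame(vals, index=[f"R{r}" for r in range(5)], columns=["p1", "p2"]),
            level="probe", probe_gene=pg,
            background=bg.set_axis([f"R{r}" for r in range(5)]),
        )
        return [mk(1, bg1), mk(2, bg2)]

    def test_threshold_half(self):
        kept = filter_probes_by_intensity(self._probe_donors(), 0.5)
        assert list(kept[0].values.columns) == ["p1"]

    def test_threshold_zero_keeps_all(self):
        kept = filter_probes_by_intensity(self._probe_donors(), 0.0)
        assert list(kept[0].values.columns) == ["p1", "p2"]

    def test_no_survivors_is_error(self):
        with pytest.raises(ValueError):
            filter_probes_by_intensity(self._probe_donors(), 0.99)


class TestProbeAggregation:
    def _donors(self, noise1=0.0, noise2=3.0, seed=0):
        rng = np.random.default_rng(seed)
        base = np.linspace(0, 1, 8)
        pg = pd.Series(["G0", "G0", "G1"], index=["pa", "pb", "pc"])
        out = []
        for i in range(2):
            vals = pd.DataFrame(
                {
                    "pa": base + rng.normal(0, noise1, 8),
                    "pb": rng.normal(0, noise2, 8),
                    "pc": base * 2,
                },
                index=[f"R{r}" for r in range(8)],
            )
            out.append(DonorExpression(f"D{i}", vals, level="probe", probe_gene=pg))
        return out

    def test_best_probe_selected(self):
        agg = aggregate_probes_to_genes(self._donors())
        # pa tracks the shared spatial profile across donors; pb is noise
        np.testing.assert_allclose(agg[0].values["G0"], np.linspace(0, 1, 8))

    def test_single_probe_passthrough(self):
        agg = aggregate_probes_to_genes(self._donors())
        np.testing.assert_allclose(agg[0].values["G1"], np.linspace(0, 2, 8))

    def test_tie_breaks_to_lowest_probe_id(self):
        # identical probes -> identical mean correlation -> lowest id wins
        base = np.linspace(0, 1, 8)
        pg = pd.Series(["G0", "G0"], index=["p2", "p1"])
        donors = [
            DonorExpression(
                f"D{i}",
                pd.DataFrame({"p2": base + 1, "p1": base}, index=[f"R{r}" for r in range(8)]),
                level="probe", probe_gene=pg,
            )
            for i in range(2)
        ]
        agg = aggregate_probes_to_genes(donors)
        np.testing.assert_allclose(agg[0].values["G0"], base)  # p1 chosen


class TestDifferentialStability:
    def test_identical_profiles_give_one(self):
        x = np.random.default_rng(1).random((6, 4))
        ds = differential_stability([donor("a", x), donor("b", x), donor("c", x)])
        np.testing.assert_allclose(ds.ds.to_numpy(), 1.0, atol=1e-12)

    def test_anticorrelated_pair_gives_minus_one(self):
        x = np.random.default_rng(2).random((6, 3))
        xc = x - x.mean(axis=0)
        ds = differential_stability([donor("a", xc), donor("b", -xc)])
        np.testing.assert_allclose(ds.ds.to_numpy(), -1.0, atol=1e-12)

    def test_three_donor_hand_mean(self):
        # construct pairwise r = (1, 0, 0) for one gene: a==b, c orthogonal
        a = np.array([1.0, 2, 3, 4])
        c = np.array([1.0, -1, -1, 1])  # orthogonal to centered a -> r(a,c)=0
        mk = lambda did, v: donor(did, v[:, None], genes=["G0"])
        ds = differential_stability([mk("a", a), mk("b", a), mk("c", c)])
        assert ds.ds["G0"] == pytest.approx(1 / 3)

    def test_constant_gene_pair_excluded_with_warning(self):
        a = np.column_stack([np.arange(4.0), np.ones(4)])
        b = np.column_stack([np.arange(4.0), np.arange(4.0)])
        with pytest.warns(UserWarning):
            ds = differential_stability([donor("a", a), donor("b", b)])
        assert np.isnan(ds.ds.iloc[1])

    def test_noise_free_cohort_ds_one_and_noise_monotonicity(self, atlas60):
        from scipy.stats import spearmanr

        from ctxprog import CohortConfig, generate_cohort

        cfg = CohortConfig(noise_sd=0.0, missing_frac=0.0, frac_noisy_genes=0.0)
        donors, _ = generate_cohort(atlas60, 3, 60, cfg, seed=3)
        ds0 = differential_stability(donors)
        assert np.allclose(ds0.ds, 1.0, atol=1e-9)
        # per-gene noise sd increasing across genes -> DS decreasing (Spearman)
        rng = np.random.default_rng(4)
        sds = np.geomspace(0.05, 5, 60)  # below signal scale so DS stays graded
        noisy = [
            DonorExpression(
                d.donor_id, d.values + rng.standard_normal(d.values.shape) * sds
            )
            for d in donors
        ]
        ds1 = differential_stability(noisy)
        rho = spearmanr(sds, ds1.ds.to_numpy()).statistic
        assert rho < -0.8


class TestGeneAndRegionFilters:
    def test_ds_filter_examples(self):
        from ctxprog import DifferentialStability

        ds = DifferentialStability(pd.Series([0.9, 0.5, 0.1, -0.2], index=list("abcd")))
        assert filter_genes_by_ds(ds, 0.5) == ["a", "b"]
        assert filter_genes_by_ds(ds, 1.0) == ["a", "b", "c", "d"]
        tied = DifferentialStability(pd.Series([0.5, 0.5, 0.1, -0.2], index=list("dabc")))
        assert filter_genes_by_ds(tied, 0.5) == ["a", "d"]  # tie -> id ascending

    def test_region_coverage(self):
        d1 = donor("a", np.ones((3, 2)), regions=["R1", "R2", "R3"])
        d2 = donor("b", np.ones((2, 2)), regions=["R1", "R2"])
        d3 = donor("c", np.ones((1, 2)), regions=["R1"])
        assert filter_regions_by_coverage([d1, d2, d3], 3) == ["R1"]
        assert filter_regions_by_coverage([d1, d2, d3], 2) == ["R1", "R2"]
        assert filter_regions_by_coverage([d1, d2, d3], 1) == ["R1", "R2", "R3"]
        with pytest.raises(ValueError):
            filter_regions_by_coverage([d1, d2, d3], 4)


class TestAssemble:
    def test_single_donor_is_its_normalized_matrix(self):
        rng = np.random.default_rng(5)
        d = donor("a", rng.random((6, 4)))
        out = assemble_group_matrix([d])
        from ctxprog.preprocess import _srs_frame

        pd.testing.assert_frame_equal(out.values, _srs_frame(d.values))

    def test_missing_region_row_taken_from_other_donor(self):
        rng = np.random.default_rng(6)
        full = donor("a", rng.random((6, 4)))
        partial = donor("b", rng.random((5, 4)), regions=[f"R{i}" for i in range(5)])
        out = assemble_group_matrix([full, partial], regions=[f"R{i}" for i in range(6)])
        from ctxprog.preprocess import _srs_frame

        np.testing.assert_allclose(
            out.values.loc["R5"], _srs_frame(full.values).loc["R5"]
        )

    def test_uncovered_region_is_error(self):
        d = donor("a", np.random.default_rng(7).random((4, 3)))
        with pytest.raises(ValueError):
            assemble_group_matrix([d], regions=["R0", "R1", "R9"])

    def test_full_chain_deterministic_and_shaped(self, clean_cohort):
        donors, _ = clean_cohort
        m1, ds1 = preprocess_cohort(donors, ds_fraction=0.5, min_donors=3)
        m2, _ = preprocess_cohort(donors, ds_fraction=0.5, min_donors=3)
        pd.testing.assert_frame_equal(m1.values, m2.values)
        assert m1.values.shape[1] == 150  # ceil(0.5 * 300)
        assert not m1.values.isna().any().any()
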