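import itertools

import numpy as np
import pandas as pd
import pytest

from dietnet import ggm, scoring, synthetic


class TestPlantedStructure:
    def test_overlapping_blocks_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            synthetic.PlantedStructure(10, [[0, 1, 2], [2, 3]], [0.2, 0.2])

    def test_out_of_range_block_rejected(self):
        with pytest.raises(ValueError, match="range"):
            synthetic.PlantedStructure(3, [[0, 5]], [0.2])

    def test_partial_magnitude_bounds(self):
        with pytest.raises(ValueError, match="inside"):
            synthetic.PlantedStructure(4, [[0, 1]], [1.0])

    def test_default_structure_six_blocks_three_networks(self):
        st = synthetic.default_structure()
        assert len(st.blocks) == 6
        assert sum(len(b) for b in st.blocks) == 30
        nets = synthetic.planted_network_nodes(st)
        assert len(nets) == 3
        assert all(len(n) == 10 for n in nets)


class TestBuildPlantedPrecision:
    def test_single_pair_partial_exact(self):
        st = synthetic.PlantedStructure(2, [[0, 1]], [0.3])
        planted = synthetic.build_planted_precision(st)
        net = ggm.precision_to_partial(planted.omega)
        assert net.rho[0, 1] == pytest.approx(0.3, abs=1e-9)

    def test_empty_blocks_identity(self):
        st = synthetic.PlantedStructure(4, [], [])
        planted = synthetic.build_planted_precision(st)
        np.testing.assert_allclose(planted.omega, np.eye(4))
        np.testing.assert_allclose(planted.achieved_partial, np.eye(4))

    def test_feasible_blocks_achieve_planted_partials(self):
        """Three blocks below the clique feasibility bound: no loading needed."""
        st = synthetic.PlantedStructure(
            35,
            [list(range(5)), list(range(5, 10)), list(range(10, 15))],
            [0.2, 0.15, 0.1],
        )
        planted = synthetic.build_planted_precision(st)
        np.linalg.cholesky(planted.omega)  # positive definite
        assert planted.diagonal_loading == 0.0
        for block, rho in zip(st.blocks, st.within_block_partial):
            for i, j in itertools.combinations(block, 2):
                assert planted.achieved_partial[i, j] == pytest.approx(rho, abs=1e-6)

    def test_loading_applied_when_infeasible_and_reported(self):
        # 5-clique at partial 0.3 exceeds the 1/(k-1) bound; loading must kick in
        st = synthetic.PlantedStructure(6, [list(range(5))], [0.3])
        planted = synthetic.build_planted_precision(st)
        np.linalg.cholesky(planted.omega)
        assert planted.diagonal_loading > 0
        assert planted.achieved_partial[0, 1] < 0.3

    def test_infeasible_structure_errors(self):
        st = synthetic.PlantedStructure(12, [list(range(12))], [0.95])
        with pytest.raises(synthetic.StructureInfeasibleError):
            synthetic.build_planted_precision(st, max_loading=1.0)


class TestSimulateIntakeTable:
    def test_deterministic_under_seed(self):
        st = synthetic.PlantedStructure(5, [[0, 1]], [0.2])
        planted = synthetic.build_planted_precision(st)
        t1 = synthetic.simulate_intake_table(planted, 100, seed=7)
        t2 = synthetic.simulate_intake_table(planted, 100, seed=7)
        pd.testing.assert_frame_equal(t1, t2)

    def test_identity_precision_near_zero_correlations(self):
        big = synthetic.simulate_intake_table(np.eye(6), 100000, seed=1)
        s = ggm.sample_correlation(big)
        off = s[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 0.02

    def test_sample_precision_recovers_planted_partial(self):
        st = synthetic.PlantedStructure(6, [[0, 1]], [0.3])
        planted = synthetic.build_planted_precision(st)
        x = synthetic.simulate_intake_table(planted, 100000, seed=2)
        omega_hat = np.linalg.inv(np.cov(x.to_numpy(), rowvar=False))
        rho_hat = ggm.precision_to_partial(omega_hat).rho
        assert rho_hat[0, 1] == pytest.approx(0.30, abs=0.02)

    def test_exponential_shift_nonnegative_and_rank_preserving(self):
        st = synthetic.PlantedStructure(4, [[0, 1]], [0.2])
        planted = synthetic.build_planted_precision(st)
        lat = synthetic.simulate_intake_table(planted, 500, seed=3)
        pos = synthetic.simulate_intake_table(
            planted, 500, seed=3, marginal_transform="exponential-shift"
        )
        assert (pos.to_numpy() > 0).all()
        for c in lat.columns:
            assert (lat[c].rank() == pos[c].rank()).all()

    def test_non_positive_definite_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            synthetic.simulate_intake_table(np.array([[1.0, 2.0], [2.0, 1.0]]), 10)

    def test_roundtrip_planted_partials_recovered(self):
        """Generator -> sample covariance inverse recovers every planted pair."""
        st = synthetic.PlantedStructure(
            12, [[0, 1, 2], [3, 4, 5, 6]], [0.25, 0.2], bridges=[(2, 3, 0.15)]
        )
        planted = synthetic.build_planted_precision(st)
        x = synthetic.simulate_intake_table(planted, 50000, seed=4)
        omega_hat = np.linalg.inv(np.cov(x.to_numpy(), rowvar=False))
        rho_hat = ggm.precision_to_partial(omega_hat).rho
        for block, rho in zip(st.blocks, st.within_block_partial):
            for i, j in itertools.combinations(block, 2):
                assert rho_hat[i, j] == pytest.approx(rho, abs=0.03)
        assert rho_hat[2, 3] == pytest.approx(0.15, abs=0.03)


class TestSimulateCovariates:
    def test_sex_proportion_matches_configured_probability(self):
        cov = synthetic.simulate_covariates(10000, seed=5)
        assert (cov["sex"] == "woman").mean() == pytest.approx(0.69, abs=0.02)

    def test_empty_table_has_full_header(self):
        cov = synthetic.simulate_covariates(0, seed=0)
        assert len(cov) == 0
        assert set(synthetic.REQUIRED_COVARIATES) <= set(cov.columns)

    def test_men_get_not_applicable_menopause(self):
        cov = synthetic.simulate_covariates(2000, seed=6)
        men = cov[cov["sex"] == "man"]
        assert (men["menopause"] == synthetic.MENOPAUSE_NOT_APPLICABLE).all()
        women = cov[cov["sex"] == "woman"]
        assert set(women["menopause"]) <= {"pre", "post"}
        assert not cov["menopause"].isna().any()

    def test_missing_required_field_named(self):
        spec = synthetic.default_covariate_spec()
        del spec["energy"]
        with pytest.raises(ValueError, match="energy"):
            synthetic.simulate_covariates(10, spec)

    def test_deterministic_under_seed(self):
        a = synthetic.simulate_covariates(50, seed=9)
        b = synthetic.simulate_covariates(50, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestSimulateOutcomes:
    def make_tertiles(self, n, seed=0):
        rng = np.random.default_rng(seed)
        scores = pd.Series(
            rng.standard_normal(n),
            name="net_score",
            index=pd.Index([f"S{i}" for i in range(n)], name="subject_id"),
        )
        return pd.DataFrame({"net_tertile": scoring.assign_tertiles(scores)})

    def test_null_model_half_prevalence(self):
        terts = self.make_tertiles(100000)
        out = synthetic.simulate_outcomes(terts, {"y": {"intercept": 0.0}}, seed=1)
        assert out["y"].mean() == pytest.approx(0.5, abs=0.01)

    def test_saturated_negative_intercept_all_zero(self):
        terts = self.make_tertiles(1000)
        out = synthetic.simulate_outcomes(terts, {"y": {"intercept": -30.0}}, seed=2)
        assert out["y"].sum() == 0

    def test_crude_cross_product_recovers_or(self):
        terts = self.make_tertiles(100000, seed=3)
        model = {"y": {"intercept": -1.0, "log_or": {("net", "T3"): float(np.log(1.5))}}}
        out = synthetic.simulate_outcomes(terts, model, seed=4)
        t = terts["net_tertile"]
        a = ((out["y"] == 1) & (t == "T3")).sum()
        b = ((out["y"] == 0) & (t == "T3")).sum()
        c = ((out["y"] == 1) & (t == "T1")).sum()
        d = ((out["y"] == 0) & (t == "T1")).sum()
        assert 1.4 < (a * d) / (b * c) < 1.6

    def test_missing_tertile_column_is_sequencing_error(self):
        terts = self.make_tertiles(100)
        model = {"y": {"intercept": 0.0, "log_or": {("other", "T3"): 0.4}}}
        with pytest.raises(ValueError, match="assign tertiles"):
            synthetic.simulate_outcomes(terts, model)
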