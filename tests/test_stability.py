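"""Rank-order, mean-level, profile-stability and dropout analyses."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from diffstab import stability, synth


class TestBayesianCorrelation:
    def test_perfect_linear_relation(self):
        x = np.linspace(0, 1, 50)
        res = stability.bayesian_correlation(x, 2 * x + 1)
        assert res.mean > 0.97
        assert res.bf10 > 1e6
        assert res.bf_string() == ">999"

    def test_strong_correlation_large_n_gives_huge_bf(self):
        rng = np.random.default_rng(0)
        n, rho = 334, 0.79
        x = rng.standard_normal(n)
        y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        res = stability.bayesian_correlation(x, y)
        assert res.bf10 > 999
        assert res.ci_low < rho < res.ci_high

    def test_null_data_favours_null(self):
        rng = np.random.default_rng(1)
        below_one = 0
        means = []
        for _ in range(15):
            x = rng.standard_normal(300)
            y = rng.standard_normal(300)
            res = stability.bayesian_correlation(x, y)
            below_one += res.bf10 < 1
            means.append(res.mean)
        assert below_one > 7  # majority of replicates
        assert np.all(np.abs(means) < 0.15)

    def test_posterior_mean_tracks_sample_r(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(200)
        y = 0.5 * x + np.sqrt(0.75) * rng.standard_normal(200)
        r = np.corrcoef(x, y)[0, 1]
        res = stability.bayesian_correlation(x, y)
        assert res.mean == pytest.approx(r, abs=0.02)

    def test_posterior_integrates_to_one_against_quadrature_oracle(self):
        # independent oracle: scipy quadrature of the same kernel
        from scipy.integrate import quad
        r, n = 0.6, 50
        kern = lambda rho: (1 - rho**2) ** ((n - 1) / 2) * (1 - rho * r) ** (-(n - 1.5))
        norm, _ = quad(kern, -1, 1)
        grid = np.linspace(-1 + 1e-9, 1 - 1e-9, 8001)
        post = stability._rho_posterior(r, n, grid)
        scale = np.trapezoid(post, grid)
        np.testing.assert_allclose(
            post / scale, np.array([kern(g) for g in grid]) / norm, rtol=1e-6
        )

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(stability.AnalysisError):
            stability.bayesian_correlation([1, 2], [2, 3])
        with pytest.raises(stability.AnalysisError):
            stability.bayesian_correlation([1, 1, 1, 1], [1, 2, 3, 4])


class TestRankOrder:
    def test_identical_columns_give_rho_near_one(self, medians_table):
        med = medians_table.copy()
        w0 = med[med.wave == 0].set_index("participant_id")["nu"]
        for w in (1, 2, 3):
            idx = med.wave == w
            med.loc[idx, "nu"] = med.loc[idx, "participant_id"].map(w0).to_numpy()
        mat = stability.rank_order_matrix(med, "nu")
        complete = mat.dropna(subset=["rho"])
        assert (complete["rho"] > 0.99).all()

    def test_true_values_match_variance_component_formula(self):
        cfg = synth.CohortConfig(
            subgroup_sizes=(10_000,), subgroup_ages=("young",),
            retention=(10_000,) * 4,
        )
        traj = synth.draw_person_trajectories(cohort=cfg, seed=3)
        med = traj.values[["participant_id", "wave", "nu", "a", "tau"]].copy()
        med["subgroup"] = 1
        mat = stability.rank_order_matrix(med, "nu").set_index(["wave_i", "wave_j"])
        model = synth.default_parameter_models()["nu"]
        for i, j in stability.TIME_PAIRS:
            expected = model.true_correlation(i, j)
            se = (1 - expected**2) / np.sqrt(10_000)
            assert abs(mat.loc[(i, j), "rho"] - expected) < 3 * se

    def test_small_subgroup_flagged_not_dropped(self, medians_table):
        mat = stability.rank_order_matrix(medians_table, "nu", subgroup=3)
        complete = mat.dropna(subset=["rho"])
        assert complete["small_n_flag"].all()
        assert len(complete) == 6

    def test_insufficient_pairs_logged_as_missing(self, medians_table):
        med = medians_table.copy()
        med.loc[med.wave == 3, "nu"] = np.nan
        mat = stability.rank_order_matrix(med, "nu").set_index(["wave_i", "wave_j"])
        assert np.isnan(mat.loc[(0, 3), "rho"])
        assert not np.isnan(mat.loc[(0, 1), "rho"])


class TestHdi:
    def test_standard_normal_interval(self):
        rng = np.random.default_rng(4)
        lo, hi = stability.hdi(rng.standard_normal(1_000_000))
        assert lo == pytest.approx(-1.96, abs=0.02)
        assert hi == pytest.approx(1.96, abs=0.02)

    def test_symmetric_sample_matches_central_interval(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(200_000)
        lo, hi = stability.hdi(x)
        clo, chi = np.quantile(x, [0.025, 0.975])
        assert lo == pytest.approx(clo, abs=0.03)
        assert hi == pytest.approx(chi, abs=0.03)

    def test_constant_sample_zero_width(self):
        lo, hi = stability.hdi(np.full(500, 2.5))
        assert lo == hi == 2.5

    def test_too_few_samples_rejected(self):
        with pytest.raises(stability.AnalysisError):
            stability.hdi(np.arange(50))


class TestMeanLevel:
    def test_identical_draws_fully_overlap(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(5000)
        rep = stability.mean_level_comparison({0: x, 1: x.copy()})
        assert rep["overlap"].all()

    def test_distant_draws_disjoint(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(5000)
        rep = stability.mean_level_comparison({0: x, 1: x + 10.0})
        assert not rep["overlap"].any()
        assert rep["mean_diff"].item() == pytest.approx(10.0, abs=0.1)


class TestProfiles:
    def test_zscores_have_zero_mean_unit_sd(self, medians_table):
        z = stability.standardize_profiles(medians_table)
        for p in stability.PARAMS:
            for w, sub in z.groupby("wave"):
                col = sub[p].dropna()
                assert abs(col.mean()) < 1e-12
                assert col.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_location_shift_leaves_zscores_unchanged(self, medians_table):
        z1 = stability.standardize_profiles(medians_table)
        shifted = medians_table.copy()
        shifted.loc[shifted.wave == 0, "nu"] += 5.0
        z2 = stability.standardize_profiles(shifted)
        pd.testing.assert_series_equal(z1["nu"], z2["nu"])

    def test_upper_percentile_person_gets_z_two(self):
        n = 10_000
        med = pd.DataFrame({
            "participant_id": np.arange(n), "wave": 0, "subgroup": 1,
            "nu": stats.norm.ppf((np.arange(n) + 0.5) / n),
            "a": 2.0 + 0.1 * np.random.default_rng(8).standard_normal(n),
            "tau": 0.4 + 0.05 * np.random.default_rng(9).standard_normal(n),
        })
        z = stability.standardize_profiles(med)
        person = int(round(0.977 * n))
        assert z.loc[person, "nu"] == pytest.approx(2.0, abs=0.02)

    def test_q_of_identical_profiles_is_one(self):
        z = pd.DataFrame({
            "participant_id": [0, 0], "wave": [0, 1],
            "nu": [1.0, 1.0], "a": [0.0, 0.0], "tau": [-1.0, -1.0],
        })
        q = stability.q_profile_correlations(z, 0, 1)
        assert q["q"].item() == pytest.approx(1.0)

    def test_q_of_reversed_profile_is_minus_one(self):
        z = pd.DataFrame({
            "participant_id": [0, 0], "wave": [0, 1],
            "nu": [1.0, -1.0], "a": [0.0, 0.0], "tau": [-1.0, 1.0],
        })
        q = stability.q_profile_correlations(z, 0, 1)
        assert q["q"].item() == pytest.approx(-1.0)

    def test_q_hand_computed_three_point_case(self):
        z = pd.DataFrame({
            "participant_id": [0, 0], "wave": [0, 1],
            "nu": [1.0, 0.8], "a": [-0.5, -0.7], "tau": [0.2, 0.1],
        })
        q = stability.q_profile_correlations(z, 0, 1)["q"].item()
        assert q == pytest.approx(0.9971, abs=5e-4)

    def test_q_invariant_to_common_rescaling(self):
        rng = np.random.default_rng(10)
        z = pd.DataFrame({
            "participant_id": [0, 0], "wave": [0, 1],
            "nu": rng.standard_normal(2), "a": rng.standard_normal(2),
            "tau": rng.standard_normal(2),
        })
        q1 = stability.q_profile_correlations(z, 0, 1)["q"].item()
        z2 = z.copy()
        z2[["nu", "a", "tau"]] *= 3.7
        q2 = stability.q_profile_correlations(z2, 0, 1)["q"].item()
        assert q1 == pytest.approx(q2, abs=1e-12)

    def test_zero_variance_profile_counted_missing(self):
        z = pd.DataFrame({
            "participant_id": [0, 0], "wave": [0, 1],
            "nu": [1.0, 1.0], "a": [1.0, 0.0], "tau": [1.0, -1.0],
        })
        q = stability.q_profile_correlations(z, 0, 1)
        assert np.isnan(q["q"].item())

    def test_summary_covers_all_six_pairs(self, medians_table):
        z = stability.standardize_profiles(medians_table)
        summ = stability.q_summary(z)
        assert len(summ) == 6
        assert (summ["n"] > 0).all()


class TestDropoutTTest:
    def test_null_favoured_under_equal_means(self):
        rng = np.random.default_rng(11)
        below = 0
        for _ in range(11):
            x = rng.standard_normal(150)
            y = rng.standard_normal(150)
            below += stability.dropout_bayes_t_test(x, y) < 1
        assert below > 5

    def test_large_effect_detected(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal(100) + 1.5
        y = rng.standard_normal(100)
        assert stability.dropout_bayes_t_test(x, y) > 100

    def test_zero_variance_rejected(self):
        with pytest.raises(stability.AnalysisError):
            stability.dropout_bayes_t_test([1.0, 1.0], [1.0, 1.0])

    def test_parameter_dependent_dropout_elevates_tau_bf(self):
        cohort = synth.CohortConfig(
            subgroup_sizes=(500,), subgroup_ages=("young",),
            retention=(500, 280, 280, 280), dropout_mode="parameter",
            dropout_weight=2.0,
        )
        traj = synth.draw_person_trajectories(cohort=cohort, seed=13)
        med = traj.values[["participant_id", "wave", "nu", "a", "tau"]].copy()
        med.loc[~traj.values["observed"].to_numpy(), ["nu", "a", "tau"]] = np.nan
        res = stability.dropout_analysis(med).set_index("parameter")
        assert res.loc["tau", "bf10"] > 10
        assert res.loc["tau", "mean_diff"] > 0  # droppers have higher tau
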