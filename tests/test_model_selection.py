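import numpy as np
import pandas as pd
import pytest

from windrift import model_selection as msel
from windrift import synthetic_data as sd
from windrift.model_selection import FittedModel, ModelSpec


class TestAicc:
    def test_direct_formula(self):
        # cross-checked by hand: AIC = -2*(-100) + 2*3 = 206; correction
        # 2*3*4/(75-3-1) = 24/71
        assert msel.aic(-100.0, 3) == 206.0
        assert msel.aicc(-100.0, 3, 75) == pytest.approx(206.0 + 24.0 / 71.0)

    def test_zero_parameters_no_correction(self):
        assert msel.aicc(-50.0, 0, 20) == msel.aic(-50.0, 0)

    def test_large_n_limit(self):
        assert msel.aicc(-100.0, 5, 10**9) == pytest.approx(msel.aic(-100.0, 5), abs=1e-5)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            msel.aicc(-10.0, 5, 6)


def fake_fit(loglik, k, n=75, criterion="aicc", name="m"):
    return FittedModel(
        spec=ModelSpec(response="y", fixed="1", criterion=criterion, name=name),
        loglik=loglik,
        k=k,
        nobs=n,
        coef=pd.DataFrame(),
        var_fixed=1.0,
        var_random={},
        var_resid=1.0,
        rows=tuple(range(n)),
    )


class TestRankModels:
    def test_equal_scores_split_weight(self):
        f1, f2 = fake_fit(-100, 3), fake_fit(-100, 3)
        table, _ = msel.rank_models([f1, f2])
        np.testing.assert_allclose(table["weight"], [0.5, 0.5])

    def test_delta_two_weights(self):
        # closed form: w = (1, e^-1) normalized -> (0.731, 0.269)
        f1 = fake_fit(-100, 3)
        f2 = fake_fit(-101, 3)
        table, _ = msel.rank_models([f1, f2])
        np.testing.assert_allclose(table["weight"], [0.7311, 0.2689], atol=1e-4)
        assert table["weight"].sum() == pytest.approx(1.0)

    def test_weights_invariant_to_loglik_shift(self):
        fits = [fake_fit(-100, 3), fake_fit(-102, 4), fake_fit(-99, 5)]
        shifted = [fake_fit(f.loglik + 37.0, f.k) for f in fits]
        t1, _ = msel.rank_models(fits)
        t2, _ = msel.rank_models(shifted)
        np.testing.assert_allclose(t1["weight"], t2["weight"], rtol=1e-10)

    def test_parsimony_rule_picks_fewest_parameters_below_delta_2(self):
        # deltas (0, 1.5) with k (10, 6): the k=6 model wins
        base = fake_fit(-100.0, 10, name="rich")
        # arrange loglik so the k=6 model sits at delta 1.5
        target_score = base.score() + 1.5
        ll = -(target_score - 2 * 6 - 2 * 6 * 7 / (75 - 6 - 1)) / 2
        lean = fake_fit(ll, 6, name="lean")
        table, best = msel.rank_models([base, lean])
        assert best.spec.name == "lean"
        # deterministic: same outcome on repeated calls and input order swap
        _, best2 = msel.rank_models([lean, base])
        assert best2.spec.name == "lean"

    def test_differing_row_sets_rejected(self):
        f1, f2 = fake_fit(-100, 3, n=75), fake_fit(-100, 3, n=74)
        with pytest.raises(ValueError, match="row sets"):
            msel.rank_models([f1, f2])


class TestFitLmm:
    def test_intercept_only_with_null_grouping_recovers_grand_mean(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "y": rng.normal(5.0, 1.0, 200),
                "individual": np.repeat([f"B{i}" for i in range(10)], 20),
            }
        )
        fit = msel.fit_lmm(ModelSpec(response="y", fixed="1", random=("individual",)), df)
        assert fit.coef["estimate"].iloc[0] == pytest.approx(df["y"].mean(), abs=0.05)
        assert fit.k == 3  # intercept + random variance + residual variance

    def test_duplicated_rows_double_the_loglik(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"y": rng.normal(size=50), "x": rng.normal(size=50)})
        spec = ModelSpec(response="y", fixed="x", random=())
        f1 = msel.fit_lmm(spec, df)
        f2 = msel.fit_lmm(spec, pd.concat([df, df], ignore_index=True))
        assert f2.loglik == pytest.approx(2 * f1.loglik, rel=1e-6)
        np.testing.assert_allclose(
            f1.coef["estimate"], f2.coef["estimate"], rtol=1e-8
        )

    def test_ols_loglik_matches_statsmodels(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"y": rng.normal(size=60), "x": rng.normal(size=60)})
        fit = msel.fit_lmm(ModelSpec(response="y", fixed="x", random=()), df)
        import statsmodels.formula.api as smf

        ref = smf.ols("y ~ x", df).fit()
        assert fit.loglik == pytest.approx(ref.llf)
        assert fit.k == 3  # 2 coefficients + residual variance

    def test_parameter_recovery_on_simulated_slope(self):
        df, truth = sd.make_regression_fixture(
            coefficients={"Intercept": 9.530, "lat_itf": 0.228},
            n=300,
            sigma=1.0,
            group_sd=0.8,
            seed=5,
        )
        fit = msel.fit_lmm(
            ModelSpec(response="mean_lat_bird", fixed="lat_itf", random=("individual",)), df
        )
        est = fit.coef.loc["lat_itf", "estimate"]
        se = fit.coef.loc["lat_itf", "se"]
        assert abs(est - 0.228) <= 2 * se

    def test_log_transform_of_nonpositive_response_rejected(self):
        df = pd.DataFrame({"y": [1.0, -1.0, 2.0], "x": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError, match="log"):
            msel.fit_lmm(ModelSpec(response="y", fixed="x", log_response=True), df)

    def test_single_level_grouping_rejected(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0], "g": ["a", "a", "a"]})
        with pytest.raises(ValueError, match="levels"):
            msel.fit_lmm(ModelSpec(response="y", fixed="1", random=("g",)), df)

    def test_zero_group_variance_fitted_near_zero(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {
                "y": rng.normal(size=300),  # no group structure at all
                "individual": np.repeat([f"B{i}" for i in range(15)], 20),
            }
        )
        fit = msel.fit_lmm(ModelSpec(response="y", fixed="1", random=("individual",)), df)
        # fit is retained with the variance at (or hovering just above) zero
        assert fit.var_random["individual"] < 0.02 * fit.var_resid


class TestPartialR2:
    def test_pure_noise_near_zero(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(
            {
                "y": rng.normal(size=400),
                "x": rng.normal(size=400),
                "individual": np.repeat([f"B{i}" for i in range(20)], 20),
            }
        )
        fit = msel.fit_lmm(ModelSpec(response="y", fixed="x", random=("individual",)), df)
        full, fixed, random = msel.partial_r2(fit)
        assert full < 0.05 and fixed < 0.05 and random < 0.05

    def test_exact_fixed_predictor(self):
        df = pd.DataFrame({"y": np.arange(50.0), "x": np.arange(50.0)})
        fit = msel.fit_lmm(ModelSpec(response="y", fixed="x", random=()), df)
        full, fixed, _ = msel.partial_r2(fit)
        assert fixed == pytest.approx(1.0, abs=1e-6)

    def test_variance_shares_recovered(self):
        """Generative shares fixed 0.5 / random 0.3 / residual 0.2 at n=2000."""
        rng = np.random.default_rng(7)
        n, n_groups = 2000, 40
        x = rng.normal(0, 1, n)
        g = rng.integers(0, n_groups, n)
        u = rng.normal(0, np.sqrt(0.3), n_groups)
        y = np.sqrt(0.5) * x + u[g] + rng.normal(0, np.sqrt(0.2), n)
        df = pd.DataFrame({"y": y, "x": x, "individual": g})
        fit = msel.fit_lmm(ModelSpec(response="y", fixed="x", random=("individual",)), df)
        full, fixed, random = msel.partial_r2(fit)
        assert fixed == pytest.approx(0.5, abs=0.05)
        assert random == pytest.approx(0.3, abs=0.05)
        assert full == pytest.approx(0.8, abs=0.05)

    def test_r2_parts_sum_to_full(self):
        df, _ = sd.make_regression_fixture(seed=8, n=200)
        fit = msel.fit_lmm(
            ModelSpec(response="mean_lat_bird", fixed="lat_itf + long", random=("individual",)),
            df,
        )
        full, fixed, random = msel.partial_r2(fit)
        assert full == pytest.approx(fixed + random)
        assert 0 <= fixed <= full <= 1


class TestCandidateSets:
    def test_sahel_set_has_eleven_structures_with_full_interaction_model(self):
        specs = msel.build_candidate_sets("sahel_latitude")
        assert len(specs) == 11
        assert specs[0].fixed == "long * lat_itf * season"
        assert all(s.random == ("individual",) for s in specs)
        assert all(s.criterion == "aicc" for s in specs)

    def test_trip_level_uses_crossed_random_intercepts_and_log_transforms(self):
        specs = msel.build_candidate_sets("trip_level")
        assert all(s.random == ("individual", "year") for s in specs)
        logged = {s.response for s in specs if s.log_response}
        assert {"duration_days", "travel_days", "stopover_days"} <= logged
        assert not any(
            s.log_response for s in specs if s.response == "mean_daily_tailwind_track"
        )

    def test_daily_level_uses_plain_aic_and_both_log_responses(self):
        specs = msel.build_candidate_sets("daily_level")
        assert all(s.criterion == "aic" for s in specs)
        assert {s.response for s in specs} == {"daily_distance_km", "mean_travel_speed_kmh"}
        assert all(s.log_response for s in specs)
        per_resp = len({s.fixed for s in specs})
        assert per_resp == 44  # exhaustive daily structure list

    def test_unknown_context_rejected(self):
        with pytest.raises(ValueError):
            msel.build_candidate_sets("nope")

    def test_sahel_candidates_rank_end_to_end(self):
        df, _ = sd.make_regression_fixture(seed=9, n=250)
        specs = msel.build_candidate_sets("sahel_latitude")
        fits = [msel.fit_lmm(s, df) for s in specs]
        table, best = msel.rank_models(fits)
        assert table["weight"].sum() == pytest.approx(1.0)
        assert (table["delta"] >= 0).all()
        # data generated with the full three-way structure: it should win
        assert best.spec.fixed == "long * lat_itf * season"
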