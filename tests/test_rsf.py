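import warnings

import numpy as np
import pandas as pd
import pytest

from circuitmig import rsf
from circuitmig.covariates import build_stack
from circuitmig.rsf import (
    DEFAULT_ALPHA_GRID,
    RSFFit,
    SeparationError,
    aicc,
    best_alpha,
    bootstrap_response,
    build_table,
    candidate_model_set,
    fit_rsf,
    kfold_validate,
    predict_suitability,
    sample_availability,
    select_decay_alpha,
    vif,
)


class TestAicc:
    def test_formula_value(self):
        assert aicc(-50.0, 3, 100) == pytest.approx(106.25)

    def test_converges_to_aic(self):
        aic = -2 * (-1000.0) + 2 * 5
        assert abs(aicc(-1000.0, 5, 10**7) - aic) < 1e-3

    def test_smaller_k_wins_at_equal_loglik(self):
        assert aicc(-80.0, 2, 500) < aicc(-80.0, 3, 500)

    def test_rejects_tiny_n(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 6)


class TestAvailability:
    def test_ratio_twenty_default(self, rng):
        pts = sample_availability((0, 0, 10, 10), n_used=10, rng=rng)
        assert len(pts) == 200

    def test_single_point_inside(self, rng):
        pts = sample_availability((2, 3, 4, 5), n_used=1, ratio=1, rng=rng)
        assert pts.shape == (1, 2)
        assert 2 <= pts[0, 0] < 4 and 3 <= pts[0, 1] < 5

    def test_seed_reproducibility(self):
        a = sample_availability((0, 0, 5, 5), 7, rng=123)
        b = sample_availability((0, 0, 5, 5), 7, rng=123)
        c = sample_availability((0, 0, 5, 5), 7, rng=124)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_empty_used_rejected(self):
        with pytest.raises(ValueError):
            sample_availability((0, 0, 1, 1), 0)


class TestFit:
    def test_intercept_only_equals_log_ratio(self, rng):
        n_used = 1000
        tab = pd.DataFrame({"response": [1] * n_used + [0] * (20 * n_used)})
        fit = fit_rsf(tab, formula=())
        assert fit.params["intercept"] == pytest.approx(np.log(1 / 20), abs=0.01)

    def test_simulation_recovery_within_3se(self, rng):
        n = 50_000
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(-3.0 + 0.5 * x)))
        tab = pd.DataFrame({"response": rng.binomial(1, p), "ruggedness": x})
        fit = fit_rsf(tab, formula=("ruggedness",))
        assert abs(fit.params["ruggedness"] - 0.5) < 3 * fit.bse["ruggedness"]
        assert abs(fit.params["intercept"] + 3.0) < 3 * fit.bse["intercept"]

    def test_duplicated_column_rejected(self, rng):
        x = rng.normal(size=200)
        tab = pd.DataFrame(
            {"response": rng.integers(0, 2, 200), "a": x, "b": x}
        )
        with pytest.raises(SeparationError):
            fit_rsf(tab, formula=("a", "b"))

    def test_complete_separation_detected(self):
        x = np.r_[np.ones(50), -np.ones(50)]
        tab = pd.DataFrame({"response": (x > 0).astype(int), "a": x})
        with pytest.raises(SeparationError):
            fit_rsf(tab, formula=("a",))

    def test_single_class_rejected(self):
        tab = pd.DataFrame({"response": np.ones(10), "a": np.arange(10.0)})
        with pytest.raises(ValueError):
            fit_rsf(tab, formula=("a",))

    def test_json_roundtrip(self, rng, tmp_path):
        x = rng.normal(size=2000)
        p = 1 / (1 + np.exp(-(-1.0 + x)))
        tab = pd.DataFrame({"response": rng.binomial(1, p), "ruggedness": x})
        fit = fit_rsf(tab, formula=("ruggedness",))
        path = tmp_path / "fit.json"
        fit.to_json(path)
        back = RSFFit.from_json(path)
        pd.testing.assert_series_equal(fit.params, back.params)
        assert back.aicc == pytest.approx(fit.aicc)


class TestGLMM:
    def test_zero_variance_boundary_equals_fixed_effects(self, rng):
        # homogeneous animals: variance hits the boundary and the GLMM
        # collapses onto the plain logistic fit
        n_per, n_animals = 300, 6
        rows = []
        for a in range(n_animals):
            x = rng.normal(size=n_per)
            p = 1 / (1 + np.exp(-(-2.0 + 0.8 * x)))
            rows.append(
                pd.DataFrame(
                    {
                        "response": rng.binomial(1, p),
                        "ruggedness": x,
                        "animal_id": f"a{a}",
                        "year": 2020,
                    }
                )
            )
        tab = pd.concat(rows, ignore_index=True)
        mixed = fit_rsf(tab, formula=("ruggedness",), random_effects=True)
        fixed = fit_rsf(tab, formula=("ruggedness",), random_effects=False)
        if max(mixed.random_variances.values()) < 1e-3:
            np.testing.assert_allclose(
                mixed.params.to_numpy(), fixed.params.to_numpy(), atol=1e-6
            )

    def test_recovers_heterogeneity(self, rng):
        # animals with genuinely different intercepts produce a positive
        # variance estimate and coefficients near truth
        rows = []
        for a in range(12):
            u = rng.normal(0, 1.0)
            x = rng.normal(size=400)
            p = 1 / (1 + np.exp(-(-2.0 + u + 0.6 * x)))
            y = rng.binomial(1, p)
            rows.append(
                pd.DataFrame(
                    {
                        "response": y,
                        "ruggedness": x,
                        "animal_id": f"a{a}",
                        "year": 2020 + (a % 2),
                    }
                )
            )
        tab = pd.concat(rows, ignore_index=True)
        fit = fit_rsf(tab, formula=("ruggedness",), random_effects=True)
        assert fit.random_variances["animal"] > 0.1
        assert abs(fit.params["ruggedness"] - 0.6) < 4 * fit.bse["ruggedness"]


class TestModelSet:
    def test_sixteen_models_from_four_groups(self):
        models = candidate_model_set()
        assert len(models) == 16
        assert () in models  # intercept-only
        assert len(set(models)) == 16

    def test_two_groups_give_four(self):
        models = candidate_model_set({"a": ("a",), "b": ("b",)})
        assert len(models) == 4

    def test_landcover_moves_as_one_group(self):
        models = candidate_model_set()
        for m in models:
            has = {c for c in ("dense", "burned", "coastal") if c in m}
            assert has in (set(), {"dense", "burned", "coastal"})


class TestVif:
    def test_orthogonal_columns_unity(self):
        n = 400
        a = np.tile([1.0, -1.0], n // 2)
        b = np.repeat([1.0, -1.0], n // 2)
        v = vif(pd.DataFrame({"a": a, "b": b}))
        np.testing.assert_allclose(v.to_numpy(), 1.0, atol=1e-10)

    def test_duplicated_column_infinite(self, rng):
        x = rng.normal(size=100)
        v = vif(pd.DataFrame({"a": x, "b": x}))
        assert np.isinf(v).all()

    def test_known_correlation_closed_form(self, rng):
        # exact sample correlation r gives VIF = 1/(1-r^2) for two columns
        x = rng.normal(size=3000)
        y = 0.6 * x + np.sqrt(1 - 0.36) * rng.normal(size=3000)
        r = np.corrcoef(x, y)[0, 1]
        v = vif(pd.DataFrame({"a": x, "b": y}))
        assert v["a"] == pytest.approx(1 / (1 - r**2), rel=1e-9)
        assert v["b"] == pytest.approx(v["a"], rel=1e-9)


class TestAlphaScan:
    def test_grid_has_36_candidates(self):
        assert len(DEFAULT_ALPHA_GRID) == 36

    def test_single_candidate_weight_one(self, rng):
        d = rng.uniform(1, 100, 3000)
        p = 1 / (1 + np.exp(-(-2.0 + 2.0 * np.exp(-10 / d))))
        tab = pd.DataFrame(
            {"response": rng.binomial(1, p), "road_distance_km": d}
        )
        sel = select_decay_alpha(tab, candidates=[10.0], include_linear=False)
        with pytest.raises(ValueError):
            select_decay_alpha(tab, candidates=[], include_linear=False)
        assert sel["akaike_weight"].iloc[0] == pytest.approx(1.0)

    def test_weights_sum_to_one(self, rng):
        d = rng.uniform(1, 100, 2000)
        p = 1 / (1 + np.exp(-(-2.0 + 2.0 * np.exp(-20 / d))))
        tab = pd.DataFrame(
            {"response": rng.binomial(1, p), "road_distance_km": d}
        )
        sel = select_decay_alpha(tab, candidates=[5.0, 20.0, 80.0])
        assert sel["akaike_weight"].sum() == pytest.approx(1.0, abs=1e-12)
        assert sel["delta_aicc"].iloc[0] == 0.0

    def test_best_alpha_parses_winner(self, rng):
        d = rng.uniform(1, 150, 20000)
        w = np.exp(4.0 * np.exp(-20 / d))
        used = rng.choice(len(d), 2000, p=w / w.sum())
        tab = pd.DataFrame(
            {
                "response": np.r_[np.ones(2000), np.zeros(len(d))],
                "road_distance_km": np.r_[d[used], d],
            }
        )
        sel = select_decay_alpha(tab, candidates=[5.0, 20.0, 80.0], include_linear=True)
        assert best_alpha(sel) == pytest.approx(20.0)


class TestPrediction:
    def test_zero_coefficients_give_unit_hs(self, small_bundle):
        stack = build_stack(small_bundle, alpha=5.0)
        fit = _dummy_fit({"ruggedness": 0.0, "river": 0.0})
        hs = predict_suitability(fit, stack)
        np.testing.assert_allclose(hs.data[hs.valid], 1.0)

    def test_max_is_exactly_one(self, small_bundle):
        stack = build_stack(small_bundle, alpha=5.0)
        fit = _dummy_fit({"ruggedness": -0.7, "dense": -1.0})
        hs = predict_suitability(fit, stack)
        assert np.nanmax(hs.data) == 1.0
        assert np.nanmin(hs.data) > 0

    def test_scaling_invariance(self, small_bundle):
        # adding a constant to the linear predictor (e.g. an intercept)
        # cancels in the max-normalisation
        stack = build_stack(small_bundle, alpha=5.0)
        f1 = _dummy_fit({"ruggedness": -0.7})
        hs1 = predict_suitability(f1, stack)
        w = np.exp(-0.7 * stack.ruggedness_z.data + 123.0)
        hs2 = w / np.nanmax(w)
        np.testing.assert_allclose(
            hs1.data[hs1.valid], hs2[hs1.valid], rtol=1e-10
        )


def _dummy_fit(coefs: dict) -> RSFFit:
    names = ["intercept"] + list(coefs)
    return RSFFit(
        params=pd.Series({"intercept": 0.0, **coefs}),
        bse=pd.Series(0.1, index=names),
        cov=pd.DataFrame(np.eye(len(names)) * 0.01, index=names, columns=names),
        loglik=-1.0,
        n=100,
        k=len(names),
        formula=tuple(coefs),
    )


class TestValidation:
    def test_informative_model_high_rho(self, rng):
        # strong selection on one covariate: validation must rank bins well
        n_av = 8000
        x_av = rng.normal(size=n_av)
        w = np.exp(2.0 * x_av)
        used = rng.choice(n_av, 800, p=w / w.sum())
        tab = pd.DataFrame(
            {
                "response": np.r_[np.ones(800), np.zeros(n_av)],
                "ruggedness": np.r_[x_av[used], x_av],
            }
        )
        rho = kfold_validate(tab, ("ruggedness",), k=5, rng=rng)
        assert rho >= 0.9

    def test_noise_model_rho_near_zero(self, rng):
        rhos = []
        for _ in range(20):
            n_av = 1000
            x = rng.normal(size=n_av + 100)
            tab = pd.DataFrame(
                {
                    "response": np.r_[np.ones(100), np.zeros(n_av)],
                    "ruggedness": x,
                }
            )
            rhos.append(kfold_validate(tab, ("ruggedness",), k=4, rng=rng))
        assert abs(np.mean(rhos)) < 0.25


class TestBootstrapResponse:
    def _fit(self, rng):
        d = rng.uniform(0.5, 150, 30000)
        w = np.exp(3.0 * np.exp(-20 / d))
        used = rng.choice(len(d), 3000, p=w / w.sum())
        tab = pd.DataFrame(
            {
                "response": np.r_[np.ones(3000), np.zeros(len(d))],
                "road_decay": np.exp(-20 / np.r_[d[used], d]),
            }
        )
        return fit_rsf(tab, formula=("road_decay",))

    def test_deterministic_given_seed(self, rng):
        fit = self._fit(rng)
        a = bootstrap_response(fit, 20.0, n_boot=100, seed=7)
        b = bootstrap_response(fit, 20.0, n_boot=100, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_degenerate_covariance_collapses_to_plugin(self, rng):
        fit = self._fit(rng)
        fit.cov = fit.cov * 1e-18
        curve = bootstrap_response(fit, 20.0, n_boot=200, seed=1)
        np.testing.assert_allclose(curve["mean"], curve["plugin"], rtol=1e-3)
        width = curve["ci_high"] - curve["ci_low"]
        assert (width < 1e-3 * curve["plugin"]).all()

    def test_ci_contains_plugin(self, rng):
        fit = self._fit(rng)
        curve = bootstrap_response(fit, 20.0, n_boot=400, seed=3)
        inside = (curve["plugin"] >= curve["ci_low"]) & (
            curve["plugin"] <= curve["ci_high"]
        )
        assert inside.mean() > 0.95
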