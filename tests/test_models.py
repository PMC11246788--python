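"""Penalized-spline fits, predictor screening, comparison and transfer."""

import warnings

import numpy as np
import pandas as pd
import pytest

from nivophen import models
from nivophen.models import (ModelError, assess_predictions,
                             compare_predictors, fit_gcc_species_model,
                             fit_phenophase_smooth, predict_cross_site,
                             screen_predictors)


def quiet_fit(*args, **kwargs):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_phenophase_smooth(*args, **kwargs)


class TestScreening:
    def test_exact_collinearity_from_constant_temperature(self):
        dfsm = np.arange(1, 40, dtype=float)
        table = pd.DataFrame({"doy": dfsm + 180, "dfsm": dfsm,
                              "gdd": 8.0 * dfsm})
        out = screen_predictors(table)
        assert out["correlation_matrix"].loc["dfsm", "gdd"] == pytest.approx(1.0)
        flagged = {(a, b) for a, b, _ in out["flagged_pairs"]}
        assert ("dfsm", "gdd") in flagged or ("gdd", "dfsm") in flagged

    def test_independent_noise_not_flagged(self, rng):
        table = pd.DataFrame({"doy": rng.normal(size=200),
                              "gdd": rng.normal(size=200)})
        out = screen_predictors(table)
        assert abs(out["correlation_matrix"].loc["doy", "gdd"]) < 0.90
        assert not out["flagged_pairs"]

    def test_constant_predictor_warned_not_flagged(self):
        table = pd.DataFrame({"doy": [1.0, 2, 3], "gdd": [5.0, 5, 5]})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = screen_predictors(table)
        assert np.isnan(out["correlation_matrix"].loc["doy", "gdd"])
        assert any("constant" in w for w in out["warnings"])

    def test_two_point_data_reported_degenerate(self):
        table = pd.DataFrame({"doy": [1.0, 2.0], "gdd": [3.0, 9.0]})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = screen_predictors(table)
        assert any("2 points" in w for w in out["warnings"])


class TestSmoothFit:
    def test_infinite_smoothing_limit_is_straight_line(self, rng):
        x = np.linspace(0, 10, 40)
        y = 2.0 + 0.5 * x + rng.normal(0, 0.3, 40)
        df = pd.DataFrame({"median_phase": y, "gdd": x})
        fit = quiet_fit(df, "gdd", random_effects=(), fixed_log_lambda=9.0)
        line = np.polyfit(x, y, 1)
        grid = np.array([1.0, 4.0, 7.5])
        got = fit.predict(grid)["predicted_unclamped"].to_numpy()
        assert np.allclose(got, np.polyval(line, grid), atol=1e-5)

    def test_noise_free_smooth_recovered_nearly_perfectly(self):
        x = np.linspace(0, 10, 50)
        y = 30 + 20 * np.sin(x / 4)
        fit = quiet_fit(pd.DataFrame({"median_phase": y, "gdd": x}), "gdd",
                        random_effects=())
        assert fit.r2 >= 0.999
        null_aic = len(y) * np.log(2 * np.pi * np.var(y)) + len(y) + 4
        assert fit.aic < null_aic

    def test_shuffled_response_near_null(self, rng):
        x = np.linspace(0, 10, 50)
        y = rng.permutation(30 + 20 * np.sin(x / 4))
        fit = quiet_fit(pd.DataFrame({"median_phase": y, "gdd": x}), "gdd",
                        random_effects=())
        assert fit.r2 < 0.2

    def test_single_level_random_effect_dropped_with_warning(self):
        x = np.linspace(0, 10, 30)
        df = pd.DataFrame({"median_phase": x, "gdd": x, "plot": "p1"})
        with pytest.warns(UserWarning, match="single level"):
            fit = fit_phenophase_smooth(df, "gdd", random_effects=("plot",))
        assert fit.random_effects == {}

    def test_random_intercepts_absorb_plot_offsets(self, rng):
        x = np.tile(np.linspace(0, 10, 20), 3)
        offsets = np.repeat([-4.0, 0.0, 4.0], 20)
        plots = np.repeat(["a", "b", "c"], 20)
        y = 20 + 2 * x + offsets + rng.normal(0, 0.1, 60)
        df = pd.DataFrame({"median_phase": y, "gdd": x, "plot": plots})
        fit = quiet_fit(df, "gdd", random_effects=("plot",))
        re = fit.random_effects["plot"]
        assert re["a"] < re["b"] < re["c"]
        assert fit.r2 > 0.99

    def test_constant_predictor_refused(self):
        df = pd.DataFrame({"median_phase": np.arange(20.0),
                           "gdd": np.full(20, 5.0)})
        with pytest.raises(ModelError):
            quiet_fit(df, "gdd", random_effects=())


class TestComparison:
    def make_fits(self, rng):
        x = np.linspace(0, 600, 60)
        y = np.clip(0.08 * x + rng.normal(0, 1.5, 60), 0, 59)
        base = pd.DataFrame({"median_phase": y, "gdd": x,
                             "dfsm": x / 8.0 + rng.normal(0, 2, 60),
                             "doy": x / 8.0 + 180 + rng.normal(0, 6, 60)})
        return {p: quiet_fit(base, p, random_effects=())
                for p in ("gdd", "dfsm", "doy")}

    def test_winner_has_lowest_aic(self, rng):
        comp = compare_predictors(self.make_fits(rng))
        table = comp["table"]
        assert table.loc[0, "aic"] == table["aic"].min()
        assert comp["winner"] == table.loc[0, "predictor"]

    def test_identical_fits_tie_break_by_priority(self, rng):
        x = np.linspace(0, 600, 50)
        y = 0.08 * x
        df = pd.DataFrame({"median_phase": y, "gdd": x, "dfsm": x})
        fits = {"dfsm": quiet_fit(df, "dfsm", random_effects=()),
                "gdd": quiet_fit(df, "gdd", random_effects=())}
        assert compare_predictors(fits)["winner"] == "gdd"

    def test_different_response_data_refused(self, rng):
        x = np.linspace(0, 10, 30)
        f1 = quiet_fit(pd.DataFrame({"median_phase": x, "gdd": x}), "gdd",
                       random_effects=())
        f2 = quiet_fit(pd.DataFrame({"median_phase": x + 1, "gdd": x}), "gdd",
                       random_effects=())
        with pytest.raises(ModelError):
            compare_predictors({"gdd": f1, "doy": f2})


class TestGCCSpeciesModel:
    def make_matched(self, rng, n=17, driver="Salix herbacea"):
        species = ["Salix herbacea", "Poa alpina", "Veronica alpina"]
        frame = {s: np.sort(rng.uniform(0, 59, n)) for s in species}
        frame = pd.DataFrame(frame)
        frame["gcc"] = (0.34 + 0.002 * frame[driver]
                        + rng.normal(0, 0.002, n))
        return frame, species

    def test_driving_species_most_significant(self, rng):
        matched, species = self.make_matched(rng)
        fit = fit_gcc_species_model(matched, species)
        pv = fit.term_pvalues
        assert pv["Salix herbacea"] == min(pv.values())
        assert pv["Salix herbacea"] < 0.05

    def test_unrelated_gcc_low_deviance_explained(self, rng):
        matched, species = self.make_matched(rng)
        matched["gcc"] = 0.38 + rng.normal(0, 0.002, len(matched))
        fit = fit_gcc_species_model(matched, species)
        assert fit.deviance_explained < 0.5

    def test_intercept_near_mean_gcc(self, rng):
        matched, species = self.make_matched(rng)
        fit = fit_gcc_species_model(matched, species)
        assert fit.intercept == pytest.approx(matched["gcc"].mean(), abs=0.01)

    def test_too_few_dates_refused(self, rng):
        matched, species = self.make_matched(rng, n=8)
        with pytest.raises(ModelError, match="10"):
            fit_gcc_species_model(matched, species)


class TestCrossSitePrediction:
    def make_fit(self, rng, noise=0.0):
        x = np.linspace(0, 600, 80)
        y = np.clip(9 + 0.08 * x + rng.normal(0, noise, 80), 0, 59)
        return quiet_fit(pd.DataFrame({"median_phase": y, "gdd": x}), "gdd",
                         random_effects=())

    def test_matched_program_error_at_noise_level(self, rng):
        fit = self.make_fit(rng, noise=1.0)
        target = pd.DataFrame({"gdd": np.linspace(50, 550, 40)})
        pred = predict_cross_site(fit, target)
        truth = np.clip(9 + 0.08 * target["gdd"], 0, 59)
        mae = np.mean(np.abs(pred["predicted"] - truth))
        assert mae < 1.5

    def test_shifted_program_leaves_systematic_residuals(self, rng):
        fit = self.make_fit(rng)
        gdd = np.linspace(150, 550, 30)
        observed = np.clip(9 + 0.08 * (gdd - 100), 0, 59)   # +100 GDD onset
        pred = predict_cross_site(fit, pd.DataFrame({"gdd": gdd}))
        resid = pred["predicted"].to_numpy() - observed
        assert resid.mean() > 5.0          # consistent over-prediction

    def test_empty_target_gives_empty_prediction(self, rng):
        fit = self.make_fit(rng)
        out = predict_cross_site(fit, pd.DataFrame({"gdd": []}))
        assert out.empty

    def test_extrapolation_flagged_and_output_clamped(self, rng):
        fit = self.make_fit(rng)
        out = predict_cross_site(fit, pd.DataFrame({"gdd": [700.0, 300.0]}))
        assert out["extrapolated"].tolist() == [True, False]
        assert (out["predicted"] <= 59).all() and (out["predicted"] >= 0).all()

    def test_wrong_predictor_refused(self, rng):
        fit = self.make_fit(rng)
        with pytest.raises(ModelError):
            predict_cross_site(fit, pd.DataFrame({"doy": [200.0]}),
                               predictor="doy")


class TestAssessment:
    def test_identity_prediction(self):
        out = assess_predictions([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert out["pearson_r"] == pytest.approx(1.0)
        assert out["mean_abs_error_phases"] == 0.0

    def test_constant_offset_separates_mae_from_correlation(self):
        obs = np.array([10.0, 20, 30, 40])
        out = assess_predictions(obs + 3, obs)
        assert out["pearson_r"] == pytest.approx(1.0)
        assert out["mean_abs_error_phases"] == pytest.approx(3.0)

    def test_matches_brute_force_mae_oracle(self, rng):
        p = rng.uniform(0, 59, 50)
        o = rng.uniform(0, 59, 50)
        out = assess_predictions(p, o)
        assert out["mean_abs_error_phases"] == pytest.approx(
            sum(abs(a - b) for a, b in zip(p, o)) / 50)

    def test_sign_symmetry_of_mae(self, rng):
        o = rng.uniform(10, 50, 30)
        e = rng.uniform(0, 5, 30)
        up = assess_predictions(o + e, o)["mean_abs_error_phases"]
        down = assess_predictions(o - e, o)["mean_abs_error_phases"]
        assert up == pytest.approx(down)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ModelError):
            assess_predictions([1.0, 2.0], [1.0])
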