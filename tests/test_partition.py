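"""Monthly fits, component algebra and the NLS estimator contract."""

import numpy as np
import pandas as pd
import pytest

import stemflux as sf
from stemflux.errors import (AlignmentError, InsufficientDataError,
                             SingularDesignError)
from stemflux.partition import (light_response_model, parameter_inference,
                                respiration_model)


def low_flow_table(r0=0.5, b=0.09, n=200, noise_sd=0.0, seed=0):
    idx = pd.date_range("2021-06-01", periods=n, freq="30min")
    rng = np.random.default_rng(seed)
    temp = np.linspace(6, 18, n)
    dfco2 = -(r0 * np.exp(b * temp))
    if noise_sd:
        dfco2 = dfco2 + rng.normal(0, noise_sd, n)
    return pd.DataFrame({"dfco2": dfco2, "tfco2": dfco2, "temp": temp,
                         "ppfd": 0.0, "rh": 60.0, "sapflux": 0.0,
                         "month": idx.month, "tree": "A"}, index=idx)


class TestFitRespiration:
    def test_noiseless_recovery_to_machine_precision(self):
        fit = sf.fit_respiration(low_flow_table(r0=0.5, b=0.09))
        assert fit["r0"] == pytest.approx(0.5, rel=1e-6)
        assert fit["b"] == pytest.approx(0.09, rel=1e-6)

    def test_constant_temperature_is_singular(self):
        table = low_flow_table()
        table["temp"] = 12.0
        with pytest.raises(SingularDesignError):
            sf.fit_respiration(table)

    def test_min_n_enforced(self):
        with pytest.raises(InsufficientDataError):
            sf.fit_respiration(low_flow_table(n=10))

    def test_nonpositive_rows_warned_but_fit_proceeds(self):
        table = low_flow_table(noise_sd=0.0)
        table.iloc[0, table.columns.get_loc("dfco2")] = 0.5  # positive dark flux
        with pytest.warns(UserWarning, match="nonpositive"):
            fit = sf.fit_respiration(table)
        assert fit["r0"] > 0

    def test_truth_in_ci_for_noisy_replicates(self):
        # 95 % CI should cover truth in most of 100 replicates (binomial slack)
        hits = 0
        for seed in range(100):
            fit = sf.fit_respiration(low_flow_table(n=500, noise_sd=0.1,
                                                    seed=seed))
            lo, hi = fit.ci_of("r0")
            hits += lo <= 0.5 <= hi
        assert hits >= 90


class TestPredictAndComponents:
    def test_prediction_at_reference_temperature(self):
        fit = sf.fit_respiration(low_flow_table(r0=0.5, b=0.1))
        temp = pd.Series([0.0, 10.0],
                         index=pd.date_range("2021-06-01", periods=2, freq="30min"))
        r = sf.predict_respiration(fit, temp)
        assert r.iloc[0] == pytest.approx(0.5, rel=1e-6)
        assert r.iloc[1] == pytest.approx(0.5 * np.e, rel=1e-6)

    def test_prediction_strictly_increasing_in_temperature(self):
        fit = sf.fit_respiration(low_flow_table())
        temp = pd.Series(np.linspace(0, 25, 50),
                         index=pd.date_range("2021-06-01", periods=50, freq="30min"))
        assert (np.diff(sf.predict_respiration(fit, temp)) > 0).all()

    def test_transport_identities(self):
        idx = pd.date_range("2021-06-01", periods=3, freq="30min")
        dfco2 = pd.Series([-2.0, -2.5, -2.0], index=idx)
        r_prime = pd.Series([2.5, 2.5, 2.0], index=idx)
        t = sf.compute_transport(dfco2, r_prime)
        assert t.tolist() == pytest.approx([0.5, 0.0, 0.0])

    def test_transport_misalignment_raises(self):
        a = pd.Series([1.0], index=pd.date_range("2021-06-01", periods=1))
        b = pd.Series([1.0], index=pd.date_range("2021-07-01", periods=1))
        with pytest.raises(AlignmentError):
            sf.compute_transport(a, b)

    def test_photosynthesis_difference_and_night_masking(self):
        idx = pd.date_range("2021-06-01", periods=4, freq="30min")
        tf = pd.Series([-1.5, -1.5, -2.0, -2.0], index=idx)
        df = pd.Series([-2.0, -2.0, -2.0, -2.0], index=idx)
        day = pd.Series([True, True, True, False], index=idx)
        p = sf.compute_photosynthesis(tf, df, day)
        assert p.iloc[0] == pytest.approx(0.5)
        assert p.iloc[2] == pytest.approx(0.0)
        assert np.isnan(p.iloc[3])

    def test_empty_daytime_raises(self):
        idx = pd.date_range("2021-06-01", periods=4, freq="30min")
        s = pd.Series([-2.0] * 4, index=idx)
        with pytest.raises(InsufficientDataError):
            sf.compute_photosynthesis(s, s, pd.Series(False, index=idx))


class TestFitPhotosynthesis:
    def make_series(self, pmax=1.0, f=0.01, n=300, noise_sd=0.0, seed=0):
        idx = pd.date_range("2021-06-01 06:00", periods=n, freq="30min")
        rng = np.random.default_rng(seed)
        ppfd = pd.Series(np.linspace(5, 1500, n), index=idx)
        p = pd.Series(light_response_model(ppfd.to_numpy(), pmax, f), index=idx)
        if noise_sd:
            p = p + rng.normal(0, noise_sd, n)
        return p, ppfd

    def test_noiseless_recovery(self):
        p, ppfd = self.make_series(pmax=1.0, f=0.01)
        fit = sf.fit_photosynthesis(p, ppfd)
        assert fit["pmax"] == pytest.approx(1.0, rel=1e-6)
        assert fit["f"] == pytest.approx(0.01, rel=1e-6)

    def test_zero_light_gives_zero_photosynthesis(self):
        p, ppfd = self.make_series()
        fit = sf.fit_photosynthesis(p, ppfd)
        assert light_response_model(0.0, fit["pmax"], fit["f"]) == 0.0

    def test_fitted_curve_bounded_by_pmax(self):
        p, ppfd = self.make_series(noise_sd=0.05, seed=3)
        fit = sf.fit_photosynthesis(p, ppfd)
        curve = light_response_model(np.linspace(0, 5000, 200), fit["pmax"],
                                     fit["f"])
        assert (curve <= fit["pmax"] + 1e-12).all()

    def test_min_n_enforced(self):
        p, ppfd = self.make_series(n=10)
        with pytest.raises(InsufficientDataError):
            sf.fit_photosynthesis(p, ppfd)


class TestFitTransport:
    def test_exact_linear_data(self):
        idx = pd.date_range("2021-06-01", periods=50, freq="30min")
        j = pd.Series(np.linspace(0, 100, 50), index=idx)
        t = 0.02 * j
        fit = sf.fit_transport(t, j, min_n=10)
        assert fit["e"] == pytest.approx(0.02, rel=1e-12)
        assert fit.rse == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_slope(self):
        idx = pd.date_range("2021-06-01", periods=3, freq="30min")
        j = pd.Series([1.0, 2.0, 3.0], index=idx)
        t = pd.Series([1.0, 2.0, 4.0], index=idx)
        fit = sf.fit_transport(t, j, min_n=3)
        assert fit["e"] == pytest.approx(17.0 / 14.0, rel=1e-12)

    def test_all_zero_sapflux_undefined(self):
        idx = pd.date_range("2021-06-01", periods=50, freq="30min")
        j = pd.Series(0.0, index=idx)
        with pytest.raises(SingularDesignError):
            sf.fit_transport(j, j, min_n=10)

    def test_closed_form_matches_nls(self):
        rng = np.random.default_rng(1)
        idx = pd.date_range("2021-06-01", periods=200, freq="30min")
        j = pd.Series(rng.uniform(0, 100, 200), index=idx)
        t = pd.Series(0.015 * j + rng.normal(0, 0.1, 200), index=idx)
        closed = sf.fit_transport(t, j, min_n=10)
        est, _, _, _ = sf.nls_fit(lambda x, e: e * x, j.to_numpy(),
                                  t.to_numpy(), np.array([0.001]))
        assert closed["e"] == pytest.approx(est[0], abs=1e-10)


class TestInference:
    def test_t_statistic_is_estimate_over_se(self):
        fit = parameter_inference(np.array([0.5]), np.array([[0.01]]), 100,
                                  "transport", ("e",), 0.1)
        assert fit.t[0] == pytest.approx(5.0)
        assert fit.dof == 99

    def test_dof_counts_parameters(self):
        fit = parameter_inference(np.array([1.0, 2.0]), np.eye(2), 100,
                                  "respiration", ("r0", "b"), 0.1)
        assert fit.dof == 98

    def test_tiny_se_gives_tiny_p(self):
        fit = parameter_inference(np.array([0.5]), np.array([[1e-12]]), 100,
                                  "transport", ("e",), 0.1)
        assert fit.p[0] < 1e-30

    def test_nonpositive_dof_raises(self):
        with pytest.raises(InsufficientDataError):
            parameter_inference(np.array([1.0, 2.0]), np.eye(2), 2,
                                "respiration", ("r0", "b"), 0.0)


class TestNlsContract:
    def test_linear_problem_matches_normal_equations(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 10, 100)
        y = 2.0 + 3.0 * x + rng.normal(0, 0.5, 100)
        est, _, _, _ = sf.nls_fit(lambda x, a, b: a + b * x, x, y,
                                  np.array([0.0, 1.0]))
        design = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        assert np.allclose(est, beta, atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_objective_dominates_coarse_grid(self, seed):
        rng = np.random.default_rng(seed)
        temp = rng.uniform(5, 20, 60)
        r0, b = rng.uniform(0.3, 0.8), rng.uniform(0.05, 0.12)
        y = respiration_model(temp, r0, b) + rng.normal(0, 0.05, 60)

        est, _, _, _ = sf.nls_fit(respiration_model, temp, y,
                                  np.array([0.5, 0.07]),
                                  bounds=(np.array([1e-9, 1e-9]),
                                          np.array([np.inf, np.inf])))
        nls_obj = np.sum((respiration_model(temp, *est) - y) ** 2)

        grid_r0 = np.linspace(0.1, 1.5, 200)
        grid_b = np.linspace(0.01, 0.2, 200)
        pred = grid_r0[:, None, None] * np.exp(grid_b[None, :, None] * temp)
        grid_obj = np.sum((pred - y) ** 2, axis=2).min()
        assert nls_obj <= grid_obj + 1e-12

    def test_restart_from_solution_is_fixed_point(self):
        rng = np.random.default_rng(2)
        temp = rng.uniform(5, 20, 80)
        y = respiration_model(temp, 0.5, 0.09) + rng.normal(0, 0.05, 80)
        est1, _, _, _ = sf.nls_fit(respiration_model, temp, y,
                                   np.array([0.4, 0.07]))
        est2, _, _, _ = sf.nls_fit(respiration_model, temp, y, est1)
        assert np.allclose(est1, est2, rtol=1e-10)


class TestSeasonPartition:
    def test_reconstruction_identity_exact(self, noiseless):
        comp = sf.partition_series(noiseless["table"], noiseless["fits"])
        resid = (-comp["r_prime"] + comp["p_all"] + comp["t_resid"]
                 - comp["tfco2"]).abs().max()
        assert resid <= 1e-12

    def test_noiseless_transport_equals_generator_truth(self, noiseless):
        comp = sf.partition_series(noiseless["table"], noiseless["fits"])
        truth_t = noiseless["truth_components"]["t_true"]
        assert np.allclose(comp["t_resid"], truth_t.loc[comp.index], atol=1e-9)

    def test_all_parameters_significant_on_season(self, noiseless):
        frame = noiseless["fits"].to_frame()
        assert (frame["p"] < 0.001).all()
        assert frame["converged"].all()

    def test_monthly_params_cover_season(self, noiseless):
        assert noiseless["fits"].months() == [6, 7, 8, 9]
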