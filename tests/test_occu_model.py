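"""Likelihood correctness (hand-worked and brute-force oracles), ML
fitting, prediction, and summary estimates for the occupancy model."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from occumap import occu_model as oc
from occumap import survey_io as sio

from conftest import make_sites, simulate_dataset


def one_site_data(history_row, psi, rho, methods=None):
    """Intercept-only ModelData with params giving the stated psi/rho."""
    y = np.array([history_row], dtype=float)
    k = y.shape[1]
    labels = methods or ["m"] * k
    hist = sio.MultiMethodHistory(y, labels, ["s0"])
    sites = make_sites(1)
    spec = oc.ModelSpec()
    data = oc.ModelData(spec, hist, sites)
    n_m = len(hist.methods)
    params = np.array([logit(psi)] + [logit(rho)] * n_m)
    return data, params


class TestNegLogLikelihood:
    def test_detection_history_with_hits(self):
        # z=0 contributes nothing once a detection occurred: L = 0.6*0.5*0.5
        data, params = one_site_data([1, 0], 0.6, 0.5)
        assert oc.neg_log_likelihood(params, data) == pytest.approx(-np.log(0.15), abs=1e-10)

    def test_all_zero_history_mixes_both_states(self):
        # L = 0.6*0.5^3 + 0.4 = 0.475
        data, params = one_site_data([0, 0, 0], 0.6, 0.5)
        assert oc.neg_log_likelihood(params, data) == pytest.approx(-np.log(0.475), abs=1e-10)

    def test_occupied_site_is_bernoulli_product(self):
        data, params = one_site_data([1, 1, 1, 1], 1 - 1e-12, 0.5)
        assert oc.neg_log_likelihood(params, data) == pytest.approx(-np.log(0.0625), abs=1e-6)

    def test_missing_occasions_excluded(self):
        y = np.array([[1.0, np.nan, 0.0]])
        hist = sio.MultiMethodHistory(y, ["m"] * 3, ["s0"])
        data = oc.ModelData(oc.ModelSpec(), hist, make_sites(1))
        params = np.array([logit(0.6), logit(0.5)])
        # same as the 2-occasion [1,0] case
        assert oc.neg_log_likelihood(params, data) == pytest.approx(-np.log(0.15), abs=1e-10)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        worst = 0.0
        for _ in range(30):
            n = int(rng.integers(1, 6))
            k1, k2 = int(rng.integers(1, 5)), int(rng.integers(1, 5))
            sites = make_sites(n, covs=("c1", "c2"), seed=int(rng.integers(1000)))
            y = rng.integers(0, 2, size=(n, k1 + k2)).astype(float)
            y[rng.random(y.shape) < 0.2] = np.nan
            y[np.isnan(y).all(axis=1), 0] = 0.0
            hist = sio.MultiMethodHistory(y, ["a"] * k1 + ["b"] * k2, list(sites["site_id"]))
            data = oc.ModelData(
                oc.ModelSpec(psi_terms=(("c1", 1),), p_terms=("c2",)), hist, sites
            )
            params = rng.normal(size=data.n_params)
            worst = max(
                worst,
                abs(oc.neg_log_likelihood(params, data) - oc.brute_force_likelihood(params, data)),
            )
        assert worst < 1e-10

    def test_gradient_matches_finite_differences(self):
        _, _, _, hist = simulate_dataset(
            8, {"(Intercept)": 0.2, "cov": 0.5}, {"m1": -0.3, "m2": 0.4},
            {"m1": 3, "m2": 2}, seed=3,
        )
        data = oc.ModelData(oc.ModelSpec(psi_terms=(("cov", 1),)), hist,
                            make_sites(8, covs=("cov",), seed=3))
        params = np.random.default_rng(4).normal(size=data.n_params)
        _, grad = oc._nll_and_grad(params, data)
        eps = 1e-6
        for i in range(len(params)):
            e = np.zeros(len(params)); e[i] = eps
            num = (oc.neg_log_likelihood(params + e, data)
                   - oc.neg_log_likelihood(params - e, data)) / (2 * eps)
            assert grad[i] == pytest.approx(num, abs=1e-6)

    def test_invariant_to_site_and_within_method_occasion_permutation(self):
        sites, _, _, hist = simulate_dataset(
            20, {"(Intercept)": 0.0, "cov": 0.8}, {"m1": -0.3, "m2": 0.2},
            {"m1": 3, "m2": 3}, seed=9,
        )
        spec = oc.ModelSpec(psi_terms=(("cov", 1),))
        data = oc.ModelData(spec, hist, sites)
        params = np.random.default_rng(1).normal(size=data.n_params)
        base = oc.neg_log_likelihood(params, data)

        perm = np.random.default_rng(2).permutation(20)
        hist_p = sio.MultiMethodHistory(
            hist.y[perm], hist.occasion_method, [hist.site_ids[i] for i in perm]
        )
        assert oc.neg_log_likelihood(params, oc.ModelData(spec, hist_p, sites)) == pytest.approx(base, abs=1e-9)

        cols = [2, 0, 1, 3, 5, 4]  # shuffle occasions within each method block
        hist_o = sio.MultiMethodHistory(hist.y[:, cols], hist.occasion_method, hist.site_ids)
        assert oc.neg_log_likelihood(params, oc.ModelData(spec, hist_o, sites)) == pytest.approx(base, abs=1e-9)


class TestFit:
    def test_constant_fit_matches_grid_search(self):
        # 5-site toy dataset with a fixed history matrix
        y = np.array(
            [[1, 0, 0, 1], [0, 0, 0, 0], [1, 1, 0, 0], [0, 0, 0, 0], [0, 1, 0, 0]],
            dtype=float,
        )
        hist = sio.MultiMethodHistory(y, ["m"] * 4, [f"s{i}" for i in range(5)])
        sites = make_sites(5)
        fitted = oc.fit(oc.ModelSpec(), hist, sites, n_starts=5, seed=0)
        data = oc.ModelData(oc.ModelSpec(), hist, sites)

        grid = np.arange(0.001, 1.0, 0.001)
        psi_g, rho_g = np.meshgrid(grid, grid, indexing="ij")
        a = (rho_g[None] ** y[:, :, None, None].sum(1)) * \
            ((1 - rho_g)[None] ** (4 - y.sum(1))[:, None, None])
        detected = y.any(axis=1)
        lik = np.where(detected[:, None, None], psi_g[None] * a,
                       psi_g[None] * a + (1 - psi_g)[None])
        nll = -np.log(lik).sum(axis=0)
        i, j = np.unravel_index(nll.argmin(), nll.shape)
        psi_hat, rho_hat = expit(fitted.params[0]), expit(fitted.params[1])
        assert abs(psi_hat - grid[i]) < 0.005
        assert abs(rho_hat - grid[j]) < 0.005

    def test_parameter_recovery_at_large_n(self):
        sites, _, _, hist = simulate_dataset(
            2000, {"(Intercept)": float(logit(0.4))}, {"m": float(logit(0.3))},
            {"m": 5}, seed=21,
        )
        fitted = oc.fit(oc.ModelSpec(), hist, sites, n_starts=3, seed=0)
        assert abs(expit(fitted.params[0]) - 0.4) < 0.05
        assert abs(expit(fitted.params[1]) - 0.3) < 0.05

    def test_saturated_histories_flag_boundary(self):
        y = np.ones((10, 4))
        hist = sio.MultiMethodHistory(y, ["m"] * 4, [f"s{i}" for i in range(10)])
        fitted = oc.fit(oc.ModelSpec(), hist, make_sites(10), n_starts=2, seed=0)
        assert fitted.boundary_flag

    def test_aic_identity(self, constant_fit):
        *_, fitted = constant_fit
        assert fitted.aic == pytest.approx(-2 * fitted.log_lik + 2 * fitted.n_params)

    def test_single_occasion_profile_is_flat_in_psi_rho_product(self):
        y = np.array([[1.0], [0.0], [0.0], [1.0], [0.0]])
        hist = sio.MultiMethodHistory(y, ["m"], [f"s{i}" for i in range(5)])
        with pytest.warns(UserWarning, match="confounded"):
            data_nll = lambda psi, rho: oc.neg_log_likelihood(
                np.array([logit(psi), logit(rho)]),
                oc.ModelData(oc.ModelSpec(), hist, make_sites(5)),
            )
            # pairs with equal product psi*rho give equal likelihood
            assert data_nll(0.8, 0.3) == pytest.approx(data_nll(0.4, 0.6), abs=1e-12)
            oc.fit(oc.ModelSpec(), hist, make_sites(5), n_starts=1, seed=0)

    def test_json_roundtrip(self, tmp_path, constant_fit):
        *_, fitted = constant_fit
        fitted.write(tmp_path / "fit.json")
        back = oc.FittedModel.read(tmp_path / "fit.json")
        np.testing.assert_allclose(back.params, fitted.params)
        assert back.aic == pytest.approx(fitted.aic)
        assert back.spec == fitted.spec


class TestPredict:
    def test_intercept_only_is_half_at_zero(self, constant_fit):
        sites, _, _, fitted = constant_fit
        f = oc.FittedModel(**{**fitted.__dict__, "params": np.array([0.0, 0.0, 0.0])})
        psi, _ = oc.predict_probabilities(f, sites.head(3), standardized=True)
        np.testing.assert_allclose(psi, 0.5)

    def test_inverse_logit_of_linear_predictor(self):
        sites, _, _, hist = simulate_dataset(
            30, {"(Intercept)": 0.0, "cov": 1.0}, {"m": 0.0}, {"m": 3}, seed=2
        )
        fitted = oc.fit(oc.ModelSpec(psi_terms=(("cov", 1),)), hist, sites, n_starts=1, seed=0)
        f = oc.FittedModel(**{**fitted.__dict__, "params": np.array([0.0, 1.0, 0.0])})
        table = sites.head(1).copy()
        table["cov"] = 2.0
        psi, _ = oc.predict_probabilities(f, table, standardized=True)
        assert psi[0] == pytest.approx(expit(2.0))
        table["cov"] = 0.0
        psi, _ = oc.predict_probabilities(f, table, standardized=True)
        assert psi[0] == pytest.approx(0.5)

    def test_missing_covariate_named(self, two_method_dataset):
        sites, _, _, hist = two_method_dataset
        fitted = oc.fit(oc.ModelSpec(psi_terms=(("cov", 1),)), hist, sites, n_starts=1, seed=0)
        with pytest.raises(KeyError, match="cov"):
            oc.predict_probabilities(fitted, sites.drop(columns="cov"))


class TestFittedValues:
    def test_product_and_missing_contract(self):
        y = np.array([[1.0, np.nan], [0.0, 0.0]])
        hist = sio.MultiMethodHistory(y, ["m", "m"], ["s0", "s1"])
        sites = make_sites(2)
        fitted = oc.fit(oc.ModelSpec(), hist, sites, n_starts=1, seed=0)
        f = oc.FittedModel(**{**fitted.__dict__, "params": np.array([logit(0.5), logit(0.4)])})
        y_hat = oc.fitted_values(f, hist, sites)
        assert y_hat[0, 0] == pytest.approx(0.2)
        assert np.isnan(y_hat[0, 1])

    def test_total_expected_matches_total_observed_detections(self, two_method_dataset):
        sites, _, _, hist = two_method_dataset
        fitted = oc.fit(oc.ModelSpec(psi_terms=(("cov", 1),)), hist, sites, n_starts=2, seed=0)
        y_hat = oc.fitted_values(fitted, hist, sites)
        total_obs = np.nansum(hist.y)
        total_exp = np.nansum(y_hat)
        sd = np.sqrt(np.nansum(y_hat * (1 - y_hat)))
        assert abs(total_exp - total_obs) < 3 * sd


class TestMeanEstimates:
    def test_constant_model_mean_equals_estimate(self, constant_fit):
        sites, _, hist, fitted = constant_fit
        means = oc.mean_estimates(fitted, hist, sites)
        psi_row = means[means["quantity"] == "psi"].iloc[0]
        assert psi_row["mean"] == pytest.approx(expit(fitted.params[0]))

    def test_mean_is_average_of_site_estimates(self, two_method_dataset):
        sites, _, _, hist = two_method_dataset
        fitted = oc.fit(oc.ModelSpec(psi_terms=(("cov", 1),)), hist, sites, n_starts=2, seed=0)
        psi, _ = oc.predict_probabilities(fitted, sites, standardized=True)
        means = oc.mean_estimates(fitted, hist, sites)
        psi_row = means[means["quantity"] == "psi"].iloc[0]
        assert psi_row["mean"] == pytest.approx(psi.mean())
        assert psi_row["se"] > 0

    def test_boundary_fit_reports_nan_se(self):
        y = np.ones((8, 3))
        hist = sio.MultiMethodHistory(y, ["m"] * 3, [f"s{i}" for i in range(8)])
        sites = make_sites(8)
        fitted = oc.fit(oc.ModelSpec(), hist, sites, n_starts=1, seed=0)
        if fitted.cov is None:
            means = oc.mean_estimates(fitted, hist, sites)
            assert means["se"].isna().all()
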