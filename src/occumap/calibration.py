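"""Simulation studies validating the estimator and selection pipeline.

These routines quantify, under the synthetic generating model, the
properties a user should expect of the method: agreement of the
vectorised likelihood with brute-force latent-state enumeration,
agreement of the optimiser with an exhaustive grid search, Wald
confidence-interval coverage and bias, how often AIC dredging retains
the generating model, uniformity of bootstrap goodness-of-fit p-values
under a well-specified model, and convergence of stacked-richness maps
with sampling effort.  Each study is a pure function of its seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from . import gof, mapping, model_selection as ms, occu_model as oc
from . import covariate_prep as cp
from . import survey_io as sio
from . import synthetic_data as sd


def _make_sites(n: int, covs: tuple[str, ...], rng: np.random.Generator) -> pd.DataFrame:
    table = {"site_id": [f"s{i}" for i in range(n)], "x": np.zeros(n), "y": np.zeros(n)}
    for c in covs:
        table[c] = rng.normal(size=n)
    return pd.DataFrame(table)


def _seed(rng: np.random.Generator) -> int:
    return int(rng.integers(2**31))


def likelihood_oracle_deviation(n_instances: int = 100, seed: int = 0) -> float:
    """Max |NLL - brute-force NLL| over random small two-method instances."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(1, 6))
        k1 = int(rng.integers(1, 5))
        k2 = int(rng.integers(1, 10 - k1))
        sites = _make_sites(n, ("c1", "c2"), rng)
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
    return worst


#: Fixed 5-site, 4-occasion toy detection matrix for the grid-search check.
TOY_HISTORY = np.array(
    [[1, 0, 0, 1], [0, 0, 0, 0], [1, 1, 0, 0], [0, 0, 0, 0], [0, 1, 0, 0]],
    dtype=float,
)


def constant_mle_vs_grid(seed: int = 0, resolution: float = 0.001) -> dict[str, float]:
    """Distance between the constant-model MLE and an exhaustive grid search."""
    hist = sio.MultiMethodHistory(TOY_HISTORY, ["m"] * 4, [f"s{i}" for i in range(5)])
    rng = np.random.default_rng(seed)
    sites = _make_sites(5, (), rng)
    fitted = oc.fit(oc.ModelSpec(), hist, sites, n_starts=5, seed=seed)

    grid = np.arange(resolution, 1.0, resolution)
    psi_g, rho_g = np.meshgrid(grid, grid, indexing="ij")
    y = TOY_HISTORY
    k = y.shape[1]
    hits = y.sum(axis=1)
    a = rho_g[None] ** hits[:, None, None] * (1 - rho_g)[None] ** (k - hits)[:, None, None]
    detected = y.any(axis=1)
    lik = np.where(detected[:, None, None], psi_g[None] * a, psi_g[None] * a + (1 - psi_g)[None])
    nll = -np.log(lik).sum(axis=0)
    i, j = np.unravel_index(nll.argmin(), nll.shape)
    return {
        "psi_deviation": abs(float(expit(fitted.params[0])) - grid[i]),
        "rho_deviation": abs(float(expit(fitted.params[1])) - grid[j]),
    }


def coverage_study(
    n_rep: int = 200, n_sites: int = 300, seed: int = 0
) -> dict[str, float]:
    """95% Wald CI coverage per coefficient and bias of mean occupancy.

    Data are generated from psi ~ intercept + one covariate with two
    sampling methods of two occasions each (K=4) at interior parameter
    values, the design of a typical well-determined species.
    """
    rng = np.random.default_rng(seed)
    true = np.array([-0.4, 1.0, -0.8, 0.4])  # beta0, beta1, gamma_m1, gamma_m2
    truth = sd.TrueParameters(
        beta={"(Intercept)": true[0], "cov": true[1]},
        gamma_method={"m1": true[2], "m2": true[3]},
    )
    design = sd.SurveyDesign(methods=["m1", "m2"], occasions_per_method={"m1": 2, "m2": 2})
    spec = oc.ModelSpec(psi_terms=(("cov", 1),))
    covered = np.zeros(4)
    used = 0
    biases = []
    for r in range(n_rep):
        sites = _make_sites(n_sites, ("cov",), rng)
        records = sd.simulate_surveys(sites, truth, design, seed=_seed(rng))
        hist = sio.build_history(records, "species", {"m1": "daily", "m2": "daily"})
        fitted = oc.fit(spec, hist, sites, n_starts=2, seed=r)
        if fitted.cov is None:
            continue
        used += 1
        covered += np.abs(fitted.params - true) < 1.96 * fitted.se
        psi_hat, _ = oc.predict_probabilities(fitted, sites, standardized=True)
        biases.append(psi_hat.mean() - truth.psi(sites).mean())
    out = {
        f"coverage_{name}": covered[i] / used
        for i, name in enumerate(["psi_intercept", "psi_slope", "p_method1", "p_method2"])
    }
    out["psi_mean_bias"] = float(np.mean(biases))
    out["n_used"] = used
    return out


def selection_retention(
    n_rep: int = 100, n_sites: int = 500, effect: float = 1.0, seed: int = 0
) -> float:
    """Fraction of replicates whose delta-AIC<6 set contains the
    generating 2-covariate occupancy model, dredging 4 candidates."""
    rng = np.random.default_rng(seed)
    truth = sd.TrueParameters(
        beta={"(Intercept)": -0.3, "c1": effect, "c2": -effect},
        gamma_method={"m1": -0.4, "m2": 0.2},
    )
    design = sd.SurveyDesign(methods=["m1", "m2"], occasions_per_method={"m1": 2, "m2": 2})
    specs = ms.enumerate_models(["c1", "c2", "c3", "c4"])
    generating = oc.ModelSpec(psi_terms=(("c1", 1), ("c2", 1)))
    hits = 0
    for r in range(n_rep):
        sites = _make_sites(n_sites, ("c1", "c2", "c3", "c4"), rng)
        records = sd.simulate_surveys(sites, truth, design, seed=_seed(rng))
        hist = sio.build_history(records, "species", {"m1": "daily", "m2": "daily"})
        fits = [oc.fit(s, hist, sites, n_starts=1, seed=r) for s in specs]
        ranked = ms.rank_by_aic(fits)
        hits += any(rec.spec == generating for rec in ms.retained_set(ranked))
    return hits / n_rep


def gof_calibration(
    n_outer: int = 50, b: int = 100, n_sites: int = 100, seed: int = 0
) -> dict[str, float]:
    """KS p-values of bootstrap GoF p-values against uniform, under a
    correctly specified one-covariate occupancy model."""
    rng = np.random.default_rng(seed)
    truth = sd.TrueParameters(
        beta={"(Intercept)": 0.2, "cov": 1.0}, gamma_method={"m1": -0.5, "m2": 0.0}
    )
    design = sd.SurveyDesign(methods=["m1", "m2"], occasions_per_method={"m1": 2, "m2": 2})
    spec = oc.ModelSpec(psi_terms=(("cov", 1),))
    pvals = {k: [] for k in gof.STATISTICS}
    for r in range(n_outer):
        sites = _make_sites(n_sites, ("cov",), rng)
        records = sd.simulate_surveys(sites, truth, design, seed=_seed(rng))
        hist = sio.build_history(records, "species", {"m1": "daily", "m2": "daily"})
        fitted = oc.fit(spec, hist, sites, n_starts=1, seed=r)
        result = gof.parametric_bootstrap(fitted, hist, sites, b=b, seed=_seed(rng))
        for k in gof.STATISTICS:
            pvals[k].append(result.p_value[k])
    return {
        f"ks_p_{k}": float(stats.kstest(np.asarray(v), "uniform").pvalue)
        for k, v in pvals.items()
    }


def _richness_species() -> list[sd.TrueParameters]:
    return [
        sd.TrueParameters({"(Intercept)": 0.4, "grad": 1.0}, {"m": -0.2}, species_id="sp_a"),
        sd.TrueParameters({"(Intercept)": -0.5, "grad": -0.8, "patch": 0.6}, {"m": 0.1},
                          species_id="sp_b"),
        sd.TrueParameters({"(Intercept)": -1.0, "patch": 1.2}, {"m": -0.5}, species_id="sp_c"),
    ]


def richness_error_by_effort(
    site_counts: tuple[int, ...] = (100, 300, 1000),
    n_rep: int = 20,
    seed: int = 0,
    grid_size: int = 40,
) -> dict[int, float]:
    """Mean absolute cell error of estimated vs true stacked richness.

    Three species with known covariate responses are surveyed with one
    method over 4 occasions at each sampling effort; each species'
    generating specification is fitted and predicted to the landscape,
    the surfaces summed, and the error against the true summed psi
    surface averaged over cells and replicates.
    """
    rng = np.random.default_rng(seed)
    species = _richness_species()
    design = sd.SurveyDesign(methods=["m"], occasions_per_method={"m": 4})
    errors: dict[int, list[float]] = {n: [] for n in site_counts}
    for r in range(n_rep):
        stack = sd.gen_landscape(grid_size, grid_size, ["grad", "patch"], seed=_seed(rng))
        cells = pd.DataFrame({c: stack.layers[c].ravel() for c in stack.names})
        true_richness = sum(t.psi(cells) for t in species).reshape(stack.shape)
        for n in site_counts:
            sites = sd.gen_sites(stack, n, seed=_seed(rng))
            std_sites, scaling = cp.standardize(sites)
            surfaces = []
            for truth in species:
                records = sd.simulate_surveys(sites, truth, design, seed=_seed(rng))
                hist = sio.build_history(records, truth.species_id, {"m": "daily"})
                spec = oc.ModelSpec(
                    psi_terms=tuple((c, 1) for c in truth.beta if c != "(Intercept)")
                )
                fitted = oc.fit(spec, hist, std_sites, n_starts=1, seed=r, scaling=scaling)
                surfaces.append(mapping.predict_raster(fitted, stack))
            est, _ = mapping.stack_richness(surfaces)
            errors[n].append(float(np.nanmean(np.abs(est - true_richness))))
    return {n: float(np.mean(v)) for n, v in errors.items()}
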