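"""Single-season occupancy-detection model with logit links.

The model treats each site's data as arising from two Bernoulli
processes: a latent presence state

    z_i ~ Bernoulli(psi_i),   logit(psi_i) = x_i' beta

and, conditional on presence, per-occasion detections

    y_ij | z_i ~ Bernoulli(z_i * rho_ij),
    logit(rho_ij) = gamma_{m(j)} + w_i' delta

where m(j) is the sampling method of occasion j (an observation-level
factor, coded as one intercept per method) and w_i are site-level
detection covariates.  Marginalising z_i gives the site likelihood

    L_i = psi_i * prod_j rho_ij^y_ij (1-rho_ij)^(1-y_ij)
          + (1 - psi_i) * 1[all observed y_ij = 0]

with missing occasions dropped from the product.  Estimation is by
maximum likelihood on the unconstrained logit-scale coefficients, with
standard errors from the inverse observed information.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

from .covariate_prep import ScalingConstants, build_design, design_column_names
from .survey_io import MultiMethodHistory
from .synthetic_data import NO_QUADRATIC, term_name

_ETA_CLIP = 35.0  # |logit| beyond which probabilities are numerically 0/1
BOUNDARY_TOL = 1e-4


@dataclass(frozen=True)
class ModelSpec:
    """Covariate structure of one candidate model.

    ``psi_terms``: (covariate, degree) pairs for occupancy, degree 2
    only together with degree 1 and never for the no-quadratic set.
    ``p_terms``: degree-1 detection covariates.  The sampling method is
    included as an observation-level factor when ``p_has_method_factor``.
    """

    psi_terms: tuple[tuple[str, int], ...] = ()
    p_terms: tuple[str, ...] = ()
    p_has_method_factor: bool = True

    def __post_init__(self) -> None:
        linear = {c for c, d in self.psi_terms if d == 1}
        for cov, degree in self.psi_terms:
            if degree == 2 and cov in NO_QUADRATIC:
                raise ValueError(f"quadratic term not permitted for '{cov}'")
            if degree == 2 and cov not in linear:
                raise ValueError(f"quadratic '{cov}' requires its linear term")

    @property
    def n_covariate_terms(self) -> int:
        """Covariate terms counted for the detections cap (intercepts and
        the method factor excluded)."""
        return len(self.psi_terms) + len(self.p_terms)

    def label(self) -> str:
        psi = " + ".join(term_name(c, d) for c, d in self.psi_terms) or "1"
        p_parts = (["method"] if self.p_has_method_factor else ["1"]) + list(self.p_terms)
        return f"psi({psi}) p({' + '.join(p_parts)})"

    def to_json(self) -> dict:
        return {
            "psi_terms": [list(t) for t in self.psi_terms],
            "p_terms": list(self.p_terms),
            "p_has_method_factor": self.p_has_method_factor,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "ModelSpec":
        return cls(
            tuple((c, int(d)) for c, d in obj["psi_terms"]),
            tuple(obj["p_terms"]),
            bool(obj["p_has_method_factor"]),
        )


NULL_SPEC = ModelSpec()


class ModelData:
    """Design matrices and history aligned for likelihood evaluation.

    Sites with zero non-missing occasions are excluded (with a warning);
    ``covariates`` must already be on the standardised scale.
    """

    def __init__(self, spec: ModelSpec, history: MultiMethodHistory, covariates: pd.DataFrame):
        cov = covariates.set_index("site_id").loc[history.site_ids].reset_index()
        y = history.y
        observed = ~np.isnan(y)
        keep = observed.any(axis=1)
        if not keep.all():
            warnings.warn(
                f"excluding {(~keep).sum()} site(s) with no non-missing occasions",
                stacklevel=2,
            )
        self.y = np.where(np.isnan(y[keep]), 0.0, y[keep])
        self.observed = observed[keep]
        self.site_ids = [s for s, k in zip(history.site_ids, keep) if k]
        self.methods = history.methods
        self.occasion_method = list(history.occasion_method)
        self.method_idx = np.array([self.methods.index(m) for m in history.occasion_method])
        self.x_psi = build_design(list(spec.psi_terms), cov.loc[keep])
        self.x_p = (
            cov.loc[keep, list(spec.p_terms)].to_numpy(dtype=float)
            if spec.p_terms
            else np.empty((int(keep.sum()), 0))
        )
        if not np.isfinite(self.x_p).all():
            raise ValueError("non-finite detection covariate values")
        self.spec = spec
        self.n_methods = len(self.methods) if spec.p_has_method_factor else 1
        self.detected = (self.y * self.observed).any(axis=1)

    @property
    def n_sites(self) -> int:
        return self.y.shape[0]

    @property
    def n_params(self) -> int:
        return self.x_psi.shape[1] + self.n_methods + self.x_p.shape[1]

    def split(self, params: np.ndarray):
        kb = self.x_psi.shape[1]
        beta = params[:kb]
        gamma_m = params[kb: kb + self.n_methods]
        delta = params[kb + self.n_methods:]
        return beta, gamma_m, delta

    def probabilities(self, params: np.ndarray):
        beta, gamma_m, delta = self.split(params)
        psi = expit(np.clip(self.x_psi @ beta, -_ETA_CLIP, _ETA_CLIP))
        if self.spec.p_has_method_factor:
            eta = gamma_m[self.method_idx][None, :]
        else:
            eta = np.full((1, len(self.method_idx)), gamma_m[0])
        eta = eta + (self.x_p @ delta)[:, None]
        rho = expit(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
        return psi, rho

    def param_names(self) -> list[str]:
        psi_names = ["psi:" + n for n in design_column_names(list(self.spec.psi_terms))]
        if self.spec.p_has_method_factor:
            p_names = [f"p:{m}" for m in self.methods]
        else:
            p_names = ["p:(Intercept)"]
        p_names += [f"p:{c}" for c in self.spec.p_terms]
        return psi_names + p_names


def neg_log_likelihood(params: np.ndarray, data: ModelData) -> float:
    nll, _ = _nll_and_grad(params, data)
    return nll


def _nll_and_grad(params: np.ndarray, data: ModelData) -> tuple[float, np.ndarray]:
    psi, rho = data.probabilities(params)
    obs = data.observed
    y = data.y
    # log prod_j Bern(y_ij | rho_ij) over observed occasions
    with np.errstate(divide="ignore", invalid="ignore"):
        log_terms = np.where(y == 1, np.log(rho), np.log1p(-rho))
    log_a = np.where(obs, log_terms, 0.0).sum(axis=1)
    a = np.exp(log_a)

    detected = data.detected
    lik_undet = psi * a + (1.0 - psi)
    log_lik = np.where(detected, np.log(psi) + log_a, np.log(lik_undet))
    nll = -float(log_lik.sum())

    # gradient
    resid = np.where(obs, y - rho, 0.0)           # (n, J)
    c = np.where(detected, 1.0, psi * a / lik_undet)   # posterior P(z=1 | y)
    g_beta_site = np.where(
        detected, 1.0 - psi, psi * (1.0 - psi) * (a - 1.0) / lik_undet
    )
    grad_beta = -(data.x_psi * g_beta_site[:, None]).sum(axis=0)

    cr = resid * c[:, None]                        # (n, J)
    if data.spec.p_has_method_factor:
        grad_gamma = np.array(
            [-cr[:, data.method_idx == m].sum() for m in range(data.n_methods)]
        )
    else:
        grad_gamma = np.array([-cr.sum()])
    row_sums = cr.sum(axis=1)
    grad_delta = -(data.x_p * row_sums[:, None]).sum(axis=0)
    return nll, np.concatenate([grad_beta, grad_gamma, grad_delta])


def brute_force_likelihood(params: np.ndarray, data: ModelData) -> float:
    """Oracle negative log-likelihood by explicit latent-state enumeration.

    Sums over z_i in {0, 1} per site with plain Python loops and no
    algebraic shortcut; intended for test instances of <= 20 sites.
    """
    if data.n_sites > 20:
        raise ValueError("brute-force oracle limited to <= 20 sites")
    psi, rho = data.probabilities(params)
    total = 0.0
    for i in range(data.n_sites):
        site_lik = 0.0
        for z in (0, 1):
            prob_z = psi[i] if z == 1 else 1.0 - psi[i]
            cond = 1.0
            for j in range(data.y.shape[1]):
                if not data.observed[i, j]:
                    continue
                p_det = z * rho[i, j]
                cond *= p_det if data.y[i, j] == 1 else 1.0 - p_det
            site_lik += prob_z * cond
        total += np.log(site_lik)
    return -total


@dataclass
class FittedModel:
    """Maximum-likelihood fit of one :class:`ModelSpec`.

    Coefficients are on the logit scale in the order psi design columns,
    method intercepts, detection slopes; ``cov`` is the inverse observed
    information (None when singular).
    """

    spec: ModelSpec
    params: np.ndarray
    param_names: list[str]
    cov: np.ndarray | None
    log_lik: float
    n_params: int
    converged: bool
    boundary_flag: bool
    methods: list[str]
    scaling: ScalingConstants | None = None
    n_sites: int = 0
    species: str = ""

    @property
    def aic(self) -> float:
        return -2.0 * self.log_lik + 2.0 * self.n_params

    @property
    def se(self) -> np.ndarray:
        if self.cov is None:
            return np.full(len(self.params), np.nan)
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.params, "se": self.se}, index=self.param_names
        )

    def to_json(self) -> dict:
        return {
            "species": self.species,
            "spec": self.spec.to_json(),
            "params": self.params.tolist(),
            "param_names": self.param_names,
            "cov": None if self.cov is None else self.cov.tolist(),
            "log_lik": self.log_lik,
            "n_params": self.n_params,
            "aic": self.aic,
            "converged": self.converged,
            "boundary_flag": self.boundary_flag,
            "methods": self.methods,
            "n_sites": self.n_sites,
            "scaling": None if self.scaling is None else self.scaling.to_json(),
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=2))

    @classmethod
    def from_json(cls, obj: dict) -> "FittedModel":
        return cls(
            spec=ModelSpec.from_json(obj["spec"]),
            params=np.asarray(obj["params"]),
            param_names=list(obj["param_names"]),
            cov=None if obj["cov"] is None else np.asarray(obj["cov"]),
            log_lik=obj["log_lik"],
            n_params=obj["n_params"],
            converged=obj["converged"],
            boundary_flag=obj["boundary_flag"],
            methods=list(obj["methods"]),
            scaling=None if obj["scaling"] is None else ScalingConstants.from_json(obj["scaling"]),
            n_sites=obj.get("n_sites", 0),
            species=obj.get("species", ""),
        )

    @classmethod
    def read(cls, path: str | Path) -> "FittedModel":
        return cls.from_json(json.loads(Path(path).read_text()))


def _initial_params(data: ModelData) -> np.ndarray:
    """Moment-style starting values: naive occupancy for the psi
    intercept, per-method detection frequency at detected sites for the
    method intercepts, zeros elsewhere."""
    naive = float(np.clip(data.detected.mean(), 0.05, 0.95))
    beta0 = np.zeros(data.x_psi.shape[1])
    beta0[0] = np.log(naive / (1 - naive))
    gammas = []
    det_rows = data.detected
    for m in range(data.n_methods):
        if data.spec.p_has_method_factor:
            cols = data.method_idx == m
        else:
            cols = np.ones(len(data.method_idx), dtype=bool)
        sub_obs = data.observed[det_rows][:, cols]
        sub_y = data.y[det_rows][:, cols]
        freq = sub_y[sub_obs].mean() if sub_obs.sum() > 0 else 0.5
        freq = float(np.clip(freq, 0.05, 0.95))
        gammas.append(np.log(freq / (1 - freq)))
    delta0 = np.zeros(data.x_p.shape[1])
    return np.concatenate([beta0, np.array(gammas), delta0])


def _numeric_hessian(params: np.ndarray, data: ModelData, eps: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian of the NLL from the analytic gradient."""
    k = len(params)
    hess = np.empty((k, k))
    for i in range(k):
        step = eps * max(1.0, abs(params[i]))
        up = params.copy()
        dn = params.copy()
        up[i] += step
        dn[i] -= step
        _, g_up = _nll_and_grad(up, data)
        _, g_dn = _nll_and_grad(dn, data)
        hess[i] = (g_up - g_dn) / (2 * step)
    return 0.5 * (hess + hess.T)


def fit(
    spec: ModelSpec,
    history: MultiMethodHistory,
    covariates: pd.DataFrame,
    n_starts: int = 5,
    seed: int = 0,
    scaling: ScalingConstants | None = None,
    start: np.ndarray | None = None,
) -> FittedModel:
    """Fit by quasi-Newton maximisation with jittered multi-starts.

    ``covariates`` must be on the standardised scale used to build the
    designs; pass ``scaling`` so predictions can standardise raw inputs
    the same way.  ``start`` warm-starts the first optimisation (the
    remaining ``n_starts - 1`` starts are jittered around the default
    initial values).
    """
    data = ModelData(spec, history, covariates)
    if data.observed.sum(axis=1).max() < 2:
        warnings.warn("single-occasion design: psi and rho are confounded", stacklevel=2)
    rng = np.random.default_rng(seed)
    base = _initial_params(data)
    starts = [base if start is None else np.asarray(start, dtype=float)]
    for _ in range(max(0, n_starts - 1)):
        starts.append(base + rng.normal(0, 0.5, size=len(base)))

    best = None
    any_converged = False
    for x0 in starts:
        res = optimize.minimize(
            _nll_and_grad,
            x0,
            args=(data,),
            jac=True,
            method="L-BFGS-B",
            options={"ftol": 1e-10, "gtol": 1e-6, "maxiter": 500},
        )
        any_converged = any_converged or res.success
        if best is None or res.fun < best.fun:
            best = res

    params = best.x
    psi, rho = data.probabilities(params)
    near = lambda p: p.size > 0 and np.all((p < BOUNDARY_TOL) | (p > 1 - BOUNDARY_TOL))
    boundary = bool(near(psi) or near(rho[data.observed]))

    cov = None
    try:
        hess = _numeric_hessian(params, data)
        if np.isfinite(hess).all() and np.linalg.cond(hess) < 1e10:
            cov = np.linalg.inv(hess)
            if not (np.diag(cov) >= 0).all():
                cov = None
                boundary = True
        else:
            boundary = True
    except np.linalg.LinAlgError:
        boundary = True

    return FittedModel(
        spec=spec,
        params=params,
        param_names=data.param_names(),
        cov=cov,
        log_lik=-float(best.fun),
        n_params=data.n_params,
        converged=bool(any_converged),
        boundary_flag=boundary,
        methods=data.methods,
        scaling=scaling,
        n_sites=data.n_sites,
        species=history.species,
    )


def _standardize_raw(fitted: FittedModel, covariates: pd.DataFrame) -> pd.DataFrame:
    out = covariates.copy()
    if fitted.scaling is not None:
        for c in covariates.columns:
            if c in fitted.scaling.mean:
                out[c] = fitted.scaling.apply(covariates[c], c)
    return out


def predict_probabilities(
    fitted: FittedModel, covariates: pd.DataFrame, standardized: bool = False
) -> tuple[np.ndarray, pd.DataFrame]:
    """psi per row and rho per row x method, from raw-scale covariates.

    Raw values are standardised with the fitting-time constants before
    the linear predictor (skip with ``standardized=True``).
    """
    needed = {c for c, _ in fitted.spec.psi_terms} | set(fitted.spec.p_terms)
    missing = needed - set(covariates.columns)
    if missing:
        raise KeyError(f"covariates missing from input: {sorted(missing)}")
    table = covariates if standardized else _standardize_raw(fitted, covariates)
    kb = len(fitted.spec.psi_terms) + 1
    beta = fitted.params[:kb]
    n_m = len(fitted.methods) if fitted.spec.p_has_method_factor else 1
    gamma_m = fitted.params[kb: kb + n_m]
    delta = fitted.params[kb + n_m:]

    x_psi = build_design(list(fitted.spec.psi_terms), table)
    psi = expit(np.clip(x_psi @ beta, -_ETA_CLIP, _ETA_CLIP))
    x_p = (
        table[list(fitted.spec.p_terms)].to_numpy(dtype=float)
        if fitted.spec.p_terms
        else np.empty((len(table), 0))
    )
    slope_part = x_p @ delta
    rho = {}
    for k, m in enumerate(fitted.methods):
        g = gamma_m[k] if fitted.spec.p_has_method_factor else gamma_m[0]
        rho[m] = expit(np.clip(g + slope_part, -_ETA_CLIP, _ETA_CLIP))
    return psi, pd.DataFrame(rho)


def fitted_values(
    fitted: FittedModel, history: MultiMethodHistory, covariates: pd.DataFrame
) -> np.ndarray:
    """Expected detections y_hat_ij = psi_i * rho_ij (NaN where missing)."""
    data = ModelData(fitted.spec, history, covariates)
    psi, rho = data.probabilities(fitted.params)
    y_hat = psi[:, None] * rho
    return np.where(data.observed, y_hat, np.nan)


def simulate_history(
    fitted: FittedModel,
    history: MultiMethodHistory,
    covariates: pd.DataFrame,
    rng: np.random.Generator,
) -> MultiMethodHistory:
    """Parametric simulation from the fitted model on the same design,
    preserving the observed missingness pattern."""
    data = ModelData(fitted.spec, history, covariates)
    psi, rho = data.probabilities(fitted.params)
    z = rng.random(data.n_sites) < psi
    y = ((rng.random(rho.shape) < rho) & z[:, None]).astype(float)
    y[~data.observed] = np.nan
    return MultiMethodHistory(y, data.occasion_method, data.site_ids, species=fitted.species)


def mean_estimates(
    fitted: FittedModel, history: MultiMethodHistory, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Mean occupancy and per-method mean detectability at fitted sites.

    The mean of site-level psi_hat (and of rho_hat over each method's
    observed site-occasions) with delta-method standard errors from the
    coefficient covariance; the spread (sd) of the site-level estimates
    is reported as a secondary column.  SEs are NaN for boundary fits
    without a valid covariance.
    """
    data = ModelData(fitted.spec, history, covariates)
    psi, rho = data.probabilities(fitted.params)
    rows = []

    def delta_se(grad_fn):
        if fitted.cov is None:
            return np.nan
        g = grad_fn()
        return float(np.sqrt(max(g @ fitted.cov @ g, 0.0)))

    kb = data.x_psi.shape[1]

    def psi_grad():
        g = np.zeros(len(fitted.params))
        w = psi * (1 - psi)
        g[:kb] = (data.x_psi * w[:, None]).mean(axis=0)
        return g

    rows.append(
        {
            "quantity": "psi",
            "method": "",
            "mean": float(psi.mean()),
            "se": delta_se(psi_grad),
            "spread": float(psi.std(ddof=1)) if len(psi) > 1 else 0.0,
        }
    )
    for k, m in enumerate(data.methods):
        cols = data.method_idx == k if fitted.spec.p_has_method_factor else slice(None)
        cells = data.observed[:, cols]
        vals = rho[:, cols][cells]
        if vals.size == 0:
            continue

        def rho_grad(k=k, cols=cols, cells=cells):
            g = np.zeros(len(fitted.params))
            w = (rho[:, cols] * (1 - rho[:, cols]))[cells]
            if fitted.spec.p_has_method_factor:
                g[kb + k] = w.mean()
            else:
                g[kb] = w.mean()
            if data.x_p.shape[1]:
                xp = np.broadcast_to(
                    data.x_p[:, None, :], (data.n_sites, cells.shape[1], data.x_p.shape[1])
                )[cells]
                g[kb + data.n_methods:] = (xp * w[:, None]).mean(axis=0)
            return g

        rows.append(
            {
                "quantity": "rho",
                "method": m,
                "mean": float(vals.mean()),
                "se": delta_se(rho_grad),
                "spread": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)
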