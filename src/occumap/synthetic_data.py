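"""Synthetic landscapes, sites and multi-method survey records.

Generates data with the statistical structure the occupancy-detection
model assumes — smooth, correlated covariate surfaces; sites with known
covariate values; latent presence/absence states; and per-method raw
detection events — so the whole pipeline is testable with known truth.

The generating model is the standard zero-inflated Bernoulli pair

    z_i ~ Bernoulli(psi_i),      y_ij | z_i ~ Bernoulli(z_i * rho_ij)

with logit-linear covariate effects on occupancy (optionally quadratic)
and a per-method intercept plus optional site-covariate slopes on
detection.  Detection covariates are site-level constants broadcast to
all occasions; no per-occasion weather effects are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import expit

from .rasters import GridStack

QUAD_SUFFIX = "^2"


def term_name(covariate: str, degree: int = 1) -> str:
    """Canonical name of a model term: ``rugged`` or ``rugged^2``."""
    if degree == 1:
        return covariate
    if degree == 2:
        return covariate + QUAD_SUFFIX
    raise ValueError(f"unsupported degree {degree}")


def parse_term(term: str) -> tuple[str, int]:
    if term.endswith(QUAD_SUFFIX):
        return term[: -len(QUAD_SUFFIX)], 2
    return term, 1


@dataclass
class TrueParameters:
    """Generating coefficients for one species, on the logit scale.

    ``beta`` maps occupancy terms (``"(Intercept)"``, covariate names,
    ``"<cov>^2"``) to coefficients; ``gamma_method`` maps method name to
    its detection intercept; ``gamma_slopes`` maps detection covariates
    (degree 1) to slopes shared across methods.
    """

    beta: dict[str, float]
    gamma_method: dict[str, float]
    gamma_slopes: dict[str, float] = field(default_factory=dict)
    species_id: str = "species"

    def __post_init__(self) -> None:
        if not self.gamma_method:
            raise ValueError("at least one method detection intercept is required")

    def psi(self, covariates: pd.DataFrame) -> np.ndarray:
        """Occupancy probability per site given site covariate values."""
        eta = np.full(len(covariates), self.beta.get("(Intercept)", 0.0))
        for term, coef in self.beta.items():
            if term == "(Intercept)":
                continue
            cov, degree = parse_term(term)
            if cov not in covariates.columns:
                raise KeyError(f"occupancy term '{term}' not resolvable: no covariate '{cov}'")
            eta = eta + coef * covariates[cov].to_numpy() ** degree
        return expit(eta)

    def rho(self, covariates: pd.DataFrame, method: str) -> np.ndarray:
        """Per-sub-event detection probability per site for one method."""
        if method not in self.gamma_method:
            raise KeyError(f"no detection intercept for method '{method}'")
        eta = np.full(len(covariates), self.gamma_method[method])
        for cov, coef in self.gamma_slopes.items():
            if cov not in covariates.columns:
                raise KeyError(f"detection term '{cov}' not resolvable")
            eta = eta + coef * covariates[cov].to_numpy()
        return expit(eta)


@dataclass
class SurveyDesign:
    """Repeat-survey layout: which methods, how many occasions each.

    ``occasions_per_method`` gives the number of repeat occasions per
    method (3-4 for daily trap/search methods, 5 for weekly camera
    occasions); ``sub_events_per_occasion`` the number of raw events
    within one occasion (e.g. three ten-minute bird surveys per day),
    defaulting to 1 for every method.
    """

    methods: list[str]
    occasions_per_method: dict[str, int]
    sub_events_per_occasion: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for m in self.methods:
            k = self.occasions_per_method.get(m, 0)
            if k < 1:
                raise ValueError(f"method '{m}' needs >= 1 occasions, got {k}")
            if self.sub_events_per_occasion.setdefault(m, 1) < 1:
                raise ValueError(f"method '{m}' needs >= 1 sub-events")


def default_design() -> SurveyDesign:
    """Three daily methods (4, 3, 3 nights/days) plus 5 weekly camera occasions."""
    return SurveyDesign(
        methods=["cage_trap", "camera", "pit_trap", "spotlight"],
        occasions_per_method={"cage_trap": 4, "camera": 5, "pit_trap": 4, "spotlight": 3},
    )


# ----------------------------------------------------------------------
# Landscape generation
# ----------------------------------------------------------------------

def gen_landscape(
    n_rows: int,
    n_cols: int,
    covariate_names: list[str],
    correlation: np.ndarray | None = None,
    seed: int = 0,
    smooth_sigma: float = 3.0,
    cell_size: float = 100.0,
) -> GridStack:
    """Correlated, spatially smooth Gaussian covariate surfaces.

    Independent white-noise fields are smoothed with a Gaussian kernel
    (``smooth_sigma`` cells), rescaled to unit marginal variance, and
    mixed through the Cholesky factor of ``correlation`` so cellwise
    cross-covariate correlation matches the target while neighbouring
    cells stay similar.
    """
    k = len(covariate_names)
    if correlation is None:
        correlation = np.eye(k)
    correlation = np.asarray(correlation, dtype=float)
    if correlation.shape != (k, k):
        raise ValueError(f"correlation must be {k}x{k}, got {correlation.shape}")
    if not np.allclose(correlation, correlation.T):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(correlation), 1.0):
        raise ValueError("correlation matrix must have unit diagonal")
    try:
        chol = np.linalg.cholesky(correlation)
    except np.linalg.LinAlgError as exc:
        eigmin = float(np.linalg.eigvalsh(correlation).min())
        raise ValueError(
            f"correlation matrix is not positive-definite (min eigenvalue {eigmin:.3g})"
        ) from exc

    rng = np.random.default_rng(seed)
    fields = rng.standard_normal((k, n_rows, n_cols))
    if smooth_sigma > 0 and min(n_rows, n_cols) > 1:
        for i in range(k):
            f = ndimage.gaussian_filter(fields[i], sigma=smooth_sigma, mode="reflect")
            sd = f.std()
            fields[i] = (f - f.mean()) / sd if sd > 0 else f
    mixed = np.einsum("ij,jrc->irc", chol, fields)
    layers = {name: mixed[i] for i, name in enumerate(covariate_names)}
    return GridStack(layers, cell_size=cell_size, meta={"seed": seed, "smooth_sigma": smooth_sigma})


def gen_sites(stack: GridStack, n_sites: int, seed: int = 0) -> pd.DataFrame:
    """Place sites at distinct unmasked cell centres, copying cell values.

    Returns a site covariate table with columns ``site_id, x, y`` plus
    one column per covariate.
    """
    finite = np.ones(stack.shape, dtype=bool)
    for arr in stack.layers.values():
        finite &= np.isfinite(arr)
    flat = np.flatnonzero(finite.ravel())
    if n_sites > flat.size:
        raise ValueError(f"n_sites={n_sites} exceeds {flat.size} available cells")
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(flat, size=n_sites, replace=False))
    rows, cols = np.unravel_index(chosen, stack.shape)
    xx, yy = stack.cell_centers()
    table = {
        "site_id": [f"site_{i:04d}" for i in range(n_sites)],
        "x": xx[rows, cols],
        "y": yy[rows, cols],
    }
    for name, arr in stack.layers.items():
        table[name] = arr[rows, cols]
    return pd.DataFrame(table)


# ----------------------------------------------------------------------
# Survey simulation
# ----------------------------------------------------------------------

def simulate_surveys(
    sites: pd.DataFrame,
    truth: TrueParameters,
    design: SurveyDesign,
    seed: int = 0,
    return_z: bool = False,
):
    """Simulate raw survey records for one species.

    Draws z_i ~ Bernoulli(psi_i) once per site, then one Bernoulli
    detection with success z_i * rho per site x method x occasion x
    sub-event.  Returns a records DataFrame (and the latent z vector
    when ``return_z``); a pure function of its inputs and the seed.
    """
    rng = np.random.default_rng(seed)
    n = len(sites)
    psi = truth.psi(sites)
    z = (rng.random(n) < psi).astype(int)

    frames = []
    for method in design.methods:
        rho = truth.rho(sites, method)
        n_occ = design.occasions_per_method[method]
        n_sub = design.sub_events_per_occasion[method]
        # detections: (site, occasion, sub_event)
        det = (rng.random((n, n_occ, n_sub)) < rho[:, None, None]) & (z[:, None, None] == 1)
        site_idx, occ_idx, sub_idx = np.meshgrid(
            np.arange(n), np.arange(n_occ), np.arange(n_sub), indexing="ij"
        )
        frames.append(
            pd.DataFrame(
                {
                    "site_id": sites["site_id"].to_numpy()[site_idx.ravel()],
                    "species": truth.species_id,
                    "method": method,
                    "occasion_index": occ_idx.ravel(),
                    "sub_event_index": sub_idx.ravel(),
                    "detected": det.ravel().astype(int),
                }
            )
        )
    records = pd.concat(frames, ignore_index=True)
    if return_z:
        return records, z
    return records


# ----------------------------------------------------------------------
# Study-scale defaults
# ----------------------------------------------------------------------

#: Covariates emulating the study's climatic / topographic / fire set.
DEFAULT_COVARIATES = [
    "max_temp",
    "rainfall",
    "min_temp",
    "elevation",
    "ruggedness",
    "soil_clay",
    "dist_water",
    "veg_cover",
    "time_since_fire",
    "fire_frequency",
    "prop_burnt",
    "fire_extent",
    "fire_patchiness",
]

#: Detection-side candidate covariates (besides the method factor).
DETECTION_COVARIATES = ["time_since_fire", "fire_frequency", "ruggedness"]

#: Covariates for which quadratic occupancy terms are disallowed.
NO_QUADRATIC = ["fire_extent", "fire_patchiness"]


def default_correlation() -> np.ndarray:
    """Correlation among the default covariates, with two pairs above the
    0.7 screening threshold (rainfall~min_temp, fire_frequency~prop_burnt)."""
    k = len(DEFAULT_COVARIATES)
    corr = np.eye(k)
    idx = {name: i for i, name in enumerate(DEFAULT_COVARIATES)}

    def set_pair(a, b, r):
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = r

    set_pair("rainfall", "min_temp", 0.85)
    set_pair("fire_frequency", "prop_burnt", 0.8)
    set_pair("elevation", "ruggedness", 0.5)
    set_pair("max_temp", "rainfall", -0.3)
    return corr


def default_landscape(seed: int = 0, n_rows: int = 120, n_cols: int = 120) -> GridStack:
    return gen_landscape(n_rows, n_cols, DEFAULT_COVARIATES, default_correlation(), seed=seed)


def gen_species_panel(n_species: int, seed: int = 0) -> list[TrueParameters]:
    """Species spanning occupancy ~0.01-0.8 and detectability ~0.01-0.9.

    Occupancy intercepts are spread on the logit scale so mean psi covers
    the observed span; each species gets 1-2 covariate effects of
    moderate size and method-specific detection intercepts.
    """
    rng = np.random.default_rng(seed)
    design = default_design()
    candidates = [c for c in DEFAULT_COVARIATES if c not in ("min_temp", "prop_burnt")]
    panel = []
    psi_targets = np.linspace(0.01, 0.8, n_species)
    for s in range(n_species):
        beta = {"(Intercept)": float(np.log(psi_targets[s] / (1 - psi_targets[s])))}
        for cov in rng.choice(candidates, size=rng.integers(1, 3), replace=False):
            beta[cov] = float(rng.normal(0, 0.8))
        rho_targets = rng.uniform(0.01, 0.9, size=len(design.methods))
        gamma = {m: float(np.log(r / (1 - r))) for m, r in zip(design.methods, rho_targets)}
        panel.append(
            TrueParameters(beta=beta, gamma_method=gamma, species_id=f"sp_{s:03d}")
        )
    return panel
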