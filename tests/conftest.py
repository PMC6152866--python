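import numpy as np
import pandas as pd
import pytest

from occumap import occu_model as oc
from occumap import survey_io as sio
from occumap import synthetic_data as sd


def make_sites(n: int, covs: tuple[str, ...] = ("cov",), seed: int = 0) -> pd.DataFrame:
    """Site table with independent standard-normal covariates."""
    rng = np.random.default_rng(seed)
    table = {"site_id": [f"s{i}" for i in range(n)], "x": np.zeros(n), "y": np.zeros(n)}
    for c in covs:
        table[c] = rng.normal(size=n)
    return pd.DataFrame(table)


def simulate_dataset(
    n_sites: int,
    beta: dict,
    gamma: dict,
    occasions: dict,
    seed: int,
    covs: tuple[str, ...] = ("cov",),
    gamma_slopes: dict | None = None,
):
    """Sites + collapsed multi-method history from known parameters."""
    sites = make_sites(n_sites, covs, seed=seed)
    truth = sd.TrueParameters(
        beta=beta, gamma_method=gamma, gamma_slopes=gamma_slopes or {}, species_id="species"
    )
    design = sd.SurveyDesign(methods=list(gamma), occasions_per_method=occasions)
    records = sd.simulate_surveys(sites, truth, design, seed=seed + 1)
    rules = {m: ("weekly" if "camera" in m else "daily") for m in gamma}
    history = sio.build_history(records, "species", rules)
    return sites, truth, records, history


@pytest.fixture
def two_method_dataset():
    """300 sites, one occupancy covariate, cage (4 nights) + camera (5 weeks)."""
    return simulate_dataset(
        n_sites=300,
        beta={"(Intercept)": -0.4, "cov": 1.0},
        gamma={"cage": -0.8, "camera": 0.2},
        occasions={"cage": 4, "camera": 5},
        seed=42,
    )


@pytest.fixture
def constant_fit():
    """Converged constant-model fit on a small simulated dataset."""
    sites, truth, _, history = simulate_dataset(
        n_sites=120,
        beta={"(Intercept)": 0.4},
        gamma={"m1": -0.5, "m2": 0.1},
        occasions={"m1": 3, "m2": 3},
        seed=7,
    )
    fitted = oc.fit(oc.ModelSpec(), history, sites, n_starts=2, seed=1)
    return sites, truth, history, fitted
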