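"""Parametric-bootstrap goodness-of-fit for fitted occupancy models.

Three discrepancy statistics — sum of squared errors, Freeman-Tukey
chi-squared, and Pearson's chi-squared — are bootstrapped under the
fitted model: B datasets are simulated on the same design and
missingness pattern, each refit with the same specification, and the
observed statistic is referred to the simulated null distribution with
the "+1" plug-in p-value convention so p is never exactly zero.

The bootstrapped statistics compare observed and expected counts of
whole detection histories (cohorted by missingness pattern, with a
remainder cell for unobserved histories), the construction standard for
occupancy models.  Cell-level residual statistics on the fitted values
y_hat_ij = psi_hat_i * rho_hat_ij are also provided
(:func:`gof_statistics`): for Bernoulli detections the maximum
likelihood equations pin the weighted detection totals those statistics
are built from, leaving them nearly ancillary — usable as descriptive
discrepancies but not as calibrated test statistics.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import occu_model
from .occu_model import FittedModel
from .survey_io import MultiMethodHistory

STATISTICS = ("sse", "freeman_tukey", "pearson")
_CLIP = 1e-6


def gof_statistics(y: np.ndarray, y_hat: np.ndarray) -> dict[str, float]:
    """SSE, Freeman-Tukey and Pearson discrepancies over non-missing cells."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {y_hat.shape}")
    mask = ~(np.isnan(y) | np.isnan(y_hat))
    yo, yh = y[mask], y_hat[mask]
    resid2 = (yo - yh) ** 2
    yh_clip = np.clip(yh, _CLIP, 1 - _CLIP)
    return {
        "sse": float(resid2.sum()),
        "freeman_tukey": float(((np.sqrt(yo) - np.sqrt(yh)) ** 2).sum()),
        "pearson": float((resid2 / (yh_clip * (1 - yh_clip))).sum()),
    }


def history_frequency_statistics(
    y: np.ndarray, observed: np.ndarray, psi: np.ndarray, rho: np.ndarray
) -> dict[str, float]:
    """SSE, Freeman-Tukey and Pearson on detection-history frequencies.

    Sites are cohorted by missingness pattern; within each cohort the
    observed count of every distinct history is compared with its
    expected count under the model,

        E_h = sum_i [ psi_i * prod_j rho_ij^h_j (1-rho_ij)^(1-h_j)
                      + (1 - psi_i) * 1[h = 0] ],

    and a single remainder cell absorbs the never-observed histories so
    expected counts sum to the cohort size.
    """
    y = np.asarray(y, dtype=float)
    observed = np.asarray(observed, dtype=bool)
    stats = {k: 0.0 for k in STATISTICS}
    by_pattern: dict[tuple, list[int]] = defaultdict(list)
    for i, row in enumerate(observed):
        by_pattern[tuple(row)].append(i)
    for pattern, members in by_pattern.items():
        idx = np.asarray(members)
        cols = np.asarray(pattern, dtype=bool)
        sub = y[np.ix_(idx, np.flatnonzero(cols))]
        histories, counts = np.unique(sub, axis=0, return_counts=True)
        r = rho[np.ix_(idx, np.flatnonzero(cols))]
        p = psi[idx]
        expected = np.empty(len(histories))
        for k, h in enumerate(histories):
            cond = np.prod(np.where(h == 1, r, 1 - r), axis=1)
            site_prob = p * cond
            if not h.any():
                site_prob = site_prob + (1 - p)
            expected[k] = site_prob.sum()
        o = counts.astype(float)
        e = expected
        e_rem = max(len(idx) - e.sum(), 0.0)
        stats["sse"] += float(((o - e) ** 2).sum() + e_rem**2)
        stats["freeman_tukey"] += float(((np.sqrt(o) - np.sqrt(e)) ** 2).sum() + e_rem)
        stats["pearson"] += float(((o - e) ** 2 / np.clip(e, _CLIP, None)).sum() + e_rem)
    return stats


@dataclass
class GofResult:
    """Observed statistics, bootstrap samples, and p-values."""

    t_obs: dict[str, float]
    t_sim: dict[str, np.ndarray]
    p_value: dict[str, float]
    b: int
    seed: int
    n_redraws: int = 0
    unstable: bool = False

    def passes(self, alpha: float = 0.05) -> bool:
        return all(p > alpha for p in self.p_value.values())

    def to_json(self) -> dict:
        return {
            "t_obs": self.t_obs,
            "t_sim": {k: v.tolist() for k, v in self.t_sim.items()},
            "p_value": self.p_value,
            "B": self.b,
            "seed": self.seed,
            "n_redraws": self.n_redraws,
            "unstable": self.unstable,
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=2))


def bootstrap_p(t_obs: float, t_sim: np.ndarray) -> float:
    """(1 + #{t_sim >= t_obs}) / (B + 1)."""
    t_sim = np.asarray(t_sim, dtype=float)
    return float((1 + (t_sim >= t_obs).sum()) / (len(t_sim) + 1))


def parametric_bootstrap(
    fitted: FittedModel,
    history: MultiMethodHistory,
    covariates: pd.DataFrame,
    b: int = 1000,
    seed: int = 0,
    max_redraw_fraction: float = 0.1,
) -> GofResult:
    """Bootstrap the three statistics under the fitted model.

    Each replicate simulates a detection history from the fit, refits the
    same specification (warm-started at the generating coefficients), and
    scores the simulated data against its own refit.  All three p-values
    share one replicate stream.  Replicates whose refit fails to converge
    are redrawn; more than ``max_redraw_fraction * b`` redraws flags the
    result unstable.
    """
    if not fitted.converged:
        raise ValueError("goodness-of-fit requires a converged fit")
    rng = np.random.default_rng(seed)
    data = occu_model.ModelData(fitted.spec, history, covariates)
    psi, rho = data.probabilities(fitted.params)
    t_obs = history_frequency_statistics(data.y, data.observed, psi, rho)

    sims = {k: np.empty(b) for k in STATISTICS}
    n_redraws = 0
    max_redraws = max(10, int(np.ceil(max_redraw_fraction * b)) + 10)
    i = 0
    while i < b:
        sim_hist = occu_model.simulate_history(fitted, history, covariates, rng)
        refit = occu_model.fit(
            fitted.spec, sim_hist, covariates, n_starts=1, seed=int(rng.integers(2**31)),
            start=fitted.params,
        )
        if not refit.converged:
            n_redraws += 1
            if n_redraws > max_redraws:
                break
            continue
        sim_data = occu_model.ModelData(refit.spec, sim_hist, covariates)
        sim_psi, sim_rho = sim_data.probabilities(refit.params)
        t = history_frequency_statistics(sim_data.y, sim_data.observed, sim_psi, sim_rho)
        for k in STATISTICS:
            sims[k][i] = t[k]
        i += 1
    b_done = i
    sims = {k: v[:b_done] for k, v in sims.items()}
    return GofResult(
        t_obs=t_obs,
        t_sim=sims,
        p_value={k: bootstrap_p(t_obs[k], sims[k]) for k in STATISTICS},
        b=b_done,
        seed=seed,
        n_redraws=n_redraws,
        unstable=n_redraws > max_redraw_fraction * b,
    )
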