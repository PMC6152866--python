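"""Covariate screening, standardisation and design matrices.

Collinearity is screened on pairwise Spearman rank correlation with a
priority list deciding which member of an offending pair is kept.
Retained covariates are centred and scaled to unit sample standard
deviation before fitting; the constants are kept so raster prediction
reuses the fitting-time scaling.  Occupancy designs may include
quadratic terms (on the standardised scale), except for covariates whose
construction makes a quadratic response unidentifiable by design (fire
extent and fire patchiness in the default configuration).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .rasters import GridStack
from .synthetic_data import NO_QUADRATIC, parse_term, term_name

ID_COLUMNS = ("site_id", "x", "y")


def covariate_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in ID_COLUMNS]


@dataclass
class ScalingConstants:
    """Per-covariate mean and (sample, n-1) standard deviation."""

    mean: dict[str, float]
    sd: dict[str, float]

    def __post_init__(self) -> None:
        for name, s in self.sd.items():
            if not s > 0:
                raise ValueError(f"covariate '{name}' has non-positive sd {s}")

    def apply(self, values, covariate: str):
        return (np.asarray(values, dtype=float) - self.mean[covariate]) / self.sd[covariate]

    def to_json(self) -> dict:
        return {"mean": self.mean, "sd": self.sd}

    @classmethod
    def from_json(cls, obj: dict) -> "ScalingConstants":
        return cls(mean=dict(obj["mean"]), sd=dict(obj["sd"]))

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=2))

    @classmethod
    def read(cls, path: str | Path) -> "ScalingConstants":
        return cls.from_json(json.loads(Path(path).read_text()))


def spearman_screen(
    table: pd.DataFrame,
    threshold: float = 0.7,
    priority: list[str] | None = None,
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Drop one of each covariate pair with |Spearman rho| above threshold.

    ``priority`` orders covariates from most to least preferred (default:
    column order); for each offending pair the lower-priority member is
    discarded, iterating until no retained pair exceeds the threshold.
    Returns (kept, discarded, rho matrix over all input covariates).
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0,1), got {threshold}")
    covs = covariate_columns(table)
    if len(table) < 3:
        raise ValueError("need at least 3 sites for rank correlation")
    for c in covs:
        if table[c].nunique() <= 1:
            raise ValueError(f"covariate '{c}' is constant; Spearman correlation undefined")
    if priority is None:
        priority = list(covs)
    rank = {c: priority.index(c) if c in priority else len(priority) for c in covs}

    rho_mat, _ = stats.spearmanr(table[covs].to_numpy())
    if np.ndim(rho_mat) == 0:  # spearmanr collapses the 2-column case
        r = float(rho_mat)
        rho_mat = np.array([[1.0, r], [r, 1.0]])
    rho = pd.DataFrame(np.atleast_2d(rho_mat), index=covs, columns=covs)

    kept = sorted(covs, key=lambda c: rank[c])
    discarded: list[str] = []
    changed = True
    while changed:
        changed = False
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                if abs(rho.loc[a, b]) > threshold:
                    kept.remove(b)  # b is lower priority by sort order
                    discarded.append(b)
                    changed = True
                    break
            if changed:
                break
    kept_in_input_order = [c for c in covs if c in kept]
    return kept_in_input_order, discarded, rho


def standardize(table: pd.DataFrame) -> tuple[pd.DataFrame, ScalingConstants]:
    """Centre and scale each covariate column to mean 0, sample sd 1."""
    out = table.copy()
    mean, sd = {}, {}
    for c in covariate_columns(table):
        mu = float(table[c].mean())
        s = float(table[c].std(ddof=1))
        if not s > 0:
            raise ValueError(f"covariate '{c}' has zero standard deviation")
        out[c] = (table[c] - mu) / s
        mean[c], sd[c] = mu, s
    return out, ScalingConstants(mean=mean, sd=sd)


def build_design(
    terms: list[tuple[str, int]],
    table: pd.DataFrame,
    no_quadratic: tuple[str, ...] | list[str] = tuple(NO_QUADRATIC),
) -> np.ndarray:
    """Design matrix [1, x, x^2, ...] from standardised covariates.

    Terms are (covariate, degree) pairs in the order the columns should
    appear; a quadratic requires its linear term (marginality) and is
    refused for covariates in ``no_quadratic``.  The intercept column is
    always first.  An empty term list yields the intercept-only design.
    """
    linear = {cov for cov, d in terms if d == 1}
    cols = [np.ones(len(table))]
    for cov, degree in terms:
        if degree not in (1, 2):
            raise ValueError(f"unsupported degree {degree} for '{cov}'")
        if degree == 2:
            if cov in no_quadratic:
                raise ValueError(f"quadratic term not permitted for covariate '{cov}'")
            if cov not in linear:
                raise ValueError(f"quadratic term for '{cov}' requires its linear term")
        if cov not in table.columns:
            raise KeyError(f"covariate '{cov}' not in table")
        x = table[cov].to_numpy(dtype=float)
        if not np.isfinite(x).all():
            raise ValueError(f"non-finite values in covariate '{cov}'")
        cols.append(x ** degree)
    return np.column_stack(cols)


def design_column_names(terms: list[tuple[str, int]]) -> list[str]:
    return ["(Intercept)"] + [term_name(cov, d) for cov, d in terms]


def extract_at_sites(stack: GridStack, coords: np.ndarray) -> pd.DataFrame:
    """Site covariate table from raster values at coordinate pairs.

    ``coords`` is (n, 2) of x, y map coordinates; each site takes the
    value of its containing cell.  Out-of-extent coordinates raise.
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 2)
    values = stack.values_at(coords[:, 0], coords[:, 1])
    table = {"site_id": [f"site_{i:04d}" for i in range(len(coords))],
             "x": coords[:, 0], "y": coords[:, 1]}
    table.update(values)
    return pd.DataFrame(table)


def reclassify_raster(stack: GridStack, factor: int) -> GridStack:
    """Coarsen the grid by an integer factor using block means.

    Each coarse cell is the mean of the finite fine cells it covers
    (all-missing blocks stay missing); trailing rows/columns that do not
    fill a block are dropped.  Used to derive coarse prediction layers
    from the fine fitting-resolution layers.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    n_rows, n_cols = stack.shape
    if factor > min(n_rows, n_cols):
        raise ValueError(f"factor {factor} exceeds grid dimensions {stack.shape}")
    if factor == 1:
        return stack.copy()
    r, c = n_rows // factor, n_cols // factor
    layers = {}
    for name, arr in stack.layers.items():
        trimmed = arr[: r * factor, : c * factor]
        blocks = trimmed.reshape(r, factor, c, factor)
        finite = np.isfinite(blocks)
        count = finite.sum(axis=(1, 3))
        total = np.where(finite, blocks, 0.0).sum(axis=(1, 3))
        layers[name] = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    new = GridStack(layers, stack.x_ll, stack.y_ll, stack.cell_size * factor, dict(stack.meta))
    # keep the coarse extent anchored at the same top-left corner
    new.y_ll = stack.y_ll + (n_rows - r * factor) * stack.cell_size
    return new
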