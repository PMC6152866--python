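"""Occupancy surfaces, extrapolation masks, and stacked richness maps.

Fitted models are predicted onto covariate raster stacks (standardising
each cell with the fitting-time constants), restricted to the sampled
environmental domain and, for restricted-range species, to a buffered
geographic region, then summed cellwise across species into a relative
richness surface — the summed probability of occupancy, not an expected
species count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .covariate_prep import covariate_columns
from .occu_model import FittedModel, predict_probabilities
from .rasters import GridStack, write_ascii_grid

from shapely import contains_xy as _shapely_contains
from shapely.geometry.base import BaseGeometry


@dataclass
class OccupancySurface:
    """Per-cell predicted occupancy for one species."""

    grid: np.ndarray
    species: str
    stack: GridStack
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        finite = self.grid[np.isfinite(self.grid)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("occupancy surface values must lie in [0, 1]")

    def apply_mask(self, mask: np.ndarray, mask_id: str = "mask") -> "OccupancySurface":
        """Masking only removes cells; it never restores them."""
        grid = np.where(np.asarray(mask, dtype=bool), self.grid, np.nan)
        prov = dict(self.provenance)
        prov["mask_ids"] = list(prov.get("mask_ids", [])) + [mask_id]
        return OccupancySurface(grid, self.species, self.stack, prov)

    def write(self, path: str | Path) -> None:
        path = Path(path)
        write_ascii_grid(path, self.grid, self.stack.x_ll, self.stack.y_ll, self.stack.cell_size)
        sidecar = {"species": self.species, "provenance": self.provenance}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def predict_raster(fitted: FittedModel, stack: GridStack) -> OccupancySurface:
    """Predict psi to every cell of a covariate stack.

    Cell values are standardised with the fitting-time scaling constants
    before the linear predictor; any cell missing a required covariate
    is missing in the output.
    """
    needed = sorted({c for c, _ in fitted.spec.psi_terms} | set(fitted.spec.p_terms))
    missing = [c for c in needed if c not in stack.layers]
    if missing:
        raise KeyError(f"raster stack missing layer(s): {missing}")
    n_rows, n_cols = stack.shape
    if needed:
        table = pd.DataFrame({c: stack.layers[c].ravel() for c in needed})
    else:
        table = pd.DataFrame(index=range(n_rows * n_cols))
    valid = np.ones(len(table), dtype=bool)
    for c in needed:
        valid &= np.isfinite(table[c].to_numpy())
    psi = np.full(len(table), np.nan)
    if valid.any():
        psi_valid, _ = predict_probabilities(fitted, table.loc[valid])
        psi[valid] = psi_valid
    return OccupancySurface(
        psi.reshape(n_rows, n_cols),
        fitted.species,
        stack,
        provenance={"model": fitted.spec.label(), "aic": fitted.aic, "mask_ids": []},
    )


@dataclass
class DomainMask:
    """Sampled environmental-domain mask: a cell passes iff every
    selected covariate lies within the closed [min, max] observed at
    the monitoring sites."""

    mask: np.ndarray
    ranges: dict[str, tuple[float, float]]


def domain_mask(
    stack: GridStack,
    sampled: pd.DataFrame,
    covariates: list[str] | None = None,
    quantile_trim: float = 0.0,
) -> DomainMask:
    """Mask cells outside the environmental domain sampled at sites.

    ``covariates`` defaults to every covariate column of the site table
    present in the stack.  ``quantile_trim`` optionally tightens the
    interval to the [q, 1-q] sample quantiles to exclude regions far
    outside the sampled domain.
    """
    if len(sampled) == 0:
        raise ValueError("empty site table: no sampled domain to compare against")
    if covariates is None:
        covariates = [c for c in covariate_columns(sampled) if c in stack.layers]
    mask = np.ones(stack.shape, dtype=bool)
    ranges = {}
    for c in covariates:
        if c not in stack.layers:
            raise KeyError(f"covariate '{c}' missing from raster stack")
        vals = sampled[c].to_numpy(dtype=float)
        if quantile_trim > 0:
            lo, hi = np.quantile(vals, [quantile_trim, 1 - quantile_trim])
        else:
            lo, hi = float(vals.min()), float(vals.max())
        ranges[c] = (lo, hi)
        layer = stack.layers[c]
        with np.errstate(invalid="ignore"):
            mask &= (layer >= lo) & (layer <= hi)
    return DomainMask(mask=mask, ranges=ranges)


def range_mask(
    region,
    buffer_distance: float,
    stack: GridStack,
) -> np.ndarray:
    """Cells within ``buffer_distance`` (map units) of a region.

    ``region`` is either a boolean grid on the stack's grid or a shapely
    geometry in the stack's coordinate system; buffering on gridded
    regions uses the Euclidean distance transform on cell centres.  Used
    both to subset sites before fitting restricted-range species and to
    clip their predicted surfaces.
    """
    if isinstance(region, np.ndarray):
        region_grid = region.astype(bool)
        if region_grid.shape != stack.shape:
            raise ValueError(
                f"region grid {region_grid.shape} does not match stack {stack.shape}"
            )
    elif isinstance(region, BaseGeometry):
        xx, yy = stack.cell_centers()
        region_grid = _shapely_contains(region, xx, yy)
    else:
        raise TypeError("region must be a boolean grid or a shapely geometry")
    if buffer_distance < 0:
        raise ValueError("buffer_distance must be >= 0")
    if buffer_distance == 0 or not region_grid.any():
        return region_grid
    dist = ndimage.distance_transform_edt(~region_grid, sampling=stack.cell_size)
    return dist <= buffer_distance


def sites_in_mask(sites: pd.DataFrame, mask: np.ndarray, stack: GridStack) -> pd.DataFrame:
    """Subset a site table to sites whose containing cell passes the mask."""
    row, col = stack.index_of(sites["x"].to_numpy(), sites["y"].to_numpy())
    return sites.loc[mask[row, col]].reset_index(drop=True)


def stack_richness(surfaces: list[OccupancySurface]) -> tuple[np.ndarray, np.ndarray]:
    """Cellwise sum of predicted occupancy across species.

    Returns (richness, coverage): a cell missing in every input is
    missing in the sum; a cell missing in only some species contributes
    zero for those species, and ``coverage`` counts contributing species
    per cell.  The result is a relative richness index (summed
    occupancy probability), not an expected species count.
    """
    if not surfaces:
        raise ValueError("no surfaces to stack")
    shapes = {s.grid.shape for s in surfaces}
    if len(shapes) > 1:
        raise ValueError(f"surfaces on different grids: {shapes}")
    grids = np.stack([s.grid for s in surfaces])
    finite = np.isfinite(grids)
    coverage = finite.sum(axis=0)
    total = np.where(finite, grids, 0.0).sum(axis=0)
    richness = np.where(coverage > 0, total, np.nan)
    return richness, coverage
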