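"""Gridded covariate layers.

A :class:`GridStack` holds one 2-D array per covariate on a shared regular
grid, with missing cells encoded as NaN.  Layers are serialized as ESRI
ASCII grid files (one ``.asc`` per covariate) plus a JSON sidecar that
records layer names and, optionally, the centring/scaling constants used
at model-fitting time.  Row 0 of each array is the *top* row of the map,
matching the ASCII-grid convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

NODATA = -9999.0


@dataclass
class GridStack:
    """A stack of co-registered single-band covariate grids.

    Parameters
    ----------
    layers
        Mapping from covariate name to a 2-D float array.  All arrays
        share one shape; NaN marks missing cells.
    x_ll, y_ll
        Coordinates of the lower-left corner of the grid extent.
    cell_size
        Side length of a (square) cell, in map units (metres).
    meta
        Free-form provenance (scaling constants, mask ids, ...).
    """

    layers: dict[str, np.ndarray]
    x_ll: float = 0.0
    y_ll: float = 0.0
    cell_size: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {a.shape for a in self.layers.values()}
        if len(shapes) > 1:
            raise ValueError(f"layers have inconsistent shapes: {shapes}")
        for name, arr in self.layers.items():
            self.layers[name] = np.asarray(arr, dtype=float)

    # ------------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def n_cells(self) -> int:
        r, c = self.shape
        return r * c

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every cell centre, row-major order."""
        n_rows, n_cols = self.shape
        cols = np.arange(n_cols)
        rows = np.arange(n_rows)
        x = self.x_ll + (cols + 0.5) * self.cell_size
        # row 0 is the top of the map
        y = self.y_ll + (n_rows - rows - 0.5) * self.cell_size
        xx, yy = np.meshgrid(x, y)
        return xx, yy

    def index_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/column of the cell containing each coordinate.

        Raises ``ValueError`` listing out-of-extent points.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        n_rows, n_cols = self.shape
        col = np.floor((x - self.x_ll) / self.cell_size).astype(int)
        row_from_bottom = np.floor((y - self.y_ll) / self.cell_size).astype(int)
        row = n_rows - 1 - row_from_bottom
        bad = (col < 0) | (col >= n_cols) | (row < 0) | (row >= n_rows)
        if bad.any():
            idx = np.flatnonzero(bad)
            raise ValueError(
                f"{bad.sum()} coordinate(s) outside raster extent "
                f"(indices {idx[:10].tolist()})"
            )
        return row, col

    def values_at(self, x, y) -> dict[str, np.ndarray]:
        row, col = self.index_of(x, y)
        return {name: arr[row, col] for name, arr in self.layers.items()}

    def copy(self) -> "GridStack":
        return GridStack(
            {k: v.copy() for k, v in self.layers.items()},
            self.x_ll,
            self.y_ll,
            self.cell_size,
            dict(self.meta),
        )

    # ------------------------------------------------------------------
    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, arr in self.layers.items():
            write_ascii_grid(directory / f"{name}.asc", arr, self.x_ll, self.y_ll, self.cell_size)
        sidecar = {
            "layers": self.names,
            "x_ll": self.x_ll,
            "y_ll": self.y_ll,
            "cell_size": self.cell_size,
            "meta": self.meta,
        }
        (directory / "stack.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def read(cls, directory: str | Path) -> "GridStack":
        directory = Path(directory)
        sidecar = json.loads((directory / "stack.json").read_text())
        layers = {}
        for name in sidecar["layers"]:
            arr, _, _, _ = read_ascii_grid(directory / f"{name}.asc")
            layers[name] = arr
        return cls(
            layers,
            sidecar["x_ll"],
            sidecar["y_ll"],
            sidecar["cell_size"],
            sidecar.get("meta", {}),
        )


def write_ascii_grid(path: str | Path, arr: np.ndarray, x_ll: float, y_ll: float, cell_size: float) -> None:
    arr = np.asarray(arr, dtype=float)
    n_rows, n_cols = arr.shape
    out = np.where(np.isnan(arr), NODATA, arr)
    header = (
        f"ncols {n_cols}\nnrows {n_rows}\n"
        f"xllcorner {x_ll}\nyllcorner {y_ll}\n"
        f"cellsize {cell_size}\nNODATA_value {NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.8g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, float, float, float]:
    with open(path) as fh:
        hdr = {}
        for _ in range(6):
            key, val = fh.readline().split()
            hdr[key.lower()] = float(val)
        arr = np.loadtxt(fh)
    arr = np.atleast_2d(arr)
    nodata = hdr.get("nodata_value", NODATA)
    arr[arr == nodata] = np.nan
    return arr, hdr["xllcorner"], hdr["yllcorner"], hdr["cellsize"]
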