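"""Detection-history construction from raw survey records.

Raw records are one row per site x species x method x occasion x
sub-event with ``detected`` in {0, 1}.  They are collapsed to
occasion-level detection histories (1 = detected at least once within
the occasion, 0 = surveyed but not detected, NaN = not surveyed) and the
per-method matrices are appended column-wise, with the sampling method
recorded as an observation-level factor on each occasion column.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

RECORD_COLUMNS = ["site_id", "species", "method", "occasion_index", "sub_event_index", "detected"]

COLLAPSE_RULES = ("daily", "weekly")


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"survey records missing columns: {missing}")
    bad = ~records["detected"].isin([0, 1])
    if bad.any():
        raise ValueError(f"{bad.sum()} record(s) with detected not in {{0,1}}")
    keys = ["site_id", "species", "method", "occasion_index", "sub_event_index"]
    dup = records.duplicated(keys)
    if dup.any():
        raise ValueError(f"{dup.sum()} duplicate (site, species, method, occasion, sub_event) row(s)")
    return records


def read_records(path: str | Path) -> pd.DataFrame:
    return validate_records(pd.read_csv(path))


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    records[RECORD_COLUMNS].to_csv(path, index=False)


@dataclass
class MultiMethodHistory:
    """Site x occasion detection matrix with per-occasion method labels.

    ``y`` holds {0.0, 1.0, NaN}; ``occasion_method[j]`` is the factor
    level of column j; columns are grouped contiguously by method.
    """

    y: np.ndarray
    occasion_method: list[str]
    site_ids: list[str]
    species: str = ""
    method_occasions: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.y.ndim != 2:
            raise ValueError("y must be 2-D (sites x occasions)")
        if self.y.shape != (len(self.site_ids), len(self.occasion_method)):
            raise ValueError(
                f"shape {self.y.shape} inconsistent with {len(self.site_ids)} sites "
                f"and {len(self.occasion_method)} occasion labels"
            )
        obs = self.y[~np.isnan(self.y)]
        if not np.isin(obs, [0.0, 1.0]).all():
            raise ValueError("non-missing history entries must be 0 or 1")
        counts: dict[str, int] = {}
        last = None
        for m in self.occasion_method:
            if m in counts and m != last:
                raise ValueError("occasion columns must be grouped contiguously by method")
            counts[m] = counts.get(m, 0) + 1
            last = m
        self.method_occasions = counts

    @property
    def methods(self) -> list[str]:
        return list(self.method_occasions)

    @property
    def n_sites(self) -> int:
        return self.y.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.y.shape[1]

    def method_columns(self, method: str) -> np.ndarray:
        return np.array([j for j, m in enumerate(self.occasion_method) if m == method])

    def detection_count(self, method: str | None = None) -> int:
        y = self.y if method is None else self.y[:, self.method_columns(method)]
        return int(np.nansum(y))

    # ------------------------------------------------------------------
    def write(self, path: str | Path) -> None:
        """CSV with method:occasion headers plus a JSON sidecar."""
        path = Path(path)
        cols = [f"{m}:{j}" for j, m in _per_method_indices(self.occasion_method)]
        df = pd.DataFrame(self.y, columns=cols)
        df.insert(0, "site_id", self.site_ids)
        df.to_csv(path, index=False)
        sidecar = {"species": self.species, "occasion_method": self.occasion_method}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def read(cls, path: str | Path) -> "MultiMethodHistory":
        path = Path(path)
        df = pd.read_csv(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        y = df.drop(columns="site_id").to_numpy(dtype=float)
        return cls(y, sidecar["occasion_method"], df["site_id"].astype(str).tolist(),
                   sidecar.get("species", ""))


def _per_method_indices(occasion_method: list[str]):
    seen: dict[str, int] = {}
    out = []
    for m in occasion_method:
        seen[m] = seen.get(m, 0) + 1
        out.append((seen[m] - 1, m))
    return [(j, m) for (j, m) in out]


# ----------------------------------------------------------------------
# Collapsing and appending
# ----------------------------------------------------------------------

def collapse_to_occasions(
    records: pd.DataFrame,
    species: str,
    method: str,
    rule: str = "daily",
    site_ids: list[str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Collapse raw events to an occasion-level site x occasion matrix.

    An occasion scores 1 if any raw event within it has ``detected=1``,
    0 if the site was surveyed that occasion with no detection, and NaN
    if the site was not surveyed then.  ``rule`` names the occasion unit
    (one day/night for trap and search methods, one week for cameras);
    occasion indices in the records are assumed pre-binned to that unit.
    """
    if rule not in COLLAPSE_RULES:
        raise ValueError(f"unknown collapsing rule '{rule}'; expected one of {COLLAPSE_RULES}")
    validate_records(records)
    sub = records[(records["species"] == species) & (records["method"] == method)]
    if site_ids is None:
        site_ids = sorted(sub["site_id"].astype(str).unique())
    site_pos = {s: i for i, s in enumerate(site_ids)}
    occasions = sorted(sub["occasion_index"].unique())
    occ_pos = {o: j for j, o in enumerate(occasions)}
    y = np.full((len(site_ids), len(occasions)), np.nan)
    grouped = sub.groupby(["site_id", "occasion_index"])["detected"].max()
    for (site, occ), val in grouped.items():
        i = site_pos.get(str(site))
        if i is not None:
            y[i, occ_pos[occ]] = float(val)
    return y, site_ids


def append_methods(
    per_method: list[np.ndarray],
    method_labels: list[str],
    site_ids_per_method: list[list[str]],
    species: str = "",
) -> MultiMethodHistory:
    """Concatenate per-method histories into one multi-method matrix.

    The site universe is the union across methods (order of first
    appearance); a site absent from a method's input gets NaN in that
    method's columns, so mixed-method designs are ragged but aligned.
    """
    if len(set(method_labels)) != len(method_labels):
        raise ValueError(f"duplicate method label in {method_labels}")
    if not (len(per_method) == len(method_labels) == len(site_ids_per_method)):
        raise ValueError("per_method, method_labels and site_ids_per_method must align")
    all_sites: list[str] = []
    for ids in site_ids_per_method:
        for s in ids:
            if s not in all_sites:
                all_sites.append(s)
    pos = {s: i for i, s in enumerate(all_sites)}
    blocks = []
    labels = []
    for mat, label, ids in zip(per_method, method_labels, site_ids_per_method):
        mat = np.asarray(mat, dtype=float)
        if mat.ndim != 2 or mat.shape[0] != len(ids):
            raise ValueError(f"method '{label}': matrix shape {mat.shape} vs {len(ids)} sites")
        block = np.full((len(all_sites), mat.shape[1]), np.nan)
        rows = [pos[s] for s in ids]
        block[rows, :] = mat
        blocks.append(block)
        labels.extend([label] * mat.shape[1])
    y = np.hstack(blocks) if blocks else np.empty((len(all_sites), 0))
    return MultiMethodHistory(y, labels, all_sites, species=species)


def build_history(
    records: pd.DataFrame,
    species: str,
    method_rules: dict[str, str],
    method_order: list[str] | None = None,
) -> MultiMethodHistory:
    """Collapse every method for one species and append the results.

    ``method_rules`` maps method name to its collapsing rule; methods are
    appended in lexicographic order unless ``method_order`` is given, so
    the factor's reference level is reproducible.
    """
    present = set(records.loc[records["species"] == species, "method"].unique())
    methods = method_order or sorted(method_rules)
    methods = [m for m in methods if m in present]
    mats, ids = [], []
    for m in methods:
        y, sites = collapse_to_occasions(records, species, m, method_rules.get(m, "daily"))
        mats.append(y)
        ids.append(sites)
    return append_methods(mats, methods, ids, species=species)


def n_detection_sites(history: MultiMethodHistory) -> int:
    """Number of sites with at least one detection (NaN-aware)."""
    with np.errstate(invalid="ignore"):
        return int(np.nansum(np.nanmax(history.y, axis=1, initial=0) > 0))
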