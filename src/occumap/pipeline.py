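"""End-to-end orchestration: records -> histories -> fits -> maps.

A single :class:`PipelineConfig` drives, per species: detection-history
construction, covariate screening/standardisation, constrained
all-subsets AIC selection with bootstrap goodness-of-fit and fallback to
the null model, mean occupancy/detectability summaries, and (when a
raster stack is configured) occupancy surfaces masked to the sampled
environmental domain.  Per species group, non-null surfaces are stacked
into a relative richness map.  Every output is deterministic given the
configured seed; a manifest records config, seeds and versions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, covariate_prep, gof, mapping, model_selection, occu_model, survey_io
from .model_selection import NullFallback
from .occu_model import ModelSpec, NULL_SPEC
from .rasters import GridStack, read_ascii_grid, write_ascii_grid
from .synthetic_data import DETECTION_COVARIATES, NO_QUADRATIC

log = logging.getLogger("occumap")


@dataclass
class PipelineConfig:
    """Everything a run needs; loadable from YAML/JSON."""

    records: str
    sites: str
    output_dir: str
    raster_dir: str | None = None
    species: list[str] | None = None           # default: all in records
    groups: dict[str, list[str]] = field(default_factory=dict)
    psi_candidates: list[str] | None = None    # default: screened site covariates
    p_candidates: list[str] = field(default_factory=lambda: list(DETECTION_COVARIATES))
    dredge_detection: bool = True
    screen_threshold: float = 0.7
    screen_priority: list[str] | None = None
    detections_ratio: int = 10
    delta_aic_cutoff: float = 6.0
    gof_b: int = 1000
    gof_alpha: float = 0.05
    n_starts: int = 5
    seed: int = 0
    method_rules: dict[str, str] = field(default_factory=dict)  # method -> daily|weekly
    method_order: list[str] | None = None
    restricted_range: dict[str, dict] = field(default_factory=dict)
    # species -> {"region": <.asc path>, "buffer": metres}
    domain_mask_covariates: list[str] | None = None
    max_models: int = 10000  # guard against combinatorial dredges

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        obj = yaml.safe_load(text)
        return cls(**obj)

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def _rule_for(method: str, config: PipelineConfig) -> str:
    if method in config.method_rules:
        return config.method_rules[method]
    return "weekly" if "camera" in method else "daily"


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full analysis; returns the populated output directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    records = survey_io.read_records(config.records)
    sites = pd.read_csv(config.sites)
    stack = GridStack.read(config.raster_dir) if config.raster_dir else None

    # --- covariate screening and standardisation -----------------------
    all_covs = covariate_prep.covariate_columns(sites)
    kept, discarded, rho = covariate_prep.spearman_screen(
        sites, threshold=config.screen_threshold, priority=config.screen_priority
    )
    rho.to_csv(out / "covariate_spearman.csv")
    (out / "covariate_screening.json").write_text(
        json.dumps({"kept": kept, "discarded": discarded}, indent=2)
    )
    std_sites, scaling = covariate_prep.standardize(sites)
    scaling.write(out / "scaling_constants.json")

    psi_candidates = config.psi_candidates or kept
    psi_candidates = [c for c in psi_candidates if c in kept]
    p_candidates = [c for c in config.p_candidates if c in kept] if config.dredge_detection else []
    quad_ok = {c: c not in NO_QUADRATIC for c in psi_candidates}

    species_list = config.species or sorted(records["species"].unique())
    rules = {m: _rule_for(m, config) for m in records["method"].unique()}

    summary_rows = []
    surfaces_by_group: dict[str, list[mapping.OccupancySurface]] = {}
    for sp in species_list:
        sp_dir = out / "species" / sp
        sp_dir.mkdir(parents=True, exist_ok=True)
        try:
            result = _run_species(
                sp, records, std_sites, sites, scaling, stack, rules,
                psi_candidates, p_candidates, quad_ok, config,
                seed=int(rng.integers(2**31)),
                sp_dir=sp_dir,
            )
        except Exception:
            log.exception("species %s failed; skipping", sp)
            summary_rows.append({"species": sp, "status": "failed"})
            continue
        summary_rows.append(result["summary"])
        if result.get("surface") is not None and not result["is_null"]:
            group = _group_of(sp, config.groups)
            surfaces_by_group.setdefault(group, []).append(result["surface"])

    # --- richness maps --------------------------------------------------
    if stack is not None:
        for group, surfaces in surfaces_by_group.items():
            richness, coverage = mapping.stack_richness(surfaces)
            write_ascii_grid(out / f"richness_{group}.asc", richness,
                             stack.x_ll, stack.y_ll, stack.cell_size)
            write_ascii_grid(out / f"richness_{group}_coverage.asc", coverage.astype(float),
                             stack.x_ll, stack.y_ll, stack.cell_size)

    pd.DataFrame(summary_rows).to_csv(out / "summary.csv", index=False)
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "occumap_version": __version__,
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "n_species": len(species_list),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


def _group_of(species: str, groups: dict[str, list[str]]) -> str:
    for g, members in groups.items():
        if species in members:
            return g
    return "all"


def _run_species(
    sp, records, std_sites, raw_sites, scaling, stack, rules,
    psi_candidates, p_candidates, quad_ok, config, seed, sp_dir,
) -> dict:
    history = survey_io.build_history(records, sp, rules, config.method_order)
    history.write(sp_dir / "history.csv")
    n_det = survey_io.n_detection_sites(history)
    multi_method = len(history.methods) > 1

    # restricted-range species: fit only on sites within the buffered region
    fit_sites = std_sites
    clip_mask = None
    rr = config.restricted_range.get(sp)
    if rr is not None and stack is not None:
        region, *_ = read_ascii_grid(rr["region"])
        clip_mask = mapping.range_mask(region.astype(bool), rr.get("buffer", 5000.0), stack)
        keep = mapping.sites_in_mask(raw_sites, clip_mask, stack)["site_id"]
        fit_sites = std_sites[std_sites["site_id"].isin(keep)].reset_index(drop=True)
        keep_ids = [s for s in history.site_ids if s in set(keep)]
        idx = [history.site_ids.index(s) for s in keep_ids]
        history = survey_io.MultiMethodHistory(
            history.y[idx], history.occasion_method, keep_ids, species=sp
        )
        n_det = survey_io.n_detection_sites(history)

    max_terms = model_selection.max_terms_for(n_det, config.detections_ratio)
    specs = model_selection.enumerate_models(
        psi_candidates, p_candidates, max_terms, quad_ok,
        p_has_method_factor=multi_method,
    )
    if len(specs) > config.max_models:
        raise RuntimeError(
            f"{len(specs)} candidate models for '{sp}' exceeds max_models="
            f"{config.max_models}; narrow psi_candidates/p_candidates or raise the cap"
        )
    rng = np.random.default_rng(seed)
    fits = [
        occu_model.fit(s, history, fit_sites, n_starts=config.n_starts,
                       seed=int(rng.integers(2**31)), scaling=scaling)
        for s in specs
    ]
    null_spec = ModelSpec(p_has_method_factor=multi_method)
    null_fit = next((f for f in fits if f.spec == null_spec), None)
    if null_fit is None:
        null_fit = occu_model.fit(null_spec, history, fit_sites,
                                  n_starts=config.n_starts,
                                  seed=int(rng.integers(2**31)), scaling=scaling)
    try:
        ranked = model_selection.rank_by_aic(fits)
    except NullFallback:
        ranked = []

    # GoF on candidates as they are considered, walking the retained set
    gof_result = None
    for rec in model_selection.retained_set(ranked, config.delta_aic_cutoff):
        if rec.boundary_flag:
            continue
        g = gof.parametric_bootstrap(
            rec.fitted, history, fit_sites, b=config.gof_b,
            seed=int(rng.integers(2**31)),
        )
        rec.gof_pass = g.passes(config.gof_alpha)
        if rec.gof_pass:
            gof_result = g
            break
    selected, ranked = model_selection.select_best(
        ranked, null_fit=null_fit, cutoff=config.delta_aic_cutoff
    )
    is_null = selected.spec == null_spec

    model_selection.records_table(ranked, species=sp).to_csv(sp_dir / "models.csv", index=False)
    selected.write(sp_dir / "selected_model.json")
    if gof_result is not None:
        gof_result.write(sp_dir / "gof.json")
    means = occu_model.mean_estimates(selected, history, fit_sites)
    means.to_csv(sp_dir / "mean_estimates.csv", index=False)

    surface = None
    if stack is not None:
        surface = mapping.predict_raster(selected, stack)
        dom = mapping.domain_mask(stack, raw_sites, config.domain_mask_covariates)
        surface = surface.apply_mask(dom.mask, "environmental_domain")
        if clip_mask is not None:
            surface = surface.apply_mask(clip_mask, "restricted_range")
        surface.write(sp_dir / "occupancy.asc")

    psi_row = means[means["quantity"] == "psi"].iloc[0]
    summary = {
        "species": sp,
        "status": "ok",
        "n_detection_sites": n_det,
        "max_terms": max_terms,
        "selected_model": selected.spec.label(),
        "is_null": is_null,
        "aic": selected.aic,
        "mean_psi": psi_row["mean"],
        "mean_psi_se": psi_row["se"],
    }
    for _, row in means[means["quantity"] == "rho"].iterrows():
        summary[f"rho_{row['method']}"] = row["mean"]
        summary[f"rho_{row['method']}_se"] = row["se"]
    if gof_result is not None:
        for k, p in gof_result.p_value.items():
            summary[f"gof_p_{k}"] = p
    return {"summary": summary, "surface": surface, "is_null": is_null}


def summarize_run(run_dir: str | Path) -> pd.DataFrame:
    """Per-species summary table of a (possibly partial) run."""
    run_dir = Path(run_dir)
    path = run_dir / "summary.csv"
    if path.exists():
        return pd.read_csv(path)
    rows = []
    species_dir = run_dir / "species"
    if species_dir.exists():
        for sp_dir in sorted(species_dir.iterdir()):
            row = {"species": sp_dir.name}
            model_path = sp_dir / "selected_model.json"
            if model_path.exists():
                fitted = occu_model.FittedModel.read(model_path)
                row.update(status="ok", selected_model=fitted.spec.label(), aic=fitted.aic)
            else:
                row["status"] = "incomplete"
            rows.append(row)
    return pd.DataFrame(rows, columns=["species", "status", "selected_model", "aic"])
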