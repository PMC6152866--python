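"""All-subsets model enumeration, AIC ranking and best-model selection.

Candidate occupancy structures are every subset of the screened
covariates, optionally with quadratic terms (a quadratic only enters
together with its linear term), crossed with every subset of the
detection covariates.  The number of covariate terms per model is capped
at a 1:10 ratio with the number of sites where the species was detected.
Models are ranked by AIC; the candidate set retained for screening is
the models with delta-AIC strictly below six, walked in rank order with
boundary-estimate, goodness-of-fit and user-supplied screens; if every
retained model is rejected the species falls back to the constant
(null) occupancy model with the method factor on detection.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Sequence

import pandas as pd

from .occu_model import FittedModel, ModelSpec

DELTA_AIC_CUTOFF = 6.0


def max_terms_for(n_detection_sites: int, ratio: int = 10) -> int:
    """Covariate-term cap from the detections rule: floor(n/ratio)."""
    if n_detection_sites < 0:
        raise ValueError("n_detection_sites must be >= 0")
    return n_detection_sites // ratio


def enumerate_models(
    psi_candidates: Sequence[str],
    p_candidates: Sequence[str] = (),
    max_terms: int | None = None,
    quadratic_allowed: dict[str, bool] | None = None,
    p_has_method_factor: bool = True,
) -> list[ModelSpec]:
    """All admissible ModelSpecs under marginality and the term cap.

    Each linear or quadratic term counts as one towards ``max_terms``
    (summed over the occupancy and detection parts); intercepts and the
    method factor are not counted.  The null model is always included.
    """
    quadratic_allowed = quadratic_allowed or {}

    psi_options = []
    for subset in _subsets(psi_candidates):
        quad_eligible = [c for c in subset if quadratic_allowed.get(c, False)]
        for quads in _subsets(quad_eligible):
            terms = tuple((c, 1) for c in subset) + tuple((c, 2) for c in quads)
            psi_options.append(terms)

    specs = []
    for psi_terms in psi_options:
        for p_sub in _subsets(p_candidates):
            n_terms = len(psi_terms) + len(p_sub)
            if max_terms is not None and n_terms > max_terms:
                continue
            specs.append(
                ModelSpec(psi_terms=psi_terms, p_terms=tuple(p_sub),
                          p_has_method_factor=p_has_method_factor)
            )
    return specs


def _subsets(items: Sequence[str]):
    for r in range(len(items) + 1):
        yield from combinations(items, r)


@dataclass
class ModelRecord:
    """One row of the ranked candidate table."""

    fitted: FittedModel
    aic: float
    delta_aic: float
    converged: bool
    boundary_flag: bool
    gof_pass: bool | None = None   # None = pending / not run
    screened_out: bool = False
    reason: str = ""

    @property
    def spec(self) -> ModelSpec:
        return self.fitted.spec


class NullFallback(Exception):
    """Raised when no candidate fit converged; caller should fit the null."""


def rank_by_aic(fits: Sequence[FittedModel]) -> list[ModelRecord]:
    """Sort converged fits ascending by AIC and attach delta-AIC.

    Ties are broken by fewer parameters, then enumeration order.  Raises
    :class:`NullFallback` when no fit converged.
    """
    converged = [(i, f) for i, f in enumerate(fits) if f.converged]
    if not converged:
        raise NullFallback("no candidate model converged")
    order = sorted(converged, key=lambda t: (t[1].aic, t[1].n_params, t[0]))
    best_aic = order[0][1].aic
    return [
        ModelRecord(
            fitted=f,
            aic=f.aic,
            delta_aic=f.aic - best_aic,
            converged=f.converged,
            boundary_flag=f.boundary_flag,
        )
        for _, f in order
    ]


def retained_set(records: Sequence[ModelRecord], cutoff: float = DELTA_AIC_CUTOFF) -> list[ModelRecord]:
    """Models with delta-AIC strictly below the cutoff."""
    return [r for r in records if r.delta_aic < cutoff]


ScreenFn = Callable[[ModelRecord], bool]


def select_best(
    records: Sequence[ModelRecord],
    screens: Sequence[ScreenFn] = (),
    null_fit: FittedModel | None = None,
    cutoff: float = DELTA_AIC_CUTOFF,
) -> tuple[FittedModel, list[ModelRecord]]:
    """Walk the retained set in rank order applying the screening rules.

    A record is rejected if it carries a boundary flag, failed any
    goodness-of-fit test (``gof_pass is False``), or any ``screens``
    predicate returns False (the hook for expert map validation).  If
    every retained model is rejected the ``null_fit`` fallback is
    returned; it must be supplied and converged in that case.
    Returns the selected fit and the (annotated) record list.
    """
    annotated = list(records)
    for rec in retained_set(annotated, cutoff):
        if rec.boundary_flag:
            rec.screened_out, rec.reason = True, "boundary estimates"
            continue
        if rec.gof_pass is False:
            rec.screened_out, rec.reason = True, "failed goodness-of-fit"
            continue
        vetoed = False
        for screen in screens:
            if not screen(rec):
                rec.screened_out, rec.reason = True, "rejected by screen"
                vetoed = True
                break
        if not vetoed:
            return rec.fitted, annotated
    if null_fit is None or not null_fit.converged:
        raise RuntimeError("all candidate models rejected and no converged null model")
    return null_fit, annotated


def records_table(records: Sequence[ModelRecord], species: str = "") -> pd.DataFrame:
    """Ranked model table for CSV export."""
    return pd.DataFrame(
        {
            "species": species,
            "model": [r.spec.label() for r in records],
            "log_lik": [r.fitted.log_lik for r in records],
            "n_params": [r.fitted.n_params for r in records],
            "aic": [r.aic for r in records],
            "delta_aic": [r.delta_aic for r in records],
            "converged": [r.converged for r in records],
            "boundary_flag": [r.boundary_flag for r in records],
            "gof_pass": [r.gof_pass for r in records],
            "screened_out": [r.screened_out for r in records],
            "reason": [r.reason for r in records],
        }
    )
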