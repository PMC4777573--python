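"""Cage-experiment models: exposure effect, distance decay, validation, surface.

* GLMM-1: binomial mixed model of 24-h mortality on sex, permethrin
  concentration and exposure status (plus the sex interactions), with random
  intercepts for treatment date and line-within-date.
* GLMM-2: binomial mixed model of mortality on distance to the spraying
  itinerary, exposed cages only, same random structure.
* Validation: for sentinel cages at known distances, the number of dead
  adults is simulated from the fixed-part predicted mortality (10,000
  binomial draws by default); observations outside the empirical
  0.025-0.975 quantile band are flagged.
* Mortality surface: fixed-part predictions over a user-supplied distance
  grid, with area fractions above mortality thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model_io import CageRecord, CageRole
from .mixed_models import MixedModelFit, ModelSpec, fit_glmm, predict_response

__all__ = [
    "ValidationResult",
    "MortalitySurface",
    "cage_data_frame",
    "run_glmm1",
    "run_glmm2",
    "validate_cages",
    "mortality_surface",
]

#: GC-MS detection threshold; concentrations below it are coded as zero.
PERMETHRIN_DETECTION_LIMIT = 0.0006


def cage_data_frame(
    cages: Sequence[CageRecord],
    roles: Sequence[CageRole] = (CageRole.EXPOSED, CageRole.CONTROL),
) -> pd.DataFrame:
    """Model-ready frame, one row per cage x sex, restricted to ``roles``."""
    rows = []
    for r in cages:
        if r.role not in roles:
            continue
        perm = r.permethrin_ug_cm2
        if perm < PERMETHRIN_DETECTION_LIMIT:
            perm = 0.0
        rows.append(
            {
                "treatment_id": r.treatment_id,
                "line_id": r.line_id,
                "role": r.role.value,
                "exposed": "exposed" if r.role == CageRole.EXPOSED else "control",
                "distance_m": r.distance_m,
                "sex": r.sex.value,
                "n_initial": r.n_initial,
                "n_dead_24h": r.n_dead_24h,
                "permethrin": perm,
            }
        )
    if not rows:
        raise ValueError("no cage records for the requested roles")
    return pd.DataFrame(rows)


GLMM1_SPEC = ModelSpec(
    family="binomial",
    response="n_dead_24h",
    trials="n_initial",
    fixed_terms=["sex", "permethrin", "exposed", "sex:permethrin", "sex:exposed"],
    random_intercepts=["treatment_id/line_id"],
    reference_levels={"sex": "female", "exposed": "control"},
)

GLMM2_SPEC = ModelSpec(
    family="binomial",
    response="n_dead_24h",
    trials="n_initial",
    fixed_terms=["distance_m"],
    random_intercepts=["treatment_id/line_id"],
)


def run_glmm1(cages: Sequence[CageRecord]) -> MixedModelFit:
    """Exposure-effect model on exposed + control cages (females/control as
    reference levels).  The all-pairwise-interaction description collapses to
    the two sex interactions: permethrin is identically zero in control cages,
    so exposure x permethrin is not identifiable and is omitted."""
    data = cage_data_frame(cages, roles=(CageRole.EXPOSED, CageRole.CONTROL))
    if data["exposed"].nunique() < 2:
        raise ValueError("need both exposed and control cages for GLMM-1")
    return fit_glmm(GLMM1_SPEC, data)


def run_glmm2(cages: Sequence[CageRecord]) -> MixedModelFit:
    """Distance-decay model on exposed cages only."""
    data = cage_data_frame(cages, roles=(CageRole.EXPOSED,))
    if data["distance_m"].nunique() < 2:
        raise ValueError("need at least two distinct distances for GLMM-2")
    return fit_glmm(GLMM2_SPEC, data)


@dataclass(frozen=True)
class ValidationResult:
    treatment_id: str
    cage_id: str
    distance_m: float
    n_initial: int
    observed_dead: int
    predicted_p: float
    q_low: float
    q_high: float
    flag: str  # "under" | "within" | "over"

    def as_dict(self) -> dict:
        return {
            "treatment_id": self.treatment_id,
            "cage_id": self.cage_id,
            "distance_m": self.distance_m,
            "n_initial": self.n_initial,
            "observed_dead": self.observed_dead,
            "predicted_p": self.predicted_p,
            "q_low": self.q_low,
            "q_high": self.q_high,
            "flag": self.flag,
        }


def validate_cages(
    fit2: MixedModelFit,
    validation_cages: Sequence[CageRecord],
    n_sim: int = 10_000,
    seed: int | None = 0,
) -> list[ValidationResult]:
    """Simulation-based validation of the distance model at sentinel cages.

    Sexes are pooled to cage-level totals.  For each treatment x cage the
    predicted mortality (fixed part only — sentinel locations are not levels
    of the fitted random effects) parameterises ``n_sim`` binomial draws;
    the observed death count is classified against the empirical 0.025 and
    0.975 quantiles.
    """
    if not fit2.converged:
        raise ValueError("distance model did not converge; refusing to validate")
    if n_sim < 1000:
        warnings.warn(
            f"n_sim={n_sim} < 1000: quantile estimates will be unstable",
            RuntimeWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    pooled: dict[tuple[str, str], dict] = {}
    for r in validation_cages:
        key = (r.treatment_id, r.line_id)
        slot = pooled.setdefault(
            key, {"n": 0, "dead": 0, "distance": r.distance_m}
        )
        slot["n"] += r.n_initial
        slot["dead"] += r.n_dead_24h
        if slot["distance"] != r.distance_m:
            raise ValueError(f"cage {key} has inconsistent distances")

    results = []
    for (tid, cage_id), slot in sorted(pooled.items()):
        p = float(
            predict_response(
                fit2,
                pd.DataFrame({"distance_m": [slot["distance"]]}),
                include_random=False,
            )[0]
        )
        draws = rng.binomial(slot["n"], p, size=n_sim)
        q_low, q_high = np.quantile(draws, [0.025, 0.975], method="inverted_cdf")
        observed = slot["dead"]
        if observed < q_low:
            flag = "under"
        elif observed > q_high:
            flag = "over"
        else:
            flag = "within"
        results.append(
            ValidationResult(
                treatment_id=tid,
                cage_id=cage_id,
                distance_m=slot["distance"],
                n_initial=slot["n"],
                observed_dead=observed,
                predicted_p=p,
                q_low=float(q_low),
                q_high=float(q_high),
                flag=flag,
            )
        )
    return results


@dataclass
class MortalitySurface:
    distance_grid: np.ndarray
    mask: np.ndarray  # True where the cell counts (not occupied by buildings)
    predicted: np.ndarray  # NaN outside the mask
    threshold_fractions: dict[float, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_cells": int(self.mask.sum()),
            "threshold_fractions": {
                str(k): v for k, v in self.threshold_fractions.items()
            },
        }


def mortality_surface(
    fit2: MixedModelFit,
    distance_grid: np.ndarray,
    mask: np.ndarray | None = None,
    thresholds: Sequence[float] = (0.5, 0.75),
) -> MortalitySurface:
    """Fixed-part mortality predictions over a plain distance grid.

    ``distance_grid`` holds the distance (m) of each cell to the spraying
    itinerary; ``mask`` selects the cells that count toward area fractions
    (e.g. excluding building footprints).  For each threshold the fraction of
    unmasked cells with predicted mortality above it is reported.
    """
    grid = np.asarray(distance_grid, dtype=float)
    if mask is None:
        mask = np.isfinite(grid)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.shape:
        raise ValueError("mask shape differs from grid shape")
    if not mask.any():
        raise ValueError("empty mask: no cells to evaluate")
    flat = grid[mask]
    pred = predict_response(
        fit2, pd.DataFrame({"distance_m": flat}), include_random=False
    )
    surface = np.full(grid.shape, np.nan)
    surface[mask] = pred
    fractions = {
        float(thr): float(np.mean(pred > thr)) for thr in sorted(thresholds)
    }
    return MortalitySurface(
        distance_grid=grid,
        mask=mask,
        predicted=surface,
        threshold_fractions=fractions,
    )
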