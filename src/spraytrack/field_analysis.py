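"""Field models: water-leftover eco-climatic proxies and abundance vs water.

* LMM-1 / LMM-2: Gaussian mixed models of trap water leftover on a weather
  driver (mean daily maximum temperature, or daily rainfall, aggregated over
  each 72-h trap exposure window), site and their interaction, with random
  intercepts for collection date and trap.
* GLMM-3: Poisson mixed model of per-trap adult counts on water leftover,
  site and their interaction, same random structure, untreated site as the
  reference level.
"""

from __future__ import annotations

import datetime as _dt
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model_io import Site, TrapRecord, WeatherRecord
from .mixed_models import MixedModelFit, ModelSpec, fit_glmm, fit_lmm

__all__ = [
    "trap_model_frame",
    "join_weather",
    "run_lmm_water",
    "run_glmm3",
    "predicted_abundance_curves",
]


def trap_model_frame(traps: Sequence[TrapRecord]) -> pd.DataFrame:
    """One row per active trap x collection, ready for the mixed models."""
    rows = [
        {
            "trap_id": r.trap_id,
            "site": r.site.value,
            "collection": r.collection_index,
            "collection_date": r.collection_date,
            "count": r.n_total,
            "water": r.water_leftover,
        }
        for r in traps
        if r.active
    ]
    if not rows:
        raise ValueError("no active trap records")
    frame = pd.DataFrame(rows)
    frame["collection"] = frame["collection"].astype(str)
    return frame


def join_weather(
    frame: pd.DataFrame,
    weather: Sequence[WeatherRecord],
    *,
    window_days: int = 3,
    rainfall_aggregate: str = "mean",
) -> pd.DataFrame:
    """Attach per-collection weather aggregates over the exposure window.

    Each collection's window is the ``window_days`` days ending on the
    collection date.  ``tmax`` is averaged; ``rainfall`` is averaged by
    default (``rainfall_aggregate="sum"`` switches to the window total).
    Collections whose window is not fully covered by the weather series raise,
    listing the missing dates.
    """
    if rainfall_aggregate not in {"mean", "sum"}:
        raise ValueError("rainfall_aggregate must be 'mean' or 'sum'")
    by_date = {w.date: w for w in weather}
    tmax_by_coll: dict[str, float] = {}
    rain_by_coll: dict[str, float] = {}
    missing: list[str] = []
    for coll, cdate in (
        frame[["collection", "collection_date"]].drop_duplicates().itertuples(index=False)
    ):
        window = [cdate - _dt.timedelta(days=k) for k in range(window_days - 1, -1, -1)]
        absent = [d for d in window if d not in by_date]
        if absent:
            missing.extend(d.isoformat() for d in absent)
            continue
        tmax_by_coll[coll] = float(np.mean([by_date[d].tmax for d in window]))
        rain = [by_date[d].rainfall for d in window]
        rain_by_coll[coll] = float(np.sum(rain) if rainfall_aggregate == "sum" else np.mean(rain))
    if missing:
        raise ValueError(
            "weather series does not cover all exposure windows; missing dates: "
            + ", ".join(sorted(set(missing)))
        )
    out = frame.copy()
    out["tmax"] = out["collection"].map(tmax_by_coll)
    out["rainfall"] = out["collection"].map(rain_by_coll)
    return out


def run_lmm_water(
    traps: Sequence[TrapRecord],
    weather: Sequence[WeatherRecord],
    driver: str = "temperature",
    *,
    rainfall_aggregate: str = "mean",
) -> MixedModelFit:
    """Water-leftover proxy model (LMM-1 for temperature, LMM-2 for rainfall)."""
    if driver not in {"temperature", "rainfall"}:
        raise ValueError("driver must be 'temperature' or 'rainfall'")
    frame = join_weather(
        trap_model_frame(traps), weather, rainfall_aggregate=rainfall_aggregate
    )
    col = "tmax" if driver == "temperature" else "rainfall"
    if frame[col].nunique() < 2:
        raise ValueError(
            f"driver {driver!r} is constant across collections; slope unidentifiable"
        )
    spec = ModelSpec(
        family="gaussian",
        response="water",
        fixed_terms=[col, "site", f"{col}:site"],
        random_intercepts=["collection", "trap_id"],
        reference_levels={"site": Site.UNTREATED.value},
    )
    return fit_lmm(spec, frame)


GLMM3_SPEC = ModelSpec(
    family="poisson",
    response="count",
    fixed_terms=["water", "site", "water:site"],
    random_intercepts=["collection", "trap_id"],
    reference_levels={"site": Site.UNTREATED.value},
)


def run_glmm3(traps: Sequence[TrapRecord]) -> MixedModelFit:
    """Abundance model: count ~ water x site + (1|collection) + (1|trap)."""
    return fit_glmm(GLMM3_SPEC, trap_model_frame(traps))


def predicted_abundance_curves(
    fit3: MixedModelFit,
    water_range: Sequence[float] | None = None,
    *,
    level: float = 0.95,
) -> pd.DataFrame:
    """Fixed-part predicted mean abundance per site over a water grid.

    Intervals are delta-method (Wald) intervals on the linear predictor,
    exponentiated.  Returns a long frame: site, water, mean, lo, hi.
    """
    if not fit3.converged:
        raise ValueError("model did not converge")
    if fit3.vcov is None or fit3.design_info is None:
        raise ValueError("fit lacks covariance/design information")
    if water_range is None:
        water_range = np.linspace(0.0, 6.0, 61)
    water = np.asarray(water_range, dtype=float)
    zq = stats.norm.ppf(0.5 + level / 2)
    frames = []
    for site in (Site.UNTREATED.value, Site.TREATED.value):
        newdata = pd.DataFrame({"water": water, "site": site})
        X = fit3.design_info.build(newdata)
        eta = X @ fit3.beta
        se = np.sqrt(np.einsum("ij,jk,ik->i", X, fit3.vcov, X))
        frames.append(
            pd.DataFrame(
                {
                    "site": site,
                    "water": water,
                    "mean": np.exp(eta),
                    "lo": np.exp(eta - zq * se),
                    "hi": np.exp(eta + zq * se),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
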