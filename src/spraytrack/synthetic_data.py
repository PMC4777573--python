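"""Synthetic two-site sticky-trap monitoring and cage-experiment generators.

The generators target the *statistical* structure assumed by the downstream
models, not mosquito biology:

* trap counts are Poisson with a log-mean built from a seasonal curve, a site
  offset, a per-site water-leftover slope, crossed random intercepts for
  collection date and trap, and a step suppression of the treated site from a
  configurable divergence collection onward;
* water leftover follows rainfall (up) and maximum-temperature excess (down)
  around the 5 dl initial fill, truncated at zero and capped;
* cage mortality is binomial with a logistic distance decay and random
  intercepts for treatment date and line-within-date; permethrin deposition
  decays exponentially with distance under log-normal noise.

Everything is reproducible: a single integer seed drives all draws.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .data_model_io import (
    CageRecord,
    CageRole,
    ScheduleEntry,
    Sex,
    Site,
    TrapRecord,
    TreatmentSchedule,
    WeatherRecord,
)

__all__ = [
    "WaterModel",
    "CageModel",
    "SyntheticConfig",
    "default_seasonal_curve",
    "simulate_monitoring",
    "simulate_cage_experiment",
    "default_schedule",
]


@dataclass(frozen=True)
class WaterModel:
    """Water leftover = clamp(5 + rain_coef*rain - temp_coef*(tmax-temp_ref) + noise)."""

    rain_coef: float = 0.10  # dl per mm of rain over the 72-h window
    temp_coef: float = 0.15  # dl per degree C of mean tmax above temp_ref
    temp_ref: float = 26.0
    sd_trap_noise: float = 0.45
    initial_fill: float = 5.0
    max_water: float = 9.0


@dataclass(frozen=True)
class CageModel:
    intercept: float = 1.5  # logit mortality of exposed cages at distance 0
    distance_slope: float = -0.087  # per metre
    control_intercept: float = -3.6  # logit mortality in control cages
    sd_date: float = 0.1
    sd_line: float = 0.9  # line nested within treatment date
    perm0: float = 0.45  # ug/cm^2 deposited at distance 0
    perm_decay: float = 0.06  # exponential decay per metre
    perm_sd_log: float = 0.6
    n_initial_per_sex: int = 10


def default_seasonal_curve(n_collections: int = 36, peak: float = 18.0) -> np.ndarray:
    """Smooth unimodal log-abundance baseline peaking in mid-season (August)."""
    c = np.arange(1, n_collections + 1, dtype=float)
    return -0.3 + 1.9 * np.exp(-0.5 * ((c - peak) / 6.5) ** 2)


@dataclass
class SyntheticConfig:
    n_traps_treated: int = 24
    n_traps_untreated: int = 19
    n_collections: int = 36
    seasonal_curve: np.ndarray | None = None
    site_effect: float = -1.0  # log-scale offset of the treated site
    treatment_effect: float = 1.0  # multiplicative suppression in (0, 1]
    divergence_index: int = 15
    water_beta_treated: float = 0.0
    water_beta_untreated: float = -0.25
    sd_collection: float = 0.5
    sd_trap: float = 0.35
    water_model: WaterModel = field(default_factory=WaterModel)
    cage_model: CageModel = field(default_factory=CageModel)
    count_family: str = "poisson"  # or "nbinom" for robustness experiments
    nb_dispersion: float = 1.0  # gamma shape when count_family == "nbinom"
    start_date: _dt.date = _dt.date(2013, 6, 17)
    seed: int = 20130617

    def validate(self) -> None:
        if min(self.n_traps_treated, self.n_traps_untreated) < 1:
            raise ValueError("need at least one trap per site")
        if self.n_collections < 2 or self.n_collections % 2:
            raise ValueError("n_collections must be even and >= 2")
        if not 0 < self.treatment_effect <= 1:
            raise ValueError("treatment_effect must be in (0, 1]")
        if not 1 <= self.divergence_index <= self.n_collections:
            raise ValueError("divergence_index outside 1..n_collections")
        for name in ("sd_collection", "sd_trap"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.cage_model.sd_date < 0 or self.cage_model.sd_line < 0:
            raise ValueError("cage random-effect SDs must be >= 0")
        if self.count_family not in {"poisson", "nbinom"}:
            raise ValueError("count_family must be 'poisson' or 'nbinom'")
        if self.seasonal_curve is not None and len(self.seasonal_curve) != self.n_collections:
            raise ValueError("seasonal_curve length must equal n_collections")

    def curve(self) -> np.ndarray:
        if self.seasonal_curve is not None:
            return np.asarray(self.seasonal_curve, dtype=float)
        return default_seasonal_curve(self.n_collections)


def collection_date(config: SyntheticConfig, index: int) -> _dt.date:
    """Collection calendar date: week w holds collections 2w+1 (day-3) and 2w+2 (day-6)."""
    week, within = divmod(index - 1, 2)
    return config.start_date + _dt.timedelta(days=7 * week + (3 if within == 0 else 6))


def default_schedule(config: SyntheticConfig) -> TreatmentSchedule:
    """Eight treatments on day-7 of alternate weeks; T3 is the spray whose
    post-treatment collection is the default divergence index (15)."""
    weeks = [2, 4, 6, 8, 10, 12, 14, 16]
    entries = []
    for i, w in enumerate(weeks, start=1):
        if 2 * w + 3 > config.n_collections:
            break
        entries.append(
            ScheduleEntry(
                treatment_id=f"T{i}",
                date=config.start_date + _dt.timedelta(days=7 * w + 7),
                pre_collection_index=2 * w + 2,
                post_collection_index=2 * w + 3,
            )
        )
    return TreatmentSchedule(entries=entries)


def _simulate_weather(config: SyntheticConfig, rng: np.random.Generator) -> list[WeatherRecord]:
    last = collection_date(config, config.n_collections)
    n_days = (last - config.start_date).days + 1
    days = np.arange(n_days, dtype=float)
    peak_day = (collection_date(config, config.n_collections // 2) - config.start_date).days
    tmax = (
        24.0
        + 8.0 * np.exp(-0.5 * ((days - peak_day) / 45.0) ** 2)
        + rng.normal(0.0, 1.5, n_days)
    )
    wet = rng.random(n_days) < 0.22
    rain = np.where(wet, rng.gamma(1.4, 6.0, n_days), 0.0)
    return [
        WeatherRecord(
            date=config.start_date + _dt.timedelta(days=int(d)),
            tmax=float(t),
            rainfall=float(r),
        )
        for d, t, r in zip(days, tmax, rain)
    ]


def simulate_monitoring(
    config: SyntheticConfig,
) -> tuple[list[TrapRecord], list[WeatherRecord]]:
    """Draw a full two-site monitoring season.

    Returns trap records for every trap x collection (all active) and the
    daily weather series that drove the water leftover.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    weather = _simulate_weather(config, rng)
    by_date = {w.date: w for w in weather}
    curve = config.curve()
    wm = config.water_model

    u_coll = rng.normal(0.0, config.sd_collection, config.n_collections)
    n_traps = config.n_traps_treated + config.n_traps_untreated
    u_trap = rng.normal(0.0, config.sd_trap, n_traps)

    traps = [
        (f"TR{i + 1:02d}", Site.TREATED, i) for i in range(config.n_traps_treated)
    ] + [
        (f"UN{i + 1:02d}", Site.UNTREATED, config.n_traps_treated + i)
        for i in range(config.n_traps_untreated)
    ]

    records: list[TrapRecord] = []
    log_suppression = np.log(config.treatment_effect)
    for c in range(1, config.n_collections + 1):
        cdate = collection_date(config, c)
        window = [cdate - _dt.timedelta(days=k) for k in (2, 1, 0)]
        rain_sum = sum(by_date[d].rainfall for d in window)
        tmax_mean = float(np.mean([by_date[d].tmax for d in window]))
        base_water = (
            wm.initial_fill
            + wm.rain_coef * rain_sum
            - wm.temp_coef * (tmax_mean - wm.temp_ref)
        )
        for trap_id, site, ti in traps:
            water = float(
                np.clip(
                    base_water + rng.normal(0.0, wm.sd_trap_noise),
                    0.0,
                    wm.max_water,
                )
            )
            beta_w = (
                config.water_beta_treated
                if site is Site.TREATED
                else config.water_beta_untreated
            )
            log_mu = (
                curve[c - 1]
                + (config.site_effect if site is Site.TREATED else 0.0)
                + beta_w * water
                + u_coll[c - 1]
                + u_trap[ti]
            )
            if site is Site.TREATED and c >= config.divergence_index:
                log_mu += log_suppression
            mu = np.exp(log_mu)
            if config.count_family == "nbinom":
                mu = mu * rng.gamma(config.nb_dispersion, 1.0 / config.nb_dispersion)
            total = int(rng.poisson(mu))
            n_female = int(rng.binomial(total, 0.5)) if total else 0
            records.append(
                TrapRecord(
                    trap_id=trap_id,
                    site=site,
                    collection_index=c,
                    collection_date=cdate,
                    n_female=n_female,
                    n_male=total - n_female,
                    n_total=total,
                    water_leftover=water,
                    active=True,
                )
            )
    return records, weather


def simulate_cage_experiment(
    config: SyntheticConfig,
    n_treatments: int = 7,
    distances: Sequence[float] = (10.0, 30.0, 50.0, 70.0),
    *,
    n_lines: int = 3,
    n_control_cages: int = 3,
    validation_distances: Sequence[float] = (),
) -> list[CageRecord]:
    """Draw cage-experiment records for ``n_treatments`` sprayings (T2, T3, ...).

    Each treatment carries ``n_lines`` road lines with one exposed cage per
    distance, ``n_control_cages`` control cages (untreated site), and
    optionally validation cages at the given distances (labelled VC-1, VC-2,
    ...).  Each cage yields one record per sex.
    """
    config.validate()
    if any(d < 0 for d in distances) or any(d < 0 for d in validation_distances):
        raise ValueError("distances must be >= 0")
    cm = config.cage_model
    rng = np.random.default_rng(config.seed + 1)
    records: list[CageRecord] = []

    def draw_cage(tid, line, role, dist, p, perm):
        for sex in (Sex.FEMALE, Sex.MALE):
            dead = int(rng.binomial(cm.n_initial_per_sex, p))
            records.append(
                CageRecord(
                    treatment_id=tid,
                    line_id=line,
                    role=role,
                    distance_m=dist,
                    sex=sex,
                    n_initial=cm.n_initial_per_sex,
                    n_dead_24h=dead,
                    permethrin_ug_cm2=perm,
                )
            )

    for t in range(n_treatments):
        tid = f"T{t + 2}"
        u_date = rng.normal(0.0, cm.sd_date)
        for l in range(n_lines):
            line = f"L{l + 1}"
            u_line = rng.normal(0.0, cm.sd_line)
            for dist in distances:
                eta = cm.intercept + cm.distance_slope * dist + u_date + u_line
                p = 1.0 / (1.0 + np.exp(-eta))
                perm = float(
                    cm.perm0
                    * np.exp(-cm.perm_decay * dist)
                    * rng.lognormal(0.0, cm.perm_sd_log)
                )
                draw_cage(tid, line, CageRole.EXPOSED, float(dist), p, perm)
        for v, dist in enumerate(validation_distances, start=1):
            u_line = rng.normal(0.0, cm.sd_line)
            eta = cm.intercept + cm.distance_slope * dist + u_date + u_line
            p = 1.0 / (1.0 + np.exp(-eta))
            perm = float(
                cm.perm0
                * np.exp(-cm.perm_decay * dist)
                * rng.lognormal(0.0, cm.perm_sd_log)
            )
            draw_cage(tid, f"VC-{v}", CageRole.VALIDATION, float(dist), p, perm)
        u_line_ctrl = rng.normal(0.0, cm.sd_line)
        for k in range(n_control_cages):
            eta = cm.control_intercept + u_date + u_line_ctrl
            p = 1.0 / (1.0 + np.exp(-eta))
            draw_cage(tid, "control", CageRole.CONTROL, 0.0, p, 0.0)
    return records
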