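"""Henderson effectiveness of single adulticide treatments, caged and field.

The estimator corrects the pre/post change in the treated unit by the
contemporaneous change in the untreated (control) unit:

    raw% = 100 * (1 - (treated_after * untreated_before)
                      / (treated_before * untreated_after))

Negative values are clamped to 0 for reporting (a "minor or no reduction"
outcome); the unclamped value is retained for diagnostics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model_io import (
    CageRecord,
    CageRole,
    Site,
    TrapRecord,
    TreatmentSchedule,
)

__all__ = [
    "EffectivenessResult",
    "henderson",
    "caged_effectiveness",
    "distance_average_effectiveness",
    "field_effectiveness",
]


@dataclass(frozen=True)
class EffectivenessResult:
    treatment_id: str
    stratum: str
    treated_before: float
    treated_after: float
    untreated_before: float
    untreated_after: float
    raw_pct: float
    effectiveness_pct: float
    defined: bool = True
    note: str = ""

    def as_dict(self) -> dict:
        return {
            "treatment_id": self.treatment_id,
            "stratum": self.stratum,
            "treated_before": self.treated_before,
            "treated_after": self.treated_after,
            "untreated_before": self.untreated_before,
            "untreated_after": self.untreated_after,
            "raw_pct": self.raw_pct,
            "effectiveness_pct": self.effectiveness_pct,
            "defined": self.defined,
            "note": self.note,
        }


def henderson(
    treated_before: float,
    treated_after: float,
    untreated_before: float,
    untreated_after: float,
    *,
    treatment_id: str = "",
    stratum: str = "",
) -> EffectivenessResult:
    """Henderson effectiveness from the four mean counts.

    If ``treated_before`` or ``untreated_after`` is zero the ratio is
    undefined; the result is flagged (``defined=False``) rather than silently
    propagating NaN.
    """
    for name, value in (
        ("treated_before", treated_before),
        ("treated_after", treated_after),
        ("untreated_before", untreated_before),
        ("untreated_after", untreated_after),
    ):
        if value < 0 or not math.isfinite(value):
            raise ValueError(f"{name} must be finite and >= 0, got {value}")
    if treated_before == 0 or untreated_after == 0:
        return EffectivenessResult(
            treatment_id,
            stratum,
            treated_before,
            treated_after,
            untreated_before,
            untreated_after,
            raw_pct=float("nan"),
            effectiveness_pct=float("nan"),
            defined=False,
            note="division by zero (treated_before or untreated_after is 0)",
        )
    raw = 100.0 * (
        1.0 - (treated_after * untreated_before) / (treated_before * untreated_after)
    )
    return EffectivenessResult(
        treatment_id,
        stratum,
        treated_before,
        treated_after,
        untreated_before,
        untreated_after,
        raw_pct=raw,
        effectiveness_pct=max(0.0, raw),
    )


def _treatment_ids(cages: Iterable[CageRecord]) -> list[str]:
    seen: dict[str, None] = {}
    for c in cages:
        seen.setdefault(c.treatment_id, None)
    return sorted(seen)


def _mean_alive_pair(records: Sequence[CageRecord]) -> tuple[float, float]:
    """(mean initial, mean alive at 24 h), pooling sexes to cage-level totals."""
    per_cage: dict[tuple[str, str, float], list[CageRecord]] = {}
    for r in records:
        per_cage.setdefault((r.treatment_id, r.line_id, r.distance_m), []).append(r)
    before = [sum(r.n_initial for r in grp) for grp in per_cage.values()]
    after = [sum(r.n_alive_24h for r in grp) for grp in per_cage.values()]
    return float(np.mean(before)), float(np.mean(after))


def caged_effectiveness(
    cages: Sequence[CageRecord],
    by: str = "distance",
    *,
    max_distance: float = 50.0,
) -> list[EffectivenessResult]:
    """Per-treatment Henderson effectiveness for caged mosquitoes.

    ``by="distance"`` yields one result per treatment x distance stratum;
    ``by="treatment_leq50m"`` pools exposed cages at distances up to
    ``max_distance`` into one stratum per treatment.  Cages are closed
    systems, so "before" is the initial stocked number and "after" the 24-h
    survivors; control cages supply the untreated terms.  Treatments lacking
    control cages are skipped with a warning.
    """
    if by not in {"distance", "treatment_leq50m"}:
        raise ValueError("by must be 'distance' or 'treatment_leq50m'")
    results: list[EffectivenessResult] = []
    for tid in _treatment_ids(cages):
        t_cages = [c for c in cages if c.treatment_id == tid]
        controls = [c for c in t_cages if c.role == CageRole.CONTROL]
        exposed = [c for c in t_cages if c.role == CageRole.EXPOSED]
        if not controls:
            warnings.warn(
                f"treatment {tid}: no control cages; skipped", RuntimeWarning,
                stacklevel=2,
            )
            continue
        if not exposed:
            continue
        ub, ua = _mean_alive_pair(controls)
        if by == "distance":
            for dist in sorted({c.distance_m for c in exposed}):
                stratum_cages = [c for c in exposed if c.distance_m == dist]
                tb, ta = _mean_alive_pair(stratum_cages)
                results.append(
                    henderson(
                        tb, ta, ub, ua, treatment_id=tid, stratum=f"{dist:g}m"
                    )
                )
        else:
            stratum_cages = [c for c in exposed if c.distance_m <= max_distance]
            if not stratum_cages:
                continue
            tb, ta = _mean_alive_pair(stratum_cages)
            results.append(
                henderson(
                    tb, ta, ub, ua, treatment_id=tid,
                    stratum=f"<={max_distance:g}m",
                )
            )
    return results


def distance_average_effectiveness(
    cages: Sequence[CageRecord],
    *,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Across-treatment average effectiveness per distance, with a t-interval.

    The interval is a plain t-interval over the per-treatment clamped
    effectiveness values (convention; the source analysis does not state its
    interval method).
    """
    per = caged_effectiveness(cages, by="distance")
    rows = []
    distances = sorted({r.stratum for r in per}, key=lambda s: float(s[:-1]))
    for stratum in distances:
        vals = np.array(
            [r.effectiveness_pct for r in per if r.stratum == stratum and r.defined]
        )
        mean = float(np.mean(vals))
        if len(vals) > 1:
            half = float(
                stats.t.ppf(0.5 + ci_level / 2, len(vals) - 1)
                * np.std(vals, ddof=1)
                / np.sqrt(len(vals))
            )
        else:
            half = float("nan")
        rows.append(
            {
                "stratum": stratum,
                "n_treatments": len(vals),
                "mean_effectiveness_pct": mean,
                "ci_low": mean - half,
                "ci_high": mean + half,
            }
        )
    return pd.DataFrame(rows)


def field_effectiveness(
    traps: Sequence[TrapRecord],
    schedule: TreatmentSchedule,
    treatment_id: str,
) -> EffectivenessResult:
    """Henderson effectiveness of one spraying on wild sticky-trap counts.

    "Before" ["after"] means are taken over the active traps of each site at
    the collection immediately preceding [following] the treatment (the 72-h
    windows around spraying).  The active-trap counts used are recorded in the
    result note.
    """
    entry = schedule.entry(treatment_id)
    means: dict[tuple[Site, str], float] = {}
    counts: dict[tuple[Site, str], int] = {}
    for site in Site:
        for label, cidx in (
            ("pre", entry.pre_collection_index),
            ("post", entry.post_collection_index),
        ):
            vals = [
                r.n_total
                for r in traps
                if r.site == site and r.collection_index == cidx and r.active
            ]
            if not vals:
                return EffectivenessResult(
                    treatment_id,
                    "field",
                    float("nan"),
                    float("nan"),
                    float("nan"),
                    float("nan"),
                    raw_pct=float("nan"),
                    effectiveness_pct=float("nan"),
                    defined=False,
                    note=f"no active traps for {site.value} at collection {cidx}",
                )
            means[(site, label)] = float(np.mean(vals))
            counts[(site, label)] = len(vals)
    result = henderson(
        means[(Site.TREATED, "pre")],
        means[(Site.TREATED, "post")],
        means[(Site.UNTREATED, "pre")],
        means[(Site.UNTREATED, "post")],
        treatment_id=treatment_id,
        stratum="field",
    )
    note = (
        f"active traps treated pre/post = {counts[(Site.TREATED, 'pre')]}"
        f"/{counts[(Site.TREATED, 'post')]}, untreated pre/post = "
        f"{counts[(Site.UNTREATED, 'pre')]}/{counts[(Site.UNTREATED, 'post')]}"
    )
    return EffectivenessResult(
        **{**result.as_dict(), "note": (result.note + "; " + note).lstrip("; ")}
    )
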