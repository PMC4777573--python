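"""Treatment-induced divergence between treated and untreated series.

The chain: per-collection site mean series -> ARIMA pre-whitening (so shared
trends and autocorrelation do not inflate cross-correlations) -> Pearson
correlation of the residuals on expanding windows (shortest window = the
first ``min_len`` collections, then one collection added at a time) ->
exact dynamic-programming segmentation of the correlation sequence into
constant-mean regimes, with the number of breaks chosen by BIC.

A drop in the mosquito correlation with no accompanying drop in the water
(eco-climatic proxy) correlation is the signature that attributes the
divergence to treatment rather than climate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model_io import Site, TrapRecord, TreatmentSchedule, site_mean_series

__all__ = [
    "ResidualSeries",
    "CorrelationSeries",
    "ChangePointResult",
    "DivergenceReport",
    "prewhiten",
    "expanding_correlations",
    "detect_changepoints",
    "divergence_report",
]

DEFAULT_ORDER_GRID = tuple(
    (p, d, q) for p in range(4) for d in range(2) for q in range(4)
)


@dataclass
class ResidualSeries:
    values: np.ndarray
    arima_order: tuple[int, int, int]
    source: str = ""
    degenerate: bool = False
    fallback: bool = False


def _fit_arima_residuals(
    series: np.ndarray, order: tuple[int, int, int]
) -> tuple[np.ndarray, float]:
    """Residuals and AICc for one candidate order (raises on failure)."""
    if order == (0, 0, 0):
        # mean-plus-white-noise model: closed form (and exactly demeaned)
        n = len(series)
        resid = series - series.mean()
        s2 = float(np.mean(resid**2))
        loglik = -0.5 * n * (math.log(2 * math.pi * s2) + 1.0)
        k = 2  # constant + innovation variance
        aicc = -2.0 * loglik + 2 * k + 2 * k * (k + 1) / (n - k - 1)
        return resid, aicc

    from statsmodels.tsa.arima.model import ARIMA

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = ARIMA(series, order=order).fit()
    if not np.all(np.isfinite(fit.resid)):
        raise RuntimeError("non-finite residuals")
    resid = np.asarray(fit.resid, dtype=float)[order[1]:]  # drop differenced starts
    return resid, float(fit.aicc)


def prewhiten(
    series: Sequence[float],
    order: tuple[int, int, int] | None = None,
    *,
    order_grid: Sequence[tuple[int, int, int]] = DEFAULT_ORDER_GRID,
    source: str = "",
) -> ResidualSeries:
    """Remove autocorrelation from a per-collection mean series.

    If ``order`` is given it is fitted directly; otherwise the grid of
    candidate (p, d, q) orders is searched and the corrected-AIC minimiser is
    kept.  Non-convergent candidates are skipped; if every candidate fails,
    the series is demeaned (order (0,0,0)) with a warning.  A constant series
    is degenerate: its residuals are identically zero and flagged as such.
    """
    y = np.asarray(series, dtype=float)
    if y.ndim != 1 or len(y) < 10:
        raise ValueError("series must be one-dimensional with length >= 10")
    if not np.all(np.isfinite(y)):
        raise ValueError(
            "series contains missing values; impute or drop before pre-whitening"
        )
    if np.ptp(y) == 0:
        return ResidualSeries(
            values=np.zeros_like(y),
            arima_order=(0, 0, 0),
            source=source,
            degenerate=True,
        )
    if order is not None:
        resid, _ = _fit_arima_residuals(y, tuple(order))
        return ResidualSeries(values=resid, arima_order=tuple(order), source=source)

    best: tuple[float, tuple[int, int, int], np.ndarray] | None = None
    for cand in order_grid:
        try:
            resid, aicc = _fit_arima_residuals(y, cand)
        except Exception:
            continue
        if not math.isfinite(aicc):
            continue
        if best is None or aicc < best[0]:
            best = (aicc, tuple(cand), resid)
    if best is None:
        warnings.warn(
            "all candidate ARIMA orders failed; falling back to demeaning",
            RuntimeWarning,
            stacklevel=2,
        )
        return ResidualSeries(
            values=y - y.mean(), arima_order=(0, 0, 0), source=source, fallback=True
        )
    return ResidualSeries(values=best[2], arima_order=best[1], source=source)


@dataclass
class CorrelationSeries:
    window_ends: np.ndarray  # collection index closing each window
    r: np.ndarray
    p: np.ndarray
    n_effective: np.ndarray  # residual pairs actually correlated
    orders_a: list[tuple[int, int, int]] = field(default_factory=list)
    orders_b: list[tuple[int, int, int]] = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window_end": self.window_ends,
                "r": self.r,
                "p": self.p,
                "n_effective": self.n_effective,
                "order_a": [str(o) for o in self.orders_a],
                "order_b": [str(o) for o in self.orders_b],
            }
        )


def _pearson(a: np.ndarray, b: np.ndarray) -> tuple[float, float, int]:
    n = min(len(a), len(b))
    a, b = a[-n:], b[-n:]  # truncate to common length from the window end
    if np.std(a) == 0 or np.std(b) == 0 or n < 3:
        return float("nan"), float("nan"), n
    r, p = stats.pearsonr(a, b)
    return float(r), float(p), n


def expanding_correlations(
    series_a: Sequence[float],
    series_b: Sequence[float],
    min_len: int = 10,
    *,
    order: tuple[int, int, int] | None = None,
    order_grid: Sequence[tuple[int, int, int]] = DEFAULT_ORDER_GRID,
    mode: str = "per_window",
) -> CorrelationSeries:
    """Expanding-window Pearson correlations of pre-whitened residuals.

    ``mode="per_window"`` refits the ARIMA on every window of each series (the
    literal reading of comparing one pair of series per window);
    ``mode="full_series"`` pre-whitens each full series once and correlates
    residual prefixes, for sensitivity analysis.  P-values are two-sided
    t-tests on the effective (possibly differencing-shortened) length.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must be aligned with equal length")
    C = len(a)
    if C < min_len:
        raise ValueError(f"series length {C} < min_len {min_len}")
    if mode not in {"per_window", "full_series"}:
        raise ValueError("mode must be 'per_window' or 'full_series'")

    ends = np.arange(min_len, C + 1)
    r = np.full(len(ends), np.nan)
    p = np.full(len(ends), np.nan)
    neff = np.zeros(len(ends), dtype=int)
    orders_a: list[tuple[int, int, int]] = []
    orders_b: list[tuple[int, int, int]] = []

    if mode == "full_series":
        ra = prewhiten(a, order, order_grid=order_grid, source="a")
        rb = prewhiten(b, order, order_grid=order_grid, source="b")
        offset_a = C - len(ra.values)
        offset_b = C - len(rb.values)
        for i, k in enumerate(ends):
            r[i], p[i], neff[i] = _pearson(
                ra.values[: k - offset_a], rb.values[: k - offset_b]
            )
            orders_a.append(ra.arima_order)
            orders_b.append(rb.arima_order)
    else:
        for i, k in enumerate(ends):
            ra = prewhiten(a[:k], order, order_grid=order_grid, source="a")
            rb = prewhiten(b[:k], order, order_grid=order_grid, source="b")
            r[i], p[i], neff[i] = _pearson(ra.values, rb.values)
            orders_a.append(ra.arima_order)
            orders_b.append(rb.arima_order)

    if np.isnan(r).any():
        warnings.warn(
            "some windows produced undefined correlations (zero-variance "
            "residuals); values left as NaN",
            RuntimeWarning,
            stacklevel=2,
        )
    return CorrelationSeries(
        window_ends=ends, r=r, p=p, n_effective=neff,
        orders_a=orders_a, orders_b=orders_b,
    )


# ---------------------------------------------------------------------------
# Change-point segmentation
# ---------------------------------------------------------------------------


@dataclass
class ChangePointResult:
    break_positions: list[int]  # 1-based: break falls after this point
    segment_means: list[float]
    n_points: int
    min_segment: int
    criterion: pd.DataFrame  # per candidate break count: rss, bic

    @property
    def n_breaks(self) -> int:
        return len(self.break_positions)

    def segments(self) -> list[tuple[int, int]]:
        """1-based inclusive (start, end) of each segment."""
        bounds = [0, *self.break_positions, self.n_points]
        return [(a + 1, b) for a, b in zip(bounds, bounds[1:])]


def _segment_cost(values: np.ndarray) -> np.ndarray:
    """cost[i, j] = within-segment sum of squares of values[i:j] (j exclusive)."""
    n = len(values)
    s1 = np.concatenate([[0.0], np.cumsum(values)])
    s2 = np.concatenate([[0.0], np.cumsum(values**2)])
    cost = np.full((n + 1, n + 1), np.inf)
    for i in range(n):
        for j in range(i + 1, n + 1):
            m = j - i
            total = s1[j] - s1[i]
            cost[i, j] = (s2[j] - s2[i]) - total * total / m
    return cost


def detect_changepoints(
    values: Sequence[float] | CorrelationSeries,
    min_segment_frac: float = 0.15,
    max_breaks: int = 3,
) -> ChangePointResult:
    """Exact mean-shift segmentation of a (correlation) series.

    Dynamic programming minimises the within-segment sum of squares for every
    candidate break count 0..``max_breaks`` under a minimum segment length of
    ``ceil(min_segment_frac * n)``; BIC picks the break count (ties go to
    fewer breaks).  Segment means are arithmetic means of the member points.
    """
    if isinstance(values, CorrelationSeries):
        values = values.r
    y = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("series contains non-finite values")
    n = len(y)
    min_seg = max(1, math.ceil(min_segment_frac * n))
    if n < 2 * min_seg:
        raise ValueError(
            f"series of length {n} too short for minimum segment length {min_seg}"
        )
    cost = _segment_cost(y)

    # dp[k][j] = best cost of splitting y[:j] into k+1 segments
    feasible_k = [k for k in range(max_breaks + 1) if (k + 1) * min_seg <= n]
    dp = np.full((max(feasible_k) + 1, n + 1), np.inf)
    arg = np.full((max(feasible_k) + 1, n + 1), -1, dtype=int)
    for j in range(min_seg, n + 1):
        dp[0, j] = cost[0, j]
    for k in range(1, max(feasible_k) + 1):
        for j in range((k + 1) * min_seg, n + 1):
            best, best_i = np.inf, -1
            for i in range(k * min_seg, j - min_seg + 1):
                c = dp[k - 1, i] + cost[i, j]
                if c < best:
                    best, best_i = c, i
            dp[k, j], arg[k, j] = best, best_i

    rows = []
    for k in feasible_k:
        rss = dp[k, n]
        bic = n * math.log(max(rss, 1e-12) / n) + (2 * k + 1) * math.log(n)
        rows.append({"n_breaks": k, "rss": rss, "bic": bic})
    crit = pd.DataFrame(rows)
    best_bic = crit["bic"].min()
    chosen = int(crit.loc[crit["bic"] <= best_bic + 1e-9, "n_breaks"].min())

    breaks: list[int] = []
    j = n
    for k in range(chosen, 0, -1):
        i = int(arg[k, j])
        breaks.append(i)
        j = i
    breaks.reverse()

    bounds = [0, *breaks, n]
    means = [float(np.mean(y[a:b])) for a, b in zip(bounds, bounds[1:])]
    return ChangePointResult(
        break_positions=breaks,
        segment_means=means,
        n_points=n,
        min_segment=min_seg,
        criterion=crit,
    )


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------


@dataclass
class DivergenceReport:
    mosquito_correlations: CorrelationSeries
    mosquito_changepoints: ChangePointResult
    water_correlations: CorrelationSeries
    water_changepoints: ChangePointResult
    mosquito_break_collections: list[int]
    water_break_collections: list[int]
    treatment_dates: dict[str, str]
    attributable_to_treatment: bool

    def as_dict(self) -> dict:
        return {
            "mosquito": {
                "breaks_at_collections": self.mosquito_break_collections,
                "segment_means": self.mosquito_changepoints.segment_means,
            },
            "water": {
                "breaks_at_collections": self.water_break_collections,
                "segment_means": self.water_changepoints.segment_means,
            },
            "treatment_dates": self.treatment_dates,
            "attributable_to_treatment": self.attributable_to_treatment,
        }


def divergence_report(
    traps: Sequence[TrapRecord],
    schedule: TreatmentSchedule | None = None,
    *,
    min_len: int = 10,
    order: tuple[int, int, int] | None = None,
    order_grid: Sequence[tuple[int, int, int]] = DEFAULT_ORDER_GRID,
    mode: str = "per_window",
    min_segment_frac: float = 0.15,
    max_breaks: int = 3,
) -> DivergenceReport:
    """Run the divergence chain for mosquito counts and water leftover.

    The report flags the divergence as attributable to treatment when the
    first mosquito-correlation break precedes (or exists without) any break in
    the water-correlation series.
    """
    results = {}
    for variable in ("count", "water"):
        series = site_mean_series(list(traps), variable)
        a = series[Site.TREATED]["mean"].to_numpy()
        b = series[Site.UNTREATED]["mean"].to_numpy()
        corr = expanding_correlations(
            a, b, min_len, order=order, order_grid=order_grid, mode=mode
        )
        cps = detect_changepoints(corr, min_segment_frac, max_breaks)
        break_colls = [int(corr.window_ends[bp - 1]) for bp in cps.break_positions]
        results[variable] = (corr, cps, break_colls)

    m_breaks = results["count"][2]
    w_breaks = results["water"][2]
    if not m_breaks:
        attributable = False
    elif not w_breaks:
        attributable = True
    else:
        attributable = m_breaks[0] <= w_breaks[0]

    return DivergenceReport(
        mosquito_correlations=results["count"][0],
        mosquito_changepoints=results["count"][1],
        water_correlations=results["water"][0],
        water_changepoints=results["water"][1],
        mosquito_break_collections=m_breaks,
        water_break_collections=w_breaks,
        treatment_dates=(
            {e.treatment_id: e.date.isoformat() for e in schedule}
            if schedule is not None
            else {}
        ),
        attributable_to_treatment=attributable,
    )
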