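"""Catch-weighted distributional statistics for survey data.

A catch-weighted statistic treats each tow's environmental value (bottom
temperature or depth) as if recorded once per individual caught there, so
a station with 30 sharks counts 30 times and a null tow not at all.  The
package compares these against the unweighted station distribution:

* **thermal bias (TB)** — median catch-weighted temperature minus the
  median temperature of all fished stations; positive → the species sits
  in water warmer than the average of what the survey covered
  (a warm-water species), negative → cold-water.
* **Steno index** — width of the central 90% (5th-95th percentile) of the
  catch-weighted temperature distribution; small → stenothermal (narrow
  thermal tolerance), large → eurythermal.
* **occupancy intervals** — weighted or unweighted quantile pairs of
  temperature or depth, the "where did most of the catch come from"
  summary read off cumulative distribution functions.

Quantile convention: linear interpolation on the expanded per-individual
vector.  For integer weights the weighted quantile equals the ordinary
sample quantile of the vector in which each station value is repeated
``weight`` times; fractional weights generalize this by interpolating the
position ``h = (W−1)·p + 1`` along the cumulative weight ``W``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import (
    ComputationError,
    ConfigError,
    DegenerateWeightError,
    InsufficientDataError,
    MissingDataError,
    NoCatchError,
)
from .io import SurveyStation

VARIABLES = ("temperature", "depth")


def weighted_quantile(values, weights, p):
    """Quantile of values carrying nonnegative frequency weights.

    For integer weights this equals ``np.quantile(expanded, p)`` with
    linear interpolation, where ``expanded`` repeats each value by its
    weight.  ``p`` may be a scalar or array; zero-weight values never
    influence the result.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape or v.ndim != 1:
        raise ValueError("values and weights must be 1-d arrays of equal length")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    keep = w > 0
    v, w = v[keep], w[keep]
    if v.size == 0:
        raise DegenerateWeightError("all weights are zero")
    p_arr = np.atleast_1d(np.asarray(p, dtype=float))
    if np.any((p_arr < 0) | (p_arr > 1)):
        raise ValueError("p must lie in [0, 1]")
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    cw = np.cumsum(w)
    total = cw[-1]
    h = np.clip((total - 1.0) * p_arr + 1.0, 1.0, total)
    j_lo = np.floor(h)
    # value at expanded position j: first k with cumulative weight ≥ j
    x_lo = v[np.searchsorted(cw, j_lo, side="left")]
    x_hi = v[np.searchsorted(cw, np.minimum(j_lo + 1.0, total), side="left")]
    out = x_lo + (h - j_lo) * (x_hi - x_lo)
    return float(out[0]) if np.isscalar(p) or np.ndim(p) == 0 else out


@dataclass(frozen=True)
class WeightedECDF:
    """Right-continuous weighted empirical CDF on a merged support."""

    support: np.ndarray  # strictly increasing
    cum_weights: np.ndarray  # normalized, nondecreasing, ends at 1

    def __call__(self, x):
        idx = np.searchsorted(self.support, np.asarray(x, dtype=float), side="right")
        padded = np.concatenate([[0.0], self.cum_weights])
        out = padded[idx]
        return float(out) if np.ndim(x) == 0 else out

    def as_table(self):
        import pandas as pd

        return pd.DataFrame({"value": self.support, "cumulative_weight": self.cum_weights})


def weighted_ecdf(values, weights=None) -> WeightedECDF:
    """Weighted ECDF; with unit weights it is the ordinary empirical CDF."""
    v = np.asarray(values, dtype=float)
    w = np.ones_like(v) if weights is None else np.asarray(weights, dtype=float)
    if v.shape != w.shape or v.ndim != 1:
        raise ValueError("values and weights must be 1-d arrays of equal length")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    keep = w > 0
    v, w = v[keep], w[keep]
    if v.size == 0:
        raise DegenerateWeightError("all weights are zero")
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    support, inverse = np.unique(v, return_inverse=True)
    mass = np.zeros_like(support)
    np.add.at(mass, inverse, w)
    cum = np.cumsum(mass) / mass.sum()
    cum[-1] = 1.0  # exact despite rounding
    return WeightedECDF(support=support, cum_weights=cum)


# ---------------------------------------------------------------------------
# station-level statistics

def _extract(stations: Sequence[SurveyStation], variable: str, season: Optional[str] = None):
    """(values, catches, n_missing) for a variable, excluding missing values."""
    if variable not in VARIABLES:
        raise ConfigError(f"unknown variable {variable!r}; expected one of {VARIABLES}")
    vals, catches, missing = [], [], 0
    for s in stations:
        if season is not None and s.survey != season:
            continue
        x = s.bottom_temp if variable == "temperature" else s.depth
        if x is None:
            missing += 1
            continue
        vals.append(float(x))
        catches.append(float(s.catch_count or 0))
    return np.asarray(vals), np.asarray(catches), missing


def thermal_bias(stations: Sequence[SurveyStation], season: Optional[str] = None) -> float:
    """Median catch-weighted temperature minus median station temperature.

    The unweighted median runs over every temperature-valid station,
    null tows included; the weighted median over the same stations with
    catch counts as frequency weights.
    """
    temps, catches, _ = _extract(stations, "temperature", season)
    if temps.size == 0:
        raise MissingDataError("no stations with valid temperature")
    if catches.sum() <= 0:
        raise NoCatchError("total catch is zero among temperature-valid stations")
    weighted = weighted_quantile(temps, catches, 0.5)
    unweighted = weighted_quantile(temps, np.ones_like(temps), 0.5)
    return float(weighted - unweighted)


def steno_index(
    stations: Sequence[SurveyStation],
    season: Optional[str] = None,
    percentiles: tuple[float, float] = (0.05, 0.95),
) -> float:
    """Width of the central catch-weighted temperature range (°C).

    Default percentiles (0.05, 0.95) span 90% of the individuals caught.
    """
    temps, catches, _ = _extract(stations, "temperature", season)
    if temps.size == 0:
        raise MissingDataError("no stations with valid temperature")
    if catches.sum() <= 0:
        raise NoCatchError("total catch is zero among temperature-valid stations")
    lo, hi = weighted_quantile(temps, catches, np.asarray(percentiles))
    return float(hi - lo)


def occupancy_interval(
    stations: Sequence[SurveyStation],
    variable: str,
    lo_p: float = 0.05,
    hi_p: float = 0.95,
    weighted: bool = True,
    season: Optional[str] = None,
) -> tuple[float, float]:
    """Quantile pair of temperature or depth, catch-weighted or not.

    ``weighted=True`` gives the range holding the central mass of
    individuals caught; ``weighted=False`` the range of fishing effort.
    """
    if not 0.0 <= lo_p < hi_p <= 1.0:
        raise ConfigError("require 0 ≤ lo_p < hi_p ≤ 1")
    vals, catches, _ = _extract(stations, variable, season)
    if vals.size == 0:
        raise MissingDataError(f"no stations with valid {variable}")
    w = catches if weighted else np.ones_like(vals)
    if w.sum() <= 0:
        raise NoCatchError("total catch is zero among valid stations")
    lo, hi = weighted_quantile(vals, w, np.asarray([lo_p, hi_p]))
    return float(lo), float(hi)


def interval_width(interval: tuple[float, float]) -> float:
    """Width ``hi − lo`` of an occupancy interval."""
    lo, hi = interval
    if hi < lo:
        raise ComputationError(f"inverted interval: ({lo}, {hi})")
    return float(hi - lo)


def seasonal_mean_compare(values_a, values_b):
    """One-way two-group ANOVA: ``(F, p, (df_between, df_within))``.

    With two groups F equals the square of the pooled-variance two-sample
    t statistic, the identity the tests verify.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs at least 2 values")
    f, p = stats.f_oneway(a, b)
    return float(f), float(p), (1, int(a.size + b.size - 2))


@dataclass
class NicheSummary:
    """Bundle of the niche indices for one variable and season scope."""

    variable: str
    season: Optional[str]
    tb: Optional[float]  # °C; temperature only
    steno: float
    interval: tuple[float, float]
    interval_unweighted: tuple[float, float]
    percentiles: tuple[float, float]
    n_stations: int
    n_missing: int
    total_catch: float

    @property
    def classification(self) -> Optional[str]:
        """Sign-based thermal-affinity label; no stenothermal cutoff is
        imposed because the index has no canonical classification
        threshold — the raw value is the result."""
        if self.tb is None:
            return None
        return "warmwater" if self.tb > 0 else "coldwater"

    def as_dict(self) -> dict:
        return {
            "variable": self.variable,
            "season": self.season,
            "tb": self.tb,
            "classification": self.classification,
            "steno": self.steno,
            "interval": list(self.interval),
            "interval_unweighted": list(self.interval_unweighted),
            "percentiles": list(self.percentiles),
            "n_stations": self.n_stations,
            "n_missing": self.n_missing,
            "total_catch": self.total_catch,
        }


def niche_summary(
    stations: Sequence[SurveyStation],
    variable: str = "temperature",
    lo_p: float = 0.05,
    hi_p: float = 0.95,
    season: Optional[str] = None,
) -> NicheSummary:
    """TB (temperature only), Steno-style range width, occupancy intervals
    and provenance counts for one variable.

    TB and the Steno index pool both seasonal surveys across all years
    unless a season filter is given; the percentile convention used is
    recorded in the summary.
    """
    vals, catches, n_missing = _extract(stations, variable, season)
    if vals.size == 0:
        raise MissingDataError(f"no stations with valid {variable}")
    if catches.sum() <= 0:
        raise NoCatchError("total catch is zero")
    interval = occupancy_interval(stations, variable, lo_p, hi_p, True, season)
    interval_unw = occupancy_interval(stations, variable, lo_p, hi_p, False, season)
    tb = thermal_bias(stations, season) if variable == "temperature" else None
    lo, hi = weighted_quantile(vals, catches, np.asarray([lo_p, hi_p]))
    return NicheSummary(
        variable=variable,
        season=season,
        tb=tb,
        steno=float(hi - lo),
        interval=interval,
        interval_unweighted=interval_unw,
        percentiles=(lo_p, hi_p),
        n_stations=int(vals.size),
        n_missing=int(n_missing),
        total_catch=float(catches.sum()),
    )
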