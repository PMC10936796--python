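"""Diet composition, subgroup habitat envelopes, and the annual
abundance index.

Diet follows standard stomach-content conventions: the vacuity index is
the percentage of all examined stomachs that are empty; frequency of
occurrence (%O) for a prey category is the percentage of *non-empty*
stomachs containing it (values may sum past 100 through co-occurrence);
weight percent is the category's share of total content mass.

Habitat envelopes summarize where a subgroup of individuals (e.g. sharks
≤ 20 cm as presumptive juveniles, or late-stage pregnant females) was
caught: each selected individual inherits its station's depth,
temperature and position, and the summary runs over individuals — a tow
with k selected sharks contributes k times.  The intersection of two
envelopes (e.g. pregnant females ∩ small juveniles) approximates a
critical reproductive habitat as a joint depth-temperature window.

The annual abundance index is mean catch per tow per (year, season),
null tows included; raw totals are kept alongside so any alternative
normalization can be recomputed, and an optional OLS trend of the index
on year carries a 95% confidence interval on its slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    EmptySubgroupError,
    InsufficientDataError,
    UndefinedVariableError,
)
from .io import STOMACH_CATEGORIES, BioSample, StomachRecord, SurveyStation


@dataclass
class DietSummary:
    """Stomach-content composition.

    ``occurrence`` and ``weight_percent`` are ``None`` when every stomach
    was empty (the ratios are then undefined, not zero).
    """

    n_stomachs: int
    n_empty: int
    vacuity: float  # % of all stomachs empty
    occurrence: Optional[dict[str, float]]  # %O of non-empty stomachs
    weight_percent: Optional[dict[str, float]]  # % of total content mass

    def as_dict(self) -> dict:
        return {
            "n_stomachs": self.n_stomachs,
            "n_empty": self.n_empty,
            "vacuity": self.vacuity,
            "occurrence": self.occurrence,
            "weight_percent": self.weight_percent,
        }


def diet_summary(stomachs: Sequence[StomachRecord]) -> DietSummary:
    """Vacuity, frequency of occurrence and weight percent per category."""
    stomachs = list(stomachs)
    if not stomachs:
        raise InsufficientDataError("no stomachs to summarize")
    n = len(stomachs)
    n_empty = sum(1 for s in stomachs if s.is_empty)
    nonempty = [s for s in stomachs if not s.is_empty]
    vacuity = 100.0 * n_empty / n
    if not nonempty:
        return DietSummary(n, n_empty, vacuity, None, None)
    occurrence = {
        c: 100.0 * sum(1 for s in nonempty if getattr(s, c) > 0) / len(nonempty)
        for c in STOMACH_CATEGORIES
    }
    total_mass = sum(s.total_content() for s in nonempty)
    if total_mass > 0:
        weight_percent = {
            c: 100.0 * sum(getattr(s, c) for s in nonempty) / total_mass
            for c in STOMACH_CATEGORIES
        }
    else:
        weight_percent = None
    return DietSummary(n, n_empty, vacuity, occurrence, weight_percent)


@dataclass
class EnvelopeSummary:
    """Environmental envelope of a subgroup, aggregated over individuals."""

    label: str
    n: int
    depth_min: float
    depth_mean: float
    depth_max: float
    temp_min: Optional[float]
    temp_mean: Optional[float]
    temp_max: Optional[float]
    n_missing_temp: int
    lat_range: tuple[float, float]
    lon_range: tuple[float, float]

    def interval(self, variable: str) -> tuple[float, float]:
        if variable == "depth":
            return (self.depth_min, self.depth_max)
        if variable == "temperature":
            if self.temp_min is None:
                raise UndefinedVariableError(
                    f"envelope {self.label!r} has no temperature data"
                )
            return (self.temp_min, self.temp_max)
        raise UndefinedVariableError(f"unknown envelope variable {variable!r}")

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "n": self.n,
            "depth": [self.depth_min, self.depth_mean, self.depth_max],
            "temperature": (
                None if self.temp_min is None
                else [self.temp_min, self.temp_mean, self.temp_max]
            ),
            "n_missing_temp": self.n_missing_temp,
            "lat_range": list(self.lat_range),
            "lon_range": list(self.lon_range),
        }


def subgroup_envelope(
    stations: Sequence[SurveyStation],
    samples: Sequence[BioSample],
    predicate: Callable[[BioSample], bool],
    label: str = "subgroup",
) -> EnvelopeSummary:
    """Depth/temperature/position envelope of the individuals selected by
    ``predicate``, each inheriting its station's environment.

    Individuals whose station lacks a temperature are excluded from the
    temperature statistics only; the exclusion count is reported.
    """
    by_id = {s.station_id: s for s in stations}
    selected = [b for b in samples if predicate(b)]
    if not selected:
        raise EmptySubgroupError(f"predicate selected no individuals for {label!r}")
    missing_station = [b for b in selected if b.station_id not in by_id]
    if missing_station:
        raise EmptySubgroupError(
            f"{len(missing_station)} selected individuals reference unknown stations"
        )
    depths = np.array([by_id[b.station_id].depth for b in selected], dtype=float)
    temps = np.array(
        [
            by_id[b.station_id].bottom_temp
            for b in selected
            if by_id[b.station_id].bottom_temp is not None
        ],
        dtype=float,
    )
    lats = np.array([by_id[b.station_id].latitude for b in selected])
    lons = np.array([by_id[b.station_id].longitude for b in selected])
    return EnvelopeSummary(
        label=label,
        n=len(selected),
        depth_min=float(depths.min()),
        depth_mean=float(depths.mean()),
        depth_max=float(depths.max()),
        temp_min=float(temps.min()) if temps.size else None,
        temp_mean=float(temps.mean()) if temps.size else None,
        temp_max=float(temps.max()) if temps.size else None,
        n_missing_temp=len(selected) - temps.size,
        lat_range=(float(lats.min()), float(lats.max())),
        lon_range=(float(lons.min()), float(lons.max())),
    )


def envelope_overlap(
    a: EnvelopeSummary, b: EnvelopeSummary, variables: Sequence[str] = ("depth", "temperature")
) -> dict[str, Optional[tuple[float, float]]]:
    """Per-variable interval intersection of two envelopes.

    An empty intersection is reported as ``None`` (disjoint), not an
    error; a variable undefined in either envelope raises.
    """
    out: dict[str, Optional[tuple[float, float]]] = {}
    for var in variables:
        lo_a, hi_a = a.interval(var)
        lo_b, hi_b = b.interval(var)
        lo, hi = max(lo_a, lo_b), min(hi_a, hi_b)
        out[var] = (lo, hi) if lo <= hi else None
    return out


@dataclass
class AbundanceSeries:
    """Per-(year, season) survey catch rates plus an optional trend."""

    table: pd.DataFrame  # year, season, n_tows, total_catch, mean_catch_per_tow
    trend_slope: Optional[float] = None
    trend_slope_ci: Optional[tuple[float, float]] = None

    def as_dict(self) -> dict:
        return {
            "table": self.table.to_dict(orient="records"),
            "trend_slope": self.trend_slope,
            "trend_slope_ci": (
                None if self.trend_slope_ci is None else list(self.trend_slope_ci)
            ),
        }


def annual_abundance_index(
    stations: Sequence[SurveyStation], trend: bool = True, level: float = 0.95
) -> AbundanceSeries:
    """Mean catch per tow per (year, season), null tows included.

    When ``trend`` is set and ≥3 (year, season) points exist, an OLS line
    of the index on calendar year is fitted and the slope's confidence
    interval attached (t distribution, ``n−2`` df).
    """
    if not stations:
        raise InsufficientDataError("no stations")
    df = pd.DataFrame(
        {
            "year": [s.year for s in stations],
            "season": [s.survey for s in stations],
            "catch": [int(s.catch_count or 0) for s in stations],
        }
    )
    grouped = (
        df.groupby(["year", "season"], sort=True)["catch"]
        .agg(n_tows="size", total_catch="sum", mean_catch_per_tow="mean")
        .reset_index()
    )
    series = AbundanceSeries(table=grouped)
    if trend and len(grouped) >= 3 and grouped["year"].nunique() >= 2:
        res = stats.linregress(grouped["year"], grouped["mean_catch_per_tow"])
        tcrit = stats.t.ppf(1 - (1 - level) / 2, df=len(grouped) - 2)
        series.trend_slope = float(res.slope)
        series.trend_slope_ci = (
            float(res.slope - tcrit * res.stderr),
            float(res.slope + tcrit * res.stderr),
        )
    return series
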