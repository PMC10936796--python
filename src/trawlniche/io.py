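"""Reading, validating and writing the three survey tables.

The package works from three delimited-text tables (comma by default, any
single-character delimiter selectable), each with a header row:

``stations``
    one row per tow — ``station_id, survey, year, latitude, longitude,
    depth_m, bottom_temp_c, catch_count``
``specimens``
    one row per measured individual — ``station_id, sex, total_length_cm,
    weight_g, maturity_stage``
``stomachs``
    one row per examined stomach — ``station_id, is_empty, teleost_g,
    crustacean_g, cephalopod_g, echinoderm_g, unidentified_g``

Missing numeric fields are an empty cell or a configurable token (``NA``);
sentinel numbers are never used.  Row-level problems (negative counts,
nonpositive lengths, unknown sex codes, stages outside 1-7) reject the row
and tally the violated rule in a :class:`ValidationReport`; nothing is
dropped silently.  Coordinates are decimal degrees, west negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

import pandas as pd

from .errors import InputError, SchemaError

SEASONS = ("spring", "autumn")

STOMACH_CATEGORIES = ("teleost", "crustacean", "cephalopod", "echinoderm", "unidentified")

#: plausibility window for bottom temperature (°C); values outside are warnings
DEFAULT_TEMP_WINDOW = (-2.0, 30.0)
#: observed survey extremes (m, °C) — outside these is flagged but never rejected
OBSERVED_DEPTH_RANGE = (18.0, 1359.0)
OBSERVED_TEMP_RANGE = (-1.0, 11.0)


@dataclass(frozen=True)
class Dialect:
    """Delimited-text conventions shared by all readers and writers."""

    delimiter: str = ","
    na_token: str = "NA"
    sex_codes: dict[str, str] = field(
        default_factory=lambda: {"M": "male", "F": "female", "U": "unknown"}
    )


@dataclass
class SurveyStation:
    """One survey tow: where it fished, what it found."""

    station_id: str
    survey: str  # "spring" | "autumn"
    year: int
    latitude: float
    longitude: float
    depth: float  # tow depth, m, positive
    bottom_temp: Optional[float]  # °C; None when not recorded
    catch_count: Optional[int]  # target-species count; None = not yet assigned


@dataclass
class BioSample:
    """One measured individual."""

    station_id: str
    sex: str  # "male" | "female" | "unknown"
    total_length: float  # TL, cm
    weight: Optional[float] = None  # g
    maturity_stage: Optional[int] = None  # Stehmann 1-7


@dataclass
class StomachRecord:
    """One examined stomach: emptiness plus per-category content mass (g)."""

    station_id: str
    is_empty: bool
    teleost: float = 0.0
    crustacean: float = 0.0
    cephalopod: float = 0.0
    echinoderm: float = 0.0
    unidentified: float = 0.0

    def category_weights(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in STOMACH_CATEGORIES}

    def total_content(self) -> float:
        return sum(self.category_weights().values())


@dataclass
class ValidationReport:
    """Tally of what a reader or cross-check accepted, rejected and flagged.

    ``n_read == n_accepted + n_rejected`` always holds; warnings never
    reject rows.  ``severity`` is ``"ok"``, ``"warning"`` or ``"error"``.
    """

    n_read: int = 0
    n_accepted: int = 0
    n_rejected: int = 0
    violations: dict[str, int] = field(default_factory=dict)
    warnings: dict[str, int] = field(default_factory=dict)

    @property
    def severity(self) -> str:
        if self.n_rejected or self.violations:
            return "error"
        if self.warnings:
            return "warning"
        return "ok"

    def reject(self, rule: str) -> None:
        self.n_rejected += 1
        self.violations[rule] = self.violations.get(rule, 0) + 1

    def violate(self, rule: str, n: int = 1) -> None:
        if n:
            self.violations[rule] = self.violations.get(rule, 0) + n

    def warn(self, rule: str, n: int = 1) -> None:
        if n:
            self.warnings[rule] = self.warnings.get(rule, 0) + n

    def as_dict(self) -> dict:
        return {
            "n_read": self.n_read,
            "n_accepted": self.n_accepted,
            "n_rejected": self.n_rejected,
            "violations": dict(self.violations),
            "warnings": dict(self.warnings),
            "severity": self.severity,
        }


# ---------------------------------------------------------------------------
# parsing helpers

def _read_frame(path, dialect: Dialect, required: Sequence[str]) -> pd.DataFrame:
    p = Path(path)
    if not p.exists():
        raise InputError(f"input file not found: {p}")
    try:
        df = pd.read_csv(
            p,
            sep=dialect.delimiter,
            na_values=[dialect.na_token],
            keep_default_na=False,
            dtype=str,
            skipinitialspace=True,
        )
    except Exception as exc:  # malformed beyond row level
        raise InputError(f"could not read {p}: {exc}") from exc
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"missing required column '{col}' in {p}")
    return df


def _num(cell) -> Optional[float]:
    """Parse a cell as float; empty/NA → None; garbage → ValueError."""
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None
    s = str(cell).strip()
    if not s:
        return None
    # tolerate the typographic minus that spreadsheets export
    return float(s.replace("−", "-"))


def _int(cell) -> Optional[int]:
    v = _num(cell)
    if v is None:
        return None
    if v != int(v):
        raise ValueError(f"not an integer: {cell}")
    return int(v)


STATION_COLUMNS = (
    "station_id", "survey", "year", "latitude", "longitude",
    "depth_m", "bottom_temp_c", "catch_count",
)
SPECIMEN_COLUMNS = ("station_id", "sex", "total_length_cm", "weight_g", "maturity_stage")
STOMACH_COLUMNS = ("station_id", "is_empty") + tuple(f"{c}_g" for c in STOMACH_CATEGORIES)


def read_stations(
    path, dialect: Dialect = Dialect(), temp_window=DEFAULT_TEMP_WINDOW
) -> tuple[list[SurveyStation], ValidationReport]:
    """Parse the station table; returns accepted stations plus a report.

    An absent temperature parses as missing, never zero.  Rows with
    logically impossible values (nonpositive depth, negative or fractional
    catch, unknown season) are rejected and tallied; temperatures outside
    the plausibility window are rejected as unparseable science.
    """
    df = _read_frame(path, dialect, STATION_COLUMNS)
    report = ValidationReport(n_read=len(df))
    out: list[SurveyStation] = []
    for row in df.itertuples(index=False):
        try:
            survey = str(row.survey).strip().lower()
            if survey not in SEASONS:
                report.reject("unknown_season")
                continue
            depth = _num(row.depth_m)
            if depth is None or depth <= 0:
                report.reject("nonpositive_depth")
                continue
            catch = _int(row.catch_count)
            if catch is not None and catch < 0:
                report.reject("negative_catch")
                continue
            temp = _num(row.bottom_temp_c)
            if temp is not None and not (temp_window[0] <= temp <= temp_window[1]):
                # plausibility is a warning, never a rejection
                report.warn("implausible_temperature")
            year = _int(row.year)
            lat = _num(row.latitude)
            lon = _num(row.longitude)
            if year is None or lat is None or lon is None:
                report.reject("missing_required_field")
                continue
        except ValueError:
            report.reject("unparseable_numeric")
            continue
        out.append(
            SurveyStation(
                station_id=str(row.station_id).strip(),
                survey=survey,
                year=year,
                latitude=lat,
                longitude=lon,
                depth=depth,
                bottom_temp=temp,
                catch_count=catch,
            )
        )
    report.n_accepted = len(out)
    return out, report


def read_biosamples(
    path, dialect: Dialect = Dialect()
) -> tuple[list[BioSample], ValidationReport]:
    """Parse the specimen table.

    Sex codes are mapped through ``dialect.sex_codes`` (default M/F/U);
    unknown codes, nonpositive lengths/weights and stages outside 1-7
    reject the row.  Station-id resolution is deferred to
    :func:`validate_dataset`.
    """
    df = _read_frame(path, dialect, SPECIMEN_COLUMNS)
    report = ValidationReport(n_read=len(df))
    out: list[BioSample] = []
    for row in df.itertuples(index=False):
        try:
            code = str(row.sex).strip().upper()
            sex = dialect.sex_codes.get(code)
            if sex is None:
                report.reject("unknown_sex_code")
                continue
            tl = _num(row.total_length_cm)
            if tl is None or tl <= 0:
                report.reject("nonpositive_length")
                continue
            w = _num(row.weight_g)
            if w is not None and w <= 0:
                report.reject("nonpositive_weight")
                continue
            stage = _int(row.maturity_stage)
            if stage is not None and not (1 <= stage <= 7):
                report.reject("stage_out_of_range")
                continue
        except ValueError:
            report.reject("unparseable_numeric")
            continue
        out.append(
            BioSample(
                station_id=str(row.station_id).strip(),
                sex=sex,
                total_length=tl,
                weight=w,
                maturity_stage=stage,
            )
        )
    report.n_accepted = len(out)
    return out, report


def read_stomachs(
    path, dialect: Dialect = Dialect()
) -> tuple[list[StomachRecord], ValidationReport]:
    """Parse the stomach table; empty stomachs must carry zero content."""
    df = _read_frame(path, dialect, STOMACH_COLUMNS)
    report = ValidationReport(n_read=len(df))
    out: list[StomachRecord] = []
    truthy = {"1", "true", "yes"}
    falsy = {"0", "false", "no"}
    for row in df.itertuples(index=False):
        try:
            flag = str(row.is_empty).strip().lower()
            if flag in truthy:
                is_empty = True
            elif flag in falsy:
                is_empty = False
            else:
                report.reject("unparseable_empty_flag")
                continue
            weights = {}
            for cat in STOMACH_CATEGORIES:
                v = _num(getattr(row, f"{cat}_g"))
                weights[cat] = 0.0 if v is None else v
            if any(v < 0 for v in weights.values()):
                report.reject("negative_content_weight")
                continue
            if is_empty and any(v > 0 for v in weights.values()):
                report.reject("content_in_empty_stomach")
                continue
        except ValueError:
            report.reject("unparseable_numeric")
            continue
        out.append(StomachRecord(station_id=str(row.station_id).strip(), is_empty=is_empty, **weights))
    report.n_accepted = len(out)
    return out, report


def validate_dataset(
    stations: Sequence[SurveyStation],
    samples: Sequence[BioSample] = (),
    stomachs: Sequence[StomachRecord] = (),
) -> ValidationReport:
    """Cross-table consistency check; pure, deterministic, never raises.

    Unresolvable station references and duplicate station ids are
    violations; depths or temperatures outside the surveys' observed
    extremes (18-1359 m, −1-11 °C) are warnings only — they are observed
    bounds, not physical limits.
    """
    report = ValidationReport(
        n_read=len(stations) + len(samples) + len(stomachs),
        n_accepted=len(stations) + len(samples) + len(stomachs),
    )
    ids = [s.station_id for s in stations]
    known = set(ids)
    report.violate("duplicate_station_id", len(ids) - len(known))
    report.violate(
        "unresolved_sample_station",
        sum(1 for b in samples if b.station_id not in known),
    )
    report.violate(
        "unresolved_stomach_station",
        sum(1 for r in stomachs if r.station_id not in known),
    )
    lo_d, hi_d = OBSERVED_DEPTH_RANGE
    report.warn(
        "depth_outside_observed_range",
        sum(1 for s in stations if not (lo_d <= s.depth <= hi_d)),
    )
    lo_t, hi_t = OBSERVED_TEMP_RANGE
    report.warn(
        "temperature_outside_observed_range",
        sum(
            1
            for s in stations
            if s.bottom_temp is not None and not (lo_t <= s.bottom_temp <= hi_t)
        ),
    )
    return report


# ---------------------------------------------------------------------------
# writing

def _fmt(value, dialect: Dialect) -> str:
    if value is None:
        return dialect.na_token
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float) and value == int(value) and abs(value) < 1e15:
        return repr(value)
    return str(value)


_WRITERS: dict[type, tuple[tuple[str, ...], Callable]] = {
    SurveyStation: (
        STATION_COLUMNS,
        lambda s: (s.station_id, s.survey, s.year, s.latitude, s.longitude,
                   s.depth, s.bottom_temp, s.catch_count),
    ),
    BioSample: (
        SPECIMEN_COLUMNS,
        lambda b: (b.station_id, b.sex[0].upper(), b.total_length, b.weight, b.maturity_stage),
    ),
    StomachRecord: (
        STOMACH_COLUMNS,
        lambda r: (r.station_id, r.is_empty) + tuple(getattr(r, c) for c in STOMACH_CATEGORIES),
    ),
}


def write_table(records: Iterable, path, dialect: Dialect = Dialect(), kind: type | None = None) -> None:
    """Write a homogeneous record collection as delimited text.

    Round-trips exactly: ``read(write(x))`` reproduces every field,
    including missing markers.  An empty collection needs an explicit
    ``kind`` to pick the header.
    """
    records = list(records)
    if kind is None:
        if not records:
            raise ValueError("empty collection: pass kind= to choose the header")
        kind = type(records[0])
    if kind not in _WRITERS:
        raise TypeError(f"unsupported record type: {kind.__name__}")
    if any(type(r) is not kind for r in records):
        raise TypeError("mixed record types in one table")
    columns, tup = _WRITERS[kind]
    try:
        with open(path, "w", newline="") as fh:
            fh.write(dialect.delimiter.join(columns) + "\n")
            for r in records:
                fh.write(dialect.delimiter.join(_fmt(v, dialect) for v in tup(r)) + "\n")
    except OSError as exc:
        raise InputError(f"cannot write {path}: {exc}") from exc


def stations_frame(stations: Sequence[SurveyStation]) -> pd.DataFrame:
    """Station collection as a DataFrame (NaN for missing), for analysis code."""
    cols, tup = _WRITERS[SurveyStation]
    return pd.DataFrame([tup(s) for s in stations], columns=list(cols)).astype(
        {"year": "int64"}, errors="ignore"
    )
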