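"""End-to-end pipeline: simulate or load tables, validate, analyze, report.

A :class:`RunConfig` names the inputs (paths to the three tables, or a
generator configuration to simulate them), the analyses to run and their
parameters.  :func:`run_pipeline` executes the requested stages in
dependency order and writes a JSON report whose every numeric result sits
next to the parameter values that produced it, plus the resolved
configuration — the report bundle alone suffices to re-run the analysis.
Output is deterministic for a fixed (config, seed): no timestamps, sorted
keys.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import ecology, io, life_history, niche
from .errors import ConfigError, InputError, TrawlnicheError
from .simulate import GeneratorConfig, generate_survey

log = logging.getLogger("trawlniche")

ALL_STAGES = ("validate", "niche", "ogive", "lw", "diet", "envelope", "abundance")


@dataclass
class RunConfig:
    """Everything one pipeline run needs; serializable to YAML."""

    # inputs: either the three paths or a generator config
    stations_path: Optional[str] = None
    specimens_path: Optional[str] = None
    stomachs_path: Optional[str] = None
    generator: Optional[dict] = None  # GeneratorConfig fields
    n_stomachs: int = 27

    analyses: tuple[str, ...] = ALL_STAGES
    # niche options
    lo_p: float = 0.05
    hi_p: float = 0.95
    season: Optional[str] = None
    # ogive options
    maturity_scheme: str = life_history.DEFAULT_SCHEME
    ogive_sex: str = "female"
    n_boot: int = 200
    boot_level: float = 0.95
    # envelope options
    juvenile_max_length: float = 20.0
    pregnant_stages: tuple[int, ...] = (5, 6)

    out_dir: str = "trawlniche_out"
    seed: int = 0
    verbosity: int = 1

    def to_dict(self) -> dict:
        d = asdict(self)
        d["analyses"] = list(self.analyses)
        d["pregnant_stages"] = list(self.pregnant_stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "analyses" in d and d["analyses"] is not None:
            d["analyses"] = tuple(d["analyses"])
        if "pregnant_stages" in d and d["pregnant_stages"] is not None:
            d["pregnant_stages"] = tuple(d["pregnant_stages"])
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown run option(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _check_config(config: RunConfig) -> None:
    for stage in config.analyses:
        if stage not in ALL_STAGES:
            raise ConfigError(f"unknown analysis stage {stage!r}")
    have_specimens = config.generator is not None or config.specimens_path is not None
    have_stomachs = config.generator is not None or config.stomachs_path is not None
    if config.generator is None and config.stations_path is None:
        raise ConfigError("either input paths or a generator config is required")
    if ("ogive" in config.analyses or "lw" in config.analyses or "envelope" in config.analyses) \
            and not have_specimens:
        raise ConfigError("ogive/lw/envelope analyses need a specimen table")
    if "diet" in config.analyses and not have_stomachs:
        raise ConfigError("diet analysis needs a stomach table")


def _load_inputs(config: RunConfig, out: Path):
    if config.generator is not None:
        gen = GeneratorConfig.from_dict(dict(config.generator))
        stations, samples, stomachs = generate_survey(
            gen, seed=config.seed, n_stomachs=config.n_stomachs
        )
        io.write_table(stations, out / "stations.csv", kind=io.SurveyStation)
        io.write_table(samples, out / "specimens.csv", kind=io.BioSample)
        io.write_table(stomachs, out / "stomachs.csv", kind=io.StomachRecord)
        log.info("simulated %d stations, %d specimens, %d stomachs",
                 len(stations), len(samples), len(stomachs))
        return stations, samples, stomachs, {}
    reports = {}
    stations, rep = io.read_stations(config.stations_path)
    reports["stations"] = rep.as_dict()
    samples: list = []
    stomachs: list = []
    if config.specimens_path:
        samples, rep = io.read_biosamples(config.specimens_path)
        reports["specimens"] = rep.as_dict()
    if config.stomachs_path:
        stomachs, rep = io.read_stomachs(config.stomachs_path)
        reports["stomachs"] = rep.as_dict()
    log.info("read %d stations, %d specimens, %d stomachs",
             len(stations), len(samples), len(stomachs))
    return stations, samples, stomachs, reports


def _stage_niche(stations, config: RunConfig) -> dict:
    out = {}
    for variable in ("temperature", "depth"):
        scopes = [None, "spring", "autumn"] if config.season is None else [config.season]
        for season in scopes:
            key = f"{variable}_{season or 'pooled'}"
            try:
                s = niche.niche_summary(stations, variable, config.lo_p, config.hi_p, season)
                out[key] = s.as_dict()
            except TrawlnicheError as exc:
                out[key] = {"error": str(exc)}
    return out


def _stage_ogive(samples, config: RunConfig, seed: int) -> dict:
    records = [
        life_history.MaturityRecord(
            b.total_length,
            life_history.binarize_maturity(b.maturity_stage, config.maturity_scheme),
        )
        for b in samples
        if b.sex == config.ogive_sex and b.maturity_stage is not None
    ]
    fit = life_history.fit_maturity_ogive(records)
    result = fit.as_dict()
    result["sex"] = config.ogive_sex
    result["scheme"] = config.maturity_scheme
    if fit.converged and config.n_boot > 0:
        lo, hi = life_history.l50_ci_bootstrap(
            records, n_boot=config.n_boot, level=config.boot_level, seed=seed
        )
        result["l50_ci"] = [lo, hi]
        result["l50_ci_level"] = config.boot_level
    return result


def _stage_lw(samples) -> dict:
    pairs = [(b.total_length, b.weight) for b in samples if b.weight is not None]
    fit = life_history.fit_length_weight(
        [p[0] for p in pairs], [p[1] for p in pairs]
    )
    return fit.as_dict()


def _stage_envelope(stations, samples, config: RunConfig) -> dict:
    out: dict = {}
    try:
        juv = ecology.subgroup_envelope(
            stations, samples,
            lambda b: b.total_length <= config.juvenile_max_length,
            label=f"TL<={config.juvenile_max_length:g}cm",
        )
        out["juvenile"] = juv.as_dict()
    except TrawlnicheError as exc:
        out["juvenile"] = {"error": str(exc)}
        juv = None
    stages = set(config.pregnant_stages)
    try:
        preg = ecology.subgroup_envelope(
            stations, samples,
            lambda b: b.sex == "female" and b.maturity_stage in stages,
            label=f"female_stages_{sorted(stages)}",
        )
        out["pregnant_female"] = preg.as_dict()
    except TrawlnicheError as exc:
        out["pregnant_female"] = {"error": str(exc)}
        preg = None
    if juv is not None and preg is not None:
        try:
            overlap = ecology.envelope_overlap(juv, preg)
            out["critical_habitat"] = {
                k: (None if v is None else list(v)) for k, v in overlap.items()
            }
        except TrawlnicheError as exc:
            out["critical_habitat"] = {"error": str(exc)}
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the report dict.

    Writes ``report.json`` and the resolved ``run_config.yaml`` (plus the
    simulated tables when a generator drives the run) under
    ``config.out_dir``.  Raises on configuration or input failure before
    any computation; stage errors abort with the stage name in the
    exception.
    """
    _check_config(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stations, samples, stomachs, read_reports = _load_inputs(config, out)

    report: dict = {"config": config.to_dict(), "io": read_reports, "stages": {}}
    for stage in config.analyses:
        log.info("stage %s: %d stations / %d specimens / %d stomachs",
                 stage, len(stations), len(samples), len(stomachs))
        try:
            if stage == "validate":
                report["stages"]["validate"] = io.validate_dataset(
                    stations, samples, stomachs
                ).as_dict()
            elif stage == "niche":
                report["stages"]["niche"] = _stage_niche(stations, config)
            elif stage == "ogive":
                report["stages"]["ogive"] = _stage_ogive(samples, config, config.seed)
            elif stage == "lw":
                report["stages"]["lw"] = _stage_lw(samples)
            elif stage == "diet":
                report["stages"]["diet"] = ecology.diet_summary(stomachs).as_dict()
            elif stage == "envelope":
                report["stages"]["envelope"] = _stage_envelope(stations, samples, config)
            elif stage == "abundance":
                report["stages"]["abundance"] = ecology.annual_abundance_index(stations).as_dict()
        except TrawlnicheError as exc:
            raise type(exc)(f"stage {stage!r} failed: {exc}") from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "run_config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return report
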