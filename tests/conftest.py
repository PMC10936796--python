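import numpy as np
import pytest

from trawlniche import (
    BioSample,
    GeneratorConfig,
    SurveyStation,
    generate_catches,
    generate_stations,
    generate_survey,
)


def station(
    station_id="s1",
    survey="autumn",
    year=2015,
    latitude=63.0,
    longitude=-20.0,
    depth=400.0,
    bottom_temp=7.0,
    catch_count=1,
):
    return SurveyStation(
        station_id=station_id,
        survey=survey,
        year=year,
        latitude=latitude,
        longitude=longitude,
        depth=depth,
        bottom_temp=bottom_temp,
        catch_count=catch_count,
    )


def stations_from(temps, catches, **kwargs):
    return [
        station(station_id=f"s{i}", bottom_temp=t, catch_count=c, **kwargs)
        for i, (t, c) in enumerate(zip(temps, catches))
    ]


@pytest.fixture(scope="session")
def config():
    return GeneratorConfig()


@pytest.fixture(scope="session")
def small_survey(config):
    """A full synthetic survey small enough for per-test use."""
    cfg = config.with_overrides(n_stations=400, seed=7)
    return generate_survey(cfg)


@pytest.fixture(scope="session")
def catch_stations(config):
    """Stations with catches only (medium size, shared across tests)."""
    cfg = config.with_overrides(n_stations=3000, seed=11)
    st = generate_stations(cfg)
    st, _ = generate_catches(st, cfg)
    return st


def biosample(station_id="s1", sex="female", total_length=50.0, weight=None, maturity_stage=None):
    return BioSample(
        station_id=station_id,
        sex=sex,
        total_length=total_length,
        weight=weight,
        maturity_stage=maturity_stage,
    )
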