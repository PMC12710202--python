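import pytest

from erwsim import MeteoForcing, generate_synthetic_forcing, validate_config
from erwsim.minerals import load_mineral_library


@pytest.fixture(scope="session")
def mineral_library():
    return load_mineral_library()


@pytest.fixture(scope="session")
def one_year_forcing():
    return generate_synthetic_forcing(seed=11, n_years=1)


@pytest.fixture(scope="session")
def short_forcing(one_year_forcing):
    """First 60 days of the shared one-year forcing."""
    return MeteoForcing(one_year_forcing.data.iloc[: 60 * 24].copy())


@pytest.fixture()
def control_config():
    return validate_config(
        {"schedule": {"start": "2017-01-01", "end": "2017-12-31"}}
    )


BASALT_FRACTIONS = {
    "albite": 0.196,
    "ferroactinolite": 0.116,
    "epidote": 0.256,
    "chlorite": 0.363,
    "quartz": 0.052,
}


@pytest.fixture()
def treatment_config():
    return validate_config(
        {
            "schedule": {"start": "2017-01-01", "end": "2017-12-31"},
            "feedstock": {
                "f_d": 1.0,
                "events": [
                    {
                        "date": "2017-03-01",
                        "rate": 5.0,
                        "mineral_fractions": dict(BASALT_FRACTIONS),
                    }
                ],
            },
        }
    )
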