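import numpy as np
import pytest
from hypothesis import settings

from nhrs_barometer import RawObservation, build_default_schema, mauritius_2020
from nhrs_barometer.schema import IndicatorKind, Scaling

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")

#: Table-2 printed sub-function indices for Mauritius 2020, schema order.
MAURITIUS_2020_PRINTED_INDICES = [
    0, 1, 0, 1, 1, 0,            # leadership & governance
    1, 0.0316, 1, 1, 0.586, 1,   # developing & sustaining resources
    0, 1, 0.561,                 # producing & utilizing
    1, 0.164,                    # financing
]

MAURITIUS_2020_FUNCTION_SCORES = {
    "leadership_governance": 50.0,
    "developing_resources": 77.0,
    "producing_utilizing": 52.0,
    "financing": 58.2,
}


@pytest.fixture(scope="session")
def schema():
    return build_default_schema()


@pytest.fixture
def mauritius():
    return mauritius_2020()


def random_observation(schema, rng: np.random.Generator, name: str = "RND") -> RawObservation:
    """A random valid observation covering every schema indicator."""
    flags = {}
    counts = {}
    population = int(rng.integers(100_000, 100_000_000))
    for ind in schema.ordered_indicators():
        if ind.kind is IndicatorKind.binary:
            flags[ind.id] = int(rng.integers(0, 2))
        elif ind.scaling is not Scaling.percent_of_total_budget:
            counts[ind.id] = int(rng.integers(0, 2000))
    total = float(rng.uniform(1e8, 1e12))
    return RawObservation(
        country=name,
        year=int(rng.integers(2000, 2030)),
        population=population,
        r4h_budget=float(rng.uniform(0, 0.05)) * total,
        total_health_budget=total,
        binary_flags=flags,
        counts=counts,
    )


@pytest.fixture
def obs_factory(schema):
    def factory(rng, name="RND"):
        return random_observation(schema, rng, name)

    return factory
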