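import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_spec():
    """Small known-truth population: quick to generate, big enough to fit."""
    from phsmoke.synthetic import default_population_spec

    return default_population_spec(
        n_individuals=6000, n_phds=4, rng_seed=321, phd_size_range=(150, 400)
    )


@pytest.fixture(scope="session")
def small_survey(small_spec):
    from phsmoke.synthetic import generate_survey

    return generate_survey(small_spec)


@pytest.fixture(scope="session")
def harmonized(small_spec, small_survey):
    from phsmoke.harmonize import harmonize_survey

    raw, _ = small_survey
    return harmonize_survey(raw, small_spec.tax_by_state)


@pytest.fixture(scope="session")
def fitted(small_spec, harmonized):
    from phsmoke.model import SmokingModel

    res = SmokingModel.from_dataframe(harmonized).fit()
    res.calibrate_threshold(harmonized, 0.33)
    return res


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
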