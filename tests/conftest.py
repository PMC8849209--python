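import logging

import pytest
from hypothesis import HealthCheck, settings

from nutriflow import synthetic

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# validation/default-coefficient warnings are expected noise in tests
logging.getLogger("nutriflow").setLevel(logging.ERROR)
for name in ("nutriflow.schema", "nutriflow.synthetic", "nutriflow.scenario",
             "nutriflow.mass_balance", "nutriflow.nutrient_engine",
             "nutriflow.io"):
    logging.getLogger(name).setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def global_2018():
    return synthetic.make_global_2018_world()


@pytest.fixture(scope="session")
def b12_world():
    return synthetic.make_b12_replacement_world()


@pytest.fixture
def small_world():
    """Factory: seeded miniature world."""

    def _make(seed=0, **kwargs):
        return synthetic.generate_world(
            synthetic.WorldConfig(seed=seed, **kwargs)
        )

    return _make
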