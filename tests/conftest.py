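import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import gaitann as g

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_gen_cfg():
    """A small study: 3 subjects x 4 circuits, short segments."""
    return g.GeneratorConfig(
        n_subjects=3,
        circuits_per_subject=4,
        segment_duration_range=(2.0, 3.0),
        seed=123,
    )


@pytest.fixture(scope="session")
def tiny_circuits(tiny_gen_cfg):
    return g.generate_dataset(tiny_gen_cfg)


@pytest.fixture(scope="session")
def seg_cfg():
    return g.SegmentationConfig()


@pytest.fixture(scope="session")
def profiles():
    return g.default_profiles()
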