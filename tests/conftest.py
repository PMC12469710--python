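import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cranioform import CohortSpec, EffectSpec, desk_template, sample_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def template():
    """Default 12-landmark desk-scale template (midface/frontal/neurocranium)."""
    return desk_template(seed=0)


@pytest.fixture(scope="session")
def null_cohort(template):
    """Two exchangeable groups: no implanted effect, typical noise."""
    return sample_cohort(
        CohortSpec(template=template, effect=EffectSpec(label="MUT"), noise_sd=0.05, seed=42)
    )


@pytest.fixture(scope="session")
def contraction_cohort(template):
    """Midface contracted by 10% in the affected group."""
    return sample_cohort(
        CohortSpec(
            template=template,
            effect=EffectSpec(region_scale={"midface": 0.9}, label="MUT"),
            noise_sd=0.05,
            seed=7,
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
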