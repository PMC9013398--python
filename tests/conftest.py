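import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bonegate import BONE_ROSTER, BoneAssessment, ValidationConfig

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def config():
    return ValidationConfig()


def make_bones(ages, scores=None):
    """Bone set on the canonical roster with the given ages/scores."""
    scores = scores or [0.0] * len(ages)
    return [
        BoneAssessment(bone_id=BONE_ROSTER[i], bone_age=a, appearance_score=s)
        for i, (a, s) in enumerate(zip(ages, scores))
    ]


@pytest.fixture
def clean_bones():
    return make_bones


@pytest.fixture(scope="session")
def film_image():
    """Film-like synthetic edge image (acquisition blur 0.6 mm)."""
    from bonegate import simulate_edge_image

    return simulate_edge_image(blur_sigma_mm=0.6, seed=7)
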