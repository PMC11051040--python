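import pytest
from hypothesis import HealthCheck, settings

import hlage

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def curves():
    return hlage.published_curves()


@pytest.fixture(scope="session")
def best_curves():
    return hlage.selected_curves()


@pytest.fixture(scope="session")
def femur_male_quadratic(curves):
    return next(
        c for c in curves
        if c.bone == hlage.Bone.FEMUR
        and c.group == hlage.SexGroup.MALE
        and c.family == hlage.ModelFamily.QUADRATIC
    )


@pytest.fixture(scope="session")
def toy_linear_curve():
    """age = 0.2 * x - 6 on (30, 100]: age 0 at x=30, adult age 14."""
    return hlage.make_curve(
        hlage.ModelFamily.LINEAR, (0.2, -6.0), bone="tibia", group="unisex"
    )
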