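import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from azeoblend import (
    ActivityModel,
    BinaryVLE,
    Component,
    make_reference_vle,
)

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference_vle() -> BinaryVLE:
    return make_reference_vle()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_ideal_vle(p_a: float = 10.0, p_b: float = 5.0, temperature: float = 323.15):
    """Ideal binary with prescribed vapour pressures at ``temperature``."""

    def comp(name, p, mm):
        a = np.log(p) + 9000.0 / temperature
        return Component(name=name, molar_mass=mm, antoine=(a, 9000.0, 0.0),
                         t_range=(250.0, 450.0))

    return BinaryVLE(
        component_a=comp("A", p_a, 100.0),
        component_b=comp("B", p_b, 150.0),
        activity=ActivityModel(()),
        temperature=temperature,
    )


def make_vle_with_coeffs(coeffs, p_a: float = 10.0, p_b: float = 5.0):
    base = make_ideal_vle(p_a, p_b)
    return BinaryVLE(
        component_a=base.component_a,
        component_b=base.component_b,
        activity=ActivityModel(tuple(coeffs)),
        temperature=base.temperature,
    )
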