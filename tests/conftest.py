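import math
from fractions import Fraction

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def oxygen():
    from oxdiff import oxygen_problem

    return oxygen_problem()


@pytest.fixture(scope="session")
def oxygen_n2(oxygen):
    from oxdiff import x_direction_components

    return x_direction_components(oxygen, 2)


def sqrt_jets(lam: float, t: float, max_order: int = 3) -> list[float]:
    """Numeric jets of s(t)=sqrt(1+2*lam*t), computed directly (not via the
    package's recurrence) for use as an independent check."""
    s = math.sqrt(1.0 + 2.0 * lam * t)
    c = [1.0]
    for j in range(1, max_order + 1):
        c.append((3 - 2 * j) * c[-1])
    return [c[j] * lam**j * s ** (1 - 2 * j) for j in range(max_order + 1)]
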