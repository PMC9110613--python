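import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tridose.kinetics import TriExpParams, lu177_lambda

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

LAM = lu177_lambda()


@pytest.fixture(scope="session")
def lam() -> float:
    return LAM


@pytest.fixture()
def kidney_params(lam) -> TriExpParams:
    """Kidney-like organ kinetics: ~3 Gy per cycle, peak ~0.02 mGy/s."""
    om3 = 8e-3
    om2 = 2.0 * om3
    return TriExpParams(
        omega1=om2 + om3, omega2=om2, omega3=om3,
        k1=3.5e-4, k2=2.7e-5, k3=2.7e-6, lam=lam,
    )


def draw_valid_params(rng: np.random.Generator, lam: float = LAM) -> TriExpParams:
    """A random organ-like parameter set honoring the population structure."""
    k3 = 2.7e-6 * rng.lognormal(0.0, 0.26)
    k2 = 10.0 * k3
    k1 = 3.5e-4 * rng.lognormal(0.0, 0.35)
    if not k1 > k2:
        k1 = 2.0 * k2
    om3 = 8e-3 * rng.lognormal(0.0, 0.4)
    om2 = 2.0 * om3
    return TriExpParams(om2 + om3, om2, om3, k1, k2, k3, lam)
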