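import numpy as np
import pytest

from refband import PairedSample, pefr_fixture


@pytest.fixture(scope="session")
def pefr() -> PairedSample:
    """The 17-subject two-meter peak-flow comparison (first readings)."""
    return pefr_fixture()


def random_sample(
    rng: np.random.Generator,
    n: int = 30,
    rho: float = 0.7,
    mu: tuple[float, float] = (0.0, 0.0),
    sigma: tuple[float, float] = (1.0, 1.0),
) -> PairedSample:
    """Correlated bivariate-normal pairs for property tests."""
    z = rng.standard_normal((2, n))
    x1 = mu[0] + sigma[0] * z[0]
    x2 = mu[1] + sigma[1] * (rho * z[0] + np.sqrt(1 - rho * rho) * z[1])
    return PairedSample(x1, x2)
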