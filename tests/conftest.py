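import numpy as np
import pytest

from pombesize import GrowthParams, calibrate_mean_size, reference_params


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def emm28_I():
    return reference_params("EMM_28C", "I")


@pytest.fixture(scope="session")
def emm28_II():
    return reference_params("EMM_28C", "II")


def make_regime(
    N: int,
    r0: float = 0.6,
    r1: float = 0.1,
    g_ratio: float = 2.0,
    alpha: float = 2.0,
    p: float = 0.5,
    nu: float | None = None,
    g0: float = 0.01,
    mean_size: float = 3.0,
) -> GrowthParams:
    """Parameter sets used in the density phenomenology studies:
    stage fractions (r0, r1), growth-rate ratio and control strength are
    fixed and ``a`` is calibrated so the mean lineage size (under
    deterministic partitioning) is ``mean_size``."""
    N0 = max(int(round(r0 * N)), 1)
    N1 = int(round(r1 * N))
    base = GrowthParams(g0=g0, g1=g_ratio * g0, a=1.0, alpha=alpha,
                        N=N, N0=N0, N1=N1, p=p, nu=None)
    cal = calibrate_mean_size(base, mean_size)
    return cal if nu is None else cal.replace(nu=nu)


@pytest.fixture(scope="session")
def regime_factory():
    return make_regime
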