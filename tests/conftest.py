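import numpy as np
import pytest

try:
    from hypothesis import HealthCheck, settings

    settings.register_profile(
        "default",
        derandomize=True,
        max_examples=50,
        deadline=None,
        suppress_health_check=[HealthCheck.too_slow],
    )
    settings.load_profile("default")
except ImportError:  # pragma: no cover - hypothesis is an optional test dep
    pass

from gremlpower import GenotypeMatrix, compute_grm, simulate_genotypes
from gremlpower.simulate import SimulationConfig


@pytest.fixture(scope="session")
def small_genotypes() -> GenotypeMatrix:
    """300 individuals x 2000 HWE SNPs; shared across tests that only read it."""
    cfg = SimulationConfig(design="univariate", n=300, m=2000, seed=42)
    return simulate_genotypes(cfg, rng=np.random.default_rng(42))


@pytest.fixture(scope="session")
def small_grm(small_genotypes):
    return compute_grm(small_genotypes)


def naive_pair_ols(z, a):
    """Independent OLS oracle on explicit pair-level vectors (loop-built lists)."""
    z = np.asarray(z, float)
    a = np.asarray(a, float)
    n = z.size
    abar, zbar = a.mean(), z.mean()
    slope = ((a - abar) * (z - zbar)).sum() / ((a - abar) ** 2).sum()
    intercept = zbar - slope * abar
    resid = z - intercept - slope * a
    se = np.sqrt((resid**2).sum() / (n - 2) / ((a - abar) ** 2).sum())
    return slope, intercept, se
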