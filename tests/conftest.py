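import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from planeval import DoseVolumeHistogram, PlanContext, default_tissue_parameters

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def cf_plan() -> PlanContext:
    return PlanContext(total_dose=50.0, n_fractions=25)


@pytest.fixture(scope="session")
def hf_plan() -> PlanContext:
    return PlanContext(total_dose=42.56, n_fractions=16)


@pytest.fixture(scope="session")
def tissue():
    return default_tissue_parameters()


@pytest.fixture
def random_dvh():
    """Factory: valid random differential DVH on an even grid."""

    def make(n_bins=5, seed=0, bin_width=1.0, start=40.0) -> DoseVolumeHistogram:
        rng = np.random.default_rng(seed)
        frac = rng.dirichlet(np.ones(n_bins))
        edges = start + bin_width * np.arange(n_bins + 1)
        return DoseVolumeHistogram("s", edges, frac, absolute_volume=100.0)

    return make
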