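import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_epithelium():
    """A modest epithelium shared by tests that only need a valid CellMap."""
    from ciliaflow.epithelium import EpitheliumSpec, generate_epithelium

    spec = EpitheliumSpec(
        n_rows=20, n_cols=20, coverage=0.5, gap_wavelength_mean=25.0,
        gap_wavelength_std=0.0, beat_order_target=0.8, seed=7,
    )
    return generate_epithelium(spec)
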