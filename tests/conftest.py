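import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cfekit import BULK_MLE, GeneratorConfig, generate_bulk_titration

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
    max_examples=25,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bulk_params():
    return BULK_MLE


@pytest.fixture(scope="session")
def small_noisy_dataset():
    """Two-level DNA titration, duplicate, 2% noise, coarse grid."""
    cfg = GeneratorConfig(
        dna_levels_nM=(1.875, 3.75), replicates=2, noise_cv=0.02,
        dt_h=0.5, seed=424242,
    )
    return generate_bulk_titration(cfg)


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise-free titration at three DNA levels."""
    cfg = GeneratorConfig(
        dna_levels_nM=(0.94, 1.875, 3.75), replicates=1, noise_cv=0.0,
        dt_h=0.5, seed=1,
    )
    return generate_bulk_titration(cfg)
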