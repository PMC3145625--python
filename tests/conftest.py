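import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cross():
    """A small two-QTL cross shared across tests (2,000 segregants)."""
    import termvar as tv
    from termvar.pipeline import simulate_cross

    config = tv.CrossConfig(n_markers=2_000, n_segregants=2_000, seed=7)
    model = tv.default_trait_model()
    return simulate_cross(config, model, seed=8), model


@pytest.fixture()
def toy_track():
    """Three equally spaced markers on one chromosome, one nonzero value."""
    import pandas as pd

    return pd.DataFrame({
        "chrom": [1, 1, 1],
        "pos": [10_000, 20_000, 30_000],
        "delta": [0.0, 0.0, 0.0],
        "corrected": [0.0, 0.9, 0.0],
    })
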