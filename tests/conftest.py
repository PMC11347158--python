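from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from mirslam import SimConfig, run_study

settings.register_profile(
    "suite", deadline=None, max_examples=50, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_study():
    """One small simulated study run through the whole pipeline, shared by
    tests that only inspect the outputs."""
    cfg = SimConfig(n_mirnas=20, reads_per_sample=5000, seed=7)
    return cfg, run_study(cfg)
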