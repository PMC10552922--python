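from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from hepvigil.faers_io import default_lmwh_dictionary  # noqa: E402
from hepvigil.synthetic import SimConfig, build_case_fixture, generate_reports  # noqa: E402


@pytest.fixture(scope="session")
def lmwh_dictionary():
    return default_lmwh_dictionary()


@pytest.fixture(scope="session")
def fixture_cases():
    """The deterministic 43-case series (seed 0)."""
    return build_case_fixture(seed=0)


@pytest.fixture(scope="session")
def small_corpus():
    """A small synthetic corpus with a strong injected signal."""
    cfg = SimConfig(n_reports=4_000, target_or=10.0, duplicate_rate=0.1, seed=11)
    reports, truth = generate_reports(cfg)
    return cfg, reports, truth
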