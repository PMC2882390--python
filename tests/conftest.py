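"""Shared fixtures: synthetic bundles at two scales.

The default fixture (300 proteins, 12 terms, planted-signal probability
0.95, generator seed 42) is the study condition for the end-to-end checks;
its full 10-fold cross-validation is expensive, so it is computed once per
session and shared.  ``tiny_bundle`` is a fast variant for unit tests.
"""

from __future__ import annotations

import pytest

from pogo import (
    PipelineConfig,
    SimulationConfig,
    cross_validate,
    simulate_bundle,
)


@pytest.fixture(scope="session")
def tiny_sim():
    cfg = SimulationConfig(n_proteins=80, n_terms=4, seed=7)
    return simulate_bundle(cfg)


@pytest.fixture(scope="session")
def tiny_bundle(tiny_sim):
    return tiny_sim[0]


@pytest.fixture(scope="session")
def tiny_truth(tiny_sim):
    return tiny_sim[1]


@pytest.fixture(scope="session")
def fixture_sim():
    return simulate_bundle(SimulationConfig())


@pytest.fixture(scope="session")
def fixture_bundle(fixture_sim):
    return fixture_sim[0]


@pytest.fixture(scope="session")
def fixture_truth(fixture_sim):
    return fixture_sim[1]


@pytest.fixture(scope="session")
def fixture_cv_report(fixture_bundle):
    """Full-pipeline 10-fold CV of the default fixture (shared: ~40 s)."""
    import time

    t0 = time.monotonic()
    report = cross_validate(fixture_bundle, PipelineConfig(), seed=1, folds=10)
    report.elapsed_seconds = time.monotonic() - t0
    return report
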