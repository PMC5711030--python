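"""Shared fixtures. The expensive reference runs (the Fisher-Kolmogorov
benchmark and the beta = 0 threshold scan) are computed once per session and
reused by several tests."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gliofront.models import ModelParams
from gliofront.recurrence import threshold_scan
from gliofront.solver import DensityProfile, Grid1D, integrate

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

SCAN_DELTAS = [0.2, 0.1, 0.05, 0.025]


@pytest.fixture(scope="session")
def fk_run():
    """Fisher-Kolmogorov benchmark: D = rho = K = 1, dx = 0.05, domain 400,
    integrated to t = 150 from a compact seed at the left edge."""
    params = ModelParams(kind="logistic")
    grid = Grid1D(x0=0.0, L=400.0, nx=8000)
    seed = DensityProfile.seed(grid, params, centre=grid.x0 + 1.0, width=2.0)
    return integrate(seed, params, 150.0)


@pytest.fixture(scope="session")
def b0_scan():
    """Borderline Allee (beta = 0) threshold scan over a delta decade."""
    return threshold_scan(ModelParams(beta=0.0, kind="allee"), SCAN_DELTAS)


@pytest.fixture(scope="session")
def b002_scan():
    """Weak Allee (beta = 0.02) scan over the same deltas."""
    return threshold_scan(ModelParams(beta=0.02, kind="allee"), SCAN_DELTAS)
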