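"""Shared fixtures: all test data are generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from lumbargait.simulate import WalkerSpec, default_grid, simulate_bout


@pytest.fixture(scope="session")
def walker():
    """One canonical noiseless walking bout with ground truth."""
    spec = WalkerSpec(f_step=1.7, duty=0.295, step_length=0.625,
                      duration_s=30.0, seed=7)
    rec, gt = simulate_bout(spec)
    return spec, rec, gt


@pytest.fixture(scope="session")
def fixture_grid():
    """The 12-bout design grid (3 cadences x noise x tilt), simulated once."""
    out = []
    for spec in default_grid(duration_s=30.0, seed=11):
        rec, gt = simulate_bout(spec)
        out.append((spec, rec, gt))
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def interior_region(rec, margin: float = 2.0):
    """Analysis region excluding bout edges, mirroring the instrumented-
    walkway convention that events off the measurement area are not scored."""
    return (margin, rec.duration - margin)
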