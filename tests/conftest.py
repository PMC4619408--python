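"""Shared fixtures: a scaled-down synthetic world for fast pipeline tests.

The full-size default domain (20x20 coarse / 240x240 fine) is exercised
in the acceptance tests; everything else runs on a 10x10 / 60x60 domain
with the same statistical structure, which keeps the default suite fast.
"""

import numpy as np
import pytest

from finedgvm.grid import build_grid
from finedgvm.pipeline import RunConfig, run_historical
from finedgvm.synthetic import cascadia_toy


SMALL = dict(coarse_resolution=0.5, refinement=6)  # 10x10 coarse, 60x60 fine


@pytest.fixture(scope="session")
def small_config():
    return RunConfig(seed=42, write_outputs=False, build_spinup_block=False, **SMALL)


@pytest.fixture(scope="session")
def small_scenario():
    return cascadia_toy(
        seed=42,
        coarse=build_grid(43.0, 48.0, -124.0, -119.0, 0.5),
        fine=build_grid(43.0, 48.0, -124.0, -119.0, 0.5 / 6.0),
    )


@pytest.fixture(scope="session")
def small_historical(small_config):
    """One shared historical run on the scaled-down domain."""
    return run_historical(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
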