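"""Shared fixtures: the default design, rendered apertures and search grid.

The full 100-pixel aperture stack and the default 15 x 15 x 12 search grid
are expensive enough to build once per session; the small grid/stack serve
tests that only need geometry.
"""

import numpy as np
import pytest

from motionprf import build_sweep_design, render_apertures
from motionprf.prf_fit import FitEngine, build_grid


@pytest.fixture(scope="session")
def exp1_design():
    return build_sweep_design()


@pytest.fixture(scope="session")
def stack100(exp1_design):
    return render_apertures(exp1_design, grid_pixels=100)


@pytest.fixture(scope="session")
def engine100(stack100):
    return FitEngine(stack100)


@pytest.fixture(scope="session")
def default_grid(stack100, engine100):
    return build_grid(None, stack100, engine=engine100)


@pytest.fixture(scope="session")
def small_grid(stack100, engine100):
    """75-point grid (5 x 5 x 3) for oracle-equivalence checks."""
    ranges = {"x0": np.linspace(-6, 6, 5), "y0": np.linspace(-6, 6, 5),
              "sigma": np.array([0.5, 1.5, 4.0])}
    return build_grid(ranges, stack100, engine=engine100)
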