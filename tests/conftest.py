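"""Shared fixtures: simulated experiments at the standard study conditions.

Expensive simulations are session-scoped; tests must not mutate them in
place (use ``.copy()`` on tables).
"""

import numpy as np
import pytest

from edgeom.prediction import Flags
from edgeom.refinement import Parameterisation, residuals_and_jacobian
from edgeom.simulator import ed_preset, mx_preset, simulate_reflections


@pytest.fixture(scope="session")
def ed_sim():
    """Standard ED simulation (seed 1): (spec, experiment, observations)."""
    spec = ed_preset(seed=1)
    exp, obs = simulate_reflections(spec)
    obs.set_flag(Flags.USED_IN_REFINEMENT)
    return spec, exp, obs


@pytest.fixture(scope="session")
def mx_sim():
    """Matched MX simulation (seed 1), sharing crystal/scan/axis with ed_sim."""
    spec = mx_preset(seed=1)
    exp, obs = simulate_reflections(spec)
    obs.set_flag(Flags.USED_IN_REFINEMENT)
    return spec, exp, obs


@pytest.fixture(scope="session")
def small_ed_sim():
    """Smaller noise-free ED simulation (d_min = 9 A) for derivative tests."""
    spec = ed_preset(seed=2, d_min=9.0, sigma_x=0.0, sigma_y=0.0, sigma_phi=0.0)
    exp, obs = simulate_reflections(spec)
    obs.set_flag(Flags.USED_IN_REFINEMENT)
    return spec, exp, obs


@pytest.fixture(scope="session")
def ed_bundle(ed_sim):
    """13-parameter Jacobian bundle at the ED truth."""
    _, exp, obs = ed_sim
    param = Parameterisation(exp)
    return param, residuals_and_jacobian(param, obs)


@pytest.fixture(scope="session")
def mx_bundle(mx_sim):
    _, exp, obs = mx_sim
    param = Parameterisation(exp)
    return param, residuals_and_jacobian(param, obs)
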