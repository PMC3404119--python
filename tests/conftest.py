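"""Shared fixtures.

The clock simulations are the expensive part of the suite, so every
trajectory or sweep that more than one test needs is computed once per
session here.
"""

import numpy as np
import pytest

from segclock import ClockParameters, make_mutant, simulate
from segclock.dimers import FullParameters, reduction_check
from segclock.experiments import kappa6_sweep, mutant_panel


@pytest.fixture(scope="session")
def wt_params():
    return ClockParameters()


@pytest.fixture(scope="session")
def wt_traj(wt_params):
    return simulate(wt_params)


@pytest.fixture(scope="session")
def hes6_traj(wt_params):
    return simulate(make_mutant(wt_params, "hes6"))


@pytest.fixture(scope="session")
def panel(wt_params):
    """Mutant panel table, indexed by genotype."""
    return mutant_panel(wt_params).set_index("genotype")


@pytest.fixture(scope="session")
def coarse_sweep(wt_params):
    """Both sweep scenarios on the coarse grid {0, 30, 60, 90}."""
    return kappa6_sweep(wt_params, grid=(0.0, 30.0, 60.0, 90.0))


@pytest.fixture(scope="session")
def fine_blue_sweep(wt_params):
    """kappa7 = kappa1 line on a 21-point grid over [0, 90], for the
    period-monotonicity and continuity checks."""
    return kappa6_sweep(
        wt_params, grid=np.linspace(0.0, 90.0, 21), scenarios=("kappa7_equal_kappa1",)
    )


@pytest.fixture(scope="session")
def delay_sweeps(wt_params):
    """Coarse sweeps (both scenarios) at tau1 = 1.00 and 1.02."""
    grid = (0.0, 30.0, 60.0, 90.0)
    return {
        tau1: kappa6_sweep(wt_params.replace(tau1=tau1), grid=grid)
        for tau1 in (1.00, 1.02)
    }


@pytest.fixture(scope="session")
def reduction_reports(wt_params):
    """Full-vs-minimal model comparison at dimerization speed-ups 10x
    and 100x."""
    p_full = FullParameters(base=wt_params)
    return {
        scale: reduction_check(p_full, wt_params, scale) for scale in (10.0, 100.0)
    }
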