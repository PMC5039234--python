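"""Shared fixtures: the standard parameter set and the heavy scenario runs.

The long simulations are session-scoped so the regime, consistency and
equilibrium-convergence tests all share one integration each.
"""

import numpy as np
import pytest

from itadori.params import preset
from itadori.simulate import make_history, integrate
from itadori.spectral import h_crit


@pytest.fixture(scope="session")
def eq52():
    """The standard simulation parameter set (Ricker birth, h = 1)."""
    return preset("table1_eq52")


@pytest.fixture(scope="session")
def hc(eq52):
    return h_crit(eq52)


def _run(params, A0, R0, t_end, step=0.05):
    history = make_history(params, A0, R0)
    return integrate(params, history, t_end=t_end, step=step)


@pytest.fixture(scope="session")
def fig1_traj(eq52, hc):
    """h just below threshold: converges to the coexistence equilibrium."""
    return _run(eq52.replace(h=hc - 1.0), 50.0, 500.0, 4000.0)


@pytest.fixture(scope="session")
def fig2_traj(eq52, hc):
    """h slightly above threshold: slower convergence, 12-day transient cycle."""
    return _run(eq52.replace(h=hc + 5.0), 50.0, 500.0, 2200.0)


@pytest.fixture(scope="session")
def insect_free_traj(eq52):
    """No psyllids: pure exponential knotweed growth."""
    return _run(eq52.replace(h=1.0), 0.0, 500.0, 1000.0)
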