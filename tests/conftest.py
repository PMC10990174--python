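"""Shared fixtures: expensive simulations/reductions are session-scoped."""

from __future__ import annotations

import pytest

import campmmo.geometry as geo
import campmmo.reduction as red
import campmmo.simulation as sim
from campmmo.model_core import ModelParameters, condition_params


@pytest.fixture(scope="session")
def ctrl300() -> ModelParameters:
    return condition_params("Ctrl").with_(IApp=300.0)


@pytest.fixture(scope="session")
def cgs250() -> ModelParameters:
    return condition_params("CGS").with_(IApp=250.0)


@pytest.fixture(scope="session")
def cgs300() -> ModelParameters:
    return condition_params("CGS").with_(IApp=300.0)


@pytest.fixture(scope="session")
def ctrl300_line(ctrl300):
    line, pts = red.projected_line(ctrl300)
    return line, pts


@pytest.fixture(scope="session")
def cgs250_reduced(cgs250):
    return red.reduce_condition(cgs250)


@pytest.fixture(scope="session")
def cgs300_reduced(cgs300):
    return red.reduce_condition(cgs300)


@pytest.fixture(scope="session")
def cgs250_fn(cgs250, cgs250_reduced):
    rr = cgs250_reduced
    nodes = [f for f in geo.folded_singularities(cgs250, rr.w_tilde,
                                                 rr.r_tilde)
             if f.kind == "folded node"]
    assert nodes, "expected a folded node at (CGS, 250)"
    return nodes[0]


@pytest.fixture(scope="session")
def cgs300_traj_5d(cgs300):
    """450 ms reference 5D run with elevated cAMP (MMO regime)."""
    return sim.integrate(cgs300, 450.0)
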