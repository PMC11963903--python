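"""Shared fixtures: the reference parameterization, its calibrated state
and a cached 1 ms reference beat."""
import numpy as np
import pytest

from cardioloop.integrators import SolverSettings, run_beat
from cardioloop.parameters import load_reference
from cardioloop.reference import reference_state


@pytest.fixture(scope="session")
def reference():
    """(ModelParameters, state-dict) of the shipped fixture."""
    return load_reference()


@pytest.fixture(scope="session")
def ref_params(reference):
    return reference[0]


@pytest.fixture()
def ref_state(reference):
    """Fresh copy of the calibrated initial state."""
    return reference_state(reference[1])


@pytest.fixture(scope="session")
def ref_beat(reference):
    """One Adams-Moulton-2 beat at 1 ms from the reference state."""
    params, sd = reference
    trace, end, status = run_beat(params, reference_state(sd),
                                  SolverSettings())
    assert status == "ok"
    return trace
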