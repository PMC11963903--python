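"""Whole-model invariants: conservation, step-size behaviour, stability."""
import numpy as np
import pytest

from cardioloop import _layout as L
from cardioloop.integrators import SolverSettings, run_beat
from cardioloop.metrics import mae
from cardioloop.reference import reference_state


def test_blood_volume_drift_below_tolerance_per_beat(ref_params, reference):
    """Without control the loop volume drifts only by integration error:
    less than 1e-6 of the total per beat at 1 ms."""
    state = reference_state(reference[1])
    total0 = np.sum(state.y[:L.N_COMP])
    _, end, status = run_beat(ref_params, state, SolverSettings())
    assert status == "ok"
    drift = abs(np.sum(end.y[:L.N_COMP]) - total0) / total0
    assert drift < 1e-6


def test_triseg_residual_independent_of_step_size(ref_params, reference):
    """The recorded junction-force residual is governed by its own
    threshold, not by the integration step."""
    maxima = {}
    for dt in (0.1, 1.0, 2.0):
        tr, _, status = run_beat(ref_params, reference_state(reference[1]),
                                 SolverSettings(dt_ms=dt, e_triseg=1e-4))
        assert status == "ok"
        maxima[dt] = tr["triseg_residual_Nm"].max()
    for v in maxima.values():
        assert v < 1e-4
    # no systematic growth with the step
    assert maxima[2.0] < 10 * maxima[0.1] + 1e-6


def test_halving_step_reduces_error_by_method_order(ref_params, reference):
    """Richardson behaviour of the trapezoidal method on the model: the
    one-beat LV-volume error against a fine-step reference drops at least
    by the method-order factor when the step halves (event-localized
    errors make the observed contraction somewhat faster than 2^order)."""
    truth, _, status = run_beat(ref_params, reference_state(reference[1]),
                                SolverSettings(dt_ms=0.01, e_triseg=1e-6))
    assert status == "ok"
    errs = {}
    for dt in (2.0, 1.0):
        tr, _, s = run_beat(ref_params, reference_state(reference[1]),
                            SolverSettings(dt_ms=dt))
        assert s == "ok"
        errs[dt] = mae(tr, truth, "V_LV_ml")
    factor = errs[2.0] / errs[1.0]
    assert 3.0 < factor < 40.0  # observed order >= method order - 0.3


def test_explicit_methods_stable_at_fine_but_not_all_steps(ref_params,
                                                           reference):
    """Explicit Euler survives a fine step; the implicit default survives
    coarse steps where explicit one-step integration degrades."""
    tr, _, status = run_beat(ref_params, reference_state(reference[1]),
                             SolverSettings(method="explicit_euler",
                                            dt_ms=0.1))
    assert status == "ok"
    tr, _, status = run_beat(ref_params, reference_state(reference[1]),
                             SolverSettings(dt_ms=5.0))
    assert status == "ok"


def test_methods_agree_at_one_millisecond(ref_params, reference):
    """All stable families land on the same beat to sub-ml accuracy."""
    traces = {}
    for m, o in (("adams_moulton", 2), ("bdf", 2), ("rk4", 4),
                 ("adams_bashforth", 2)):
        tr, _, status = run_beat(ref_params, reference_state(reference[1]),
                                 SolverSettings(method=m, order=o))
        assert status == "ok"
        traces[(m, o)] = tr
    base = traces[("adams_moulton", 2)]
    for k, tr in traces.items():
        assert mae(tr, base, "V_LV_ml") < 0.5
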