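"""Trace metrics: MAE, assumed-true reference, energy residual, spread."""
import numpy as np
import pytest

from cardioloop.integrators import SolverSettings, run_beat
from cardioloop.metrics import (Trace, assumed_true, energy_balance_error,
                                mae, multistart_spread)


def _trace(values, dt=1e-3, name="x"):
    values = np.asarray(values, dtype=float)
    return Trace(time=dt * np.arange(values.size),
                 signals={name: values})


def test_mae_identical_traces_is_zero():
    t = _trace([1.0, 2.0, 3.0, 2.0])
    assert mae(t, t, "x") == 0.0


def test_mae_constant_offset():
    a = _trace(np.linspace(0, 5, 11))
    b = _trace(np.linspace(0, 5, 11) + 0.1)
    assert mae(a, b, "x") == pytest.approx(0.1, rel=1e-12)


def test_mae_small_example():
    a = _trace([1.0, 2.0, 3.0])
    b = _trace([1.0, 2.0, 4.0])
    assert mae(a, b, "x") == pytest.approx(1.0 / 3.0, rel=1e-12)


def test_mae_is_symmetric_and_nonnegative():
    rng = np.random.default_rng(0)
    a = _trace(rng.normal(size=50))
    b = _trace(rng.normal(size=50))
    assert mae(a, b, "x") == mae(b, a, "x") >= 0.0


def test_mae_resamples_different_grids():
    """A 2 ms trace compared against a 1 ms trace of the same signal."""
    t_fine = _trace(np.sin(np.linspace(0, 1, 101)), dt=1e-3)
    t_coarse = _trace(np.sin(np.linspace(0, 1, 51)), dt=2e-3)
    assert mae(t_fine, t_coarse, "x") < 1e-4


def test_mae_rejects_mismatched_beat_lengths():
    a = _trace(np.zeros(11))
    b = _trace(np.zeros(31))
    with pytest.raises(ValueError):
        mae(a, b, "x")


def test_assumed_true_single_trace_is_identity():
    t = _trace([1.0, 2.0, 3.0])
    ref = assumed_true([t])
    assert ref is t


def test_assumed_true_is_pointwise_mean_and_order_invariant():
    base = np.linspace(0, 1, 21)
    a = _trace(base)
    b = _trace(base + 0.2)
    r1 = assumed_true([a, b])
    r2 = assumed_true([b, a])
    assert np.allclose(r1["x"], base + 0.1)
    assert np.array_equal(r1["x"], r2["x"])


def test_assumed_true_requires_a_stable_trace():
    with pytest.raises(ValueError):
        assumed_true([])


def test_energy_residual_zero_for_static_system(ref_beat):
    """A motionless trace dissipates nothing and does no work."""
    n = 11
    sig = {k: np.full(n, v[0]) for k, v in ref_beat.signals.items()}
    static = Trace(time=1e-3 * np.arange(n), signals=sig)
    # dissipation is constant in a frozen state; zero it like a true rest
    static.signals["P_diss_W"] = np.zeros(n)
    for q in [k for k in sig if k.startswith("q_")]:
        static.signals[q] = np.zeros(n)
    assert energy_balance_error(static) == pytest.approx(0.0, abs=1e-15)


def test_energy_residual_decreases_with_step_size(ref_params, reference):
    """The per-beat energy-balance residual is integration error: halving
    the step reduces it."""
    from cardioloop.reference import reference_state
    res = {}
    for dt in (5.0, 2.0, 1.0, 0.1):
        tr, _, status = run_beat(ref_params, reference_state(reference[1]),
                                 SolverSettings(dt_ms=dt))
        assert status == "ok"
        res[dt] = energy_balance_error(tr)
    assert res[2.0] < res[5.0]
    assert res[1.0] < res[2.0]
    assert res[0.1] < res[1.0]


def test_spread_of_identical_starts_is_zero(ref_beat):
    out = multistart_spread(index_values=[4.0, 4.0, 4.0],
                            traces=[ref_beat, ref_beat, ref_beat],
                            signal="V_LV_ml")
    assert out["sd"] == 0.0
    assert out["median_mae"] < 1e-12


def test_spread_population_standard_deviation():
    out = multistart_spread(index_values=[4.0, 6.0])
    assert out["sd"] == pytest.approx(1.0)


def test_spread_mae_against_mean_signal():
    """Three starts x, x, x+3e: mean x+e; MAEs e, e, 2e."""
    base = np.linspace(0, 1, 21)
    eps = 0.03
    tr = [_trace(base), _trace(base), _trace(base + 3 * eps)]
    out = multistart_spread(traces=tr, signal="x")
    assert out["mae_vs_mean"] == pytest.approx([eps, eps, 2 * eps])


def test_spread_undefined_below_two_starts():
    out = multistart_spread(index_values=[4.0])
    assert np.isnan(out["sd"])


def test_spread_permutation_invariance():
    rng = np.random.default_rng(1)
    xs = list(rng.normal(5, 1, size=6))
    a = multistart_spread(index_values=xs)["sd"]
    b = multistart_spread(index_values=xs[::-1])["sd"]
    assert a == b
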