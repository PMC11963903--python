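"""Multistep integrators: coefficient algebra, classical results,
stability surrogates and consistency of the compiled model path."""
import numpy as np
import pytest
from fractions import Fraction

from cardioloop.integrators import (AB_COEFFS, AM_C0, AM_PAST, BDF_ALPHA,
                                    BDF_BETA, SolverSettings, estimate_order,
                                    integrate, run_beat, step)


# ---------------------------------------------------------------------
# coefficient exactness (algebraic oracle)
# ---------------------------------------------------------------------
@pytest.mark.parametrize("order", [1, 2, 3, 4])
def test_adams_bashforth_coefficients_integrate_polynomials(order):
    """AB(k) must integrate polynomials up to degree k-1 exactly over one
    unit step: sum_j b_j * (-j)^m = 1/(m+1)."""
    b = AB_COEFFS[order]
    for m in range(order):
        lhs = sum(Fraction(bj) * Fraction(-j) ** m for j, bj in enumerate(b))
        assert lhs == Fraction(1, m + 1)


@pytest.mark.parametrize("order", [1, 2, 3, 4])
def test_adams_moulton_coefficients_integrate_polynomials(order):
    """AM(k) nodes are t = 1, 0, -1, ...: exact up to degree k-1."""
    coeffs = [AM_C0[order]] + list(AM_PAST[order])
    nodes = [Fraction(1 - j) for j in range(len(coeffs))]
    for m in range(order):
        lhs = sum(c * t ** m for c, t in zip(coeffs, nodes))
        assert lhs == Fraction(1, m + 1)


@pytest.mark.parametrize("order", [1, 2, 3, 4])
def test_bdf_formulas_exact_on_polynomials(order):
    """BDF(k) reproduces y(1) exactly for y = t^m, m <= k."""
    a = BDF_ALPHA[order]
    beta = BDF_BETA[order]
    for m in range(order + 1):
        y1 = Fraction(1)  # 1^m
        rhs = sum(ai * Fraction(-i) ** m for i, ai in enumerate(a))
        rhs += beta * (m * Fraction(1) ** (m - 1) if m > 0 else 0)
        assert y1 == rhs


# ---------------------------------------------------------------------
# classical single-equation results
# ---------------------------------------------------------------------
def test_trapezoidal_step_on_linear_decay():
    """AM2 on y' = -y with h = 0.1: y1 = 0.95/1.05 exactly."""
    f = lambda t, y: -y
    y1 = step(f, 0.0, [np.array([1.0])], [np.array([-1.0])], 0.1,
              "adams_moulton", 2)
    assert y1[0] == pytest.approx(0.95 / 1.05, rel=1e-12)


def test_bdf2_matches_linear_recurrence_oracle():
    """BDF2 on y' = lam*y reproduces the closed-form recurrence
    (1 - 2/3 lam h) y_{n+1} = 4/3 y_n - 1/3 y_{n-1}."""
    lam, h, n = -2.0, 0.05, 40
    f = lambda t, y: lam * y
    _, out = integrate(f, 1.0, 0.0, h, n, "bdf", 2)
    y = [1.0, out[1, 0]]  # first step comes from the rk4 bootstrap
    for _ in range(n - 1):
        y_next = (4.0 / 3.0 * y[-1] - 1.0 / 3.0 * y[-2]) \
            / (1.0 - 2.0 / 3.0 * lam * h)
        y.append(y_next)
    assert out[-1, 0] == pytest.approx(y[-1], rel=1e-9)


@pytest.mark.parametrize("method,order", [
    ("explicit_euler", 1), ("adams_bashforth", 2), ("adams_moulton", 2),
    ("adams_moulton", 3), ("bdf", 2), ("bdf", 3), ("rk4", 4)])
def test_zero_rhs_leaves_state_unchanged(method, order):
    f = lambda t, y: 0.0 * y
    _, out = integrate(f, np.array([3.0, -1.0]), 0.0, 0.1, 20, method, order)
    assert np.all(out == out[0])


@pytest.mark.parametrize("method,order,expect,tol", [
    ("adams_moulton", 2, 2.0, 0.1),
    ("bdf", 2, 2.0, 0.15),
    ("bdf", 3, 3.0, 0.2),
    ("adams_bashforth", 2, 2.0, 0.15),
    ("rk4", 4, 4.0, 0.2),
])
def test_observed_convergence_order_on_linear_equation(method, order,
                                                       expect, tol):
    obs = estimate_order(method, order, lam=-1.0, t_end=1.0, h=0.1)
    assert obs == pytest.approx(expect, abs=tol)


def test_order_undefined_for_zero_solution():
    f = lambda t, y: 0.0 * y
    obs = estimate_order("adams_moulton", 2, f=f, y0=0.0,
                         exact=lambda t: 0.0)
    assert np.isnan(obs)


def test_a_stability_surrogate():
    """On y' = lam*y with lam*h = -10 the A-stable implicit methods decay;
    fourth-order Adams-Bashforth blows up."""
    f = lambda t, y: -100.0 * y
    h, n = 0.1, 60
    for method, order in (("adams_moulton", 2), ("bdf", 2)):
        _, out = integrate(f, 1.0, 0.0, h, n, method, order)
        assert abs(out[-1, 0]) < 1.0
    _, out = integrate(f, 1.0, 0.0, h, n, "adams_bashforth", 4)
    assert abs(out[-1, 0]) > 1e3


# ---------------------------------------------------------------------
# compiled model path
# ---------------------------------------------------------------------
def test_beat_length_arithmetic(ref_params, ref_state):
    trace, _, status = run_beat(ref_params, ref_state, SolverSettings())
    assert status == "ok"
    assert trace.time.size == round(ref_params.t_cycle / 1e-3) + 1


def test_identical_settings_give_bit_identical_traces(ref_params,
                                                      reference):
    from cardioloop.reference import reference_state
    s = SolverSettings()
    t1, _, _ = run_beat(ref_params, reference_state(reference[1]), s)
    t2, _, _ = run_beat(ref_params, reference_state(reference[1]), s)
    for k in t1.signals:
        assert np.array_equal(t1[k], t2[k])


def test_compiled_path_matches_generic_stepper(ref_params, ref_state):
    """A few RK4 steps of the compiled loop agree with the generic
    pure-Python stepper driving the same right-hand side."""
    from cardioloop.model import system_derivatives, SystemState

    state = ref_state.copy()

    def f(t, y):
        st = SystemState(y=np.asarray(y, dtype=float),
                         triseg=state.triseg, t=t)
        dy, _ = system_derivatives(st, ref_params, e_triseg=1e-7)
        return dy

    h = 1e-4
    n = 5
    _, out = integrate(f, ref_state.y, 0.0, h, n, "rk4", 4)

    s = SolverSettings(method="rk4", dt_ms=0.1, e_triseg=1e-7)
    trace, _, status = run_beat(ref_params, ref_state.copy(), s)
    assert status == "ok"
    v_generic = out[:, 2] / 1e-6          # LV volume, ml
    v_compiled = trace["V_LV_ml"][:n + 1]
    assert v_compiled == pytest.approx(v_generic, abs=1e-6)


def test_solver_settings_validation():
    with pytest.raises(ValueError):
        SolverSettings(method="leapfrog")
    with pytest.raises(ValueError):
        SolverSettings(order=5)
    with pytest.raises(ValueError):
        SolverSettings(dt_ms=-1.0)
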