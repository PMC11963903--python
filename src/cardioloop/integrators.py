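"""Fixed-step multistep time integration.

Two code paths share one set of method coefficients:

* a generic pure-Python stepper (:func:`step`, :func:`integrate`) for
  arbitrary right-hand sides — used for verification against classical
  results on test equations and as an independent cross-check of the
  compiled path;
* the compiled model loop (:func:`run_beat`) driving the closed-loop
  circulation through :func:`cardioloop._kernels.integrate_fixed`.

Families: Adams-Bashforth (explicit), Adams-Moulton (implicit; order 2 is
the trapezoidal rule), backward differentiation formulae (implicit), plus
explicit Euler and classical RK4.  Implicit stage equations are solved by
Newton iteration with finite-difference Jacobians.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from . import _kernels as K
from . import _layout as L
from . import units as U
from .parameters import ModelParameters
from .model import SystemState

METHODS = ("explicit_euler", "adams_bashforth", "adams_moulton", "bdf", "rk4")
_METHOD_IDS = {"explicit_euler": K.M_EULER, "adams_bashforth": K.M_AB,
               "adams_moulton": K.M_AM, "bdf": K.M_BDF, "rk4": K.M_RK4}

#: step sizes exercised by the study protocols (ms)
SUPPORTED_DT_MS = (1e-3, 1e-2, 1e-1, 1.0, 2.0, 5.0, 10.0)
#: TriSeg tension-balance thresholds exercised by the protocols (N/m)
SUPPORTED_E_TRISEG = (1e-6, 1e-5, 1e-4, 1e-3, 1e-2, 1e-1)

# ---------------------------------------------------------------------
# method coefficients (exact rationals; orders 1..4)
# ---------------------------------------------------------------------
AB_COEFFS = {
    1: [Fraction(1)],
    2: [Fraction(3, 2), Fraction(-1, 2)],
    3: [Fraction(23, 12), Fraction(-16, 12), Fraction(5, 12)],
    4: [Fraction(55, 24), Fraction(-59, 24), Fraction(37, 24), Fraction(-9, 24)],
}
AM_C0 = {1: Fraction(1), 2: Fraction(1, 2), 3: Fraction(5, 12),
         4: Fraction(9, 24)}
AM_PAST = {
    1: [],
    2: [Fraction(1, 2)],
    3: [Fraction(8, 12), Fraction(-1, 12)],
    4: [Fraction(19, 24), Fraction(-5, 24), Fraction(1, 24)],
}
BDF_ALPHA = {
    1: [Fraction(1)],
    2: [Fraction(4, 3), Fraction(-1, 3)],
    3: [Fraction(18, 11), Fraction(-9, 11), Fraction(2, 11)],
    4: [Fraction(48, 25), Fraction(-36, 25), Fraction(16, 25), Fraction(-3, 25)],
}
BDF_BETA = {1: Fraction(1), 2: Fraction(2, 3), 3: Fraction(6, 11),
            4: Fraction(12, 25)}


@dataclass
class SolverSettings:
    """Integration settings for one run.

    dt_ms is the fixed step (the protocols use the supported ladder
    0.001..10 ms); e_triseg the TriSeg tension-balance threshold (N/m).
    """
    method: str = "adams_moulton"
    order: int = 2
    dt_ms: float = 1.0
    e_triseg: float = 1e-4
    newton_tol: float = 1e-10
    max_newton: int = 12

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.method in ("explicit_euler", "rk4"):
            pass
        elif not 1 <= self.order <= 4:
            raise ValueError("order must be in 1..4")
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be positive")
        if not 1e-7 <= self.e_triseg <= 1.0:
            raise ValueError("e_triseg outside supported range")

    def to_dict(self) -> dict:
        return {"method": self.method, "order": self.order,
                "dt_ms": self.dt_ms, "e_triseg": self.e_triseg,
                "newton_tol": self.newton_tol,
                "max_newton": self.max_newton}

    @classmethod
    def from_dict(cls, d: dict) -> "SolverSettings":
        return cls(**d)


# ---------------------------------------------------------------------
# generic stepper (reference path)
# ---------------------------------------------------------------------
def _newton_stage(f, t1, r, c0h, y_guess, tol=1e-12, max_iter=50):
    """Solve y = r + c0h*f(t1, y) by Newton with FD Jacobians."""
    y = np.atleast_1d(np.asarray(y_guess, dtype=float)).copy()
    r = np.atleast_1d(np.asarray(r, dtype=float))
    n = y.size
    for _ in range(max_iter):
        fy = np.atleast_1d(np.asarray(f(t1, y), dtype=float))
        g = y - r - c0h * fy
        jac = np.empty((n, n))
        for j in range(n):
            h = 1e-7 * abs(y[j]) + 1e-10
            yj = y.copy()
            yj[j] += h
            jac[:, j] = (np.atleast_1d(np.asarray(f(t1, yj), dtype=float)) - fy) / h
        m = np.eye(n) - c0h * jac
        d = np.linalg.solve(m, -g)
        y = y + d
        if np.max(np.abs(d) / (np.abs(y) + 1e-12)) < tol:
            return y
    raise RuntimeError("implicit stage Newton did not converge")


def step(f, t, y_hist, f_hist, h, method: str, order: int):
    """One fixed step of the requested multistep method.

    ``y_hist`` and ``f_hist`` are sequences newest-first: y_hist[0] = y_n,
    f_hist[0] = f(t_n, y_n), etc.  Requires ``order`` y-values for BDF,
    ``order`` f-values for Adams-Bashforth and ``order - 1`` f-values for
    Adams-Moulton.  Returns y_{n+1}.
    """
    y = np.atleast_1d(np.asarray(y_hist[0], dtype=float))
    t1 = t + h
    if method == "rk4":
        k1 = np.atleast_1d(np.asarray(f(t, y), dtype=float))
        k2 = np.atleast_1d(np.asarray(f(t + h / 2, y + h / 2 * k1), dtype=float))
        k3 = np.atleast_1d(np.asarray(f(t + h / 2, y + h / 2 * k2), dtype=float))
        k4 = np.atleast_1d(np.asarray(f(t1, y + h * k3), dtype=float))
        return y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    if method == "explicit_euler":
        return y + h * np.atleast_1d(np.asarray(f_hist[0], dtype=float))
    if method == "adams_bashforth":
        if len(f_hist) < order:
            raise ValueError("insufficient f history for AB step")
        acc = y.copy()
        for j, b in enumerate(AB_COEFFS[order]):
            acc = acc + h * float(b) * np.atleast_1d(np.asarray(f_hist[j], dtype=float))
        return acc
    if method == "adams_moulton":
        if len(f_hist) < order - 1:
            raise ValueError("insufficient f history for AM step")
        r = y.copy()
        for j, b in enumerate(AM_PAST[order]):
            r = r + h * float(b) * np.atleast_1d(np.asarray(f_hist[j], dtype=float))
        guess = y + h * np.atleast_1d(np.asarray(f_hist[0], dtype=float)) \
            if f_hist else y
        return _newton_stage(f, t1, r, float(AM_C0[order]) * h, guess)
    if method == "bdf":
        if len(y_hist) < order:
            raise ValueError("insufficient y history for BDF step")
        r = np.zeros_like(y)
        for j, a in enumerate(BDF_ALPHA[order]):
            r = r + float(a) * np.atleast_1d(np.asarray(y_hist[j], dtype=float))
        guess = y if not f_hist else y + h * np.atleast_1d(
            np.asarray(f_hist[0], dtype=float))
        return _newton_stage(f, t1, r, float(BDF_BETA[order]) * h, guess)
    raise ValueError(f"unknown method {method!r}")


def integrate(f, y0, t0, h, n_steps, method: str, order: int = 2):
    """Generic fixed-step run; RK4-bootstraps multistep history.

    Returns (t, Y) with Y of shape (n_steps+1, len(y0)).
    """
    y = np.atleast_1d(np.asarray(y0, dtype=float))
    ys = [y]
    fs = [np.atleast_1d(np.asarray(f(t0, y), dtype=float))]
    out = np.empty((n_steps + 1, y.size))
    out[0] = y
    need = {"adams_bashforth": order, "adams_moulton": order - 1,
            "bdf": order}.get(method, 0)
    for i in range(n_steps):
        t = t0 + i * h
        if len(ys) < need:
            ynew = step(f, t, ys, fs, h, "rk4", order)
        else:
            ynew = step(f, t, ys, fs, h, method, order)
        ys.insert(0, ynew)
        fs.insert(0, np.atleast_1d(np.asarray(f(t + h, ynew), dtype=float)))
        del ys[5:], fs[5:]
        out[i + 1] = ynew
    t = t0 + h * np.arange(n_steps + 1)
    return t, out


# ---------------------------------------------------------------------
# model beat runner (compiled path)
# ---------------------------------------------------------------------
#: trace column order (deterministic): time, volumes, flows, then algebra
TRACE_COLUMNS = (
    ["time_s"]
    + [f"V_{n}_ml" for n in L.COMP_NAMES]
    + [f"q_{n}_Lmin" for n in L.VALVE_NAMES]
    + [f"zeta_{n}" for n in L.VALVE_NAMES]
    + [f"p_{n}_mmHg" for n in L.COMP_NAMES]
    + ["p_peri_mmHg", "V_S_ml", "Y_S_cm", "triseg_residual_Nm"]
    + [f"Tm_{n}_Nm" for n in L.WALL_NAMES]
    + [f"Am_{n}_cm2" for n in L.WALL_NAMES]
    + ["q_artven_Sy_Lmin", "q_artven_Pu_Lmin", "P_diss_W"]
)


def n_steps_per_beat(t_cycle: float, dt_ms: float) -> int:
    """Steps per beat; t_cycle must be commensurate with dt (protocols
    round the sampled cycle length so that every supported dt divides it)."""
    n = int(round(t_cycle / (dt_ms * U.MS)))
    if n < 2:
        raise ValueError("t_cycle shorter than two steps")
    return n


def run_beat(params: ModelParameters, state: SystemState,
             settings: SolverSettings, s_p: float = 1.0,
             p0_artven_sys: float | None = None):
    """Simulate one cardiac cycle from ``state``.

    Returns (trace, end_state, status) where ``trace`` is a
    :class:`cardioloop.metrics.Trace`, ``end_state`` the state after the
    beat (or after the last stable step) and ``status`` one of "ok",
    "nonfinite", "negative_volume", "newton_failed", "triseg_failed".
    PFC enters through ``s_p`` (beat-constant sensing value) and the
    adjusted systemic microcirculation reference drop ``p0_artven_sys``
    (mmHg).
    """
    from .metrics import Trace  # local import to avoid a cycle

    p = params.to_array()
    if p0_artven_sys is None:
        p0_artven_sys = params.artvens["Sy"].p0_artven
    n = n_steps_per_beat(params.t_cycle, settings.dt_ms)
    dt = params.t_cycle / n
    cache = np.array([state.triseg[0], state.triseg[1], settings.e_triseg])
    ys, auxs, status, n_done = K.integrate_fixed(
        state.y, state.t, dt, n, _METHOD_IDS[settings.method],
        settings.order, p, s_p, p0_artven_sys * U.MMHG,
        settings.e_triseg, settings.newton_tol, settings.max_newton, cache)
    m = n_done + 1
    t = state.t + dt * np.arange(m)
    data = np.empty((m, len(TRACE_COLUMNS)))
    data[:, 0] = t
    data[:, 1:9] = ys[:m, :L.IQ0] / U.ML
    data[:, 9:15] = ys[:m, L.IQ0:L.IZ0] / U.LMIN
    data[:, 15:21] = ys[:m, L.IZ0:L.N_STATE]
    c = 21
    data[:, c:c + 8] = auxs[:m, L.AUX_P0:L.AUX_P0 + 8] / U.MMHG
    data[:, c + 8] = auxs[:m, L.AUX_PPERI] / U.MMHG
    data[:, c + 9] = auxs[:m, L.AUX_VS] / U.ML
    data[:, c + 10] = auxs[:m, L.AUX_YS] / U.CM
    data[:, c + 11] = auxs[:m, L.AUX_TSRES]
    data[:, c + 12:c + 17] = auxs[:m, L.AUX_TM0:L.AUX_TM0 + 5]
    data[:, c + 17:c + 22] = auxs[:m, L.AUX_AM0:L.AUX_AM0 + 5] / U.CM2
    data[:, c + 22] = auxs[:m, L.AUX_QAV_SYS] / U.LMIN
    data[:, c + 23] = auxs[:m, L.AUX_QAV_PULM] / U.LMIN
    data[:, c + 24] = auxs[:m, L.AUX_PDISS]
    trace = Trace.from_matrix(data, TRACE_COLUMNS)
    end = SystemState(y=ys[n_done].copy(),
                      triseg=np.array([cache[0], cache[1]]),
                      t=state.t + dt * n_done)
    status_name = {K.OK: "ok", K.UNSTABLE_NONFINITE: "nonfinite",
                   K.UNSTABLE_NEGVOL: "negative_volume",
                   K.UNSTABLE_NEWTON: "newton_failed",
                   K.UNSTABLE_TRISEG: "triseg_failed"}[status]
    return trace, end, status_name


def run_beats(params, state, settings, n_beats, s_p=1.0,
              p0_artven_sys=None, keep_last_trace_only=True):
    """Run several beats back to back (no control updates between beats)."""
    traces = []
    for _ in range(n_beats):
        trace, state, status = run_beat(params, state, settings, s_p,
                                        p0_artven_sys)
        if not keep_last_trace_only:
            traces.append(trace)
        if status != "ok":
            return (traces if not keep_last_trace_only else trace,
                    state, status)
    return (traces if not keep_last_trace_only else trace, state, "ok")


# ---------------------------------------------------------------------
# observed convergence order
# ---------------------------------------------------------------------
def estimate_order(method: str, order: int, f=None, y0=1.0, t_end=1.0,
                   h=0.1, exact=None, lam=-1.0):
    """Observed convergence order on a smooth test problem.

    Runs the method at steps h, h/2 and h/4 and returns the mean log2
    error ratio against ``exact(t_end)`` (default: the linear test
    equation y' = lam*y with its closed-form solution).  Errors of zero
    (e.g. an identically-zero right-hand side) make the order undefined:
    returns NaN.
    """
    if f is None:
        f = lambda t, y: lam * y
        exact = lambda t: np.exp(lam * t) * np.asarray(y0, dtype=float)
    if exact is None:
        raise ValueError("an exact solution is required")
    errs = []
    for hh in (h, h / 2, h / 4):
        n = int(round(t_end / hh))
        _, out = integrate(f, y0, 0.0, hh, n, method, order)
        errs.append(float(np.max(np.abs(out[-1] - np.atleast_1d(exact(t_end))))))
    if min(errs) == 0.0:
        return float("nan")
    r1 = np.log2(errs[0] / errs[1])
    r2 = np.log2(errs[1] / errs[2])
    return float((r1 + r2) / 2)
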