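"""Error metrics for the verification harness.

Mean absolute error of haemodynamic traces against an assumed-true
reference, per-beat energy-balance residuals, and the across-start spread
statistics of the multi-start protocol.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class Trace:
    """Uniformly sampled named signals over one (or more) beats."""
    time: np.ndarray                 # s, uniform grid
    signals: dict[str, np.ndarray]

    @classmethod
    def from_matrix(cls, data: np.ndarray, columns) -> "Trace":
        sig = {c: np.ascontiguousarray(data[:, i])
               for i, c in enumerate(columns) if c != "time_s"}
        return cls(time=np.ascontiguousarray(data[:, 0]), signals=sig)

    def __post_init__(self):
        n = self.time.size
        for k, v in self.signals.items():
            if v.size != n:
                raise ValueError(f"signal {k!r} length mismatch")
        if n >= 2:
            dt = np.diff(self.time)
            if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
                raise ValueError("time grid is not uniform")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0]) if self.time.size > 1 else 0.0

    @property
    def columns(self) -> list[str]:
        return ["time_s"] + list(self.signals)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.signals[name]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time, **self.signals})

    def resample(self, grid: np.ndarray) -> "Trace":
        """Linear interpolation of every signal onto ``grid`` (s)."""
        t0 = self.time - self.time[0]
        sig = {k: np.interp(grid, t0, v) for k, v in self.signals.items()}
        return Trace(time=np.asarray(grid, dtype=float), signals=sig)


#: comparison grid spacing for cross-step-size MAE (s)
MAE_GRID_DT = 1e-3


def _common_grid(a: Trace, b: Trace) -> np.ndarray:
    ta = a.time[-1] - a.time[0]
    tb = b.time[-1] - b.time[0]
    if abs(ta - tb) > MAE_GRID_DT + 1e-12:
        raise ValueError("traces cover different beat lengths")
    n = int(round(min(ta, tb) / MAE_GRID_DT))
    return MAE_GRID_DT * np.arange(n + 1)


def mae(trace_a: Trace, trace_b: Trace, signal: str) -> float:
    """Mean absolute error of one signal between two beat traces.

    Both traces are resampled by linear interpolation onto a common 1 ms
    grid aligned at beat start before averaging |a - b|.
    """
    grid = _common_grid(trace_a, trace_b)
    a = trace_a.resample(grid)[signal]
    b = trace_b.resample(grid)[signal]
    return float(np.mean(np.abs(a - b)))


def assumed_true(traces: list[Trace]) -> Trace:
    """Pointwise mean across methods of the stable finest-step traces.

    The single-beat protocol defines truth as the average signal over the
    integration methods at the smallest timestep; with one stable trace the
    reference is that trace itself.  Traces are averaged on the common 1 ms
    grid; the result is independent of input ordering.
    """
    if not traces:
        raise ValueError("no stable trace available for the reference")
    if len(traces) == 1:
        return traces[0]
    grid = _common_grid(traces[0], traces[-1])
    rs = [t.resample(grid) for t in traces]
    sig = {k: np.mean([r[k] for r in rs], axis=0) for k in rs[0].signals}
    return Trace(time=grid.copy(), signals=sig)


def _loop_integral(p: np.ndarray, v: np.ndarray) -> float:
    """Trapezoidal closed-loop integral of p dV over the trace."""
    dv = np.diff(v)
    pm = 0.5 * (p[1:] + p[:-1])
    return float(np.sum(pm * dv))


def stroke_work(trace: Trace, cavity: str = "LV") -> float:
    """Pump work (J) of one cavity over the beat: -loop p dV in SI."""
    from . import units as U
    p = trace[f"p_{cavity}_mmHg"] * U.MMHG
    v = trace[f"V_{cavity}_ml"] * U.ML
    return -_loop_integral(p, v)


def energy_balance_error(trace: Trace) -> float:
    """Per-beat energy residual (J).

    For the closed loop, the sum of closed-loop integrals of p dV over all
    compartments equals minus the dissipated energy (valve Bernoulli
    losses, microcirculation, characteristic resistances); the residual
    |sum p dV + dissipation| isolates time-integration and quadrature
    error and vanishes with the step size.  Meaningful with the
    pressure-flow control off (volume-conserving loop).
    """
    from . import units as U
    from ._layout import COMP_NAMES
    total = 0.0
    for n in COMP_NAMES:
        p = trace[f"p_{n}_mmHg"] * U.MMHG
        v = trace[f"V_{n}_ml"] * U.ML
        total += _loop_integral(p, v)
    diss = float(np.trapezoid(trace["P_diss_W"], dx=trace.dt))
    return abs(total + diss)


def wall_work(trace: Trace) -> float:
    """Total myocardial work (J) over the beat: -sum of loop Tm dAm."""
    from . import units as U
    from ._layout import WALL_NAMES
    total = 0.0
    for n in WALL_NAMES:
        tm = trace[f"Tm_{n}_Nm"]
        am = trace[f"Am_{n}_cm2"] * U.CM2
        total += _loop_integral(tm, am)
    return -total


def multistart_spread(index_values: np.ndarray | None = None,
                      traces: list[Trace] | None = None,
                      signal: str | None = None) -> dict:
    """Across-start spread of a converged steady state.

    ``index_values``: one scalar cardiac index per start; the convergence
    error is their population standard deviation.  ``traces``: final-beat
    traces per start; each start's signal is compared (MAE) against the
    across-start mean signal.  Fewer than two starts make the spread
    undefined (returns NaNs).
    """
    out: dict = {}
    if index_values is not None:
        x = np.asarray(index_values, dtype=float)
        out["sd"] = float(np.std(x)) if x.size >= 2 else float("nan")
        out["n"] = int(x.size)
    if traces is not None:
        if signal is None:
            raise ValueError("signal name required with traces")
        if len(traces) < 2:
            out["mae_vs_mean"] = [float("nan")] * len(traces)
            return out
        grid = _common_grid(traces[0], traces[-1])
        rs = [t.resample(grid)[signal] for t in traces]
        mean_sig = np.mean(rs, axis=0)
        out["mae_vs_mean"] = [float(np.mean(np.abs(r - mean_sig))) for r in rs]
        out["median_mae"] = float(np.median(out["mae_vs_mean"]))
    return out
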