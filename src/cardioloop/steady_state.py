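"""Beat summaries, steady-state criteria and the run-to-steady-state loop.

Steady state is detected from beat-mean valve flows.  Without control the
criterion is the RMS beat-to-beat change of the six valve means normalised
by the mean valve flow; with pressure-flow control the venous-return
target error is added in quadrature.  A run is excluded when the beat-mean
left atrial pressure exceeds 50 mmHg (beyond the pathological envelope the
model is trusted in).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import units as U
from ._layout import VALVE_NAMES, VENRA
from .integrators import SolverSettings, run_beat
from .metrics import Trace
from .parameters import ModelParameters
from .model import SystemState
from .pfc import PfcParameters, PfcState, beat_update

N_VALVE = 6
#: beat-mean LA pressure above which a simulation is excluded (mmHg)
LA_PRESSURE_EXCLUSION_MMHG = 50.0
#: standard steady-state threshold ladder
THRESHOLD_LADDER = (1e-1, 1e-2, 1e-3, 1e-4)


@dataclass
class BeatSummary:
    """Beat-mean quantities entering the steady-state criteria."""
    beat: int
    q_valve: np.ndarray          # mean flow per valve connection, L/min (6,)
    q_venous_return: float       # mean systemic-venous -> RA flow, L/min
    p_la_mean: float             # mean left atrial pressure, mmHg
    p_art_mean: float            # mean systemic arterial pressure, mmHg
    v_lv_ed: float               # end-diastolic LV volume, ml
    v_lv_es: float               # end-systolic LV volume, ml

    def __post_init__(self):
        self.q_valve = np.asarray(self.q_valve, dtype=float)
        if self.q_valve.size != N_VALVE:
            raise ValueError("expected six valve-connection means")


def summarize_beat(trace: Trace, beat: int) -> BeatSummary:
    """Time-averages of one full beat trace (trapezoidal means)."""
    t = trace.time
    span = t[-1] - t[0]

    def tmean(x):
        return float(np.trapezoid(x, t) / span)

    q = np.array([tmean(trace[f"q_{n}_Lmin"]) for n in VALVE_NAMES])
    v_lv = trace["V_LV_ml"]
    return BeatSummary(
        beat=beat,
        q_valve=q,
        q_venous_return=q[VENRA],
        p_la_mean=tmean(trace["p_LA_mmHg"]),
        p_art_mean=tmean(trace["p_SyArt_mmHg"]),
        v_lv_ed=float(np.max(v_lv)),
        v_lv_es=float(np.min(v_lv)),
    )


def criterion_no_pfc(current: BeatSummary, previous: BeatSummary) -> float:
    """Dimensionless beat-periodicity criterion (control off).

    (n_valve / sum_v |q_v,b|) * sqrt( sum_v (q_v,b - q_v,b-1)^2 / n_valve );
    absolute values in the normalisation guard against regurgitant means.
    Returns NaN (reported as non-converged) when the mean valve flow is not
    positive.
    """
    denom = float(np.sum(np.abs(current.q_valve)))
    if denom <= 0:
        return float("nan")
    d = current.q_valve - previous.q_valve
    rms = np.sqrt(float(np.sum(d * d)) / N_VALVE)
    return N_VALVE / denom * rms


def criterion_pfc(current: BeatSummary, previous: BeatSummary,
                  q0_pfc: float) -> float:
    """Homeostatic steady-state criterion (control on).

    Combines the venous-return target error with the beat-periodicity term
    under a single square root (sum of squares), so it reduces to the
    control-off criterion when venous return sits on target.
    """
    denom = float(np.sum(np.abs(current.q_valve)))
    if denom <= 0 or q0_pfc <= 0:
        return float("nan")
    d = current.q_valve - previous.q_valve
    term_flow = (N_VALVE / denom) ** 2 * float(np.sum(d * d)) / N_VALVE
    term_vr = (current.q_venous_return / q0_pfc - 1.0) ** 2
    return float(np.sqrt(term_vr + term_flow))


def is_excluded(summary: BeatSummary) -> bool:
    """Exclusion rule: beat-mean LA pressure strictly above 50 mmHg."""
    return summary.p_la_mean > LA_PRESSURE_EXCLUSION_MMHG


@dataclass
class SteadyResult:
    """Outcome of a run-to-steady-state loop."""
    beats: int
    criteria: list[float]                 # criterion after beats 2, 3, ...
    converged: bool
    beats_to_threshold: dict[float, int]  # threshold -> first beat meeting it
    excluded: bool = False
    exclusion_reason: str = ""
    stable: bool = True
    status: str = "ok"
    summaries: list[BeatSummary] = field(default_factory=list)
    threshold_traces: dict = field(default_factory=dict)
    final_trace: Trace | None = None
    final_state: SystemState | None = None
    pfc_state: PfcState | None = None

    def beats_to(self, threshold: float) -> int | None:
        return self.beats_to_threshold.get(threshold)


def run_to_steady(params: ModelParameters, state: SystemState,
                  settings: SolverSettings, e_steady: float = 1e-3,
                  max_beats: int = 100, pfc: PfcParameters | None = None,
                  pfc_state: PfcState | None = None,
                  thresholds=THRESHOLD_LADDER,
                  keep_summaries: bool = True,
                  record_threshold_traces: bool = False,
                  stop_when_excluded: bool = False) -> SteadyResult:
    """Simulate beats until the steady-state criterion drops below e_steady.

    With ``pfc`` given, the control loop is active: the criterion includes
    the venous-return target and the control state is updated after every
    completed beat.  Instability keeps the last stable beat; exclusion
    (mean LA pressure > 50 mmHg on any beat) is flagged but the partial
    history is retained.  ``stop_when_excluded`` abandons an excluded run
    at the first offending beat (excluded runs are dropped from analysis,
    so their remaining beats carry no information).
    """
    if max_beats < 1:
        raise ValueError("max_beats must be >= 1")
    pfc_on = pfc is not None
    if pfc_on and pfc_state is None:
        pfc_state = PfcState(p0_artven_sys=params.artvens["Sy"].p0_artven)

    thresholds = tuple(sorted(thresholds, reverse=True))
    beats_to: dict[float, int] = {}
    threshold_traces: dict[float, Trace] = {}
    criteria: list[float] = []
    summaries: list[BeatSummary] = []
    prev: BeatSummary | None = None
    converged = False
    excluded = False
    reason = ""
    status = "ok"
    last_trace = None
    last_state = state
    beats = 0

    for b in range(1, max_beats + 1):
        s_p = pfc_state.s_p if pfc_on else 1.0
        p0 = pfc_state.p0_artven_sys if pfc_on else None
        trace, new_state, status = run_beat(params, state, settings,
                                            s_p=s_p, p0_artven_sys=p0)
        if status != "ok":
            # numerically unstable: retain the last stable beat
            break
        beats = b
        last_trace = trace
        last_state = new_state
        state = new_state
        summary = summarize_beat(trace, b)
        if keep_summaries:
            summaries.append(summary)
        if is_excluded(summary) and not excluded:
            excluded = True
            reason = (f"mean LA pressure {summary.p_la_mean:.1f} mmHg > "
                      f"{LA_PRESSURE_EXCLUSION_MMHG:.0f} mmHg on beat {b}")
        if excluded and stop_when_excluded:
            prev = summary
            break
        if pfc_on:
            pfc_state = beat_update(pfc_state, summary.p_art_mean,
                                    summary.q_venous_return, pfc)
        if prev is not None:
            c = (criterion_pfc(summary, prev, pfc.q0_pfc) if pfc_on
                 else criterion_no_pfc(summary, prev))
            criteria.append(c)
            if np.isfinite(c):
                for th in thresholds:
                    if th not in beats_to and c < th:
                        beats_to[th] = b
                        if record_threshold_traces:
                            threshold_traces[th] = trace
                if c < e_steady:
                    converged = True
                    prev = summary
                    break
        prev = summary

    return SteadyResult(
        beats=beats, criteria=criteria, converged=converged,
        beats_to_threshold=beats_to, excluded=excluded,
        exclusion_reason=reason, stable=(status == "ok"), status=status,
        summaries=summaries, threshold_traces=threshold_traces,
        final_trace=last_trace,
        final_state=last_state, pfc_state=pfc_state if pfc_on else None)
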