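"""Parameter sampling and the four verification protocols.

The numerical accuracy of the closed loop is probed over a 25-parameter
uniform sample space covering contractility, passive stiffness, activation
timing, wall geometry, valve pathology (regurgitation/stenosis branches),
heart rate and — with the pressure-flow control active — its pressure and
flow targets.  Four drivers reproduce the study designs:

* single-beat: one beat per sample over a grid of integrators, step sizes
  and TriSeg thresholds, scored against the finest-timestep assumed-true
  signal;
* multi-beat: beats-to-steady-state without control;
* pfc: beats-to-steady-state with homeostatic control and the 50 mmHg
  left-atrial exclusion rule;
* multistart: uniqueness of the controlled steady state across many
  initial states.
"""
from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import units as U
from .integrators import SolverSettings, run_beat
from .metrics import Trace, assumed_true, energy_balance_error, mae, \
    multistart_spread
from .parameters import ModelParameters, load_reference
from .pfc import PfcParameters
from .reference import reference_state
from .steady_state import SteadyResult, run_to_steady, THRESHOLD_LADDER

#: sampled parameter columns, in fixed order (Table-style naming)
VENT_WALLS = ("LVfw", "IVS", "RVfw")
SAMPLED_VALVES = ("MV", "AV")
PARAMETER_NAMES = (
    [f"patch.Sf_Act:{w}" for w in VENT_WALLS]
    + [f"patch.k1:{w}" for w in VENT_WALLS]
    + [f"patch.Sf_pas:{w}" for w in VENT_WALLS]
    + [f"patch.dt:{w}" for w in VENT_WALLS]
    + [f"patch.V_wall:{w}" for w in VENT_WALLS]
    + [f"patch.Am_ref:{w}" for w in VENT_WALLS]
    + [f"valve.A_leak:{v}" for v in SAMPLED_VALVES]
    + [f"valve.A_open:{v}" for v in SAMPLED_VALVES]
    + ["t_cycle", "PFC.p0", "PFC.q0"]
)

#: uniform bounds (units as in the parameter table; % relative to reference)
BOUNDS = {
    "patch.Sf_Act": (60.0, 120.0),    # kPa
    "patch.k1": (5.0, 15.0),
    "patch.Sf_pas": (100.0, 2500.0),  # kPa
    "patch.dt": (0.0, 50.0),          # ms
    "patch.V_wall": (80.0, 120.0),    # %
    "patch.Am_ref": (80.0, 120.0),    # %
    "valve.A_open": (75.0, 100.0),    # % (stenosis branch)
    "t_cycle": (0.5, 1.5),            # s
    "PFC.p0": (73.0, 110.0),          # mmHg
    "PFC.q0": (4.0, 6.0),             # L/min
}
#: pathological-branch probability for valve leak and stenosis
VALVE_BRANCH_PROB = 0.25
A_LEAK_DEFAULT_PCT = 1e-10
A_LEAK_PATHOLOGICAL_PCT = 25.0

#: fraction of the cycle between atrial and ventricular activation onset
AV_DELAY_FRACTION = 0.15
#: sampled cycle lengths are rounded to this grid so every supported step
#: size divides the beat exactly
T_CYCLE_ROUND_S = 0.01


@dataclass
class SampleSet:
    """Matrix of sampled parameter values plus the valve branch flags."""
    seed: int
    pfc_enabled: bool
    values: pd.DataFrame              # one row per sample
    branches: pd.DataFrame            # boolean pathology flags per sample

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def n_parameters(self) -> int:
        return self.values.shape[1]

    def row(self, i: int) -> pd.Series:
        return self.values.iloc[i]


def sample_parameters(n: int, seed: int, pfc_enabled: bool = True
                      ) -> SampleSet:
    """Draw n independent uniform samples of the 25 varied parameters.

    Valve pathology branches: each sampled valve takes the leak
    (regurgitation) branch with probability 0.25, otherwise the leak area
    stays at its nominal 1e-10 %; independently the stenosis branch (open
    area uniform in 75..100 %) is taken with probability 0.25, otherwise
    the open area stays at 100 %.  Without the control loop the two PFC
    target columns are omitted.  Each sample has its own child random
    stream, so sample i does not depend on n.
    """
    if n < 1:
        raise ValueError("need at least one sample")
    streams = [np.random.default_rng(s)
               for s in np.random.SeedSequence(seed).spawn(n)]
    names = list(PARAMETER_NAMES)
    if not pfc_enabled:
        names = [c for c in names if not c.startswith("PFC.")]
    rows = []
    brows = []
    for rng in streams:
        row = {}
        for group in ("patch.Sf_Act", "patch.k1", "patch.Sf_pas",
                      "patch.dt", "patch.V_wall", "patch.Am_ref"):
            lo, hi = BOUNDS[group]
            for w in VENT_WALLS:
                row[f"{group}:{w}"] = rng.uniform(lo, hi)
        flags = {}
        for v in SAMPLED_VALVES:
            leak = rng.uniform() < VALVE_BRANCH_PROB
            flags[f"leak:{v}"] = leak
            row[f"valve.A_leak:{v}"] = (A_LEAK_PATHOLOGICAL_PCT if leak
                                        else A_LEAK_DEFAULT_PCT)
            sten = rng.uniform() < VALVE_BRANCH_PROB
            flags[f"stenosis:{v}"] = sten
            row[f"valve.A_open:{v}"] = (rng.uniform(*BOUNDS["valve.A_open"])
                                        if sten else 100.0)
        row["t_cycle"] = rng.uniform(*BOUNDS["t_cycle"])
        if pfc_enabled:
            row["PFC.p0"] = rng.uniform(*BOUNDS["PFC.p0"])
            row["PFC.q0"] = rng.uniform(*BOUNDS["PFC.q0"])
        rows.append(row)
        brows.append(flags)
    values = pd.DataFrame(rows, columns=names)
    return SampleSet(seed=seed, pfc_enabled=pfc_enabled, values=values,
                     branches=pd.DataFrame(brows))


def apply_sample(reference: ModelParameters, sample: pd.Series
                 ) -> ModelParameters:
    """Build the model parameterization of one sample.

    Absolute columns (stresses, exponents, delays, t_cycle) replace the
    reference values; percent columns scale them.  The ventricular
    activation delay is the atrioventricular delay (a fixed fraction of
    the cycle) plus the sampled per-wall offset; the sampled cycle length
    is rounded so that every supported step size divides the beat.
    """
    p = reference.copy()
    t_cycle = round(float(sample["t_cycle"]) / T_CYCLE_ROUND_S) \
        * T_CYCLE_ROUND_S
    p.t_cycle = t_cycle
    for w in VENT_WALLS:
        wp = p.walls[w]
        wp.Sf_act = float(sample[f"patch.Sf_Act:{w}"])
        wp.k1 = float(sample[f"patch.k1:{w}"])
        wp.Sf_pas = float(sample[f"patch.Sf_pas:{w}"])
        wp.dt_act = AV_DELAY_FRACTION * t_cycle * 1e3 \
            + float(sample[f"patch.dt:{w}"])
        wp.V_wall = reference.walls[w].V_wall \
            * float(sample[f"patch.V_wall:{w}"]) / 100.0
        wp.Am_ref = reference.walls[w].Am_ref \
            * float(sample[f"patch.Am_ref:{w}"]) / 100.0
    for v in SAMPLED_VALVES:
        vp = p.valves[v]
        ref_open = reference.valves[v].A_open
        vp.A_open = ref_open * float(sample[f"valve.A_open:{v}"]) / 100.0
        vp.A_leak = ref_open * float(sample[f"valve.A_leak:{v}"]) / 100.0
    p.validate()
    return p


def pfc_of_sample(sample: pd.Series) -> PfcParameters:
    return PfcParameters(p0_pfc=float(sample["PFC.p0"]),
                         q0_pfc=float(sample["PFC.q0"]))


@dataclass
class ProtocolReport:
    """Per-run rows plus aggregates; aggregates are recomputable from rows."""
    protocol: str
    config: dict
    rows: pd.DataFrame
    aggregates: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {"protocol": self.protocol, "config": self.config,
                "aggregates": self.aggregates,
                "rows": self.rows.to_dict(orient="records")}


def _quantiles(x, qs=(0.05, 0.5, 0.95)) -> dict:
    x = np.asarray([v for v in x if np.isfinite(v)], dtype=float)
    if x.size == 0:
        return {f"q{int(q * 100)}": float("nan") for q in qs}
    return {f"q{int(q * 100)}": float(np.quantile(x, q)) for q in qs}


def _load_start():
    params, state_dict = load_reference()
    return params, reference_state(state_dict)


# ---------------------------------------------------------------------
# single-beat protocol
# ---------------------------------------------------------------------
def run_single_beat_protocol(n_samples: int = 25, seed: int = 1,
                             methods=(("adams_moulton", 2),),
                             dt_grid_ms=(1.0, 2.0),
                             e_triseg_grid=(1e-4,),
                             truth_methods=(("adams_moulton", 2),
                                            ("bdf", 2)),
                             truth_dt_ms: float = 0.01,
                             truth_e_triseg: float = 1e-6,
                             progress=None) -> ProtocolReport:
    """One beat per sample x method x step x threshold from the shared
    reference state, scored against the assumed-true signal (mean of the
    truth methods at the finest step)."""
    reference, start = _load_start()
    samples = sample_parameters(n_samples, seed, pfc_enabled=False)
    rows = []
    for i in range(samples.n):
        params = apply_sample(reference, samples.row(i))
        truths = []
        for (m, o) in truth_methods:
            s = SolverSettings(method=m, order=o, dt_ms=truth_dt_ms,
                               e_triseg=truth_e_triseg)
            tr, _, status = run_beat(params, start.copy(), s)
            if status == "ok":
                truths.append(tr)
        truth = assumed_true(truths) if truths else None
        for (m, o) in methods:
            for dt in dt_grid_ms:
                for et in e_triseg_grid:
                    s = SolverSettings(method=m, order=o, dt_ms=dt,
                                       e_triseg=et)
                    t0 = time.perf_counter()
                    tr, _, status = run_beat(params, start.copy(), s)
                    wall = time.perf_counter() - t0
                    row = {"sample": i, "method": m, "order": o,
                           "dt_ms": dt, "e_triseg": et, "status": status,
                           "stable": status == "ok", "wall_s": wall,
                           "mae_lv_volume_ml": float("nan"),
                           "mae_lv_pressure_mmHg": float("nan"),
                           "energy_residual_J": float("nan"),
                           "triseg_residual_max": float("nan")}
                    if status == "ok":
                        row["energy_residual_J"] = energy_balance_error(tr)
                        row["triseg_residual_max"] = \
                            float(tr["triseg_residual_Nm"].max())
                        if truth is not None:
                            row["mae_lv_volume_ml"] = \
                                mae(tr, truth, "V_LV_ml")
                            row["mae_lv_pressure_mmHg"] = \
                                mae(tr, truth, "p_LV_mmHg")
                    rows.append(row)
        if progress:
            progress(i + 1, samples.n)
    df = pd.DataFrame(rows)
    stable = df[df.stable]
    agg = {
        "n_runs": len(df),
        "n_stable": int(df.stable.sum()),
        "mae_lv_volume_ml": _quantiles(stable.mae_lv_volume_ml),
        "mae_lv_pressure_mmHg": _quantiles(stable.mae_lv_pressure_mmHg),
        "energy_residual_J": _quantiles(stable.energy_residual_J),
    }
    cfg = {"n_samples": n_samples, "seed": seed,
           "methods": list(map(list, methods)),
           "dt_grid_ms": list(dt_grid_ms),
           "e_triseg_grid": list(e_triseg_grid),
           "truth_methods": list(map(list, truth_methods)),
           "truth_dt_ms": truth_dt_ms, "truth_e_triseg": truth_e_triseg}
    return ProtocolReport("single_beat", cfg, df, agg)


# ---------------------------------------------------------------------
# multi-beat (no control) and PFC protocols
# ---------------------------------------------------------------------
def _steady_row(i: int, res: SteadyResult) -> dict:
    row = {"sample": i, "stable": res.stable, "status": res.status,
           "converged": res.converged, "beats": res.beats,
           "excluded": res.excluded,
           "exclusion_reason": res.exclusion_reason}
    for th in THRESHOLD_LADDER:
        b = res.beats_to_threshold.get(th)
        row[f"beats_to_{th:g}"] = b if b is not None else np.nan
    if res.summaries:
        sm = res.summaries[-1]
        row.update(p_art_mean=sm.p_art_mean, p_la_mean=sm.p_la_mean,
                   q_venous_return=sm.q_venous_return,
                   v_lv_ed=sm.v_lv_ed, v_lv_es=sm.v_lv_es)
    return row


def run_multi_beat_protocol(n_samples: int = 50, seed: int = 1,
                            settings: SolverSettings | None = None,
                            max_beats: int = 100,
                            e_steady: float = 1e-4,
                            progress=None) -> ProtocolReport:
    """Beats to steady state without control, per sample, with the full
    threshold ladder recorded.

    Every run continues to its stopping threshold (default: the tightest
    ladder rung) so the ladder rungs above it are all recorded.
    """
    reference, start = _load_start()
    if settings is None:
        settings = SolverSettings()
    samples = sample_parameters(n_samples, seed, pfc_enabled=False)
    rows = []
    results = []
    for i in range(samples.n):
        params = apply_sample(reference, samples.row(i))
        res = run_to_steady(params, start.copy(), settings,
                            e_steady=e_steady, max_beats=max_beats)
        rows.append(_steady_row(i, res))
        results.append(res)
        if progress:
            progress(i + 1, samples.n)
    df = pd.DataFrame(rows)
    agg = {"n_samples": n_samples,
           "n_stable": int(df.stable.sum()),
           "n_converged": int(df.converged.sum())}
    for th in THRESHOLD_LADDER:
        agg[f"beats_to_{th:g}"] = _quantiles(df[f"beats_to_{th:g}"])
    cfg = {"n_samples": n_samples, "seed": seed, "max_beats": max_beats,
           "e_steady": e_steady, "solver": settings.to_dict(), "pfc": False}
    report = ProtocolReport("multi_beat", cfg, df, agg)
    report.results = results  # final states reusable by callers
    return report


def run_pfc_protocol(n_samples: int = 50, seed: int = 1,
                     settings: SolverSettings | None = None,
                     max_beats: int = 250,
                     e_steady: float = 1e-4,
                     baseline: ProtocolReport | None = None,
                     stop_when_excluded: bool = False,
                     progress=None) -> ProtocolReport:
    """Beats to homeostatic steady state with the control loop active.

    Samples include the control targets; the left-atrial 50 mmHg exclusion
    rule is applied per beat.  When ``baseline`` (a multi-beat report run
    with the same seed and count) is given, the per-sample beats ratio
    with-control / without-control is reported.
    """
    reference, start = _load_start()
    if settings is None:
        settings = SolverSettings()
    samples = sample_parameters(n_samples, seed, pfc_enabled=True)
    rows = []
    results = []
    for i in range(samples.n):
        params = apply_sample(reference, samples.row(i))
        res = run_to_steady(params, start.copy(), settings,
                            e_steady=e_steady, max_beats=max_beats,
                            pfc=pfc_of_sample(samples.row(i)),
                            stop_when_excluded=stop_when_excluded)
        row = _steady_row(i, res)
        if res.pfc_state is not None:
            row["s_p"] = res.pfc_state.s_p
            row["s_q"] = res.pfc_state.s_q
        rows.append(row)
        results.append(res)
        if progress:
            progress(i + 1, samples.n)
    df = pd.DataFrame(rows)
    agg = {"n_samples": n_samples,
           "n_stable": int(df.stable.sum()),
           "n_converged": int(df.converged.sum()),
           "n_excluded": int(df.excluded.sum())}
    for th in THRESHOLD_LADDER:
        agg[f"beats_to_{th:g}"] = _quantiles(df[f"beats_to_{th:g}"])
    if baseline is not None:
        base = baseline.rows.set_index("sample")
        ratios = []
        for th in THRESHOLD_LADDER:
            col = f"beats_to_{th:g}"
            r = df.set_index("sample")[col] / base[col]
            ratios.append(r.rename(f"ratio_{th:g}"))
            agg[f"beats_ratio_{th:g}"] = _quantiles(r)
        for r in ratios:
            df = df.join(r, on="sample")
    cfg = {"n_samples": n_samples, "seed": seed, "max_beats": max_beats,
           "e_steady": e_steady, "solver": settings.to_dict(), "pfc": True}
    report = ProtocolReport("pfc", cfg, df, agg)
    report.results = results
    return report


# ---------------------------------------------------------------------
# multi-start protocol
# ---------------------------------------------------------------------
def run_multistart_protocol(n_samples: int = 10, n_starts: int = 10,
                            seed: int = 1,
                            settings: SolverSettings | None = None,
                            beats: int = 50,
                            source: ProtocolReport | None = None,
                            progress=None) -> ProtocolReport:
    """Uniqueness of the controlled steady state across starting points.

    Starting points are the final states of controlled runs of the first
    ``n_starts`` samples (from ``source`` if given, else computed here);
    each of the ``n_samples`` samples is then rerun from every start for a
    fixed number of beats.  Reported per sample: the standard deviation of
    end-diastolic/end-systolic LV volume across starts and the MAE of the
    final-beat LV volume and pressure signals against the across-start
    mean signal.
    """
    reference, start = _load_start()
    if settings is None:
        settings = SolverSettings()
    samples = sample_parameters(n_samples, seed, pfc_enabled=True)
    if source is None:
        source = run_pfc_protocol(n_samples=max(n_samples, n_starts),
                                  seed=seed, settings=settings,
                                  max_beats=beats)
    starts = [r.final_state for r in source.results[:n_starts]
              if r.stable and r.final_state is not None]
    rows = []
    for i in range(samples.n):
        params = apply_sample(reference, samples.row(i))
        pfc = pfc_of_sample(samples.row(i))
        finals = []
        n_stable = 0
        for k, st in enumerate(starts):
            st = st.copy()
            st.t = 0.0
            res = run_to_steady(params, st, settings, e_steady=0.0,
                                max_beats=beats, pfc=pfc,
                                keep_summaries=True)
            if res.stable and res.final_trace is not None \
                    and res.beats == beats:
                n_stable += 1
                finals.append(res)
        row = {"sample": i, "n_starts": len(starts),
               "n_stable": n_stable}
        if n_stable >= 2:
            ed = np.array([r.summaries[-1].v_lv_ed for r in finals])
            es = np.array([r.summaries[-1].v_lv_es for r in finals])
            row["sd_v_lv_ed_ml"] = multistart_spread(index_values=ed)["sd"]
            row["sd_v_lv_es_ml"] = multistart_spread(index_values=es)["sd"]
            traces = [r.final_trace for r in finals]
            row["mae_lv_volume_ml"] = multistart_spread(
                traces=traces, signal="V_LV_ml")["median_mae"]
            row["mae_lv_pressure_mmHg"] = multistart_spread(
                traces=traces, signal="p_LV_mmHg")["median_mae"]
        else:
            row.update(sd_v_lv_ed_ml=np.nan, sd_v_lv_es_ml=np.nan,
                       mae_lv_volume_ml=np.nan, mae_lv_pressure_mmHg=np.nan)
        rows.append(row)
        if progress:
            progress(i + 1, samples.n)
    df = pd.DataFrame(rows)
    agg = {"n_runs_scheduled": samples.n * len(starts),
           "n_stable": int(df.n_stable.sum()),
           "mae_lv_volume_ml": _quantiles(df.mae_lv_volume_ml),
           "mae_lv_pressure_mmHg": _quantiles(df.mae_lv_pressure_mmHg),
           "sd_v_lv_ed_ml": _quantiles(df.sd_v_lv_ed_ml)}
    cfg = {"n_samples": n_samples, "n_starts": n_starts, "seed": seed,
           "beats": beats, "solver": settings.to_dict(), "pfc": True}
    return ProtocolReport("multistart", cfg, df, agg)
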