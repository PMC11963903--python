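"""Reference parameterization and its calibrated steady state.

The package ships a healthy-adult closed-loop parameterization together
with the state variables of its homeostatic steady state (mean systemic
arterial pressure 91 mmHg, venous return 5 L/min — the midpoints of the
sampled control-target ranges — at a 0.85 s cycle).  Every protocol run
starts from this shared state.

:func:`calibrate_reference` rebuilds the fixture from scratch: it settles
the loop from a resting guess, runs the pressure-flow control to a tight
homeostatic steady state, and freezes the state vector, the TriSeg warm
start and the adapted peripheral-resistance reference.  The shipped JSON
was produced by exactly this routine (see ``scripts/make_reference.py``).
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from . import units as U
from .integrators import SolverSettings, run_beats
from .model import SystemState, initial_state_guess
from .parameters import ModelParameters, default_parameters
from .pfc import PfcParameters, PfcState
from .steady_state import run_to_steady

#: homeostatic calibration targets (midpoints of the sampled PFC ranges)
CALIBRATION_P0_MMHG = 91.0
CALIBRATION_Q0_LMIN = 5.0


def calibrate_reference(e_steady: float = 1e-5, max_beats: int = 400,
                        settings: SolverSettings | None = None,
                        ) -> tuple[ModelParameters, dict]:
    """Run the pressure-flow control to steady state and freeze the result.

    Returns (parameters, state_dict); the state dict matches the fixture
    schema of :func:`cardioloop.parameters.load_reference`.
    """
    params = default_parameters()
    if settings is None:
        settings = SolverSettings()  # Adams-Moulton 2, 1 ms
    state = initial_state_guess(params)
    # gentle settling before the control loop engages
    _, state, status = run_beats(params, state,
                                 SolverSettings(method="rk4", dt_ms=0.1), 3)
    if status != "ok":
        raise RuntimeError(f"reference settling failed: {status}")
    _, state, status = run_beats(params, state, settings, 7)
    if status != "ok":
        raise RuntimeError(f"reference settling failed: {status}")
    res = run_to_steady(params, state, settings, e_steady=e_steady,
                        max_beats=max_beats,
                        pfc=PfcParameters(CALIBRATION_P0_MMHG,
                                          CALIBRATION_Q0_LMIN))
    if not (res.converged and res.stable):
        raise RuntimeError("reference calibration did not converge "
                           f"(beats={res.beats}, status={res.status})")
    final = res.final_state
    params.artvens["Sy"].p0_artven = float(res.pfc_state.p0_artven_sys)
    state_dict = {
        "y": [float(v) for v in final.y],
        "triseg": [float(final.triseg[0]), float(final.triseg[1])],
        "p0_artven_sys": float(res.pfc_state.p0_artven_sys),
        "calibration": {
            "p0_mmHg": CALIBRATION_P0_MMHG,
            "q0_Lmin": CALIBRATION_Q0_LMIN,
            "e_steady": e_steady,
            "beats": res.beats,
            "solver": settings.to_dict(),
            "p_art_mean_mmHg": res.summaries[-1].p_art_mean,
            "q_venous_return_Lmin": res.summaries[-1].q_venous_return,
        },
    }
    return params, state_dict


def fixture_checksum(d: dict) -> str:
    """Stable content hash of a fixture dict (reported in protocol runs)."""
    text = json.dumps(d, sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def write_fixture(path: str | Path, params: ModelParameters,
                  state_dict: dict) -> None:
    d = {"parameters": params.to_dict(), "state": state_dict}
    d["checksum"] = fixture_checksum(d)
    Path(path).write_text(json.dumps(d, indent=1))


def reference_state(state_dict: dict) -> SystemState:
    """Materialize the fixture's initial state."""
    return SystemState(y=np.asarray(state_dict["y"], dtype=float),
                       triseg=np.asarray(state_dict["triseg"], dtype=float),
                       t=0.0)
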