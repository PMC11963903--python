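"""Model parameterization of the closed-loop circulation.

:class:`ModelParameters` carries every constitutive constant of the model in
the conventional clinical units (kPa, ms, ml, cm2, mmHg, L/min, s) and packs
itself into the flat SI vector consumed by the compiled kernels.

The shipped healthy-adult reference parameterization lives in
``data/reference.json`` together with the steady-state initial condition it
was calibrated to (see :mod:`cardioloop.reference`).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np

from . import _layout as L
from . import units as U

WALLS = L.WALL_NAMES
VALVES = L.VALVE_NAMES
TUBES = L.TUBE_NAMES
ARTVENS = ("Sy", "Pu")


@dataclass
class WallParams:
    """One-patch wall: contractile, passive and geometric constants."""
    Sf_act: float     # active stress scale, kPa
    k1: float         # passive (collagen) stiffness exponent
    Sf_pas: float     # passive stiffness constant, kPa
    dt_act: float     # activation delay, ms (from cycle start)
    t_twitch: float   # activation duration, fraction of t_cycle
    V_wall: float     # wall volume, ml
    Am_ref: float     # midwall reference area, cm2


@dataclass
class ValveParams:
    A_open: float     # open orifice area, cm2
    A_leak: float     # closed (leak) orifice area, cm2
    L: float          # effective inertance length, cm


@dataclass
class TubeParams:
    V_ref: float      # reference volume, ml
    p_ref: float      # pressure at V_ref, mmHg
    k_tube: float     # stiffness exponent
    R_z: float        # characteristic (series) resistance, mmHg/(L/min)


@dataclass
class ArtVenParams:
    p0_artven: float  # reference pressure drop, mmHg
    q_ref: float      # flow at the reference drop, L/min
    k_av: float       # flow exponent


@dataclass
class ModelParameters:
    """Full parameter set of the closed loop, clinical units at the surface."""
    walls: dict[str, WallParams]
    valves: dict[str, ValveParams]
    tubes: dict[str, TubeParams]
    artvens: dict[str, ArtVenParams]
    t_cycle: float = 0.85        # s
    rho: float = 1050.0          # blood density, kg/m3
    V_ref_bag: float = 800.0     # pericardial reference volume, ml
    p_adapt_bag: float = 1.0     # pericardial pressure at V_ref_bag, mmHg
    k_bag: float = 10.0
    # sarcomere constants (um)
    Ls_ref: float = 2.0
    Ls0_toe: float = 1.8
    Ls0_col: float = 2.2
    c_toe: float = 0.02
    Ls_iso: float = 1.51
    Ls_act_norm: float = 0.4
    # valve leaflet dynamics: opening-target width, flow weighting and
    # time constant
    p_blend: float = 0.75        # mmHg
    r_open: float = 1.5          # mmHg per L/min of forward flow
    tau_valve: float = 5.0       # ms
    # near-collapse wall-contact barrier of the cardiac cavities
    V_collapse: float = 5.0      # ml
    p_collapse: float = 10.0     # mmHg
    version: str = "cardioloop-reference-1"

    def validate(self) -> None:
        """Raise ValueError on any violated physical invariant."""
        for n, w in self.walls.items():
            if w.Sf_act < 0 or w.Sf_pas <= 0 or w.V_wall <= 0 or w.Am_ref <= 0:
                raise ValueError(f"wall {n}: non-positive scale parameter")
            if not 0.0 < w.k1 <= 50.0:
                raise ValueError(f"wall {n}: k1 must lie in (0, 50]")
        for n, v in self.valves.items():
            if v.A_open <= 0 or v.A_leak <= 0 or v.L <= 0:
                raise ValueError(f"valve {n}: non-positive area or length")
            if v.A_leak > v.A_open * (1 + 1e-12):
                raise ValueError(f"valve {n}: A_leak exceeds A_open")
        for n, t in self.tubes.items():
            if t.V_ref <= 0 or t.p_ref <= 0 or t.k_tube <= 0 or t.R_z < 0:
                raise ValueError(f"tube {n}: invalid parameter")
        for n, a in self.artvens.items():
            if a.p0_artven <= 0 or a.q_ref <= 0 or a.k_av <= 0:
                raise ValueError(f"artven {n}: invalid parameter")
        if not 0.1 <= self.t_cycle <= 5.0:
            raise ValueError("t_cycle outside [0.1, 5] s")
        if self.rho <= 0:
            raise ValueError("rho must be positive")

    # ---- packing ------------------------------------------------------
    def to_array(self) -> np.ndarray:
        """Pack into the flat SI parameter vector for the kernels."""
        p = np.zeros(L.N_PARAMS)
        for i, name in enumerate(WALLS):
            w = self.walls[name]
            b = L.PW0 + L.NWP * i
            p[b + L.W_SF_ACT] = w.Sf_act * U.KPA
            p[b + L.W_K1] = w.k1
            p[b + L.W_SF_PAS] = w.Sf_pas * U.KPA
            p[b + L.W_DELAY] = w.dt_act * U.MS
            p[b + L.W_T_TW] = w.t_twitch * self.t_cycle
            p[b + L.W_V_WALL] = w.V_wall * U.ML
            p[b + L.W_AM_REF] = w.Am_ref * U.CM2
        for i, name in enumerate(VALVES):
            v = self.valves[name]
            b = L.PV0 + L.NVP * i
            p[b + L.V_A_OPEN] = v.A_open * U.CM2
            p[b + L.V_A_LEAK] = v.A_leak * U.CM2
            p[b + L.V_LEN] = v.L * U.CM
        for i, name in enumerate(TUBES):
            t = self.tubes[name]
            b = L.PT0 + L.NTP * i
            p[b + L.T_V_REF] = t.V_ref * U.ML
            p[b + L.T_P_REF] = t.p_ref * U.MMHG
            p[b + L.T_K] = t.k_tube
            p[b + L.T_RZ] = t.R_z * U.MMHG / U.LMIN
        for i, name in enumerate(ARTVENS):
            a = self.artvens[name]
            b = L.PA0 + L.NAP * i
            p[b + L.A_P0] = a.p0_artven * U.MMHG
            p[b + L.A_QREF] = a.q_ref * U.LMIN
            p[b + L.A_KAV] = a.k_av
        g = L.PG0
        p[g + L.G_T_CYCLE] = self.t_cycle
        p[g + L.G_RHO] = self.rho
        p[g + L.G_BAG_VREF] = self.V_ref_bag * U.ML
        p[g + L.G_BAG_PADAPT] = self.p_adapt_bag * U.MMHG
        p[g + L.G_BAG_K] = self.k_bag
        p[g + L.G_LS_REF] = self.Ls_ref * U.UM
        p[g + L.G_LS0_TOE] = self.Ls0_toe * U.UM
        p[g + L.G_LS0_COL] = self.Ls0_col * U.UM
        p[g + L.G_C_TOE] = self.c_toe
        p[g + L.G_LS_ISO] = self.Ls_iso * U.UM
        p[g + L.G_ACT_NORM] = self.Ls_act_norm * U.UM
        p[g + L.G_WP] = self.p_blend * U.MMHG
        p[g + L.G_TAUV] = self.tau_valve * U.MS
        p[g + L.G_ROPEN] = self.r_open * U.MMHG / U.LMIN
        p[g + L.G_V_COLL] = self.V_collapse * U.ML
        p[g + L.G_P_COLL] = self.p_collapse * U.MMHG
        return p

    # ---- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        d = dict(d)
        d["walls"] = {k: WallParams(**v) for k, v in d["walls"].items()}
        d["valves"] = {k: ValveParams(**v) for k, v in d["valves"].items()}
        d["tubes"] = {k: TubeParams(**v) for k, v in d["tubes"].items()}
        d["artvens"] = {k: ArtVenParams(**v) for k, v in d["artvens"].items()}
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ModelParameters":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def copy(self) -> "ModelParameters":
        return self.from_dict(json.loads(json.dumps(self.to_dict())))


def default_parameters() -> ModelParameters:
    """Hand-built healthy-adult parameterization (pre-calibration values).

    The shipped reference fixture is derived from this set by running the
    pressure-flow control to its homeostatic steady state (91 mmHg mean
    arterial pressure, 5 L/min venous return) and freezing the state; see
    :mod:`cardioloop.reference`.
    """
    walls = {
        "LA":   WallParams(Sf_act=13.0, k1=10.0, Sf_pas=800.0, dt_act=0.0,
                           t_twitch=0.20, V_wall=14.0, Am_ref=78.0),
        "RA":   WallParams(Sf_act=13.0, k1=10.0, Sf_pas=800.0, dt_act=0.0,
                           t_twitch=0.20, V_wall=10.0, Am_ref=76.0),
        "LVfw": WallParams(Sf_act=90.0, k1=10.0, Sf_pas=800.0, dt_act=0.0,
                           t_twitch=0.40, V_wall=87.0, Am_ref=105.0),
        "IVS":  WallParams(Sf_act=90.0, k1=10.0, Sf_pas=800.0, dt_act=0.0,
                           t_twitch=0.40, V_wall=38.0, Am_ref=55.0),
        "RVfw": WallParams(Sf_act=90.0, k1=10.0, Sf_pas=800.0, dt_act=0.0,
                           t_twitch=0.40, V_wall=40.0, Am_ref=130.0),
    }
    # ventricular walls activate one AV delay after the atria
    av_delay_ms = 0.15 * 850.0
    for n in ("LVfw", "IVS", "RVfw"):
        walls[n].dt_act = av_delay_ms
    valves = {
        "VenRa": ValveParams(A_open=8.0, A_leak=8.0, L=1.2),
        "TV":    ValveParams(A_open=7.0, A_leak=7.0e-10, L=1.4),
        "PV":    ValveParams(A_open=5.0, A_leak=5.0e-10, L=1.4),
        "VenLa": ValveParams(A_open=8.0, A_leak=8.0, L=1.2),
        "MV":    ValveParams(A_open=6.0, A_leak=6.0e-10, L=1.4),
        "AV":    ValveParams(A_open=4.5, A_leak=4.5e-10, L=1.6),
    }
    tubes = {
        "SyArt": TubeParams(V_ref=550.0, p_ref=91.0, k_tube=8.0, R_z=0.8),
        "SyVen": TubeParams(V_ref=3100.0, p_ref=6.0, k_tube=6.0, R_z=0.2),
        "PuArt": TubeParams(V_ref=150.0, p_ref=16.0, k_tube=4.0, R_z=0.3),
        "PuVen": TubeParams(V_ref=350.0, p_ref=8.0, k_tube=4.0, R_z=0.2),
    }
    artvens = {
        "Sy": ArtVenParams(p0_artven=85.0, q_ref=5.0, k_av=1.0),
        "Pu": ArtVenParams(p0_artven=8.0, q_ref=5.0, k_av=1.0),
    }
    return ModelParameters(walls=walls, valves=valves, tubes=tubes,
                           artvens=artvens)


def load_reference() -> tuple[ModelParameters, dict]:
    """Load the shipped reference fixture: (parameters, initial-state dict).

    The state dict has keys ``y`` (SI state vector), ``triseg`` ([V_S, Y_S]
    SI warm start), ``p0_artven_sys`` (mmHg, PFC-calibrated) and
    ``checksum``/``version`` metadata.
    """
    text = resources.files("cardioloop.data").joinpath(
        "reference.json").read_text()
    d = json.loads(text)
    params = ModelParameters.from_dict(d["parameters"])
    return params, d["state"]
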