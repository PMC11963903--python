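"""Public surface of the closed-loop model (constitutive laws and RHS).

The circulation is the classic four-chamber closed loop: left and right
atria as single-wall spherical chambers, the two ventricles coupled through
the three-wall TriSeg ventricular unit, six Bernoulli valve connections
(four cardiac valves plus the two always-open venous-atrial inlets), a
systemic and a pulmonary Tube0D vessel pair joined by microcirculatory
ArtVen resistances, and a pericardial bag around the heart.

All functions here take and return clinical units (kPa, cm2, ml, mmHg,
L/min, um, s); SI conversion happens at this boundary.  The heavy lifting
is done by the compiled kernels in :mod:`cardioloop._kernels`.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from . import _layout as L
from . import units as U
from .parameters import ModelParameters


@dataclass
class WallGeometry:
    """Midwall geometry and tension state of a single wall."""
    Am: float   # midwall area, cm2
    Cm: float   # midwall curvature, 1/cm
    Tm: float   # midwall tension, N/m
    Tx: float   # axial junction component, N/m
    Ty: float   # radial junction component, N/m


@dataclass
class SystemState:
    """ODE state plus the TriSeg warm start.

    ``y`` is the SI state vector: 8 compartment volumes (LA, RA, LV, RV,
    SyArt, SyVen, PuArt, PuVen; m3), 6 valve flows (m3/s) and 6 valve
    leaflet opening fractions (dimensionless).  ``triseg`` is the
    [V_S, Y_S] warm start (m3, m).  The per-patch contractile state
    (sarcomere length, activation) is algebraic: it follows wall area and
    cycle time and is therefore not integrated.
    """
    y: np.ndarray
    triseg: np.ndarray
    t: float = 0.0

    def copy(self) -> "SystemState":
        return SystemState(self.y.copy(), self.triseg.copy(), self.t)

    @property
    def volumes_ml(self) -> dict[str, float]:
        return {n: self.y[i] / U.ML for i, n in enumerate(L.COMP_NAMES)}

    @property
    def total_blood_volume_ml(self) -> float:
        return float(np.sum(self.y[: L.N_COMP])) / U.ML


def patch_stress(L_s: float, C: float, wall, params: ModelParameters,
                 t_in_cycle: float | None = None,
                 t_cycle: float | None = None) -> tuple[float, float]:
    """Fibre stress (kPa) and stiffness dsigma/deps (kPa) of one patch.

    Parameters
    ----------
    L_s : sarcomere length, um (must be positive).
    C : activation level in [0, 1]; if ``t_in_cycle`` is given, C is
        instead evaluated from the wall's twitch at that cycle time.
    wall : wall name ("LA", "RA", "LVfw", "IVS", "RVfw") or WallParams.
    """
    if L_s <= 0:
        raise ValueError("sarcomere length must be positive")
    w = params.walls[wall] if isinstance(wall, str) else wall
    if t_in_cycle is not None:
        tc = params.t_cycle if t_cycle is None else t_cycle
        if not 0.0 <= t_in_cycle < tc:
            raise ValueError("t_in_cycle outside [0, t_cycle)")
        C = K.twitch(t_in_cycle, tc, w.dt_act * U.MS, w.t_twitch * tc)
    ls = L_s * U.UM
    sp = K.passive_stress(ls, w.Sf_pas * U.KPA, w.k1,
                          params.Ls0_toe * U.UM, params.Ls0_col * U.UM,
                          params.c_toe)
    sa = K.active_stress(ls, C, w.Sf_act * U.KPA, params.Ls_iso * U.UM,
                         params.Ls_act_norm * U.UM)
    # analytic stiffness wrt natural strain (d ls / d eps = ls), using the
    # same smoothed hinges as the kernels (derivative 0/ramp/1)
    def dhinge(u, eps):
        if u <= -eps:
            return 0.0
        if u >= eps:
            return 1.0
        return (u + eps) / (2.0 * eps)

    e = K.HINGE_EPS
    dsp = 0.0
    r = ls / (params.Ls0_toe * U.UM)
    dsp += w.Sf_pas * U.KPA * params.c_toe * 2.0 * r * r
    rc = ls / (params.Ls0_col * U.UM)
    dsp += w.Sf_pas * U.KPA * dhinge(rc ** w.k1 - 1.0, e) * w.k1 * rc ** w.k1
    dsa = (w.Sf_act * U.KPA * C * dhinge(ls - params.Ls_iso * U.UM, 1e-9)
           * ls / (params.Ls_act_norm * U.UM))
    return (sp + sa) / U.KPA, (dsp + dsa) / U.KPA


def spherical_cap_geometry(Vm: float, Ym: float) -> tuple[float, float]:
    """Midwall area Am (cm2) and curvature Cm (1/cm) of a spherical cap.

    ``Vm`` is the signed cap volume (ml), ``Ym`` the junction (rim) radius
    (cm).  The cap height x solves Vm = (pi/6) x (x^2 + 3 Ym^2), which has a
    unique real root for any Vm.
    """
    if Ym <= 0:
        raise ValueError("junction radius must be positive")
    am, cm, _ = K.cap_geometry(Vm * U.ML, Ym * U.CM)
    return am / U.CM2, cm * U.CM


def wall_tension(Am: float, Cm: float, sigma_f: float, V_wall: float,
                 Ym: float | None = None) -> WallGeometry:
    """Tension state of a wall patch.

    Am in cm2, Cm in 1/cm, sigma_f in kPa, V_wall in ml.  Tm uses the
    thickness/curvature corrected midwall form; with the junction radius
    ``Ym`` (cm) the axial/radial components Tx, Ty at the rim are filled in
    (otherwise they are NaN).  Transmural pressure is 2*Tm*Cm.
    """
    if Am <= 0:
        raise ValueError("midwall area must be positive")
    if V_wall <= 0:
        raise ValueError("wall volume must be positive")
    tm = K.wall_tension(Am * U.CM2, Cm / U.CM, sigma_f * U.KPA, V_wall * U.ML)
    tx = ty = float("nan")
    if Ym is not None:
        ym = Ym * U.CM
        # recover signed cap height from area and curvature
        s = Am * U.CM2 / np.pi
        x2 = s - ym * ym
        x = np.sign(Cm) * np.sqrt(max(x2, 0.0))
        tx = tm * 2.0 * x * ym / s
        ty = tm * (ym * ym - x * x) / s
    return WallGeometry(Am=Am, Cm=Cm, Tm=tm, Tx=tx, Ty=ty)


def transmural_pressure(geom: WallGeometry) -> float:
    """Laplace transmural pressure (mmHg) of a wall state."""
    return 2.0 * geom.Tm * (geom.Cm / U.CM) / U.MMHG


def triseg_solve(V_LV: float, V_RV: float, params: ModelParameters,
                 t_in_cycle: float = 0.0, e_triseg: float = 1e-6,
                 warm_start: tuple[float, float] | None = None,
                 ) -> dict:
    """Solve the TriSeg tension balance at given cavity volumes (ml).

    Returns a dict with V_S (ml), Y_S (cm), p_LV and p_RV transmural
    pressures (mmHg, pericardial pressure not included), the junction force
    residual norm (N/m) and the converged flag.
    """
    if V_LV <= 0 or V_RV <= 0:
        raise ValueError("cavity volumes must be positive")
    if e_triseg <= 0:
        raise ValueError("e_triseg must be positive")
    p = params.to_array()
    tc = params.t_cycle
    c = [K.twitch(t_in_cycle, tc, params.walls[n].dt_act * U.MS,
                  params.walls[n].t_twitch * tc)
         for n in ("LVfw", "IVS", "RVfw")]
    if warm_start is None:
        # flat-septum, ring-radius guess from the LV midwall sphere
        vml = V_LV * U.ML + 0.5 * (params.walls["LVfw"].V_wall
                                   + params.walls["IVS"].V_wall) * U.ML
        ys0 = 0.75 * (3.0 * vml / (4.0 * np.pi)) ** (1.0 / 3.0)
        vs0 = 0.3 * V_LV * U.ML
    else:
        vs0, ys0 = warm_start[0] * U.ML, warm_start[1] * U.CM
    out = np.empty(11)
    vs, ys, ok = K.triseg_solve(V_LV * U.ML, V_RV * U.ML, c[0], c[1], c[2],
                                p, vs0, ys0, e_triseg, 200, out)
    res = float(np.hypot(out[0], out[1]))
    return {
        "V_S": vs / U.ML,
        "Y_S": ys / U.CM,
        "p_LV": -2.0 * out[2] * out[8] / U.MMHG,
        "p_RV": 2.0 * out[4] * out[10] / U.MMHG,
        "residual": res,
        "converged": bool(ok),
        "Tm": {"LVfw": out[2], "IVS": out[3], "RVfw": out[4]},
        "Am": {"LVfw": out[5] / U.CM2, "IVS": out[6] / U.CM2,
               "RVfw": out[7] / U.CM2},
    }


def bag_pressure(V_enclosed: float, params: ModelParameters) -> float:
    """Pericardial pressure (mmHg) at enclosed heart volume (ml)."""
    if V_enclosed <= 0:
        raise ValueError("enclosed volume must be positive")
    return K.bag_pressure(V_enclosed * U.ML, params.to_array()) / U.MMHG


def valve_dqdt(p_up: float, p_down: float, q: float, valve,
               params: ModelParameters, zeta: float | None = None) -> float:
    """Valve flow acceleration dq/dt in (L/min)/s.

    Pressures in mmHg, q in L/min; ``valve`` is a valve name or
    ValveParams.  The effective orifice area interpolates between A_leak
    and A_open with the leaflet opening fraction ``zeta``; when omitted,
    zeta takes its steady-state pressure-driven target (open for a forward
    gradient, leak for a backward one).
    """
    v = params.valves[valve] if isinstance(valve, str) else valve
    dp = (p_up - p_down) * U.MMHG
    if zeta is None:
        zeta = K.valve_opening_target(dp, q * U.LMIN,
                                      params.r_open * U.MMHG / U.LMIN,
                                      params.p_blend * U.MMHG)
    dq = K.valve_dqdt(dp, q * U.LMIN, zeta,
                      v.A_open * U.CM2, v.A_leak * U.CM2, v.L * U.CM,
                      params.rho)
    return dq / U.LMIN


def tube0d_pressure(V_tube: float, tube, params: ModelParameters) -> float:
    """Tube0D pressure (mmHg) at volume (ml)."""
    t = params.tubes[tube] if isinstance(tube, str) else tube
    if V_tube <= 0:
        raise ValueError("tube volume must be positive (instability)")
    return K.tube_pressure(V_tube * U.ML, t.V_ref * U.ML, t.p_ref * U.MMHG,
                           t.k_tube) / U.MMHG


def artven_flow(p_art: float, p_ven: float, artven,
                params: ModelParameters,
                p0_override: float | None = None) -> float:
    """Microcirculatory flow (L/min) from the arterial-venous drop (mmHg)."""
    a = params.artvens[artven] if isinstance(artven, str) else artven
    p0 = a.p0_artven if p0_override is None else p0_override
    return K.artven_flow(p_art * U.MMHG, p_ven * U.MMHG, p0 * U.MMHG,
                         a.q_ref * U.LMIN, a.k_av) / U.LMIN


def system_derivatives(state: SystemState, params: ModelParameters,
                       s_p: float = 1.0,
                       p0_artven_sys: float | None = None,
                       e_triseg: float = 1e-6) -> tuple[np.ndarray, dict]:
    """Assembled dState/dt (SI) plus the algebraic signals.

    ``s_p`` is the PFC sensing value applied to the systemic
    microcirculation this beat (1 = control off / homeostatic), and
    ``p0_artven_sys`` the PFC-adjusted systemic reference drop in mmHg
    (defaults to the parameter value).  Raises RuntimeError if the TriSeg
    inner solve does not converge.
    """
    p = params.to_array()
    if p0_artven_sys is None:
        p0_artven_sys = params.artvens["Sy"].p0_artven
    cache = np.array([state.triseg[0], state.triseg[1], e_triseg])
    dy = np.empty(L.N_STATE)
    aux = np.empty(L.N_AUX)
    ok = K.system_rhs(state.t, state.y, p, s_p, p0_artven_sys * U.MMHG,
                      cache, dy, aux)
    if not ok:
        raise RuntimeError("TriSeg tension balance did not converge")
    state.triseg[0], state.triseg[1] = cache[0], cache[1]
    signals = {
        "pressures_mmHg": {n: aux[L.AUX_P0 + i] / U.MMHG
                           for i, n in enumerate(L.COMP_NAMES)},
        "p_peri_mmHg": aux[L.AUX_PPERI] / U.MMHG,
        "V_S_ml": aux[L.AUX_VS] / U.ML,
        "Y_S_cm": aux[L.AUX_YS] / U.CM,
        "triseg_residual": aux[L.AUX_TSRES],
        "q_artven_sys_Lmin": aux[L.AUX_QAV_SYS] / U.LMIN,
        "q_artven_pulm_Lmin": aux[L.AUX_QAV_PULM] / U.LMIN,
        "P_diss_W": aux[L.AUX_PDISS],
    }
    return dy, signals


def initial_state_guess(params: ModelParameters) -> SystemState:
    """Plausible resting initial condition used to seed calibration runs."""
    y = np.zeros(L.N_STATE)
    y[L.C_LA] = 55.0 * U.ML
    y[L.C_RA] = 55.0 * U.ML
    y[L.C_LV] = 115.0 * U.ML
    y[L.C_RV] = 115.0 * U.ML
    y[L.C_SYART] = params.tubes["SyArt"].V_ref * U.ML
    y[L.C_SYVEN] = params.tubes["SyVen"].V_ref * U.ML
    y[L.C_PUART] = params.tubes["PuArt"].V_ref * U.ML
    y[L.C_PUVEN] = params.tubes["PuVen"].V_ref * U.ML
    # venous inlets start open; pressure-gated valves start shut
    y[L.IZ0 + L.VENRA] = 1.0
    y[L.IZ0 + L.VENLA] = 1.0
    vml = y[L.C_LV] + 0.5 * (params.walls["LVfw"].V_wall
                             + params.walls["IVS"].V_wall) * U.ML
    ys0 = 0.7 * (3.0 * vml / (4.0 * np.pi)) ** (1.0 / 3.0)
    return SystemState(y=y, triseg=np.array([0.35 * y[L.C_LV], ys0]), t=0.0)
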