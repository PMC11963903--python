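"""Homeostatic pressure-flow control (PFC).

A per-beat negative feedback that regulates mean systemic arterial
pressure and venous return towards the targets p0 and q0: the sensing
variables

    s_p = (p_mean / p0) ** f        s_q = (q_mean / q0) ** f

both equal 1 at the homeostatic steady state.  s_p modulates effective
blood volume by splitting the systemic microcirculatory flow into unequal
proximal/distal parts (q_prox = q * s_p, q_dist = q / s_p); after every
completed beat the peripheral resistance reference drop is updated
multiplicatively, p0_artven <- p0_artven * s_q / s_p.
"""
from __future__ import annotations

from dataclasses import dataclass


@dataclass
class PfcParameters:
    """Targets and gain of the control loop."""
    p0_pfc: float = 91.0   # target mean systemic arterial pressure, mmHg
    q0_pfc: float = 5.0    # target venous return, L/min
    f: float = 1.0         # sensing exponent (loop gain)

    def __post_init__(self):
        if self.p0_pfc <= 0 or self.q0_pfc <= 0:
            raise ValueError("PFC targets must be positive")
        if self.f <= 0:
            raise ValueError("sensing exponent f must be positive")


@dataclass
class PfcState:
    """Control state carried across beats."""
    s_p: float = 1.0
    s_q: float = 1.0
    p0_artven_sys: float = 85.0   # current systemic reference drop, mmHg
    p_mean: float = float("nan")  # last completed beat means
    q_mean: float = float("nan")

    def copy(self) -> "PfcState":
        return PfcState(self.s_p, self.s_q, self.p0_artven_sys,
                        self.p_mean, self.q_mean)


def sense(p_mean: float, q_mean: float, params: PfcParameters
          ) -> tuple[float, float]:
    """Sensing variables (s_p, s_q) from beat-mean pressure and flow."""
    if p_mean <= 0 or q_mean <= 0:
        raise ValueError("beat means must be positive to sense")
    s_p = (p_mean / params.p0_pfc) ** params.f
    s_q = (q_mean / params.q0_pfc) ** params.f
    return s_p, s_q


def volume_control(q_artven: float, s_p: float) -> tuple[float, float]:
    """Split the microcirculatory flow into proximal and distal parts.

    With s_p != 1 the two differ, draining (s_p > 1) or loading (s_p < 1)
    the stressed blood volume at a net rate q_artven * (s_p - 1/s_p).
    """
    if s_p <= 0:
        raise ValueError("s_p must be positive")
    return q_artven * s_p, q_artven / s_p


def update_resistance(p0_artven: float, s_p: float, s_q: float) -> float:
    """Per-beat multiplicative peripheral-resistance update."""
    if p0_artven <= 0 or s_p <= 0 or s_q <= 0:
        raise ValueError("inputs must be positive")
    return p0_artven * s_q / s_p


def beat_update(state: PfcState, p_mean: float, q_mean: float,
                params: PfcParameters) -> PfcState:
    """Full end-of-beat PFC update: sense, then adapt the resistance.

    The returned state's s_p applies to the *next* beat (piecewise-constant
    volume control within each beat).
    """
    s_p, s_q = sense(p_mean, q_mean, params)
    new = state.copy()
    new.s_p, new.s_q = s_p, s_q
    new.p_mean, new.q_mean = p_mean, q_mean
    new.p0_artven_sys = update_resistance(state.p0_artven_sys, s_p, s_q)
    return new
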