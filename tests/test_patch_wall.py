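"""Sarcomere stress law and one-fibre wall tension."""
import numpy as np
import pytest

from cardioloop import units as U
from cardioloop.model import (patch_stress, wall_tension,
                              transmural_pressure)
from cardioloop.parameters import default_parameters


@pytest.fixture(scope="module")
def params():
    return default_parameters()


def test_no_active_stress_before_activation_onset(params):
    """Before the activation delay the twitch is zero: purely passive."""
    w = params.walls["LVfw"]
    # ventricular delay is 127.5 ms; probe at 10 ms into the cycle
    s_total, _ = patch_stress(2.0, 0.0, "LVfw", params, t_in_cycle=0.010)
    s_passive, _ = patch_stress(2.0, 0.0, "LVfw", params)
    assert s_total == pytest.approx(s_passive, rel=1e-12)


def test_passive_stress_scales_linearly_with_stiffness_constant(params):
    """Sf_pas is a pure scale factor of the passive stress."""
    p2 = params.copy()
    for ls in (1.9, 2.0, 2.15, 2.3):
        base, _ = patch_stress(ls, 0.0, "LVfw", params)
        p2.walls["LVfw"].Sf_pas = 2.0 * params.walls["LVfw"].Sf_pas
        doubled, _ = patch_stress(ls, 0.0, "LVfw", p2)
        assert doubled == pytest.approx(2.0 * base, rel=1e-12)


def test_passive_stress_monotone_in_length(params):
    ls_grid = np.linspace(1.2, 2.5, 300)
    s = [patch_stress(ls, 0.0, "LVfw", params)[0] for ls in ls_grid]
    assert np.all(np.diff(s) > 0)


def test_passive_stiffness_increases_with_collagen_exponent(params):
    """At a collagen-engaged stretch, dsigma/deps grows with k1 over the
    sampled 5..15 range (finite-difference sweep)."""
    ls = 2.35  # above the collagen slack length
    slopes = []
    for k1 in np.linspace(5.0, 15.0, 11):
        p = params.copy()
        p.walls["LVfw"].k1 = k1
        eps = 1e-6
        s_hi, _ = patch_stress(ls * (1 + eps), 0.0, "LVfw", p)
        s_lo, _ = patch_stress(ls * (1 - eps), 0.0, "LVfw", p)
        slopes.append((s_hi - s_lo) / (2 * eps))
    assert np.all(np.diff(slopes) > 0)


def test_analytic_stiffness_matches_finite_difference(params):
    for ls in (1.9, 2.05, 2.25):
        _, dsig = patch_stress(ls, 0.5, "LVfw", params, t_in_cycle=0.3)
        eps = 1e-7
        hi, _ = patch_stress(ls * (1 + eps), 0.5, "LVfw", params,
                             t_in_cycle=0.3)
        lo, _ = patch_stress(ls * (1 - eps), 0.5, "LVfw", params,
                             t_in_cycle=0.3)
        assert dsig == pytest.approx((hi - lo) / (2 * eps), rel=1e-4)


def test_rejects_nonpositive_sarcomere_length(params):
    with pytest.raises(ValueError):
        patch_stress(0.0, 0.0, "LVfw", params)


def test_stress_free_wall_has_no_tension_or_pressure():
    g = wall_tension(Am=80.0, Cm=0.3, sigma_f=0.0, V_wall=90.0)
    assert g.Tm == 0.0
    assert transmural_pressure(g) == 0.0


def test_flat_wall_has_no_transmural_pressure():
    g = wall_tension(Am=80.0, Cm=0.0, sigma_f=40.0, V_wall=90.0)
    assert g.Tm > 0.0
    assert transmural_pressure(g) == 0.0


def test_wall_tension_rejects_degenerate_geometry():
    with pytest.raises(ValueError):
        wall_tension(Am=0.0, Cm=0.1, sigma_f=10.0, V_wall=90.0)
    with pytest.raises(ValueError):
        wall_tension(Am=80.0, Cm=0.1, sigma_f=10.0, V_wall=0.0)


def test_quasistatic_inflation_work_identity(params):
    """Energy conservation of the one-fibre wall: for a closed spherical
    wall inflated quasi-statically around a loop with varying activation,
    the p dV work equals the Tm dAm membrane work to within 0.1%."""
    w = params.walls["LVfw"]
    vw = w.V_wall

    def wall_state(v_cav, c_act):
        vm = (v_cav + 0.5 * vw) * U.ML
        r = (3.0 * vm / (4.0 * np.pi)) ** (1.0 / 3.0)
        am = 4.0 * np.pi * r * r / U.CM2      # cm2
        cm = U.CM / r                         # 1/cm
        ls = params.Ls_ref * np.sqrt(am * U.CM2 / (w.Am_ref * U.CM2))
        sigma, _ = patch_stress(ls, c_act, "LVfw", params)
        g = wall_tension(am, cm, sigma, vw)
        p = transmural_pressure(g) * U.MMHG   # Pa
        return p, g.Tm, am * U.CM2            # Pa, N/m, m2

    # inflate relaxed, deflate half-activated: a closed loop with net work
    n = 4000
    up = np.linspace(60.0, 140.0, n)
    down = np.linspace(140.0, 60.0, n)
    volumes = np.concatenate([up, down])
    acts = np.concatenate([np.zeros(n), 0.5 * np.ones(n)])
    p = np.empty(2 * n)
    tm = np.empty(2 * n)
    am = np.empty(2 * n)
    for i, (v, c) in enumerate(zip(volumes, acts)):
        p[i], tm[i], am[i] = wall_state(v, c)
    v_si = volumes * U.ML
    w_pdv = np.sum(0.5 * (p[1:] + p[:-1]) * np.diff(v_si))
    w_tda = np.sum(0.5 * (tm[1:] + tm[:-1]) * np.diff(am))
    assert w_pdv != 0.0
    assert w_tda == pytest.approx(w_pdv, rel=1e-3)
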