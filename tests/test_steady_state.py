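"""Steady-state criteria, threshold bookkeeping and the exclusion rule."""
import numpy as np
import pytest

from cardioloop.integrators import SolverSettings
from cardioloop.steady_state import (BeatSummary, criterion_no_pfc,
                                     criterion_pfc, is_excluded,
                                     run_to_steady, summarize_beat)


def _summary(q, beat=1, p_la=8.0, vr=None):
    q = np.asarray(q, dtype=float)
    return BeatSummary(beat=beat, q_valve=q,
                       q_venous_return=q[0] if vr is None else vr,
                       p_la_mean=p_la, p_art_mean=91.0,
                       v_lv_ed=130.0, v_lv_es=60.0)


def test_criterion_zero_for_identical_beats():
    a = _summary([5.0] * 6, beat=2)
    b = _summary([5.0] * 6, beat=1)
    assert criterion_no_pfc(a, b) == 0.0


def test_criterion_hand_evaluated_example():
    """Six valve means of 5 L/min, previous beat identical except one
    valve at 4.9: (6/30)*sqrt(0.01/6) = 0.008165."""
    cur = _summary([5.0] * 6, beat=2)
    prev = _summary([5.0] * 5 + [4.9], beat=1)
    assert criterion_no_pfc(cur, prev) == pytest.approx(0.0081649658, abs=1e-9)


@pytest.mark.parametrize("c", [0.1, 2.0, 7.3])
def test_criterion_invariant_under_flow_rescaling(c):
    rng = np.random.default_rng(3)
    qa = rng.uniform(3, 6, 6)
    qb = qa + rng.uniform(-0.2, 0.2, 6)
    base = criterion_no_pfc(_summary(qb, 2), _summary(qa, 1))
    scaled = criterion_no_pfc(_summary(c * qb, 2), _summary(c * qa, 1))
    assert scaled == pytest.approx(base, rel=1e-12)


def test_criterion_undefined_for_nonpositive_total_flow():
    cur = _summary([0.0] * 6, beat=2)
    prev = _summary([0.0] * 6, beat=1)
    assert np.isnan(criterion_no_pfc(cur, prev))


def test_controlled_criterion_zero_at_homeostasis():
    cur = _summary([5.0] * 6, beat=2, vr=5.0)
    prev = _summary([5.0] * 6, beat=1, vr=5.0)
    assert criterion_pfc(cur, prev, q0_pfc=5.0) == 0.0


def test_controlled_criterion_reduces_to_target_error_when_stationary():
    """Stationary waveforms with venous return 5% off target: 0.05."""
    q = [5.25] * 6
    cur = _summary(q, beat=2, vr=5.25)
    prev = _summary(q, beat=1, vr=5.25)
    assert criterion_pfc(cur, prev, q0_pfc=5.0) == pytest.approx(0.05)


def test_controlled_criterion_bounds_target_error():
    rng = np.random.default_rng(8)
    for _ in range(20):
        qa = rng.uniform(3, 6, 6)
        qb = qa + rng.uniform(-0.3, 0.3, 6)
        vr = qb[0]
        c = criterion_pfc(_summary(qb, 2, vr=vr), _summary(qa, 1), 5.0)
        assert c >= abs(vr / 5.0 - 1.0) - 1e-12


@pytest.mark.parametrize("p_la,expect", [
    (49.0, False), (49.999, False), (50.0, False), (50.001, True),
    (55.0, True), (80.0, True)])
def test_exclusion_rule_straddles_fifty_mmhg(p_la, expect):
    assert is_excluded(_summary([5.0] * 6, p_la=p_la)) is expect


def test_geometric_convergence_reaches_thresholds_at_predicted_beats():
    """A synthetic beat sequence whose valve means converge geometrically
    (rate rho) crosses each threshold at the analytically predicted beat:
    criterion_b = C * rho^(b-1)."""
    rho = 0.5
    q_inf = np.full(6, 5.0)
    amp = np.array([0.6, -0.4, 0.5, -0.3, 0.2, 0.35])
    summaries = [_summary(q_inf + amp * rho ** (b - 1), beat=b)
                 for b in range(1, 40)]
    crits = [criterion_no_pfc(summaries[i], summaries[i - 1])
             for i in range(1, len(summaries))]
    # geometric decay of the criterion itself
    ratios = np.array(crits[1:]) / np.array(crits[:-1])
    assert np.allclose(ratios, rho, rtol=0.05)
    # first crossing of each rung matches ceil(log(th/C)/log(rho)) + 2
    c0 = crits[0]
    for th in (1e-2, 1e-3, 1e-4):
        predicted = int(np.ceil(np.log(th / c0) / np.log(rho))) + 2
        observed = next(i + 2 for i, c in enumerate(crits) if c < th)
        assert observed == predicted


def test_run_from_converged_state_stops_immediately(ref_params, ref_state):
    """Starting at a previously computed steady state, the criterion is
    already below 1e-3 at its first evaluation."""
    res = run_to_steady(ref_params, ref_state, SolverSettings(),
                        e_steady=1e-3, max_beats=10)
    assert res.converged
    assert res.beats == 2
    assert res.criteria[0] < 1e-3


def test_single_beat_budget_cannot_converge(ref_params, ref_state):
    """The criterion needs beats b and b-1: with max_beats=1 no criterion
    is evaluated and the run reports non-convergence."""
    res = run_to_steady(ref_params, ref_state, SolverSettings(),
                        e_steady=1e-3, max_beats=1)
    assert not res.converged
    assert res.criteria == []
    assert res.beats == 1


def test_threshold_ladder_is_monotone(ref_params, ref_state):
    """Tighter thresholds can never be reached earlier than looser ones."""
    p = ref_params.copy()
    p.walls["LVfw"].Sf_act *= 0.8   # perturb so a real transient develops
    res = run_to_steady(p, ref_state, SolverSettings(),
                        e_steady=1e-4, max_beats=60)
    bt = res.beats_to_threshold
    rungs = sorted(bt, reverse=True)
    assert len(rungs) >= 2
    for loose, tight in zip(rungs, rungs[1:]):
        assert bt[tight] >= bt[loose]


def test_run_to_steady_rejects_empty_budget(ref_params, ref_state):
    with pytest.raises(ValueError):
        run_to_steady(ref_params, ref_state, SolverSettings(), max_beats=0)
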