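"""Parameter sampler and protocol drivers."""
import numpy as np
import pandas as pd
import pytest

from cardioloop.parameters import load_reference
from cardioloop.protocols import (BOUNDS, PARAMETER_NAMES, apply_sample,
                                  run_multi_beat_protocol,
                                  run_multistart_protocol,
                                  run_single_beat_protocol,
                                  sample_parameters)


def test_sample_set_has_twenty_five_varied_parameters():
    ss = sample_parameters(3, 0, pfc_enabled=True)
    assert ss.n_parameters == 25
    assert list(ss.values.columns) == PARAMETER_NAMES


def test_control_target_columns_only_present_with_control():
    ss = sample_parameters(3, 0, pfc_enabled=False)
    assert ss.n_parameters == 23
    assert not any(c.startswith("PFC.") for c in ss.values.columns)


def test_samples_respect_uniform_bounds():
    ss = sample_parameters(400, 7)
    v = ss.values
    for w in ("LVfw", "IVS", "RVfw"):
        assert v[f"patch.Sf_Act:{w}"].between(60, 120).all()
        assert v[f"patch.k1:{w}"].between(5, 15).all()
        assert v[f"patch.Sf_pas:{w}"].between(100, 2500).all()
        assert v[f"patch.dt:{w}"].between(0, 50).all()
        assert v[f"patch.V_wall:{w}"].between(80, 120).all()
        assert v[f"patch.Am_ref:{w}"].between(80, 120).all()
    assert v["t_cycle"].between(0.5, 1.5).all()
    assert v["PFC.p0"].between(73, 110).all()
    assert v["PFC.q0"].between(4, 6).all()


def test_valve_branches_are_two_point():
    ss = sample_parameters(400, 7)
    v = ss.values
    for valve in ("MV", "AV"):
        leak = v[f"valve.A_leak:{valve}"]
        assert set(np.round(leak[leak > 1], 6)) <= {25.0}
        assert ((leak == 1e-10) | (leak == 25.0)).all()
        op = v[f"valve.A_open:{valve}"]
        assert ((op == 100.0) | op.between(75, 100)).all()


def test_valve_branch_frequency_near_one_quarter():
    ss = sample_parameters(4000, 123)
    for flag in ("leak:MV", "leak:AV", "stenosis:MV", "stenosis:AV"):
        frac = ss.branches[flag].mean()
        assert frac == pytest.approx(0.25, abs=0.03)


def test_sampling_is_seed_reproducible_and_sample_independent():
    a = sample_parameters(10, 42)
    b = sample_parameters(10, 42)
    pd.testing.assert_frame_equal(a.values, b.values)
    # child streams: the first rows do not depend on how many are drawn
    c = sample_parameters(3, 42)
    pd.testing.assert_frame_equal(a.values.iloc[:3], c.values)


def test_apply_sample_builds_valid_parameterization():
    ref, _ = load_reference()
    ss = sample_parameters(5, 9)
    for i in range(5):
        p = apply_sample(ref, ss.row(i))
        # cycle commensurate with every supported step size
        assert round(p.t_cycle * 1000) % 10 == 0
        # percent parameters applied multiplicatively to the reference
        w = ss.row(i)[f"patch.V_wall:LVfw"] / 100.0
        assert p.walls["LVfw"].V_wall == pytest.approx(
            ref.walls["LVfw"].V_wall * w)
        # ventricular delay = AV delay + sampled offset
        assert p.walls["IVS"].dt_act == pytest.approx(
            0.15 * p.t_cycle * 1e3 + ss.row(i)["patch.dt:IVS"])


def test_single_beat_report_combinatorics():
    """2 step sizes x 1 method x 3 samples -> 6 rows, cheap truth."""
    rep = run_single_beat_protocol(n_samples=3, seed=2,
                                   dt_grid_ms=(1.0, 2.0),
                                   truth_methods=(("adams_moulton", 2),),
                                   truth_dt_ms=0.1)
    assert len(rep.rows) == 6
    assert rep.aggregates["n_runs"] == 6
    stable = rep.rows[rep.rows.stable]
    assert (stable.mae_lv_volume_ml >= 0).all()


def test_single_beat_self_comparison_is_exact():
    """With the probe settings equal to the truth settings the MAE against
    the assumed-true signal vanishes."""
    rep = run_single_beat_protocol(n_samples=1, seed=3,
                                   methods=(("adams_moulton", 2),),
                                   dt_grid_ms=(1.0,),
                                   e_triseg_grid=(1e-6,),
                                   truth_methods=(("adams_moulton", 2),),
                                   truth_dt_ms=1.0, truth_e_triseg=1e-6)
    row = rep.rows.iloc[0]
    assert row.stable
    assert row.mae_lv_volume_ml == pytest.approx(0.0, abs=1e-12)
    assert row.mae_lv_pressure_mmHg == pytest.approx(0.0, abs=1e-12)


def test_multi_beat_report_reproducible_and_ladder_monotone():
    r1 = run_multi_beat_protocol(n_samples=4, seed=6, max_beats=40)
    r2 = run_multi_beat_protocol(n_samples=4, seed=6, max_beats=40)
    pd.testing.assert_frame_equal(r1.rows, r2.rows)
    df = r1.rows
    both = df.dropna(subset=["beats_to_0.1", "beats_to_0.01"])
    assert (both["beats_to_0.01"] >= both["beats_to_0.1"]).all()


def test_multi_beat_aggregates_recomputable_from_rows():
    rep = run_multi_beat_protocol(n_samples=4, seed=6, max_beats=40)
    med = rep.rows["beats_to_0.01"].dropna().quantile(0.5)
    assert rep.aggregates["beats_to_0.01"]["q50"] == pytest.approx(med)


def test_multistart_scheduling_and_spread():
    """3 samples x 2 starts scheduled; identical physics across starts of
    the controlled steady state keeps the spread small."""
    rep = run_multistart_protocol(n_samples=3, n_starts=2, seed=4, beats=8)
    assert rep.aggregates["n_runs_scheduled"] == 6
    assert len(rep.rows) == 3
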