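# cardioloop

A zero-dimensional closed-loop model of the human heart and circulation,
built for studying the *numerical* behaviour of beat-periodic steady-state
simulation: which time integrator, step size, tension-balance tolerance and
steady-state threshold give clinically accurate haemodynamics at the lowest
cost, and how many heartbeats a simulation must run before its "steady
state" can be trusted.

It is aimed at developers and users of lumped-parameter cardiovascular
models who need to quantify integration error, steady-state convergence
error and the cost of homeostatic regulation, rather than at clinical
prediction.

## The model in brief

Eight compartments (four cardiac cavities, systemic and pulmonary arterial
and venous vessels) are joined by six valve connections and two
microcirculatory resistances.  Myocardial walls follow the one-fibre
model: fibre strain `eps_f = 1/2 ln(Am/Am_ref)` maps midwall area to
sarcomere length, fibre stress (passive toe + collagen branch, plus a
time-gated active twitch) maps to midwall tension
`Tm = (sigma_f Vw / 2 Am)(1 + z^2/3 + z^4/5)` with `z = 3 Cm Vw / 2 Am`,
and the Laplace relation `p = 2 Tm Cm` closes the loop to pressures.  The
two ventricles interact through three spherical-cap walls meeting at a
junction ring; the septal cap volume `V_S` and ring radius `Y_S` solve the
junction force balance `sum Tm sin(phi) = sum Tm cos(phi) = 0` to a
configurable tension threshold.  Valves obey a Bernoulli-plus-inertance
momentum balance with a dynamic leaflet opening state; a pericardial bag
constrains the heart.  A per-beat pressure-flow control senses mean
arterial pressure and venous return (`s_p = (p/p0)^f`, `s_q = (q/q0)^f`),
modulates stressed blood volume (`q_prox = q s_p`, `q_dist = q / s_p`) and
adapts peripheral resistance (`p0 <- p0 s_q / s_p`).

Steady state is detected from beat-mean flows through the six connections:
without control, `(n/sum|q_v|) sqrt(sum (q_v,b - q_v,b-1)^2 / n) <
e_steady`; with control, the venous-return target error joins in
quadrature.  Runs whose beat-mean left atrial pressure exceeds 50 mmHg are
flagged excluded.

The harness integrates the loop with fixed-step Adams-Bashforth,
Adams-Moulton, BDF (orders 1-4), explicit Euler and RK4, and ships four
protocol drivers (single-beat accuracy, multi-beat steady state, controlled
steady state, multi-start uniqueness) over a 25-parameter
(patho)physiological sample space.  `docs/methods.md` has the full model
description and the numerical design choices.

## Worked example

Simulate three beats of the calibrated reference heart and print a few
haemodynamic indices:

```python
from cardioloop import (SolverSettings, load_reference, reference_state,
                        run_beat, summarize_beat, stroke_work)

params, state_dict = load_reference()
state = reference_state(state_dict)
settings = SolverSettings()          # Adams-Moulton 2, dt = 1 ms
for beat in range(3):
    trace, state, status = run_beat(params, state, settings)
    s = summarize_beat(trace, beat + 1)
    print(f"beat {beat + 1}: {status}, "
          f"LV {s.v_lv_es:.1f}-{s.v_lv_ed:.1f} ml, "
          f"MAP {s.p_art_mean:.1f} mmHg, "
          f"VR {s.q_venous_return:.2f} L/min, "
          f"SW {stroke_work(trace):.2f} J")
```

```
beat 1: ok, LV 63.7-136.1 ml, MAP 91.0 mmHg, VR 5.00 L/min, SW 1.30 J
beat 2: ok, LV 63.7-136.1 ml, MAP 91.0 mmHg, VR 5.00 L/min, SW 1.30 J
beat 3: ok, LV 63.7-136.1 ml, MAP 91.0 mmHg, VR 5.00 L/min, SW 1.30 J
```

The reference state is a converged homeostatic steady state, so successive
beats repeat: the left ventricle cycles between 64 and 136 ml (ejection
fraction 0.53), mean arterial pressure sits on the 91 mmHg control target,
venous return on the 5 L/min target, and each beat delivers 1.3 J of left
ventricular stroke work.

The same machinery is scriptable from the shell:

```bash
cardioloop simulate --beats 3 --out-dir results     # per-beat CSV traces
cardioloop sample --n 100 --seed 1 --out samples.csv
cardioloop protocol single-beat --seed 1 --n-samples 10 --out-dir results
cardioloop protocol pfc --seed 1 --n-samples 25 --out-dir results
```

Protocol reports land as JSON (aggregates + per-run rows) with a CSV row
table beside them.

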