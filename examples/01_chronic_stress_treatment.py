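"""Treat a chronically stressed axis with a CRH-neutralizing antibody.

The axis is first equilibrated under a 2-fold chronic stressor (cortisol
settles ~1.85-fold above baseline because the adrenal mass grows), then the
antibody is switched on at day 0 at the x-fold dose (doubled CRH removal
cancels the doubled input).
"""

from hpaxis import (
    HPAState, DrugRegimen, StressProtocol, calibrate_baseline,
    normalizing_dose, simulate, solve_full_steady_state,
)

params = calibrate_baseline()
u = 2.0

stressed = solve_full_steady_state(params, u=u)
print("untreated chronic-stress steady state (fold of healthy baseline):")
print(f"  CRH {stressed.x1:.3f}  ACTH {stressed.x2:.3f}  cortisol {stressed.x3:.3f}"
      f"  P {stressed.P:.3f}  A {stressed.A:.3f}")

dose = normalizing_dose(u, "anti_crh_antibody")
traj = simulate(
    params=params,
    protocol=StressProtocol(chronic=(-1.0, u)),
    regimens=(DrugRegimen("anti_crh_antibody", dose=dose, t_start=0.0),),
    t_span=(0.0, 200.0),
    y0=HPAState(stressed.x1, stressed.x2, stressed.x3, stressed.P, stressed.A),
)

for day in (0.0, 7.0, 30.0, 100.0, 200.0):
    s = traj.state_at(day)
    print(f"  day {day:5.0f}: cortisol {s.x3:.3f}  CRH {s.x1:.3f}  ACTH {s.x2:.3f}"
          f"  P {s.P:.3f}  A {s.A:.3f}")

# Cortisol drops within days and the whole axis — hormones and both gland
# masses — converges back to 1.0 over a few weeks: full normalization.
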