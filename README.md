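# hpaxis

Why do most drugs that target the stress-hormone axis fail to lower
long-term cortisol in chronic stress and mood disorders, while the very same
drugs work in Cushing's syndrome?  `hpaxis` implements a
systems-pharmacology model of the hypothalamic–pituitary–adrenal (HPA) axis
that answers this question quantitatively, and an in-silico screen over all
nine single-mechanism drug classes (plus combinations) built on top of it.
It is written for computational endocrinologists and systems-pharmacology
modelers who want to reason about *long-term* (weeks-to-months) hormone
dynamics rather than the minutes-to-hours timescale of classical HPA
models.

## The model

The axis is a three-hormone cascade with negative feedback and two slow
gland variables, all in fold-of-healthy-baseline units:

```
dx1/dt = I1 b1 GR(C3 x3) MR(C3 x3) u − A1 a1 x1          (CRH)
dx2/dt = I2 b2 C1 x1 GR(C3 x3) P   − A2 a2 x2            (ACTH)
dx3/dt = I3 b3 C2 x2 A             − A3 a3 x3            (cortisol)
dP/dt  = P (bP C1 x1 − aP)                               (corticotroph mass)
dA/dt  = A (bA C2 x2 − aA)                               (adrenal mass)
```

with `GR(x) = 1/(1+(x/K_GR)^n)` and `MR(x) = 1/x` the glucocorticoid and
mineralocorticoid feedback functions.  The gland functional masses `P` and
`A` grow in proportion to their upstream hormone and turn over on the
months timescale — each gland is an integral-feedback controller that pins
its upstream hormone's steady state (`x1,st = aP/(C1 bP)`,
`x2,st = aA/(C2 bA)`).  As a consequence, steady-state cortisol in the
low-cortisol regime is

```
cortisol_st = (C1 I1 b1 bP) / (C3 A1 a1 aP) · u
```

— it depends *only* on CRH-associated parameters and the stressor input
`u`.  Synthesis inhibitors, antibodies and receptor antagonists aimed at
ACTH or cortisol (the multipliers `I2, I3, A2, A3, C2, C3`) are erased by
gland-mass compensation within weeks; only CRH-targeting interventions
(`I1`, `A1`, `C1`), stress reduction (`u`), or enhanced corticotroph
removal (`aP`) can move long-term cortisol.  Feedback-escaping tumors
break this compensation, which is why a different drug set works in each
type of Cushing's syndrome.

The drug multipliers follow one convention: dose `d ≥ 0` maps to
`1/(1+d)` for inhibitors/antagonists and `1+d` for antibodies/agonists, so
dose 0 is always "no drug".  The x-fold rule: cortisol elevated x-fold is
normalized by changing the relevant CRH parameter x-fold (`dose = x − 1`).

Four model variants are provided: adaptive glands (default), frozen glands
(`P = A = 1`, the classical cascade), ACTH-secreting pituitary adenoma
(with adrenal carrying capacity `K_A`), and cortisol-secreting adrenal
adenoma — each with analytic steady states, subclinical/clinical
thresholds, and a stiff-ODE simulator (`scipy` BDF, segmented at input
discontinuities).

## Worked example

```python
from hpaxis import (HPAState, DrugRegimen, StressProtocol, calibrate_baseline,
                    normalizing_dose, simulate, solve_full_steady_state)

params = calibrate_baseline()          # Table rates; all-ones healthy baseline
stressed = solve_full_steady_state(params, u=2.0)
dose = normalizing_dose(2.0, "anti_crh_antibody")   # x-fold rule: dose = 1
traj = simulate(
    params=params,
    protocol=StressProtocol(chronic=(-1.0, 2.0)),
    regimens=(DrugRegimen("anti_crh_antibody", dose=dose, t_start=0.0),),
    t_span=(0.0, 200.0),
    y0=HPAState(stressed.x1, stressed.x2, stressed.x3, stressed.P, stressed.A),
)
```

Running `python examples/01_chronic_stress_treatment.py` prints:

```
untreated chronic-stress steady state (fold of healthy baseline):
  CRH 1.000  ACTH 1.000  cortisol 1.849  P 1.082  A 1.849
  day     0: cortisol 1.849  CRH 1.000  ACTH 1.000  P 1.082  A 1.849
  day     7: cortisol 1.224  CRH 0.806  ACTH 0.726  P 0.912  A 1.684
  day    30: cortisol 0.985  CRH 1.015  ACTH 0.785  P 0.773  A 1.254
  day   100: cortisol 0.991  CRH 1.010  ACTH 1.006  P 0.995  A 0.985
  day   200: cortisol 1.000  CRH 1.000  ACTH 1.000  P 1.000  A 1.000
```

Under a 2-fold chronic stressor the adapted axis holds CRH and ACTH at
baseline (exact adaptation) while cortisol and adrenal mass sit ~1.85-fold
high.  Doubling CRH removal with the antibody cancels the doubled input
exactly: every hormone *and both gland masses* return to 1.0 within weeks —
full-axis normalization.  Try the same with a cortisol-synthesis inhibitor
(`examples/02_drug_screen.py`): cortisol dips for a few weeks, the adrenal
mass regrows, and the level returns to 1.849 at any dose.

Other capabilities, one script each, under `examples/`: the three-condition
drug screen, dose–response and treatment cessation, Cushing disease
progression with threshold detection, and acute-stress-response
preservation.

A thin CLI wraps the same library functions:

```sh
hpaxis screen chronic_stress --out-dir out/
hpaxis simulate --config run.yaml --out-dir out/
hpaxis steady-state --u 2
hpaxis presets
```

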