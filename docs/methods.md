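# Methods

## Model

The HPA axis is modeled as a cascade CRH (`x1`) → ACTH (`x2`) → cortisol
(`x3`) with cortisol feedback on both upstream hormones, extended with two
slow variables: the functional secreting mass of the pituitary
corticotrophs (`P`, grown by CRH) and of the adrenal cortex (`A`, grown by
ACTH).  Feedback enters through two receptor functions of the net cortisol
signal `y = C3·x3`: the glucocorticoid receptor `GR(y) = 1/(1+(y/K_GR)^n)`
(saturable, half-active at `K_GR`) and the mineralocorticoid receptor
`MR(y) = 1/y` (high-affinity, operating in its reciprocal range at normal
cortisol).  The model is agnostic to whether mass changes by hypertrophy or
hyperplasia; "functional mass" is secretion capacity.

Assumptions worth stating explicitly:

* hormone kinetics (minutes–hours) are far faster than gland turnover
  (weeks–months), so hormones are quasi-static on the gland timescale;
* gland growth is strictly proportional to the upstream hormone signal —
  each gland is an integral controller that pins its upstream hormone's
  steady state, the mechanism behind every compensation result here;
* no circadian/ultradian pulsatility, no pharmacokinetics, no vasopressin
  state variable (V1b antagonism is represented as an effective reduction
  of ACTH synthesis), no fitting to clinical hormone data.

## Units, parameters, calibration

All five state variables are folds of the healthy baseline; time is in
days (simulations span hundreds of days and gland rates are per day).
Default removal rates: `a1 = 0.17/min`, `a2 = 0.035/min`, `a3 = 0.0086/min`
(converted to 244.8, 50.4, 12.384 per day), `aP = 0.1/day`, `aA =
0.05/day`, `K_GR = 4` (fold), `n = 3`.  Production rates are not free:
`calibrate_baseline` fixes `b1 = a1/(GR(1)·MR(1))`, `b2 = a2/GR(1)`,
`b3 = a3`, `bP = aP`, `bA = aA` so the all-ones state is an *exact* fixed
point at `u = 1` (right-hand sides < 1e-12).  This analytic initialization
replaces a long warm-up simulation; warming up numerically gives the same
state and remains possible by simply integrating the identity scenario.

Drug interventions are multiplicative parameters: `I_i` on synthesis,
`A_i` on removal, `C_i` on the receptor-effective hormone signal (applied
everywhere that hormone acts: `C1` in ACTH production *and* corticotroph
growth, `C2` in cortisol production *and* adrenal growth, `C3` inside GR
and MR).  Dose `d ≥ 0` maps to factor `1/(1+d)` (inhibitors, antagonists,
stress reduction) or `1+d` (antibodies, agonists, corticotroph-removal
enhancement): continuous, monotone, identity at zero.  No dose unit is
implied and antibody saturation is not modeled; explicit factors can be
given in configs when exact parameter values are wanted.

## Steady states

The gland balances give `x1,st = aP·aP_mult/(C1·bP)` and
`x2,st = aA/(C2·bA)` independent of `u` (exact adaptation).  Cortisol then
solves `I1·b1·GR(y)·MR(y)·u = A1·a1·x1,st` — since `GR(y)/y` falls
strictly monotonically from +∞ to 0, a bracketed Brent solve on `log y`
over `y ∈ [1e-9, 1e9]` finds the unique root; `P` and `A` follow from the
remaining balances and all residuals are checked (< 1e-10).  Because this
equation contains only `I1, A1, C1, u` (and CRH/gland rates), the net GR
signal is invariant to every ACTH/cortisol-side parameter — the
compensation theorem the screen rests on, asserted to 1e-10 in tests.

Printed closed forms are kept alongside the numeric solver with validity
flags rather than silent switching: a GR-saturated regime (`x3 ≫ K_GR`,
cortisol ∝ u^(1/4)) and a GR-linear regime (`x3 ≪ K_GR`, cortisol ∝ u);
`classify_regime` labels `x3 ≥ 2K_GR` saturated, `x3 ≤ K_GR/2` linear, the
band between intermediate (numeric only).  The frozen-gland variant
(`P = A = 1`) has both a closed saturated form (cortisol ∝ u^(1/8),
containing *all nine* intervention parameters) and an exact cascade solver.

### The x-fold dosing rule

In the GR-linear regime steady cortisol equals
`(C1·I1·b1·bP)/(C3·A1·a1·aP)·u`, so cortisol elevated x-fold is normalized
by an x-fold change of a CRH-side parameter.  `normalizing_dose` therefore
returns `dose = x − 1`; the screen passes the chronic input fold for `x`
(in the linear regime the two coincide).  For `I1`, `A1`, `C1` and
`u_mult` the rule is in fact exact in the full-Hill model, because these
factors multiply the same product as `u` in the cortisol balance.  For any
ACTH/cortisol-targeting drug no finite dose changes long-term cortisol and
`None` is returned.

## Tumor variants

Adenomas escape feedback: a pituitary tumor adds ACTH secretion
`I2·T_P(t)` (sensitive to synthesis inhibition, insensitive to cortisol),
an adrenal tumor adds `I3·T_A(t)` to cortisol production.  Secretion grows
logistically, `T(t) = T_max/(1+e^{−r(t−t0)})`, as a closed form rather
than a tumor-mass ODE; steady-state conclusions depend only on where `T`
stands relative to a threshold, not on the growth law.

* **Pituitary adenoma.**  Below `T_P* = A2·a2·aA/(C2·I2·bA)` (equal to
  total baseline ACTH production `a2` when untreated) the corticotroph
  mass shrinks linearly and every hormone stays at its no-tumor value
  (subclinical phase).  Above it `P → 0` and the adrenal would grow
  without bound, so adrenal growth carries a carrying-capacity factor
  `(1 − A/K_A)`; the clinical branch then has `x2 = I2·T_P/(A2·a2)` and
  cortisol growing linearly in the excess secretion, reaching `K_A`-fold at
  `T_P = 2T_P*` (untreated).
* **Adrenal adenoma.**  Two steady states exchange stability at
  `T_A* = C1·I1·A3·b1·a3·bP·u/(A1·C3·I3·a1·aP)`: a compensated branch
  (healthy adrenal shrinks, hormones normal) and a clinical branch
  (`x2, P, A → 0`, `x3 = I3·T_A/(A3·a3)` set by the tumor alone).
  Stability is decided by the threshold inequality and cross-checked by
  Jacobian eigenvalues in the tests.

Defaults where the biology does not pin a number: `K_A = 10` (finite,
well-separated clinical state; configurable), `T_max = 2×` threshold,
`r = 0.005/day` (secretion developing over years, slow against gland
turnover `aP = 0.1/day`), onset `t0 = 7/r` so the tumor starts at ~0.1% of
its plateau and the axis genuinely begins at baseline.

One subtlety of the carrying capacity: with `K_A` finite the no-tumor
fixed point of the pituitary-adenoma variant sits at
`x2 = (K_A+1)/K_A`, `A = K_A/(K_A+1)` — the slow manifold keeps `x2·A = 1`
so *cortisol remains exactly at baseline*, but ACTH runs ~10% high for
`K_A = 10`.  The analytic subclinical branch follows the capacity-free
printed forms; the simulator keeps the capacity throughout.  The
clinical-branch cortisol line `x3 = K_A(T_P/T_P* − 1)` is exact either way
and crosses zero at `T_P*` exactly, which is what the threshold estimator
uses (below).

## Simulation

The system is stiff (rate span ~245/day to 0.05/day, ~5000-fold), so the
default integrator is scipy's BDF with `rtol = 1e-8`, `atol = 1e-10`;
explicit RK45 agrees to ~1e-7 relative on a 200-day chronic-stress run and
is available as an option.  Integration is segmented at every input
discontinuity (chronic-stress onset, pulse edges, drug start/stop) so step
events are exact; within a segment the input and intervention vector are
constant and tumor secretion is evaluated continuously.  Samples at a
segment boundary carry the incoming segment's interventions (a drug active
from `t` applies at `t`).  Pulse windows are sampled at ~2-minute
resolution so acute peaks are resolved; elsewhere the default grid is
0.25 day.

Degenerate-state handling: only cortisol enters the singular feedback
functions, so `x3 ≤ 1e-12` aborts integration with a diagnostic; CRH,
ACTH and the gland masses may legitimately decay toward zero in clinical
tumor phases, so for them only clearly negative values (beyond solver
noise, 10·atol) are errors and sub-noise negatives are clipped.

## Scenarios (the generated "data")

All inputs are synthetic and defined by the scenario module: stressor
protocols (baseline 1; chronic step, default fold 2 — the GR-linear regime
where the dosing rule is exact, with fold 50 used in tests for the
saturated forms; square acute pulses, default 3-fold for 2 h, composing
multiplicatively with the chronic level), logistic tumors, and step drug
regimens with optional cessation.  Acute-response comparisons are made as
peak-to-steady *ratios* against each trajectory's own pre-pulse level, so
the (unspecified) pulse shape cancels.  Named presets cover the standard
designs: drug-on-adapted-stress (200-day horizon), stress-then-drug
normalization, twin-pulse acute-response, dose–response, 50-day treatment
cessation, and the two adenoma progressions.  What these scenarios do not
emulate: diurnal rhythm, stochastic stressor streams, measurement noise —
so passing tests validate the circuit logic, not fidelity to raw clinical
cortisol time series.

## The screen

Per condition and mechanism the verdict asks: does some dose bring the
long-term decision signal into a ±5% band around baseline?  The decision
signal is the net GR signal `C3·x3` for receptor antagonists/agonists
(a GR antagonist raises measured cortisol while leaving target-cell
signaling unchanged — judging it on raw cortisol would be wrong in both
directions) and measured cortisol otherwise.  Under chronic stress each
drug is simulated for 200 days on the fully adapted axis (normalizing dose
where finite, else a 2-fold probe) and evaluated over the last 20 days
with a drift check; transient depth and duration are reported from the
trajectory.  The Cushing verdicts are evaluated on the analytic branch
steady states with a 1-D dose search (grid plus Brent refinement),
including the branch switch when a drug lifts the threshold above the
tumor plateau (possible while the suppressed gland mass is still nonzero);
the dynamic counterpart — rescue to the subclinical branch and
months-long post-rescue hypoadrenalism — is verified by simulation in the
tests.  Pairs are screened by scaling both members' doses jointly from
zero; the combined signal crosses the band exactly when the pair contains
an effective mechanism, and agonists are excluded from the default table.

## Clinical-onset detection

Onset is the first sustained (≥10 days) excursion of cortisol beyond the
normal band.  The tumor secretion *at* that moment is a biased estimator
of the bifurcation threshold: below threshold the compensating gland
tracks the growing tumor with a lag that elevates cortisol slightly
(diverging as the threshold nears), and above it cortisol needs time to
build — so band-crossing fires early for fast tumors and late for slow
ones.  `detect_clinical_onset` therefore also fits cortisol against
secretion over the middle of the clinical rise, where the branch is
exactly linear in `T`, and extrapolates to the branch intercept (zero
cortisol for the pituitary case; the pre-tumor baseline for the adrenal
case, where the branches exchange stability at equality).  Quantitative
threshold measurements use a slow drive, `r = 2.5e-4/day`: quasi-static
tracking requires `r ≪ 2·bP·ε·δ` for band half-width ε and tolerance δ,
and this rate recovers both analytic thresholds to ~1–2%.

## Numerical choices and limitations

* Root solves: Brent on log-transformed monotone scalar equations,
  brackets `[1e-9, 1e9]`, `xtol = 1e-14`.
* Steadiness: long-term metrics flag drift > 1e-4 over the averaging
  window instead of silently averaging transients.
* Problem sizes: the oracle-equivalence check uses 100 random draws of
  400-day simulations; screens use 200-day horizons; threshold
  measurements use single slow-drive runs (~2×10^4 simulated days).
* Known limitations: no pulsatility or pharmacokinetics (see assumptions);
  antibody dose–neutralization linearity is a convention; the subclinical
  pituitary branch keeps the printed GR-linear approximation (the numeric
  solver covers the full-Hill case); `P` regrowth after deep clinical
  suppression depends exponentially on how close `P` came to zero, so
  rescue simulations administer drugs while the corticotroph mass is small
  but not numerically extinct, matching the biological statement that
  recovery requires surviving corticotrophs.
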