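"""The in-silico drug screen and its metrics.

For each hypercortisolism condition the screen asks one question per drug
mechanism: does any dose bring the *long-term* decision signal back into the
normal band?  The decision signal is measured cortisol for synthesis
inhibitors and antibodies, and the net GR signal ``C3*x3`` for receptor
antagonists/agonists (a GR antagonist leaves target-cell signaling unchanged
even though measured cortisol rises, so raw cortisol would misclassify it in
both directions).

Under chronic stress the long-term verdict is evaluated by simulating 200
days of treatment on a fully adapted stressed axis; gland-mass compensation
erases every ACTH- and cortisol-targeting intervention, so only the three
CRH-associated mechanisms pass.  In the two Cushing conditions the verdict
is evaluated on the analytic clinical/subclinical branch steady states with
a one-dimensional dose search (drugs act on the tumor-dominated steady
state within hours-days there, and the branch formulas are exact), which
flips the effective sets.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .interventions import (
    DrugRegimen,
    RECEPTOR_KINDS,
    SCREEN_PANEL,
    drug_class,
    normalizing_dose,
    vector_for,
)
from .model import IDENTITY, HPAState, InterventionVector, ModelParams, TumorParams, calibrate_baseline
from .scenarios import CHRONIC_STRESS_FOLD, Pulse, StressProtocol
from .simulate import Trajectory, simulate
from .steady_state import (
    adrenal_states,
    adrenal_threshold,
    pituitary_states,
    pituitary_threshold,
    solve_full_steady_state,
)

__all__ = [
    "CONDITIONS",
    "EfficacyRow",
    "EfficacyReport",
    "DoseResponseCurve",
    "OnsetReport",
    "long_term_metrics",
    "acute_response_metric",
    "run_screen",
    "dose_response",
    "detect_clinical_onset",
]

CONDITIONS = ("chronic_stress", "pituitary_adenoma", "adrenal_adenoma")

#: half-width of the "normal level" band around the healthy baseline
NORMAL_BAND = 0.05
#: probe dose (2-fold parameter change) for drugs with no finite normalizing dose
PROBE_DOSE = 1.0


def _decision_signal(drug_names, cortisol_fold: float, net_fold: float) -> float:
    kinds = {drug_class(n).kind for n in drug_names}
    return net_fold if kinds & set(RECEPTOR_KINDS) else cortisol_fold


# ---------------------------------------------------------------------------
# trajectory metrics


def long_term_metrics(traj: Trajectory, window: float = 20.0) -> dict:
    """Time-averaged folds over the final window, with a steadiness check.

    Returns means of all five variables and the net GR signal over the last
    ``window`` days, the maximum relative drift across the window, and a
    ``converged`` flag (drift < 1e-4).  Non-converged trajectories are
    flagged, never silently averaged away.
    """
    t1 = traj.t[-1]
    w = traj.window(t1 - window, t1)
    if len(w) < 3:
        raise ValueError(f"averaging window [{t1 - window}, {t1}] contains too few samples")
    cols = ["x1", "x2", "x3", "P", "A", "net_gr_signal"]
    out = {c: float(w[c].mean()) for c in cols}
    drift = 0.0
    for c in cols:
        v = w[c].to_numpy()
        scale = max(abs(out[c]), 1e-9)
        drift = max(drift, abs(v[-1] - v[0]) / scale)
    out["drift"] = drift
    out["converged"] = drift < 1e-4
    return out


def acute_response_metric(traj: Trajectory, pulse: Pulse, tail_days: float = 0.5) -> float:
    """Peak cortisol during/after a pulse relative to the pre-pulse level."""
    t = traj.t
    if pulse.t_start <= t[0] or pulse.t_end >= t[-1]:
        raise ValueError(f"pulse [{pulse.t_start}, {pulse.t_end}] not inside trajectory")
    x3 = traj["x3"]
    pre = x3[t < pulse.t_start]
    baseline = float(pre[-1])
    m = (t >= pulse.t_start) & (t <= pulse.t_end + tail_days)
    peak = float(x3[m].max())
    return peak / baseline


# ---------------------------------------------------------------------------
# efficacy screen


@dataclass(frozen=True)
class EfficacyRow:
    """Long-term outcome of one drug (or drug pair) in one condition."""

    condition: str
    drugs: tuple[str, ...]
    doses: tuple[float, ...]
    cortisol_fold: float
    net_gr_fold: float
    x1_fold: float
    x2_fold: float
    P_fold: float
    A_fold: float
    decision_signal: float
    verdict: str  # "effective" | "failed"
    normalized: dict = field(default_factory=dict)
    transient_depth: float | None = None
    transient_duration: float | None = None
    converged: bool | None = None

    @property
    def label(self) -> str:
        return "+".join(self.drugs)


@dataclass
class EfficacyReport:
    """Verdict table of a screen run."""

    condition: str
    rows: list[EfficacyRow]
    band: float = NORMAL_BAND
    meta: dict = field(default_factory=dict)

    @property
    def effective(self) -> set[str]:
        return {r.label for r in self.rows if r.verdict == "effective"}

    @property
    def failed(self) -> set[str]:
        return {r.label for r in self.rows if r.verdict == "failed"}

    def single_rows(self) -> list[EfficacyRow]:
        return [r for r in self.rows if len(r.drugs) == 1]

    def frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            d = asdict(r)
            d["drug"] = r.label
            d["drugs"] = "+".join(r.drugs)
            d["doses"] = ";".join(f"{x:g}" for x in r.doses)
            d["normalized"] = ";".join(k for k, v in r.normalized.items() if v)
            recs.append(d)
        cols = [
            "condition", "drug", "doses", "cortisol_fold", "net_gr_fold",
            "x1_fold", "x2_fold", "P_fold", "A_fold", "decision_signal",
            "verdict", "normalized", "transient_depth", "transient_duration",
            "converged",
        ]
        return pd.DataFrame(recs)[cols]

    def to_csv(self, path) -> None:
        self.frame().to_csv(path, index=False, float_format="%.8g")

    def to_json(self, **kw) -> str:
        return json.dumps(
            {
                "condition": self.condition,
                "band": self.band,
                "meta": self.meta,
                "rows": [asdict(r) for r in self.rows],
            },
            default=str,
            **kw,
        )


def _normalization_flags(vals: dict, band: float) -> dict:
    return {k: abs(vals[k] - 1.0) <= band for k in ("x1", "x2", "x3", "P", "A")}


def _transient_metrics(traj: Trajectory, t_on: float, signal_col: str, band: float):
    """Depth and duration of the post-drug transient relative to the final value."""
    t = traj.t
    m = t >= t_on
    sig = traj[signal_col][m]
    tt = t[m]
    final = sig[-1]
    rel = np.abs(sig - final) / max(abs(final), 1e-9)
    depth = float(rel.max())
    outside = rel > band
    duration = float(tt[outside][-1] - t_on) if outside.any() else 0.0
    return depth, duration


def _chronic_single(
    name: str,
    params: ModelParams,
    u_fold: float,
    band: float,
    horizon: float,
    window: float,
    **solver_kw,
) -> EfficacyRow:
    d = drug_class(name)
    dose = normalizing_dose(u_fold, d)
    if dose is None:
        dose = PROBE_DOSE
    ss0 = solve_full_steady_state(params, IDENTITY, u_fold)
    y0 = HPAState(ss0.x1, ss0.x2, ss0.x3, ss0.P, ss0.A)
    traj = simulate(
        params=params,
        protocol=StressProtocol(chronic=(-1.0, u_fold)),
        regimens=(DrugRegimen(d, dose=dose, t_start=0.0),),
        t_span=(0.0, horizon),
        y0=y0,
        **solver_kw,
    )
    met = long_term_metrics(traj, window)
    signal = _decision_signal([name], met["x3"], met["net_gr_signal"])
    verdict = "effective" if abs(signal - 1.0) <= band else "failed"
    sig_col = "net_gr_signal" if drug_class(name).kind in RECEPTOR_KINDS else "x3"
    depth, duration = _transient_metrics(traj, 0.0, sig_col, band)
    return EfficacyRow(
        condition="chronic_stress",
        drugs=(name,),
        doses=(dose,),
        cortisol_fold=met["x3"],
        net_gr_fold=met["net_gr_signal"],
        x1_fold=met["x1"],
        x2_fold=met["x2"],
        P_fold=met["P"],
        A_fold=met["A"],
        decision_signal=signal,
        verdict=verdict,
        normalized=_normalization_flags(met, band),
        transient_depth=depth,
        transient_duration=duration,
        converged=bool(met["converged"]),
    )


def _chronic_pair_signal(params, u_fold, members, doses, lam):
    iv = IDENTITY
    for name, dmax in zip(members, doses):
        iv = iv.compose(vector_for(name, lam * dmax))
    sol = solve_full_steady_state(params, iv, u_fold)
    return sol, _decision_signal(members, sol.x3, sol.net_gr_signal)


def _search_normalizing(eval_signal, band: float, grid) -> tuple[float, float]:
    """Scan a dose grid and refine sign changes; return (best_dose, best_signal)."""
    vals = [eval_signal(g) for g in grid]
    best = min(zip(grid, vals), key=lambda p: abs(p[1] - 1.0))
    for (g0, v0), (g1, v1) in zip(zip(grid, vals), list(zip(grid, vals))[1:]):
        if np.isfinite(v0) and np.isfinite(v1) and (v0 - 1.0) * (v1 - 1.0) < 0:
            try:
                root = brentq(lambda g: eval_signal(g) - 1.0, g0, g1, xtol=1e-10)
            except ValueError:
                continue
            v = eval_signal(root)
            if abs(v - 1.0) < abs(best[1] - 1.0):
                best = (root, v)
    return best


def _cushing_solution(condition, params, iv, u, tumor):
    """Long-term steady state of a treated Cushing condition.

    A drug that lifts the subclinical-clinical threshold above the tumor's
    plateau secretion pushes the system back to the compensated branch
    (assuming the healthy gland mass was not yet fully lost); otherwise the
    clinical branch applies.
    """
    if condition == "pituitary_adenoma":
        thr = pituitary_threshold(params, iv)
        if tumor.T_max < thr:
            healthy = solve_full_steady_state(params, iv, u)
            sub, _ = pituitary_states(params, iv, u, tumor)
            # hormones from the exact solve; corticotroph mass at its reduced
            # compensating value
            return healthy, {"P": sub.P}
        _, clin = pituitary_states(params, iv, u, tumor)
        return clin, {}
    if condition == "adrenal_adenoma":
        thr = adrenal_threshold(params, iv, u)
        if tumor.T_max < thr:
            healthy = solve_full_steady_state(params, iv, u)
            sub, _, _ = adrenal_states(params, iv, u, tumor)
            return healthy, {"A": sub.A}
        _, clin, _ = adrenal_states(params, iv, u, tumor)
        return clin, {}
    raise ValueError(f"unknown condition {condition!r}")


def _cushing_row(
    condition: str,
    names: tuple[str, ...],
    params: ModelParams,
    u: float,
    tumor: TumorParams,
    band: float,
) -> EfficacyRow:
    classes = [drug_class(n) for n in names]

    def eval_signal(scale):
        iv = IDENTITY
        for c in classes:
            iv = iv.compose(vector_for(c, scale))
        sol, _ = _cushing_solution(condition, params, iv, u, tumor)
        return _decision_signal(names, sol.x3, sol.net_gr_signal)

    grid = np.concatenate([[0.0], np.geomspace(1e-2, 1e2, 41)])
    best_dose, best_signal = _search_normalizing(eval_signal, band, grid)
    iv = IDENTITY
    for c in classes:
        iv = iv.compose(vector_for(c, best_dose))
    sol, overrides = _cushing_solution(condition, params, iv, u, tumor)
    vals = {
        "x1": sol.x1,
        "x2": sol.x2,
        "x3": sol.x3,
        "P": overrides.get("P", sol.P),
        "A": overrides.get("A", sol.A),
    }
    verdict = "effective" if abs(best_signal - 1.0) <= band else "failed"
    return EfficacyRow(
        condition=condition,
        drugs=names,
        doses=(best_dose,) * len(names),
        cortisol_fold=vals["x3"],
        net_gr_fold=sol.net_gr_signal,
        x1_fold=vals["x1"],
        x2_fold=vals["x2"],
        P_fold=vals["P"],
        A_fold=vals["A"],
        decision_signal=best_signal,
        verdict=verdict,
        normalized=_normalization_flags(vals, band),
    )


def run_screen(
    condition: str,
    drugs=SCREEN_PANEL,
    include_pairs: bool = False,
    params: ModelParams | None = None,
    u_fold: float = CHRONIC_STRESS_FOLD,
    tumor: TumorParams | None = None,
    band: float = NORMAL_BAND,
    horizon: float = 200.0,
    window: float = 20.0,
    **solver_kw,
) -> EfficacyReport:
    """Screen drug mechanisms (and optionally unordered pairs) in a condition.

    ``chronic_stress``: each drug is simulated for ``horizon`` days on an
    axis fully adapted to a ``u_fold`` chronic stressor, at its normalizing
    dose where one exists (the x-fold rule) and at a 2-fold probe dose
    otherwise.  ``pituitary_adenoma``/``adrenal_adenoma``: the drug's best
    achievable long-term decision signal is found by a dose search over the
    analytic clinical/subclinical branches with the tumor at its plateau
    secretion (default: twice the untreated threshold).

    A pair is screened by scaling both members' doses jointly from zero and
    asking whether the combined decision signal crosses the normal band —
    so a pair passes exactly when it contains an effective mechanism.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; known: {CONDITIONS}")
    params = params or calibrate_baseline()
    drugs = tuple(drugs)
    rows: list[EfficacyRow] = []
    meta: dict = {"u_fold": u_fold, "band": band}

    if condition == "chronic_stress":
        for name in drugs:
            rows.append(
                _chronic_single(name, params, u_fold, band, horizon, window, **solver_kw)
            )
        if include_pairs:
            single_doses = {r.drugs[0]: r.doses[0] for r in rows}
            for i in range(len(drugs)):
                for j in range(i + 1, len(drugs)):
                    members = (drugs[i], drugs[j])
                    doses = tuple(single_doses[m] for m in members)

                    def eval_signal(lam, members=members, doses=doses):
                        _, sig = _chronic_pair_signal(params, u_fold, members, doses, lam)
                        return sig

                    lam, sig = _search_normalizing(
                        eval_signal, band, np.linspace(0.0, 1.0, 21)
                    )
                    sol, _ = _chronic_pair_signal(params, u_fold, members, doses, lam)
                    verdict = "effective" if abs(sig - 1.0) <= band else "failed"
                    vals = {"x1": sol.x1, "x2": sol.x2, "x3": sol.x3, "P": sol.P, "A": sol.A}
                    rows.append(
                        EfficacyRow(
                            condition=condition,
                            drugs=members,
                            doses=tuple(lam * d for d in doses),
                            cortisol_fold=sol.x3,
                            net_gr_fold=sol.net_gr_signal,
                            x1_fold=sol.x1,
                            x2_fold=sol.x2,
                            P_fold=sol.P,
                            A_fold=sol.A,
                            decision_signal=sig,
                            verdict=verdict,
                            normalized=_normalization_flags(vals, band),
                        )
                    )
    else:
        if tumor is None:
            thr = (
                pituitary_threshold(params)
                if condition == "pituitary_adenoma"
                else adrenal_threshold(params, IDENTITY, 1.0)
            )
            site = "pituitary" if condition == "pituitary_adenoma" else "adrenal"
            tumor = TumorParams(site, T_max=2.0 * thr)
        meta["tumor"] = {"site": tumor.site, "T_max": tumor.T_max, "K_A": tumor.K_A}
        u = 1.0  # Cushing conditions are screened without chronic stress
        for name in drugs:
            rows.append(_cushing_row(condition, (name,), params, u, tumor, band))
        if include_pairs:
            for i in range(len(drugs)):
                for j in range(i + 1, len(drugs)):
                    rows.append(
                        _cushing_row(condition, (drugs[i], drugs[j]), params, u, tumor, band)
                    )

    return EfficacyReport(condition, rows, band=band, meta=meta)


# ---------------------------------------------------------------------------
# dose-response


@dataclass
class DoseResponseCurve:
    """Steady-state outputs across a dose grid for one drug under chronic stress."""

    drug: str
    frame: pd.DataFrame  # dose, cortisol, acth, crh, net_gr_signal [, acute_peak_ratio]

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.8g")


def dose_response(
    drug: str,
    doses,
    params: ModelParams | None = None,
    u_fold: float = CHRONIC_STRESS_FOLD,
    include_acute: bool = False,
    **solver_kw,
) -> DoseResponseCurve:
    """Long-term steady states as a function of dose under chronic stress.

    For CRH-targeting drugs cortisol decreases monotonically with dose while
    CRH and ACTH steady states stay pinned by the gland integral feedbacks;
    for ACTH/cortisol-targeting drugs the whole curve is flat.  With
    ``include_acute`` the peak/steady cortisol ratio of a standard acute
    pulse is simulated at each dose.
    """
    params = params or calibrate_baseline()
    d = drug_class(drug)
    recs = []
    for dose in doses:
        iv = vector_for(d, dose)
        sol = solve_full_steady_state(params, iv, u_fold)
        rec = {
            "dose": dose,
            "cortisol": sol.x3,
            "acth": sol.x2,
            "crh": sol.x1,
            "net_gr_signal": sol.net_gr_signal,
            "P": sol.P,
            "A": sol.A,
        }
        if include_acute:
            y0 = HPAState(sol.x1, sol.x2, sol.x3, sol.P, sol.A)
            pulse = Pulse(t_start=2.0)
            traj = simulate(
                params=params,
                protocol=StressProtocol(chronic=(-1.0, u_fold), pulses=(pulse,)),
                regimens=(DrugRegimen(d, dose=dose, t_start=-1.0),),
                t_span=(0.0, 4.0),
                y0=y0,
                **solver_kw,
            )
            rec["acute_peak_ratio"] = acute_response_metric(traj, pulse)
        recs.append(rec)
    return DoseResponseCurve(d.name, pd.DataFrame(recs))


# ---------------------------------------------------------------------------
# clinical-onset detection


@dataclass(frozen=True)
class OnsetReport:
    """Detected transition from subclinical to clinical hypercortisolism.

    ``t_onset``/``secretion_at_onset``: first sustained exit of cortisol
    from the normal band and the tumor secretion then.  The band-crossing
    secretion is a biased threshold estimate under a growing tumor (the
    compensating gland tracks with a lag below threshold, and cortisol needs
    time to build above it), so ``threshold_estimate`` extrapolates the
    clinical branch — which is exactly linear in tumor secretion — back to
    its bifurcation intercept.
    """

    t_onset: float | None
    secretion_at_onset: float | None
    threshold_estimate: float | None
    subclinical_only: bool


def detect_clinical_onset(
    traj: Trajectory,
    tumor: TumorParams,
    band: float = NORMAL_BAND,
    sustain: float = 10.0,
) -> OnsetReport:
    """Locate clinical onset in a simulated tumor progression.

    Onset is the first time cortisol exceeds ``1 + band`` and stays above it
    for at least ``sustain`` days (or to the end of the run).  The threshold
    estimate fits cortisol against tumor secretion over the middle of the
    clinical rise and extrapolates to the branch intercept: zero cortisol
    for an ACTH-secreting pituitary tumor (clinical cortisol is
    ``K_A*(T/T* - 1)`` fold), the pre-tumor baseline for an adrenal tumor
    (transcritical exchange where the branches meet).
    """
    t, x3, T = traj.t, traj["x3"], traj["T"]
    above = x3 > 1.0 + band
    t_onset = None
    idx = None
    for i in np.flatnonzero(above & ~np.roll(above, 1)):
        j = np.searchsorted(t, t[i] + sustain)
        if above[i : max(j, i + 1)].all():
            t_onset, idx = float(t[i]), i
            break
    if t_onset is None:
        return OnsetReport(None, None, None, subclinical_only=True)

    base = float(np.median(x3[T < 0.2 * T.max()])) if (T < 0.2 * T.max()).any() else 1.0
    mx = float(x3.max())
    lo = base + 0.25 * (mx - base)
    hi = base + 0.75 * (mx - base)
    m = (x3 > lo) & (x3 < hi) & (t >= t_onset)
    thr_est = None
    if m.sum() >= 5:
        slope, intercept = np.polyfit(T[m], x3[m], 1)
        target = 0.0 if tumor.site == "pituitary" else base
        if slope > 0:
            thr_est = float((target - intercept) / slope)
    return OnsetReport(t_onset, float(T[idx]), thr_est, subclinical_only=False)
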