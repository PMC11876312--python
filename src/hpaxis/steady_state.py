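"""Closed-form and semi-analytic steady states of the HPA gland-mass model.

The gland equations pin the steady hormone levels upstream of them:
``dP/dt = 0`` forces ``x1 = aP*aP_mult/(C1*bP)`` and ``dA/dt = 0`` forces
``x2 = aA/(C2*bA)`` — integral feedback that makes CRH and ACTH steady
states independent of the stressor input and of every downstream parameter
(exact adaptation).  Cortisol then solves the CRH balance
``I1*b1*GR(C3*x3)*MR(C3*x3)*u = A1*a1*x1``, a strictly decreasing 1-D
problem in the net GR signal ``y = C3*x3`` with a unique positive root.

Two printed-form approximations bracket the full Hill solution: a
GR-saturated regime (``x3 >> KGR``, cortisol ~ u^(1/4)) and a GR-linear
regime (``x3 << KGR``, cortisol proportional to u).  A nonadjustable-gland
variant (P = A = 1 frozen) is solved both in closed saturated form
(cortisol ~ u^(1/8)) and with the full Hill cascade.

Feedback-escaping tumors add a subclinical/clinical bifurcation: below an
analytic secretion threshold the healthy gland mass shrinks and every
hormone stays at its no-tumor value; above it compensation fails and the
hormones are slaved to the tumor.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.optimize import brentq

from .model import (
    IDENTITY,
    InterventionVector,
    ModelParams,
    TumorParams,
    gr_response,
    rhs_adrenal_adenoma,
    rhs_fixed_gland,
    rhs_intact,
    rhs_pituitary_adenoma,
)

__all__ = [
    "SteadyStateSolution",
    "solve_full_steady_state",
    "solve_fixed_gland_steady_state",
    "closed_form_saturated",
    "closed_form_linear",
    "closed_form_fixed_gland",
    "pituitary_threshold",
    "adrenal_threshold",
    "pituitary_states",
    "adrenal_states",
    "classify_regime",
]

_ROOT_BRACKET = (1e-9, 1e9)


@dataclass(frozen=True)
class SteadyStateSolution:
    """A steady state of one model variant/regime, with validity bookkeeping.

    ``regime`` is one of: full-numeric, GR-saturated, GR-linear, fixed-gland,
    fixed-gland-numeric, pituitary-subclinical, pituitary-clinical,
    adrenal-subclinical, adrenal-clinical.  ``valid`` is False when the
    branch does not exist or is unstable under the given conditions (e.g. a
    clinical branch below the tumor-secretion threshold); ``notes`` says why.
    """

    regime: str
    x1: float
    x2: float
    x3: float
    P: float
    A: float
    net_gr_signal: float
    valid: bool = True
    residual: float = float("nan")
    notes: str = ""

    def as_array(self) -> np.ndarray:
        return np.array([self.x1, self.x2, self.x3, self.P, self.A])

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def classify_regime(x3: float, KGR: float = 4.0) -> str:
    """Which closed form approximates the full solution at this cortisol level."""
    if x3 <= 0:
        raise ValueError(f"x3 must be positive, got {x3}")
    if x3 >= 2.0 * KGR:
        return "saturated"
    if x3 <= 0.5 * KGR:
        return "linear"
    return "intermediate"


def _max_abs_rhs(rhs, y, *args) -> float:
    return float(np.max(np.abs(rhs(0.0, np.asarray(y, dtype=float), *args))))


def _solve_net_signal(params: ModelParams, iv: InterventionVector, u: float, x1: float) -> float:
    """Root of GR(y)/y = rhs_const in the CRH balance; unique since the
    left side decreases monotonically from +inf to 0."""
    u_eff = u * iv.u_mult
    const = iv.A1 * params.a1 * x1 / (iv.I1 * params.b1 * u_eff)

    def f(logy):
        y = np.exp(logy)
        return np.log(gr_response(y, params.KGR, params.n) / y) - np.log(const)

    lo, hi = np.log(_ROOT_BRACKET[0]), np.log(_ROOT_BRACKET[1])
    return float(np.exp(brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16)))


def solve_full_steady_state(
    params: ModelParams, iv: InterventionVector = IDENTITY, u: float = 1.0
) -> SteadyStateSolution:
    """Exact (full Hill) steady state of the intact adaptive-gland model.

    The gland balances give ``x1`` and ``x2`` in closed form; the net GR
    signal ``y = C3*x3`` is found by bracketed root finding on the CRH
    balance, and ``P``, ``A`` follow from the two remaining hormone
    balances.  ``y`` depends only on I1, A1, C1, C3 (via x3 = y/C3), u and
    the CRH/gland rates — the robustness at the heart of the drug screen.
    """
    p = params
    x1 = p.aP * iv.aP_mult / (iv.C1 * p.bP)
    x2 = p.aA / (iv.C2 * p.bA)
    y = _solve_net_signal(p, iv, u, x1)
    x3 = y / iv.C3
    gr = p.gr(y)
    P = iv.A2 * p.a2 * x2 / (iv.I2 * p.b2 * iv.C1 * x1 * gr)
    A = iv.A3 * p.a3 * x3 / (iv.I3 * p.b3 * iv.C2 * x2)
    resid = _max_abs_rhs(rhs_intact, [x1, x2, x3, P, A], p, iv, u)
    return SteadyStateSolution("full-numeric", x1, x2, x3, P, A, y, residual=resid)


def solve_fixed_gland_steady_state(
    params: ModelParams, iv: InterventionVector = IDENTITY, u: float = 1.0
) -> SteadyStateSolution:
    """Exact steady state with P = A = 1 frozen (full Hill feedback).

    Cascade substitution collapses the three hormone balances to
    ``x3 * (1 + (C3*x3/KGR)^n) = sqrt(Q * u_eff / C3)`` with ``Q`` the product
    of all production/removal ratios and intervention factors; the left side
    is strictly increasing so the root is unique.
    """
    p = params
    u_eff = u * iv.u_mult
    Q = (
        (iv.I1 * p.b1 / (iv.A1 * p.a1))
        * (iv.I2 * p.b2 * iv.C1 / (iv.A2 * p.a2))
        * (iv.I3 * p.b3 * iv.C2 / (iv.A3 * p.a3))
    )
    target = np.sqrt(Q * u_eff / iv.C3)

    def f(logx):
        x = np.exp(logx)
        return np.log(x * (1.0 + (iv.C3 * x / p.KGR) ** p.n)) - np.log(target)

    lo, hi = np.log(_ROOT_BRACKET[0]), np.log(_ROOT_BRACKET[1])
    x3 = float(np.exp(brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16)))
    gr = p.gr(iv.C3 * x3)
    x2 = iv.A3 * p.a3 * x3 / (iv.I3 * p.b3 * iv.C2)
    x1 = iv.A2 * p.a2 * x2 / (iv.I2 * p.b2 * iv.C1 * gr)
    resid = _max_abs_rhs(rhs_fixed_gland, [x1, x2, x3, 1.0, 1.0], p, iv, u)
    return SteadyStateSolution("fixed-gland-numeric", x1, x2, x3, 1.0, 1.0, iv.C3 * x3, residual=resid)


def closed_form_saturated(
    params: ModelParams, iv: InterventionVector = IDENTITY, u: float = 1.0
) -> SteadyStateSolution:
    """GR-saturated printed form (x3 >> KGR): cortisol scales as u^(1/4).

    Transcribed verbatim (with the extended ``u_mult``/``aP_mult`` modifiers
    folded into ``u`` and ``aP``); validity flag set from the regime of the
    resulting cortisol level.
    """
    p = params
    u_eff = u * iv.u_mult
    aP = p.aP * iv.aP_mult
    K = p.KGR
    core = iv.C1 * iv.I1 * p.b1 * p.bP * u_eff / (iv.A1 * p.a1 * aP)
    x1 = aP / (iv.C1 * p.bP)
    x2 = p.aA / (iv.C2 * p.bA)
    x3 = (K**3 * core) ** 0.25 / iv.C3
    P = (iv.A2 * p.a2 * p.bP * p.aA / (iv.C2 * iv.I2 * p.b2 * aP * p.bA)) * (core / K) ** 0.75
    A = (iv.A3 * p.a3 * p.bA / (iv.C3 * iv.I3 * p.b3 * p.aA)) * (K**3 * core) ** 0.25
    regime = classify_regime(x3, K)
    return SteadyStateSolution(
        "GR-saturated",
        x1,
        x2,
        x3,
        P,
        A,
        iv.C3 * x3,
        valid=regime == "saturated",
        notes=f"approximation assumes x3 >> KGR (found regime: {regime})",
    )


def closed_form_linear(
    params: ModelParams, iv: InterventionVector = IDENTITY, u: float = 1.0
) -> SteadyStateSolution:
    """GR-linear printed form (x3 << KGR): cortisol proportional to u.

    This is the regime of the x-fold dosing rule: steady cortisol equals
    ``C1*I1*b1*bP*u / (C3*A1*a1*aP)``, so only CRH-associated parameters and
    the input can move it.
    """
    p = params
    u_eff = u * iv.u_mult
    aP = p.aP * iv.aP_mult
    x1 = aP / (iv.C1 * p.bP)
    x2 = p.aA / (iv.C2 * p.bA)
    x3 = iv.C1 * iv.I1 * p.b1 * p.bP * u_eff / (iv.C3 * iv.A1 * p.a1 * aP)
    P = iv.A2 * p.a2 * p.bP * p.aA / (iv.C2 * iv.I2 * p.b2 * aP * p.bA)
    A = (
        iv.C1 * iv.I1 * iv.A3 * p.b1 * p.a3 * p.bP * p.bA
        / (iv.A1 * iv.C3 * iv.I3 * p.a1 * p.b3 * aP * p.aA)
    ) * u_eff
    regime = classify_regime(x3, p.KGR)
    return SteadyStateSolution(
        "GR-linear",
        x1,
        x2,
        x3,
        P,
        A,
        iv.C3 * x3,
        valid=regime == "linear",
        notes=f"approximation assumes x3 << KGR (found regime: {regime})",
    )


def closed_form_fixed_gland(
    params: ModelParams, iv: InterventionVector = IDENTITY, u: float = 1.0
) -> SteadyStateSolution:
    """Saturated printed form of the nonadjustable-gland model.

    Cortisol is the eighth root of a product containing *every* intervention
    parameter — without gland-mass adaptation each of the nine drug classes
    moves steady cortisol (weakly).
    """
    p = params
    u_eff = u * iv.u_mult
    K = p.KGR
    R = (
        iv.C1 * iv.C2 * iv.I1 * iv.I2 * iv.I3 * K**6 * p.b1 * p.b2 * p.b3 * u_eff
        / (iv.A1 * iv.A2 * iv.A3 * iv.C3**7 * p.a1 * p.a2 * p.a3)
    )
    x3 = R**0.125
    x2 = (iv.A3 * p.a3 / (iv.C2 * iv.I3 * p.b3)) * R**0.125
    x1 = (
        iv.A2 * iv.A3 * iv.C3**3 * p.a2 * p.a3
        / (iv.C1 * iv.C2 * iv.I2 * iv.I3 * K**3 * p.b2 * p.b3)
    ) * R**0.5
    regime = classify_regime(x3, K)
    return SteadyStateSolution(
        "fixed-gland",
        x1,
        x2,
        x3,
        1.0,
        1.0,
        iv.C3 * x3,
        valid=regime == "saturated",
        notes=f"approximation assumes x3 >> KGR (found regime: {regime})",
    )


def pituitary_threshold(params: ModelParams, iv: InterventionVector = IDENTITY) -> float:
    """Tumor ACTH secretion rate above which pituitary compensation fails.

    ``T_P* = A2*a2*aA / (C2*I2*bA)``; with calibrated parameters and no drug
    this equals ``a2`` (total baseline ACTH production).  ACTH-targeting
    drugs (I2 down, A2 up, C2 down) raise the threshold — the route by which
    they push a patient back into the subclinical regime.
    """
    return iv.A2 * params.a2 * params.aA / (iv.C2 * iv.I2 * params.bA)


def adrenal_threshold(
    params: ModelParams, iv: InterventionVector = IDENTITY, u: float = 1.0
) -> float:
    """Tumor cortisol secretion rate above which adrenal compensation fails.

    ``T_A* = C1*I1*A3*b1*a3*bP*u / (A1*C3*I3*a1*aP)``; cortisol-targeting
    drugs (I3 down, A3 up, C3 down) raise it.
    """
    p = params
    return (
        iv.C1 * iv.I1 * iv.A3 * p.b1 * p.a3 * p.bP * u * iv.u_mult
        / (iv.A1 * iv.C3 * iv.I3 * p.a1 * p.aP * iv.aP_mult)
    )


def pituitary_states(
    params: ModelParams,
    iv: InterventionVector = IDENTITY,
    u: float = 1.0,
    tumor: TumorParams | None = None,
    T_P: float | None = None,
) -> tuple[SteadyStateSolution, SteadyStateSolution]:
    """Subclinical and clinical steady states of the pituitary-adenoma model.

    Subclinical branch (GR-linear printed form): every hormone at its
    no-tumor value while the healthy corticotroph mass shrinks linearly in
    tumor secretion, ``P_st = P_no_tumor - T_P*bP/(b2*aP)``; valid while
    ``P_st > 0``, i.e. ``T_P`` below :func:`pituitary_threshold`.  Clinical
    branch (P -> 0, GR-saturated, adrenal at carrying capacity): ACTH and
    cortisol slaved to the tumor, cortisol growing linearly in the excess
    secretion above threshold.
    """
    if tumor is None or tumor.site != "pituitary":
        raise ValueError("pituitary_states requires TumorParams with site='pituitary'")
    p = params
    TP = tumor.T_max if T_P is None else T_P
    thr = pituitary_threshold(p, iv)
    aP = p.aP * iv.aP_mult
    u_eff = u * iv.u_mult
    K, KA = p.KGR, tumor.K_A

    sub = closed_form_linear(p, iv, u)
    P_sub = sub.P - TP * p.bP / (p.b2 * aP)
    subclinical = SteadyStateSolution(
        "pituitary-subclinical",
        sub.x1,
        sub.x2,
        sub.x3,
        P_sub,
        sub.A,
        sub.net_gr_signal,
        valid=P_sub > 0,
        notes="valid while corticotroph mass can still compensate (T_P below threshold)"
        if P_sub > 0
        else "tumor secretion above threshold: corticotroph mass fully suppressed",
    )

    excess = iv.C2 * iv.I2 * TP * p.bA - iv.A2 * p.a2 * p.aA  # > 0 above threshold
    if TP > 0:
        x2_c = iv.I2 * TP / (iv.A2 * p.a2)
        x3_c = iv.I3 * KA * p.b3 * excess / (iv.A2 * iv.A3 * p.a2 * p.a3 * p.bA)
        A_c = KA - iv.A2 * KA * p.a2 * p.aA / (iv.C2 * iv.I2 * TP * p.bA)
        if excess > 0:
            x1_c = (
                iv.A2**4 * iv.A3**4 * iv.I1 * K**3 * p.a2**4 * p.a3**4 * p.b1 * p.bA**4 * u_eff
                / (iv.A1 * iv.C3**4 * iv.I3**4 * KA**4 * p.a1 * p.b3**4 * excess**4)
            )
        else:
            x1_c = float("nan")
    else:
        x1_c = x2_c = x3_c = A_c = float("nan")
    clinical = SteadyStateSolution(
        "pituitary-clinical",
        x1_c,
        x2_c,
        x3_c,
        0.0,
        A_c,
        iv.C3 * x3_c,
        valid=TP > thr,
        notes="valid only above the subclinical-clinical threshold"
        if TP <= thr
        else "P fully suppressed; adrenal at carrying capacity",
    )
    return subclinical, clinical


def adrenal_states(
    params: ModelParams,
    iv: InterventionVector = IDENTITY,
    u: float = 1.0,
    tumor: TumorParams | None = None,
    T_A: float | None = None,
) -> tuple[SteadyStateSolution, SteadyStateSolution, float]:
    """Both steady states of the adrenal-adenoma model plus the threshold.

    Branch 1 (healthy-compensated): hormones at their no-tumor (GR-linear)
    values while the healthy adrenal mass shrinks linearly in tumor
    secretion; stable iff ``T_A`` below :func:`adrenal_threshold`.  Branch 2
    (compensation lost): healthy adrenal and corticotroph masses and ACTH go
    to zero and cortisol is set by the tumor alone,
    ``x3 = I3*T_A/(A3*a3)``; stable iff ``T_A`` above the threshold.
    """
    if tumor is None or tumor.site != "adrenal":
        raise ValueError("adrenal_states requires TumorParams with site='adrenal'")
    p = params
    TA = tumor.T_max if T_A is None else T_A
    thr = adrenal_threshold(p, iv, u)
    u_eff = u * iv.u_mult

    lin = closed_form_linear(p, iv, u)
    A1_branch = lin.A - TA * p.bA / (p.aA * p.b3)
    branch1 = SteadyStateSolution(
        "adrenal-subclinical",
        lin.x1,
        lin.x2,
        lin.x3,
        lin.P,
        A1_branch,
        lin.net_gr_signal,
        valid=TA < thr,
        notes="stable while tumor secretion is below threshold"
        if TA < thr
        else "unstable: tumor secretion above threshold",
    )

    if TA > 0:
        x1_2 = iv.I1 * iv.A3 * p.b1 * p.a3 * u_eff / (iv.A1 * iv.C3 * iv.I3 * p.a1 * TA)
        x3_2 = iv.I3 * TA / (p.a3 * iv.A3)
        branch2 = SteadyStateSolution(
            "adrenal-clinical",
            x1_2,
            0.0,
            x3_2,
            0.0,
            0.0,
            iv.C3 * x3_2,
            valid=TA > thr,
            notes="stable: compensation lost, cortisol set by the tumor"
            if TA > thr
            else "unstable below threshold",
        )
    else:
        branch2 = SteadyStateSolution(
            "adrenal-clinical", float("nan"), 0.0, float("nan"), 0.0, 0.0, float("nan"),
            valid=False, notes="no tumor secretion: clinical branch does not exist",
        )
    return branch1, branch2, thr
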