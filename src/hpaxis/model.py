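"""Core HPA-axis gland-mass circuit model.

The hypothalamic-pituitary-adrenal (HPA) axis is modelled as a cascade of
three hormones -- CRH (``x1``), ACTH (``x2``) and cortisol (``x3``) -- with
two slow variables for the functional secreting mass of the pituitary
corticotrophs (``P``) and the adrenal cortex (``A``).  Cortisol feeds back on
both upstream hormones through the glucocorticoid receptor (a Hill function)
and the mineralocorticoid receptor (a reciprocal function), while each gland
mass grows in proportion to its upstream hormone and turns over slowly, so
the glands act as integral-feedback controllers on weeks-to-months
timescales.

All state variables are expressed as fold-of-healthy-baseline; the
production rates ``b*`` are fixed by :func:`calibrate_baseline` so that the
all-ones state is an exact fixed point at baseline input ``u = 1``.

Drug interventions enter as multiplicative parameters: synthesis inhibitors
``I1..I3`` scale production, neutralizing antibodies ``A1..A3`` scale
removal, and receptor antagonists/agonists ``C1..C3`` scale the effective
hormone signal wherever that hormone acts on a receptor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "MINUTES_PER_DAY",
    "DomainError",
    "ModelParams",
    "HPAState",
    "InterventionVector",
    "IDENTITY",
    "TumorParams",
    "gr_response",
    "mr_response",
    "calibrate_baseline",
    "rhs_intact",
    "rhs_fixed_gland",
    "rhs_pituitary_adenoma",
    "rhs_adrenal_adenoma",
]

MINUTES_PER_DAY = 1440.0


class DomainError(ValueError):
    """A quantity left the domain where the model is defined (e.g. x3 <= 0)."""


def gr_response(y: float, KGR: float = 4.0, n: float = 3) -> float:
    """Glucocorticoid-receptor occupancy factor GR(y) = 1 / (1 + (y/KGR)^n).

    ``y`` is the net cortisol signal (C3*x3, fold of baseline).  Strictly
    decreasing in ``y``; equals 1/2 at ``y = KGR`` and tends to 1 as
    ``y -> 0+``.
    """
    if y <= 0:
        raise DomainError(f"GR is defined for positive cortisol signal, got {y}")
    return 1.0 / (1.0 + (y / KGR) ** n)


def mr_response(y: float) -> float:
    """Mineralocorticoid-receptor factor MR(y) = 1/y (singular at 0)."""
    if y <= 0:
        raise DomainError(f"MR is defined for positive cortisol signal, got {y}")
    return 1.0 / y


def _require_positive(obj, names) -> None:
    for name in names:
        v = getattr(obj, name)
        if not (v > 0) or not math.isfinite(v):
            raise ValueError(f"{type(obj).__name__}.{name} must be a finite positive number, got {v}")


@dataclass(frozen=True)
class ModelParams:
    """Rate constants of the gland-mass model, all in per-day units.

    ``b1..b3``: hormone production rates; ``a1..a3``: hormone removal rates;
    ``bP, bA``: gland growth gains per unit upstream hormone; ``aP, aA``:
    gland removal rates; ``KGR``: GR half-activation cortisol level (fold of
    baseline); ``n``: GR Hill coefficient.
    """

    b1: float
    b2: float
    b3: float
    a1: float = 0.17 * MINUTES_PER_DAY   # 244.8 / day
    a2: float = 0.035 * MINUTES_PER_DAY  # 50.4 / day
    a3: float = 0.0086 * MINUTES_PER_DAY  # 12.384 / day
    bP: float = 0.1
    bA: float = 0.05
    aP: float = 0.1
    aA: float = 0.05
    KGR: float = 4.0
    n: float = 3

    def __post_init__(self):
        _require_positive(self, [f.name for f in fields(self)])
        if self.n < 1:
            raise ValueError(f"Hill coefficient n must be >= 1, got {self.n}")

    def gr(self, y: float) -> float:
        return gr_response(y, self.KGR, self.n)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def calibrate_baseline(
    a1: float = 0.17 * MINUTES_PER_DAY,
    a2: float = 0.035 * MINUTES_PER_DAY,
    a3: float = 0.0086 * MINUTES_PER_DAY,
    aP: float = 0.1,
    aA: float = 0.05,
    KGR: float = 4.0,
    n: float = 3,
) -> ModelParams:
    """Fix the production rates so the all-ones state is the healthy baseline.

    With state in fold-of-baseline units the removal rates are the free
    physiological parameters; production rates follow from requiring that
    every balance closes at ``x1 = x2 = x3 = P = A = 1`` under ``u = 1``:

    * ``b1 = a1 / (GR(1) * MR(1))``
    * ``b2 = a2 / GR(1)``
    * ``b3 = a3``
    * ``bP = aP`` and ``bA = aA`` (unit upstream hormone balances growth).
    """
    gr1 = gr_response(1.0, KGR, n)
    mr1 = mr_response(1.0)
    return ModelParams(
        b1=a1 / (gr1 * mr1),
        b2=a2 / gr1,
        b3=a3,
        a1=a1,
        a2=a2,
        a3=a3,
        bP=aP,
        bA=aA,
        aP=aP,
        aA=aA,
        KGR=KGR,
        n=n,
    )


@dataclass(frozen=True)
class HPAState:
    """The five dynamic variables, in fold-of-healthy-baseline units."""

    x1: float = 1.0
    x2: float = 1.0
    x3: float = 1.0
    P: float = 1.0
    A: float = 1.0

    def __post_init__(self):
        for name in ("x1", "x2", "x3"):
            if not getattr(self, name) > 0:
                raise ValueError(f"hormone {name} must be positive, got {getattr(self, name)}")
        for name in ("P", "A"):
            if getattr(self, name) < 0:
                raise ValueError(f"gland mass {name} must be >= 0, got {getattr(self, name)}")

    def as_array(self) -> np.ndarray:
        return np.array([self.x1, self.x2, self.x3, self.P, self.A], dtype=float)

    @classmethod
    def from_array(cls, y) -> "HPAState":
        return cls(*(float(v) for v in y))


@dataclass(frozen=True)
class InterventionVector:
    """Multiplicative drug parameters; the all-ones vector is 'no drug'.

    ``I1..I3`` scale hormone synthesis (<1 = inhibitor), ``A1..A3`` scale
    hormone removal (>1 = neutralizing antibody), ``C1..C3`` scale the
    receptor-effective hormone signal (<1 = antagonist, >1 = agonist).
    ``u_mult`` scales the stressor input (stress-reduction interventions) and
    ``aP_mult`` scales the corticotroph removal rate.
    """

    I1: float = 1.0
    I2: float = 1.0
    I3: float = 1.0
    A1: float = 1.0
    A2: float = 1.0
    A3: float = 1.0
    C1: float = 1.0
    C2: float = 1.0
    C3: float = 1.0
    u_mult: float = 1.0
    aP_mult: float = 1.0

    def __post_init__(self):
        _require_positive(self, [f.name for f in fields(self)])

    def compose(self, other: "InterventionVector") -> "InterventionVector":
        """Multiplicative (commutative) composition of two interventions."""
        return InterventionVector(
            **{f.name: getattr(self, f.name) * getattr(other, f.name) for f in fields(self)}
        )

    def with_field(self, name: str, factor: float) -> "InterventionVector":
        return replace(self, **{name: getattr(self, name) * factor})

    def is_identity(self, tol: float = 0.0) -> bool:
        return all(abs(getattr(self, f.name) - 1.0) <= tol for f in fields(self))

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


IDENTITY = InterventionVector()


@dataclass(frozen=True)
class TumorParams:
    """A feedback-escaping adenoma with logistic secretion growth.

    ``site`` is ``"pituitary"`` (ACTH-secreting, Cushing's disease) or
    ``"adrenal"`` (cortisol-secreting).  Secretion follows
    ``T(t) = T_max / (1 + exp(-r (t - t0)))`` in the same normalized units as
    the corresponding gland's total baseline production.  ``K_A`` is the
    adrenal carrying capacity (fold of baseline adrenal mass), used only in
    the pituitary-adenoma clinical model.
    """

    site: str
    T_max: float
    r: float = 0.005
    t0: float = 0.0
    K_A: float = 10.0

    def __post_init__(self):
        if self.site not in ("pituitary", "adrenal"):
            raise ValueError(f"tumor site must be 'pituitary' or 'adrenal', got {self.site!r}")
        if self.T_max < 0:
            raise ValueError(f"T_max must be >= 0, got {self.T_max}")
        if not self.r > 0:
            raise ValueError(f"logistic growth rate r must be > 0, got {self.r}")
        if not self.K_A > 1:
            raise ValueError(f"adrenal carrying capacity K_A must be > 1, got {self.K_A}")

    def secretion_at(self, t) -> float:
        """Logistic secretion trajectory; midpoint T_max/2 at t = t0."""
        z = np.clip(-self.r * (np.asarray(t, dtype=float) - self.t0), -700.0, 700.0)
        return self.T_max / (1.0 + np.exp(z))


def _check_hormones(y) -> None:
    # Only x3 enters the singular feedback functions (GR, MR); a hard check on
    # it is mandatory.  x1, x2 appear polynomially, so transient solver probes
    # slightly below zero are harmless and positivity is enforced on the
    # reported trajectory instead.
    if y[2] <= 0:
        raise DomainError(f"cortisol must stay positive (x3 = {y[2]}); MR(x)=1/x is singular at 0")


def rhs_intact(t, y, params: ModelParams, iv: InterventionVector = IDENTITY, u: float = 1.0):
    """Right-hand side of the adaptive-gland model.

    ``y = [x1, x2, x3, P, A]``; ``u`` is the stressor input at time ``t``
    (the ``u_mult`` intervention is applied internally).  Receptor factors
    multiply the hormone wherever it acts: ``C1*x1`` in ACTH production and
    corticotroph growth, ``C2*x2`` in cortisol production and adrenal growth,
    ``C3*x3`` inside GR and MR.
    """
    _check_hormones(y)
    x1, x2, x3, P, A = y
    p = params
    net = iv.C3 * x3
    gr = p.gr(net)
    mr = 1.0 / net
    u_eff = u * iv.u_mult
    dx1 = iv.I1 * p.b1 * gr * mr * u_eff - iv.A1 * p.a1 * x1
    dx2 = iv.I2 * p.b2 * iv.C1 * x1 * gr * P - iv.A2 * p.a2 * x2
    dx3 = iv.I3 * p.b3 * iv.C2 * x2 * A - iv.A3 * p.a3 * x3
    dP = P * (p.bP * iv.C1 * x1 - p.aP * iv.aP_mult)
    dA = A * (p.bA * iv.C2 * x2 - p.aA)
    return np.array([dx1, dx2, dx3, dP, dA])


def rhs_fixed_gland(t, y, params: ModelParams, iv: InterventionVector = IDENTITY, u: float = 1.0):
    """Nonadjustable-gland variant: hormone equations with P = A = 1 frozen."""
    frozen = np.array([y[0], y[1], y[2], 1.0, 1.0])
    d = rhs_intact(t, frozen, params, iv, u)
    d[3] = 0.0
    d[4] = 0.0
    return d


def rhs_pituitary_adenoma(
    t,
    y,
    params: ModelParams,
    iv: InterventionVector = IDENTITY,
    u: float = 1.0,
    tumor: TumorParams | None = None,
):
    """ACTH-secreting adenoma: tumor term in the ACTH balance plus an adrenal
    carrying capacity.

    The tumor secretes ACTH at rate ``T_P(t)`` regardless of cortisol (it has
    escaped the feedback loop) but remains sensitive to ACTH-synthesis
    inhibition, so ``I2`` multiplies the tumor term.  Adrenal growth
    saturates at carrying capacity ``K_A`` via a logistic factor
    ``(1 - A/K_A)``, which keeps the clinical-phase steady state finite.
    ``P`` and ``A`` here are the healthy (non-tumor) functional masses.
    """
    if tumor is None or tumor.site != "pituitary":
        raise ValueError("rhs_pituitary_adenoma requires TumorParams with site='pituitary'")
    d = rhs_intact(t, y, params, iv, u)
    x2, P, A = y[1], y[3], y[4]
    TP = float(tumor.secretion_at(t))
    d[1] += iv.I2 * TP
    # replace the unbounded adrenal growth term with the capacity-limited one
    d[4] = A * (params.bA * iv.C2 * x2 * (1.0 - A / tumor.K_A) - params.aA)
    return d


def rhs_adrenal_adenoma(
    t,
    y,
    params: ModelParams,
    iv: InterventionVector = IDENTITY,
    u: float = 1.0,
    tumor: TumorParams | None = None,
):
    """Cortisol-secreting adenoma: tumor term in the cortisol balance.

    ``I3`` (cortisol-synthesis inhibition) scales both the healthy-gland and
    the tumor secretion terms.  ``A`` is the healthy (non-tumor) adrenal
    functional mass.
    """
    if tumor is None or tumor.site != "adrenal":
        raise ValueError("rhs_adrenal_adenoma requires TumorParams with site='adrenal'")
    d = rhs_intact(t, y, params, iv, u)
    d[2] += iv.I3 * float(tumor.secretion_at(t))
    return d
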