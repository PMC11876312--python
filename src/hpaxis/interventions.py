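"""Drug classes, dosing regimens, and the normalizing-dose rule.

Each drug class touches exactly one multiplicative intervention parameter.
Dose semantics: a nonnegative dose ``d`` maps to a parameter factor
``1/(1+d)`` for inhibitors/antagonists (and stress reduction) or ``1+d``
for antibodies, agonists and removal enhancers, so dose 0 is always the
identity and the mapping is continuous and monotone.  A regimen may instead
carry an explicit parameter ``factor`` for exact reproduction of analytic
cases.

The normalizing-dose rule: in the GR-linear regime steady cortisol is
proportional to ``C1*I1*b1*bP*u/(A1*a1*aP)``, so cortisol elevated x-fold is
returned to baseline by changing a CRH-associated parameter (or the input)
by the same x-fold.  No finite dose of any ACTH- or cortisol-targeting drug
moves long-term cortisol — the gland masses compensate exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .model import IDENTITY, InterventionVector

__all__ = [
    "DrugClass",
    "DrugRegimen",
    "DRUG_CLASSES",
    "SCREEN_PANEL",
    "RECEPTOR_KINDS",
    "drug_class",
    "vector_for",
    "intervention_vector_at",
    "normalizing_dose",
    "cessation",
]


@dataclass(frozen=True)
class DrugClass:
    """A named intervention mechanism acting on one parameter.

    ``field`` is the :class:`InterventionVector` attribute it scales and
    ``kind`` decides the dose -> factor direction (``down``: 1/(1+d),
    ``up``: 1+d).
    """

    name: str
    field: str
    kind: str  # inhibitor | antibody | antagonist | agonist | input | gland

    @property
    def lowers_parameter(self) -> bool:
        return self.kind in ("inhibitor", "antagonist") or (
            self.kind == "input" and self.field == "u_mult"
        )

    def factor(self, dose: float) -> float:
        if dose < 0:
            raise ValueError(f"dose must be nonnegative, got {dose}")
        return 1.0 / (1.0 + dose) if self.lowers_parameter else 1.0 + dose

    def dose_for_factor(self, factor: float) -> float:
        """Inverse of :meth:`factor`; factor must be on the drug's side of 1."""
        d = 1.0 / factor - 1.0 if self.lowers_parameter else factor - 1.0
        if d < 0:
            raise ValueError(
                f"{self.name} can only move {self.field} "
                f"{'below' if self.lowers_parameter else 'above'} 1 (asked for {factor})"
            )
        return d


_CLASSES = [
    DrugClass("crh_synthesis_inhibitor", "I1", "inhibitor"),
    DrugClass("acth_synthesis_inhibitor", "I2", "inhibitor"),
    DrugClass("cortisol_synthesis_inhibitor", "I3", "inhibitor"),
    DrugClass("anti_crh_antibody", "A1", "antibody"),
    DrugClass("anti_acth_antibody", "A2", "antibody"),
    DrugClass("anti_cortisol_antibody", "A3", "antibody"),
    DrugClass("crh_receptor_antagonist", "C1", "antagonist"),
    DrugClass("acth_receptor_antagonist", "C2", "antagonist"),
    DrugClass("gr_antagonist", "C3", "antagonist"),
    DrugClass("crh_receptor_agonist", "C1", "agonist"),
    DrugClass("acth_receptor_agonist", "C2", "agonist"),
    DrugClass("gr_agonist", "C3", "agonist"),
    # vasopressin potentiates CRH-dependent ACTH release; V1b antagonism is
    # therefore equivalent to lowering effective ACTH synthesis.
    DrugClass("v1b_antagonist", "I2", "inhibitor"),
    DrugClass("stress_reduction", "u_mult", "input"),
    DrugClass("corticotroph_removal_enhancer", "aP_mult", "gland"),
]

DRUG_CLASSES: dict[str, DrugClass] = {c.name: c for c in _CLASSES}

#: The nine-mechanism screen: synthesis inhibitors, neutralizing antibodies
#: and receptor antagonists for each of the three hormones.
SCREEN_PANEL: tuple[str, ...] = (
    "crh_synthesis_inhibitor",
    "acth_synthesis_inhibitor",
    "cortisol_synthesis_inhibitor",
    "anti_crh_antibody",
    "anti_acth_antibody",
    "anti_cortisol_antibody",
    "crh_receptor_antagonist",
    "acth_receptor_antagonist",
    "gr_antagonist",
)

RECEPTOR_KINDS = ("antagonist", "agonist")

#: Fields whose x-fold change cancels an x-fold cortisol elevation in the
#: GR-linear steady state (the CRH-associated knobs of the dosing rule).
_NORMALIZING_FIELDS = ("I1", "A1", "C1", "u_mult", "aP_mult")


def drug_class(name: str) -> DrugClass:
    try:
        return DRUG_CLASSES[name]
    except KeyError:
        raise KeyError(
            f"unknown drug class {name!r}; known: {sorted(DRUG_CLASSES)}"
        ) from None


@dataclass(frozen=True)
class DrugRegimen:
    """A drug held at constant dose between ``t_start`` and ``t_stop`` (days).

    ``t_stop = None`` means open-ended.  ``factor``, when given, overrides
    the dose -> factor mapping with an explicit parameter multiplier.
    """

    drug: DrugClass
    dose: float = 0.0
    t_start: float = 0.0
    t_stop: float | None = None
    factor: float | None = None

    def __post_init__(self):
        if isinstance(self.drug, str):
            object.__setattr__(self, "drug", drug_class(self.drug))
        if self.dose < 0:
            raise ValueError(f"dose must be nonnegative, got {self.dose}")
        if self.t_stop is not None and not self.t_start < self.t_stop:
            raise ValueError(
                f"t_start ({self.t_start}) must precede t_stop ({self.t_stop})"
            )
        if self.factor is not None and not self.factor > 0:
            raise ValueError(f"explicit factor must be positive, got {self.factor}")

    @property
    def parameter_factor(self) -> float:
        return self.factor if self.factor is not None else self.drug.factor(self.dose)

    def active_at(self, t: float) -> bool:
        return t >= self.t_start and (self.t_stop is None or t < self.t_stop)

    def event_times(self) -> list[float]:
        return [self.t_start] + ([] if self.t_stop is None else [self.t_stop])


def vector_for(drug: DrugClass | str, dose: float | None = None, factor: float | None = None) -> InterventionVector:
    """The intervention vector of a single drug at the given dose or factor."""
    d = drug_class(drug) if isinstance(drug, str) else drug
    if factor is None:
        factor = d.factor(0.0 if dose is None else dose)
    return IDENTITY.with_field(d.field, factor)


def intervention_vector_at(t: float, regimens) -> InterventionVector:
    """Multiplicative composition of all regimens active at time ``t``."""
    iv = IDENTITY
    for reg in regimens:
        if reg.active_at(t):
            iv = iv.with_field(reg.drug.field, reg.parameter_factor)
    return iv


def normalizing_dose(cortisol_fold_x: float, drug: DrugClass | str) -> float | None:
    """Dose that returns x-fold-elevated steady cortisol to baseline.

    For CRH-associated drugs (and stress reduction / corticotroph-removal
    enhancement) the required parameter factor is ``x`` or ``1/x`` and the
    corresponding dose is ``x - 1``.  For every ACTH- or cortisol-targeting
    drug gland-mass compensation makes steady cortisol dose-independent, so
    no finite dose normalizes it and ``None`` is returned.
    """
    d = drug_class(drug) if isinstance(drug, str) else drug
    if not cortisol_fold_x > 1:
        raise ValueError(
            f"normalizing_dose applies to elevated cortisol (x > 1), got x = {cortisol_fold_x}"
        )
    if d.field not in _NORMALIZING_FIELDS or d.kind == "agonist":
        return None
    return cortisol_fold_x - 1.0


def cessation(regimen: DrugRegimen, t_stop: float) -> DrugRegimen:
    """Truncate a regimen: parameters return to identity from ``t_stop`` on."""
    if not t_stop > regimen.t_start:
        raise ValueError(
            f"cessation time {t_stop} must be after regimen start {regimen.t_start}"
        )
    return replace(regimen, t_stop=t_stop)
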