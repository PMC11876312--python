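"""Synthetic input protocols: stressors, tumors, and named study presets.

The model is driven entirely by generated inputs: a stressor protocol
``u(t)`` (baseline 1, optional chronic step, optional short square pulses
composing multiplicatively with the chronic level), a logistic tumor
secretion trajectory for the Cushing variants, and step-function drug
regimens.  :func:`preset` packages the handful of standard simulation
designs used by the drug screen (chronic-stress treatment, acute-response
probing, dose-response, cessation, and the two adenoma progressions).

Defaults define the study conditions: chronic stress is a 2-fold step (the
GR-linear regime where the x-fold dosing rule is exact); acute stress is a
3-fold, 2-hour pulse above the current baseline (the acute-response
comparison is relative, so its conclusions do not depend on this shape);
adenomas grow slowly (logistic rate 0.005/day, i.e. over years) so the
subclinical branch is tracked quasi-statically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .interventions import DrugRegimen, cessation, drug_class, normalizing_dose
from .model import TumorParams

__all__ = [
    "Pulse",
    "StressProtocol",
    "ScenarioPreset",
    "input_at",
    "tumor_secretion_at",
    "preset",
    "PRESET_NAMES",
    "CHRONIC_STRESS_FOLD",
    "ACUTE_PULSE_FOLD",
    "ACUTE_PULSE_HOURS",
]

CHRONIC_STRESS_FOLD = 2.0
ACUTE_PULSE_FOLD = 3.0
ACUTE_PULSE_HOURS = 2.0
TUMOR_GROWTH_RATE = 0.005  # 1/day: adenoma secretion doubles over ~5 months
TUMOR_EXCESS_FOLD = 2.0    # plateau secretion relative to the analytic threshold


@dataclass(frozen=True)
class Pulse:
    """A square acute-stress pulse: ``fold`` times the current baseline for
    ``duration_h`` hours starting at day ``t_start``."""

    t_start: float
    duration_h: float = ACUTE_PULSE_HOURS
    fold: float = ACUTE_PULSE_FOLD

    def __post_init__(self):
        if not self.duration_h > 0:
            raise ValueError(f"pulse duration must be positive, got {self.duration_h}")
        if not self.fold > 1:
            raise ValueError(f"pulse fold must exceed 1, got {self.fold}")

    @property
    def t_end(self) -> float:
        return self.t_start + self.duration_h / 24.0


@dataclass(frozen=True)
class StressProtocol:
    """Stressor input u(t): baseline, optional chronic step, acute pulses.

    ``chronic = (t_on, fold)`` multiplies the input by ``fold`` from day
    ``t_on`` onward; pulses multiply whatever level is current (a pulse
    "above the baseline"), and may not overlap each other.
    """

    u_base: float = 1.0
    chronic: tuple[float, float] | None = None
    pulses: tuple[Pulse, ...] = ()

    def __post_init__(self):
        if not self.u_base > 0:
            raise ValueError(f"u_base must be positive, got {self.u_base}")
        if self.chronic is not None and not self.chronic[1] > 0:
            raise ValueError(f"chronic fold must be positive, got {self.chronic[1]}")
        ordered = sorted(self.pulses, key=lambda p: p.t_start)
        for a, b in zip(ordered, ordered[1:]):
            if b.t_start < a.t_end:
                raise ValueError(
                    f"pulses overlap ambiguously at day {b.t_start} (previous ends {a.t_end})"
                )

    def input_at(self, t: float) -> float:
        u = self.u_base
        if self.chronic is not None and t >= self.chronic[0]:
            u *= self.chronic[1]
        for p in self.pulses:
            if p.t_start <= t < p.t_end:
                u *= p.fold
        return u

    def event_times(self) -> list[float]:
        times = [] if self.chronic is None else [self.chronic[0]]
        for p in self.pulses:
            times += [p.t_start, p.t_end]
        return times


def input_at(t: float, protocol: StressProtocol) -> float:
    return protocol.input_at(t)


def tumor_secretion_at(t, tumor: TumorParams):
    """Logistic tumor secretion T_max / (1 + exp(-r (t - t0)))."""
    return tumor.secretion_at(t)


@dataclass(frozen=True)
class ScenarioPreset:
    """A fully specified simulation design.

    ``init`` selects the initial condition: ``"baseline"`` (all-ones healthy
    fixed point) or ``"stressed_steady"`` (pre-equilibrated at the chronic
    stress level, emulating a long pre-treatment stress period).
    ``dose_grid`` is populated only by the dose-response preset.
    """

    name: str
    variant: str
    protocol: StressProtocol
    regimens: tuple[DrugRegimen, ...] = ()
    tumor: TumorParams | None = None
    t_span: tuple[float, float] = (0.0, 200.0)
    init: str = "baseline"
    dose_grid: tuple[float, ...] | None = None
    description: str = ""


def _drug_regimen(drug, dose, t_start, t_stop=None, u_fold=CHRONIC_STRESS_FOLD):
    d = drug_class(drug) if isinstance(drug, str) else drug
    if dose is None:
        dose = normalizing_dose(u_fold, d)
        if dose is None:
            dose = 1.0  # probe dose: a 2-fold parameter change
    return DrugRegimen(d, dose=dose, t_start=t_start, t_stop=t_stop)


def _tumor(site: str, threshold: float) -> TumorParams:
    # onset at t0 = 7/r so initial secretion is ~1e-3 of the plateau: the
    # adenoma grows from nothing and the axis starts at its true baseline
    return TumorParams(
        site=site,
        T_max=TUMOR_EXCESS_FOLD * threshold,
        r=TUMOR_GROWTH_RATE,
        t0=7.0 / TUMOR_GROWTH_RATE,
    )


def preset(
    name: str,
    drug: str = "crh_synthesis_inhibitor",
    dose: float | None = None,
    u_fold: float = CHRONIC_STRESS_FOLD,
    threshold: float | None = None,
) -> ScenarioPreset:
    """Named simulation designs.

    ``drug``/``dose`` parameterize the treatment presets (``dose=None``
    picks the normalizing dose where one exists, else a 2-fold probe).
    ``threshold`` must be supplied for the adenoma presets (the analytic
    subclinical-clinical secretion threshold for the chosen parameters,
    from which the tumor plateau is scaled).

    * ``chronic_drug_screen`` — pre-equilibrated chronic stress, one drug
      switched on at day 0, 200-day horizon.
    * ``chronic_normalization`` — stress step at day 0, drug from day 200,
      run to day 500 (full-axis normalization check).
    * ``acute_response`` — an identical pulse probed twice: once at the
      healthy baseline, once during treated chronic stress.
    * ``dose_response`` — treated chronic stress with a dose grid attached.
    * ``cessation`` — drug on at day 0 under steady chronic stress, off
      after 50 days, observed for 250 more days.
    * ``pituitary_adenoma`` / ``adrenal_adenoma`` — logistic tumor crossing
      its threshold, no drug.
    """
    chronic_now = StressProtocol(chronic=(0.0, u_fold))
    if name == "chronic_drug_screen":
        return ScenarioPreset(
            name,
            "adaptive",
            chronic_now,
            regimens=(_drug_regimen(drug, dose, 0.0, u_fold=u_fold),),
            t_span=(-20.0, 200.0),
            init="stressed_steady",
            description="single drug at day 0 on a chronically stressed, fully adapted axis",
        )
    if name == "chronic_normalization":
        return ScenarioPreset(
            name,
            "adaptive",
            chronic_now,
            regimens=(_drug_regimen(drug, dose, 200.0, u_fold=u_fold),),
            t_span=(0.0, 500.0),
            init="baseline",
            description="chronic stress from day 0, drug from day 200",
        )
    if name == "acute_response":
        protocol = StressProtocol(
            chronic=(50.0, u_fold),
            pulses=(Pulse(t_start=20.0), Pulse(t_start=400.0)),
        )
        return ScenarioPreset(
            name,
            "adaptive",
            protocol,
            regimens=(_drug_regimen(drug, dose, 250.0, u_fold=u_fold),),
            t_span=(0.0, 450.0),
            init="baseline",
            description="identical pulses before chronic stress and during treatment",
        )
    if name == "dose_response":
        return ScenarioPreset(
            name,
            "adaptive",
            chronic_now,
            regimens=(_drug_regimen(drug, dose, 0.0, u_fold=u_fold),),
            t_span=(-20.0, 200.0),
            init="stressed_steady",
            dose_grid=tuple(np.linspace(0.0, 3.0, 13)),
            description="steady-state outputs across a dose grid under chronic stress",
        )
    if name == "cessation":
        reg = cessation(_drug_regimen(drug, dose, 0.0, u_fold=u_fold), 50.0)
        return ScenarioPreset(
            name,
            "adaptive",
            chronic_now,
            regimens=(reg,),
            t_span=(-20.0, 300.0),
            init="stressed_steady",
            description="drug for 50 days under steady chronic stress, then stopped",
        )
    if name in ("pituitary_adenoma", "adrenal_adenoma"):
        if threshold is None:
            raise ValueError(f"preset {name!r} needs the analytic secretion threshold")
        site = "pituitary" if name == "pituitary_adenoma" else "adrenal"
        tumor = _tumor(site, threshold)
        return ScenarioPreset(
            name,
            site + "_adenoma",
            StressProtocol(),
            tumor=tumor,
            t_span=(0.0, tumor.t0 + 600.0),
            init="baseline",
            description="slow logistic tumor crossing the compensation threshold",
        )
    raise ValueError(f"unknown preset {name!r}; known: {sorted(PRESET_NAMES)}")


PRESET_NAMES: tuple[str, ...] = (
    "chronic_drug_screen",
    "chronic_normalization",
    "acute_response",
    "dose_response",
    "cessation",
    "pituitary_adenoma",
    "adrenal_adenoma",
)
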