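"""Run configuration: YAML/TOML loading with unit-aware parameter parsing.

Rates may be given as plain numbers (interpreted as per-day) or as strings
with an explicit unit, ``"0.17/min"`` or ``"0.1/day"``; per-minute values
are converted to per-day on load.  Unknown keys are rejected so typos fail
loudly rather than silently running the defaults.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .interventions import DrugRegimen, drug_class
from .model import ModelParams, TumorParams, calibrate_baseline
from .scenarios import PRESET_NAMES, Pulse, ScenarioPreset, StressProtocol, preset

__all__ = ["RunConfig", "load_config", "parse_rate"]

_RATE_KEYS = ("a1", "a2", "a3", "aP", "aA")
_PLAIN_KEYS = ("KGR", "n")


class ConfigError(ValueError):
    """A configuration file failed validation; the message names the field."""


def parse_rate(value, key: str = "") -> float:
    """A rate as a float (per day) or a '<number>/<unit>' string."""
    if isinstance(value, (int, float)):
        return float(value)
    if isinstance(value, str):
        try:
            num, unit = value.split("/")
            num = float(num)
        except ValueError:
            raise ConfigError(f"{key}: cannot parse rate {value!r}; use e.g. '0.17/min' or 12.4") from None
        unit = unit.strip().lower()
        if unit in ("min", "minute"):
            return num * 1440.0
        if unit in ("day", "d"):
            return num
        raise ConfigError(f"{key}: unknown rate unit {unit!r} (use 'min' or 'day')")
    raise ConfigError(f"{key}: expected number or rate string, got {type(value).__name__}")


def _check_keys(section: dict, allowed, where: str) -> None:
    unknown = set(section) - set(allowed)
    if unknown:
        raise ConfigError(f"{where}: unknown keys {sorted(unknown)}; allowed: {sorted(allowed)}")


@dataclass
class RunConfig:
    """Everything one run needs: variant, parameters, scenario, solver, outputs."""

    variant: str = "adaptive"
    params: ModelParams = field(default_factory=calibrate_baseline)
    protocol: StressProtocol = field(default_factory=StressProtocol)
    regimens: tuple[DrugRegimen, ...] = ()
    tumor: TumorParams | None = None
    t_span: tuple[float, float] = (0.0, 200.0)
    init: str = "baseline"
    preset_name: str | None = None
    condition: str | None = None
    solver: dict = field(default_factory=lambda: {"method": "BDF", "rtol": 1e-8, "atol": 1e-10, "sample_dt": 0.25})
    out_dir: str = "."
    seed: int | None = None  # reserved; current computations are deterministic

    def scenario(self) -> ScenarioPreset:
        return ScenarioPreset(
            name=self.preset_name or "custom",
            variant=self.variant,
            protocol=self.protocol,
            regimens=self.regimens,
            tumor=self.tumor,
            t_span=self.t_span,
            init=self.init,
        )

    def resolved(self) -> dict:
        return {
            "variant": self.variant,
            "params": self.params.to_dict(),
            "t_span": list(self.t_span),
            "init": self.init,
            "preset": self.preset_name,
            "condition": self.condition,
            "solver": self.solver,
            "seed": self.seed,
            "regimens": [
                {"drug": r.drug.name, "dose": r.dose, "factor": r.factor,
                 "t_start": r.t_start, "t_stop": r.t_stop}
                for r in self.regimens
            ],
            "tumor": None if self.tumor is None else {
                "site": self.tumor.site, "T_max": self.tumor.T_max,
                "r": self.tumor.r, "t0": self.tumor.t0, "K_A": self.tumor.K_A,
            },
        }

    def resolved_json(self, **kw) -> str:
        return json.dumps(self.resolved(), **kw)


def _parse_params(section: dict) -> ModelParams:
    _check_keys(section, _RATE_KEYS + _PLAIN_KEYS, "params")
    kw = {}
    for k in _RATE_KEYS:
        if k in section:
            kw[k] = parse_rate(section[k], k)
    for k in _PLAIN_KEYS:
        if k in section:
            kw[k] = float(section[k])
    return calibrate_baseline(**kw)


def _parse_protocol(section: dict) -> StressProtocol:
    _check_keys(section, ("u_base", "chronic", "pulses"), "protocol")
    chronic = section.get("chronic")
    if chronic is not None:
        _check_keys(chronic, ("t_on", "fold"), "protocol.chronic")
        chronic = (float(chronic["t_on"]), float(chronic["fold"]))
    pulses = []
    for i, p in enumerate(section.get("pulses", [])):
        _check_keys(p, ("t_start", "duration_h", "fold"), f"protocol.pulses[{i}]")
        pulses.append(Pulse(**{k: float(v) for k, v in p.items()}))
    return StressProtocol(
        u_base=float(section.get("u_base", 1.0)), chronic=chronic, pulses=tuple(pulses)
    )


def _parse_regimens(items) -> tuple[DrugRegimen, ...]:
    regs = []
    for i, r in enumerate(items):
        _check_keys(r, ("drug", "dose", "factor", "t_start", "t_stop"), f"regimens[{i}]")
        regs.append(
            DrugRegimen(
                drug=drug_class(r["drug"]),
                dose=float(r.get("dose", 0.0)),
                factor=None if r.get("factor") is None else float(r["factor"]),
                t_start=float(r.get("t_start", 0.0)),
                t_stop=None if r.get("t_stop") is None else float(r["t_stop"]),
            )
        )
    return tuple(regs)


def _parse_tumor(section: dict) -> TumorParams:
    _check_keys(section, ("site", "T_max", "r", "t0", "K_A"), "tumor")
    kw = {k: (v if k == "site" else float(v)) for k, v in section.items()}
    return TumorParams(**kw)


def load_config(path) -> RunConfig:
    """Load and validate a YAML (.yml/.yaml) or TOML (.toml) run config."""
    path = Path(path)
    if path.suffix in (".yml", ".yaml"):
        raw = yaml.safe_load(path.read_text()) or {}
    elif path.suffix == ".toml":
        raw = tomllib.loads(path.read_text())
    else:
        raise ConfigError(f"unsupported config format {path.suffix!r} (use .yaml or .toml)")

    allowed = (
        "variant", "params", "protocol", "regimens", "tumor", "t_span",
        "init", "preset", "condition", "solver", "out_dir", "seed",
    )
    _check_keys(raw, allowed, str(path))

    cfg = RunConfig()
    if "preset" in raw:
        name = raw["preset"]
        if name not in PRESET_NAMES:
            raise ConfigError(f"unknown preset {name!r}; known: {sorted(PRESET_NAMES)}")
        cfg.preset_name = name
    if "params" in raw:
        cfg.params = _parse_params(raw["params"])
    if "variant" in raw:
        cfg.variant = raw["variant"]
    if "protocol" in raw:
        cfg.protocol = _parse_protocol(raw["protocol"])
    if "regimens" in raw:
        cfg.regimens = _parse_regimens(raw["regimens"])
    if "tumor" in raw:
        cfg.tumor = _parse_tumor(raw["tumor"])
    if "t_span" in raw:
        cfg.t_span = (float(raw["t_span"][0]), float(raw["t_span"][1]))
    if "init" in raw:
        if raw["init"] not in ("baseline", "stressed_steady"):
            raise ConfigError(f"init must be 'baseline' or 'stressed_steady', got {raw['init']!r}")
        cfg.init = raw["init"]
    if "condition" in raw:
        cfg.condition = raw["condition"]
    if "solver" in raw:
        _check_keys(raw["solver"], ("method", "rtol", "atol", "sample_dt", "max_step"), "solver")
        cfg.solver.update(raw["solver"])
    if "out_dir" in raw:
        cfg.out_dir = str(raw["out_dir"])
    if "seed" in raw:
        cfg.seed = int(raw["seed"])
    return cfg
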