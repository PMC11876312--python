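"""Trajectory simulation for every model variant.

The system is stiff: hormone removal rates span ~12-245 per day while gland
turnover is 0.05-0.1 per day, a ~5000-fold separation.  Integration uses
scipy's implicit BDF method with tight tolerances by default and is
segmented at every input discontinuity (chronic-stress onset, pulse edges,
drug start/stop), so step events are exact and the solver never thrashes
across a jump.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .interventions import intervention_vector_at
from .model import (
    DomainError,
    HPAState,
    IDENTITY,
    InterventionVector,
    ModelParams,
    TumorParams,
    calibrate_baseline,
    rhs_adrenal_adenoma,
    rhs_fixed_gland,
    rhs_intact,
    rhs_pituitary_adenoma,
)
from .scenarios import ScenarioPreset, StressProtocol

__all__ = ["Trajectory", "IntegrationError", "VARIANTS", "simulate", "run_preset"]

VARIANTS = ("adaptive", "fixed_gland", "pituitary_adenoma", "adrenal_adenoma")

_COLUMNS = ["t_days", "x1", "x2", "x3", "P", "A", "u", "T", "net_gr_signal"]


class IntegrationError(RuntimeError):
    """The ODE solver failed or the trajectory left the physical domain."""


@dataclass
class Trajectory:
    """A simulated trajectory with its inputs and derived columns.

    ``frame`` holds ``t_days, x1, x2, x3, P, A`` plus the stressor input
    ``u``, tumor secretion ``T`` and the net GR signal ``C3*x3`` at each
    sample.  ``meta`` records the resolved parameters and solver settings.
    """

    frame: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def t(self) -> np.ndarray:
        return self.frame["t_days"].to_numpy()

    def __getitem__(self, col: str) -> np.ndarray:
        return self.frame[col].to_numpy()

    def state_at(self, t: float) -> HPAState:
        """State at time ``t`` by linear interpolation of the samples."""
        tt = self.t
        vals = [float(np.interp(t, tt, self.frame[c].to_numpy())) for c in ("x1", "x2", "x3", "P", "A")]
        return HPAState(*vals)

    def final_state(self) -> HPAState:
        row = self.frame.iloc[-1]
        return HPAState(row.x1, row.x2, row.x3, row.P, row.A)

    def window(self, t_lo: float, t_hi: float) -> pd.DataFrame:
        m = (self.frame["t_days"] >= t_lo) & (self.frame["t_days"] <= t_hi)
        return self.frame[m]

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.10g")

    def metadata_json(self, **kw) -> str:
        return json.dumps(self.meta, default=str, **kw)


def _rhs_for(variant: str):
    try:
        return {
            "adaptive": rhs_intact,
            "fixed_gland": rhs_fixed_gland,
            "pituitary_adenoma": rhs_pituitary_adenoma,
            "adrenal_adenoma": rhs_adrenal_adenoma,
        }[variant]
    except KeyError:
        raise ValueError(f"unknown model variant {variant!r}; known: {VARIANTS}") from None


def _breakpoints(t_span, protocol: StressProtocol, regimens) -> np.ndarray:
    t0, t1 = t_span
    times = {float(t0), float(t1)}
    for t in protocol.event_times():
        if t0 < t < t1:
            times.add(float(t))
    for reg in regimens:
        for t in reg.event_times():
            if t0 < t < t1:
                times.add(float(t))
    return np.array(sorted(times))


def simulate(
    variant: str = "adaptive",
    params: ModelParams | None = None,
    protocol: StressProtocol | None = None,
    regimens=(),
    tumor: TumorParams | None = None,
    t_span: tuple[float, float] = (0.0, 200.0),
    y0: HPAState | None = None,
    method: str = "BDF",
    rtol: float = 1e-8,
    atol: float = 1e-10,
    sample_dt: float = 0.25,
    max_step: float = np.inf,
) -> Trajectory:
    """Integrate a model variant under time-varying inputs.

    Within each segment between input discontinuities the stressor level and
    the active intervention vector are constant (tumor secretion varies
    smoothly and is evaluated inside the right-hand side).  Pulse windows
    are sampled densely (about a minute) so acute peaks are resolved.
    Raises :class:`IntegrationError` on solver failure or if any hormone
    leaves the positive domain / a gland mass turns negative.
    """
    params = params or calibrate_baseline()
    protocol = protocol or StressProtocol()
    regimens = tuple(regimens)
    base_rhs = _rhs_for(variant)
    if variant.endswith("_adenoma"):
        if tumor is None:
            raise ValueError(f"variant {variant!r} requires TumorParams")
        rhs_args = lambda iv, u: (params, iv, u, tumor)
    else:
        rhs_args = lambda iv, u: (params, iv, u)

    y = (y0 or HPAState()).as_array()
    bps = _breakpoints(t_span, protocol, regimens)
    rows = []
    pulse_windows = [(p.t_start, p.t_end) for p in protocol.pulses]

    for ta, tb in zip(bps[:-1], bps[1:]):
        mid = 0.5 * (ta + tb)
        u = protocol.input_at(mid)
        iv = intervention_vector_at(mid, regimens)
        args = rhs_args(iv, u)

        in_pulse = any(a <= mid < b for a, b in pulse_windows)
        dt = min(sample_dt, 1.0 / 1440.0 * 2) if in_pulse else sample_dt
        n = max(int(np.ceil((tb - ta) / dt)), 2)
        t_eval = np.linspace(ta, tb, n + 1)

        try:
            sol = solve_ivp(
                base_rhs,
                (ta, tb),
                y,
                args=args,
                method=method,
                rtol=rtol,
                atol=atol,
                t_eval=t_eval,
                max_step=max_step,
            )
        except DomainError as e:
            raise IntegrationError(
                f"state left the model domain during [{ta}, {tb}]: {e}"
            ) from e
        if not sol.success:
            raise IntegrationError(
                f"solver failed on segment [{ta}, {tb}]: {sol.message}"
            )
        Y = sol.y
        if np.any(Y[2] < 1e-12):
            raise IntegrationError(
                f"cortisol collapsed below 1e-12 in [{ta}, {tb}]; MR feedback is singular there"
            )
        # x1/x2 and the gland masses may decay to ~0 (e.g. clinical adenoma
        # phases); values a hair below zero are solver noise and are clipped,
        # anything clearly negative is a real failure.
        if np.any(Y[[0, 1, 3, 4]] < -10 * atol):
            raise IntegrationError(f"negative state variable in [{ta}, {tb}]")
        Y = Y.copy()
        Y[[0, 1]] = np.clip(Y[[0, 1]], 1e-300, None)
        Y[[3, 4]] = np.clip(Y[[3, 4]], 0.0, None)

        seg = pd.DataFrame(
            {
                "t_days": sol.t,
                "x1": Y[0],
                "x2": Y[1],
                "x3": Y[2],
                "P": Y[3],
                "A": Y[4],
                "u": [protocol.input_at(t) * iv.u_mult for t in sol.t],
                "T": tumor.secretion_at(sol.t) if tumor is not None else 0.0,
                "net_gr_signal": iv.C3 * Y[2],
            }
        )
        # boundary samples belong to the segment that starts there: a drug or
        # stress step active from t applies to the sample at t (matches
        # DrugRegimen.active_at), so drop the previous segment's last row
        if rows:
            rows[-1] = rows[-1].iloc[:-1]
        rows.append(seg)
        y = Y[:, -1]

    frame = pd.concat(rows, ignore_index=True)
    meta = {
        "variant": variant,
        "params": params.to_dict(),
        "protocol": {
            "u_base": protocol.u_base,
            "chronic": protocol.chronic,
            "pulses": [(p.t_start, p.duration_h, p.fold) for p in protocol.pulses],
        },
        "regimens": [
            {
                "drug": r.drug.name,
                "dose": r.dose,
                "factor": r.parameter_factor,
                "t_start": r.t_start,
                "t_stop": r.t_stop,
            }
            for r in regimens
        ],
        "tumor": None
        if tumor is None
        else {"site": tumor.site, "T_max": tumor.T_max, "r": tumor.r, "t0": tumor.t0, "K_A": tumor.K_A},
        "solver": {"method": method, "rtol": rtol, "atol": atol, "sample_dt": sample_dt},
        "t_span": list(t_span),
        "y0": list((y0 or HPAState()).as_array()),
    }
    return Trajectory(frame, meta)


def run_preset(
    p: ScenarioPreset, params: ModelParams | None = None, **solver_kw
) -> Trajectory:
    """Resolve a preset's initial condition and simulate it.

    ``init="stressed_steady"`` starts from the exact steady state under the
    chronic stress level (full-Hill solve), emulating an axis that has fully
    adapted to a long stress period before treatment begins.
    """
    from .steady_state import solve_full_steady_state

    params = params or calibrate_baseline()
    if p.init == "stressed_steady":
        if p.protocol.chronic is None:
            raise ValueError("stressed_steady initialization needs a chronic stress level")
        ss = solve_full_steady_state(params, IDENTITY, p.protocol.chronic[1] * p.protocol.u_base)
        y0 = HPAState(ss.x1, ss.x2, ss.x3, ss.P, ss.A)
        # the chronic step must already be on at the start of the window
        if p.protocol.chronic[0] > p.t_span[0]:
            protocol = StressProtocol(
                u_base=p.protocol.u_base,
                chronic=(p.t_span[0], p.protocol.chronic[1]),
                pulses=p.protocol.pulses,
            )
        else:
            protocol = p.protocol
    else:
        y0 = HPAState()
        protocol = p.protocol
    traj = simulate(
        variant=p.variant,
        params=params,
        protocol=protocol,
        regimens=p.regimens,
        tumor=p.tumor,
        t_span=p.t_span,
        y0=y0,
        **solver_kw,
    )
    traj.meta["preset"] = p.name
    traj.meta["init"] = p.init
    return traj
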