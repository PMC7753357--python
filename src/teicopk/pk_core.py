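"""Closed-form one-compartment intravenous-infusion kinetics.

The whole pipeline rests on the linear one-compartment model with
first-order elimination: during a constant-rate infusion ``R = amount /
duration`` the concentration rises as ``(R/CL) * (1 - exp(-k*t))`` with
``k = CL/V``, and decays mono-exponentially once the pump stops.  Multi-dose
profiles are plain superposition of per-dose contributions, so every
concentration is exactly linear in each dose amount.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PKParameters",
    "DoseEvent",
    "Regimen",
    "conc_profile",
    "trough",
    "steady_state_auc24",
    "BOLUS_DURATION",
]

#: Infusions shorter than this (hours) are treated as instantaneous boluses
#: to avoid the 0/0 limit in the infusion solution.
BOLUS_DURATION = 1e-6

#: Default infusion length (h) when a regimen does not specify one.
DEFAULT_INFUSION_DURATION = 0.5


@dataclass(frozen=True)
class PKParameters:
    """Individual clearance (L/h) and distribution volume (L)."""

    cl: float
    v: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.cl) and math.isfinite(self.v)):
            raise ValueError("PK parameters must be finite")
        if self.cl <= 0 or self.v <= 0:
            raise ValueError("PK parameters must be strictly positive")

    @property
    def k(self) -> float:
        """First-order elimination rate constant (1/h)."""
        return self.cl / self.v


@dataclass(frozen=True)
class DoseEvent:
    """A single timed intravenous dose.

    Parameters
    ----------
    time
        Infusion start (h, >= 0).
    amount
        Dose (mg, > 0).
    duration
        Infusion length (h, > 0).  Values below :data:`BOLUS_DURATION`
        are handled as instantaneous boluses.
    """

    time: float
    amount: float
    duration: float = DEFAULT_INFUSION_DURATION

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("dose time must be non-negative")
        if self.amount <= 0:
            raise ValueError("dose amount must be positive")
        if self.duration < 0:
            raise ValueError("infusion duration must be non-negative")


@dataclass(frozen=True)
class Regimen:
    """An ordered sequence of dose events.

    Events are sorted by start time on construction, so callers may pass
    them in any order.
    """

    events: tuple[DoseEvent, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.events, key=lambda e: e.time))
        object.__setattr__(self, "events", ordered)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def scaled(self, factor: float) -> "Regimen":
        """Regimen with every dose amount multiplied by ``factor``."""
        return Regimen(
            tuple(
                DoseEvent(e.time, e.amount * factor, e.duration) for e in self.events
            )
        )


def _single_dose_conc(
    params: PKParameters, dose: DoseEvent, times: np.ndarray
) -> np.ndarray:
    """Contribution of one dose to the concentration at ``times``."""
    k = params.k
    tau = times - dose.time
    out = np.zeros_like(tau, dtype=float)
    if dose.duration < BOLUS_DURATION:
        on = tau >= 0
        out[on] = (dose.amount / params.v) * np.exp(-k * tau[on])
        return out
    rate = dose.amount / dose.duration
    during = (tau >= 0) & (tau < dose.duration)
    after = tau >= dose.duration
    out[during] = (rate / params.cl) * (1.0 - np.exp(-k * tau[during]))
    ceoi = (rate / params.cl) * (1.0 - np.exp(-k * dose.duration))
    out[after] = ceoi * np.exp(-k * (tau[after] - dose.duration))
    return out


def conc_profile(params: PKParameters, regimen: Regimen, times) -> np.ndarray:
    """Concentration (mg/L) at each requested time (h).

    Superposition over all dose events; a dose contributes nothing before
    its start time.  Times need not be sorted.
    """
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(t < 0):
        raise ValueError("evaluation times must be non-negative")
    total = np.zeros_like(t)
    for dose in regimen:
        total += _single_dose_conc(params, dose, t)
    return total


def trough(params: PKParameters, regimen: Regimen, eval_time: float) -> float:
    """Concentration at a single (pre-dose) evaluation time.

    Emits a warning when ``eval_time`` falls inside an ongoing infusion —
    the value returned is then not a trough in the clinical sense.
    """
    for dose in regimen:
        if dose.time <= eval_time < dose.time + dose.duration:
            warnings.warn(
                f"evaluation time {eval_time} h falls inside an infusion; "
                "the value is not a trough",
                stacklevel=2,
            )
    return float(conc_profile(params, regimen, [eval_time])[0])


def steady_state_auc24(daily_dose: float, cl: float) -> float:
    """Steady-state 24-h area under the curve, ``daily_dose / CL`` (mg·h/L)."""
    if not math.isfinite(cl) or cl <= 0:
        raise ValueError("clearance must be positive and finite")
    if daily_dose < 0:
        raise ValueError("daily dose must be non-negative")
    return daily_dose / cl
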