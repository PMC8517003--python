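"""Standard-method comparator: Henssge's double-exponential cooling model.

The forensic standard method correlates the normalised rectal-ambient
temperature ratio

    Q = (T_rectal - T_ambient) / (T0 - T_ambient)

with the PMI t through a double exponential

    Q(t) = A exp(B t) - (A - 1) exp(p B t),
    B = -1.2815 (cf * kg)^(-0.625) + 0.0284,

with A = 1.25, p = 5 for ambient temperatures up to 23 deg C (the default
branch here) and A = 1.11, p = 10 for warmer environments.  ``cf`` is the
practitioner's corrective factor for coverage/surface contact.  Q is
strictly decreasing in t, so the PMI is the unique positive root, found
numerically.  The published best-case uncertainty band is +/-2.8 h.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

#: Best-case published uncertainty band, hours.
DEFAULT_UNCERTAINTY_H = 2.8
WARM_AMBIENT_THRESHOLD_C = 23.0


class NotApplicableError(ValueError):
    """The nomogram model does not apply to the given inputs."""


@dataclass(frozen=True)
class HenssgeConstants:
    """Branch constants of the double-exponential model (config values)."""

    A: float
    p: float
    b_scale: float = -1.2815
    b_exponent: float = -0.625
    b_offset: float = 0.0284


COOL_AMBIENT = HenssgeConstants(A=1.25, p=5.0)
WARM_AMBIENT = HenssgeConstants(A=1.11, p=10.0)


@dataclass(frozen=True)
class HenssgeInput:
    rectal_temp_C: float
    ambient_temp_C: float
    body_weight_kg: float
    corrective_factor: float = 1.0
    t0_C: float = 37.2
    fever_at_death: bool = False

    def __post_init__(self):
        if self.body_weight_kg <= 0:
            raise ValueError("body weight must be positive")
        if self.corrective_factor <= 0:
            raise ValueError("corrective factor must be positive")


@dataclass
class HenssgeResult:
    pmi_h: float
    uncertainty_h: float
    q: float
    branch: str


def henssge_pmi(inp: HenssgeInput,
                uncertainty_h: float = DEFAULT_UNCERTAINTY_H,
                warm_branch: bool | None = None) -> HenssgeResult:
    """Solve the standard cooling model for the PMI.

    ``warm_branch=None`` selects the branch from the ambient temperature;
    the cool-ambient branch applies up to 23 deg C.  Raises
    :class:`NotApplicableError` when the model's preconditions fail
    (body temperature at death above the model's T0, or rectal temperature
    outside the ambient..T0 span).
    """
    if inp.fever_at_death:
        raise NotApplicableError(
            "body temperature at death exceeded the model's initial "
            "temperature (fever); the nomogram is not applicable")
    denom = inp.t0_C - inp.ambient_temp_C
    if denom <= 0:
        raise NotApplicableError(
            f"ambient temperature {inp.ambient_temp_C} deg C is not below "
            f"T0={inp.t0_C} deg C")
    q = (inp.rectal_temp_C - inp.ambient_temp_C) / denom
    if q >= 1.0:
        raise NotApplicableError(
            f"Q={q:.3f} >= 1: rectal temperature at or above T0 "
            "(t=0 boundary); not applicable")
    if q <= 0.0:
        raise NotApplicableError(
            f"Q={q:.3f} <= 0: rectal temperature at or below ambient "
            "(thermal equilibrium); not applicable")
    if warm_branch is None:
        warm_branch = inp.ambient_temp_C > WARM_AMBIENT_THRESHOLD_C
    consts = WARM_AMBIENT if warm_branch else COOL_AMBIENT

    b = (consts.b_scale
         * (inp.corrective_factor * inp.body_weight_kg) ** consts.b_exponent
         + consts.b_offset)
    if b >= 0:
        raise NotApplicableError(f"non-negative cooling constant B={b:.4f}")

    def q_of_t(t):
        return (consts.A * np.exp(b * t)
                - (consts.A - 1.0) * np.exp(consts.p * b * t)) - q

    t_hi = 1.0
    while q_of_t(t_hi) > 0:
        t_hi *= 2.0
        if t_hi > 1e4:
            raise NotApplicableError("no root below 10000 h")
    pmi = float(brentq(q_of_t, 0.0, t_hi, xtol=1e-4))
    return HenssgeResult(pmi, uncertainty_h, q,
                         "warm" if warm_branch else "cool")


@dataclass
class TimeOfDeathInterval:
    """Clock-time interval for the time of death."""

    clock: pd.Timestamp
    pmi_h: float
    uncertainty_h: float
    estimate: pd.Timestamp
    earliest: pd.Timestamp
    latest: pd.Timestamp

    def as_dict(self) -> dict:
        return {
            "measurement_clock": self.clock.isoformat(),
            "pmi_h": self.pmi_h,
            "uncertainty_h": self.uncertainty_h,
            "estimate": self.estimate.isoformat(),
            "earliest": self.earliest.isoformat(),
            "latest": self.latest.isoformat(),
        }


def time_of_death_interval(clock, pmi_h: float,
                           uncertainty_h: float) -> TimeOfDeathInterval:
    """Map a PMI +/- uncertainty at a measurement clock time to clock times.

    Crossing midnight is handled naturally by date arithmetic (day offsets
    are retained in the returned timestamps).
    """
    if pmi_h < 0 or uncertainty_h < 0:
        raise ValueError("pmi and uncertainty must be non-negative")
    clock = pd.Timestamp(clock)
    estimate = clock - pd.Timedelta(hours=pmi_h)
    return TimeOfDeathInterval(
        clock=clock, pmi_h=float(pmi_h), uncertainty_h=float(uncertainty_h),
        estimate=estimate,
        earliest=estimate - pd.Timedelta(hours=uncertainty_h),
        latest=estimate + pd.Timedelta(hours=uncertainty_h))
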