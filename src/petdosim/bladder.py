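"""Dynamic urinary-bladder model.

Activity excreted by the kidneys accumulates in the bladder, decays
physically, and is removed (instantaneously, to a configurable residual
fraction) every voiding interval.  With urine delivery described by a sum
of biological exponentials -- cumulative decay-corrected inflow

    B(t) = sum_i f_i * (1 - exp(-lambda_bio_i * t))

-- the bladder content between voids and its time integral have closed
forms per inter-void interval, so the residence time is evaluated
semi-analytically, summing intervals until the remaining tail is
negligible (< 1e-9 MBq.h/MBq).

The default calibrated urine kinetics are in
:data:`petdosim.simulate.DEFAULT_URINE_KINETICS`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import LN2
from .reference import Nuclide

__all__ = [
    "UrineKinetics",
    "VoidingSchedule",
    "bladder_residence_time",
    "extrapolate_voiding",
]

_TAIL_TOL = 1e-9


@dataclass(frozen=True)
class UrineKinetics:
    """Urinary excretion: (fraction, biological half-time h) components."""

    components: tuple  # ((fraction, half_time_h), ...)

    def __post_init__(self):
        comps = tuple((float(f), float(t)) for f, t in self.components)
        object.__setattr__(self, "components", comps)
        if not 0.0 <= self.excreted_fraction <= 1.0:
            raise ValueError("total excreted fraction must lie in [0, 1]")
        for f, t in comps:
            if f < 0:
                raise ValueError("component fractions must be non-negative")
            if t <= 0:
                raise ValueError("biological half-times must be positive")

    @property
    def excreted_fraction(self) -> float:
        return sum(f for f, _ in self.components)

    @property
    def rates(self) -> tuple:
        """(fraction, biological rate 1/h) pairs."""
        return tuple((f, LN2 / t) for f, t in self.components)


@dataclass(frozen=True)
class VoidingSchedule:
    """Voiding interval (h) and residual fraction left in the bladder."""

    interval_h: float
    residual_fraction: float = 0.0

    def __post_init__(self):
        if self.interval_h <= 0:
            raise ValueError("voiding interval must be positive")
        if not 0.0 <= self.residual_fraction < 1.0:
            raise ValueError("residual fraction must lie in [0, 1)")


def bladder_residence_time(
    kin: UrineKinetics, sched: VoidingSchedule, nuclide: Nuclide
) -> float:
    """Residence time (h) of the bladder contents under a voiding schedule."""
    lam_p = nuclide.lambda_phys
    T = sched.interval_h
    r = sched.residual_fraction
    rates = kin.rates

    tau = 0.0
    carried = 0.0  # activity left in the bladder just after the last void
    t0 = 0.0
    while True:
        t1 = t0 + T
        e0, e1 = math.exp(-lam_p * t0), math.exp(-lam_p * t1)
        # carried-over residual decays physically through the interval
        tau += carried * (1.0 - math.exp(-lam_p * T)) / lam_p
        end_carried = carried * math.exp(-lam_p * T)
        # fresh inflow: integral of exp(-lam_p t) * (B(t) - B(t0)) over (t0, t1)
        fresh_end = 0.0
        for f, lam_b in rates:
            mu = lam_p + lam_b
            g0, g1 = math.exp(-mu * t0), math.exp(-mu * t1)
            tau += f * (math.exp(-lam_b * t0) * (e0 - e1) / lam_p - (g0 - g1) / mu)
            fresh_end += f * (math.exp(-lam_b * t0) * e1 - g1)
        carried = r * (end_carried + fresh_end)
        t0 = t1
        # upper bound on everything still to come (future inflow + residual)
        remaining = carried / lam_p
        for f, lam_b in rates:
            remaining += f * math.exp(-(lam_p + lam_b) * t0) / lam_p
        if remaining < _TAIL_TOL:
            break
    return tau


def extrapolate_voiding(
    tau_measured: float,
    from_sched: VoidingSchedule,
    to_sched: VoidingSchedule,
    kin: UrineKinetics,
    nuclide: Nuclide,
) -> float:
    """Rescale a measured bladder residence time to another voiding schedule.

    Ratio extrapolation anchored to the measurement: the model supplies the
    ratio of residence times under the two schedules, the measurement the
    absolute scale.
    """
    denom = bladder_residence_time(kin, from_sched, nuclide)
    if denom <= 0:
        raise ValueError("model residence time under the measured schedule is zero")
    return tau_measured * bladder_residence_time(kin, to_sched, nuclide) / denom
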