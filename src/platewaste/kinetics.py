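"""Closed-form models of cumulative food-mass intake during a school lunch.

The cumulative intake ``e(t)`` is the integral of the instantaneous eating
speed ``v(t) = v0 + a0*t + x*t**2`` (grams per minute), giving

    e(t) = v0*t + a0*t**2/2 + x*t**3/3

with the integration constant fixed at zero (nothing has been eaten at
``t = 0``).  Setting ``x = 0`` recovers the decelerating quadratic model of
school-lunch eating measured in the literature; setting ``a0 = x = 0``
recovers constant-speed eating.  Speed is physically non-negative: on any
interval where the polynomial speed would be negative it is clamped to zero,
so cumulative intake never decreases.  For the pure quadratic model with
deceleration this produces a plateau at the speed-zero extremum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "IntakeModelParams",
    "IntakeSpeedRelation",
    "DEFAULT_GIRLS",
    "DEFAULT_BOYS",
    "cumulative_intake",
    "extremum_time",
    "max_intake",
    "doubled_deceleration",
    "solve_cubic_acceleration",
    "average_speed",
    "intake_from_speed",
    "speed_from_intake",
    "intake_summary",
]


@dataclass(frozen=True)
class IntakeModelParams:
    """Parameters of the cubic cumulative-intake model.

    Attributes
    ----------
    v0 : float
        Initial eating speed (g/min); must be non-negative.
    a0 : float
        Initial eating-speed acceleration (g/min^2); negative values model
        the measured deceleration over a meal.
    x : float
        Eating-speed acceleration of the cubic model (g/min^3); with the
        measured decelerations a small positive ``x`` lets the speed level
        off instead of reaching zero.
    """

    v0: float
    a0: float = 0.0
    x: float = 0.0

    def __post_init__(self) -> None:
        if self.v0 < 0:
            raise ValueError(f"initial speed v0 must be >= 0, got {self.v0}")

    def speed(self, t: float) -> float:
        """Instantaneous (unclamped) eating speed at time ``t`` (g/min)."""
        return self.v0 + self.a0 * t + self.x * t * t


@dataclass(frozen=True)
class IntakeSpeedRelation:
    """Linear relation between eating speed and total lunch intake.

    ``intake(v) = slope * v + intercept`` with the empirical school-lunch
    fit ``slope = 6.8`` min-equivalents and ``intercept = 125`` g.
    """

    slope: float = 6.8
    intercept: float = 125.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError(f"slope must be > 0, got {self.slope}")


#: Published school-lunch eating-rate measurements used as worked reference
#: cases: initial speed (g/min), reported deceleration (g/min^2, before the
#: integration-driven doubling), mean lunch intake (g) and duration (min).
DEFAULT_GIRLS = {"v0": 34.0, "reported_decel": -2.6, "intake": 258.0, "duration": 10.7}
DEFAULT_BOYS = {"v0": 42.0, "reported_decel": -2.7, "intake": 289.0, "duration": 8.8}


def _poly_intake(p: IntakeModelParams, t: float) -> float:
    return p.v0 * t + p.a0 * t * t / 2.0 + p.x * t ** 3 / 3.0


def _positive_speed_intervals(p: IntakeModelParams, t: float) -> list[tuple[float, float]]:
    """Sub-intervals of [0, t] on which the polynomial speed is positive."""
    # Real roots of x*s^2 + a0*s + v0 = 0 inside (0, t)
    roots: list[float] = []
    if p.x == 0.0:
        if p.a0 != 0.0:
            r = -p.v0 / p.a0
            if 0.0 < r < t:
                roots.append(r)
    else:
        disc = p.a0 * p.a0 - 4.0 * p.x * p.v0
        if disc >= 0.0:
            sq = math.sqrt(disc)
            for r in ((-p.a0 - sq) / (2.0 * p.x), (-p.a0 + sq) / (2.0 * p.x)):
                if 0.0 < r < t:
                    roots.append(r)
    cuts = [0.0] + sorted(set(roots)) + [t]
    out = []
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        if hi > lo and p.speed(0.5 * (lo + hi)) > 0.0:
            out.append((lo, hi))
    return out


def cumulative_intake(params: IntakeModelParams, t: float) -> float:
    """Cumulative food-mass intake (g) after ``t`` minutes of eating.

    Integrates the non-negative part of the model speed, so the result is
    monotone in ``t`` and plateaus wherever the polynomial speed would drop
    below zero (e.g. past the extremum of the decelerating quadratic model).

    Raises
    ------
    ValueError
        If ``t`` is negative.
    """
    if t < 0:
        raise ValueError(f"time t must be >= 0, got {t}")
    if t == 0:
        return 0.0
    return sum(_poly_intake(params, hi) - _poly_intake(params, lo)
               for lo, hi in _positive_speed_intervals(params, t))


def extremum_time(v0: float, a: float) -> float:
    """Time (min) at which the quadratic model's speed reaches zero.

    Solves ``v0 + a*t = 0``; defined only for deceleration ``a < 0``.
    """
    if a >= 0:
        raise ValueError("no extremum: speed never reaches zero for a >= 0")
    return v0 / (-a)


def max_intake(v0: float, a: float) -> float:
    """Maximal cumulative intake (g) of the decelerating quadratic model.

    Equals ``v0**2 / (2*|a|)``, the cumulative intake at the speed-zero
    extremum time.
    """
    if a >= 0:
        raise ValueError("intake is unbounded for a >= 0")
    return v0 * v0 / (2.0 * -a)


def doubled_deceleration(reported: float) -> float:
    """Convert a reported speed-model deceleration to the intake-model one.

    Studies fitting cumulative intake as ``k*t**2 + v0*t`` report ``k``;
    integrating ``v(t) = v0 + a*t`` shows the coefficient of ``t**2`` is
    ``a/2``, so the deceleration entering the speed model is ``2*k``.
    """
    return 2.0 * reported


def solve_cubic_acceleration(v0: float, a0: float, total_intake: float, t: float) -> float:
    """Cubic coefficient ``x`` (g/min^3) reproducing a known total intake.

    Rearranges ``e(t) = v0*t + a0*t**2/2 + x*t**3/3`` for ``x`` so that the
    cubic model passes through the observed ``(t, total_intake)`` point.
    """
    if t <= 0:
        raise ValueError(f"time t must be > 0, got {t}")
    return 3.0 * (total_intake - v0 * t - a0 * t * t / 2.0) / t ** 3


def average_speed(params: IntakeModelParams, t: float) -> float:
    """Mean eating speed (g/min) over ``[0, t]``: cumulative intake / t."""
    if t <= 0:
        raise ValueError(f"time t must be > 0, got {t}")
    return cumulative_intake(params, t) / t


def intake_from_speed(rel: IntakeSpeedRelation, v: float) -> float:
    """Expected lunch intake (g) for an average eating speed ``v`` (g/min)."""
    if v < 0:
        raise ValueError(f"speed v must be >= 0, got {v}")
    return rel.slope * v + rel.intercept


def speed_from_intake(rel: IntakeSpeedRelation, intake: float) -> float:
    """Average eating speed (g/min) implied by a lunch intake (g).

    Inverse of :func:`intake_from_speed`; may be negative for intakes below
    the intercept, which callers should treat as outside the fitted range.
    """
    return (intake - rel.intercept) / rel.slope


def intake_summary(v0: float, reported_decel: float, intake: float, duration: float) -> dict:
    """Worked intake-kinetics table for one measured group.

    Doubles the reported deceleration, locates the quadratic model's
    extremum and maximal intake, recalibrates the cubic coefficient so the
    model reproduces the observed mean intake at the observed mean duration,
    and reports the resulting average speed.
    """
    a0 = doubled_deceleration(reported_decel)
    t_star = extremum_time(v0, a0)
    x = solve_cubic_acceleration(v0, a0, intake, duration)
    params = IntakeModelParams(v0=v0, a0=a0, x=x)
    return {
        "v0_g_min": v0,
        "deceleration_g_min2": a0,
        "extremum_time_min": t_star,
        "max_quadratic_intake_g": max_intake(v0, a0),
        "cubic_x_g_min3": x,
        "mean_intake_g": intake,
        "mean_duration_min": duration,
        "average_speed_g_min": average_speed(params, duration),
    }
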