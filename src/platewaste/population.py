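"""Generation of child agents: eating rates, habits and food preferences.

Each child carries a solid-food eating rate (liquids are consumed twice as
fast), a competitive-food flag (the child also eats home food, the optional
school menu or food bought outside), a satisfaction flag, a five-day
hated-menu vector marking weekdays on which the served food is rejected,
and a stop/continue disposition when lunch time runs out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Child",
    "PopulationConfig",
    "SURVEY_COMPETITIVE_YES_PERCENT",
    "competitive_food_probability",
    "generate_child",
    "generate_hated_days",
    "generate_population",
]

#: Parent-survey "yes" shares (%) for the three competitive-food sources:
#: home food, the school optional menu, food bought outside the school.
SURVEY_COMPETITIVE_YES_PERCENT = (12.5, 33.3, 16.7)


def competitive_food_probability(
    yes_percent: tuple[float, ...] = SURVEY_COMPETITIVE_YES_PERCENT,
) -> float:
    """Pooled probability (%) that a child eats competitive food.

    The mean of the per-source "yes" shares; display code rounds it to the
    whole percent.
    """
    return float(np.mean(yes_percent))


@dataclass(frozen=True)
class Child:
    """One simulated child."""

    vs: float                    # solid-food eating rate (g/min)
    vl: float                    # liquid-food eating rate (g/min), 2 * vs
    ef: int                      # eats competitive food (0/1)
    u: int                       # unsatisfied with school food (0/1)
    hated_days: tuple[int, ...]  # weekday rejection flags, length 5
    stops_when_out_of_time: int  # stops eating when time runs out (0/1)

    def __post_init__(self) -> None:
        if self.vs <= 0:
            raise ValueError(f"eating rate vs must be > 0, got {self.vs}")
        if len(self.hated_days) != 5 or any(d not in (0, 1) for d in self.hated_days):
            raise ValueError("hated_days must be five 0/1 flags")


@dataclass(frozen=True)
class PopulationConfig:
    """Survey-derived behavioural parameters of the child generator.

    Defaults: 27% of children unsatisfied with school food, 30% eating
    competitive food, a compromise eating rate of 35(5) g/min, 67% stopping
    when lunch time runs out, and hated-day counts of 3(0.5) days per week
    for unsatisfied children versus 0(0.5) for satisfied ones.
    """

    pr_unsatisfied: float = 0.27
    ef_prob: float = 0.30
    rate_mean: float = 35.0
    rate_sd: float = 5.0
    stop_prob: float = 0.67
    hated_mean_unsatisfied: float = 3.0
    hated_sd_unsatisfied: float = 0.5
    hated_mean_satisfied: float = 0.0
    hated_sd_satisfied: float = 0.5

    def __post_init__(self) -> None:
        for name in ("pr_unsatisfied", "ef_prob", "stop_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.rate_mean <= 0:
            raise ValueError(f"rate_mean must be > 0, got {self.rate_mean}")


def generate_hated_days(
    u: int, cfg: PopulationConfig, rng: np.random.Generator
) -> tuple[int, ...]:
    """Draw the five-day hated-menu vector for a (un)satisfied child.

    The weekly count ``h`` is drawn from the satisfaction-appropriate
    normal, clamped to [0, 5] and rounded to the nearest integer; ``h``
    distinct weekdays chosen uniformly at random are flagged.

    The normal deviate and the weekday permutation are always drawn, so the
    generator consumes a fixed number of random variates regardless of
    ``u`` — this keeps coupled-replay comparisons across scenarios exact.
    """
    if u:
        h = rng.normal(cfg.hated_mean_unsatisfied, cfg.hated_sd_unsatisfied)
    else:
        h = rng.normal(cfg.hated_mean_satisfied, cfg.hated_sd_satisfied)
    count = int(round(min(5.0, max(0.0, h))))
    order = rng.permutation(5)
    days = [0] * 5
    for day in order[:count]:
        days[day] = 1
    return tuple(days)


def generate_child(cfg: PopulationConfig, rng: np.random.Generator) -> Child:
    """Generate one child agent.

    The solid-food rate is normal(rate_mean, rate_sd) with negative draws
    rejected and resampled; the liquid rate is exactly double (soups and
    drinks go down faster).  Flags are Bernoulli draws implemented as
    uniform-threshold comparisons so that raising a probability can only
    flip flags from 0 to 1 under a shared random stream.
    """
    vs = rng.normal(cfg.rate_mean, cfg.rate_sd)
    while vs <= 0:
        vs = rng.normal(cfg.rate_mean, cfg.rate_sd)
    ef = int(rng.random() < cfg.ef_prob)
    u = int(rng.random() < cfg.pr_unsatisfied)
    hated = generate_hated_days(u, cfg, rng)
    stops = int(rng.random() < cfg.stop_prob)
    return Child(vs=vs, vl=2.0 * vs, ef=ef, u=u, hated_days=hated,
                 stops_when_out_of_time=stops)


def generate_population(
    n: int, cfg: PopulationConfig, rng: np.random.Generator
) -> list[Child]:
    """Generate ``n`` independent children; deterministic for a fixed rng."""
    if n < 1:
        raise ValueError(f"population size must be >= 1, got {n}")
    return [generate_child(cfg, rng) for _ in range(n)]
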