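"""Monte Carlo driver: week-level simulation, repetitions, scenario sweeps.

One repetition is the interaction of one child with one week menu: five
daily portions pass through the three-stage waste decomposition at the
effective eating time (nominal lunch duration minus walking time).  The
scenario inputs are the lunch duration and the share of children
unsatisfied with school food; repeating the pairing many times yields the
expected weekly plate-waste fraction and its Monte Carlo error, and sweeping
the two inputs produces the surfaces used to reason about lunch scheduling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .menu_gen import COMPONENTS, MenuConfig, WeekMenu, default_menu_config, generate_week
from .population import Child, PopulationConfig, generate_child
from .waste_model import (
    CompetitiveImpactConfig,
    WasteBreakdown,
    WasteFractionConfig,
    simulate_child_day,
)

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "SweepGrid",
    "OptimalDurationResult",
    "effective_duration",
    "run_week",
    "run_simulation",
    "sweep_grid",
    "optimal_duration",
]


def effective_duration(nominal: float, walking_delay: float) -> float:
    """Eating time (min) left after walking to and from the canteen."""
    if nominal <= 0:
        raise ValueError(f"nominal lunch duration must be > 0, got {nominal}")
    return max(0.0, nominal - walking_delay)


@dataclass(frozen=True)
class SimulationConfig:
    """Scenario, behavioural and distribution parameters of one simulation.

    ``pr_unsatisfied`` and ``ef_prob`` are the scenario-level values and
    override the corresponding population defaults at run time.  In
    ``ideal_mode`` competitive food, hated days and the stable soup/main
    skips are all disabled, so only insufficient time produces waste.
    """

    lunch_duration: float = 25.0
    pr_unsatisfied: float = 0.27
    ef_prob: float = 0.30
    repetitions: int = 10_000
    walking_delay: float = 6.0
    seed: int = 0
    ideal_mode: bool = False
    menu: MenuConfig = field(default_factory=default_menu_config)
    population: PopulationConfig = field(default_factory=PopulationConfig)
    waste_fractions: WasteFractionConfig = field(default_factory=WasteFractionConfig)
    competitive: CompetitiveImpactConfig = field(default_factory=CompetitiveImpactConfig)

    def __post_init__(self) -> None:
        if self.lunch_duration <= 0:
            raise ValueError(f"lunch_duration must be > 0, got {self.lunch_duration}")
        if self.repetitions < 1:
            raise ValueError(f"repetitions must be >= 1, got {self.repetitions}")
        if self.walking_delay < 0:
            raise ValueError(f"walking_delay must be >= 0, got {self.walking_delay}")
        for name in ("pr_unsatisfied", "ef_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")


@dataclass(frozen=True)
class SimulationResult:
    """Aggregate of one Monte Carlo run.

    Waste fractions are mass-weighted: per repetition the weekly waste
    grams are divided by the weekly served grams, then averaged over
    repetitions.  ``mean_waste_fraction_excl_ld`` re-reports the same
    simulated weeks with the liquid dessert removed from both numerator and
    denominator (a reporting convention, not a model change).
    """

    n_reps: int
    t_avail: float
    mean_waste_fraction: float
    sd_waste_fraction: float
    se_waste_fraction: float
    quantiles: dict
    mean_waste_fraction_excl_ld: float
    mean_weekly_portion_g: float
    mean_weekly_waste_g: float
    by_cause: dict        # cause -> mean fraction of served mass
    by_component: dict    # component -> mean wasted fraction of that component
    fractions: np.ndarray  # per-repetition weekly waste fractions

    def to_dict(self) -> dict:
        return {
            "n_reps": self.n_reps,
            "t_avail_min": self.t_avail,
            "mean_waste_fraction": self.mean_waste_fraction,
            "sd_waste_fraction": self.sd_waste_fraction,
            "se_waste_fraction": self.se_waste_fraction,
            "quantiles": self.quantiles,
            "mean_waste_fraction_excl_ld": self.mean_waste_fraction_excl_ld,
            "mean_weekly_portion_g": self.mean_weekly_portion_g,
            "mean_weekly_waste_g": self.mean_weekly_waste_g,
            "by_cause": self.by_cause,
            "by_component": self.by_component,
        }


def run_week(
    child: Child,
    menu: WeekMenu,
    t_avail: float,
    waste_cfg: WasteFractionConfig,
    competitive_cfg: CompetitiveImpactConfig,
    rng: np.random.Generator,
) -> WasteBreakdown:
    """Simulate one child through one week menu; totals conserve mass."""
    week = WasteBreakdown.zero()
    for day_index, portion in enumerate(menu):
        week = week + simulate_child_day(
            portion, child, day_index, t_avail, waste_cfg, competitive_cfg, rng
        )
    return week


def _scenario_configs(cfg: SimulationConfig):
    """Resolve scenario overrides (and ideal mode) into stage configs."""
    pop = replace(cfg.population, pr_unsatisfied=cfg.pr_unsatisfied, ef_prob=cfg.ef_prob)
    waste = cfg.waste_fractions
    if cfg.ideal_mode:
        # All children satisfied, no competitive food, no stable dislikes:
        # only insufficient time produces waste.
        pop = replace(pop, pr_unsatisfied=0.0, ef_prob=0.0,
                      hated_mean_satisfied=0.0, hated_sd_satisfied=0.0,
                      hated_mean_unsatisfied=0.0, hated_sd_unsatisfied=0.0)
        waste = replace(waste, soup_skip_prob=0.0, main_skip_prob=0.0)
    return pop, waste


def run_simulation(cfg: SimulationConfig) -> SimulationResult:
    """Run ``cfg.repetitions`` independent (child, week-menu) pairs.

    Each repetition derives three independent random streams (child, menu,
    waste draws) from ``(seed, repetition index)``, so results are
    bit-reproducible for a fixed seed and scenario changes can be replayed
    against identical draws.
    """
    pop_cfg, waste_cfg = _scenario_configs(cfg)
    t_avail = effective_duration(cfg.lunch_duration, cfg.walking_delay)

    n = cfg.repetitions
    fractions = np.empty(n)
    ld_idx = COMPONENTS.index("ld")
    sum_portion = np.zeros(len(COMPONENTS))
    sum_by_cause = {"competitive": 0.0, "rejected": 0.0, "time": 0.0}
    sum_waste_comp = np.zeros(len(COMPONENTS))
    excl_waste = 0.0
    excl_portion = 0.0

    for rep in range(n):
        streams = np.random.SeedSequence([cfg.seed, rep]).spawn(3)
        rng_child = np.random.default_rng(streams[0])
        rng_menu = np.random.default_rng(streams[1])
        rng_waste = np.random.default_rng(streams[2])

        child = generate_child(pop_cfg, rng_child)
        menu = generate_week(cfg.menu, rng_menu)
        week = run_week(child, menu, t_avail, waste_cfg, cfg.competitive, rng_waste)

        portion = week.portion
        waste = week.total_waste
        fractions[rep] = week.waste_fraction
        sum_portion += portion
        sum_waste_comp += waste
        sum_by_cause["competitive"] += float(week.w_ef.sum())
        sum_by_cause["rejected"] += float(week.w_h.sum())
        sum_by_cause["time"] += float(week.w_t.sum())
        excl_waste += float(waste.sum() - waste[ld_idx])
        excl_portion += float(portion.sum() - portion[ld_idx])

    total_served = float(sum_portion.sum())
    mean = float(fractions.mean())
    sd = float(fractions.std(ddof=1)) if n > 1 else 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        by_component = {
            c: (float(sum_waste_comp[i] / sum_portion[i]) if sum_portion[i] > 0 else 0.0)
            for i, c in enumerate(COMPONENTS)
        }
    return SimulationResult(
        n_reps=n,
        t_avail=t_avail,
        mean_waste_fraction=mean,
        sd_waste_fraction=sd,
        se_waste_fraction=sd / np.sqrt(n) if n > 1 else 0.0,
        quantiles={q: float(np.quantile(fractions, q)) for q in (0.05, 0.25, 0.5, 0.75, 0.95)},
        mean_waste_fraction_excl_ld=(excl_waste / excl_portion if excl_portion > 0 else 0.0),
        mean_weekly_portion_g=total_served / n,
        mean_weekly_waste_g=float(sum_waste_comp.sum()) / n,
        by_cause={k: v / total_served for k, v in sum_by_cause.items()},
        by_component=by_component,
        fractions=fractions,
    )


@dataclass(frozen=True)
class SweepGrid:
    """Mean waste fraction over a (lunch duration x unsatisfied share) grid."""

    durations: tuple[float, ...]
    shares: tuple[float, ...]
    mean: np.ndarray  # shape (len(durations), len(shares))
    se: np.ndarray
    n_reps: int

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "duration_min": d,
                "unsatisfied_share": s,
                "mean_waste_frac": float(self.mean[i, j]),
                "se": float(self.se[i, j]),
                "n_reps": self.n_reps,
            }
            for i, d in enumerate(self.durations)
            for j, s in enumerate(self.shares)
        ]
        return pd.DataFrame(rows)


def _cell_seed(base_seed: int, i: int, j: int) -> int:
    return int(np.random.SeedSequence([base_seed, i, j]).generate_state(1)[0] % 2**31)


def sweep_grid(durations, shares, cfg: SimulationConfig) -> SweepGrid:
    """Run one simulation per (duration, unsatisfied share) grid cell.

    Cell seeds are derived from ``(cfg.seed, cell index)``; the grid is
    bit-reproducible for a fixed base seed regardless of evaluation order.
    """
    durations = tuple(float(d) for d in durations)
    shares = tuple(float(s) for s in shares)
    if not durations or not shares:
        raise ValueError("sweep axes must be non-empty")
    mean = np.empty((len(durations), len(shares)))
    se = np.empty_like(mean)
    for i, d in enumerate(durations):
        for j, s in enumerate(shares):
            cell_cfg = replace(
                cfg, lunch_duration=d, pr_unsatisfied=s, seed=_cell_seed(cfg.seed, i, j)
            )
            res = run_simulation(cell_cfg)
            mean[i, j] = res.mean_waste_fraction
            se[i, j] = res.se_waste_fraction
    return SweepGrid(durations=durations, shares=shares, mean=mean, se=se,
                     n_reps=cfg.repetitions)


@dataclass(frozen=True)
class OptimalDurationResult:
    """Waste-versus-duration curve under ideal conditions."""

    optimal_duration: float
    threshold: float
    reached: bool
    durations: tuple[float, ...]
    mean_waste_fractions: tuple[float, ...]


def optimal_duration(
    cfg: SimulationConfig,
    rate_mean: float = 27.0,
    rate_sd: float = 2.0,
    threshold: float = 0.02,
    durations=None,
) -> OptimalDurationResult:
    """Minimal eating duration keeping expected waste below ``threshold``.

    Runs the simulator in ideal mode (all children satisfied, no
    competitive food) with the given eating rate, on a 1-minute duration
    grid of pure eating time (no walking adjustment), and returns the
    smallest duration whose mean waste fraction falls below the threshold.
    If the threshold is never reached the grid maximum is returned with a
    warning.
    """
    if durations is None:
        durations = np.arange(8.0, 41.0)
    durations = tuple(float(d) for d in durations)
    pop = replace(cfg.population, rate_mean=rate_mean, rate_sd=rate_sd)
    means = []
    for d in durations:
        run_cfg = replace(cfg, lunch_duration=d, walking_delay=0.0, ideal_mode=True,
                          population=pop)
        means.append(run_simulation(run_cfg).mean_waste_fraction)
    for d, m in zip(durations, means):
        if m < threshold:
            return OptimalDurationResult(d, threshold, True, durations, tuple(means))
    warnings.warn(
        f"waste threshold {threshold} not reached on the duration grid; "
        "returning the grid maximum"
    )
    return OptimalDurationResult(durations[-1], threshold, False, durations, tuple(means))
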