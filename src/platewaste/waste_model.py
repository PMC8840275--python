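"""Three-stage decomposition of a lunch portion into eaten food and waste.

For one child and one daily portion the served mass is split, component by
component, into

    portion = eaten + w_ef + w_h + w_t

where ``w_ef`` is waste displaced by competitive food, ``w_h`` is rejected
(hated) food, and ``w_t`` is food left because lunch time ran out.  The
stages are applied in that order; rejected food is capped by what
competitive food left on the plate (a child already filled elsewhere cannot
reject more than remains), and the time stage acts on the remainder the
child still intends to eat.  The identity above holds exactly on every
simulated child-day.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .menu_gen import COMPONENTS, LIQUID_COMPONENTS, MealPortion
from .population import Child

__all__ = [
    "CompetitiveImpactConfig",
    "WasteFractionConfig",
    "WasteBreakdown",
    "competitive_impact",
    "rejected_impact",
    "time_limited_waste",
    "simulate_child_day",
]

_LIQUID_MASK = np.array([name in LIQUID_COMPONENTS for name in COMPONENTS])
_MILK_IDX = COMPONENTS.index("mk")

#: Survey shares (%) of how much of the packaged lunch children still eat
#: when competitive food is present, per consumed-share bin (0-24, 25-49,
#: 50-74, 75-100), averaged over the two competitive-food sources; used by
#: the ``complement`` semantics.
_SURVEY_EATEN_BIN_WEIGHTS = (
    (22.2 + 25.0) / 2,
    (11.1 + 25.0) / 2,
    (33.3 + 25.0) / 2,
    (33.3 + 25.0) / 2,
)


@dataclass(frozen=True)
class CompetitiveImpactConfig:
    """Parameters of the competitive-food waste stage.

    ``k_values`` are the midpoints of the survey's quartile share bins;
    one is drawn uniformly per child-day and each component loses a
    normal(k, k_sd) fraction of its mass (clamped to [0, 1]).  Under the
    alternative ``complement`` semantics the drawn fraction is the share
    still *eaten* (bins weighted by the survey answers) and the waste is
    its complement.
    """

    k_values: tuple[float, ...] = (0.12, 0.37, 0.62, 0.87)
    k_sd: float = 0.06
    semantics: str = "literal"  # or "complement"

    def __post_init__(self) -> None:
        if any(not 0.0 <= k <= 1.0 for k in self.k_values):
            raise ValueError(f"k_values must lie in [0, 1], got {self.k_values}")
        if self.semantics not in ("literal", "complement"):
            raise ValueError(f"unknown competitive semantics {self.semantics!r}")


@dataclass(frozen=True)
class WasteFractionConfig:
    """Rejected-food waste fractions per category, plus stable dislikes.

    ``fractions`` maps each component to the (mean, sd) of the normal
    fraction of its mass wasted on a hated day (sd 0 denotes a constant);
    draws are clamped to [0, 1].  Milk has no observed rejected-waste
    category and defaults to 0.  Independently of hated days, a child skips
    the whole soup with probability 0.5 and the whole main dish with
    probability 0.08 (stable dislikes); set ``skips_on_hated_days_only`` to
    confine those skips to hated days.
    """

    fractions: dict = field(default_factory=lambda: dict(_DEFAULT_FRACTIONS))
    soup_skip_prob: float = 0.5
    main_skip_prob: float = 0.08
    skips_on_hated_days_only: bool = False

    def __post_init__(self) -> None:
        missing = set(COMPONENTS) - set(self.fractions)
        if missing:
            raise ValueError(f"missing waste fractions for components: {sorted(missing)}")
        for name in ("soup_skip_prob", "main_skip_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")

    def means(self) -> np.ndarray:
        return np.array([self.fractions[c][0] for c in COMPONENTS], dtype=float)

    def sds(self) -> np.ndarray:
        return np.array([self.fractions[c][1] for c in COMPONENTS], dtype=float)


_DEFAULT_FRACTIONS: dict[str, tuple[float, float]] = {
    "m": (0.30, 0.05),
    "s": (0.15, 0.03),
    "sd": (0.02, 0.0),
    "ld": (0.35, 0.07),
    "b": (0.05, 0.0),
    "fp": (0.30, 0.10),
    "mk": (0.0, 0.0),
}


@dataclass(frozen=True)
class WasteBreakdown:
    """Per-component split of one portion into eaten food and waste causes."""

    eaten: np.ndarray
    w_ef: np.ndarray
    w_h: np.ndarray
    w_t: np.ndarray

    @property
    def portion(self) -> np.ndarray:
        return self.eaten + self.w_ef + self.w_h + self.w_t

    @property
    def total_waste(self) -> np.ndarray:
        return self.w_ef + self.w_h + self.w_t

    @property
    def waste_fraction(self) -> float:
        served = float(self.portion.sum())
        return float(self.total_waste.sum()) / served if served > 0 else 0.0

    def __add__(self, other: "WasteBreakdown") -> "WasteBreakdown":
        return WasteBreakdown(
            eaten=self.eaten + other.eaten,
            w_ef=self.w_ef + other.w_ef,
            w_h=self.w_h + other.w_h,
            w_t=self.w_t + other.w_t,
        )

    @classmethod
    def zero(cls) -> "WasteBreakdown":
        z = np.zeros(len(COMPONENTS))
        return cls(eaten=z.copy(), w_ef=z.copy(), w_h=z.copy(), w_t=z.copy())


def competitive_impact(
    portion: MealPortion,
    child: Child,
    cfg: CompetitiveImpactConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Grams of each component displaced by competitive food.

    Zero for children who do not eat competitive food.  Milk is never
    displaced (it is not part of the packaged meal the competitive food
    replaces).  All random variates are drawn even when the result is zero,
    keeping the stream layout independent of the child's flags.
    """
    p = portion.as_array()
    if cfg.semantics == "literal":
        k = cfg.k_values[int(rng.integers(len(cfg.k_values)))]
        frac = np.clip(rng.normal(k, cfg.k_sd, size=len(COMPONENTS)), 0.0, 1.0)
    else:
        weights = np.asarray(_SURVEY_EATEN_BIN_WEIGHTS, dtype=float)
        weights = weights / weights.sum()
        u = rng.random()
        k = cfg.k_values[int(np.searchsorted(np.cumsum(weights), u))]
        eaten_frac = np.clip(rng.normal(k, cfg.k_sd, size=len(COMPONENTS)), 0.0, 1.0)
        frac = 1.0 - eaten_frac
    if not child.ef:
        return np.zeros(len(COMPONENTS))
    w_ef = p * frac
    w_ef[_MILK_IDX] = 0.0
    return w_ef


def rejected_impact(
    portion: MealPortion,
    w_ef: np.ndarray,
    day_hated: int,
    cfg: WasteFractionConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Grams of each component wasted as rejected food.

    On a hated day each component loses its category fraction of the served
    mass; the whole-soup and whole-main-dish skips are then drawn (every
    day by default).  Finally the result is capped at what competitive food
    left on the plate: ``w_h <= portion - w_ef`` componentwise, floored at
    zero.
    """
    p = portion.as_array()
    frac = np.clip(rng.normal(cfg.means(), cfg.sds()), 0.0, 1.0)
    soup_skip = rng.random() < cfg.soup_skip_prob
    main_skip = rng.random() < cfg.main_skip_prob

    w_h = p * frac if day_hated else np.zeros(len(COMPONENTS))
    if day_hated or not cfg.skips_on_hated_days_only:
        if soup_skip:
            w_h[COMPONENTS.index("s")] = p[COMPONENTS.index("s")]
        if main_skip:
            w_h[COMPONENTS.index("m")] = p[COMPONENTS.index("m")]
    return np.clip(np.minimum(w_h, p - w_ef), 0.0, None)


def time_limited_waste(
    remaining: np.ndarray, child: Child, t_avail: float
) -> np.ndarray:
    """Grams of each component left uneaten because lunch time ran out.

    The child eats the remaining food in serving order (main part, dessert,
    then bread / fresh product / milk), liquids at ``vl`` and solids at
    ``vs``.  If the available time covers everything there is no time
    waste; otherwise a child who stops when time runs out wastes the
    unconsumed remainder, while one who eats on (arriving late to class)
    wastes nothing to time.
    """
    if t_avail < 0:
        raise ValueError(f"available time must be >= 0, got {t_avail}")
    remaining = np.asarray(remaining, dtype=float)
    rates = np.where(_LIQUID_MASK, child.vl, child.vs)
    eaten = np.zeros_like(remaining)
    t_left = float(t_avail)
    for i in range(len(remaining)):
        if t_left <= 0:
            break
        can_eat = min(remaining[i], rates[i] * t_left)
        eaten[i] = can_eat
        t_left -= can_eat / rates[i]
    unfinished = remaining - eaten
    if unfinished.sum() <= 0 or not child.stops_when_out_of_time:
        return np.zeros_like(remaining)
    return unfinished


def simulate_child_day(
    portion: MealPortion,
    child: Child,
    day_index: int,
    t_avail: float,
    waste_cfg: WasteFractionConfig,
    competitive_cfg: CompetitiveImpactConfig,
    rng: np.random.Generator,
) -> WasteBreakdown:
    """Run the three waste stages for one child on one day.

    Applies the competitive-food stage, then the rejected-food stage using
    the child's hated-day flag for ``day_index``, then the time stage on
    whatever the child still intends to eat.  The returned breakdown
    satisfies conservation exactly.
    """
    p = portion.as_array()
    w_ef = competitive_impact(portion, child, competitive_cfg, rng)
    w_h = rejected_impact(portion, w_ef, child.hated_days[day_index], waste_cfg, rng)
    intended = p - w_ef - w_h
    w_t = time_limited_waste(intended, child, t_avail)
    eaten = intended - w_t
    return WasteBreakdown(eaten=eaten, w_ef=w_ef, w_h=w_h, w_t=w_t)
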