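"""Stochastic generation of daily school-lunch portions and week menus.

A regulated Latvian school lunch is one of three compositions — main dish
plus soup (MS), main dish plus dessert (MD), or soup plus dessert (SD) —
served with a dessert, optionally bread, and exactly one of {fresh product,
milk, nothing}.  Each component mass is drawn from a bounded distribution
distilled from published weekly menus; a portion is the seven-component
vector (m, s, sd, ld, b, fp, mk) and the served mass is their sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "COMPONENTS",
    "LIQUID_COMPONENTS",
    "MealPortion",
    "ComponentDistribution",
    "MenuConfig",
    "WeekMenu",
    "OBSERVED_WEEK_MENU",
    "default_menu_config",
    "draw_component",
    "draw_menu_type",
    "generate_portion",
    "generate_week",
    "portion_mass",
]

#: Component order used by every 7-vector in the package: main dish, soup,
#: solid dessert, liquid dessert, bread, fresh product, milk.
COMPONENTS = ("m", "s", "sd", "ld", "b", "fp", "mk")

#: Components consumed at the liquid eating rate (soup, drinks).
LIQUID_COMPONENTS = ("s", "ld", "mk")

MENU_TYPES = ("MS", "MD", "SD")
DESSERT_TYPES = ("solid", "liquid", "both")
OPTIONAL_TYPES = ("fp", "mk", "none")

_MAX_REJECTION_DRAWS = 100_000


@dataclass(frozen=True)
class MealPortion:
    """One day's lunch portion, component masses in grams."""

    m: float = 0.0
    s: float = 0.0
    sd: float = 0.0
    ld: float = 0.0
    b: float = 0.0
    fp: float = 0.0
    mk: float = 0.0

    def __post_init__(self) -> None:
        for name in COMPONENTS:
            if getattr(self, name) < 0:
                raise ValueError(f"portion component {name!r} must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in COMPONENTS], dtype=float)

    @property
    def total(self) -> float:
        return float(sum(getattr(self, name) for name in COMPONENTS))


@dataclass(frozen=True)
class ComponentDistribution:
    """Bounded sampling distribution for one portion component.

    ``family`` is one of ``normal``, ``gumbel``, ``exponential-shifted`` or
    ``constant``.  ``loc``/``scale`` are in grams (for the shifted
    exponential, ``loc`` is the support start and ``scale`` the exponential
    scale).  Samples are guaranteed to lie in ``bounds`` by rejection
    sampling, which preserves the distribution's shape inside the interval.
    """

    family: str
    loc: float
    scale: float = 0.0
    bounds: tuple[float, float] = (0.0, float("inf"))

    def __post_init__(self) -> None:
        if self.family not in ("normal", "gumbel", "exponential-shifted", "constant"):
            raise ValueError(f"unknown distribution family {self.family!r}")
        if self.bounds[0] > self.bounds[1]:
            raise ValueError(f"invalid bounds {self.bounds}: min > max")


def draw_component(dist: ComponentDistribution, rng: np.random.Generator) -> float:
    """Draw one component mass (g), rejected-resampled into its bounds."""
    if dist.family == "constant":
        return float(dist.loc)
    lo, hi = dist.bounds
    for _ in range(_MAX_REJECTION_DRAWS):
        if dist.family == "normal":
            value = rng.normal(dist.loc, dist.scale)
        elif dist.family == "gumbel":
            value = rng.gumbel(dist.loc, dist.scale)
        else:  # exponential-shifted
            value = dist.loc + rng.exponential(dist.scale)
        if lo <= value <= hi:
            return float(value)
    raise RuntimeError(f"rejection sampling failed for {dist}")


@dataclass(frozen=True)
class MenuConfig:
    """Probabilities and component distributions of the portion generator."""

    menu_type_probs: tuple[float, float, float] = (0.65, 0.30, 0.05)  # MS, MD, SD
    bread_prob: float = 0.5
    dessert_type_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)  # solid, liquid, both
    optional_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)  # fp, mk, none
    distributions: dict = field(default_factory=lambda: dict(_DEFAULT_DISTRIBUTIONS))

    def __post_init__(self) -> None:
        for name, probs in (
            ("menu_type_probs", self.menu_type_probs),
            ("dessert_type_probs", self.dessert_type_probs),
            ("optional_probs", self.optional_probs),
        ):
            if any(p < 0 or p > 1 for p in probs):
                raise ValueError(f"{name} entries must be in [0, 1], got {probs}")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1, got {probs}")
        if not 0 <= self.bread_prob <= 1:
            raise ValueError(f"bread_prob must be in [0, 1], got {self.bread_prob}")
        missing = set(_DEFAULT_DISTRIBUTIONS) - set(self.distributions)
        if missing:
            raise ValueError(f"missing component distributions: {sorted(missing)}")


_DEFAULT_DISTRIBUTIONS: dict[str, ComponentDistribution] = {
    # Marginal distributions (grams), used when a component stands alone.
    "main": ComponentDistribution("gumbel", 225.0, 37.5, (150.0, 430.0)),
    "soup": ComponentDistribution("normal", 225.0, 37.5, (150.0, 300.0)),
    "solid_dessert": ComponentDistribution("normal", 75.0, 12.5, (50.0, 100.0)),
    "liquid_dessert": ComponentDistribution("normal", 200.0, 25.0, (150.0, 250.0)),
    "bread": ComponentDistribution("exponential-shifted", 20.0, 1.2, (20.0, 35.0)),
    "fresh_product": ComponentDistribution("normal", 75.0, 12.5, (50.0, 100.0)),
    "milk": ComponentDistribution("constant", 200.0),
    # Joint category: a main dish served together with soup is smaller.
    "ms_main": ComponentDistribution("normal", 200.0, 25.0, (150.0, 250.0)),
    "ms_soup": ComponentDistribution("normal", 175.0, 12.5, (150.0, 200.0)),
    # Joint category: solid and liquid dessert served together.
    "both_solid_dessert": ComponentDistribution("normal", 32.5, 8.75, (15.0, 50.0)),
    "both_liquid_dessert": ComponentDistribution("normal", 150.0, 25.0, (100.0, 200.0)),
}


def default_menu_config() -> MenuConfig:
    """Menu configuration distilled from the reviewed published menus."""
    return MenuConfig()


def draw_menu_type(cfg: MenuConfig, rng: np.random.Generator) -> str:
    """Draw the day's menu composition label: 'MS', 'MD' or 'SD'."""
    return MENU_TYPES[_categorical(cfg.menu_type_probs, rng)]


def _categorical(probs, rng: np.random.Generator) -> int:
    u = rng.random()
    acc = 0.0
    for i, p in enumerate(probs):
        acc += p
        if u < acc:
            return i
    return len(probs) - 1


def generate_portion(cfg: MenuConfig, rng: np.random.Generator) -> MealPortion:
    """Generate one daily portion.

    The mandatory part follows the menu type (MS draws the joint
    main-dish-and-soup pair, MD only the main dish, SD only the soup).  A
    dessert is always served, its type uniform over solid / liquid / both.
    Bread appears with probability ``bread_prob``, and exactly one of fresh
    product, milk or nothing is added.
    """
    d = cfg.distributions
    m = s = sd = ld = b = fp = mk = 0.0

    menu_type = draw_menu_type(cfg, rng)
    if menu_type == "MD":
        m = draw_component(d["main"], rng)
    elif menu_type == "SD":
        s = draw_component(d["soup"], rng)
    else:  # MS
        m = draw_component(d["ms_main"], rng)
        s = draw_component(d["ms_soup"], rng)

    dessert = DESSERT_TYPES[_categorical(cfg.dessert_type_probs, rng)]
    if dessert == "solid":
        sd = draw_component(d["solid_dessert"], rng)
    elif dessert == "liquid":
        ld = draw_component(d["liquid_dessert"], rng)
    else:
        sd = draw_component(d["both_solid_dessert"], rng)
        ld = draw_component(d["both_liquid_dessert"], rng)

    if rng.random() < cfg.bread_prob:
        b = draw_component(d["bread"], rng)

    optional = OPTIONAL_TYPES[_categorical(cfg.optional_probs, rng)]
    if optional == "fp":
        fp = draw_component(d["fresh_product"], rng)
    elif optional == "mk":
        mk = draw_component(d["milk"], rng)

    return MealPortion(m=m, s=s, sd=sd, ld=ld, b=b, fp=fp, mk=mk)


@dataclass(frozen=True)
class WeekMenu:
    """Five daily portions, Monday through Friday."""

    portions: tuple[MealPortion, ...]

    def __post_init__(self) -> None:
        if len(self.portions) != 5:
            raise ValueError(f"a week menu has exactly 5 portions, got {len(self.portions)}")

    def __iter__(self):
        return iter(self.portions)

    def __getitem__(self, i: int) -> MealPortion:
        return self.portions[i]

    @property
    def total(self) -> float:
        return float(sum(p.total for p in self.portions))


def generate_week(cfg: MenuConfig, rng: np.random.Generator) -> WeekMenu:
    """Five independent daily portions (no weekday effect is modelled)."""
    return WeekMenu(tuple(generate_portion(cfg, rng) for _ in range(5)))


def portion_mass(p: MealPortion) -> float:
    """Total served mass (g): the sum of the seven components."""
    return p.total


#: The school menus recorded during the observation week (grams), used as a
#: fixed worked example for portion arithmetic.
OBSERVED_WEEK_MENU = WeekMenu((
    MealPortion(m=300, s=0, sd=40, ld=210, b=25, fp=0, mk=0),    # Mon, 575 g
    MealPortion(m=205, s=0, sd=180, ld=200, b=25, fp=25, mk=0),  # Tue, 635 g
    MealPortion(m=230, s=255, sd=0, ld=200, b=25, fp=30, mk=0),  # Wed, 740 g
    MealPortion(m=230, s=0, sd=180, ld=200, b=25, fp=30, mk=0),  # Thu, 665 g
    MealPortion(m=240, s=125, sd=0, ld=200, b=25, fp=0, mk=0),   # Fri, 590 g
))
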