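"""Waste-decomposition checks: stage semantics, caps, conservation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from platewaste.menu_gen import COMPONENTS, MealPortion
from platewaste.waste_model import (
    CompetitiveImpactConfig,
    WasteFractionConfig,
    competitive_impact,
    rejected_impact,
    simulate_child_day,
    time_limited_waste,
)

from conftest import make_child

SOUP = COMPONENTS.index("s")
MAIN = COMPONENTS.index("m")
MILK = COMPONENTS.index("mk")


class TestCompetitiveImpact:
    def test_non_user_wastes_nothing(self, rng, fixed_portion, competitive_cfg):
        w = competitive_impact(fixed_portion, make_child(ef=0), competitive_cfg, rng)
        assert np.all(w == 0.0)

    def test_waste_never_exceeds_component_mass(self, rng, fixed_portion, competitive_cfg):
        p = fixed_portion.as_array()
        child = make_child(ef=1)
        for _ in range(2000):
            w = competitive_impact(fixed_portion, child, competitive_cfg, rng)
            assert np.all(w >= 0.0) and np.all(w <= p + 1e-12)

    def test_mean_waste_fraction_matches_bin_midpoints(self, rng, fixed_portion,
                                                       competitive_cfg):
        # k is uniform over {0.12, 0.37, 0.62, 0.87}; clamping at 0/1 shifts
        # the extreme bins slightly (exact mixture mean ~0.4948).
        child = make_child(ef=1)
        total = fixed_portion.as_array().sum()
        fracs = [
            competitive_impact(fixed_portion, child, competitive_cfg, rng).sum() / total
            for _ in range(10_000)
        ]
        assert abs(np.mean(fracs) - 0.495) < 0.01

    def test_milk_is_never_displaced(self, rng, competitive_cfg):
        portion = MealPortion(m=200.0, s=0.0, ld=150.0, mk=200.0)
        child = make_child(ef=1)
        for _ in range(200):
            w = competitive_impact(portion, child, competitive_cfg, rng)
            assert w[MILK] == 0.0

    def test_complement_semantics_wastes_less_on_average(self, rng, fixed_portion):
        # Survey weights lean toward high eaten shares, so complement waste
        # sits below the literal reading's ~0.495.
        cfg = CompetitiveImpactConfig(semantics="complement")
        child = make_child(ef=1)
        total = fixed_portion.as_array().sum()
        fracs = [
            competitive_impact(fixed_portion, child, cfg, rng).sum() / total
            for _ in range(5000)
        ]
        assert np.mean(fracs) < 0.495

    def test_unknown_semantics_rejected(self):
        with pytest.raises(ValueError, match="semantics"):
            CompetitiveImpactConfig(semantics="weighted")


class TestRejectedImpact:
    def test_fully_displaced_portion_rejects_nothing(self, rng, fixed_portion, waste_cfg):
        w_ef = fixed_portion.as_array()
        w_h = rejected_impact(fixed_portion, w_ef, day_hated=1, cfg=waste_cfg, rng=rng)
        assert np.all(w_h == 0.0)

    def test_cap_respects_remaining_food(self, rng, fixed_portion, waste_cfg):
        p = fixed_portion.as_array()
        w_ef = 0.6 * p
        for _ in range(2000):
            w_h = rejected_impact(fixed_portion, w_ef, 1, waste_cfg, rng)
            assert np.all(w_h >= 0.0)
            assert np.all(w_h <= p - w_ef + 1e-12)

    def test_soup_skip_wastes_whole_soup(self, rng, fixed_portion):
        cfg = WasteFractionConfig(soup_skip_prob=1.0, main_skip_prob=0.0)
        w_h = rejected_impact(fixed_portion, np.zeros(7), 0, cfg, rng)
        assert w_h[SOUP] == fixed_portion.s

    def test_hated_day_main_dish_mixture_mean(self, rng, fixed_portion):
        # normal(0.30, 0.05) fraction with an 8% full-rejection override:
        # mean = 0.92 * 0.30 + 0.08 * 1.0 = 0.356.
        cfg = WasteFractionConfig(soup_skip_prob=0.0, main_skip_prob=0.08)
        fracs = [
            rejected_impact(fixed_portion, np.zeros(7), 1, cfg, rng)[MAIN]
            / fixed_portion.m
            for _ in range(10_000)
        ]
        assert abs(np.mean(fracs) - 0.356) < 0.01

    def test_non_hated_day_without_skips_wastes_nothing(self, rng, fixed_portion):
        cfg = WasteFractionConfig(soup_skip_prob=0.0, main_skip_prob=0.0)
        w_h = rejected_impact(fixed_portion, np.zeros(7), 0, cfg, rng)
        assert np.all(w_h == 0.0)

    def test_skips_can_be_confined_to_hated_days(self, rng, fixed_portion):
        cfg = WasteFractionConfig(soup_skip_prob=1.0, main_skip_prob=1.0,
                                  skips_on_hated_days_only=True)
        w_h = rejected_impact(fixed_portion, np.zeros(7), 0, cfg, rng)
        assert np.all(w_h == 0.0)
        w_h = rejected_impact(fixed_portion, np.zeros(7), 1, cfg, rng)
        assert w_h[SOUP] == fixed_portion.s and w_h[MAIN] == fixed_portion.m


class TestTimeLimitedWaste:
    def test_ample_time_wastes_nothing(self):
        remaining = np.array([200.0, 175.0, 30.0, 150.0, 25.0, 75.0, 0.0])
        w = time_limited_waste(remaining, make_child(vs=35.0, stops=1), 60.0)
        assert np.all(w == 0.0)

    def test_no_time_wastes_everything(self):
        remaining = np.array([200.0, 175.0, 30.0, 150.0, 25.0, 75.0, 0.0])
        w = time_limited_waste(remaining, make_child(stops=1), 0.0)
        assert np.allclose(w, remaining)

    def test_partial_time_solid_only(self):
        # 350 g of solid food at 35 g/min with 5 min leaves 175 g.
        remaining = np.zeros(7)
        remaining[MAIN] = 350.0
        w = time_limited_waste(remaining, make_child(vs=35.0, stops=1), 5.0)
        assert w[MAIN] == pytest.approx(175.0)

    def test_liquids_consumed_at_double_rate(self):
        remaining = np.zeros(7)
        remaining[SOUP] = 350.0
        w = time_limited_waste(remaining, make_child(vs=35.0, stops=1), 5.0)
        assert w[SOUP] == pytest.approx(0.0)  # 350 / 70 g/min = 5 min exactly

    def test_non_stopper_wastes_nothing_to_time(self):
        remaining = np.array([200.0, 175.0, 30.0, 150.0, 25.0, 75.0, 0.0])
        w = time_limited_waste(remaining, make_child(stops=0), 1.0)
        assert np.all(w == 0.0)

    def test_eating_order_is_serving_order(self):
        # Enough time for the main dish only: later components are wasted.
        remaining = np.array([70.0, 0.0, 50.0, 0.0, 10.0, 0.0, 0.0])
        w = time_limited_waste(remaining, make_child(vs=35.0, stops=1), 2.0)
        assert w[MAIN] == pytest.approx(0.0)
        assert w[COMPONENTS.index("sd")] == pytest.approx(50.0)
        assert w[COMPONENTS.index("b")] == pytest.approx(10.0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            time_limited_waste(np.zeros(7), make_child(), -1.0)


portions = st.builds(
    MealPortion,
    m=st.floats(0.0, 430.0),
    s=st.floats(0.0, 300.0),
    sd=st.floats(0.0, 100.0),
    ld=st.floats(0.0, 250.0),
    b=st.floats(0.0, 35.0),
    fp=st.floats(0.0, 100.0),
    mk=st.floats(0.0, 200.0),
)


class TestSimulateChildDay:
    @settings(max_examples=200, derandomize=True)
    @given(
        portion=portions,
        ef=st.integers(0, 1),
        hated=st.integers(0, 1),
        stops=st.integers(0, 1),
        t_avail=st.floats(0.0, 30.0),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_conservation_and_nonnegativity(self, portion, ef, hated, stops, t_avail,
                                            seed):
        child = make_child(ef=ef, hated=(hated,) * 5, stops=stops)
        rng = np.random.default_rng(seed)
        b = simulate_child_day(portion, child, 0, t_avail, WasteFractionConfig(),
                               CompetitiveImpactConfig(), rng)
        for arr in (b.eaten, b.w_ef, b.w_h, b.w_t):
            assert np.all(arr >= -1e-9)
        assert np.allclose(b.portion, portion.as_array(), atol=1e-9)

    def test_benign_child_with_time_wastes_nothing(self, rng, fixed_portion,
                                                   competitive_cfg):
        cfg = WasteFractionConfig(soup_skip_prob=0.0, main_skip_prob=0.0)
        child = make_child(ef=0, hated=(0,) * 5, stops=1)
        b = simulate_child_day(fixed_portion, child, 0, 60.0, cfg, competitive_cfg, rng)
        assert b.total_waste.sum() == 0.0

    def test_waste_non_increasing_in_available_time(self, fixed_portion, waste_cfg,
                                                    competitive_cfg):
        # Coupled replay: identical draws at each point of a time grid.
        child = make_child(ef=1, hated=(1,) * 5, stops=1)
        fractions = []
        for t in (0.0, 2.0, 5.0, 10.0, 20.0, 40.0):
            rng = np.random.default_rng(99)
            b = simulate_child_day(fixed_portion, child, 0, t, waste_cfg,
                                   competitive_cfg, rng)
            fractions.append(b.waste_fraction)
        assert all(a >= b - 1e-12 for a, b in zip(fractions, fractions[1:]))

    def test_rejection_cap_holds(self, fixed_portion, waste_cfg, competitive_cfg):
        p = fixed_portion.as_array()
        child = make_child(ef=1, hated=(1,) * 5)
        for seed in range(500):
            rng = np.random.default_rng(seed)
            b = simulate_child_day(fixed_portion, child, 0, 10.0, waste_cfg,
                                   competitive_cfg, rng)
            assert np.all(b.w_h <= p - b.w_ef + 1e-9)
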