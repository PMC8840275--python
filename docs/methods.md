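# Methods

## Model overview

The simulator forecasts the weekly plate-waste fraction of a school
canteen as the expectation, over many Monte Carlo repetitions, of the
interaction between two stochastic agents: a generated week menu (five
daily portions) and a generated child. The time unit is one school week.
Each repetition draws one fresh (child, week-menu) pair; this keeps
repetitions i.i.d., so the standard error of the grand mean is the sample
standard deviation over √n, and doubling repetitions shrinks it by √2.
Whether several children should share one menu realisation is left open by
the underlying field framing; the one-child-one-menu pairing was chosen as
the simplest i.i.d. design and is the package's fixed convention.

## Intake kinetics

Cumulative intake is `e(t) = v0 t + a0 t²/2 + x t³/3`, the integral of the
speed polynomial `v(t) = v0 + a0 t + x t²` with integration constant 0
(nothing eaten at `t = 0`). Published measurements report the quadratic
intake fit `e(t) = k t² + v0 t`; comparing coefficients shows the speed
deceleration is `2k`, hence `doubled_deceleration`. The quadratic model is
physically valid only up to its speed-zero extremum `t* = v0/|a0|`;
`cumulative_intake` integrates `max(v(t), 0)` piecewise-analytically, so
intake plateaus over any interval where the polynomial speed would be
negative and never decreases. The cubic coefficient is recalibrated per
group from `(v0, a0, observed intake E, observed duration t)` as
`x = 3(E − v0 t − a0 t²/2)/t³`.

For the girls' group the stated inputs (v0 = 34, a0 = −5.2, E = 258 g,
t = 10.7 min) give x ≈ 0.470 g/min³ algebraically, while the conventional
printed value is 0.55 (whose implied average speed is 27.16 g/min). The
library always returns the algebraic value and never silently substitutes
the printed one; display code may round or truncate as it sees fit. The
boys' inputs give 0.5656, printed as 0.56 by truncation.

Inside the waste simulation itself a simpler compromise is used, following
the source analyses: every child eats at a constant personal rate drawn
from N(35, 5) g/min for solids, doubled for liquids (soup, liquid dessert,
milk), because restricted lunch windows flatten the deceleration and the
cubic model degenerates toward the linear one.

## Menu generation

Component masses are sampled from the bounded families distilled from
published menus (Gumbel(225, 37.5) on [150, 430] for a stand-alone main
dish, N(225, 37.5) on [150, 300] for stand-alone soup, joint
N(200, 25)/N(175, 12.5) when main dish and soup are served together,
etc.). Bounds are enforced by rejection sampling rather than clipping so
the shape inside the interval is preserved; the bread distribution is a
shifted exponential whose support already starts at the lower bound, so
only the upper bound rejects. Gumbel parameters are (location, scale).

The generator follows the published generation scheme literally: a dessert
is drawn every day regardless of menu type (observed menus show a daily
liquid dessert, supporting this reading), its type uniform over
solid/liquid/both; bread with probability 0.5; exactly one of fresh
product / milk / nothing, uniformly. One line of the published scheme
assigns a liquid dessert from the solid-dessert distribution; this is
treated as a typo and the liquid-dessert distribution N(200, 25) is used.
Joint distributions are used only for the categories that define them (MS
pair, solid-and-liquid dessert pair); MD and SD days use the marginals.

## Child generation

Children carry: rate `vs` (negative draws resampled; the rejected mass of
N(35, 5) below zero is ~10⁻¹²), `vl = 2 vs` exactly, a competitive-food
flag Bernoulli(0.30), a satisfaction flag Bernoulli(0.27 unsatisfied), a
stop-when-out-of-time disposition Bernoulli(0.67) drawn once per child (a
stable trait, since the survey reports it as a share of children), and a
five-day hated-menu vector. The weekly hated-day count is N(3, 0.5) for
unsatisfied children and N(0, 0.5) for satisfied ones, clamped to [0, 5]
and rounded to the nearest integer (the source leaves rounding unstated);
the flagged weekdays are chosen uniformly without replacement. Under this
rule a satisfied child has zero hated days with probability Φ(1) ≈ 0.84
and one hated day with probability ≈ 0.16 — satisfied children can still
occasionally reject a menu, which is consistent with the two-peak survey
distribution the mixture emulates.

All Bernoulli draws are implemented as `uniform < p` threshold
comparisons, and the generator consumes a fixed number of variates per
child regardless of the flags drawn. This draw discipline makes
common-random-number (coupled-replay) comparisons across scenarios exact:
raising a probability can only flip flags from 0 to 1 against the same
uniforms, which is what makes the monotonicity tests deterministic rather
than statistical.

## Waste decomposition

Per child-day, in order:

1. **Competitive food** (`w_ef`): only for competitive-food users. One bin
   midpoint `k` is drawn uniformly from {0.12, 0.37, 0.62, 0.87}; each
   component loses a `N(k, 0.06)` fraction of its mass, clamped to [0, 1].
   This follows the published calculation scheme literally even though the
   survey bins are phrased as shares *eaten*; the alternative reading
   (waste = 1 − eaten fraction, bins weighted by the survey answers) is
   available as `competitive_semantics: complement`. Milk is never
   displaced — the published scheme's return vector omits it.
2. **Rejected food** (`w_h`): on a hated day each component loses its
   category fraction (main N(0.30, 0.05), soup N(0.15, 0.03), solid
   dessert 0.02, liquid dessert N(0.35, 0.07), fresh product N(0.30,
   0.10), bread 0.05; fractions clamped to [0, 1]). Milk has no observed
   rejected-waste category and defaults to 0 with a config override. The
   whole-soup skip (P = 0.5) and whole-main-dish skip (P = 0.08) encode
   stable dislikes from the preference survey, which is not conditioned on
   satisfaction, so by default they apply every day; the stricter
   hated-days-only reading is a config flag. Finally
   `w_h ← min(w_h, p − w_ef)` componentwise, floored at 0: a child already
   filled by competitive food cannot reject more than remains.
3. **Insufficient time** (`w_t`): the remainder the child still intends to
   eat is consumed in serving order (main part, dessert, then
   bread/fresh/milk — the source fixes only the rates, so the order is a
   package assumption), liquids at `vl`, solids at `vs`, within the
   effective eating time (nominal duration minus a 6-minute walking
   delay, 3 min each way). A child whose food outlasts the time either
   stops (wasting the remainder) or eats on and is late (no time waste),
   per the stop disposition.

`eaten + w_ef + w_h + w_t = p` holds componentwise to machine precision on
every simulated child-day.

## Scenario driver, sweeps, ideal conditions

`run_simulation` derives three independent random streams (child, menu,
waste draws) per repetition from `(seed, repetition index)`, so results
are bit-reproducible and scenario changes can be replayed against
identical draws. Sweep cells get seeds derived from `(base seed, cell
index)`, making grids reproducible regardless of evaluation order. Waste
fractions are mass-weighted (weekly waste grams / weekly served grams per
repetition, then averaged); the liquid-dessert exclusion is a reporting
flag that removes that component from numerator and denominator without
changing the model.

Ideal mode emulates the best achievable canteen: all children satisfied,
no competitive food, no stable dislikes — only time limits bind.
`optimal_duration` runs ideal mode on a 1-minute grid of pure eating time
(no walking adjustment) at the slower recalculated rate of 27(2) g/min and
returns the smallest duration whose mean waste fraction falls below a
threshold (default 0.02, a package choice: 2% is comfortably below the
smallest waste levels observed in practice, and the curve's plateau makes
the result insensitive to thresholds in the 1–5% range). Under these
defaults the minimal adequate eating duration lands near 20 minutes.

## Validation and synthetic observations

RMSE pools all (school × duration) cells unweighted (a weight column is
accepted for sensitivity analyses); MAPE uses absolute errors — the
conventional definition — since signed percentage errors of opposite sign
would cancel and make the statistic uninterpretable. Observations and
forecasts must share a declared unit (waste fraction or grams/week);
mixed-unit input and duplicate (school, duration) pairs are rejected
rather than silently reconciled.

Real per-school field measurements of weekly plate waste are not publicly
available, so `synthesize_observations` stands in for them: it runs the
simulator itself at each walking-adjusted duration and perturbs the means
with multiplicative normal noise. Records are format-identical to real
observation files (CSV: school, duration_min, observed_weekly_waste, unit,
n_children). Validation against these synthetic records demonstrates
pipeline self-consistency — with zero noise the residuals are pure Monte
Carlo error — but not field accuracy: passing tests show the model is
internally coherent and correctly wired, not that its survey-derived
parameters describe any particular school population. The same limitation
applies to the generator tests: they confirm the implementation samples
the stated distributions, not that the distributions (24 survey responses)
generalise.

## Numerical choices and problem sizes

* Fraction draws from normals are clamped to [0, 1]; this shifts the mean
  of the extreme competitive bins slightly (the 0.12 bin's clamped mean is
  ≈ 0.1205), which the tests account for.
* Rejection sampling guards against pathological configs with a 100,000
  draw cap before raising.
* The default test and acceptance runs use 10,000 repetitions for mean and
  self-consistency properties, 1,000–2,000 repetitions per point for curve
  and sweep shapes, and 10,000 draws for frequency checks with 4σ binomial
  bands — sizes chosen so Monte Carlo error is far below every asserted
  tolerance while the whole suite stays quick on a laptop.
* Quantities are computed and returned at full precision; rounding or
  truncating to printed precision is left to display code.

## Known limitations

* Behavioural probabilities rest on a small survey (24 responses) from one
  city; other regions must re-survey and reconfigure.
* Competitive-food use is a child-level flag applied every school day; a
  per-day stochastic reading is plausible and flagged for sensitivity
  analysis.
* Nutrient-level recomputation of waste, plate-size effects, menu
  optimisation and BMI- or gender-stratified eating rates are out of
  scope.
* The dissatisfaction distribution is modelled as a two-group mixture;
  field data may suggest an exponential form instead.
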