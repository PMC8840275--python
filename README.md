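# platewaste

Monte Carlo forecasting of plate waste in school canteens.

Canteen managers need to know how much served food will come back uneaten,
and what scheduling or menu decisions would reduce it — but running field
experiments in schools is slow, costly and often impossible. `platewaste`
forecasts the weekly plate-waste fraction from two scenario inputs a school
actually controls or can survey: the **lunch duration** and the **share of
children unsatisfied with the school meal**. Everything else is a
survey- and literature-derived stochastic model. It is aimed at
food-service researchers and school administrations; the simulator doubles
as a training tool for exploring "what if" scenarios.

## The model

One repetition pairs two generated agents, a week menu and a child:

* **Week menu** `P = (p_mon, …, p_fri)`. Each daily portion is the
  seven-component vector `p = m + s + sd + ld + b + fp + mk` (main dish,
  soup, solid dessert, liquid dessert, bread, fresh product, milk; grams).
  The composition is drawn from the three regulated menu types — main dish
  + soup (65%), main dish + dessert (30%), soup + dessert (5%) — with a
  dessert always served, bread with probability 0.5, and exactly one of
  {fresh product, milk, nothing}. Component masses come from bounded
  normal/Gumbel/shifted-exponential distributions distilled from published
  school menus.
* **Child** `c = {v, ef, N′}`: a solid-food eating rate
  `v_s ~ N(35, 5)` g/min (liquids at `v_l = 2 v_s`), a competitive-food
  flag (P = 0.30), a satisfaction flag (27% unsatisfied), a five-day
  hated-menu vector (3(0.5) hated days per week if unsatisfied, 0(0.5)
  otherwise), and a stop-when-out-of-time disposition (P = 0.67).

Each child-day the served portion is decomposed, component by component,
into

```
p = eaten + w_ef + w_h + w_t
```

applying three stages in order: **competitive food** (`w_ef`: a
`N(k, 0.06)` fraction of each component, `k` uniform over
{0.12, 0.37, 0.62, 0.87}), **rejected food** (`w_h`: per-category waste
fractions such as `N(0.30, 0.05)` for the main dish on hated days, plus
stable whole-soup/whole-main skips at 50%/8%, capped by
`w_h ≤ p − w_ef`), and **insufficient time** (`w_t`: whatever a stopping
child cannot finish in the effective eating time, i.e. the nominal lunch
duration minus 6 min of walking). Conservation holds exactly at every
aggregation level.

The eating-time stage is grounded in closed-form intake kinetics
(`platewaste.kinetics`): cumulative intake
`e(t) = v0·t + a0·t²/2 + x·t³/3`, its speed-zero extremum `t* = v0/|a0|`,
maximal intake `v0²/(2|a0|)`, and the empirical intake–speed relation
`E(v) = 6.8·v + 125`.

Forecast quality is scored with RMSE and MAPE against per-school weekly
observations grouped by lunch duration; a synthetic-observation generator
produces format-identical records for pipeline self-consistency checks.

## Worked example

```bash
$ platewaste kinetics
       v0_g_min  deceleration_g_min2  extremum_time_min  max_quadratic_intake_g  cubic_x_g_min3  mean_intake_g  mean_duration_min  average_speed_g_min
group
girls      34.0                 -5.2              6.538                 111.154           0.470          258.0               10.7               24.112
boys       42.0                 -5.4              7.778                 163.333           0.566          289.0                8.8               32.841

Implied eating-rate range for drink-free portions of 390-540 g: [39; 61] g/min
```

Reading the table: with the measured initial speeds and (doubled)
decelerations, the pure quadratic model stalls at 111.15 g after 6.5 min
for girls and 163.3 g after 7.8 min for boys — far below the measured mean
intakes (258 g and 289 g), which is why the cubic term `x` is recalibrated
so the model reproduces the observed intake over the observed duration
(0.47 and 0.57 g/min³). The last line inverts the intake–speed relation for
the 390–540 g drink-free portion range.

```bash
$ platewaste simulate --duration 25 --unsatisfied 0.27 --reps 10000 --seed 42
mean weekly waste fraction: 28.06% (29.79% excluding liquid dessert)
   competitive: 12.96%
      rejected: 14.96%
          time: 0.06%
```

At the default scenario (25-min lunch, 27% unsatisfied children, 30%
competitive-food users) the simulator forecasts about 28% of served mass
wasted per week — in the 20–30% range reported for European school
canteens — split into its three causes: with 19 effective eating minutes
almost nothing is lost to time, so competitive and rejected food dominate.

Sweeps over the two scenario inputs, and the ideal-conditions
waste-versus-duration curve behind the "at least 20 minutes of eating
time" scheduling rule:

```bash
platewaste sweep --durations 8:40:1 --shares 0:1:0.05 --reps 1000 --out grid.csv
platewaste validate --observations obs.csv --reps 10000 --out report.json
```

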