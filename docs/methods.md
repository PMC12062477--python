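# Methods notes

## Model

Adherent-cell density `X(t)` (cells cm⁻²) in a well follows

```
dX/dt = μ X,   μ = μ_m (1 − ε K_s)(1 − X/X_m),   X(24 h) = α X_seed
```

a logistic law whose effective rate `r = μ_m (1 − ε K_s)` is damped by the
Day-1 seeding heterogeneity `ε` (spatially clumped seeding slows apparent
growth because crowded regions saturate early) and whose contact-inhibition
term uses the saturation density `X_m`. `K_s = 24.7` is a fixed literature
constant. The clock starts at the Day-1 observation (24 h post seeding);
harvest times in days map to ODE time `t − 24 h`. The assumptions inherited
with the model: daily half-medium exchange keeps nutrient/metabolite
effects constant (no substrate terms), growth is number-based with no
explicit migration, morphology or aging effects, and `α, ε, X_m` are
*measured* per sample, never fitted.

Because the right-hand side is exactly logistic in `X`, the closed form
`X(t) = X_m / (1 + ((X_m−X0)/X0) e^{−r (t−24h)})` is available alongside the
numerical integrator (LSODA, rtol 1e-10, atol 1e-8 — tight enough that the
closed-form agreement test at 1e-6 relative error is meaningful). The
Monte-Carlo layers evaluate the closed form, vectorised over draws and
times; `simulate_limits(..., method="ode")` keeps the integrator path as a
cross-check. A negative effective rate (`ε K_s > 1`) is allowed and logged,
never clipped: it signals a data problem that clipping would hide.

## Parameter measurement

Per sample, from the 64-tile counts: `α` = Day-1 total / (S·X_seed);
`ε` = population SD of the normalised Day-1 tile fractions (0 for uniform
seeding, √63/64 ≈ 0.124 for all cells in one tile); `X_m` = 64·max over all
tiles and timepoints / S. "Day 1" is the observation nearest 24 h, required
within ±3 h. `S` defaults to the square 15.3 × 15.3 mm tiling area
(2.3409 cm²); a circular reading (1.8385 cm²) is selectable. Totals-only
data support `α`/`X_m` under an explicit uniformity flag; `ε` is undefined
without tiles.

## Estimation and intervals

Each sample's `μ_m` minimises the RSS between measured whole-area counts
and `N(t) = S·X(t)`, with `(α, ε, X_m)` fixed at the dataset means
(per-density or per-sample modes exist behind flags) and all timepoints
from Day 1 used. Nelder–Mead, iteration cap 5000, objective tolerance 1e-10
*relative to the initial objective value* — an absolute 1e-10 would sit
below double-precision noise on count-scale RSS values. The initial guess
(0.03 h⁻¹) is uncritical: the 1-D objective is smooth and unimodal here.
`μ_m` is unconstrained in sign; negative optima and non-converged fits are
logged and kept.

The prediction interval uses `n − 1` degrees of freedom with `n` = number
of fitted samples, and the √(1+1/n) prediction factor — it brackets a *new
sample's* rate, which is what the growth limits represent. NRMSE (RMSE
over a seeding-density group normalised by that group's measured range, in
percent) gates model validity at 10%.

## Stochastic simulation and the design space

θ is an M×3 matrix resampled with replacement from the per-sample
measurements; the default draws each column independently (the paper-style
per-parameter random choice), a joint mode preserves within-sample triples.
One θ is shared across the entire condition grid, and each (θ row, X_seed)
yields one trajectory pair (μ_m^UP, μ_m^LO) evaluated at all 33 harvest
times, so all grid probabilities derive from the same simulated
trajectories. Confluency uses each draw's own `X_m`, and since a logistic
trajectory cannot cross its own asymptote, `P ≤ 1` always. The success
indicator requires *both* limits in the specification set (inclusive
`N ≥ N_min`, exclusive `P < P_max`, inclusive `h ≥ π`), which makes the
interval-based DS provably a subset of the point-estimate (mean-rate)
reference DS and nested across rising π.

Convergence is diagnosed on the final (Day-9) cell number as the relative
standard deviation *of its Monte-Carlo mean*: the batch-means estimate
`std(batch means)/(√n_batches · mean)`, which for i.i.d. draws estimates
`σ/(√M·mean)`. It is reported (warning above 0.2%), never enforced.

## Validation

`h_exp` per condition is the fraction of validation samples meeting the
specification, with `P_exp = N_exp/(S·X_m)` using each sample's own
measured `X_m` by default (global-mean mode available). Conditions match
grid cells exactly — no snapping. Ratios with zero denominators (e.g. an
empty DS) are reported as missing, never as 0 or 1. The permutation study
rotates the pre-experiment role over the labelled operator groups and
re-runs estimation → interval → DS → validation per π; an empty DS at high
π is a legitimate outcome reported as zero conditions with missing R1.

## Synthetic-data generator: what it emulates, and calibration

The generator reproduces the study design: 3 operators × 3 seeding
densities (1500/3000/4500 cells cm⁻²) × 6 replicates, imaged every 6 h
from Day 1 to Day 9, 64 tiles over 2.3409 cm². Per sample it draws
`μ_m ~ N(2.76e-2, 1.46e-3) h⁻¹` (the study's re-estimated distribution,
optionally offset per operator), `α ~ Beta(mean 0.80, concentration 200)`,
`X_m ~ N(4.0e4, 5.0e2)` truncated above the inoculum, then allocates the
rounded `α·S·X_seed` Day-1 cells to tiles by a Dirichlet(1000)–multinomial.
The *realized* ε of that allocation (typically ≈ 2e-3, dominated by the
multinomial seeding randomness) drives the true growth penalty — ε is
emergent and recorded as truth, mirroring how the analysis measures rather
than sets it. Totals follow the closed-form growth law, carry multiplicative
lognormal counting noise (CV 3%, mean 1; per-tile Poisson optional) and are
capped at `S·X_m`.

Tile allocation at later timepoints redraws a multinomial over the sample's
fixed spatial weights, with a per-tile capacity `S·X_m/64` scaled by a
per-tile local-saturation factor (CV 1.5%): tiles fill up locally and a
confluent well ends near-uniform with its densest tile slightly above the
well mean — the behaviour the max-tile `X_m` statistic depends on. A
`proportional` mode that freezes Day-1 fractions exists, but freezing
~40-cell Day-1 tile allocations into late times would inflate the max-tile
statistic by ~35% and is not how confluent monolayers look.

Calibration targets for the values the study design does not pin down were
its printed observables: the fitted spread `s` (the per-sample fits absorb
α and X_m variability on top of the injected μ_m spread, so overly wide
α/X_m distributions would overstate `s`), the <10% NRMSE gate, the
sub-0.2% Monte-Carlo convergence, and the feasibility-window geometry.
With `α = 0.8`, `X_m = 4.0e4` and `ε K_s ≈ 0.05`, the mean-curve feasible
windows fall at ≈ day 6.7–8.7 / 6.2–6.9 / 5.4–6.3 for 1500/3000/4500
cells cm⁻², and the interval-based DS narrows them to ≈ 0.5–1 day — the
published qualitative structure (lower seeding ⇒ later, narrower windows).

What the generator does *not* emulate: spatial correlation between
neighbouring tiles, migration between tiles as a dynamic process, lag and
adhesion-phase kinetics before Day 1, operator-dependent systematic count
bias, and any drift of `X_m` over passages. Tests passing on this generator
therefore certify the workflow's statistical machinery under the model's
own assumptions, not the model's adequacy for any particular real culture.

## Numerical and degenerate-input choices

* Times are hours internally, days at interfaces; densities cells cm⁻²;
  probabilities percent; tile indices 0-based.
* `s = 0` collapses the interval to the mean; both limits then coincide.
* Sample CVs, thresholds: NRMSE gate 10%, convergence warning 0.2%,
  default π = 90, M = 1000, default RNG seed 20240101 — all overridable in
  `RunConfig` / CLI flags.
* The expensive stages are vectorised: a full 297-condition map at
  M = 1000 takes ~20 ms, a complete synthetic study (generate, fit,
  interval, map, validate) well under a second, so the test suite and the
  acceptance script replicate runs tens of times within seconds.

## Known limitations

* The per-sample `μ_m` fits absorb any mismatch between a sample's true
  `(α, ε, X_m)` and the fixed means; `s` therefore slightly overstates the
  intrinsic rate spread (~15% on calibrated synthetic data). This is
  inherent to the one-parameter re-estimation design.
* An 18-sample pre-experiment makes `s` itself noisy; high-`s` draws can
  empty the DS at π = 90. This mirrors the documented behaviour of
  high-variance pre-experiments and is reported, not suppressed.
* `X_m` measured from never-confluent wells (low seeding, short horizon)
  underestimates saturation; the measured pool inherits a small
  density-dependent spread that dominates the Monte-Carlo convergence
  diagnostic.
* Only the 2-D (X_seed, t_h) process-parameter space is implemented.
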