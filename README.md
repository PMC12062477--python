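# mscds — probabilistic design spaces for MSC cultivation

`mscds` implements a model-based quality-by-design workflow for adherent
mesenchymal stem cell (MSC) expansion. Given time-lapse adhesion-cell counts
from replicate cultivation wells, it determines — and validates against
held-out experiments — the *design space* (DS): the set of seeding densities
`X_seed` and harvesting times `t_h` for which the predicted probability of
meeting the quality specification

```
A = { (N, P) : 5.0e4 <= N  and  P < 0.8 }
```

(at least 50 000 harvested cells `N = S·X` and confluency `P = X/X_m` below
80%) is at least a minimum acceptable risk π.

## The model and workflow

Cell density follows a logistic law with a seeding-heterogeneity penalty,
started at the Day-1 (24 h) observation:

```
dX/dt = μ X,   μ = μ_m (1 − ε K_s)(1 − X/X_m),   X(24 h) = α X_seed
```

* `α` — adhesion ratio: attached Day-1 cells / seeded cells,
* `ε` — seeding heterogeneity: population SD of the normalised per-tile
  Day-1 counts over the 8×8 imaging tiles, penalising growth via the
  constant `K_s = 24.7`,
* `X_m` — saturation (maximum) density: `64·max(tile count)/S`,
* `μ_m` — maximum specific growth rate (h⁻¹).

The workflow (each stage is a module and a CLI subcommand):

1. **extract** — measure `(α, ε, X_m)` per sample from tiled counts.
2. **fit** — estimate `μ_m` per sample by Nelder–Mead least squares on the
   count curves (other inputs fixed at the measured means); aggregate to
   mean, sample SD `s` and sample count `n`. Model fit is gated at 10%
   NRMSE per seeding density.
3. **interval** — two-sided 95% Student-t *prediction* interval,
   `μ_m ± t(0.975, n−1)·s·√(1+1/n)`, giving `μ_m^UP` and `μ_m^LO`.
4. **ds** — Monte-Carlo simulation: resample `(α, ε, X_m)` triples from the
   per-sample measurements (M = 1000), integrate each draw with `μ_m^UP`
   and `μ_m^LO`, and score each grid condition with the probability `h`
   that *both* limits satisfy `A`. The DS is `{h ≥ π}` over a
   9 × 33 = 297-condition grid (1500–4500 cells cm⁻² step 375,
   Day 1–9 every 6 h).
5. **validate** — compare against held-out experiments: per condition the
   experimental probability `h_exp` (fraction of the 12 validation samples
   meeting `A`) crosses `h` at π to classify CDS / C-DS̄ / IDS / I-DS̄, and
   R1 = nCDS/(nCDS+nIDS), R2 = nCDS/(nCDS+nI-DS̄), R3 = nC-DS̄/(nC-DS̄+nIDS)
   summarise precision, recall and specificity of the DS.

A first-class synthetic-data generator (`mscds.synthetic_data`) emulates the
full three-operator study design with per-sample ground truth, so every
stage runs and is tested without any external data.

## Worked example

```
$ mscds synth --out exp.csv --seed 7          # 54 synthetic wells, 33 timepoints
$ mscds pipeline --data exp.csv --pre-operator A --out run --seed 7
$ cat run/interval.json
{
  "mean": 0.028404177188873288,
  "s": 0.0014070331959120466,
  "n": 18,
  "level": 0.95,
  "upper": 0.031454103779508254,
  "lower": 0.025354250598238325
}
$ cat run/metrics.json
{
  "pi_percent": 90.0,
  "ds_conditions": 11,
  "nrmse_pass": true,
  "nrmse_percent": {"1500.0": 6.63, "3000.0": 3.88, "4500.0": 5.12},
  "nCDS": 4, "nC_notDS": 89, "nIDS": 0, "nI_notDS": 6,
  "R1": 1.0, "R2": 0.4, "R3": 1.0
}
```

Operator A's 18 wells give `μ_m = 2.84e-2 ± 1.41e-3 h⁻¹` (n = 18), hence
prediction bounds `3.15e-2` / `2.54e-2 h⁻¹`. The model passes the 10% NRMSE
gate on the held-out operators (6.6% worst). At π = 90% the DS contains 11
of 297 conditions; validation on operators B and C classifies all 99
validation conditions, with no condition wrongly admitted to the DS
(nIDS = 0, so R1 = 1.0 and R3 = 1.0) at the price of recall (R2 = 0.4) —
the characteristic conservatism of interval-based design spaces.

Library use mirrors the CLI: see `mscds.estimate_mu`,
`mscds.mu_m_prediction_interval`, `mscds.probability_map`,
`mscds.determine_design_space`, `mscds.validate_design_space` and
`mscds.permutation_study` (which rotates the pre-experiment role across
operator groups for π ∈ {50, 70, 90}).

## Layout

```
src/mscds/
  growth_model.py           # logistic ODE + closed form
  tile_metrics.py           # α, ε, X_m from tiled counts; CSV dialect
  mu_estimation.py          # per-sample μ_m fits, NRMSE validation
  prediction_interval.py    # Student-t prediction interval
  stochastic_simulation.py  # θ resampling, limit trajectories, convergence
  design_space.py           # probability maps, DS thresholding
  validation.py             # h_exp, categories, R1–R3, permutation study
  synthetic_data.py         # study-design generator with ground truth
  config.py, cli.py         # run configuration and the command line
docs/methods.md             # modelling and calibration notes
```
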