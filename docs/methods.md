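# Methods

## Growth model

Growth is light-limited and temperature-modulated:
`mu(q_ph, T) = mu_opt(q_ph) * phi(T)`. The light term is Monod-like
with a maintenance offset,
`mu_opt = mu_max (q_ph - m_ph) / (q_ph - m_ph + K_S_ph)`, evaluated at
the optimum temperature. It is deliberately *not* clamped at zero for
`q_ph < m_ph`: maintenance-dominated biomass decline is a real penalty
the productivity optimizer must see at excessive standing
concentrations. The temperature term is the Cardinal Temperature Model
with Inflexion (CTMI), parameterized by `(T_min, T_opt, T_max)` with the
strict validity constraint `T_opt > (T_min + T_max)/2`; constructing a
parameter set violating ordering or that midpoint rule raises.

Light availability treats the tubular reactor as `c = 20` one-sidedly
illuminated compartments of equal projection area `A_z = A/c`, each with
a constant measured surface intensity. The per-compartment split is a
modeling convention (the physical tubes are decomposed into two modeled
compartments each, already folded into the 20-entry light map); it is
the convention under which the closed-form continuous-operation optimum
reproduces the fixed-cycle optimization results, which is why it is
used. Intensities are converted from umol m^-2 s^-1 to mol m^-2 d^-1
assuming permanent 24 h illumination. Internally concentrations are
g/L, volumes L, times days, rates 1/d.

Two geometric quantities deliberately coexist: the flat-panel-equivalent
path length `pi r / 2` is provided for reactor characterization, but the
photon-availability calculation uses the measured projection surface
directly; the two are not forced to agree (the projection area of this
reactor exceeds the flat-panel-equivalent area by ~30%), and nothing in
the pipeline depends on reconciling them.

## Simulation

Batch growth integrates `dc_X/dt = mu * c_X` with `q_ph` recomputed from
the instantaneous concentration. Two integrators: fixed-step explicit
Euler (default step 0.01 d, the scheme used inside estimation replays,
where its discretization error is far below sensor noise) and LSODA
(`rtol 1e-8` by default) for optimization and verification. Temperature
between samples is linearly interpolated — measured signals change
slowly. A vectorized constant-temperature Euler path evaluates many
parameter vectors simultaneously; the sensitivity scan and the
productivity surfaces run on it. pH is carried through the data
structures but never enters the model.

## Data preparation

Biomass is obtained from near-infrared OD through a per-experiment
linear correlation fitted by ordinary least squares against the daily
dry-weight samples (duplicates averaged, each off-line time paired with
the nearest on-line sample). Growth rates use the central difference
over +-1 h, `mu_delta(t) = (c(t+1h) - c(t-1h)) / (2h c(t))`, with the
stencil values looked up as the nearest recorded samples within
+-0.25 h (the logging cadence of the original recorder is not
documented; 0.25 h accepts 10-60 min cadences and rejects sparser
records). A +-1 h moving average smooths `mu_delta`; points whose
stencil or smoothing window leaves the record are dropped, not padded.

Reorganization pools all experiments, quantizes `q_ph` to 3 significant
digits before equality grouping (continuous values are almost surely
distinct; grouping presupposes recurring values), rounds temperatures to
0.1 degC (sensor resolution) and averages growth rates at identical
temperatures, splits the pooled `q_ph` range into 10 equal-width
clusters (half-open intervals, the last closed so the maximum belongs to
cluster 10) and keeps per cluster the dataset with the widest
temperature span. Ties go to the dataset with more observations, then
to the lowest `q_ph` label — deterministic and documented.

## Estimation

Stage 1 fits `(mu_opt_1..s, T_min, T_opt, T_max)` to the cluster
datasets by Nelder-Mead from every CTMI-valid cardinal triple on a
5-degree grid spanning the search range (70 starts on the reference
ranges); per-cluster `mu_opt_k` starts at the cluster's maximum observed
rate. Stage 2 fits `(mu_max, K_S_ph, m_ph)` to the cluster optima
against their `q_ph` labels from a 10-per-axis lattice (1,000 starts).
Search ranges follow fixed rules: cardinal temperatures within
[-5, 50] degC constrained by the observed data range, `mu_max` from the
highest observed rate up to 3.8 1/d, `K_S_ph` up to the highest observed
`q_ph`, `m_ph` up to 0.32 (literature caps). The lower `T_max` bound
defaults to the highest observed temperature; a literature variant
(32 degC) is selectable. Each cluster's `q_ph` label is the selected
dataset's own (quantized) value.

The final stage fits the `m + 6` parameters (per-experiment inoculation
concentrations plus the six shared parameters) by least squares of
measured vs ODE-simulated biomass, each experiment replayed with its
recorded temperatures. Range bounds are *not* enforced here — only CTMI
validity, via a smooth quadratic penalty — because a maintenance
coefficient slightly above its literature cap must remain reachable.
Nelder-Mead runs from every distinct initial candidate (distinct =
objective within 10% of the best and parameters differing beyond
tolerance) with a 200-iteration default budget; optional re-seeding of
the simplex at the incumbent ("restarts") tightens convergence, which
matters for noise-free identifiability tests where the optimum is an
exact zero of the objective. The whole chain is deterministic: ordered
starts, fixed budgets, no randomness.

Delete-2 jackknife: the final fit is repeated on every leave-two-out
subset of experiments (C(m,2) refits, 105 for m = 15), warm-started from
the full-sample estimate; the delete-d standard error
`sigma = sqrt((m-d)/(d C(m,d)) * sum (theta_s - mean)^2)` gives
normal-theory 95% intervals. Failed refits are excluded with a warning.

## Sensitivity analysis

Saltelli cross-sampling over a scrambled Sobol' base sequence of
dimension 2k: base matrices A and B plus column-swapped AB_i and BA_i,
i.e. `N (2k+2)` model evaluations including second-order blocks. All
six parameters vary by default (`k = 6`), uniformly within +-3 sigma of
the point estimates; a reduced variant holding any parameter fixed
(e.g. `k = 5`) is supported. First-order indices use the
`mean(Y_B (Y_ABi - Y_A))/Var` estimator, total-order
`mean((Y_A - Y_ABi)^2)/(2 Var)`, second-order from the BA/AB cross
terms. Classification thresholds: below 0.01 non-sensitive, at or above
0.1 highly sensitive. The scenario grid takes low/medium/high (20, 50,
80% of the experimental range) inoculation concentration and
temperature — nine combinations — at the medium cycle time (3.85 d),
since only those two process parameters are varied across scenarios.
Zero output variance flags the result as degenerate rather than raising.

## Productivity optimization

Nelder-Mead maximizes simulated batch productivity over any free subset
of `(c_X0, t_cyc, T)`. Bounds are handled by smooth coordinate
transforms (log for the positive variables, logistic for temperature),
avoiding penalties near optima; the free cycle time bottoms out at
0.01 d to keep the `0/0` productivity quotient away from the exact
corner. Every returned optimum is re-simulated with the adaptive
integrator at `rtol 1e-8` and reported from that verification run. The
continuous-operation limit has a closed form (derived independently in
`algrow.optimize`): `c* = S/(m_ph + sqrt(m_ph K_S_ph))` and
`Pr* = mu_max c* sqrt(m_ph K_S_ph)/(sqrt(m_ph K_S_ph) + K_S_ph)` with
`S` the volumetric photon supply; it anchors the numerical optimizer as
an analytic oracle.

The campaign re-optimization simulates each recorded cycle time at its
own optimal inoculation concentration and the optimum temperature and
reports per-experiment optima with their mean *and* median: for
campaigns mixing sub-day and week-long cycles the two differ noticeably
(week-long cycles cap near 0.37 g L^-1 d^-1 and pull the mean below the
median), so both are reported rather than a single summary.

## Synthetic campaigns

The generator emulates the 15-experiment repeated-batch design:
inoculation concentrations 0.27-1.03 g/L and cycle times 0.7-7 d from
the recorded campaign design, set temperatures mostly 20-25 degC with
one warm experiment at 31 degC, a 1-day-period sinusoidal temperature
fluctuation (amplitude 2 K) clipped to the controller's +-1 K hysteresis
band, 10-min on-line logging (dense enough for the +-1 h stencil; the
true cadence is undocumented), per-experiment OD-correlation
coefficients spanning the observed 0.09-0.23 range, multiplicative OD
noise (sigma 1%) and additive dry-weight noise (sigma 0.02 g/L) in
daily duplicates. One campaign seed spawns independent per-experiment
substreams, so campaigns are reproducible and experiments independent.

What it does not emulate: lag phases, nutrient limitation or pH effects
(absent from the model), light gradients within the culture, sensor
drift, and day/night cycling — illumination is permanent, as in the
emulated reactor. Passing recovery tests therefore demonstrate
estimator correctness under the model's own assumptions, not robustness
to structural mismatch.

The forward model defaults to LSODA at `rtol 1e-8`; an Euler variant
reproduces the estimator's fixed-step replay exactly, making generator
and estimator exact inverses in the noise-free limit. Noise-free
identifiability tests use that variant together with a
temperature-rich design (set-points 8-31 degC): with data confined to
the realistic 19-31 degC span, `T_min` is nearly unidentifiable — its
jackknife uncertainty is of the order of the estimate itself — so exact
recovery is only a meaningful estimator property under an informative
design.

## Problem sizes used in tests

The default suite runs the estimator chain on 3-5-experiment campaigns
with hourly sampling, reduced light-stage lattices (4-6 per axis) where
the full 1,000-start lattice is not itself under test, Sobol scans at
N = 2^12-2^14 base samples, and the full 15-experiment campaign only for
the deterministic optimization analyses. The delete-2 jackknife CI
coverage study (repeated synthetic campaigns) lives in
`analysis/03_estimate_parameters.py --jackknife`, not in the suite; the
suite tests the jackknife mechanics (resample count, zero-variance
collapse, failure handling) directly.

## Known limitations

- `T_min` is weakly identified by realistic campaigns (data far above
  it); report it with its uncertainty, not as a point value.
- The model aggregates light over the whole culture volume; it does not
  resolve light gradients, photoinhibition (none observed in the
  calibration range) or photoacclimation.
- Transfer to outdoor/industrial scale needs extensions (variable
  irradiance, night biomass loss) that are out of scope here.
- MAPE is undefined for near-zero measured productivities; experiments
  with `Pr ~ 0` would need a different accuracy metric.
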