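# Methods

## The models

All models describe two-alternative preferential choice between a left and a
right item with pre-rated integer values `r_left`, `r_right` (rating units,
non-negative in choice trials).  A scalar decision variable `x` starts at 0
and accumulates noisy evidence until it reaches one of two symmetric
absorbing bounds at `±B`.  Throughout the package the accumulation noise has
unit variance per second unless stated otherwise, positive drift favors the
right item, and the upper bound maps to the right choice.  (The left/right
orientation of the axis is a pure convention: the process is mirror
symmetric, and the mirror-symmetry of likelihoods is tested.)

### Attentional drift-diffusion (aDDM) family

Gaze alternates between the items in discrete dwells; the drift tracks the
attended item:

- **Multiplicative** (`addm_mult`): while looking left the drift is
  `κ(θ·r_right − r_left)`, while looking right it is `κ(r_right − θ·r_left)`.
  The unattended item's value is discounted by `θ ∈ [0, 1]`; `θ = 1` recovers
  the standard DDM.
- **Additive** (`addm_add`): drift `κ(r_right − r_left + s·ω)` with `s = +1`
  when attending right and `−1` when attending left; attention shifts the
  drift by a constant rather than rescaling value.
- **Inter-trial drift variability** (`addm_driftvar`): multiplicative rule
  plus a perturbation `v ~ N(0, σ_d)` drawn once per trial and added to the
  drift in both gaze states.
- **Value noise** (`addm_valuenoise`): multiplicative rule with the item
  values themselves perturbed once per trial (`r_left + v₁`, `r_right + v₂`,
  `v ~ N(0, σ_d)`), modeling ratings that imperfectly reflect the values
  used during choice.

The aDDM's response time is the bound-crossing time plus a fixed mean
non-decision time `μ_nd`.  Simulated gaze follows the exogenous dwell
sequence until the crossing, where dwell sampling stops; gaze is then held
on the item under gaze at the crossing (the model has no post-commitment
gaze mechanism).

An equivalent form of the classic per-millisecond parameterization
(per-step gain `d`, per-step noise SD `σ`, bounds `±1`, steps `dt`) is
obtained by `κ = (d/σ)·√(1/dt)` and `B = B_orig / (σ·√(1/dt))`; for
`d = 0.0002`/ms, `σ = 0.02`, `dt` = 1 ms this gives `κ = 0.3162`,
`B = 1.5811`, which together with `θ = 0.3` and `t_nd = 0.355` s are the
package's aDDM defaults.

### Post-decision-gaze (PDG) model

Attention plays no causal role.  The drift is `μ = κ(r_right − r_left)` and
the momentary-evidence variance scales with the overall value,
`σ² = 1 + γ(r_left + r_right)` — the mechanism by which the model produces
faster responses at higher overall value (the magnitude effect on RT).
Accumulation starts after a sensory delay `τ_s`; the response follows the
crossing after a motor latency, with the total non-decision time
`τ_nd ~ N(μ_nd, σ_nd)` truncated to be non-negative.  Gaze follows the
exogenous dwell sequence until latency `τ_e ~ N(μ_e, σ_e ) ≥ 0` after the
crossing, then jumps to the chosen item and stays there; the jump can land
after the report, which is what produces the continued post-report rise in
gaze to the chosen item.

### Hybrid model

aDDM dynamics before the crossing (accumulation onset delayed by `τ_s`),
then a PDG-style shift of gaze to the chosen item at latency `τ_e` after
the crossing.  Defaults `τ_s = 0.25` s, `μ_e = 0.2` s, `σ_e = 0.05` s.

## Parameters (units, defaults, why)

| parameter | units | default | role |
|---|---|---|---|
| κ | 1/(rating·s^½) | 0.3162 (aDDM), 0.3 (PDG) | signal-to-noise per rating unit |
| B | √s | 1.5811 (aDDM), 1.5 (PDG) | bound height (unit-variance form) |
| θ | – | 0.3 | multiplicative discount of the unattended item |
| ω | rating units | 0 | additive attentional drift shift |
| σ_d | drift (or rating) units | 0 | SD of trial-constant drift/value noise |
| γ | 1/rating | 0.05 | variance scaling with overall value |
| μ_nd, σ_nd | s | 0.65, 0.15 (PDG) | non-decision mean / SD |
| μ_nd (aDDM) | s | 0.355 | fixed non-decision time |
| τ_s | s | 0.3 (PDG), 0.25 (hybrid) | sensory delay before accumulation |
| μ_e, σ_e | s | 0.35, 0.35/3 (PDG); 0.2, 0.05 (hybrid) | gaze-shift latency after commitment |

aDDM defaults are the published best-fitting values in the unit-variance
form.  PDG defaults are chosen so that simulated behavior is realistic for
the task (mean RT ≈ 2 s, accuracy ≈ 0.8) and so that the motor latency
`τ_m = τ_nd − τ_s` (mean 0.35 s) is comparable to the gaze-shift latency
`τ_e`, giving both a last-fixation bias and a post-report rise.

## Synthetic-data generator

The generator emulates the study design the analyses assume: 39
participants × 100 choice trials from 70 rated items; integer ratings;
only non-negative ratings enter choice trials; pairs constrained to
`|Δr| ≤ 5`; each item reused at most six times per participant (repeats of
a pair via `n_reps` emulate the simulation protocol of re-running the same
value pairs and do not count against reuse); the first fixation lands on
the left item with probability 0.74; first and middle dwell durations are
log-normal.  The study's rating histogram is not published, so ratings
default to uniform integers 0–10, with an explicit categorical-weights
option for skewed value distributions (a right-skewed choice induces the
positive |Δr|–Σr correlation seen in such designs; the uniform default
leaves them uncorrelated — both covered by tests).

Dwell-duration defaults (log-mean ln 0.35, ln 0.45; log-SD 0.5; first
dwells shorter than middle dwells) are typical free-viewing values for
two-item food choice.  What the generator does **not** emulate: off-item
("none") gaze, blinks, saccade kinematics, rating-phase behavior, or any
dependence of dwell durations on value.  Passing tests therefore show that
the pipeline recovers the behavior the models generate — not that real
gaze data obey the dwell model.

A master `numpy` Generator is split into independent per-participant
substreams (`Generator.spawn`), so datasets are bit-reproducible under a
fixed seed regardless of participant-level parallelism.

## Numerics

**First-passage solver.** The Fokker–Planck equation on `(−B, B)` with
absorbing boundaries is discretized with an implicit-in-time finite-volume
scheme with Chang–Cooper flux weighting (exact for the stationary flux,
positivity preserving, unconditionally stable).  First-passage densities
are the recorded boundary fluxes, not probability piled at the boundary;
with implicit flux bookkeeping the interior mass plus cumulative absorbed
flux telescopes to 1 at machine precision, and the suite asserts
`|1 − total| < 1e−6` per step.  Default grids: `dx = B/100`, `dt = 0.5` ms
for solving (oracle-facing); fitting uses `dt = 2` ms, `dx = B/40`, which
changes recovered parameters well below the recovery tolerance.  Flux of
the step ending at `(k+1)·dt` is attributed to time `k·dt`, which centers
the implicit scheme's effective timing (mean decision times then match
closed forms to < 5·10⁻⁴ s).  Non-decision convolution uses a truncated
normal kernel on the same grid (FFT convolution, negatives clipped at 0).
Drift-noise marginalization averages solutions over `n_bins = 11`
quantile-midpoint samples of `N(0, σ_d)`; the 2-D value-noise variant uses
a 5 × 5 quantile grid.

**Simulation.** Euler–Maruyama at `dt = 1` ms with within-step bound
crossings resolved by the Brownian-bridge crossing probability, so
simulated crossing statistics match the continuous-time process (and hence
the FP likelihood) rather than the discrete skeleton.  Trials that fail to
cross within 20 s are flagged censored and dropped by the generator with a
logged count.

**Likelihoods.** Per-trial densities are floored at 1e−10 before the log
(optimizer robustness on outlier RTs).  The PDG likelihood caches one FP
solve per unique `(Δr, Σr)` cell; `1 + γΣr ≤ 0` returns `−inf`.  The aDDM
likelihood (choice and decision time given the trial's dwell schedule)
carries no non-decision term; the schedule is truncated at the decision
time, and `μ_nd` is set post hoc as the participant's mean RT minus the
mean simulated decision time under the fitted parameters.  For simulated
trials the recorded bound-crossing time is used as the decision time; for
empirical-format data without one, the summed item-dwell time before the
report stands in (the approximation the dwell-conditioned likelihood
implies).

**Optimization.** Multi-start Nelder–Mead (adaptive simplex) within
declared box bounds; the study names a Bayesian direct-search optimizer but
prescribes no bounds or starts, so the bounds here are package defaults
(documented in `fitting.DEFAULT_BOUNDS`).  Standard errors come from a
central-difference Hessian of the negative log-likelihood at the optimum
(pseudo-inverse; non-positive curvature yields NaN).  Fits are strictly
per participant.  BIC = `k·ln n − 2·logL`; ties break toward fewer
parameters.

## Analysis conventions

- Times are trial-relative seconds, stimulus onset 0, fixation intervals
  half-open `[t_on, t_off)`.  Dwell totals truncate at the report; gaze
  after the report (emitted 0.6 s past it by the simulators) feeds only the
  post-report analyses.
- `last_fixated` is the item under gaze at the moment of the report
  (an epoch ending exactly at the report counts when no epoch covers it);
  the "last item looked at before the report" rule is available via a flag
  and agrees with the primary rule on ≥ 95% of simulated trials.  Trials
  with gaze on neither item at the report are excluded from last-fixation
  analyses.
- Σr quintile edges are pooled across the dataset by default (the bias
  regression is a single pooled model); a flag switches to per-participant
  edges.  Decile curves use per-participant edges by default.
- The consistency regression uses RT in raw seconds; the one-tailed test is
  of `β_c < 0`.  The magnitude-effect-on-RT analysis detrends RT with a
  3-parameter Gaussian ("bell-shaped") function of Δr per participant,
  falling back (flagged) to a quadratic in |Δr| when the curve fit fails.
- Logistic fits are unpenalized ML with a separation detector; on
  separation or non-convergence a small ridge penalty is used and flagged,
  never silently.
- Cascade curves average a 1-ms 1/0/NaN gaze matrix within, then across
  participants; the stimulus-aligned curve blanks the 500 ms before the
  report and records where ≥ 50% of trials fixate an item; the
  fixation-time alignment removes off-item gaze (for models whose drift is
  undefined off-item).

## Problem sizes

The test suite exercises the battery at the study scale it needs: the
consistency and dissociation checks use 39 × 100-trial studies (aDDM runs
with each pair repeated 10 times, ≈ 39,000 trials); recovery uses
1,000-trial synthetic participants; solver–simulation equivalence uses
10⁵-rep Monte Carlo per schedule.  Unit tests use smaller replicas of the
same design.

## Known limitations

- The aDDM likelihood conditions on observed dwell schedules, so recovery
  of `μ_nd` is post hoc and approximate by construction.
- The value-noise variant's 2-D marginalization is coarse (5 × 5 bins) for
  tractability; refining bins changes likelihoods little but is available.
- Simulated gaze is gapless; analyses that depend on off-item gaze (e.g.,
  the stimulus-aligned display-start rule) are exercised structurally, not
  against eye-tracker artifacts.
- No hierarchical pooling across participants, no collapsing bounds, no
  more than two items, no attribute-level accumulation.
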