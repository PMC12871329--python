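# gazeflux

Models and diagnostics for **preferential choice with eye tracking**: did
gaze *cause* the choice, or does gaze merely *reflect* a choice already
made?

The package implements, on a common synthetic-data backbone, the two
competing accounts of the gaze–choice association in two-item value-based
choice (the "which snack do you prefer" paradigm):

- the **attentional drift-diffusion model (aDDM)** family, in which gaze
  modulates evidence accumulation *during* the decision — multiplicative
  discount of the unattended item, an additive variant, and variants with
  inter-trial drift or value noise;
- the **post-decision-gaze (PDG) model**, in which attention is causally
  inert and gaze shifts to the chosen item only *after* the decision
  variable covertly crosses a bound — plus a hybrid of the two.

It provides Monte-Carlo forward simulators (full gaze traces, including
post-report gaze), numerical **Fokker–Planck first-passage likelihoods**
(constant drift for PDG; dwell-schedule-switching drift for the aDDM),
per-participant **maximum-likelihood fitting** with BIC comparison and a
parameter-recovery harness, and the **behavioral test battery** that
dissociates the accounts: the magnitude effect on the last-fixation bias
(MELFB), the ΔDwell-by-consistency regression, first-dwell regressions,
gaze-cascade curves, the post-report gaze test, and the magnitude effect
on RT (MERT).  It is aimed at computational cognitive scientists who want
to run these diagnostics on their own fixation datasets or stress-test
model variants on simulated studies.

## The models in brief

A decision variable `x` accumulates noisy evidence between absorbing
bounds `±B` (unit variance per second; upper bound → right choice).

**aDDM** (multiplicative): while looking at the left item
`dx = κ(θ·r_right − r_left)dt + dW`; while looking right
`dx = κ(r_right − θ·r_left)dt + dW`, with `θ ∈ [0,1]` the attentional
discount.  The classic per-millisecond parameterization (`d`, `σ`,
bounds ±1) maps to this form by `κ = (d/σ)√(1/dt)`, `B = 1/(σ√(1/dt))` —
for `d = 0.0002`/ms, `σ = 0.02`: `κ = 0.3162`, `B = 1.5811`.

**PDG**: `dx = κ(r_right − r_left)dt + σdW` with
`σ² = 1 + γ(r_left + r_right)`, accumulation beginning after a sensory
delay `τ_s`; RT = crossing time + truncated-normal non-decision time; gaze
follows an exogenous alternating dwell process until `τ_e` after the
crossing, then locks onto the chosen item — possibly after the report.

Likelihoods of (choice, RT) / (choice, decision time | dwell schedule) are
computed by propagating the interior density with an implicit
Chang–Cooper finite-volume scheme and reading first-passage densities off
the absorbing-boundary fluxes.

## Worked example

`examples/04_behavioral_battery.py` simulates a full study from each model
and runs the two diagnostic regressions plus the post-report gaze test:

```
aDDM (15600 trials)
  MELFB interaction slope = +0.1127, p = 7.90e-78
  consistency beta_c      = -0.2530, one-tailed p = 5.98e-85
  post- vs pre-report gaze on chosen: Wilcoxon p = 1.00e+00

PDG (3900 trials)
  MELFB interaction slope = -0.0015, p = 9.02e-01
  consistency beta_c      = +0.0116, one-tailed p = 6.95e-01
  post- vs pre-report gaze on chosen: Wilcoxon p = 3.64e-12
```

Reading: under multiplicative attention the last-fixation bias grows with
the overall value of the pair (positive interaction slope) and the chosen
item's dwell advantage is larger on preference-inconsistent trials
(`β_c < 0`) — attention that causes choices leaves both fingerprints.  The
PDG model shows neither, but uniquely predicts that the probability of
looking at the chosen item keeps rising *after* the report (tiny Wilcoxon
p), because the post-commitment gaze shift is not time-locked to the
key press.  The other examples cover simulation (`01`), the first-passage
solver vs. closed forms (`02`), and parameter recovery (`03`).

A thin CLI mirrors the library: `gazeflux simulate | validate | fit |
analyze` (see `--help`).

## Data format

CSV, one row per trial:
`participant_id, r_left, r_right, choice, rt, fixations[, decision_time]`
where `fixations` is a JSON list of `[item, t_on, t_off]` with
`item ∈ {left, right, none}`, times in trial-relative seconds (stimulus
onset 0, half-open intervals).  `gazeflux validate data.csv` checks
invariants and reports dropped rows.

## Layout

- `src/gazeflux/data_model.py` — trial/fixation types, CSV I/O, feature table
- `src/gazeflux/synthetic.py` — study design, dwell model, dataset generator
- `src/gazeflux/simulators.py` — Monte-Carlo simulators for all variants
- `src/gazeflux/fokker_planck.py` — first-passage solver and convolutions
- `src/gazeflux/fitting.py` — likelihoods, Nelder-Mead fits, BIC comparison
- `src/gazeflux/analyses.py` — the behavioral test battery
- `docs/methods.md` — modeling assumptions, numerics, and design choices
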