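"""Monte-Carlo forward simulation of the aDDM family and the PDG model.

All models accumulate evidence with unit-variance-per-second noise
(``sigma = 1`` for the aDDM variants; ``sigma^2 = 1 + gamma * sum_r`` for
the PDG model) between symmetric absorbing bounds.  Sign convention used
throughout the package: positive drift favors the right item and the
upper bound maps to the right choice.

Drift rules per variant (right-positive axis):

- ``addm_mult``    attending left: kappa*(theta*r_right - r_left);
                   attending right: kappa*(r_right - theta*r_left)
- ``addm_add``     kappa*(r_right - r_left + s*omega), s=+1 attending right,
                   s=-1 attending left
- ``addm_driftvar``  multiplicative rule plus a trial-constant Gaussian
                   drift perturbation v ~ N(0, sigma_d)
- ``addm_valuenoise``  multiplicative rule with item values perturbed once
                   per trial: r_left+v1, r_right+v2, v ~ N(0, sigma_d)
- ``pdg``          constant drift kappa*(r_right - r_left); gaze is causally
                   inert and shifts to the chosen item only after the bound
                   crossing, with latency tau_e
- ``hybrid``       aDDM dynamics before the crossing (onset delayed by
                   tau_s), PDG-style post-commitment gaze shift after it
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import stats

from gazeflux.data_model import (
    LEFT,
    RIGHT,
    DwellSequence,
    FixationEpoch,
)

__all__ = [
    "AddmParams",
    "PdgParams",
    "HybridPost",
    "ModelSpec",
    "SimTrial",
    "reparameterize_addm",
    "simulate_addm_trial",
    "simulate_pdg_trial",
    "simulate_hybrid_trial",
    "ADDM_VARIANTS",
]

ADDM_VARIANTS = ("addm_mult", "addm_add", "addm_driftvar", "addm_valuenoise")

#: hard cap on accumulation time; non-crossing trials are flagged censored
T_MAX = 20.0
#: gaze is emitted for this long past the choice report (post-report analyses)
POST_MARGIN = 0.6
DEFAULT_DT = 1e-3


@dataclass
class AddmParams:
    """aDDM-family parameters in the unit-variance-per-second form.

    Defaults are the published best-fitting values of the original study
    (kappa and B via the reparameterization of the d/sigma/B=+-1 form,
    theta = 0.3, fixed non-decision time 0.355 s).
    """

    kappa: float = 0.3162
    B: float = 1.5811
    theta: float = 0.3
    omega: float = 0.0
    sigma_d: float = 0.0
    mu_nd: float = 0.355

    def __post_init__(self) -> None:
        if self.B <= 0:
            raise ValueError("B must be positive")
        if not 0 <= self.theta <= 1:
            raise ValueError("theta must be in [0, 1]")
        if self.sigma_d < 0:
            raise ValueError("sigma_d must be >= 0")


@dataclass
class PdgParams:
    """Post-decision-gaze model parameters.

    ``tau_s`` (sensory delay, fixed at 0.3 s in the study) and the gaze-shift
    latency (mu_e = 0.35 s, sigma_e = mu_e / 3) do not enter the choice/RT
    likelihood; they shape the simulated gaze trace only.
    """

    kappa: float = 0.3
    B: float = 1.5
    gamma: float = 0.05
    mu_nd: float = 0.65
    sigma_nd: float = 0.15
    tau_s: float = 0.3
    mu_e: float = 0.35
    sigma_e: float = 0.35 / 3.0

    def __post_init__(self) -> None:
        if self.B <= 0:
            raise ValueError("B must be positive")
        if self.sigma_nd < 0 or self.sigma_e < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.tau_s < 0:
            raise ValueError("tau_s must be >= 0")

    def sigma2(self, sum_r: float) -> float:
        s2 = 1.0 + self.gamma * sum_r
        if s2 <= 0:
            raise ValueError(f"1 + gamma*sum_r must be positive (sum_r={sum_r})")
        return s2


@dataclass
class HybridPost:
    """Post-commitment gaze parameters of the combined aDDM-PDG model
    (study values: tau_s = 0.25 s, mu_e = 0.2 s, sigma_e = 0.05 s)."""

    tau_s: float = 0.25
    mu_e: float = 0.2
    sigma_e: float = 0.05


@dataclass
class ModelSpec:
    """Variant tag plus its parameter vector (and, for the hybrid model,
    the post-commitment gaze parameters and the underlying aDDM rule)."""

    variant: str
    params: AddmParams | PdgParams
    hybrid_post: HybridPost | None = None
    hybrid_variant: str = "addm_mult"

    def __post_init__(self) -> None:
        valid = ADDM_VARIANTS + ("pdg", "hybrid")
        if self.variant not in valid:
            raise ValueError(f"variant must be one of {valid}")
        if self.variant == "pdg" and not isinstance(self.params, PdgParams):
            raise TypeError("pdg variant requires PdgParams")
        if self.variant != "pdg" and not isinstance(self.params, AddmParams):
            raise TypeError(f"{self.variant} requires AddmParams")
        if self.variant == "hybrid" and self.hybrid_post is None:
            self.hybrid_post = HybridPost()


@dataclass
class SimTrial:
    """Outcome of one simulated trial.

    ``decision_time`` is the duration of evidence accumulation (excluding
    any onset delay); ``bound_crossing_time`` is on the trial clock.  The
    gaze trace extends ``POST_MARGIN`` seconds past the report.
    """

    choice: str
    decision_time: float
    rt: float
    bound_crossing_time: float
    fixations: list[FixationEpoch]
    censored: bool = False


def reparameterize_addm(
    d: float, sigma: float, B_orig: float, dt_orig: float
) -> tuple[float, float]:
    """Convert original aDDM parameters (per-step drift gain ``d`` at step
    ``dt_orig`` seconds, per-step noise SD ``sigma``, bound ``B_orig``) to
    the parameterization with unit accumulation variance per second:

        kappa = (d / sigma) * sqrt(1 / dt_orig)
        B     = B_orig / (sigma * sqrt(1 / dt_orig))

    With d = 0.0002 per ms, sigma = 0.02, B_orig = 1, dt_orig = 0.001 s this
    yields kappa = 0.3162 and B = 1.5811.
    """
    if sigma <= 0 or dt_orig <= 0 or B_orig <= 0 or d <= 0:
        raise ValueError("all reparameterization inputs must be positive")
    scale = math.sqrt(1.0 / dt_orig)
    return d / sigma * scale, B_orig / (sigma * scale)


# ---------------------------------------------------------------------------
# Monte-Carlo kernels


@njit(cache=True)
def _mc_batch(mu_epochs, dur_epochs, n_epochs, sigma, B, dt, t_start, t_max, seeds):
    """Euler-Maruyama first passage for a batch of trials with epoch-wise
    piecewise-constant drift.  Within-step bound crossings are resolved
    with the Brownian-bridge crossing probability, so crossing statistics
    match the continuous-time diffusion rather than the discrete skeleton.

    Accumulation runs from ``t_start``; the attended-epoch clock runs from
    0.  Returns (side, t_cross) with side +1 for the upper bound, -1 for
    the lower, 0 if censored at ``t_max``; ``t_cross`` is on the trial
    clock."""
    n = mu_epochs.shape[0]
    side = np.zeros(n, dtype=np.int8)
    t_cross = np.full(n, t_max)
    for i in range(n):
        np.random.seed(seeds[i])
        x = 0.0
        t = 0.0
        e = 0
        edge = dur_epochs[i, 0]
        last = n_epochs[i] - 1
        sq = sigma[i] * math.sqrt(dt)
        s2dt = sigma[i] * sigma[i] * dt
        while t < t_max:
            while t >= edge and e < last:
                e += 1
                edge += dur_epochs[i, e]
            if t >= t_start:
                x1 = x + mu_epochs[i, e] * dt + sq * np.random.normal()
                t += dt
                if x1 >= B:
                    side[i] = 1
                    t_cross[i] = t
                    break
                elif x1 <= -B:
                    side[i] = -1
                    t_cross[i] = t
                    break
                # within-step excursion beyond a bound (Brownian bridge)
                p_up = math.exp(-2.0 * (B - x) * (B - x1) / s2dt)
                p_lo = math.exp(-2.0 * (x + B) * (x1 + B) / s2dt)
                u = np.random.random()
                if u < p_up:
                    side[i] = 1
                    t_cross[i] = t
                    break
                elif u < p_up + p_lo:
                    side[i] = -1
                    t_cross[i] = t
                    break
                x = x1
            else:
                t += dt
    return side, t_cross


def drift_pair(
    variant: str,
    p: AddmParams,
    r_left: float,
    r_right: float,
    v: float = 0.0,
    v1: float = 0.0,
    v2: float = 0.0,
) -> tuple[float, float]:
    """Drift while attending (left, right), on the right-positive axis."""
    k, th = p.kappa, p.theta
    if variant == "addm_mult":
        return k * (th * r_right - r_left), k * (r_right - th * r_left)
    if variant == "addm_add":
        base = k * (r_right - r_left)
        return base - k * p.omega, base + k * p.omega
    if variant == "addm_driftvar":
        return (
            k * (th * r_right - r_left) + v,
            k * (r_right - th * r_left) + v,
        )
    if variant == "addm_valuenoise":
        rl, rr = r_left + v1, r_right + v2
        return k * (th * rr - rl), k * (rr - th * rl)
    raise ValueError(f"unknown aDDM variant: {variant}")


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, size=None):
    """Normal(mean, sd) truncated to non-negative values."""
    if sd == 0:
        val = max(mean, 0.0)
        return val if size is None else np.full(size, val)
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(
        a=a, b=np.inf, loc=mean, scale=sd, size=size, random_state=rng
    )


def _seed_for(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def _epoch_arrays(dwells: DwellSequence):
    items = dwells.items.astype(np.int8)
    durs = dwells.durations.astype(float)
    return items, durs


def _hold_then_shift(
    dwells: DwellSequence,
    t_freeze: float,
    t_shift: float,
    chosen: str,
    horizon: float,
) -> list[FixationEpoch]:
    """Exogenous dwells until ``t_freeze`` (the bound crossing, where dwell
    sampling stops), gaze held on the item under gaze there, then a shift
    to the chosen item at ``t_shift`` (never, if ``t_shift`` is inf)."""
    if t_freeze >= horizon:
        return dwells.to_epochs(horizon=horizon)
    epochs = dwells.to_epochs(horizon=t_freeze)
    hold_until = min(t_shift, horizon)
    if epochs and hold_until > epochs[-1].t_on:
        prev = epochs.pop()
        epochs.append(FixationEpoch(prev.item, prev.t_on, hold_until))
    if hold_until < horizon:
        if epochs and epochs[-1].item == chosen:
            prev = epochs.pop()
            epochs.append(FixationEpoch(chosen, prev.t_on, horizon))
        else:
            epochs.append(FixationEpoch(chosen, hold_until, horizon))
    return epochs


def _trace_with_shift(
    dwells: DwellSequence, t_shift: float, chosen: str, horizon: float
) -> list[FixationEpoch]:
    """Exogenous dwell trace up to ``t_shift``, then gaze held on the chosen
    item through ``horizon`` (merged if already on it)."""
    if t_shift >= horizon:
        return dwells.to_epochs(horizon=horizon)
    epochs = dwells.to_epochs(horizon=t_shift)
    if epochs and epochs[-1].item == chosen:
        prev = epochs.pop()
        epochs.append(FixationEpoch(chosen, prev.t_on, horizon))
    else:
        if epochs and epochs[-1].t_off < t_shift:
            t_shift = epochs[-1].t_off  # gapless sequences: should not occur
        epochs.append(FixationEpoch(chosen, t_shift, horizon))
    return epochs


def _run_single(
    mu_left: float,
    mu_right: float,
    dwells: DwellSequence,
    sigma: float,
    B: float,
    dt: float,
    t_start: float,
    rng: np.random.Generator,
):
    items, durs = _epoch_arrays(dwells)
    mus = np.where(items == 0, mu_left, mu_right).astype(float)
    side, t_cross = _mc_batch(
        mus.reshape(1, -1),
        durs.reshape(1, -1),
        np.array([items.size], dtype=np.int64),
        np.array([sigma]),
        B,
        dt,
        t_start,
        T_MAX,
        np.array([_seed_for(rng)], dtype=np.int64),
    )
    return int(side[0]), float(t_cross[0])


def simulate_addm_trial(
    params: AddmParams,
    variant: str,
    r_left: float,
    r_right: float,
    dwells: DwellSequence,
    rng: np.random.Generator,
    dt: float = DEFAULT_DT,
) -> SimTrial:
    """One aDDM-family trial: drift follows the attended item through the
    exogenous dwell sequence; RT = decision time + mu_nd.  Dwell sampling
    stops at the crossing; gaze then stays on the item under gaze there
    (the model has no post-commitment gaze mechanism)."""
    if variant not in ADDM_VARIANTS:
        raise ValueError(f"variant must be one of {ADDM_VARIANTS}")
    v = v1 = v2 = 0.0
    if variant == "addm_driftvar":
        v = rng.normal(0.0, params.sigma_d)
    elif variant == "addm_valuenoise":
        v1, v2 = rng.normal(0.0, params.sigma_d, size=2)
    mu_l, mu_r = drift_pair(variant, params, r_left, r_right, v=v, v1=v1, v2=v2)
    side, t_cross = _run_single(mu_l, mu_r, dwells, 1.0, params.B, dt, 0.0, rng)
    censored = side == 0
    choice = RIGHT if side > 0 else LEFT
    rt = t_cross + params.mu_nd
    fixations = _hold_then_shift(dwells, t_cross, np.inf, choice, rt + POST_MARGIN)
    return SimTrial(choice, t_cross, rt, t_cross, fixations, censored)


def simulate_pdg_trial(
    params: PdgParams,
    r_left: float,
    r_right: float,
    dwells: DwellSequence,
    rng: np.random.Generator,
    dt: float = DEFAULT_DT,
) -> SimTrial:
    """One PDG trial: constant drift kappa*(r_right - r_left), variance
    1 + gamma*sum_r, accumulation onset at tau_s.  After the crossing the
    gaze shifts to the chosen item with latency tau_e; the shift may land
    after the report."""
    mu = params.kappa * (r_right - r_left)
    sigma = math.sqrt(params.sigma2(r_left + r_right))
    side, t_cross = _run_single(
        mu, mu, dwells, sigma, params.B, dt, params.tau_s, rng
    )
    censored = side == 0
    choice = RIGHT if side > 0 else LEFT
    tau_m = float(_truncnorm(rng, params.mu_nd - params.tau_s, params.sigma_nd))
    tau_e = float(_truncnorm(rng, params.mu_e, params.sigma_e))
    rt = t_cross + tau_m
    decision_time = t_cross - params.tau_s
    fixations = _trace_with_shift(dwells, t_cross + tau_e, choice, rt + POST_MARGIN)
    return SimTrial(choice, decision_time, rt, t_cross, fixations, censored)


def simulate_hybrid_trial(
    params: AddmParams,
    r_left: float,
    r_right: float,
    dwells: DwellSequence,
    rng: np.random.Generator,
    post: HybridPost | None = None,
    variant: str = "addm_mult",
    dt: float = DEFAULT_DT,
) -> SimTrial:
    """Combined model: aDDM dynamics before the crossing (onset delayed by
    tau_s); gaze holds the crossing item, then shifts to the chosen item
    with latency tau_e, PDG-style."""
    post = post or HybridPost()
    v = v1 = v2 = 0.0
    if variant == "addm_driftvar":
        v = rng.normal(0.0, params.sigma_d)
    elif variant == "addm_valuenoise":
        v1, v2 = rng.normal(0.0, params.sigma_d, size=2)
    mu_l, mu_r = drift_pair(variant, params, r_left, r_right, v=v, v1=v1, v2=v2)
    side, t_cross = _run_single(
        mu_l, mu_r, dwells, 1.0, params.B, dt, post.tau_s, rng
    )
    censored = side == 0
    choice = RIGHT if side > 0 else LEFT
    tau_e = float(_truncnorm(rng, post.mu_e, post.sigma_e))
    rt = t_cross + params.mu_nd
    decision_time = t_cross - post.tau_s
    fixations = _hold_then_shift(
        dwells, t_cross, t_cross + tau_e, choice, rt + POST_MARGIN
    )
    return SimTrial(choice, decision_time, rt, t_cross, fixations, censored)
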