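"""Independent oracles used by the test-suite only.

These deliberately do not share code with the package's solvers: the
Monte-Carlo first-passage oracle uses Euler steps with a Brownian-bridge
within-step crossing correction (removing the leading-order crossing
bias), and the original-parameterization accumulator reproduces the
classic per-millisecond update rule directly.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def mc_first_passage(durs, drifts, sigma, B, dt, n_reps, seed, t_max):
    """Bridge-corrected Euler first passage under a piecewise-constant
    drift schedule.  Returns (side, time): +1 upper, -1 lower, 0 censored."""
    np.random.seed(seed)
    sides = np.zeros(n_reps, dtype=np.int8)
    times = np.full(n_reps, t_max)
    nseg = durs.size
    sq = sigma * np.sqrt(dt)
    s2dt = sigma * sigma * dt
    for r in range(n_reps):
        x = 0.0
        t = 0.0
        e = 0
        edge = durs[0]
        while t < t_max:
            while t >= edge and e < nseg - 1:
                e += 1
                edge += durs[e]
            x1 = x + drifts[e] * dt + sq * np.random.normal()
            t += dt
            if x1 >= B:
                sides[r] = 1
                times[r] = t
                break
            if x1 <= -B:
                sides[r] = -1
                times[r] = t
                break
            pu = np.exp(-2.0 * (B - x) * (B - x1) / s2dt)
            pl = np.exp(-2.0 * (x + B) * (x1 + B) / s2dt)
            u = np.random.random()
            if u < pu:
                sides[r] = 1
                times[r] = t
                break
            elif u < pu + pl:
                sides[r] = -1
                times[r] = t
                break
            x = x1
    return sides, times


def original_addm_trial(d, sigma, theta, r_left, r_right, dwell_durs,
                        dwell_items, rng, t_max_steps=20_000):
    """One trial of the classic per-millisecond accumulator: per-step update
    d*(r_attended - theta*r_unattended) with per-step noise SD ``sigma``,
    bounds at +-1, upper bound = left choice (original convention).
    Returns (choice_left, decision_time_s) or (None, nan) if censored."""
    edges_ms = np.cumsum(np.asarray(dwell_durs) * 1000.0)
    x = 0.0
    e = 0
    for step in range(t_max_steps):
        t_ms = step
        while t_ms >= edges_ms[e] and e < len(edges_ms) - 1:
            e += 1
        if dwell_items[e] == 0:  # attending left
            mu = d * (r_left - theta * r_right)
        else:
            mu = d * (theta * r_left - r_right)
        x += mu + sigma * rng.standard_normal()
        if x >= 1.0:
            return True, (step + 1) / 1000.0
        if x <= -1.0:
            return False, (step + 1) / 1000.0
    return None, float("nan")
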