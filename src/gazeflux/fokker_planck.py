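"""Numerical first-passage distributions for bounded drift-diffusion.

The decision variable follows ``dx = mu dt + sigma dW`` between absorbing
bounds at ``+B`` and ``-B``, starting from 0.  The joint density of
(which bound, crossing time) is obtained by propagating the interior
probability density with a fully implicit finite-volume scheme using
Chang-Cooper flux weighting, and recording the probability flux absorbed
at each bound on every time step.  Recording flux (rather than density
piled at the boundary) conserves mass exactly in the implicit scheme:
at every step the interior mass plus the cumulative absorbed flux sums
to one up to floating-point round-off.

Drift may be constant (``solve_constant``) or piecewise-constant in time
(``solve_switching``), the latter serving likelihoods in which the drift
tracks the momentary focus of gaze.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import signal, stats

__all__ = [
    "ChoiceRTDistribution",
    "DriftSchedule",
    "solve_constant",
    "solve_switching",
    "convolve_nondecision",
    "marginalize_drift_noise",
]

#: per-trial densities are clipped here before taking logs, so a single
#: outlier RT cannot send an optimizer to -inf
LIKELIHOOD_FLOOR = 1e-10


@dataclass
class ChoiceRTDistribution:
    """Discretized joint density of (bound, crossing time).

    ``f_upper[k]`` / ``f_lower[k]`` are the first-passage densities
    (probability per second) attributed to time ``t[k]``; ``survival[k]``
    is the probability mass still strictly between the bounds after the
    step ending near ``t[k]``.
    """

    t: np.ndarray
    f_upper: np.ndarray
    f_lower: np.ndarray
    survival: np.ndarray
    dt: float

    @property
    def p_upper(self) -> float:
        return float(np.sum(self.f_upper) * self.dt)

    @property
    def p_lower(self) -> float:
        return float(np.sum(self.f_lower) * self.dt)

    @property
    def total_mass(self) -> float:
        """Absorbed plus surviving mass; 1 up to round-off."""
        return self.p_upper + self.p_lower + float(self.survival[-1])

    def mean_decision_time(self) -> float:
        """Mean crossing time over both bounds (conditional on absorption)."""
        f = self.f_upper + self.f_lower
        w = np.sum(f) * self.dt
        return float(np.sum(self.t * f) * self.dt / w)

    def density_at(self, upper: bool, t: float | np.ndarray) -> np.ndarray:
        """Linearly interpolated first-passage density at time(s) ``t``."""
        f = self.f_upper if upper else self.f_lower
        return np.interp(t, self.t, f, left=0.0, right=0.0)


@dataclass
class DriftSchedule:
    """Piecewise-constant drift: ordered (duration, drift) segments."""

    durations: np.ndarray
    drifts: np.ndarray

    def __post_init__(self) -> None:
        self.durations = np.asarray(self.durations, dtype=float)
        self.drifts = np.asarray(self.drifts, dtype=float)
        if self.durations.size != self.drifts.size:
            raise ValueError("durations and drifts must have equal length")
        if self.durations.size == 0:
            raise ValueError("schedule must have at least one segment")
        if np.any(self.durations <= 0):
            raise ValueError("segment durations must be positive")

    @property
    def total_duration(self) -> float:
        return float(np.sum(self.durations))


@njit(cache=True)
def _cc_coeffs(mu, D, dx):
    """Chang-Cooper face coefficients: flux = alpha*p_left + beta*p_right."""
    w = mu * dx / D
    if abs(w) < 1e-8:
        delta = 0.5 - w / 12.0
    else:
        delta = 1.0 / w - 1.0 / np.expm1(w)
    alpha = mu * (1.0 - delta) + D / dx
    beta = mu * delta - D / dx
    return alpha, beta


@njit(cache=True)
def _propagate(p, mu, D, dx, dt, nsteps, f_up, f_low, surv, k0):
    """Implicit-Euler propagation with constant drift for ``nsteps`` steps.

    ``p`` holds the interior nodes (bounds excluded, density zero there) and
    is updated in place.  Fluxes and surviving mass are written into the
    output arrays starting at index ``k0``.
    """
    n = p.size
    alpha, beta = _cc_coeffs(mu, D, dx)
    a = -dt * alpha / dx          # sub-diagonal
    b = 1.0 + dt * (alpha - beta) / dx
    c = dt * beta / dx            # super-diagonal
    # Thomas prefactorization (Toeplitz tridiagonal)
    cp = np.empty(n)
    inv = np.empty(n)
    inv[0] = 1.0 / b
    cp[0] = c * inv[0]
    for i in range(1, n):
        inv[i] = 1.0 / (b - a * cp[i - 1])
        cp[i] = c * inv[i]
    d = np.empty(n)
    for k in range(nsteps):
        d[0] = p[0] * inv[0]
        for i in range(1, n):
            d[i] = (p[i] - a * d[i - 1]) * inv[i]
        p[n - 1] = d[n - 1]
        for i in range(n - 2, -1, -1):
            p[i] = d[i] - cp[i] * p[i + 1]
        f_up[k0 + k] = alpha * p[n - 1]
        f_low[k0 + k] = -beta * p[0]
        s = 0.0
        for i in range(n):
            s += p[i]
        surv[k0 + k] = s * dx
    return k0 + nsteps


@njit(cache=True)
def _propagate_switching(p, mus, seg_steps, D, dx, dt, f_up, f_low, surv):
    k = 0
    for j in range(mus.size):
        k = _propagate(p, mus[j], D, dx, dt, seg_steps[j], f_up, f_low, surv, k)
    return k


@njit(cache=True)
def _switching_density_at(durs, drifts, D, dx, dt, n_interior, t_query):
    """First-passage densities (upper, lower) at ``t_query`` under a
    piecewise-constant drift schedule, without materializing the full
    distribution.  Slim path for per-trial likelihood evaluation."""
    nseg = durs.size
    seg_steps = np.empty(nseg, dtype=np.int64)
    total = 0
    for j in range(nseg):
        s = int(round(durs[j] / dt))
        if s < 1:
            s = 1
        seg_steps[j] = s
        total += s
    p = np.zeros(n_interior)
    p[n_interior // 2] = 1.0 / dx
    f_up = np.empty(total)
    f_low = np.empty(total)
    surv = np.empty(total)
    _propagate_switching(p, drifts, seg_steps, D, dx, dt, f_up, f_low, surv)
    # grid convention: flux of step k attributed to time k*dt
    pos = t_query / dt
    k0 = int(pos)
    if k0 >= total - 1:
        return f_up[total - 1], f_low[total - 1]
    w = pos - k0
    return (
        f_up[k0] * (1 - w) + f_up[k0 + 1] * w,
        f_low[k0] * (1 - w) + f_low[k0 + 1] * w,
    )


def _initial_density(B: float, dx: float) -> tuple[np.ndarray, int]:
    """Delta at x=0 on the interior grid; returns (p, n_interior)."""
    n_cells = int(round(2 * B / dx))
    if n_cells % 2 == 1:
        n_cells += 1
    n = n_cells - 1  # interior nodes
    p = np.zeros(n)
    p[n // 2] = 1.0 / dx
    return p, n


def _grid_spacing(B: float, dx: float | None) -> float:
    if dx is None:
        dx = B / 100.0
    if dx <= 0 or dx > B / 10.0:
        raise ValueError("dx must be positive and resolve the bound (dx <= B/10)")
    return 2 * B / int(round(2 * B / dx))


def solve_constant(
    mu: float,
    sigma2: float,
    B: float,
    dt: float = 5e-4,
    dx: float | None = None,
    horizon: float = 20.0,
    stop_mass: float = 1e-8,
) -> ChoiceRTDistribution:
    """First-passage distribution for constant drift ``mu`` and variance
    ``sigma2`` (per second) between absorbing bounds at ``+/-B``.

    Propagation stops early once the surviving interior mass drops below
    ``stop_mass`` (checked in blocks), else at ``horizon`` seconds.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if B <= 0 or dt <= 0:
        raise ValueError("B and dt must be positive")
    dx = _grid_spacing(B, dx)
    p, _ = _initial_density(B, dx)
    D = sigma2 / 2.0
    total_steps = int(np.ceil(horizon / dt))
    block = max(1, min(total_steps, 2000))
    f_up = np.empty(total_steps)
    f_low = np.empty(total_steps)
    surv = np.empty(total_steps)
    k = 0
    while k < total_steps:
        nb = min(block, total_steps - k)
        k = _propagate(p, mu, D, dx, dt, nb, f_up, f_low, surv, k)
        if surv[k - 1] < stop_mass:
            break
    t = np.arange(k) * dt
    return ChoiceRTDistribution(t, f_up[:k], f_low[:k], surv[:k], dt)


def solve_switching(
    schedule: DriftSchedule,
    sigma2: float,
    B: float,
    dt: float = 5e-4,
    dx: float | None = None,
) -> ChoiceRTDistribution:
    """First-passage distribution under a piecewise-constant drift schedule.

    The interior density is propagated segment by segment with each
    segment's drift; the returned grid covers the full schedule duration.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    dx = _grid_spacing(B, dx)
    p, _ = _initial_density(B, dx)
    D = sigma2 / 2.0
    seg_steps = np.maximum(1, np.round(schedule.durations / dt)).astype(np.int64)
    total = int(np.sum(seg_steps))
    f_up = np.empty(total)
    f_low = np.empty(total)
    surv = np.empty(total)
    _propagate_switching(p, schedule.drifts, seg_steps, D, dx, dt, f_up, f_low, surv)
    t = np.arange(total) * dt
    return ChoiceRTDistribution(t, f_up, f_low, surv, dt)


def nondecision_kernel(mu_nd: float, sigma_nd: float, dt: float) -> np.ndarray:
    """Truncated-normal (non-negative) non-decision density sampled at k*dt,
    normalized so that ``sum(kernel) * dt == 1``."""
    if sigma_nd < 0:
        raise ValueError("sigma_nd must be >= 0")
    if sigma_nd == 0:
        k = np.zeros(int(round(max(mu_nd, 0.0) / dt)) + 1)
        k[-1] = 1.0 / dt
        return k
    upper = mu_nd + 6 * sigma_nd
    tgrid = np.arange(0.0, upper + dt, dt)
    a = (0.0 - mu_nd) / sigma_nd
    pdf = stats.truncnorm.pdf(tgrid, a=a, b=np.inf, loc=mu_nd, scale=sigma_nd)
    s = pdf.sum() * dt
    if s <= 0:
        raise ValueError("degenerate non-decision kernel")
    return pdf / s


def convolve_nondecision(
    dist: ChoiceRTDistribution, mu_nd: float, sigma_nd: float
) -> ChoiceRTDistribution:
    """Joint (bound, RT) distribution: decision time plus an independent
    truncated-normal non-decision latency (support restricted to t >= 0,
    renormalized).  Mass at each bound is preserved."""
    kernel = nondecision_kernel(mu_nd, sigma_nd, dist.dt)
    if kernel.size > 64 and dist.f_upper.size > 64:
        f_up = signal.fftconvolve(dist.f_upper, kernel) * dist.dt
        f_low = signal.fftconvolve(dist.f_lower, kernel) * dist.dt
        np.maximum(f_up, 0.0, out=f_up)  # FFT round-off can dip below zero
        np.maximum(f_low, 0.0, out=f_low)
    else:
        f_up = np.convolve(dist.f_upper, kernel) * dist.dt
        f_low = np.convolve(dist.f_lower, kernel) * dist.dt
    n = f_up.size
    t = dist.t[0] + np.arange(n) * dist.dt
    # survival in RT terms is not tracked past the decision horizon; carry
    # the terminal surviving mass forward for the mass-balance invariant
    surv = np.full(n, dist.survival[-1])
    surv[: dist.survival.size] = dist.survival
    return ChoiceRTDistribution(t, f_up, f_low, surv, dist.dt)


def marginalize_drift_noise(
    solver,
    sigma_d: float,
    n_bins: int = 11,
) -> ChoiceRTDistribution:
    """Average first-passage solutions over a zero-mean Gaussian drift
    perturbation, discretized into ``n_bins`` quantile-midpoint samples.

    ``solver`` maps a drift offset to a ``ChoiceRTDistribution``; all calls
    must return the same time grid (use a fixed horizon / schedule).
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if sigma_d < 0:
        raise ValueError("sigma_d must be >= 0")
    if sigma_d == 0:
        return solver(0.0)
    qs = (np.arange(n_bins) + 0.5) / n_bins
    offsets = stats.norm.ppf(qs) * sigma_d
    dists = [solver(v) for v in offsets]
    n = min(d.t.size for d in dists)
    f_up = np.mean([d.f_upper[:n] for d in dists], axis=0)
    f_low = np.mean([d.f_lower[:n] for d in dists], axis=0)
    surv = np.mean([d.survival[:n] for d in dists], axis=0)
    return ChoiceRTDistribution(dists[0].t[:n], f_up, f_low, surv, dists[0].dt)
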