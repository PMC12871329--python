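"""Maximum-likelihood fitting of the PDG and aDDM-family models.

The PDG likelihood is the joint density of (choice, RT) from the
constant-drift first-passage solution with variance ``1 + gamma*sum_r``,
convolved with a truncated-normal non-decision time; trials sharing a
``(delta_r, sum_r)`` cell share one solve.  The aDDM likelihood is the
joint density of (choice, decision time) under the trial's observed dwell
schedule, with the drift switching as gaze alternates; it carries no
non-decision term, and the mean non-decision time is instead set post hoc
as the participant's mean RT minus the mean simulated decision time.

Fits are strictly per participant; optimization is derivative-free
(multi-start Nelder-Mead within box bounds).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from gazeflux.data_model import RIGHT, TrialSet
from gazeflux.fokker_planck import (
    LIKELIHOOD_FLOOR,
    _switching_density_at,
    convolve_nondecision,
    solve_constant,
)
from gazeflux.simulators import (
    ADDM_VARIANTS,
    T_MAX,
    AddmParams,
    PdgParams,
    _mc_batch,
    drift_pair,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FitConfig",
    "FitResult",
    "pdg_loglik",
    "addm_loglik",
    "fit_model",
    "compare_models",
    "DEFAULT_BOUNDS",
]

#: free parameters per variant, in optimization order
FREE_PARAMS = {
    "pdg": ("kappa", "B", "gamma", "mu_nd", "sigma_nd"),
    "addm_mult": ("kappa", "B", "theta"),
    "addm_add": ("kappa", "B", "omega"),
    "addm_driftvar": ("kappa", "B", "theta", "sigma_d"),
    "addm_valuenoise": ("kappa", "B", "theta", "sigma_d"),
}

#: declared default box bounds (the study reports none)
DEFAULT_BOUNDS = {
    "kappa": (0.01, 2.0),
    "B": (0.3, 5.0),
    "gamma": (-0.04, 0.5),
    "mu_nd": (0.05, 1.5),
    "sigma_nd": (0.01, 0.6),
    "theta": (0.0, 1.0),
    "omega": (0.0, 5.0),
    "sigma_d": (0.0, 3.0),
}


@dataclass
class FitConfig:
    """Optimizer and numerics configuration for ``fit_model``."""

    n_starts: int = 5
    seed: int = 0
    maxfev_per_start: int = 250
    dt: float = 2e-3
    dx_frac: int = 40  # spatial grid: dx = B / dx_frac during fitting
    bounds: dict = field(default_factory=dict)
    starts: list | None = None
    compute_se: bool = True
    set_mu_nd: bool = True  # post-hoc mu_nd for aDDM variants
    n_bins: int = 11  # drift-noise marginalization bins
    n_bins_value: int = 5  # per-dimension bins for value-noise


@dataclass
class FitResult:
    """Per-participant maximum-likelihood fit summary."""

    variant: str
    params: dict
    loglik: float
    bic: float
    n_trials: int
    k: int
    seed: int
    n_evals: int
    converged: bool
    se: dict | None = None
    mu_nd_post_hoc: float | None = None
    starts_trace: list = field(default_factory=list)
    data_fingerprint: tuple = ()

    def params_object(self):
        if self.variant == "pdg":
            return PdgParams(**{k: v for k, v in self.params.items()})
        fields = {k: v for k, v in self.params.items()}
        if self.mu_nd_post_hoc is not None:
            fields["mu_nd"] = self.mu_nd_post_hoc
        return AddmParams(**fields)


def _trial_arrays(trials: TrialSet):
    dr = np.array([t.r_right - t.r_left for t in trials], dtype=float)
    sr = np.array([t.r_right + t.r_left for t in trials], dtype=float)
    rt = np.array([t.rt for t in trials], dtype=float)
    right = np.array([t.choice == RIGHT for t in trials], dtype=bool)
    return dr, sr, rt, right


def pdg_loglik(
    params: PdgParams,
    trials: TrialSet,
    dt: float = 1e-3,
    dx: float | None = None,
) -> float:
    """Summed log density of (choice, RT) under the PDG model.

    Returns ``-inf`` if ``1 + gamma*sum_r`` is non-positive for any trial.
    Per-trial densities are floored at ``LIKELIHOOD_FLOOR`` before the log.
    """
    dr, sr, rt, right = _trial_arrays(trials)
    s2 = 1.0 + params.gamma * sr
    if np.any(s2 <= 0):
        logger.warning("pdg_loglik: inadmissible gamma (1 + gamma*sum_r <= 0)")
        return -np.inf
    if params.sigma_nd < 0 or params.B <= 0:
        return -np.inf
    total = 0.0
    for dri, sri in {(a, b) for a, b in zip(dr, sr)}:
        mask = (dr == dri) & (sr == sri)
        mu = params.kappa * dri
        dist = solve_constant(
            mu, 1.0 + params.gamma * sri, params.B,
            dt=dt, dx=dx, horizon=float(rt[mask].max()) + 2 * dt,
            stop_mass=1e-10,
        )
        conv = convolve_nondecision(dist, params.mu_nd, params.sigma_nd)
        dens_r = conv.density_at(True, rt[mask])
        dens_l = conv.density_at(False, rt[mask])
        dens = np.where(right[mask], dens_r, dens_l)
        total += float(np.sum(np.log(np.maximum(dens, LIKELIHOOD_FLOOR))))
    return total


def _trial_schedule(trial, params=None, variant=None):
    """(durations, attended_items, DT) from a trial's item-directed epochs.

    DT is the recorded bound-crossing time when available (simulated data),
    otherwise the summed item-dwell time before the report.  The dwell
    schedule is truncated so its total duration equals DT.
    """
    epochs = [f for f in trial.fixations if f.item in ("left", "right")]
    if not epochs:
        return None
    durs, items = [], []
    for f in epochs:
        durs.append(min(f.t_off, trial.rt) - f.t_on)
        items.append(0 if f.item == "left" else 1)
    durs = np.array(durs)
    keep = durs > 0
    durs, items = durs[keep], np.array(items)[keep]
    if durs.size == 0:
        return None
    total = durs.sum()
    dt_obs = trial.decision_time if trial.decision_time is not None else total
    dt_obs = min(dt_obs, total)
    # truncate the schedule at DT
    cum = np.cumsum(durs)
    n = int(np.searchsorted(cum, dt_obs) + 1)
    n = min(n, durs.size)
    durs = durs[:n].copy()
    durs[-1] -= cum[n - 1] - dt_obs if cum[n - 1] > dt_obs else 0.0
    if durs[-1] <= 0:
        durs = durs[: n - 1]
        items = items[: n - 1]
    else:
        items = items[:n]
    if durs.size == 0:
        return None
    return durs, items, dt_obs


def _value_noise_offsets(params: AddmParams, n_bins: int):
    """Quantile-midpoint grid over (v1, v2) mapped to per-side drift offsets."""
    qs = (np.arange(n_bins) + 0.5) / n_bins
    vs = stats.norm.ppf(qs) * params.sigma_d
    k, th = params.kappa, params.theta
    offsets = []
    for v1 in vs:
        for v2 in vs:
            offsets.append((k * (th * v2 - v1), k * (v2 - th * v1)))
    return offsets


def prepare_addm_trials(trials: TrialSet) -> list:
    """Precompute per-trial dwell schedules for repeated likelihood
    evaluation (they do not depend on the parameters).  Trials with no
    item-directed gaze are excluded (logged count)."""
    prepared = []
    n_skipped = 0
    for trial in trials:
        sched = _trial_schedule(trial, None, None)
        if sched is None:
            n_skipped += 1
            continue
        durs, items, dt_obs = sched
        durs = np.ascontiguousarray(durs, dtype=float)
        prepared.append(
            (durs, np.asarray(items) == 0, dt_obs,
             float(trial.r_left), float(trial.r_right), trial.choice == RIGHT)
        )
    if n_skipped:
        logger.info("addm likelihood: skipped %d trials with no item gaze",
                    n_skipped)
    return prepared


def addm_loglik(
    params: AddmParams,
    variant: str,
    trials,
    dt: float = 1e-3,
    dx: float | None = None,
    n_bins: int = 11,
    n_bins_value: int = 5,
) -> float:
    """Summed log density of (choice, decision time) under the trial-wise
    dwell schedules.  ``addm_driftvar`` and ``addm_valuenoise`` marginalize
    the trial-constant perturbation over quantile-midpoint bins.

    ``trials`` is a TrialSet or the output of :func:`prepare_addm_trials`.
    """
    if variant not in ADDM_VARIANTS:
        raise ValueError(f"variant must be one of {ADDM_VARIANTS}")
    if params.B <= 0:
        return -np.inf
    if isinstance(trials, TrialSet):
        trials = prepare_addm_trials(trials)
    B = params.B
    if dx is None:
        dx = B / 100.0
    dx_eff = 2 * B / int(round(2 * B / dx))
    n_cells = int(round(2 * B / dx_eff))
    if n_cells % 2 == 1:
        n_cells += 1
    n_interior = n_cells - 1
    pad = 3 * dt
    if variant == "addm_driftvar" and params.sigma_d > 0:
        qs = (np.arange(n_bins) + 0.5) / n_bins
        offsets = [(v, v) for v in stats.norm.ppf(qs) * params.sigma_d]
    elif variant == "addm_valuenoise" and params.sigma_d > 0:
        offsets = _value_noise_offsets(params, n_bins_value)
    else:
        offsets = [(0.0, 0.0)]
    base = "addm_mult" if variant in ("addm_driftvar", "addm_valuenoise") else variant
    total = 0.0
    for durs, is_left, dt_obs, r_l, r_r, upper in trials:
        mu_l, mu_r = drift_pair(base, params, r_l, r_r)
        durs_p = durs.copy()
        durs_p[-1] += pad
        dens = 0.0
        for off_l, off_r in offsets:
            drifts = np.where(is_left, mu_l + off_l, mu_r + off_r)
            fu, fl = _switching_density_at(
                durs_p, drifts, 0.5, dx_eff, dt, n_interior, dt_obs
            )
            dens += fu if upper else fl
        dens /= len(offsets)
        total += math.log(max(dens, LIKELIHOOD_FLOOR))
    return total


def _objective(variant: str, trials: TrialSet, cfg: FitConfig):
    names = FREE_PARAMS[variant]
    prepared = None if variant == "pdg" else prepare_addm_trials(trials)

    def build(x):
        kw = dict(zip(names, x))
        if variant == "pdg":
            return PdgParams(**kw)
        return AddmParams(**kw, mu_nd=0.0)

    def f(x):
        try:
            p = build(x)
        except ValueError:
            return 1e12
        dx = p.B / cfg.dx_frac
        if variant == "pdg":
            ll = pdg_loglik(p, trials, dt=cfg.dt, dx=dx)
        else:
            ll = addm_loglik(
                p, variant, prepared, dt=cfg.dt, dx=dx,
                n_bins=cfg.n_bins, n_bins_value=cfg.n_bins_value,
            )
        if not np.isfinite(ll):
            return 1e12
        return -ll

    return f, names


def _post_hoc_mu_nd(params: AddmParams, variant: str, trials: TrialSet,
                    seed: int, n_reps: int = 3) -> float:
    """Mean observed RT minus mean simulated decision time, simulating the
    fitted variant on the trials' own dwell schedules."""
    scheds = []
    rts = []
    for tr in trials:
        s = _trial_schedule(tr, params, variant)
        if s is None:
            continue
        durs, items, _ = s
        # let the schedule run on: recycle it to cover the simulation cap
        reps = int(np.ceil((T_MAX + 1.0) / durs.sum()))
        scheds.append((np.tile(durs, reps), np.tile(items, reps), tr))
        rts.append(tr.rt)
    if not scheds:
        return float("nan")
    kmax = max(d.size for d, _, _ in scheds)
    n = len(scheds)
    durs_m = np.full((n, kmax), 1e-3)
    mu_m = np.zeros((n, kmax))
    n_ep = np.empty(n, dtype=np.int64)
    base_variant = "addm_mult" if variant in ("addm_driftvar", "addm_valuenoise") else variant
    for i, (durs, items, tr) in enumerate(scheds):
        mu_l, mu_r = drift_pair(base_variant, params, tr.r_left, tr.r_right)
        durs_m[i, : durs.size] = durs
        mu_m[i, : durs.size] = np.where(items == 0, mu_l, mu_r)
        n_ep[i] = durs.size
    rng = np.random.default_rng(seed)
    dts = []
    for _ in range(n_reps):
        seeds = rng.integers(0, 2**31 - 1, size=n)
        side, t_cross = _mc_batch(
            mu_m, durs_m, n_ep, np.ones(n), params.B, 1e-3, 0.0, T_MAX, seeds
        )
        dts.append(t_cross[side != 0])
    mean_dt = float(np.concatenate(dts).mean())
    return max(float(np.mean(rts)) - mean_dt, 0.0)


def _hessian_se(f, x, names):
    """Standard errors from a central-difference Hessian of -loglik."""
    k = x.size
    h = np.maximum(1e-3 * np.abs(x), 1e-4)
    H = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.pinv(H)
        var = np.diag(cov)
        se = np.sqrt(np.where(var > 0, var, np.nan))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
    return dict(zip(names, se))


def fit_model(
    variant: str,
    trials: TrialSet,
    config: FitConfig | None = None,
) -> FitResult:
    """Multi-start derivative-free maximum-likelihood fit of one variant to
    one participant's trials.  Returns the best run; non-convergence is
    flagged (best-so-far parameters are still returned)."""
    cfg = config or FitConfig()
    if variant not in FREE_PARAMS:
        raise ValueError(f"unknown variant {variant!r}")
    n = len(trials)
    if n < 50:
        logger.warning("fit_model: only %d trials; fits may be unstable", n)
    f, names = _objective(variant, trials, cfg)
    bounds = [cfg.bounds.get(p, DEFAULT_BOUNDS[p]) for p in names]
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    rng = np.random.default_rng(cfg.seed)
    if cfg.starts is not None:
        starts = [np.asarray(s, dtype=float) for s in cfg.starts]
    else:
        starts = [0.5 * (lo + hi)]
        for _ in range(cfg.n_starts - 1):
            starts.append(lo + (hi - lo) * rng.random(len(names)))
    best = None
    trace = []
    n_evals = 0
    converged = False
    for x0 in starts:
        res = optimize.minimize(
            f, x0, method="Nelder-Mead", bounds=bounds,
            options={
                "maxfev": cfg.maxfev_per_start,
                "xatol": 1e-3,
                "fatol": 1e-2,
                "adaptive": True,
            },
        )
        n_evals += res.nfev
        trace.append({"x0": list(x0), "x": list(res.x), "nll": float(res.fun),
                      "success": bool(res.success)})
        if best is None or res.fun < best.fun:
            best = res
        converged = converged or bool(res.success)
    x = np.clip(best.x, lo, hi)
    loglik = -float(best.fun)
    k = len(names)
    bic = k * math.log(n) - 2 * loglik
    params = dict(zip(names, (float(v) for v in x)))
    se = _hessian_se(f, x, names) if cfg.compute_se else None
    mu_nd = None
    if variant != "pdg" and cfg.set_mu_nd:
        p_obj = AddmParams(**params, mu_nd=0.0)
        mu_nd = _post_hoc_mu_nd(p_obj, variant, trials, seed=cfg.seed)
    dr, sr, rt, right = _trial_arrays(trials)
    return FitResult(
        variant=variant,
        params=params,
        loglik=loglik,
        bic=bic,
        n_trials=n,
        k=k,
        seed=cfg.seed,
        n_evals=n_evals,
        converged=converged,
        se=se,
        mu_nd_post_hoc=mu_nd,
        starts_trace=trace,
        data_fingerprint=(n, round(float(rt.sum()), 6)),
    )


def compare_models(fits) -> pd.DataFrame:
    """BIC comparison table.

    ``fits`` is either a list of FitResults on one trial set, or a list of
    per-participant lists (one FitResult per variant, same order in each).
    Delta-BIC is relative to the best (lowest) BIC; ties break toward the
    model with fewer parameters.  Mismatched trial sets raise ValueError.
    """
    if fits and isinstance(fits[0], (list, tuple)):
        rows = []
        for pi, group in enumerate(fits):
            tbl = compare_models(list(group))
            tbl.insert(0, "participant", pi)
            rows.append(tbl)
        per = pd.concat(rows, ignore_index=True)
        summed = (
            per.groupby("variant", sort=False)
            .agg(k=("k", "first"), loglik=("loglik", "sum"), bic=("bic", "sum"))
            .reset_index()
        )
        summed["delta_bic"] = summed["bic"] - summed["bic"].min()
        summed["participant"] = "sum"
        return pd.concat([per, summed], ignore_index=True)
    prints = {f.data_fingerprint for f in fits}
    if len(prints) > 1:
        raise ValueError("model comparison requires identical trial sets")
    df = pd.DataFrame(
        {
            "variant": [f.variant for f in fits],
            "k": [f.k for f in fits],
            "loglik": [f.loglik for f in fits],
            "bic": [f.bic for f in fits],
        }
    )
    # rank by BIC; numerical ties (< 1e-9) break toward fewer parameters
    order = np.lexsort((df["k"].to_numpy(), np.round(df["bic"].to_numpy(), 9)))
    df = df.iloc[order].reset_index(drop=True)
    df["delta_bic"] = df["bic"] - df["bic"].iloc[0]
    return df
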