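"""Behavioral test battery for choice/RT/gaze data.

Runs identically on empirical-format and simulated trial sets:

- ``melfb_quintiles`` / ``melfb_interaction``: does the last-fixation bias
  on choice grow with the overall value of the pair (the magnitude effect
  on the last-fixation bias)?  Attention-causal accumulation models with a
  multiplicative gaze discount predict it does; a purely post-decisional
  gaze account predicts it does not.
- ``dwell_consistency_regression``: is the dwell-time advantage of the
  chosen item larger when the choice contradicts the stated ratings?
- ``first_dwell_regression``: does a longer first dwell raise the chance
  of choosing the first-fixated item, conditioning on dwell count?
- ``gaze_cascade`` / ``post_report_gaze_test``: the gradual rise of
  P(gaze on the to-be-chosen item) toward - and past - the choice report.
- ``residual_rt_vs_sum``: the magnitude effect on response times (faster
  responses at higher overall value, at fixed value difference).

All regressions operate on the feature table of
:func:`gazeflux.data_model.derive_features`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from gazeflux.data_model import LEFT, RIGHT, TrialSet

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionResult",
    "CascadeCurve",
    "melfb_quintiles",
    "melfb_interaction",
    "dwell_consistency_regression",
    "first_dwell_regression",
    "gaze_cascade",
    "post_report_gaze_test",
    "residual_rt_vs_sum",
    "summary_curves",
]


@dataclass
class RegressionResult:
    """Named coefficients with model-based inference and analysis flags."""

    name: str
    params: pd.Series
    bse: pd.Series
    statistics: pd.Series
    pvalues: pd.Series
    n: int
    df_resid: float
    flags: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)


@dataclass
class CascadeCurve:
    """P(gaze on chosen item) over time with across-participant 95% CI."""

    t: np.ndarray
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    alignment: str
    n_participants: int
    display_start: float | None = None


# ---------------------------------------------------------------------------
# logistic helpers


def _fit_logit(y, X: pd.DataFrame, name: str) -> tuple[sm.Logit, dict]:
    """Unpenalized ML logit with a separation detector; on separation or
    non-convergence, refit with a small ridge penalty and flag it."""
    flags = {"separation": False, "penalized": False}
    model = sm.Logit(np.asarray(y, dtype=float), X)
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        try:
            res = model.fit(disp=False, maxiter=200)
        except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
            res = None
        sep = any("separat" in str(w.message).lower() for w in wlist)
    big = res is not None and np.any(np.abs(res.params) > 50)
    if res is None or not res.mle_retvals.get("converged", False) or sep or big:
        flags["separation"] = sep or big or res is None
        flags["penalized"] = True
        logger.warning("%s: separation/non-convergence; ridge fallback", name)
        res = model.fit_regularized(
            alpha=1e-3, L1_wt=0.0, disp=False, maxiter=500
        )
    return res, flags


def _subject_design(df: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Per-subject value slope (r_left - r_right) and per-subject intercept."""
    subs = list(dict.fromkeys(df["participant_id"]))
    cols = {}
    dr_left = (df["r_left"] - df["r_right"]).to_numpy(dtype=float)
    for s in subs:
        mask = (df["participant_id"] == s).to_numpy()
        cols[f"dr:{s}"] = dr_left * mask
        cols[f"int:{s}"] = mask.astype(float)
    return pd.DataFrame(cols, index=df.index), subs


def _lastfix_frame(features: pd.DataFrame) -> pd.DataFrame:
    df = features[features["last_fixated"].isin([LEFT, RIGHT])].copy()
    if df.empty:
        raise ValueError("no trials with a resolved last fixation")
    return df


def melfb_quintiles(
    features: pd.DataFrame, pooled_edges: bool = True
) -> RegressionResult:
    """Last-fixation influence on choice, estimated separately per quintile
    of the overall value sum_r.

    Logistic model: P(choose left) on per-subject value slope and bias plus
    an indicator (left fixated last) interacted with sum_r quintile.  The
    per-quintile coefficients are returned in
    ``extra['beta_lastfix_by_quintile']``.
    """
    df = _lastfix_frame(features)
    if df["sum_r"].nunique() < 5:
        raise ValueError("need at least 5 distinct sum_r values for quintiles")
    X, _ = _subject_design(df)
    g = _quintile_labels(df, pooled_edges)
    ilf = (df["last_fixated"] == LEFT).to_numpy(dtype=float)
    for q in range(5):
        X[f"lastfix:q{q + 1}"] = ilf * (g == q)
    y = (df["choice"] == LEFT).to_numpy(dtype=float)
    res, flags = _fit_logit(y, X, "melfb_quintiles")
    betas = pd.Series(
        {f"q{q + 1}": res.params[f"lastfix:q{q + 1}"] for q in range(5)}
    )
    return RegressionResult(
        name="melfb_quintiles",
        params=res.params,
        bse=getattr(res, "bse", pd.Series(np.nan, index=res.params.index)),
        statistics=getattr(res, "tvalues", pd.Series(np.nan, index=res.params.index)),
        pvalues=getattr(res, "pvalues", pd.Series(np.nan, index=res.params.index)),
        n=len(df),
        df_resid=float(len(df) - X.shape[1]),
        flags=flags,
        extra={"beta_lastfix_by_quintile": betas},
    )


def _quintile_labels(df: pd.DataFrame, pooled_edges: bool) -> np.ndarray:
    def labels(sr: pd.Series) -> np.ndarray:
        edges = np.quantile(sr, [0.2, 0.4, 0.6, 0.8])
        return np.clip(np.searchsorted(edges, sr, side="right"), 0, 4)

    if pooled_edges:
        return labels(df["sum_r"])
    out = np.empty(len(df), dtype=int)
    for _, idx in df.groupby("participant_id").groups.items():
        pos = df.index.get_indexer(idx)
        out[pos] = labels(df.loc[idx, "sum_r"])
    return out


def melfb_interaction(features: pd.DataFrame) -> RegressionResult:
    """Magnitude effect on the last-fixation bias as a single interaction:
    adds lastfix and lastfix x sum_r terms; the slope of the interaction is
    tested against zero with a model-based z-test
    (``extra['interaction_p']``)."""
    df = _lastfix_frame(features)
    X, _ = _subject_design(df)
    ilf = (df["last_fixated"] == LEFT).to_numpy(dtype=float)
    X["lastfix"] = ilf
    X["lastfix_x_sumr"] = ilf * df["sum_r"].to_numpy(dtype=float)
    y = (df["choice"] == LEFT).to_numpy(dtype=float)
    res, flags = _fit_logit(y, X, "melfb_interaction")
    bse = getattr(res, "bse", None)
    if bse is None or not np.all(np.isfinite(bse)):
        z = p = np.nan
    else:
        z = res.params["lastfix_x_sumr"] / bse["lastfix_x_sumr"]
        p = 2 * stats.norm.sf(abs(z))
    return RegressionResult(
        name="melfb_interaction",
        params=res.params,
        bse=bse if bse is not None else pd.Series(np.nan, index=res.params.index),
        statistics=getattr(res, "tvalues", pd.Series(np.nan, index=res.params.index)),
        pvalues=getattr(res, "pvalues", pd.Series(np.nan, index=res.params.index)),
        n=len(df),
        df_resid=float(len(df) - X.shape[1]),
        flags=flags,
        extra={
            "interaction_slope": float(res.params["lastfix_x_sumr"]),
            "interaction_z": float(z) if np.isfinite(z) else np.nan,
            "interaction_p": float(p) if np.isfinite(p) else np.nan,
        },
    )


def dwell_consistency_regression(features: pd.DataFrame) -> RegressionResult:
    """Linear model of the chosen-minus-unchosen dwell difference on
    per-subject intercepts, per-subject RT slopes, and the consistency
    indicator c (1 if the higher-rated item was chosen).  Rating ties are
    excluded.  One-tailed t-test of c < 0 in ``extra['p_one_tailed']``."""
    df = features[features["consistent"].isin([0.0, 1.0])].copy()
    if df.empty:
        raise ValueError("no trials with defined consistency")
    c = df["consistent"].to_numpy(dtype=float)
    if np.all(c == 1.0):
        raise ValueError("all choices consistent: c coefficient inestimable")
    subs = list(dict.fromkeys(df["participant_id"]))
    cols = {}
    rt = df["rt"].to_numpy(dtype=float)
    for s in subs:
        mask = (df["participant_id"] == s).to_numpy(dtype=float)
        cols[f"int:{s}"] = mask
        cols[f"rt:{s}"] = rt * mask
    X = pd.DataFrame(cols, index=df.index)
    X["c"] = c
    res = sm.OLS(df["delta_dwell"].to_numpy(dtype=float), X).fit()
    t_c = res.tvalues["c"]
    p_one = float(stats.t.cdf(t_c, res.df_resid))
    return RegressionResult(
        name="dwell_consistency",
        params=res.params,
        bse=res.bse,
        statistics=res.tvalues,
        pvalues=res.pvalues,
        n=len(df),
        df_resid=float(res.df_resid),
        extra={
            "beta_c": float(res.params["c"]),
            "t_c": float(t_c),
            "p_one_tailed": p_one,
            "p_two_tailed": float(res.pvalues["c"]),
        },
    )


def first_dwell_regression(features: pd.DataFrame, n_dwells: int) -> RegressionResult:
    """Logistic model of choosing the first-fixated item on the
    standardized first-dwell duration and the two ratings, restricted to
    trials with exactly ``n_dwells`` dwells.  The first-dwell coefficient
    is tested with a likelihood-ratio test (full vs. without-duration
    model); p in ``extra['lr_p']``."""
    if not 2 <= n_dwells <= 5:
        raise ValueError("n_dwells must be in 2..5")
    df = features[
        (features["n_dwells"] == n_dwells)
        & features["first_fixated"].isin([LEFT, RIGHT])
    ].copy()
    flags = {}
    if len(df) < 20:
        flags["few_trials"] = True
        logger.warning("first_dwell_regression: only %d trials", len(df))
    if df.empty:
        raise ValueError(f"no trials with {n_dwells} dwells")
    d = df["first_dwell_duration"].to_numpy(dtype=float)
    if np.std(d) < 1e-12:
        raise ValueError("constant first-dwell duration: slope inestimable")
    dz = (d - d.mean()) / d.std()
    first_left = df["first_fixated"] == LEFT
    r_first = np.where(first_left, df["r_left"], df["r_right"]).astype(float)
    r_other = np.where(first_left, df["r_right"], df["r_left"]).astype(float)
    y = (df["choice"] == df["first_fixated"]).to_numpy(dtype=float)
    X = pd.DataFrame(
        {"const": 1.0, "first_dwell": dz, "r_first": r_first, "r_other": r_other},
        index=df.index,
    )
    full, f_flags = _fit_logit(y, X, "first_dwell_full")
    red, _ = _fit_logit(y, X.drop(columns=["first_dwell"]), "first_dwell_reduced")
    flags.update(f_flags)
    lr = 2 * (full.llf - red.llf)
    lr_p = float(stats.chi2.sf(max(lr, 0.0), df=1))
    return RegressionResult(
        name=f"first_dwell_{n_dwells}",
        params=full.params,
        bse=getattr(full, "bse", pd.Series(np.nan, index=full.params.index)),
        statistics=getattr(full, "tvalues", pd.Series(np.nan, index=full.params.index)),
        pvalues=getattr(full, "pvalues", pd.Series(np.nan, index=full.params.index)),
        n=len(df),
        df_resid=float(len(df) - X.shape[1]),
        flags=flags,
        extra={
            "beta_first_dwell": float(full.params["first_dwell"]),
            "lr_stat": float(lr),
            "lr_p": lr_p,
        },
    )


# ---------------------------------------------------------------------------
# gaze timelines


def _gaze_value_grid(trial, times: np.ndarray) -> np.ndarray:
    """1 on chosen, 0 on unchosen, NaN off-item/out-of-trace, at ``times``
    (trial clock)."""
    out = np.full(times.size, np.nan)
    chosen = trial.choice
    for f in trial.fixations:
        if f.item not in (LEFT, RIGHT):
            continue
        m = (times >= f.t_on) & (times < f.t_off)
        out[m] = 1.0 if f.item == chosen else 0.0
    out[times < 0] = np.nan
    return out


def gaze_cascade(
    trials: TrialSet,
    alignment: str = "response",
    window: tuple[float, float] | None = None,
    step: float = 1e-3,
) -> CascadeCurve:
    """P(gaze on the to-be-chosen item) over time, averaged within then
    across participants (NaN-ignoring), with a 95% CI across participants.

    Alignments:
      - ``"response"``: time relative to the choice report.
      - ``"stimulus"``: time from stimulus onset; gaze in the final 500 ms
        before the report is blanked, and ``display_start`` marks the first
        time at which >= 50% of trials fixate an item.
      - ``"fixation_time"``: off-item gaze removed; trials aligned to the
        total fixation time at the report (for models whose drift is
        undefined off-item).
    """
    if alignment not in ("response", "stimulus", "fixation_time"):
        raise ValueError("alignment must be response|stimulus|fixation_time")
    if window is None:
        window = (-1.5, 0.5) if alignment != "stimulus" else (0.0, 3.0)
    taus = np.arange(window[0], window[1] + step / 2, step)
    per_part_mean: dict = {}
    per_part_sum: dict = {}
    per_part_cnt: dict = {}
    for tr in trials:
        if alignment == "response":
            vals = _gaze_value_grid(tr, tr.rt + taus)
        elif alignment == "stimulus":
            vals = _gaze_value_grid(tr, taus)
            vals[taus >= tr.rt - 0.5] = np.nan
        else:
            vals = _fixation_time_values(tr, taus)
        pid = tr.participant_id
        if pid not in per_part_sum:
            per_part_sum[pid] = np.zeros(taus.size)
            per_part_cnt[pid] = np.zeros(taus.size)
        ok = ~np.isnan(vals)
        per_part_sum[pid][ok] += vals[ok]
        per_part_cnt[pid][ok] += 1
    means = []
    for pid in per_part_sum:
        with np.errstate(invalid="ignore", divide="ignore"):
            means.append(per_part_sum[pid] / per_part_cnt[pid])
    M = np.vstack(means)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(M, axis=0)
        n_eff = np.sum(~np.isnan(M), axis=0)
        sd = np.nanstd(M, axis=0, ddof=1)
    sem = np.where(n_eff > 1, sd / np.sqrt(np.maximum(n_eff, 1)), np.nan)
    display_start = None
    if alignment == "stimulus":
        pooled_frac = np.nanmean(np.vstack([c > 0 for c in per_part_cnt.values()]), 0)
        total = np.sum([c for c in per_part_cnt.values()], axis=0)
        n_trials = len(trials)
        frac = total / n_trials
        idx = np.flatnonzero(frac >= 0.5)
        display_start = float(taus[idx[0]]) if idx.size else None
    return CascadeCurve(
        t=taus,
        mean=mean,
        ci_low=mean - 1.96 * sem,
        ci_high=mean + 1.96 * sem,
        alignment=alignment,
        n_participants=M.shape[0],
        display_start=display_start,
    )


def _fixation_time_values(trial, taus: np.ndarray) -> np.ndarray:
    """Values on the concatenated item-gaze clock, aligned to the total
    fixation time at the report."""
    durs, vals = [], []
    for f in trial.fixations:
        if f.item not in (LEFT, RIGHT):
            continue
        d = min(f.t_off, trial.rt) - f.t_on
        if d > 0:
            durs.append(d)
            vals.append(1.0 if f.item == trial.choice else 0.0)
    if not durs:
        return np.full(taus.size, np.nan)
    edges = np.concatenate(([0.0], np.cumsum(durs)))
    total = edges[-1]
    t = total + taus
    idx = np.searchsorted(edges, t, side="right") - 1
    out = np.full(taus.size, np.nan)
    ok = (idx >= 0) & (idx < len(durs)) & (t >= 0) & (t < total)
    out[ok] = np.asarray(vals)[idx[ok]]
    return out


def post_report_gaze_test(
    trials: TrialSet, window: float = 0.2
) -> tuple[pd.DataFrame, dict]:
    """Per-participant proportion of on-item gaze time spent on the chosen
    item in the ``window`` seconds before vs. after the choice report, and
    a two-tailed Wilcoxon signed-rank test across participants.

    Participants with zero on-item time in either window are excluded
    (count in the test dict)."""
    acc: dict = {}
    for tr in trials:
        pid = tr.participant_id
        if pid not in acc:
            acc[pid] = np.zeros(4)  # chosen_pre, either_pre, chosen_post, either_post
        for f in tr.fixations:
            if f.item not in (LEFT, RIGHT):
                continue
            pre = max(0.0, min(f.t_off, tr.rt) - max(f.t_on, tr.rt - window))
            post = max(0.0, min(f.t_off, tr.rt + window) - max(f.t_on, tr.rt))
            ch = f.item == tr.choice
            acc[pid][0] += pre * ch
            acc[pid][1] += pre
            acc[pid][2] += post * ch
            acc[pid][3] += post
    rows, n_excluded = [], 0
    for pid, (cp, ep, cq, eq) in acc.items():
        if ep <= 0 or eq <= 0:
            n_excluded += 1
            logger.info("post_report_gaze_test: excluding %s (empty window)", pid)
            continue
        rows.append({"participant_id": pid, "p_pre": cp / ep, "p_post": cq / eq})
    df = pd.DataFrame(rows)
    if len(df) < 2 or np.allclose(df["p_pre"], df["p_post"]):
        test = {"statistic": np.nan, "pvalue": 1.0}
    else:
        w = stats.wilcoxon(df["p_post"], df["p_pre"], alternative="two-sided")
        test = {"statistic": float(w.statistic), "pvalue": float(w.pvalue)}
    test.update({"n_participants": len(df), "n_excluded": n_excluded})
    return df, test


# ---------------------------------------------------------------------------
# magnitude effect on RT


def _bell(dr, a, b, c):
    return a + b * np.exp(-(dr**2) / (2 * c**2))


def residual_rt_vs_sum(features: pd.DataFrame) -> RegressionResult:
    """Magnitude effect on RT: per participant, detrend RT by a bell-shaped
    (Gaussian) function of delta_r, then regress the pooled residuals on
    sum_r.  A negative slope means faster responses at higher overall value.
    Falls back to a quadratic-in-|delta_r| detrend on non-convergence."""
    if features["delta_r"].abs().nunique() < 3:
        raise ValueError("need at least 3 distinct |delta_r| levels")
    residuals = np.empty(len(features))
    flags = {"bell_fallback_participants": 0}
    for _, idx in features.groupby("participant_id").groups.items():
        sub = features.loc[idx]
        dr = sub["delta_r"].to_numpy(dtype=float)
        rt = sub["rt"].to_numpy(dtype=float)
        pos = features.index.get_indexer(idx)
        try:
            p0 = (float(rt.min()), float(max(rt.max() - rt.min(), 0.1)), 2.0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = optimize.curve_fit(
                    _bell, dr, rt, p0=p0,
                    bounds=([0, 0, 0.3], [np.inf, np.inf, 20.0]),
                    maxfev=2000,
                )
            residuals[pos] = rt - _bell(dr, *popt)
        except (RuntimeError, ValueError):
            flags["bell_fallback_participants"] += 1
            coeffs = np.polyfit(np.abs(dr), rt, 2)
            residuals[pos] = rt - np.polyval(coeffs, np.abs(dr))
    X = sm.add_constant(features["sum_r"].to_numpy(dtype=float))
    res = sm.OLS(residuals, X).fit()
    return RegressionResult(
        name="residual_rt_vs_sum",
        params=pd.Series(res.params, index=["const", "sum_r"]),
        bse=pd.Series(res.bse, index=["const", "sum_r"]),
        statistics=pd.Series(res.tvalues, index=["const", "sum_r"]),
        pvalues=pd.Series(res.pvalues, index=["const", "sum_r"]),
        n=len(features),
        df_resid=float(res.df_resid),
        flags=flags,
        extra={
            "slope": float(res.params[1]),
            "slope_se": float(res.bse[1]),
            "p": float(res.pvalues[1]),
        },
    )


# ---------------------------------------------------------------------------
# descriptive curves


def _per_participant_mean(df: pd.DataFrame, x: str, y: str) -> pd.DataFrame:
    per = df.groupby(["participant_id", x])[y].mean().reset_index()
    out = per.groupby(x)[y].agg(["mean", "sem", "count"]).reset_index()
    return out.rename(columns={"mean": y, "sem": f"{y}_sem", "count": "n_participants"})


def _decile_curve(
    df: pd.DataFrame, xcol: str, ycol: str, per_participant_edges: bool
) -> pd.DataFrame:
    rows = []
    for pid, sub in df.groupby("participant_id"):
        x = sub[xcol].to_numpy(dtype=float)
        src = x if per_participant_edges else df[xcol].to_numpy(dtype=float)
        edges = np.quantile(src, np.linspace(0.1, 0.9, 9))
        g = np.clip(np.searchsorted(edges, x, side="right"), 0, 9)
        for d in range(10):
            m = g == d
            if m.any():
                rows.append(
                    {
                        "participant_id": pid,
                        "decile": d + 1,
                        "x_mean": float(x[m].mean()),
                        "y_mean": float(sub[ycol].to_numpy(dtype=float)[m].mean()),
                    }
                )
    per = pd.DataFrame(rows)
    return (
        per.groupby("decile")
        .agg(
            x=("x_mean", "mean"),
            y=("y_mean", "mean"),
            y_sem=("y_mean", "sem"),
            n_participants=("y_mean", "count"),
        )
        .reset_index()
    )


def summary_curves(
    features: pd.DataFrame, per_participant_edges: bool = True
) -> dict[str, pd.DataFrame]:
    """Psychometric, chronometric, and gaze-association summary tables,
    each computed per participant then averaged.

    Keys: ``psychometric`` (P(right) vs delta_r), ``psychometric_by_lastfix``,
    ``chronometric`` (mean RT vs delta_r), ``p_left_vs_delta_dwell``
    (P(left) vs deciles of dwell_left - dwell_right),
    ``p_first_vs_first_dwell`` (P(chose first-fixated) vs first-dwell
    deciles, among resolved trials).
    """
    df = features.copy()
    df["chose_right"] = (df["choice"] == RIGHT).astype(float)
    df["chose_left"] = (df["choice"] == LEFT).astype(float)
    out = {"psychometric": _per_participant_mean(df, "delta_r", "chose_right")}
    sub = df[df["last_fixated"].isin([LEFT, RIGHT])]
    by = []
    for lf, g in sub.groupby("last_fixated"):
        tbl = _per_participant_mean(g, "delta_r", "chose_right")
        tbl.insert(0, "last_fixated", lf)
        by.append(tbl)
    out["psychometric_by_lastfix"] = (
        pd.concat(by, ignore_index=True) if by else pd.DataFrame()
    )
    out["chronometric"] = _per_participant_mean(df, "delta_r", "rt")
    df["delta_dwell_lr"] = df["dwell_left"] - df["dwell_right"]
    out["p_left_vs_delta_dwell"] = _decile_curve(
        df, "delta_dwell_lr", "chose_left", per_participant_edges
    )
    first = df[df["first_fixated"].isin([LEFT, RIGHT])].copy()
    first["chose_first"] = (first["choice"] == first["first_fixated"]).astype(float)
    out["p_first_vs_first_dwell"] = _decile_curve(
        first, "first_dwell_duration", "chose_first", per_participant_edges
    )
    return out
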