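"""Synthetic study generation with the food-choice design's structure.

Emulates the study design the analyses assume: 39 participants x 100
choice trials drawn from 70 rated items, non-negative integer ratings,
pairing constraint |r_left - r_right| <= 5, each item reused at most six
times per participant, first fixation on the left with probability 0.74,
and log-normal first/middle dwell durations.  Trials are produced by the
forward simulators of :mod:`gazeflux.simulators`, so a generated dataset
carries its ground-truth parameters in the metadata.

The rating histogram of the original study is not published; the default
rating distribution is uniform over 0..10, with an optional categorical
weighting (``StudyDesign.rating_weights``) to emulate skewed value
distributions explicitly rather than implicitly.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
from gazeflux.data_model import (
    LEFT,
    RIGHT,
    DwellSequence,
    TrialRecord,
    TrialSet,
)
from gazeflux.simulators import (
    POST_MARGIN,
    T_MAX,
    AddmParams,
    ModelSpec,
    PdgParams,
    _hold_then_shift,
    _mc_batch,
    _trace_with_shift,
    _truncnorm,
    drift_pair,
)

__all__ = [
    "DwellModel",
    "StudyDesign",
    "fit_dwell_model",
    "generate_value_pairs",
    "sample_dwell_sequence",
    "generate_dataset",
]


@dataclass
class DwellModel:
    """Log-normal dwell-duration model plus first-fixation laterality.

    Parameters are in log-seconds.  Defaults approximate typical
    free-viewing fixation behavior in two-item food choice: first dwells
    a bit shorter (median ~0.35 s) than middle dwells (median ~0.45 s),
    and a 0.74 probability that the first fixation lands on the left item.
    """

    first_log_mean: float = math.log(0.35)
    first_log_sd: float = 0.5
    middle_log_mean: float = math.log(0.45)
    middle_log_sd: float = 0.5
    p_first_left: float = 0.74

    def __post_init__(self) -> None:
        if self.first_log_sd <= 0 or self.middle_log_sd <= 0:
            raise ValueError("log-sd parameters must be positive")
        if not 0 <= self.p_first_left <= 1:
            raise ValueError("p_first_left must be in [0, 1]")

    def mean_first(self) -> float:
        return math.exp(self.first_log_mean + self.first_log_sd**2 / 2)

    def mean_middle(self) -> float:
        return math.exp(self.middle_log_mean + self.middle_log_sd**2 / 2)


@dataclass
class StudyDesign:
    """Study-level design constants (defaults mirror the food-choice task)."""

    n_participants: int = 39
    n_trials_per_participant: int = 100
    n_items: int = 70
    rating_min: int = 0
    rating_max: int = 10
    max_abs_delta_r: int = 5
    max_item_reuse: int = 6
    n_reps: int = 1
    rating_weights: tuple | None = None

    def __post_init__(self) -> None:
        if self.max_abs_delta_r < 0:
            raise ValueError("max_abs_delta_r must be >= 0")
        if self.rating_min < 0:
            raise ValueError("choice-phase ratings must be non-negative")
        if self.rating_weights is not None:
            w = np.asarray(self.rating_weights, dtype=float)
            if w.size != self.rating_max - self.rating_min + 1 or np.any(w < 0):
                raise ValueError(
                    "rating_weights must be non-negative with one weight per "
                    "rating value"
                )

    @property
    def n_rating_values(self) -> int:
        return self.rating_max - self.rating_min + 1


def fit_dwell_model(trials: TrialSet) -> DwellModel:
    """Maximum-likelihood log-normal fits to first and middle dwells.

    Middle dwells are item-directed epochs that are neither the first nor
    the last of the trial's viewing sequence.  ``p_first_left`` is the
    empirical fraction of trials whose first item fixation is on the left.
    """
    firsts, middles, first_left = [], [], []
    for tr in trials:
        epochs = [f for f in tr.fixations if f.item in (LEFT, RIGHT) and f.t_on < tr.rt]
        if not epochs:
            continue
        firsts.append(epochs[0].duration)
        first_left.append(epochs[0].item == LEFT)
        for f in epochs[1:-1]:
            middles.append(f.duration)
    if len(firsts) < 2 or len(middles) < 2:
        raise ValueError("need at least 2 first dwells and 2 middle dwells")
    firsts = np.asarray(firsts)
    middles = np.asarray(middles)
    if np.any(firsts <= 0) or np.any(middles <= 0):
        raise ValueError("dwell durations must be positive")
    lf, lm = np.log(firsts), np.log(middles)
    return DwellModel(
        first_log_mean=float(lf.mean()),
        first_log_sd=float(max(lf.std(), 1e-9)),
        middle_log_mean=float(lm.mean()),
        middle_log_sd=float(max(lm.std(), 1e-9)),
        p_first_left=float(np.mean(first_left)),
    )


def _draw_ratings(design: StudyDesign, rng: np.random.Generator) -> np.ndarray:
    values = np.arange(design.rating_min, design.rating_max + 1)
    if design.rating_weights is None:
        return rng.choice(values, size=design.n_items)
    w = np.asarray(design.rating_weights, dtype=float)
    return rng.choice(values, size=design.n_items, p=w / w.sum())


def generate_value_pairs(
    design: StudyDesign,
    rng: np.random.Generator,
    ratings: np.ndarray | None = None,
) -> np.ndarray:
    """Value pairs (r_left, r_right) for one participant's choice trials.

    Pairs satisfy |r_left - r_right| <= max_abs_delta_r with each item used
    at most ``max_item_reuse`` times; side assignment is random.  Raises
    ``ValueError`` if the constraints are infeasible.
    """
    n_trials = design.n_trials_per_participant
    if 2 * n_trials > design.n_items * design.max_item_reuse:
        raise ValueError("infeasible design: too few item slots for the trials")
    if ratings is None:
        ratings = _draw_ratings(design, rng)
    ratings = np.asarray(ratings)
    usage = np.zeros(ratings.size, dtype=int)
    pairs = np.empty((n_trials, 2), dtype=int)
    for t in range(n_trials):
        placed = False
        for _ in range(2000):
            i, j = rng.integers(0, ratings.size, size=2)
            if i == j or usage[i] >= design.max_item_reuse or usage[j] >= design.max_item_reuse:
                continue
            if abs(int(ratings[i]) - int(ratings[j])) <= design.max_abs_delta_r:
                placed = True
                break
        if not placed:
            # exhaustive fallback over remaining eligible pairs
            elig = np.flatnonzero(usage < design.max_item_reuse)
            cand = [
                (a, b)
                for ai, a in enumerate(elig)
                for b in elig[ai + 1 :]
                if abs(int(ratings[a]) - int(ratings[b])) <= design.max_abs_delta_r
            ]
            if not cand:
                raise ValueError("infeasible pairing constraints: no eligible pair")
            i, j = cand[rng.integers(0, len(cand))]
        usage[i] += 1
        usage[j] += 1
        if rng.random() < 0.5:
            i, j = j, i
        pairs[t] = (int(ratings[i]), int(ratings[j]))
    return pairs


def sample_dwell_sequence(
    dwell_model: DwellModel,
    horizon: float,
    rng: np.random.Generator,
    first_item: int | None = None,
) -> DwellSequence:
    """Alternating dwell sequence covering at least ``horizon`` seconds.

    The first dwell is on the left with probability ``p_first_left`` (or
    forced via ``first_item``: 0 left, 1 right); the first duration is
    drawn from the first-dwell log-normal and all subsequent ones from the
    middle-dwell log-normal.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if first_item is None:
        first_item = 0 if rng.random() < dwell_model.p_first_left else 1
    durations = [float(rng.lognormal(dwell_model.first_log_mean, dwell_model.first_log_sd))]
    total = durations[0]
    while total < horizon:
        d = float(rng.lognormal(dwell_model.middle_log_mean, dwell_model.middle_log_sd))
        durations.append(d)
        total += d
    n = len(durations)
    items = (np.arange(n) + first_item) % 2
    return DwellSequence(items=items, durations=np.asarray(durations))


def _sample_dwell_matrix(
    dwell_model: DwellModel,
    n_trials: int,
    horizon: float,
    rng: np.random.Generator,
):
    """Padded (n_trials, K) dwell durations + first-item draws, every row
    covering at least ``horizon`` seconds."""
    k = max(4, int(np.ceil(horizon / math.exp(dwell_model.middle_log_mean))) + 8)
    first = rng.lognormal(dwell_model.first_log_mean, dwell_model.first_log_sd, n_trials)
    mid = rng.lognormal(
        dwell_model.middle_log_mean, dwell_model.middle_log_sd, (n_trials, k - 1)
    )
    durs = np.column_stack([first, mid])
    while True:
        totals = durs.sum(axis=1)
        short = totals < horizon
        if not short.any():
            break
        extra = rng.lognormal(
            dwell_model.middle_log_mean,
            dwell_model.middle_log_sd,
            (n_trials, max(4, k // 2)),
        )
        extra[~short] = 0.0
        # keep padding positive so DwellSequence invariants hold after trim
        extra[extra == 0.0] = 1e-6
        durs = np.column_stack([durs, extra])
        k = durs.shape[1]
    first_items = (rng.random(n_trials) >= dwell_model.p_first_left).astype(np.int8)
    return durs, first_items


def _trim_sequence(durs_row: np.ndarray, first_item: int, horizon: float) -> DwellSequence:
    cum = np.cumsum(durs_row)
    n = int(np.searchsorted(cum, horizon) + 1)
    n = min(n, durs_row.size)
    items = (np.arange(n) + first_item) % 2
    return DwellSequence(items=items, durations=durs_row[:n].copy())


def generate_dataset(
    model: ModelSpec,
    design: StudyDesign,
    dwell_model: DwellModel,
    rng: np.random.Generator,
) -> TrialSet:
    """Simulate a full synthetic study under ``model``.

    Each participant gets independent item ratings, value pairs (each pair
    repeated ``design.n_reps`` times), and dwell sequences; trials are run
    through the forward simulator of the requested variant.  Ground-truth
    parameters, the design, and the dwell model are stored in the metadata.
    Trials that fail to reach a bound within the simulation cap are dropped
    and counted in ``metadata['n_censored']``.
    """
    trials: list[TrialRecord] = []
    n_censored = 0
    sub_rngs = rng.spawn(design.n_participants)
    for p_idx in range(design.n_participants):
        prng = sub_rngs[p_idx]
        pid = f"S{p_idx:02d}"
        pairs = generate_value_pairs(design, prng)
        pairs = np.repeat(pairs, design.n_reps, axis=0)
        n = pairs.shape[0]
        durs, first_items = _sample_dwell_matrix(dwell_model, n, T_MAX + 1.0, prng)
        n_epochs = np.full(n, durs.shape[1], dtype=np.int64)
        # per-trial drift while attending (left, right)
        mu_l = np.empty(n)
        mu_r = np.empty(n)
        sigma = np.ones(n)
        variant = model.variant
        params = model.params
        if variant == "pdg":
            assert isinstance(params, PdgParams)
            mu = params.kappa * (pairs[:, 1] - pairs[:, 0]).astype(float)
            mu_l[:] = mu
            mu_r[:] = mu
            s2 = 1.0 + params.gamma * (pairs[:, 0] + pairs[:, 1]).astype(float)
            if np.any(s2 <= 0):
                raise ValueError("1 + gamma*sum_r must be positive for all trials")
            sigma = np.sqrt(s2)
            t_start = params.tau_s
        else:
            assert isinstance(params, AddmParams)
            addm_variant = (
                model.hybrid_variant if variant == "hybrid" else variant
            )
            v = (
                prng.normal(0.0, params.sigma_d, n)
                if addm_variant == "addm_driftvar"
                else np.zeros(n)
            )
            if addm_variant == "addm_valuenoise":
                v12 = prng.normal(0.0, params.sigma_d, (n, 2))
            else:
                v12 = np.zeros((n, 2))
            for i in range(n):
                mu_l[i], mu_r[i] = drift_pair(
                    addm_variant,
                    params,
                    pairs[i, 0],
                    pairs[i, 1],
                    v=v[i],
                    v1=v12[i, 0],
                    v2=v12[i, 1],
                )
            t_start = model.hybrid_post.tau_s if variant == "hybrid" else 0.0
        # epoch-wise drift matrix: item 0 (left) -> mu_l, item 1 -> mu_r
        k = durs.shape[1]
        items_mat = (np.arange(k)[None, :] + first_items[:, None]) % 2
        mu_mat = np.where(items_mat == 0, mu_l[:, None], mu_r[:, None])
        seeds = prng.integers(0, 2**31 - 1, size=n)
        side, t_cross = _mc_batch(
            np.ascontiguousarray(mu_mat, dtype=float),
            np.ascontiguousarray(durs, dtype=float),
            n_epochs,
            sigma,
            float(params.B),
            1e-3,
            float(t_start),
            T_MAX,
            seeds,
        )
        # post-commitment latencies
        if variant == "pdg":
            tau_m = _truncnorm(prng, params.mu_nd - params.tau_s, params.sigma_nd, n)
            tau_e = _truncnorm(prng, params.mu_e, params.sigma_e, n)
            rt = t_cross + tau_m
            dec_time = t_cross - params.tau_s
            shift_t = t_cross + tau_e
        elif variant == "hybrid":
            hp = model.hybrid_post
            tau_e = _truncnorm(prng, hp.mu_e, hp.sigma_e, n)
            rt = t_cross + params.mu_nd
            dec_time = t_cross - hp.tau_s
            shift_t = t_cross + tau_e
        else:
            rt = t_cross + params.mu_nd
            dec_time = t_cross
            shift_t = np.full(n, np.inf)
        for i in range(n):
            if side[i] == 0:
                n_censored += 1
                continue
            choice = RIGHT if side[i] > 0 else LEFT
            horizon = float(rt[i]) + POST_MARGIN
            seq = _trim_sequence(durs[i], int(first_items[i]), horizon)
            if variant == "pdg":
                fixations = _trace_with_shift(seq, float(shift_t[i]), choice, horizon)
            else:
                # dwell sampling stops at the crossing; gaze holds there,
                # and the hybrid model later shifts it to the chosen item
                fixations = _hold_then_shift(
                    seq, float(t_cross[i]), float(shift_t[i]), choice, horizon
                )
            trials.append(
                TrialRecord(
                    participant_id=pid,
                    r_left=int(pairs[i, 0]),
                    r_right=int(pairs[i, 1]),
                    choice=choice,
                    rt=float(rt[i]),
                    fixations=fixations,
                    decision_time=float(dec_time[i]),
                )
            )
    metadata = {
        "model": model.variant,
        "hybrid_variant": model.hybrid_variant if model.variant == "hybrid" else None,
        "params": asdict(model.params),
        "design": asdict(design),
        "dwell_model": asdict(dwell_model),
        "n_censored": n_censored,
    }
    return TrialSet(trials, metadata=metadata)
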