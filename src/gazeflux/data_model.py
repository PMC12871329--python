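"""Domain types, dataset I/O, and per-trial feature derivation.

A trial of the food-choice task pairs two previously rated snack items
(integer ratings), records the left/right choice and response time, and
an ordered sequence of fixation epochs on the left item, the right item,
or neither.  Times are trial-relative seconds with stimulus onset at 0
and fixation intervals half-open ``[t_on, t_off)``.

The canonical on-disk format is CSV with one row per trial and the
fixation sequence JSON-encoded::

    participant_id, r_left, r_right, choice, rt, fixations[, decision_time]

where ``fixations`` is a JSON list of ``[item, t_on, t_off]`` triples.
``decision_time`` is optional and only present for simulated trials, where
the bound-crossing time is known exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LEFT, RIGHT, NONE = "left", "right", "none"
_ITEMS = (LEFT, RIGHT, NONE)

__all__ = [
    "FixationEpoch",
    "TrialRecord",
    "TrialSet",
    "DwellSequence",
    "load_trials",
    "save_trials",
    "derive_features",
    "validate_trial",
]


@dataclass(frozen=True)
class FixationEpoch:
    """One gaze epoch: item in {left,right,none}, half-open [t_on, t_off)."""

    item: str
    t_on: float
    t_off: float

    def __post_init__(self) -> None:
        if self.item not in _ITEMS:
            raise ValueError(f"item must be one of {_ITEMS}, got {self.item!r}")
        if not (self.t_off > self.t_on >= 0):
            raise ValueError("require 0 <= t_on < t_off")

    @property
    def duration(self) -> float:
        return self.t_off - self.t_on


@dataclass
class TrialRecord:
    """One choice trial: ratings, choice, RT, and the fixation sequence."""

    participant_id: str | int
    r_left: int
    r_right: int
    choice: str
    rt: float
    fixations: list[FixationEpoch] = field(default_factory=list)
    #: bound-crossing time where known (simulated trials); None for
    #: empirical data, in which case decision time is approximated
    #: downstream by the summed item-dwell time
    decision_time: float | None = None


@dataclass
class DwellSequence:
    """Alternating left/right dwell sequence (items: 0=left, 1=right)."""

    items: np.ndarray
    durations: np.ndarray

    def __post_init__(self) -> None:
        self.items = np.asarray(self.items, dtype=np.int8)
        self.durations = np.asarray(self.durations, dtype=float)
        if self.items.size != self.durations.size:
            raise ValueError("items and durations must have equal length")
        if np.any(self.durations <= 0):
            raise ValueError("dwell durations must be strictly positive")

    @property
    def total_duration(self) -> float:
        return float(self.durations.sum())

    def onsets(self) -> np.ndarray:
        return np.concatenate(([0.0], np.cumsum(self.durations)[:-1]))

    def to_epochs(self, horizon: float | None = None) -> list[FixationEpoch]:
        """Materialize as FixationEpochs, optionally truncated at ``horizon``."""
        out = []
        t = 0.0
        for it, dur in zip(self.items, self.durations):
            t_off = t + dur
            if horizon is not None:
                t_off = min(t_off, horizon)
            if t_off > t:
                out.append(FixationEpoch(LEFT if it == 0 else RIGHT, t, t_off))
            t += dur
            if horizon is not None and t >= horizon:
                break
        return out


@dataclass
class TrialSet:
    """A validated collection of trials plus free-form metadata."""

    trials: list[TrialRecord]
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def __getitem__(self, i):
        return self.trials[i]

    @property
    def participants(self) -> list:
        seen: dict = {}
        for tr in self.trials:
            seen.setdefault(tr.participant_id, None)
        return list(seen)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for tr in self.trials:
            rows.append(
                {
                    "participant_id": tr.participant_id,
                    "r_left": tr.r_left,
                    "r_right": tr.r_right,
                    "choice": tr.choice,
                    "rt": tr.rt,
                    "fixations": json.dumps(
                        [[f.item, f.t_on, f.t_off] for f in tr.fixations]
                    ),
                    "decision_time": (
                        np.nan if tr.decision_time is None else tr.decision_time
                    ),
                }
            )
        return pd.DataFrame(rows)


def validate_trial(tr: TrialRecord) -> list[str]:
    """Return a list of invariant violations (empty if the trial is valid)."""
    errs = []
    if tr.choice not in (LEFT, RIGHT):
        errs.append(f"choice must be 'left' or 'right', got {tr.choice!r}")
    if not tr.rt > 0:
        errs.append(f"rt must be > 0, got {tr.rt}")
    for r, name in ((tr.r_left, "r_left"), (tr.r_right, "r_right")):
        if not (-10 <= r <= 10):
            errs.append(f"{name} outside [-10, 10]: {r}")
        if r < 0:
            errs.append(f"{name} negative; choice trials use non-negative ratings")
    prev_off = -np.inf
    for f in tr.fixations:
        if f.t_on < prev_off:
            errs.append("fixation epochs overlap or are unsorted")
            break
        prev_off = f.t_off
    return errs


def _parse_fixations(raw: str, row_idx: int) -> list[FixationEpoch]:
    try:
        triples = json.loads(raw) if isinstance(raw, str) and raw.strip() else []
    except json.JSONDecodeError as e:
        raise ValueError(f"row {row_idx}: unparseable fixation list: {e}") from e
    out = []
    for trip in triples:
        if len(trip) != 3:
            raise ValueError(f"row {row_idx}: fixation entries must be triples")
        out.append(FixationEpoch(str(trip[0]), float(trip[1]), float(trip[2])))
    return out


REQUIRED_COLUMNS = ("participant_id", "r_left", "r_right", "choice", "rt", "fixations")


def load_trials(path, dialect: dict | None = None) -> TrialSet:
    """Load and validate a trial CSV; invalid rows are dropped with a logged
    count (recorded in ``metadata['n_dropped']``).

    Raises ``ValueError`` if required columns are missing or a fixation list
    cannot be parsed (with the offending row index).
    """
    dialect = dict(dialect or {})
    dialect.setdefault("float_precision", "round_trip")
    df = pd.read_csv(path, **dialect)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    trials, dropped = [], 0
    for idx, row in df.iterrows():
        fixations = _parse_fixations(row["fixations"], idx)
        dec = row.get("decision_time", np.nan)
        try:
            tr = TrialRecord(
                participant_id=row["participant_id"],
                r_left=int(row["r_left"]),
                r_right=int(row["r_right"]),
                choice=str(row["choice"]),
                rt=float(row["rt"]),
                fixations=fixations,
                decision_time=None if pd.isna(dec) else float(dec),
            )
            errs = validate_trial(tr)
        except (TypeError, ValueError) as e:
            errs = [str(e)]
        if errs:
            dropped += 1
            logger.warning("dropping row %d: %s", idx, "; ".join(errs))
            continue
        trials.append(tr)
    if dropped:
        logger.info("load_trials: dropped %d invalid rows", dropped)
    return TrialSet(trials, metadata={"n_dropped": dropped, "source": str(path)})


def save_trials(trials: TrialSet, path) -> None:
    df = trials.to_dataframe()
    if df["decision_time"].isna().all():
        df = df.drop(columns=["decision_time"])
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# feature derivation


def _gaze_at(fixations: list[FixationEpoch], t: float) -> str:
    """Item under gaze at time t ([t_on, t_off) half-open; an epoch ending
    exactly at t counts if no epoch starts at t, so traces truncated at the
    report remain resolvable)."""
    last_ending_here = None
    for f in fixations:
        if f.t_on <= t < f.t_off:
            return f.item
        if f.t_off == t:
            last_ending_here = f.item
    return last_ending_here if last_ending_here is not None else NONE


def _last_item_before(fixations: list[FixationEpoch], t: float) -> str:
    out = NONE
    for f in fixations:
        if f.t_on < t and f.item in (LEFT, RIGHT):
            out = f.item
    return out


def derive_features(
    trials: TrialSet, last_fixated_rule: str = "at_report"
) -> pd.DataFrame:
    """Per-trial derived quantities used by every downstream analysis.

    Dwell totals are truncated at the report time (``rt``); gaze recorded
    after the report is retained on the trial records and used only by the
    post-report analyses.

    ``last_fixated_rule``:
      - ``"at_report"`` (default): the item under gaze at the moment of the
        choice report; ``"unresolved"`` if gaze is on neither item.
      - ``"last_before"``: the item-directed epoch that started last before
        the report, regardless of gaze at the report itself.

    Columns: participant_id, r_left, r_right, choice, rt, decision_time,
    delta_r (right - left), sum_r, dwell_left, dwell_right, delta_dwell
    (chosen - unchosen), last_fixated, first_fixated, first_dwell_duration,
    n_dwells, consistent (1 consistent / 0 inconsistent / NaN rating tie).
    """
    if last_fixated_rule not in ("at_report", "last_before"):
        raise ValueError("last_fixated_rule must be 'at_report' or 'last_before'")
    rows = []
    for tr in trials:
        rt = tr.rt
        dwell = {LEFT: 0.0, RIGHT: 0.0}
        n_dwells = 0
        first_item, first_dur = None, np.nan
        for f in tr.fixations:
            if f.item == NONE:
                continue
            overlap = max(0.0, min(f.t_off, rt) - f.t_on)
            dwell[f.item] += overlap
            if f.t_on < rt:
                n_dwells += 1
                if first_item is None:
                    first_item = f.item
                    first_dur = min(f.t_off, rt) - f.t_on
        if last_fixated_rule == "at_report":
            last = _gaze_at(tr.fixations, rt)
            last = last if last in (LEFT, RIGHT) else "unresolved"
        else:
            last = _last_item_before(tr.fixations, rt)
            last = last if last in (LEFT, RIGHT) else "unresolved"
        chosen, unchosen = (
            (LEFT, RIGHT) if tr.choice == LEFT else (RIGHT, LEFT)
        )
        r_chosen = tr.r_left if tr.choice == LEFT else tr.r_right
        r_unchosen = tr.r_right if tr.choice == LEFT else tr.r_left
        consistent = (
            np.nan if r_chosen == r_unchosen else float(r_chosen > r_unchosen)
        )
        rows.append(
            {
                "participant_id": tr.participant_id,
                "r_left": tr.r_left,
                "r_right": tr.r_right,
                "choice": tr.choice,
                "rt": rt,
                "decision_time": (
                    np.nan if tr.decision_time is None else tr.decision_time
                ),
                "delta_r": tr.r_right - tr.r_left,
                "sum_r": tr.r_left + tr.r_right,
                "dwell_left": dwell[LEFT],
                "dwell_right": dwell[RIGHT],
                "delta_dwell": dwell[chosen] - dwell[unchosen],
                "last_fixated": last,
                "first_fixated": first_item if first_item is not None else "unresolved",
                "first_dwell_duration": first_dur,
                "n_dwells": n_dwells,
                "consistent": consistent,
            }
        )
    return pd.DataFrame(rows)
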