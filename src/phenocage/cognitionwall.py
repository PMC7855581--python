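"""Discrimination (DL) and reversal (RL) learning scores from entry streams.

The task: a wall with three entrances (left/middle/right) stands in front
of a pellet dispenser.  During DL the left entrance is correct; a pellet
is dispensed for every ``fr``-th correct entry (FR5), except during the
initial 30-entry bias window in which nothing is rewarded.  At 50.5 h the
contingency reverses to the right entrance (RL).  Learning is summarised
as the number of entries needed to reach >= 80% correct within a moving
window of the last 30 entries, analysed as a survival time with censoring
for subjects that never reach it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .core import (
    ENTRANCES,
    ConfigurationError,
    CriterionResult,
    EntryStream,
    TaskSchedule,
    Track,
    ValidationError,
)

__all__ = [
    "RLErrorCounts",
    "ActivityMeasures",
    "entrance_bias",
    "fr5_reward_ledger",
    "entries_to_criterion",
    "split_phases",
    "split_rl_days",
    "classify_rl_errors",
    "activity_measures",
    "km_survival",
]

RL_DAY_S = 24.0 * 3600.0


@dataclass(frozen=True)
class RLErrorCounts:
    """Error tally of one subject on one reversal day.

    Perseverative errors are entries through the previously rewarded
    entrance; neutral errors are entries through the never-rewarded middle
    entrance.  Together with correct entries these partition all entries of
    the day.
    """

    subject_id: str
    day: str  # "RL1" or "RL2"
    perseverative: int
    neutral: int
    correct: int = 0

    def __post_init__(self) -> None:
        if self.day not in ("RL1", "RL2"):
            raise ValidationError("day must be 'RL1' or 'RL2'")
        if min(self.perseverative, self.neutral, self.correct) < 0:
            raise ValidationError("error counts must be non-negative")


@dataclass(frozen=True)
class ActivityMeasures:
    """Total entries over DL+RL and total distance moved (meters).

    Distance is absent when no position track was supplied; the camera does
    not see behind the wall or inside the shelter, so those regions are
    masked out of the distance sum.
    """

    subject_id: str
    total_entries: int
    total_distance_m: Optional[float] = None


# ---------------------------------------------------------------------------
# scoring operations
# ---------------------------------------------------------------------------


def entrance_bias(stream: EntryStream) -> Dict[str, float]:
    """Per-entrance choice proportions over the first ``bias_window`` entries.

    The bias window (default 30 entries) is the unrewarded start of the DL
    task; with fewer entries than the window, all available entries are
    used.  Proportions sum to one.
    """
    if len(stream) == 0:
        raise ValidationError("no entries: entrance bias undefined")
    n = min(stream.schedule.bias_window, len(stream))
    head = stream.entrances[:n]
    return {e: float(np.mean(head == e)) for e in ENTRANCES}


def fr5_reward_ledger(stream: EntryStream, target: str,
                      schedule: Optional[TaskSchedule] = None) -> pd.DataFrame:
    """Entry-by-entry reward bookkeeping under the fixed-ratio schedule.

    Correct entries are counted only after the bias window (the first
    ``bias_window`` entries of the stream are never rewarded); every
    ``fr``-th post-bias correct entry delivers a pellet.  Returns a frame
    with 1-based ``entry_index``, ``entrance``, ``correct`` and
    ``rewarded`` columns; total rewards equal
    ``floor(post-bias correct count / fr)``.
    """
    if target not in ENTRANCES:
        raise ConfigurationError(f"target {target!r} not in {ENTRANCES}")
    sched = schedule if schedule is not None else stream.schedule
    ent = stream.entrances
    correct = ent == target
    idx = np.arange(1, len(ent) + 1)
    post_bias = idx > sched.bias_window
    countable = correct & post_bias
    cum = np.cumsum(countable)
    rewarded = countable & (cum % sched.fr == 0)
    return pd.DataFrame({
        "entry_index": idx,
        "entrance": ent,
        "correct": correct,
        "rewarded": rewarded,
    })


def entries_to_criterion(stream: EntryStream, target: str,
                         schedule: Optional[TaskSchedule] = None) -> CriterionResult:
    """Entries needed to first reach the moving-window performance criterion.

    The criterion is met at the smallest entry count ``k >= window`` such
    that the fraction of correct entries among the last ``window`` entries
    is at least ``threshold`` (inclusive: 24/30 passes at 80%).  Streams
    with fewer than ``window`` entries, or that never satisfy the
    criterion, yield a censored result at the subject's total entry count.

    The stream must be restricted to a single phase; RL streams are
    re-indexed from reversal onset (see :func:`split_phases`).
    """
    if target not in ENTRANCES:
        raise ConfigurationError(f"target {target!r} not in {ENTRANCES}")
    sched = schedule if schedule is not None else stream.schedule
    correct = (stream.entrances == target).astype(np.int64)
    n = len(correct)
    w = sched.window
    need = sched.threshold * w - 1e-9  # inclusive threshold, float-safe
    if n >= w:
        csum = np.concatenate(([0], np.cumsum(correct)))
        window_counts = csum[w:] - csum[:-w]  # counts ending at entries w..n
        hits = np.flatnonzero(window_counts >= need)
        if len(hits):
            k = int(hits[0]) + w
            return CriterionResult(stream.subject_id, k, False, n)
    return CriterionResult(stream.subject_id, None, True, n)


def split_phases(stream: EntryStream,
                 schedule: Optional[TaskSchedule] = None
                 ) -> Tuple[EntryStream, EntryStream]:
    """Split a full task stream into DL and RL substreams.

    Entries at or after the reversal offset belong to RL; RL times are
    re-zeroed to reversal onset so RL entries-to-criterion counts restart
    there.
    """
    sched = schedule if schedule is not None else stream.schedule
    t = stream.t
    is_rl = t >= sched.rl_start_offset_s
    dl = stream.subset(~is_rl)
    rl = stream.subset(is_rl, rezero=sched.rl_start_offset_s)
    return dl, rl


def split_rl_days(rl_stream: EntryStream,
                  schedule: Optional[TaskSchedule] = None
                  ) -> Tuple[EntryStream, EntryStream]:
    """Partition an RL substream into day one (RL1) and day two (RL2).

    The boundary is 24 h after reversal onset, half-open: an entry at
    exactly 24 h belongs to RL2.  Times are relative to reversal onset (the
    output of :func:`split_phases`).
    """
    t = rl_stream.t
    in_day1 = t < RL_DAY_S
    return rl_stream.subset(in_day1), rl_stream.subset(~in_day1)


def classify_rl_errors(substream: EntryStream, previous_target: str,
                       new_target: str, day: str = "RL1") -> RLErrorCounts:
    """Count perseverative and neutral errors within one RL day.

    Perseverative = entries through the previously rewarded entrance,
    neutral = entries through the middle entrance; entries through the new
    target are correct.  Targets must be the two distinct outer entrances.
    """
    if previous_target == new_target:
        raise ConfigurationError("previous and new targets must differ")
    if "middle" in (previous_target, new_target):
        raise ConfigurationError("targets must be outer entrances, not middle")
    for t in (previous_target, new_target):
        if t not in ENTRANCES:
            raise ConfigurationError(f"target {t!r} not in {ENTRANCES}")
    ent = substream.entrances
    return RLErrorCounts(
        subject_id=substream.subject_id,
        day=day,
        perseverative=int(np.sum(ent == previous_target)),
        neutral=int(np.sum(ent == "middle")),
        correct=int(np.sum(ent == new_target)),
    )


def activity_measures(stream: EntryStream, track: Optional[Track] = None,
                      mask_zones: Sequence[str] = ("shelter", "behind_wall")
                      ) -> ActivityMeasures:
    """Activity over the whole DL+RL task: entry count and distance moved.

    Distance is the sum of Euclidean center-of-gravity steps, in meters,
    over consecutive valid samples whose endpoints both lie outside every
    mask zone (the untracked behind-wall region and shelter interior).
    Tracking gaps contribute zero.  Distance is absent without a track.
    """
    if track is None:
        return ActivityMeasures(stream.subject_id, len(stream), None)
    cog = track.cog
    ok = track.valid_mask()
    masked = np.zeros(len(track), dtype=bool)
    for name in mask_zones:
        if name in track.arena.zones:
            with np.errstate(invalid="ignore"):
                inz = track.arena.zone_contains(name, cog[:, 0], cog[:, 1])
            masked |= np.where(ok, inz, False)
    usable = ok & ~masked
    step_ok = usable[:-1] & usable[1:]
    steps = np.linalg.norm(np.diff(cog, axis=0), axis=1)
    dist_cm = float(np.sum(steps[step_ok]))
    return ActivityMeasures(stream.subject_id, len(stream), dist_cm / 100.0)


def km_survival(results_by_group: Mapping[str, Iterable[CriterionResult]]
                ) -> Dict[str, pd.DataFrame]:
    """Kaplan-Meier step functions of entries-to-criterion per group.

    Returns, per group, a frame with ``entries`` and ``fraction_remaining``
    (the estimated fraction of mice not yet at criterion after that many
    entries).  Censored subjects shrink the risk set without contributing
    an event step; the curve starts at 1.0 and is non-increasing.
    """
    out: Dict[str, pd.DataFrame] = {}
    for group, results in results_by_group.items():
        results = list(results)
        if not results:
            raise ValidationError(f"empty group {group!r} in survival input")
        durations = [r.duration for r in results]
        events = [r.event for r in results]
        kmf = KaplanMeierFitter()
        kmf.fit(durations, event_observed=events, label=str(group))
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["entries", "fraction_remaining"]
        out[str(group)] = sf
    return out
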