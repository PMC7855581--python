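"""Dark-light box anxiety metrics from a position track.

The mouse starts in the dark compartment; after one minute a motorised
door opens and the mouse may explore the brightly lit compartment for ten
minutes.  Anxiety is read out as the latency to first enter the light,
total time spent in the light, and the number of visits to the light
compartment.  The mouse counts as "in the light" when its body center is
at least 2 cm beyond the door line (inclusive); the <2 cm corridor counts
as dark.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import ArenaGeometry, Track, ValidationError

__all__ = ["DLBMetrics", "SCORING_WINDOW_S", "dlb_metrics"]

SCORING_WINDOW_S = 600.0


@dataclass(frozen=True)
class DLBMetrics:
    """Latency, time and visit metrics over the 10-min open-door window.

    ``latency_to_light_s`` is None exactly when the mouse never entered the
    light compartment (``visits_to_light == 0``).
    """

    subject_id: str
    latency_to_light_s: Optional[float]
    time_in_light_s: float
    visits_to_light: int

    def __post_init__(self) -> None:
        if (self.latency_to_light_s is None) != (self.visits_to_light == 0):
            raise ValidationError(
                "latency absent exactly when there are no light visits"
            )
        if not (0.0 <= self.time_in_light_s <= SCORING_WINDOW_S + 1e-9):
            raise ValidationError("time in light outside the scoring window")
        if self.latency_to_light_s is not None and not (
            0.0 <= self.latency_to_light_s <= SCORING_WINDOW_S
        ):
            raise ValidationError("latency outside the scoring window")


def dlb_metrics(track: Track, arena: Optional[ArenaGeometry] = None,
                door_open_offset_s: float = 60.0,
                min_visit_s: float = 0.0) -> DLBMetrics:
    """Score the dark-light box from one track.

    The scoring window is ``[door_open, door_open + 600 s)`` with
    ``door_open`` measured from the first track sample, so all metrics are
    invariant under shifting every timestamp by a constant.  The in-light
    state at a sample holds while the body center is inside the light
    compartment and at least ``door_margin`` (2 cm, inclusive) beyond the
    door line; each inter-sample interval is attributed to the state at its
    starting sample, and the last in-window sample extends to the window
    end.  A visit is a maximal in-light run; ``min_visit_s > 0`` drops
    shorter visits (off by default — no debounce is part of the protocol).
    """
    arena = arena if arena is not None else track.arena
    if arena.kind != "dlb":
        raise ValidationError(f"expected a dlb arena, got {arena.kind!r}")
    t = track.t
    if len(t) == 0:
        raise ValidationError("empty track")
    door_open = t[0] + door_open_offset_s
    if t[-1] < door_open:
        raise ValidationError("track ends before the door opens")
    window_end = door_open + SCORING_WINDOW_S

    keep = (t >= door_open) & (t < window_end)
    tw = t[keep]
    cog = track.cog[keep]
    ok = np.isfinite(cog).all(axis=1)
    door_x = arena.meta["door_x"]
    with np.errstate(invalid="ignore"):
        in_light = ok & (cog[:, 0] >= door_x + arena.door_margin)

    if len(tw) == 0 or not in_light.any():
        return DLBMetrics(track.subject_id, None, 0.0, 0)

    # run-length encode the in-light indicator into visit intervals
    edges = np.diff(in_light.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if in_light[0]:
        starts.insert(0, 0)
    if in_light[-1]:
        ends.append(len(tw))
    bounds = np.append(tw, window_end)  # sample i covers [t_i, t_{i+1})
    intervals = [(bounds[s], bounds[e]) for s, e in zip(starts, ends)]
    if min_visit_s > 0:
        intervals = [(a, b) for a, b in intervals if b - a >= min_visit_s]
    if not intervals:
        return DLBMetrics(track.subject_id, None, 0.0, 0)

    latency = float(intervals[0][0] - door_open)
    time_in_light = float(sum(b - a for a, b in intervals))
    return DLBMetrics(track.subject_id, latency, min(time_in_light, SCORING_WINDOW_S),
                      len(intervals))
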