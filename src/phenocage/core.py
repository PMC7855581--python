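"""Domain types, arena geometry and time conventions for home-cage behavioural data.

Conventions used throughout the package
---------------------------------------

* **Time** is kept as seconds since the start of the relevant recording or
  task phase.  Wall-clock anchoring — needed only to label light/dark
  phases — lives in :class:`TaskSchedule`, which maps task-relative seconds
  to datetimes.
* **Space** is in centimetres.  The origin sits at an arena corner with *y*
  increasing away from the shelter/door wall; each arena factory documents
  its own layout.
* **Visit and bout intervals** are half-open ``[t_enter, t_exit)`` so that
  abutting intervals never double-count time.

The three arena factories (:func:`phenotyper_arena`, :func:`ymaze_arena`,
:func:`dlb_arena`) build named zone polygons with the published dimensions:
a 30x30 cm observation home-cage, a Y-maze with 40x9.5 cm arms whose
arm/center border sits 3 cm into each arm, and a dark-light box of two
25x25 cm compartments separated by a door.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime, time, timedelta
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import shapely
import shapely.affinity
from shapely.geometry import Polygon
from shapely.ops import unary_union

__all__ = [
    "ENTRANCES",
    "GENOTYPES",
    "SEXES",
    "ARMS",
    "ValidationError",
    "ParseError",
    "ConfigurationError",
    "SubjectMeta",
    "TaskSchedule",
    "ArenaGeometry",
    "EntryStream",
    "Track",
    "ArmVisitSequence",
    "CriterionResult",
    "phenotyper_arena",
    "ymaze_arena",
    "dlb_arena",
]

ENTRANCES = ("left", "middle", "right")
GENOTYPES = ("wildtype", "mdx")
SEXES = ("male", "female")
ARMS = ("A", "B", "C")


class ValidationError(ValueError):
    """An input table or object violates a domain invariant."""


class ParseError(ValidationError):
    """A delimited input file could not be interpreted."""


class ConfigurationError(ValueError):
    """Mutually inconsistent analysis parameters."""


# ---------------------------------------------------------------------------
# subject metadata
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubjectMeta:
    """Identity and grouping factors of one mouse.

    ``genotype`` x ``sex`` defines the four analysis groups used by every
    group comparison.  Excluded subjects (lost files, quality-control
    failures, deaths) carry a non-empty ``exclusion_reason`` so that
    exclusions are always explicit, never silent.
    """

    subject_id: str
    genotype: str
    sex: str
    batch: int = 1
    exclusion_reason: Optional[str] = None

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValidationError(
                f"genotype {self.genotype!r} not in {GENOTYPES}"
            )
        if self.sex not in SEXES:
            raise ValidationError(f"sex {self.sex!r} not in {SEXES}")
        if self.exclusion_reason is not None and not self.exclusion_reason.strip():
            raise ValidationError("excluded subjects need a non-empty reason")

    @property
    def group(self) -> str:
        """Group label, e.g. ``'wildtype_male'``."""
        return f"{self.genotype}_{self.sex}"

    @property
    def included(self) -> bool:
        return self.exclusion_reason is None


# ---------------------------------------------------------------------------
# task schedule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TaskSchedule:
    """Timing and reward parameters of the discrimination/reversal task.

    Defaults follow the published protocol: the discrimination-learning (DL)
    phase starts at 16:30, no rewards are given during the first 30 entries
    (the entrance-bias window), a pellet is dispensed for every fifth entry
    through the correct entrance (FR5), and the reversal (RL) phase starts
    50.5 h after DL onset (19:00 on the third task day) with the opposite
    outer entrance rewarded.  Learning criterion: >= 80% correct in a moving
    window of the last 30 entries.

    Parameters
    ----------
    dl_start
        Wall-clock datetime of DL onset; anchors phase labelling.
    rl_start_offset_s
        Seconds between DL onset and the reversal (default 50.5 h).
    task_duration_s
        Total DL+RL observation window (default 96 h, a four-day task).
    bias_window
        Number of initial unrewarded entries used for entrance-bias scoring.
    fr
        Fixed-ratio of the reinforcement schedule (reward every ``fr``-th
        correct entry).
    window, threshold
        Moving-window length and correct fraction of the learning criterion.
    dark_onset, light_onset
        Times of day bounding the dark phase (19:00-07:00 by default).
    count_bias_phase
        Whether DL entries-to-criterion counts from the very first task
        entry, i.e. including the bias window (default) or only from the
        first rewarded entry.
    min_interentry_s
        Optional de-duplication filter: entries closer than this to their
        predecessor are dropped on read.  Off (0.0) by default since the
        acquisition system registers an entry only once the mouse body
        moves away from the entrance.
    track_start
        Wall-clock datetime mapped to ``t = 0`` of position tracks; defaults
        to ``dl_start`` when unset.
    """

    dl_start: datetime = datetime(2020, 1, 6, 16, 30)
    rl_start_offset_s: float = 50.5 * 3600.0
    task_duration_s: float = 96.0 * 3600.0
    bias_window: int = 30
    fr: int = 5
    window: int = 30
    threshold: float = 0.8
    dark_onset: time = time(19, 0)
    light_onset: time = time(7, 0)
    target_dl: str = "left"
    target_rl: str = "right"
    count_bias_phase: bool = True
    min_interentry_s: float = 0.0
    track_start: Optional[datetime] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold <= 1.0):
            raise ConfigurationError("threshold must be in (0, 1]")
        if self.fr < 1:
            raise ConfigurationError("fr must be >= 1")
        if self.window < 1:
            raise ConfigurationError("window must be >= 1")
        if self.bias_window < 0:
            raise ConfigurationError("bias_window must be >= 0")
        if self.target_dl == self.target_rl:
            raise ConfigurationError("DL and RL targets must differ")
        for t in (self.target_dl, self.target_rl):
            if t not in ENTRANCES:
                raise ConfigurationError(f"target {t!r} not in {ENTRANCES}")
        if self.rl_start_offset_s <= 0 or self.task_duration_s <= self.rl_start_offset_s:
            raise ConfigurationError(
                "need 0 < rl_start_offset_s < task_duration_s"
            )

    # -- wall-clock helpers -------------------------------------------------

    @property
    def track_anchor(self) -> datetime:
        return self.track_start if self.track_start is not None else self.dl_start

    def wall_clock(self, t_s: float, anchor: Optional[datetime] = None) -> datetime:
        """Map task-relative seconds to a wall-clock datetime."""
        base = anchor if anchor is not None else self.dl_start
        return base + timedelta(seconds=float(t_s))

    def is_dark(self, when: datetime) -> bool:
        """True during the dark phase [dark_onset, light_onset) of the cycle."""
        tod = when.time()
        if self.dark_onset > self.light_onset:  # dark spans midnight
            return tod >= self.dark_onset or tod < self.light_onset
        return self.dark_onset <= tod < self.light_onset

    def phase_at(self, t_s: float, anchor: Optional[datetime] = None) -> str:
        return "dark" if self.is_dark(self.wall_clock(t_s, anchor)) else "light"

    def with_(self, **changes) -> "TaskSchedule":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


# ---------------------------------------------------------------------------
# arena geometry
# ---------------------------------------------------------------------------


@dataclass
class ArenaGeometry:
    """Named zone polygons plus the scalar geometry rules scorers need.

    ``zones`` maps zone names (``'arm_A'``, ``'light'``, ``'shelter'`` ...)
    to shapely polygons in arena coordinates.  ``meta`` carries
    arena-specific scalars (door line position, arm axis directions) used
    by scorers and by the synthetic-track generators.
    """

    kind: str
    width: float
    height: float
    zones: dict
    arm_border_inset: float = 3.0
    door_margin: float = 2.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("phenotyper_cage", "ymaze", "dlb"):
            raise ValidationError(f"unknown arena kind {self.kind!r}")

    def zone(self, name: str) -> Polygon:
        try:
            return self.zones[name]
        except KeyError:
            raise ValidationError(
                f"arena {self.kind!r} has no zone {name!r}; "
                f"available: {sorted(self.zones)}"
            ) from None

    def zone_contains(self, name: str, x, y) -> np.ndarray:
        """Vectorised point-in-zone test (boundary counts as inside)."""
        poly = self.zone(name)
        return shapely.intersects_xy(poly, np.asarray(x, float), np.asarray(y, float))

    def in_bounds(self, x, y, tol: float = 0.0) -> np.ndarray:
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        return (
            (x >= -tol) & (x <= self.width + tol)
            & (y >= -tol) & (y <= self.height + tol)
        )


def phenotyper_arena() -> ArenaGeometry:
    """The 30x30 cm observation home-cage.

    Origin at the front-left floor corner.  The triangular shelter sits in
    the back-left corner (hypotenuse 17.5 cm) and the pellet dispenser in
    the opposite front-right corner; during the learning task a
    three-entrance wall cuts off a triangular region in front of the
    dispenser.  Movement behind the wall and inside the shelter is not
    tracked, so both regions are exposed as mask zones for distance scoring.
    """
    w = h = 30.0
    shelter = Polygon([(0, h), (17.5, h), (0, h - 17.5)])
    # wall chord ~17 cm across the dispenser corner -> legs 17/sqrt(2)
    leg = 17.0 / math.sqrt(2.0)
    behind_wall = Polygon([(w - leg, 0), (w, 0), (w, leg)])
    return ArenaGeometry(
        kind="phenotyper_cage",
        width=w,
        height=h,
        zones={"shelter": shelter, "behind_wall": behind_wall},
        meta={"shelter_corner": (0.0, h), "dispenser_corner": (w, 0.0)},
    )


def ymaze_arena(arm_length: float = 40.0, arm_width: float = 9.5,
                inset: float = 3.0) -> ArenaGeometry:
    """Three-arm Y-maze with 120-degree arm spacing.

    Arms A, B, C point up, lower-left and lower-right.  Zone ``arm_X`` is
    the portion of arm X beyond the center/arm border, which sits ``inset``
    (3 cm) into the arm; the ``center`` zone covers the central junction
    plus the 3-cm arm stubs.  Coordinates are shifted so the bounding box
    has its corner at the origin.
    """
    half = arm_width / 2.0
    # arm mouth distance from the maze center so adjacent arm walls meet
    r0 = half / math.tan(math.pi / 3.0)
    angles = {"A": math.pi / 2.0, "B": math.pi / 2.0 + 2 * math.pi / 3.0,
              "C": math.pi / 2.0 + 4 * math.pi / 3.0}

    def arm_rect(theta: float, d0: float, d1: float) -> Polygon:
        ux, uy = math.cos(theta), math.sin(theta)
        px, py = -uy, ux  # unit normal
        return Polygon([
            (d0 * ux + half * px, d0 * uy + half * py),
            (d1 * ux + half * px, d1 * uy + half * py),
            (d1 * ux - half * px, d1 * uy - half * py),
            (d0 * ux - half * px, d0 * uy - half * py),
        ])

    arm_zones = {f"arm_{a}": arm_rect(th, r0 + inset, r0 + arm_length)
                 for a, th in angles.items()}
    center = unary_union(
        [arm_rect(th, 0.0, r0 + inset) for th in angles.values()]
    ).convex_hull
    zones = dict(arm_zones)
    zones["center"] = center

    all_shapes = unary_union(list(zones.values()))
    minx, miny, maxx, maxy = all_shapes.bounds
    zones = {name: shapely.affinity.translate(p, -minx, -miny)
             for name, p in zones.items()}
    cx, cy = -minx, -miny  # maze center after the shift
    return ArenaGeometry(
        kind="ymaze",
        width=maxx - minx,
        height=maxy - miny,
        zones=zones,
        arm_border_inset=inset,
        meta={
            "center": (cx, cy),
            "arm_angles": angles,
            "arm_mouth": r0,
            "arm_length": arm_length,
            "arm_width": arm_width,
        },
    )


def dlb_arena(compartment: float = 25.0, door_margin: float = 2.0) -> ArenaGeometry:
    """Dark-light box: two 25x25 cm compartments separated by a door at x=25.

    Dark compartment occupies x < 25, light x > 25.  A mouse counts as
    being in the light only when its body center is at least
    ``door_margin`` (2 cm) beyond the door line; the <2 cm corridor counts
    as dark, the complement of the stated light rule.
    """
    d = compartment
    dark = Polygon([(0, 0), (d, 0), (d, d), (0, d)])
    light = Polygon([(d, 0), (2 * d, 0), (2 * d, d), (d, d)])
    return ArenaGeometry(
        kind="dlb",
        width=2 * d,
        height=d,
        zones={"dark": dark, "light": light},
        door_margin=door_margin,
        meta={"door_x": d},
    )


# ---------------------------------------------------------------------------
# event and track containers
# ---------------------------------------------------------------------------


def _check_strictly_increasing(t: np.ndarray, what: str) -> None:
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
        raise ValidationError(
            f"{what}: timestamps must strictly increase "
            f"(violation at sample index {bad})"
        )


@dataclass
class EntryStream:
    """Ordered entrance-choice events of one subject in the learning task.

    ``df`` has columns ``t`` (seconds since DL onset, strictly increasing)
    and ``entrance`` (one of ``left``/``middle``/``right``).
    """

    subject_id: str
    df: pd.DataFrame
    schedule: TaskSchedule

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True)
        missing = {"t", "entrance"} - set(df.columns)
        if missing:
            raise ValidationError(f"EntryStream missing columns {sorted(missing)}")
        t = df["t"].to_numpy(float)
        if len(t) and (not np.all(np.isfinite(t)) or t.min() < 0):
            raise ValidationError("entry times must be finite and non-negative")
        _check_strictly_increasing(t, f"EntryStream({self.subject_id})")
        bad = ~df["entrance"].isin(ENTRANCES)
        if bad.any():
            first = df.loc[bad, "entrance"].iloc[0]
            raise ValidationError(
                f"unknown entrance label {first!r}; allowed: {list(ENTRANCES)}"
            )
        if len(t) and t.max() > self.schedule.task_duration_s:
            raise ValidationError(
                "entry beyond the scheduled observation interval"
            )
        self.df = df[["t", "entrance"]]

    def __len__(self) -> int:
        return len(self.df)

    @property
    def t(self) -> np.ndarray:
        return self.df["t"].to_numpy(float)

    @property
    def entrances(self) -> np.ndarray:
        return self.df["entrance"].to_numpy()

    def subset(self, mask, rezero: float = 0.0) -> "EntryStream":
        """New stream with the masked rows; times shifted by ``-rezero``."""
        sub = self.df.loc[np.asarray(mask)].copy()
        sub["t"] = sub["t"] - rezero
        return EntryStream(self.subject_id, sub.reset_index(drop=True), self.schedule)


@dataclass
class Track:
    """Time-stamped nose and center-of-gravity positions in arena coordinates.

    Rows with NaN positions are retained as tracking gaps, never
    interpolated; downstream scorers skip them explicitly.
    """

    subject_id: str
    df: pd.DataFrame
    arena: ArenaGeometry

    REQUIRED = ("t", "nose_x", "nose_y", "cog_x", "cog_y")

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True)
        missing = set(self.REQUIRED) - set(df.columns)
        if missing:
            raise ValidationError(f"Track missing columns {sorted(missing)}")
        t = df["t"].to_numpy(float)
        if len(t) and not np.all(np.isfinite(t)):
            raise ValidationError("track times must be finite")
        _check_strictly_increasing(t, f"Track({self.subject_id})")
        self.df = df[list(self.REQUIRED)]

    def __len__(self) -> int:
        return len(self.df)

    @property
    def t(self) -> np.ndarray:
        return self.df["t"].to_numpy(float)

    @property
    def nose(self) -> np.ndarray:
        return self.df[["nose_x", "nose_y"]].to_numpy(float)

    @property
    def cog(self) -> np.ndarray:
        return self.df[["cog_x", "cog_y"]].to_numpy(float)

    def valid_mask(self) -> np.ndarray:
        """Samples with finite nose and cog positions (non-gap rows)."""
        return np.isfinite(
            self.df[["nose_x", "nose_y", "cog_x", "cog_y"]].to_numpy(float)
        ).all(axis=1)


@dataclass
class ArmVisitSequence:
    """Ordered Y-maze arm visits of one subject.

    ``visits`` is a list of ``(arm, t_enter, t_exit)`` with arms in
    ``{'A','B','C'}`` and half-open, non-overlapping, ordered intervals.
    Consecutive visits may share the same arm: re-entries into the
    previously visited arm are real visits and are included in the
    alternation calculation.
    """

    subject_id: str
    visits: list

    def __post_init__(self) -> None:
        prev_exit = -math.inf
        for arm, t0, t1 in self.visits:
            if arm not in ARMS:
                raise ValidationError(f"unknown arm {arm!r}; allowed: {list(ARMS)}")
            if not (t0 < t1):
                raise ValidationError("visit interval must satisfy t_enter < t_exit")
            if t0 < prev_exit:
                raise ValidationError("visit intervals must be ordered, non-overlapping")
            prev_exit = t1

    def __len__(self) -> int:
        return len(self.visits)

    @property
    def labels(self) -> list:
        return [v[0] for v in self.visits]

    @classmethod
    def from_labels(cls, subject_id: str, labels: Sequence[str],
                    visit_s: float = 2.0, gap_s: float = 1.0) -> "ArmVisitSequence":
        """Build a sequence from bare arm labels with synthetic timings."""
        visits = []
        t = 0.0
        for lab in labels:
            visits.append((lab, t, t + visit_s))
            t += visit_s + gap_s
        return cls(subject_id, visits)


@dataclass(frozen=True)
class CriterionResult:
    """Entries-to-criterion of one subject, with survival-style censoring.

    ``censored`` is True when the subject never reached the moving-window
    criterion within its observed entries; then ``entries_to_criterion`` is
    None and the subject contributes ``total_entries`` of risk time to the
    survival analysis.
    """

    subject_id: str
    entries_to_criterion: Optional[int]
    censored: bool
    total_entries: int

    def __post_init__(self) -> None:
        if self.censored != (self.entries_to_criterion is None):
            raise ValidationError(
                "censored must hold exactly when entries_to_criterion is absent"
            )
        if self.total_entries < 0:
            raise ValidationError("total_entries must be >= 0")
        if self.entries_to_criterion is not None:
            if not (0 < self.entries_to_criterion <= self.total_entries):
                raise ValidationError(
                    "entries_to_criterion must be in 1..total_entries"
                )

    @property
    def duration(self) -> int:
        """Survival duration: event entry count, or total entries if censored."""
        return self.total_entries if self.censored else int(self.entries_to_criterion)

    @property
    def event(self) -> bool:
        return not self.censored
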