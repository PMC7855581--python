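"""Synthetic behavioural data with known ground truth.

Every input the scoring pipeline consumes can be generated here: FR5
entry streams from a reinforcement-learning choice agent with an initial
left bias and a mid-task reversal, Y-maze arm-visit sequences from a
Markov walker with tunable alternation tendency, dark-light-box tracks
with exponential latency/bout structure, and circadian-modulated
home-cage random walks.  Generators are bit-reproducible from their seeds
and retain the ground truth needed for recovery tests.

The choice agent is a softmax Rescorla-Wagner learner with a stickiness
bonus for the previous entrance — the minimal generative family that can
express the phenomena the task elicits (initial side bias, perseverative
errors after reversal, non-learners when the post-reversal learning rate
collapses).  It is a stand-in for generating realistic data, not a claim
about murine learning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .core import (
    ARMS,
    ENTRANCES,
    ArenaGeometry,
    ArmVisitSequence,
    EntryStream,
    SubjectMeta,
    TaskSchedule,
    Track,
    ValidationError,
    dlb_arena,
    phenotyper_arena,
    ymaze_arena,
)

__all__ = [
    "AgentParams",
    "WalkerParams",
    "Cohort",
    "simulate_cognitionwall",
    "simulate_ymaze_walker",
    "expected_alternation_pct",
    "walker_track",
    "simulate_dlb",
    "simulate_homecage_track",
    "simulate_cohort",
    "default_design",
    "subject_rng",
    "write_cohort",
]


@dataclass(frozen=True)
class AgentParams:
    """Generative parameters of the simulated choice agent.

    ``alpha`` is the value-learning rate, ``beta`` the softmax sharpness
    and ``kappa`` a stickiness bonus added to the previous entrance's value
    inside the softmax.  ``q0`` encodes the initial entrance values
    (left/middle/right); the default favours the left entrance, matching
    the side bias the task design exploits.  ``alpha_reversal`` optionally
    replaces ``alpha`` after the reversal; 0.0 produces a non-learner that
    never reaches the RL criterion.  ``entry_rate`` is entries per *dark*
    hour; the light phase runs at ``entry_rate * light_multiplier``.

    Defaults were chosen once so a typical agent acquires the DL criterion
    within a few hundred entries and makes realistic perseverative runs
    after reversal.
    """

    alpha: float = 0.15
    beta: float = 8.0
    kappa: float = 0.4
    q0: Tuple[float, float, float] = (0.25, 0.05, 0.05)
    alpha_reversal: Optional[float] = None
    max_entries: int = 2000
    entry_rate: float = 15.0
    light_multiplier: float = 0.2

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValidationError("alpha must be in [0, 1]")
        if self.alpha_reversal is not None and not (0.0 <= self.alpha_reversal <= 1.0):
            raise ValidationError("alpha_reversal must be in [0, 1]")
        if self.beta < 0:
            raise ValidationError("beta must be >= 0")
        if not (0.0 <= self.light_multiplier <= 1.0):
            raise ValidationError("light_multiplier must be in [0, 1]")
        if self.entry_rate <= 0 or self.max_entries < 1:
            raise ValidationError("entry_rate > 0 and max_entries >= 1 required")


@dataclass(frozen=True)
class WalkerParams:
    """Markov parameters of the simulated Y-maze walker.

    At each step the walker re-enters the arm it just left with
    probability ``p_repeat``; otherwise it completes an alternation (enters
    the arm not among the last two) with probability ``p_alt`` and enters
    the remaining arm with ``1 - p_alt``.  The iid-uniform null is
    ``p_repeat = 1/3, p_alt = 1/2``.  Visit and transit durations are
    exponential with the given means; the session ends at ``session_s``.
    """

    p_repeat: float = 0.15
    p_alt: float = 0.65
    session_s: float = 600.0
    mean_visit_s: float = 5.0
    mean_transit_s: float = 10.0

    def __post_init__(self) -> None:
        for p in (self.p_repeat, self.p_alt):
            if not (0.0 <= p <= 1.0):
                raise ValidationError("probabilities must be in [0, 1]")
        if min(self.session_s, self.mean_visit_s, self.mean_transit_s) <= 0:
            raise ValidationError("durations must be positive")


# ---------------------------------------------------------------------------
# CognitionWall choice agent
# ---------------------------------------------------------------------------


def simulate_cognitionwall(params: AgentParams, schedule: TaskSchedule,
                           seed) -> EntryStream:
    """Simulate one subject's full DL+RL entry stream.

    Entry times follow an inhomogeneous Poisson process whose rate tracks
    the light/dark phase of the schedule (mice work mostly at night).
    Each entry is chosen by a softmax over entrance values plus a
    stickiness bonus for the previous entrance; the chosen entrance's value
    moves toward the trial outcome (1 on pellet delivery, else 0) at rate
    ``alpha`` (``alpha_reversal`` after the reversal).  The reward signal is
    pellet delivery under the FR schedule — every ``fr``-th correct entry,
    with no rewards during the DL bias window — not per-correct-entry
    credit.
    """
    rng = np.random.default_rng(seed)
    q = np.array(params.q0, dtype=float)
    kappa_vec = np.zeros(3)
    t = 0.0
    times: List[float] = []
    choices: List[int] = []
    n = 0
    correct_count = 0  # post-bias correct entries within the current phase
    in_rl = False
    dark_rate = params.entry_rate / 3600.0
    light_rate = dark_rate * params.light_multiplier
    idx_of = {e: i for i, e in enumerate(ENTRANCES)}

    while n < params.max_entries:
        rate = dark_rate if schedule.phase_at(t) == "dark" else light_rate
        t += rng.exponential(1.0 / rate)
        if t >= schedule.task_duration_s:
            break
        now_rl = t >= schedule.rl_start_offset_s
        if now_rl and not in_rl:
            in_rl = True
            correct_count = 0  # FR counter restarts with the new contingency
        target = idx_of[schedule.target_rl if in_rl else schedule.target_dl]
        alpha = params.alpha
        if in_rl and params.alpha_reversal is not None:
            alpha = params.alpha_reversal

        logits = params.beta * (q + kappa_vec)
        logits -= logits.max()
        p = np.exp(logits)
        p /= p.sum()
        choice = int(np.searchsorted(np.cumsum(p), rng.random()))
        n += 1
        times.append(t)
        choices.append(choice)

        reward = 0.0
        # during DL the first bias_window entries of the task are unrewarded
        past_bias = in_rl or n > schedule.bias_window
        if choice == target and past_bias:
            correct_count += 1
            if correct_count % schedule.fr == 0:
                reward = 1.0
        q[choice] += alpha * (reward - q[choice])
        kappa_vec[:] = 0.0
        kappa_vec[choice] = params.kappa

    df = pd.DataFrame({
        "t": np.array(times),
        "entrance": np.array([ENTRANCES[c] for c in choices], dtype=object),
    })
    return EntryStream(str(seed) if not isinstance(seed, str) else seed, df, schedule)


# ---------------------------------------------------------------------------
# Y-maze walker
# ---------------------------------------------------------------------------


def simulate_ymaze_walker(params: WalkerParams, seed,
                          subject_id: Optional[str] = None) -> ArmVisitSequence:
    """Generate an arm-visit sequence from the Markov walking rule.

    The first arm is uniform; the second repeats with ``p_repeat`` and is
    otherwise uniform over the two remaining arms; later arms follow the
    repeat/alternate rule documented on :class:`WalkerParams`.  Visits are
    laid on a timeline of exponential visit and transit durations until
    the session ends.
    """
    rng = np.random.default_rng(seed)
    sid = subject_id if subject_id is not None else f"walker-{seed}"
    labels: List[int] = []
    t = float(rng.exponential(params.mean_transit_s))
    visits = []
    while t < params.session_s:
        if not labels:
            arm = int(rng.integers(3))
        else:
            last = labels[-1]
            others = [a for a in range(3) if a != last]
            if rng.random() < params.p_repeat:
                arm = last
            elif len(labels) == 1 or labels[-2] == last:
                arm = others[int(rng.integers(2))]
            else:
                alternating = 3 - last - labels[-2]  # the arm not in the last two
                other = labels[-2]
                arm = alternating if rng.random() < params.p_alt else other
        dur = float(rng.exponential(params.mean_visit_s))
        dur = max(dur, 0.05)
        visits.append((ARMS[arm], t, min(t + dur, params.session_s)))
        labels.append(arm)
        t += dur + float(rng.exponential(params.mean_transit_s))
    visits = [v for v in visits if v[2] > v[1]]
    return ArmVisitSequence(sid, visits)


def expected_alternation_pct(params: WalkerParams) -> float:
    """Closed-form expected alternation percentage of the walker.

    A triad is correct iff the middle visit differs from the first
    (probability ``1 - p_repeat``) and the third visit is the remaining arm
    (no repeat, then the alternating choice): ``(1-p_repeat)^2 * p_alt``.
    """
    return 100.0 * (1.0 - params.p_repeat) ** 2 * params.p_alt


def walker_track(seq: ArmVisitSequence, arena: Optional[ArenaGeometry] = None,
                 fs: float = 12.5) -> Track:
    """Render an arm-visit sequence as a nose+COG track.

    Scripted zone path: between visits both tracked points sit at the maze
    center; during each visit both points sit inside the arm zone (beyond
    the 3-cm border) with the nose deeper into the arm than the body
    center.  Extraction by the Y-maze scorer recovers the visit labels
    exactly.
    """
    arena = arena if arena is not None else ymaze_arena()
    cx, cy = arena.meta["center"]
    angles = arena.meta["arm_angles"]
    r_in = arena.meta["arm_mouth"] + arena.arm_border_inset

    end = max((v[2] for v in seq.visits), default=1.0) + 1.0
    t = np.arange(0.0, end, 1.0 / fs)
    nose = np.tile([cx, cy], (len(t), 1)).astype(float)
    cog = nose.copy()
    for arm, t0, t1 in seq.visits:
        ux, uy = math.cos(angles[arm]), math.sin(angles[arm])
        sel = (t >= t0) & (t < t1)
        cog[sel] = [cx + (r_in + 3.0) * ux, cy + (r_in + 3.0) * uy]
        nose[sel] = [cx + (r_in + 6.0) * ux, cy + (r_in + 6.0) * uy]
    df = pd.DataFrame({
        "t": t, "nose_x": nose[:, 0], "nose_y": nose[:, 1],
        "cog_x": cog[:, 0], "cog_y": cog[:, 1],
    })
    return Track(seq.subject_id, df, arena)


# ---------------------------------------------------------------------------
# dark-light box
# ---------------------------------------------------------------------------


def simulate_dlb(latency_rate: float = 1.0 / 30.0,
                 bout_means: Tuple[float, float] = (60.0, 60.0),
                 seed=0, fs: float = 12.5,
                 door_open_offset_s: float = 60.0,
                 subject_id: Optional[str] = None):
    """Simulate a dark-light box track plus its continuous-time ground truth.

    After the door opens the first light entry occurs after an exponential
    latency with rate ``latency_rate``; thereafter the mouse alternates
    exponential light/dark bouts with means ``bout_means``.  The state
    timeline is rendered at ``fs`` Hz with the body center 7 cm beyond the
    door while in the light (satisfying the 2-cm rule) and mid-dark
    otherwise.  Returns ``(track, truth)`` where ``truth`` holds the exact
    latency, in-light time and visit count of the continuous timeline over
    the 600-s scoring window.
    """
    rng = np.random.default_rng(seed)
    window = 600.0
    t_end = door_open_offset_s + window
    # continuous in-light intervals within [door_open, door_open + 600)
    intervals = []
    t = door_open_offset_s + float(rng.exponential(1.0 / latency_rate))
    state_light = True
    while t < t_end:
        if state_light:
            dur = float(rng.exponential(bout_means[0]))
            intervals.append((t, min(t + dur, t_end)))
        else:
            dur = float(rng.exponential(bout_means[1]))
        t += dur
        state_light = not state_light
    truth = {
        "latency_s": intervals[0][0] - door_open_offset_s if intervals else None,
        "time_in_light_s": float(sum(b - a for a, b in intervals)),
        "visits": len(intervals),
        "intervals": intervals,
    }

    arena = dlb_arena()
    door_x = arena.meta["door_x"]
    ts = np.arange(0.0, t_end + 1.0 / fs, 1.0 / fs)
    in_light = np.zeros(len(ts), dtype=bool)
    for a, b in intervals:
        in_light |= (ts >= a) & (ts < b)
    x = np.where(in_light, door_x + arena.door_margin + 5.0, door_x / 2.0)
    y = np.full(len(ts), arena.height / 2.0)
    df = pd.DataFrame({
        "t": ts, "nose_x": x + 1.0, "nose_y": y, "cog_x": x, "cog_y": y,
    })
    sid = subject_id if subject_id is not None else f"dlb-{seed}"
    return Track(sid, df, arena), truth


# ---------------------------------------------------------------------------
# home-cage random walk
# ---------------------------------------------------------------------------


def simulate_homecage_track(circadian_multiplier: float = 3.0,
                            speed_cm_s: float = 1.0,
                            days: float = 2.5,
                            seed=0,
                            schedule: Optional[TaskSchedule] = None,
                            fs: float = 0.5,
                            subject_id: Optional[str] = None):
    """Bounded random walk in the 30x30 cm cage with a circadian speed profile.

    The walk starts at dark onset (19:00); during dark hours the step speed
    is ``speed_cm_s * circadian_multiplier``, during light hours
    ``speed_cm_s``.  Steps have random headings and reflect off the walls.
    Returns ``(track, truth_hourly_m, schedule)`` — the schedule carries
    the track's wall-clock anchor — where the truth is the per-hour sum
    of realised sample-to-sample displacements computed by the generator's
    own bookkeeping (start-sample binning), for oracle tests against the
    activity scorer.
    """
    sched = schedule if schedule is not None else TaskSchedule()
    anchor = sched.dl_start.replace(hour=sched.dark_onset.hour,
                                    minute=sched.dark_onset.minute,
                                    second=0, microsecond=0)
    sched = sched.with_(track_start=anchor)
    rng = np.random.default_rng(seed)
    arena = phenotyper_arena()
    dt = 1.0 / fs
    n = int(days * 86400.0 * fs)
    t = np.arange(n) * dt

    # hour-of-cycle dark mask (anchor is dark onset, hour-aligned)
    hours = (t // 3600.0).astype(int)
    dark = np.array([sched.is_dark(sched.wall_clock(h * 3600.0, anchor))
                     for h in range(int(hours.max()) + 1)])
    speed = np.where(dark[hours], speed_cm_s * circadian_multiplier, speed_cm_s)

    headings = rng.uniform(0.0, 2.0 * math.pi, size=n - 1)
    steps = (speed[:-1] * dt)[:, None] * np.column_stack(
        [np.cos(headings), np.sin(headings)]
    )
    pos = np.empty((n, 2))
    pos[0] = (arena.width / 2.0, arena.height / 2.0)
    raw = pos[0] + np.cumsum(steps, axis=0)
    # reflect off the walls by folding the unconstrained path
    period = np.array([2.0 * arena.width, 2.0 * arena.height])
    lims = np.array([arena.width, arena.height])
    folded = np.mod(raw, period)
    pos[1:] = np.where(folded > lims, period - folded, folded)

    disp = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    n_hours = int(math.ceil(days * 24.0))
    truth = np.zeros(n_hours)
    np.add.at(truth, np.minimum(hours[:-1], n_hours - 1), disp)
    truth_m = truth / 100.0

    nose = pos + np.array([0.5, 0.0])
    df = pd.DataFrame({
        "t": t, "nose_x": nose[:, 0], "nose_y": nose[:, 1],
        "cog_x": pos[:, 0], "cog_y": pos[:, 1],
    })
    sid = subject_id if subject_id is not None else f"cage-{seed}"
    return Track(sid, df, arena), truth_m, sched


# ---------------------------------------------------------------------------
# full cohort
# ---------------------------------------------------------------------------

_ASSAY_CODES = {"cognitionwall": 0, "ymaze": 1, "dlb": 2, "homecage": 3}


def subject_rng_seed(master_seed: int, subject_index: int, assay: str):
    """Deterministic per-subject, per-assay seed material.

    Counter scheme: ``SeedSequence([master, subject_index, assay_code])``.
    Adding subjects never reshuffles existing ones.
    """
    return np.random.SeedSequence(
        [int(master_seed), int(subject_index), _ASSAY_CODES[assay]]
    )


def subject_rng(master_seed: int, subject_index: int, assay: str) -> np.random.Generator:
    return np.random.default_rng(subject_rng_seed(master_seed, subject_index, assay))


@dataclass
class Cohort:
    """A full synthetic study: metadata plus per-subject assay data."""

    subjects: List[SubjectMeta]
    schedule: TaskSchedule
    streams: Dict[str, EntryStream]
    ymaze_visits: Dict[str, ArmVisitSequence] = field(default_factory=dict)
    dlb_tracks: Dict[str, Track] = field(default_factory=dict)
    dlb_truth: Dict[str, dict] = field(default_factory=dict)

    def by_group(self) -> Dict[str, List[SubjectMeta]]:
        groups: Dict[str, List[SubjectMeta]] = {}
        for s in self.subjects:
            groups.setdefault(s.group, []).append(s)
        return groups


def default_design(n_per_group: int = 15, **param_overrides) -> Dict[str, dict]:
    """Null study design: four genotype x sex groups with identical parameters.

    Group sizes default to the 15-per-sex-per-genotype design.  Returns a
    dict mapping group label to ``{"n", "agent", "walker"}``; modify a
    group's entries (e.g. set ``alpha_reversal=0.0`` on one group's agent)
    to build effect cohorts.
    """
    agent = AgentParams(**param_overrides)
    walker = WalkerParams()
    return {
        f"{g}_{s}": {"n": n_per_group, "agent": agent, "walker": walker}
        for g in ("wildtype", "mdx") for s in ("male", "female")
    }


def simulate_cohort(design: Dict[str, dict], seed: int,
                    schedule: Optional[TaskSchedule] = None,
                    include_ymaze: bool = True,
                    include_dlb: bool = False) -> Cohort:
    """Simulate a full cohort from a design of per-group sizes and parameters.

    Subject seeds derive from the master seed and a global subject counter
    (see :func:`subject_rng_seed`), so identical master seeds reproduce the
    cohort bit-for-bit and extending a group leaves earlier subjects
    untouched.
    """
    sched = schedule if schedule is not None else TaskSchedule()
    subjects: List[SubjectMeta] = []
    streams: Dict[str, EntryStream] = {}
    ym: Dict[str, ArmVisitSequence] = {}
    dlb_tracks: Dict[str, Track] = {}
    dlb_truths: Dict[str, dict] = {}
    counter = 0
    for group in sorted(design):
        spec = design[group]
        n = int(spec["n"])
        if n < 1:
            raise ValidationError(f"group {group!r} must have n >= 1")
        genotype, sex = group.rsplit("_", 1)
        for j in range(n):
            sid = f"{group}_{j + 1:02d}"
            subjects.append(SubjectMeta(sid, genotype, sex, batch=1))
            stream = simulate_cognitionwall(
                spec["agent"], sched, subject_rng_seed(seed, counter, "cognitionwall")
            )
            streams[sid] = EntryStream(sid, stream.df, sched)
            if include_ymaze:
                ym[sid] = simulate_ymaze_walker(
                    spec.get("walker", WalkerParams()),
                    subject_rng_seed(seed, counter, "ymaze"),
                    subject_id=sid,
                )
            if include_dlb:
                track, truth = simulate_dlb(
                    seed=subject_rng_seed(seed, counter, "dlb"), subject_id=sid
                )
                dlb_tracks[sid] = track
                dlb_truths[sid] = truth
            counter += 1
    return Cohort(subjects, sched, streams, ym, dlb_tracks, dlb_truths)


def write_cohort(cohort: Cohort, out_dir) -> None:
    """Emit a cohort as the CSV files the readers consume."""
    from pathlib import Path

    from . import io as pio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pio.write_subjects(cohort.subjects, out / "subjects.csv")
    events_dir = out / "events"
    events_dir.mkdir(exist_ok=True)
    for sid, stream in cohort.streams.items():
        pio.write_entry_stream(stream, events_dir / f"{sid}.csv")
    if cohort.dlb_tracks:
        dlb_dir = out / "dlb"
        dlb_dir.mkdir(exist_ok=True)
        for sid, track in cohort.dlb_tracks.items():
            pio.write_track(track, dlb_dir / f"{sid}.csv")
    if cohort.ymaze_visits:
        rows = []
        for sid, seq in cohort.ymaze_visits.items():
            for arm, t0, t1 in seq.visits:
                rows.append({"subject_id": sid, "arm": arm,
                             "t_enter": t0, "t_exit": t1})
        pd.DataFrame(rows).to_csv(out / "ymaze_visits.csv", index=False,
                                  float_format="%.6g", lineterminator="\n")
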