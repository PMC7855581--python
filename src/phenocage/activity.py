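"""Spontaneous activity: hourly distance moved and light/dark aggregation.

Home-cage video tracking starts at dark onset (19:00) and runs for two and
a half days.  The total distance moved per hour is extracted from the
center-of-gravity trajectory and aggregated over the dark (19:00-07:00)
and light (07:00-19:00) phases.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .core import TaskSchedule, Track, ValidationError

__all__ = ["HourlyActivity", "hourly_distance", "phase_totals"]


@dataclass
class HourlyActivity:
    """Hour-binned distance moved, with phase labels.

    ``bins`` has columns ``bin_start`` (wall-clock datetime, hour-aligned),
    ``distance_m``, ``phase`` (dark/light, from the bin start time of day)
    and ``partial`` (True for the edge bins not fully covered by the track).
    Bins are contiguous and one hour wide.
    """

    subject_id: str
    bins: pd.DataFrame


def hourly_distance(track: Track, schedule: TaskSchedule,
                    track_start: Optional[datetime] = None) -> HourlyActivity:
    """Per-hour path length of the center of gravity, in meters.

    ``track_start`` anchors track second 0 on the wall clock; it defaults
    to ``schedule.track_anchor`` (for spontaneous-behaviour recordings this
    is dark onset, 19:00).  Each movement step between consecutive valid
    samples is assigned to the hour bin of its *starting* sample, so bin
    sums conserve the total path length exactly.  Tracking gaps (NaN
    samples) contribute zero distance — a gap is not a teleport.
    """
    anchor = track_start if track_start is not None else schedule.track_anchor
    t = track.t
    if len(t) == 0:
        raise ValidationError("empty track")
    cog = track.cog
    ok = track.valid_mask()
    steps = np.linalg.norm(np.diff(cog, axis=0), axis=1)
    step_ok = ok[:-1] & ok[1:]
    steps = np.where(step_ok, steps, 0.0)

    # hour-aligned bins covering the track, in wall-clock time
    start_dt = anchor + timedelta(seconds=float(t[0]))
    end_dt = anchor + timedelta(seconds=float(t[-1]))
    first_bin = start_dt.replace(minute=0, second=0, microsecond=0)
    n_bins = int((end_dt - first_bin).total_seconds() // 3600) + 1

    offset_s = (start_dt - first_bin).total_seconds()  # of first sample in bin 0
    rel = t - t[0] + offset_s
    bin_idx = np.minimum((rel[:-1] // 3600.0).astype(int), n_bins - 1)
    dist_cm = np.bincount(bin_idx, weights=steps, minlength=n_bins)

    rows = []
    for i in range(n_bins):
        bstart = first_bin + timedelta(hours=i)
        bend = bstart + timedelta(hours=1)
        rows.append({
            "bin_start": bstart,
            "distance_m": dist_cm[i] / 100.0,
            "phase": "dark" if schedule.is_dark(bstart) else "light",
            "partial": (start_dt > bstart) or (end_dt < bend),
        })
    return HourlyActivity(track.subject_id, pd.DataFrame(rows))


def phase_totals(hourly: HourlyActivity) -> Dict:
    """Dark/light totals and per-day totals from hourly bins.

    ``dark_m + light_m`` equals the grand total exactly; days are indexed
    from the first bin in 24-h blocks.
    """
    bins = hourly.bins
    dark = float(bins.loc[bins["phase"] == "dark", "distance_m"].sum())
    light = float(bins.loc[bins["phase"] == "light", "distance_m"].sum())
    if len(bins):
        day_idx = (
            (bins["bin_start"] - bins["bin_start"].iloc[0]).dt.total_seconds()
            // 86400.0
        ).astype(int)
        per_day = (
            bins.assign(day=day_idx)
            .groupby("day", as_index=False)["distance_m"].sum()
        )
    else:
        per_day = pd.DataFrame({"day": [], "distance_m": []})
    return {"dark_m": dark, "light_m": light, "per_day": per_day,
            "total_m": dark + light}
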