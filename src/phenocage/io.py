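"""Readers and writers for event tables, position tracks and result tables.

Input tables are delimited text (CSV or TSV, UTF-8, header row, ``.``
decimal).  Outputs are TSV result tables plus a JSON manifest recording
file name, row count and content checksum; floats are rendered with six
significant digits and re-runs on identical inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .core import (
    ENTRANCES,
    ArenaGeometry,
    EntryStream,
    ParseError,
    SubjectMeta,
    TaskSchedule,
    Track,
    ValidationError,
)

__all__ = [
    "read_entry_stream",
    "write_entry_stream",
    "read_track",
    "write_track",
    "read_subjects",
    "write_subjects",
    "write_results",
    "load_schedule",
]

FLOAT_FMT = "%.6g"       # result tables: six significant digits
RAW_FLOAT_FMT = "%.12g"  # raw event/track data: lossless for seconds-scale times


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        return pd.read_csv(path, sep=sep)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc


def read_entry_stream(path, schedule: TaskSchedule,
                      subject_id: Optional[str] = None) -> EntryStream:
    """Read one subject's entrance-event table.

    Expects columns ``t`` (or ``timestamp``) and ``entrance``; an optional
    ``subject_id`` column must be single-valued unless ``subject_id``
    selects one subject.  Rows violating the strictly-increasing time or
    the closed entrance vocabulary raise :class:`ParseError` naming the
    offending data line (1-based, excluding the header).
    """
    df = _read_table(path)
    if "t" not in df.columns and "timestamp" in df.columns:
        df = df.rename(columns={"timestamp": "t"})
    for col in ("t", "entrance"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    if "subject_id" in df.columns:
        ids = df["subject_id"].astype(str)
        if subject_id is not None:
            df = df[ids == subject_id]
        elif ids.nunique() > 1:
            raise ParseError(
                f"{path}: multiple subjects present; pass subject_id"
            )
        elif len(ids):
            subject_id = ids.iloc[0]
    sid = subject_id if subject_id is not None else Path(path).stem
    df = df.reset_index(drop=True)

    t = pd.to_numeric(df["t"], errors="coerce").to_numpy(float)
    for i in np.flatnonzero(~np.isfinite(t)):
        raise ParseError(f"{path}: line {i + 1}: unparseable timestamp {df['t'].iloc[i]!r}")
    bad_lab = ~df["entrance"].isin(ENTRANCES)
    if bad_lab.any():
        i = int(np.flatnonzero(bad_lab.to_numpy())[0])
        raise ParseError(
            f"{path}: line {i + 1}: unknown entrance "
            f"{df['entrance'].iloc[i]!r}; allowed: {list(ENTRANCES)}"
        )
    dec = np.flatnonzero(np.diff(t) <= 0)
    if len(dec):
        i = int(dec[0]) + 1
        raise ParseError(
            f"{path}: line {i + 1}: timestamp {t[i]:g} does not increase "
            f"past previous value {t[i - 1]:g}"
        )
    out = pd.DataFrame({"t": t, "entrance": df["entrance"].to_numpy()})
    if schedule.min_interentry_s > 0 and len(out) > 1:
        keep = [0]
        last = t[0]
        for i in range(1, len(t)):
            if t[i] - last >= schedule.min_interentry_s:
                keep.append(i)
                last = t[i]
        out = out.iloc[keep].reset_index(drop=True)
    return EntryStream(sid, out, schedule)


def write_entry_stream(stream: EntryStream, path) -> None:
    df = stream.df.copy()
    df.insert(0, "subject_id", stream.subject_id)
    _write_tsv_like(df, path, float_format=RAW_FLOAT_FMT)


def read_track(path, arena: ArenaGeometry, subject_id: Optional[str] = None,
               outside_warn_frac: float = 0.05) -> Track:
    """Read a position track (``t, nose_x, nose_y, cog_x, cog_y``).

    Rows with NaN positions are retained as tracking gaps.  Non-monotone
    timestamps are an error; more than ``outside_warn_frac`` of samples
    outside the arena bounding box triggers a warning (not an error — the
    track may legitimately be in a differently-registered frame).
    """
    df = _read_table(path)
    missing = set(Track.REQUIRED) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing required columns {sorted(missing)}")
    if "subject_id" in df.columns and subject_id is None:
        sid = str(df["subject_id"].iloc[0]) if len(df) else Path(path).stem
    else:
        sid = subject_id if subject_id is not None else Path(path).stem
    num = df[list(Track.REQUIRED)].apply(pd.to_numeric, errors="coerce")
    t = num["t"].to_numpy(float)
    if not np.all(np.isfinite(t)):
        i = int(np.flatnonzero(~np.isfinite(t))[0])
        raise ParseError(f"{path}: line {i + 1}: unparseable time")
    dec = np.flatnonzero(np.diff(t) <= 0)
    if len(dec):
        raise ParseError(
            f"{path}: line {int(dec[0]) + 2}: non-monotone timestamps"
        )
    track = Track(sid, num, arena)
    valid = track.valid_mask()
    if valid.any():
        inside = arena.in_bounds(num["cog_x"][valid], num["cog_y"][valid])
        frac_out = 1.0 - inside.mean()
        if frac_out > outside_warn_frac:
            warnings.warn(
                f"{path}: {int((~inside).sum())} of {int(valid.sum())} samples "
                f"({100 * frac_out:.1f}%) outside the {arena.kind} bounding box",
                stacklevel=2,
            )
    return track


def write_track(track: Track, path) -> None:
    _write_tsv_like(track.df, path, float_format=RAW_FLOAT_FMT)


def read_subjects(path) -> list:
    """Read subject metadata (subject_id, genotype, sex, batch[, exclusion_reason])."""
    df = _read_table(path)
    subjects = []
    for _, row in df.iterrows():
        reason = row.get("exclusion_reason")
        if isinstance(reason, float) and np.isnan(reason):
            reason = None
        if reason == "":
            reason = None
        subjects.append(SubjectMeta(
            subject_id=str(row["subject_id"]),
            genotype=str(row["genotype"]),
            sex=str(row["sex"]),
            batch=int(row.get("batch", 1)),
            exclusion_reason=reason,
        ))
    ids = [s.subject_id for s in subjects]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate subject ids")
    return subjects


def write_subjects(subjects, path) -> None:
    df = pd.DataFrame([
        {
            "subject_id": s.subject_id,
            "genotype": s.genotype,
            "sex": s.sex,
            "batch": s.batch,
            "exclusion_reason": s.exclusion_reason or "",
        }
        for s in subjects
    ])
    _write_tsv_like(df, path)


def _write_tsv_like(df: pd.DataFrame, path, float_format: str = FLOAT_FMT) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df.to_csv(path, sep=sep, index=False, float_format=float_format,
              lineterminator="\n")


def write_results(tables: Mapping[str, pd.DataFrame], out_dir) -> Dict:
    """Write one TSV per result table plus a JSON manifest.

    Tables are written in sorted name order with their column order
    preserved; the manifest records file name, row count and the SHA-256 of
    the file bytes, so identical inputs always produce byte-identical
    output trees.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for name in sorted(tables):
        fname = f"{name}.tsv"
        fpath = out / fname
        _write_tsv_like(tables[name], fpath)
        digest = hashlib.sha256(fpath.read_bytes()).hexdigest()
        manifest[name] = {
            "file": fname,
            "rows": int(len(tables[name])),
            "sha256": digest,
        }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


_TIME_FIELDS = ("dark_onset", "light_onset")
_DT_FIELDS = ("dl_start", "track_start")


def load_schedule(path) -> TaskSchedule:
    """Load a :class:`TaskSchedule` from a YAML or JSON config file.

    Unknown keys are rejected; omitted keys take the documented defaults.
    Times of day are ``HH:MM`` strings, datetimes ISO-8601.
    """
    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh) if path.suffix.lower() == ".json" else yaml.safe_load(fh)
    raw = dict(raw or {})
    import dataclasses
    allowed = {f.name for f in dataclasses.fields(TaskSchedule)}
    unknown = set(raw) - allowed
    if unknown:
        raise ValidationError(f"{path}: unknown schedule keys {sorted(unknown)}")
    from datetime import datetime, time
    for key in _TIME_FIELDS:
        if key in raw and isinstance(raw[key], str):
            hh, mm = raw[key].split(":")
            raw[key] = time(int(hh), int(mm))
    for key in _DT_FIELDS:
        if key in raw and isinstance(raw[key], str):
            raw[key] = datetime.fromisoformat(raw[key])
    return TaskSchedule(**raw)
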