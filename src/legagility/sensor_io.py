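"""Reading and writing inertial recordings, manifests and rating sets.

Recordings are comma-separated text with a header row, one row per sample,
as exported by common smartphone sensor-logging apps.  The column names are
configurable through a :class:`ColumnMap`; the defaults match the canonical
schema this package writes (``time, acc_x..acc_z, gyr_x..gyr_z, pitch``).

Units on ingest: acceleration in g (m/s^2 accepted and converted), angular
velocity in degrees per second, pitch in degrees.  Timestamps may be seconds
or milliseconds; the dialect is auto-detected from the median inter-sample
interval and logged.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ._utils import round_half_away
from .errors import FormatError, ManifestError, TooShortError

logger = logging.getLogger(__name__)

G_PER_MS2 = 1.0 / 9.80665

#: Canonical recording-file column names.
CANONICAL_COLUMNS = (
    "time",
    "acc_x", "acc_y", "acc_z",
    "gyr_x", "gyr_y", "gyr_z",
    "pitch",
)


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from a logger export's column names to the canonical schema.

    Parameters
    ----------
    time, accel, gyro, pitch
        Source column names.  ``pitch`` may be ``None`` when the app did not
        log orientation; the preprocessing stage then recomputes pitch from
        the gravity direction.
    accel_unit
        ``"g"`` or ``"m/s2"``; the latter is divided by 9.80665 on load.
    gyro_unit
        ``"dps"`` or ``"rad/s"``.
    """

    time: str = "time"
    accel: tuple[str, str, str] = ("acc_x", "acc_y", "acc_z")
    gyro: tuple[str, str, str] = ("gyr_x", "gyr_y", "gyr_z")
    pitch: Optional[str] = "pitch"
    accel_unit: str = "g"
    gyro_unit: str = "dps"


@dataclass
class InertialRecording:
    """One Leg Agility execution recorded by a thigh-mounted device.

    Channels: ``accel`` (n x 3, in g, device axes), ``gyro`` (n x 3, in dps)
    and optionally ``pitch`` (rotation about the device x-axis, degrees).
    """

    recording_id: str
    subject_id: str
    leg: str  # "left" | "right"
    fs: float
    t: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    pitch: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.leg not in ("left", "right"):
            raise ValueError(f"leg must be 'left' or 'right', got {self.leg!r}")
        self.t = np.asarray(self.t, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.pitch is not None:
            self.pitch = np.asarray(self.pitch, dtype=float)

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) > 1 else 0.0

    def validate(self) -> None:
        n = self.n_samples
        for name, ch in (("accel", self.accel), ("gyro", self.gyro)):
            if ch.shape != (n, 3):
                raise FormatError(f"{name} shape {ch.shape} != ({n}, 3)")
        if self.pitch is not None and self.pitch.shape != (n,):
            raise FormatError(f"pitch shape {self.pitch.shape} != ({n},)")
        if n < 2 * self.fs:
            raise TooShortError(
                f"{self.recording_id}: {n} samples < 2*fs = {2 * self.fs:.0f}"
            )
        if np.any(np.diff(self.t) <= 0):
            raise FormatError(f"{self.recording_id}: time vector not strictly increasing")
        for name, ch in (("t", self.t), ("accel", self.accel), ("gyro", self.gyro)):
            if not np.all(np.isfinite(ch)):
                raise FormatError(f"{self.recording_id}: non-finite values in {name}")
        if self.pitch is not None and not np.all(np.isfinite(self.pitch)):
            raise FormatError(f"{self.recording_id}: non-finite values in pitch")


@dataclass
class RatingSet:
    """Integer clinical scores (0-4) from up to four raters for one recording.

    ``label`` is the rounded (half away from zero) mean score, the class
    label used for supervised classification; ``mean_score`` keeps the
    un-rounded mean used as the continuous regression target.
    """

    recording_id: str
    scores: list[int]
    mean_score: float = field(init=False)
    label: int = field(init=False)

    def __post_init__(self):
        if not self.scores:
            raise ValueError("at least one rater score required")
        for s in self.scores:
            if not (0 <= s <= 4 and float(s).is_integer()):
                raise ValueError(f"rater scores must be integers in [0, 4], got {s}")
        self.scores = [int(s) for s in self.scores]
        self.mean_score = float(np.mean(self.scores))
        self.label = int(round_half_away(self.mean_score))


@dataclass
class ManifestEntry:
    recording_id: str
    subject_id: str
    leg: str
    path: Optional[str]
    ratings: RatingSet
    recording: Optional[InertialRecording] = None  # populated for in-memory cohorts


@dataclass
class CohortManifest:
    """The cohort: one entry per Leg Agility execution (<= 2 per subject)."""

    entries: list[ManifestEntry]

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        ids = [e.recording_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ManifestError("duplicate recording_id in manifest")
        pairs = [(e.subject_id, e.leg) for e in self.entries]
        if len(set(pairs)) != len(pairs):
            dupes = {p for p in pairs if pairs.count(p) > 1}
            raise ManifestError(f"duplicate (subject, leg) pairs: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.subject_id, None)
        return list(seen)


@dataclass
class SamplingReport:
    """Report of inter-sample gaps and the effective sampling rate."""

    recording_id: str
    n_gaps: int
    gap_times: np.ndarray  # start times (s) of flagged gaps
    effective_rate: float
    nominal_rate: float


def _detect_time_unit(t: np.ndarray) -> float:
    """Return a divisor converting the raw time column to seconds.

    A median inter-sample interval >= 0.5 at a plausibly >2 Hz sampling
    rate means milliseconds; intervals below that are taken as seconds.
    """
    dt = float(np.median(np.diff(t)))
    if dt >= 0.5:
        logger.info("timestamps interpreted as milliseconds (median dt %.3f)", dt)
        return 1000.0
    return 1.0


def read_recording(
    path,
    column_map: ColumnMap | None = None,
    fs_hint: float | None = None,
    recording_id: str | None = None,
    subject_id: str = "",
    leg: str = "left",
) -> InertialRecording:
    """Read one recording from a CSV file.

    Rows with unparsable values are dropped (count logged); duplicated
    timestamps are collapsed keeping the first occurrence.  When ``fs_hint``
    is absent the rate is estimated as the reciprocal of the median
    inter-sample interval.
    """
    cmap = column_map or ColumnMap()
    path = Path(path)
    df = pd.read_csv(path)

    needed = [cmap.time, *cmap.accel, *cmap.gyro]
    if cmap.pitch is not None and cmap.pitch in df.columns:
        pitch_col: Optional[str] = cmap.pitch
    else:
        pitch_col = None
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing mandatory columns {missing}")

    cols = needed + ([pitch_col] if pitch_col else [])
    numeric = df[cols].apply(pd.to_numeric, errors="coerce")
    n_raw = len(numeric)
    numeric = numeric.dropna()
    n_dropped = n_raw - len(numeric)
    if n_dropped:
        logger.warning("%s: dropped %d unparsable rows", path.name, n_dropped)

    t = numeric[cmap.time].to_numpy(dtype=float)
    t = t / _detect_time_unit(t)
    order = np.argsort(t, kind="stable")
    t = t[order]
    numeric = numeric.iloc[order]
    keep = np.concatenate([[True], np.diff(t) > 0])
    if not np.all(keep):
        logger.warning("%s: collapsed %d duplicated timestamps", path.name, int((~keep).sum()))
    t = t[keep]
    numeric = numeric.iloc[keep]

    accel = numeric[list(cmap.accel)].to_numpy(dtype=float)
    gyro = numeric[list(cmap.gyro)].to_numpy(dtype=float)
    if cmap.accel_unit == "m/s2":
        accel = accel * G_PER_MS2
    elif cmap.accel_unit != "g":
        raise FormatError(f"unknown accel unit {cmap.accel_unit!r}")
    if cmap.gyro_unit == "rad/s":
        gyro = np.degrees(gyro)
    elif cmap.gyro_unit != "dps":
        raise FormatError(f"unknown gyro unit {cmap.gyro_unit!r}")
    pitch = numeric[pitch_col].to_numpy(dtype=float) if pitch_col else None

    if len(t) < 2:
        raise TooShortError(f"{path.name}: fewer than 2 usable samples")
    fs = float(fs_hint) if fs_hint else float(1.0 / np.median(np.diff(t)))

    rec = InertialRecording(
        recording_id=recording_id or path.stem,
        subject_id=subject_id,
        leg=leg,
        fs=fs,
        t=t,
        accel=accel,
        gyro=gyro,
        pitch=pitch,
    )
    rec.validate()
    return rec


def write_recording(rec: InertialRecording, path) -> None:
    """Write a recording in the canonical CSV dialect (round-trip safe)."""
    data = {
        "time": rec.t,
        "acc_x": rec.accel[:, 0],
        "acc_y": rec.accel[:, 1],
        "acc_z": rec.accel[:, 2],
        "gyr_x": rec.gyro[:, 0],
        "gyr_y": rec.gyro[:, 1],
        "gyr_z": rec.gyro[:, 2],
    }
    if rec.pitch is not None:
        data["pitch"] = rec.pitch
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.12g")


def validate_sampling(rec: InertialRecording, max_gap_factor: float = 2.0) -> SamplingReport:
    """Flag inter-sample gaps longer than ``max_gap_factor / fs`` (report only)."""
    dt = np.diff(rec.t)
    threshold = max_gap_factor / rec.fs
    gap_idx = np.flatnonzero(dt > threshold)
    effective = float(1.0 / np.mean(dt))
    return SamplingReport(
        recording_id=rec.recording_id,
        n_gaps=len(gap_idx),
        gap_times=rec.t[gap_idx],
        effective_rate=effective,
        nominal_rate=rec.fs,
    )


def count_recordings(manifest: CohortManifest) -> tuple[int, int]:
    """Return ``(n_subjects, n_recordings)`` for a validated manifest."""
    manifest.validate()
    return len(manifest.subjects), len(manifest.entries)


def expected_recordings(n_subjects: int, n_single_leg: int) -> int:
    """Recordings expected when each subject performs both legs except
    ``n_single_leg`` subjects who could test a single leg only."""
    if n_single_leg > n_subjects:
        raise ValueError("more single-leg subjects than subjects")
    return 2 * n_subjects - n_single_leg


def read_manifest(path, base_dir=None) -> CohortManifest:
    """Read a cohort manifest CSV.

    Columns: ``recording_id, subject_id, leg, path, score_r1..score_r4``
    (an empty score cell means the rater did not score that recording).
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = ["recording_id", "subject_id", "leg", "path"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: manifest missing columns {missing}")
    score_cols = [c for c in df.columns if c.startswith("score_r")]
    base = Path(base_dir) if base_dir else path.parent
    entries = []
    for _, row in df.iterrows():
        scores = [int(row[c]) for c in score_cols if pd.notna(row[c])]
        rid = str(row["recording_id"])
        rec_path = base / str(row["path"])
        entries.append(
            ManifestEntry(
                recording_id=rid,
                subject_id=str(row["subject_id"]),
                leg=str(row["leg"]),
                path=str(rec_path),
                ratings=RatingSet(recording_id=rid, scores=scores),
            )
        )
    return CohortManifest(entries=entries)


def write_manifest(manifest: CohortManifest, path, max_raters: int = 4) -> None:
    """Write a manifest CSV; recording paths are stored relative to it."""
    path = Path(path)
    rows = []
    for e in manifest.entries:
        rel = ""
        if e.path:
            try:
                rel = os.path.relpath(e.path, path.parent)
            except ValueError:  # different drive on Windows
                rel = e.path
        row = {
            "recording_id": e.recording_id,
            "subject_id": e.subject_id,
            "leg": e.leg,
            "path": rel,
        }
        for i in range(max_raters):
            row[f"score_r{i + 1}"] = e.ratings.scores[i] if i < len(e.ratings.scores) else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def load_recording_for_entry(entry: ManifestEntry, column_map: ColumnMap | None = None,
                             fs_hint: float | None = None) -> InertialRecording:
    """Return the in-memory recording of a manifest entry, reading the file
    lazily when the cohort was written to disk."""
    if entry.recording is not None:
        return entry.recording
    if entry.path is None:
        raise ManifestError(f"{entry.recording_id}: no recording object and no path")
    return read_recording(
        entry.path,
        column_map=column_map,
        fs_hint=fs_hint,
        recording_id=entry.recording_id,
        subject_id=entry.subject_id,
        leg=entry.leg,
    )
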