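"""Recording CSVs and the cohort manifest.

A recording is a wide CSV emulating an inertial motion-capture export: first
column ``time_s`` (uniform step, 1/fs), remaining columns named
``<side>_<joint>_<measure>`` (e.g. ``left_knee_flexion``) holding joint
angles in degrees.  The cohort manifest is a flat CSV with columns
``file,participant_id,group,dance,recording_id`` mapping each recording file
to its participant, clinical group (PD = Parkinson's disease, OA = healthy
older adult) and dance type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CohortError, FormatError

log = logging.getLogger(__name__)

GROUPS = ("PD", "OA")
DANCES = ("tango", "waltz", "foxtrot", "line", "rumba", "swing")
SIDES = ("left", "right")
JOINTS = ("elbow", "hip", "knee")
MEASURES = ("flexion", "abduction", "rotation")

#: valid (joint, measure) combinations; elbow and knee are hinge joints here
JOINT_MEASURES = (
    ("elbow", "flexion"),
    ("hip", "flexion"),
    ("hip", "abduction"),
    ("hip", "rotation"),
    ("knee", "flexion"),
)

#: the lower-limb channels the analysis uses by default (upper limb is read
#: but excluded from analysis unless explicitly allowed)
LOWER_LIMB = tuple(
    (joint, measure) for joint, measure in JOINT_MEASURES if joint != "elbow"
)


def channel_name(side: str, joint: str, measure: str) -> str:
    return f"{side}_{joint}_{measure}"


def parse_channel_name(name: str) -> tuple[str, str, str] | None:
    """(side, joint, measure) for a valid channel column, else None."""
    parts = name.split("_")
    if len(parts) != 3:
        return None
    side, joint, measure = parts
    if side in SIDES and (joint, measure) in JOINT_MEASURES:
        return side, joint, measure
    return None


@dataclass
class JointSeries:
    """One channel of joint-angle samples with its identifying metadata."""

    values: np.ndarray
    fs: float = 100.0
    joint: str = "knee"
    measure: str = "flexion"
    side: str = "right"
    recording_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if (self.joint, self.measure) not in JOINT_MEASURES:
            raise ValueError(f"invalid joint/measure: {self.joint}/{self.measure}")
        if self.side not in SIDES:
            raise ValueError(f"invalid side: {self.side}")

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def duration_s(self) -> float:
        return self.n / self.fs

    @property
    def name(self) -> str:
        return channel_name(self.side, self.joint, self.measure)


@dataclass
class Recording:
    """All channels of one capture session, plus cohort metadata."""

    recording_id: str
    participant_id: str
    group: str
    dance: str
    channels: dict[str, JointSeries] = field(default_factory=dict)
    fs: float = 100.0

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.dance not in DANCES:
            raise ValueError(f"dance must be one of {DANCES}, got {self.dance!r}")
        lengths = {ch.n for ch in self.channels.values()}
        if len(lengths) > 1:
            raise ValueError("all channels must share the same length")
        for ch in self.channels.values():
            if ch.fs != self.fs:
                raise ValueError("all channels must share the recording fs")

    @property
    def n_samples(self) -> int:
        if not self.channels:
            return 0
        return next(iter(self.channels.values())).n

    @property
    def duration_min(self) -> float:
        return self.n_samples / self.fs / 60.0


@dataclass(frozen=True)
class ManifestEntry:
    file: str
    participant_id: str
    group: str
    dance: str
    recording_id: str
    note: str = ""


#: deterministic column order: left before right, proximal before distal,
#: flexion/abduction/rotation within a joint
CHANNEL_ORDER = tuple(
    channel_name(side, joint, measure)
    for side in SIDES
    for joint in JOINTS
    for measure in MEASURES
    if (joint, measure) in JOINT_MEASURES
)


def read_recording_csv(path, meta: ManifestEntry) -> Recording:
    """Parse one recording CSV against its manifest entry.

    Validates a uniform time base (step deviations beyond 1% of the median
    step are a format error), numeric cells, and at least one recognizable
    channel column; unknown columns are ignored with a logged warning.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - rewrap as a format error
        raise FormatError(f"{path}: unreadable CSV ({exc})") from exc
    if df.shape[0] < 2:
        raise FormatError(f"{path}: need at least 2 rows")
    if df.columns[0] != "time_s":
        raise FormatError(f"{path}: first column must be 'time_s'")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            row = int(bad[0]) if len(bad) else -1
            raise FormatError(f"{path}: non-numeric value in column {col!r}, row {row}")
        if df[col].isna().any():
            row = int(df.index[df[col].isna()][0])
            raise FormatError(f"{path}: missing value in column {col!r}, row {row}")

    t = df["time_s"].to_numpy(dtype=np.float64)
    dt = np.diff(t)
    step = float(np.median(dt))
    if step <= 0:
        raise FormatError(f"{path}: time_s must be strictly increasing")
    if np.any(np.abs(dt - step) > 0.01 * step):
        k = int(np.argmax(np.abs(dt - step) > 0.01 * step))
        raise FormatError(
            f"{path}: non-uniform sampling at row {k + 1} "
            f"(step {dt[k]:.6g}, expected {step:.6g})"
        )
    fs = 1.0 / step

    channels: dict[str, JointSeries] = {}
    for col in df.columns[1:]:
        parsed = parse_channel_name(col)
        if parsed is None:
            log.warning("%s: ignoring unrecognized column %r", path, col)
            continue
        side, joint, measure = parsed
        channels[col] = JointSeries(
            values=df[col].to_numpy(dtype=np.float64),
            fs=fs,
            joint=joint,
            measure=measure,
            side=side,
            recording_id=meta.recording_id,
        )
    if not channels:
        raise FormatError(f"{path}: no recognizable channel columns")
    return Recording(
        recording_id=meta.recording_id,
        participant_id=meta.participant_id,
        group=meta.group,
        dance=meta.dance,
        channels=channels,
        fs=fs,
    )


def write_recording_csv(recording: Recording, path) -> None:
    """Emit the CSV dialect above at full float precision, deterministically."""
    if not recording.channels:
        raise ValueError("recording has no channels to write")
    path = Path(path)
    n = recording.n_samples
    t = np.arange(n) / recording.fs
    cols: dict[str, np.ndarray] = {"time_s": t}
    ordered = [c for c in CHANNEL_ORDER if c in recording.channels]
    extra = sorted(c for c in recording.channels if c not in CHANNEL_ORDER)
    for name in ordered + extra:
        cols[name] = recording.channels[name].values
    # %.17g guarantees exact float64 round-trips
    pd.DataFrame(cols).to_csv(
        path, index=False, lineterminator="\n", float_format="%.17g"
    )


def read_manifest(path) -> list[ManifestEntry]:
    path = Path(path)
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"file", "participant_id", "group", "dance", "recording_id"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: manifest missing columns {sorted(missing)}")
    entries = [
        ManifestEntry(
            file=row["file"],
            participant_id=row["participant_id"],
            group=row["group"],
            dance=row["dance"],
            recording_id=row["recording_id"],
            note=row.get("note", ""),
        )
        for row in df.to_dict("records")
    ]
    keys = [(e.participant_id, e.recording_id) for e in entries]
    if len(set(keys)) != len(keys):
        dup = sorted({k for k in keys if keys.count(k) > 1})
        raise FormatError(f"{path}: duplicate (participant_id, recording_id): {dup}")
    rec_ids = [e.recording_id for e in entries]
    if len(set(rec_ids)) != len(rec_ids):
        dup = sorted({r for r in rec_ids if rec_ids.count(r) > 1})
        raise FormatError(f"{path}: duplicate recording_id: {dup}")
    return entries


@dataclass
class CohortLoadResult:
    recordings: list[Recording]
    exclusions: list[tuple[ManifestEntry, str]]


def load_cohort(manifest_path) -> CohortLoadResult:
    """Load every manifest entry; exclude (and report) entries that fail.

    Mirrors study practice: an invalid recording is dropped with a reason, the
    rest of the cohort is analyzed.  Zero loadable recordings is fatal.
    """
    manifest_path = Path(manifest_path)
    entries = read_manifest(manifest_path)
    base = manifest_path.parent
    recordings: list[Recording] = []
    exclusions: list[tuple[ManifestEntry, str]] = []
    for entry in entries:
        fpath = Path(entry.file)
        if not fpath.is_absolute():
            fpath = base / fpath
        try:
            recordings.append(read_recording_csv(fpath, entry))
        except (FormatError, ValueError, OSError) as exc:
            log.warning("excluding recording %s: %s", entry.recording_id, exc)
            exclusions.append((entry, str(exc)))
    if not recordings:
        raise CohortError(
            f"{manifest_path}: no loadable recordings "
            f"({len(exclusions)} excluded)"
        )
    return CohortLoadResult(recordings=recordings, exclusions=exclusions)
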