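"""Read/write Kinect-v2 skeleton recordings and subject tables.

A recording is one CSV per subject in camera space (X lateral, Y vertical,
Z distance from the camera, meters): columns ``t``, then ``<Joint>_x``,
``<Joint>_y``, ``<Joint>_z`` for each of the 25 Kinect-v2 joints, then
``valid`` and ``facing_front``.  ``facing_front`` is tri-state: ``true``,
``false`` or empty (unknown, e.g. while turning); the column as a whole may
be absent, in which case facing is inferred downstream from SpineBase
motion.  Frames whose coordinate cells fail to parse are kept but marked
invalid so that one corrupt row degrades, not aborts, a recording.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .subjects import GAD7_MAX, GENDERS, ITEM_COLUMNS, SUBJECT_COLUMNS, SubjectRecord

logger = logging.getLogger(__name__)

#: Kinect-v2 joint names in SDK order.
JOINT_NAMES: tuple[str, ...] = (
    "SpineBase", "SpineMid", "Neck", "Head",
    "ShoulderLeft", "ElbowLeft", "WristLeft", "HandLeft",
    "ShoulderRight", "ElbowRight", "WristRight", "HandRight",
    "HipLeft", "KneeLeft", "AnkleLeft", "FootLeft",
    "HipRight", "KneeRight", "AnkleRight", "FootRight",
    "SpineShoulder", "HandTipLeft", "ThumbLeft", "HandTipRight", "ThumbRight",
)
N_JOINTS = len(JOINT_NAMES)
AXES = ("x", "y", "z")

# facing codes used in the in-memory array representation
FACING_FRONT = np.int8(1)
FACING_BACK = np.int8(0)
FACING_UNKNOWN = np.int8(-1)


class FormatError(ValueError):
    """A recording or subject file does not conform to the expected layout."""


@dataclass(frozen=True)
class SkeletonFrame:
    """One time point: 25 named joints in meters, plus validity and facing."""

    timestamp_s: float
    joints: dict[str, tuple[float, float, float]]
    valid: bool = True
    facing_front: Optional[bool] = None

    def __post_init__(self) -> None:
        if set(self.joints) != set(JOINT_NAMES) and len(self.joints) != 24:
            raise ValueError(
                f"expected the 25 Kinect joints (or 24 after re-centering), "
                f"got {len(self.joints)}"
            )
        if self.valid:
            coords = np.array(list(self.joints.values()), dtype=float)
            if not np.all(np.isfinite(coords)):
                raise ValueError("valid frame contains non-finite coordinates")


@dataclass
class GaitRecording:
    """Ordered skeleton frames at a fixed sampling rate for one subject.

    Frames are stored columnar for speed: ``positions`` has shape
    ``(n_frames, n_joints, 3)``.  ``facing`` is ``None`` when the file
    carried no facing annotation, else an int8 array with 1=front, 0=back,
    -1=unknown.
    """

    subject_id: str
    fs_hz: float
    positions: np.ndarray
    valid: np.ndarray
    facing: Optional[np.ndarray] = None
    joint_names: tuple[str, ...] = JOINT_NAMES
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.fs_hz <= 0:
            raise ValueError(f"fs_hz must be positive, got {self.fs_hz}")
        n = self.positions.shape[0]
        if self.positions.ndim != 3 or self.positions.shape[1:] != (
            len(self.joint_names),
            3,
        ):
            raise ValueError(
                f"positions must have shape (n, {len(self.joint_names)}, 3), "
                f"got {self.positions.shape}"
            )
        if self.valid.shape != (n,):
            raise ValueError("valid must have one flag per frame")
        if self.facing is not None:
            self.facing = np.asarray(self.facing, dtype=np.int8)
            if self.facing.shape != (n,):
                raise ValueError("facing must have one code per frame")
        bad = self.valid & ~np.isfinite(self.positions).all(axis=(1, 2))
        if np.any(bad):
            raise ValueError(
                f"{bad.sum()} frames marked valid contain non-finite coordinates"
            )

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fs_hz

    @property
    def timestamps(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.n_frames) / self.fs_hz

    def frame(self, i: int) -> SkeletonFrame:
        facing: Optional[bool]
        if self.facing is None or self.facing[i] == FACING_UNKNOWN:
            facing = None
        else:
            facing = bool(self.facing[i] == FACING_FRONT)
        return SkeletonFrame(
            timestamp_s=float(self.timestamps[i]),
            joints={
                name: tuple(self.positions[i, j])
                for j, name in enumerate(self.joint_names)
            },
            valid=bool(self.valid[i]),
            facing_front=facing,
        )


def _coordinate_columns(joint_names: Sequence[str]) -> list[str]:
    return [f"{j}_{a}" for j in joint_names for a in AXES]


def _parse_floats(values: np.ndarray) -> np.ndarray:
    """Correctly-rounded float parsing; unparseable cells become NaN."""
    try:
        return values.astype(np.float64)
    except (ValueError, TypeError):
        out = np.full(values.shape, np.nan)
        flat_in, flat_out = values.ravel(), out.ravel()
        for i, v in enumerate(flat_in):
            try:
                flat_out[i] = float(v)
            except (ValueError, TypeError):
                pass
        return out


def write_recording(recording: GaitRecording, path: str | Path) -> None:
    """Write a recording as CSV; byte-deterministic for identical input."""
    path = Path(path)
    cols = _coordinate_columns(recording.joint_names)
    n = recording.n_frames
    flat = recording.positions.reshape(n, -1) if n else np.empty((0, len(cols)))
    frame = pd.DataFrame(flat, columns=cols)
    frame.insert(0, "t", recording.timestamps)
    frame["valid"] = np.where(recording.valid, "true", "false")
    if recording.facing is not None:
        facing = np.full(n, "", dtype=object)
        facing[recording.facing == FACING_FRONT] = "true"
        facing[recording.facing == FACING_BACK] = "false"
        frame["facing_front"] = facing
    # %.17g guarantees exact float64 round-trip through text
    frame.to_csv(path, index=False, lineterminator="\n", float_format="%.17g")


def read_recording(
    path: str | Path,
    subject_id: Optional[str] = None,
    joint_names: tuple[str, ...] = JOINT_NAMES,
) -> GaitRecording:
    """Parse a recording CSV.

    Malformed coordinate cells mark the affected frame invalid instead of
    aborting.  Missing or extra joint columns, a missing ``t``/``valid``
    column, or an empty file raise :class:`FormatError`.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty recording file") from exc

    expected = set(_coordinate_columns(joint_names)) | {"t", "valid"}
    present = set(raw.columns)
    missing = expected - present
    extra = present - expected - {"facing_front"}
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)[:5]}")
    if extra:
        raise FormatError(f"{path}: unexpected columns {sorted(extra)[:5]}")

    cols = _coordinate_columns(joint_names)
    n = len(raw)
    coords = _parse_floats(raw[cols].to_numpy(dtype=object))
    positions = coords.reshape(n, len(joint_names), 3)
    parse_ok = np.isfinite(positions).all(axis=(1, 2))
    valid = raw["valid"].str.strip().str.lower().eq("true").to_numpy() & parse_ok
    n_degraded = int((~parse_ok).sum())
    if n_degraded:
        logger.warning("%s: %d frames with unparseable coordinates marked invalid",
                       path.name, n_degraded)

    t = _parse_floats(raw["t"].to_numpy(dtype=object))
    if n == 0:
        raise FormatError(f"{path}: recording has no frames")
    if n > 1:
        dt = np.diff(t)
        if np.any(~np.isfinite(dt)) or np.any(dt <= 0):
            raise FormatError(f"{path}: timestamps must be strictly increasing")
        fs = 1.0 / float(np.median(dt))
    else:
        fs = 30.0

    facing = None
    if "facing_front" in raw.columns:
        s = raw["facing_front"].str.strip().str.lower()
        facing = np.full(n, FACING_UNKNOWN, dtype=np.int8)
        facing[s == "true"] = FACING_FRONT
        facing[s == "false"] = FACING_BACK

    return GaitRecording(
        subject_id=subject_id or path.stem,
        fs_hz=fs,
        positions=positions,
        valid=valid,
        facing=facing,
        joint_names=joint_names,
        start_time_s=float(t[0]),
    )


def write_subjects(subjects: Sequence[SubjectRecord], path: str | Path) -> None:
    from .subjects import subjects_to_frame

    subjects_to_frame(subjects).to_csv(path, index=False, lineterminator="\n", na_rep="")


def read_subjects(path: str | Path) -> list[SubjectRecord]:
    """Read the subject table, range-validating scores.

    Rows with an out-of-range GAD-7 score (or unparseable core fields) are
    dropped with a logged count.  Rows whose PHQ-9 items are incomplete,
    out of range, or inconsistent with the stated total keep their GAD-7
    data but carry no PHQ-9 data (a per-row warning names the row).
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty subject file") from exc
    missing = set(SUBJECT_COLUMNS) - set(raw.columns)
    if missing:
        raise FormatError(f"{path}: missing subject columns {sorted(missing)}")

    records: list[SubjectRecord] = []
    n_dropped = 0
    for idx, row in raw.iterrows():
        try:
            gad7 = int(row["gad7"])
            if not 0 <= gad7 <= GAD7_MAX:
                raise ValueError(f"gad7={gad7} outside [0, {GAD7_MAX}]")
            gender = str(row["gender"]).strip().lower()
            if gender not in GENDERS:
                raise ValueError(f"unknown gender {row['gender']!r}")
            age = float(row["age"])
        except (ValueError, TypeError) as exc:
            logger.warning("%s row %s: dropped (%s)", path.name, idx, exc)
            n_dropped += 1
            continue

        phq9_total: Optional[int] = None
        phq9_items: Optional[tuple[int, ...]] = None
        item_values = row[list(ITEM_COLUMNS)]
        if not item_values.isna().any() and not pd.isna(row["phq9"]):
            try:
                items = tuple(int(v) for v in item_values)
                total = int(row["phq9"])
                if any(not 0 <= v <= 3 for v in items):
                    raise ValueError(f"item scores outside 0..3: {items}")
                if total != sum(items):
                    raise ValueError(
                        f"phq9={total} != sum of items ({sum(items)})"
                    )
                phq9_total, phq9_items = total, items
            except (ValueError, TypeError) as exc:
                logger.warning(
                    "%s row %s (%s): PHQ-9 data discarded (%s)",
                    path.name, idx, row["subject_id"], exc,
                )
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                gender=gender,
                age=age,
                gad7_total=gad7,
                phq9_total=phq9_total,
                phq9_items=phq9_items,
            )
        )
    if n_dropped:
        logger.warning("%s: dropped %d invalid rows", path.name, n_dropped)
    return records
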