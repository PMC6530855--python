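"""Skeleton preprocessing: smoothing, re-centering and segment selection.

The stages mirror the standard Kinect-gait recipe.  Each joint-axis time
series is denoised by a width-5 sliding-window Gaussian filter with kernel
[1, 4, 6, 4, 1]/16, written causally so the output is 4 samples shorter
than the input:

    Out[i] = (In[i] + 4 In[i+1] + 6 In[i+2] + 4 In[i+3] + In[i+4]) / 16.

Every frame is then re-expressed with the SpineBase joint as origin (and
SpineBase dropped, leaving 24 joints), removing the walker's absolute
position relative to the camera.  Finally only runs of frames in which the
walker faces the camera are kept, each run is tiled into non-overlapping
64-frame windows (~2.1 s at 30 Hz, a power of two so the FFT applies
directly and long enough to cover a gait cycle), and one window per subject
is drawn uniformly at random.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, TypeVar, Union

import numpy as np

from .kinect_io import (
    FACING_BACK,
    FACING_FRONT,
    FACING_UNKNOWN,
    JOINT_NAMES,
    GaitRecording,
    SkeletonFrame,
)

logger = logging.getLogger(__name__)

GAUSSIAN_KERNEL = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0
KERNEL_SIZE = 5
SEGMENT_LENGTH = 64
#: facing-heuristic runs shorter than this are treated as turning
MIN_RUN_FRAMES = 15

#: the 24 joints retained after re-centering (SpineBase becomes the origin)
RETAINED_JOINTS: tuple[str, ...] = tuple(j for j in JOINT_NAMES if j != "SpineBase")
_SPINE_BASE = JOINT_NAMES.index("SpineBase")


class SubjectExcluded(RuntimeError):
    """No usable 64-frame front-facing segment exists for this subject."""


@dataclass(frozen=True)
class Segment:
    """A 64-frame re-centered front-facing window over 24 joints."""

    subject_id: str
    start_frame: int
    positions: np.ndarray  # (64, 24, 3)
    fs_hz: float = 30.0
    joint_names: tuple[str, ...] = RETAINED_JOINTS

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (SEGMENT_LENGTH, len(self.joint_names), 3):
            raise ValueError(
                f"segment must be {SEGMENT_LENGTH} x {len(self.joint_names)} x 3, "
                f"got {pos.shape}"
            )
        if not np.all(np.isfinite(pos)):
            raise ValueError("segment contains non-finite coordinates")
        object.__setattr__(self, "positions", pos)


def gaussian_filter(series: np.ndarray) -> np.ndarray:
    """Width-5 Gaussian smoothing along the first axis; output 4 shorter."""
    arr = np.asarray(series, dtype=float)
    n = arr.shape[0]
    if n < KERNEL_SIZE:
        raise ValueError(f"series must have at least {KERNEL_SIZE} samples, got {n}")
    out = (
        arr[0 : n - 4]
        + 4.0 * arr[1 : n - 3]
        + 6.0 * arr[2 : n - 2]
        + 4.0 * arr[3 : n - 1]
        + arr[4:n]
    ) / 16.0
    return out


def filter_recording(recording: GaitRecording) -> GaitRecording:
    """Apply the Gaussian filter to every joint-axis series of a recording.

    The output has 4 fewer frames.  An output frame is valid only if all
    five input frames under its window are valid (a smoothed value mixing
    in turning-frame coordinates is itself unusable); its facing flag is
    taken from the window's center frame.
    """
    n = recording.n_frames
    if n < KERNEL_SIZE:
        raise ValueError(f"recording must have at least {KERNEL_SIZE} frames")
    positions = gaussian_filter(recording.positions)
    v = recording.valid
    valid = v[0 : n - 4] & v[1 : n - 3] & v[2 : n - 2] & v[3 : n - 1] & v[4:n]
    facing = None if recording.facing is None else recording.facing[2 : n - 2]
    return GaitRecording(
        subject_id=recording.subject_id,
        fs_hz=recording.fs_hz,
        positions=positions,
        valid=valid,
        facing=facing,
        joint_names=recording.joint_names,
        start_time_s=recording.start_time_s + 2.0 / recording.fs_hz,
    )


def recenter(frame: SkeletonFrame) -> SkeletonFrame:
    """Re-express one frame with SpineBase as origin; 24 joints remain."""
    if not frame.valid:
        return SkeletonFrame(
            timestamp_s=frame.timestamp_s,
            joints={j: frame.joints[j] for j in RETAINED_JOINTS},
            valid=False,
            facing_front=frame.facing_front,
        )
    origin = np.asarray(frame.joints["SpineBase"], dtype=float)
    joints = {
        name: tuple(np.asarray(frame.joints[name], dtype=float) - origin)
        for name in RETAINED_JOINTS
    }
    return SkeletonFrame(
        timestamp_s=frame.timestamp_s,
        joints=joints,
        valid=frame.valid,
        facing_front=frame.facing_front,
    )


def recenter_recording(recording: GaitRecording) -> GaitRecording:
    """Vectorized re-centering of a whole recording (SpineBase dropped)."""
    if recording.joint_names != JOINT_NAMES:
        raise ValueError("recording must carry the full 25-joint skeleton")
    origin = recording.positions[:, _SPINE_BASE : _SPINE_BASE + 1, :]
    keep = [i for i in range(len(JOINT_NAMES)) if i != _SPINE_BASE]
    positions = recording.positions[:, keep, :] - origin
    # invalid frames may hold NaNs from degraded parsing; keep them NaN-free
    positions = np.where(np.isfinite(positions), positions, 0.0)
    return GaitRecording(
        subject_id=recording.subject_id,
        fs_hz=recording.fs_hz,
        positions=positions,
        valid=recording.valid.copy(),
        facing=None if recording.facing is None else recording.facing.copy(),
        joint_names=RETAINED_JOINTS,
        start_time_s=recording.start_time_s,
    )


def infer_facing(recording: GaitRecording) -> np.ndarray:
    """Heuristic facing annotation from SpineBase motion.

    The walker is taken to face the camera while the smoothed SpineBase Z
    coordinate decreases (approaching).  Runs shorter than
    ``MIN_RUN_FRAMES`` are relabelled unknown ("turning"), since direction
    flips that brief reflect the turn, not a traversal.
    """
    if recording.joint_names != JOINT_NAMES:
        raise ValueError("facing inference needs the raw 25-joint recording")
    z = recording.positions[:, _SPINE_BASE, 2]
    n = z.shape[0]
    if n < KERNEL_SIZE + 1:
        return np.full(n, FACING_UNKNOWN, dtype=np.int8)
    z_smooth = np.convolve(z, GAUSSIAN_KERNEL, mode="same")
    vz = np.gradient(z_smooth)
    facing = np.where(vz < 0, FACING_FRONT, FACING_BACK).astype(np.int8)
    # demote short runs to turning
    change = np.flatnonzero(np.diff(facing)) + 1
    bounds = np.concatenate(([0], change, [n]))
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a < MIN_RUN_FRAMES:
            facing[a:b] = FACING_UNKNOWN
    return facing


def split_front_segments(recording: GaitRecording) -> list[tuple[int, int]]:
    """Maximal runs [start, stop) of valid, front-facing frames.

    Uses the recording's facing annotation when present, otherwise the
    SpineBase-velocity heuristic of :func:`infer_facing`.
    """
    if recording.n_frames == 0:
        raise ValueError("recording is empty")
    if recording.facing is not None:
        facing = recording.facing
    else:
        facing = infer_facing(recording)
    mask = recording.valid & (facing == FACING_FRONT)
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[0::2], edges[1::2]
    return list(zip(starts.tolist(), stops.tolist()))


def extract_candidate_segments(
    ranges: Sequence[tuple[int, int]], min_len: int = SEGMENT_LENGTH
) -> list[int]:
    """Start indices of non-overlapping ``min_len``-frame windows tiled
    from the start of each range; ranges shorter than ``min_len`` yield none."""
    starts: list[int] = []
    for a, b in ranges:
        starts.extend(range(a, b - min_len + 1, min_len))
    return starts


_T = TypeVar("_T")


def select_segment(candidates: Sequence[_T], rng_seed: Union[int, np.random.Generator]) -> _T:
    """Uniform, seed-reproducible choice of one candidate."""
    if len(candidates) == 0:
        raise SubjectExcluded("no usable 64-frame front-facing segment")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    return candidates[int(rng.integers(len(candidates)))]


def preprocess_recording(
    recording: GaitRecording,
    rng_seed: Union[int, np.random.Generator],
    use_facing_metadata: bool = True,
) -> Optional[Segment]:
    """Full preprocessing of one recording down to a single Segment.

    Denoise -> re-center -> split into front runs -> tile 64-frame windows
    -> pick one at random.  Returns ``None`` (with a log message) when the
    subject has no candidate window and must be excluded.
    """
    filtered = filter_recording(recording)
    if not use_facing_metadata:
        # infer facing on the filtered 25-joint recording, pre-re-centering
        filtered = GaitRecording(
            subject_id=filtered.subject_id,
            fs_hz=filtered.fs_hz,
            positions=filtered.positions,
            valid=filtered.valid,
            facing=None,
            joint_names=filtered.joint_names,
            start_time_s=filtered.start_time_s,
        )
    ranges = split_front_segments(filtered)
    candidates = extract_candidate_segments(ranges)
    if not candidates:
        logger.info("subject %s excluded: no candidate segment", recording.subject_id)
        return None
    start = select_segment(candidates, rng_seed)
    recentered = recenter_recording(filtered)
    return Segment(
        subject_id=recording.subject_id,
        start_frame=start,
        positions=recentered.positions[start : start + SEGMENT_LENGTH],
        fs_hz=recording.fs_hz,
    )
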