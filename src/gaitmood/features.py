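"""FFT amplitude features, z-scoring and correlation-based selection.

For each of the 24 retained joints and each axis (X, Y, Z), the 64-frame
segment series x_n is transformed by the discrete Fourier transform

    X_k = sum_{n=0}^{N-1} x_n exp(-i 2 pi k n / N),   k = 0..N-1,  N = 64,

and all 64 moduli |X_k| are kept as features, giving 24 x 3 x 64 = 4608
columns per subject.  Columns are z-scored across subjects, then, per
(joint, axis) group, the 5 columns whose Pearson correlation with the
target score has the largest absolute value are retained:
5 x 3 x 24 = 360 selected features.

Selecting on the full sample before cross-validation leaks target
information into the evaluation; the modeling layer therefore exposes both
this "as-published" order and a nested variant that re-runs the selection
inside every training fold (see :func:`make_selector`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import RETAINED_JOINTS, SEGMENT_LENGTH, Segment

AXES = ("X", "Y", "Z")
N_FREQS = SEGMENT_LENGTH
N_RAW_FEATURES = len(RETAINED_JOINTS) * len(AXES) * N_FREQS  # 4608
TOP_K_PER_GROUP = 5


@dataclass(frozen=True)
class FeatureLabel:
    """Identifies one feature column: joint, axis and frequency index."""

    joint: str
    axis: str
    freq_index: int

    def __post_init__(self) -> None:
        if self.joint not in RETAINED_JOINTS:
            raise ValueError(f"unknown joint {self.joint!r}")
        if self.axis not in AXES:
            raise ValueError(f"axis must be one of {AXES}")
        if not 0 <= self.freq_index < N_FREQS:
            raise ValueError(f"freq_index must lie in 0..{N_FREQS - 1}")


@dataclass
class FeatureMatrix:
    """Subjects x features table with (joint, axis, freq) column labels."""

    data: pd.DataFrame  # MultiIndex columns (joint, axis, freq_index)
    normalized: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.data.columns, pd.MultiIndex) or self.data.columns.nlevels != 3:
            raise ValueError("columns must be a (joint, axis, freq_index) MultiIndex")
        if self.data.isna().any().any():
            raise ValueError("feature matrix contains missing values")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def labels(self) -> list[FeatureLabel]:
        return [FeatureLabel(j, a, int(k)) for j, a, k in self.data.columns]

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def loc_subjects(self, subject_ids: Sequence[str]) -> "FeatureMatrix":
        return FeatureMatrix(self.data.loc[list(subject_ids)], normalized=self.normalized)


def fft_amplitudes(series: Sequence[float]) -> np.ndarray:
    """The 64 DFT amplitudes |X_k| of a 64-sample series (no 1/N scaling)."""
    arr = np.asarray(series, dtype=float)
    if arr.shape != (SEGMENT_LENGTH,):
        raise ValueError(f"series must have exactly {SEGMENT_LENGTH} samples, got {arr.shape}")
    return np.abs(np.fft.fft(arr))


def _column_index() -> pd.MultiIndex:
    return pd.MultiIndex.from_product(
        [RETAINED_JOINTS, AXES, range(N_FREQS)], names=["joint", "axis", "freq_index"]
    )


def segment_amplitudes(segment: Segment) -> np.ndarray:
    """All 4608 amplitudes of one segment, in (joint, axis, freq) order."""
    if segment.joint_names != RETAINED_JOINTS:
        raise ValueError("segment joints do not match the retained joint set")
    amps = np.abs(np.fft.fft(segment.positions, axis=0))  # (64, 24, 3)
    return amps.transpose(1, 2, 0).reshape(-1)


def build_feature_matrix(segments: Mapping[str, Segment]) -> FeatureMatrix:
    """One row of 4608 raw FFT amplitudes per subject."""
    if not segments:
        raise ValueError("no segments supplied")
    rows = {sid: segment_amplitudes(seg) for sid, seg in segments.items()}
    data = pd.DataFrame.from_dict(rows, orient="index", columns=_column_index())
    data.index.name = "subject_id"
    return FeatureMatrix(data, normalized=False)


def zscore(matrix: FeatureMatrix) -> FeatureMatrix:
    """Standardize each column to mean 0, population SD 1 across subjects.

    Zero-variance columns become all-zero rather than NaN.  The population
    (divide-by-n) convention is used; downstream Pearson correlations are
    invariant to this choice.
    """
    if matrix.normalized:
        raise ValueError("matrix is already normalized")
    if matrix.n_subjects < 2:
        raise ValueError("z-scoring needs at least 2 subjects")
    values = matrix.values
    mean = values.mean(axis=0)
    sd = values.std(axis=0)  # population convention
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - mean) / sd
    z[:, sd == 0] = 0.0
    return FeatureMatrix(
        pd.DataFrame(z, index=matrix.data.index, columns=matrix.data.columns),
        normalized=True,
    )


def pearson_with_target(values: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Pearson r of every column against the target; zero-variance -> 0."""
    y = np.asarray(target, dtype=float)
    yc = y - y.mean()
    sy = np.sqrt((yc**2).sum())
    if sy == 0:
        raise ValueError("target has zero variance")
    xc = values - values.mean(axis=0)
    sx = np.sqrt((xc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc.T @ yc) / (sx * sy)
    r[sx == 0] = 0.0
    return r


def _rank_within_groups(columns: pd.MultiIndex, r: np.ndarray, top_k: int) -> np.ndarray:
    """Column indices of the top-k |r| per (joint, axis) group.

    Ties at the k-th rank break toward the lower frequency index, which the
    lexsort below guarantees because freq_index ascends within each group.
    """
    joints = columns.get_level_values("joint")
    axes = columns.get_level_values("axis")
    keep: list[int] = []
    for joint in RETAINED_JOINTS:
        for axis in AXES:
            idx = np.flatnonzero((joints == joint) & (axes == axis))
            order = idx[np.lexsort((idx, -np.abs(r[idx])))]
            keep.extend(order[:top_k].tolist())
    return np.array(keep)


def select_features(
    matrix: FeatureMatrix, target: Sequence[float], top_k: int = TOP_K_PER_GROUP
) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Keep the ``top_k`` columns by |Pearson r| within each (joint, axis).

    Returns the reduced matrix (5 x 3 x 24 = 360 columns at the default
    ``top_k``) and a report table of (joint, axis, freq_index, r, rank).
    """
    if not matrix.normalized:
        raise ValueError("select_features expects a z-scored matrix")
    y = np.asarray(target, dtype=float)
    if y.shape != (matrix.n_subjects,):
        raise ValueError("target length must equal the number of subjects")
    r = pearson_with_target(matrix.values, y)
    keep = _rank_within_groups(matrix.data.columns, r, top_k)
    selected = FeatureMatrix(matrix.data.iloc[:, keep], normalized=matrix.normalized)
    cols = matrix.data.columns[keep]
    report = pd.DataFrame(
        {
            "joint": cols.get_level_values("joint"),
            "axis": cols.get_level_values("axis"),
            "freq_index": cols.get_level_values("freq_index"),
            "r": r[keep],
        }
    )
    report["rank"] = report.groupby(["joint", "axis"], sort=False).cumcount() + 1
    return selected, report


def make_selector(top_k: int = TOP_K_PER_GROUP) -> Callable[[np.ndarray, pd.MultiIndex, np.ndarray], np.ndarray]:
    """A (values, columns, target) -> column-indices callable for use
    inside cross-validation folds (nested selection)."""

    def _select(values: np.ndarray, columns: pd.MultiIndex, target: np.ndarray) -> np.ndarray:
        r = pearson_with_target(values, np.asarray(target, dtype=float))
        return _rank_within_groups(columns, r, top_k)

    return _select
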