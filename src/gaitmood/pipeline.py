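"""End-to-end orchestration: simulate -> validate -> preprocess -> features
-> evaluate, driven by one serializable configuration.

Every stage writes plain-text artifacts that the producing module can read
back, and a final ``manifest.json`` records the resolved configuration and
a SHA-256 checksum of every emitted file, so a run is bit-reproducible
given its seed and auditable from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import features as features_mod
from . import kinect_io, modeling, preprocess, synthetic_cohort
from .features import FeatureMatrix
from .kinect_io import GaitRecording
from .preprocess import RETAINED_JOINTS, SEGMENT_LENGTH, Segment
from .subjects import SubjectRecord, subjects_to_frame

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one study run."""

    seed: int = 0
    n_subjects: int = 60
    effect_size: Union[str, float] = "strong"
    duration_s: float = 120.0
    fs_hz: float = 30.0
    use_facing_metadata: bool = True
    nested_selection: bool = False
    n_folds: int = 10
    regression_models: tuple[str, ...] = modeling.REGRESSION_MODELS
    classification_models: tuple[str, ...] = modeling.CLASSIFICATION_MODELS
    strata: tuple[str, ...] = modeling.STRATA
    out_dir: str = "gaitmood_run"

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("regression_models", "classification_models", "strata"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("regression_models", "classification_models", "strata"):
            d[key] = list(d[key])
        return d


def _seed_for(config_seed: int, stage: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=config_seed, spawn_key=(stage,))


# ---------------------------------------------------------------------------
# in-memory pipeline (no disk round-trip); used by the evaluation scripts


def build_cohort_features(
    model: synthetic_cohort.EffectModel,
    n: int,
    rng_seed: int,
    duration_s: float = 120.0,
    fs_hz: float = 30.0,
    use_facing_metadata: bool = True,
) -> tuple[pd.DataFrame, FeatureMatrix, list[str]]:
    """Simulate a cohort and take it straight to the raw feature matrix.

    Recordings are processed one at a time and discarded, so memory stays
    at one recording regardless of cohort size.  Returns the subject
    table, the z-scored 4608-column matrix, and any excluded subject ids.
    """
    cohort_rng = np.random.default_rng(_seed_for(rng_seed, 1))
    segment_rng = np.random.default_rng(_seed_for(rng_seed, 2))
    subjects: list[SubjectRecord] = []
    segments: dict[str, Segment] = {}
    excluded: list[str] = []
    for record, recording in synthetic_cohort.iter_cohort(
        n, model, cohort_rng, duration_s=duration_s, fs_hz=fs_hz
    ):
        seg = preprocess.preprocess_recording(
            recording, segment_rng, use_facing_metadata=use_facing_metadata
        )
        if seg is None:
            excluded.append(record.subject_id)
            continue
        subjects.append(record)
        segments[record.subject_id] = seg
    subject_table = subjects_to_frame(subjects)
    raw = features_mod.build_feature_matrix(segments)
    return subject_table, features_mod.zscore(raw), excluded


# ---------------------------------------------------------------------------
# file-driven stages


def _write_segment(segment: Segment, path: Path) -> None:
    rec = GaitRecording(
        subject_id=segment.subject_id,
        fs_hz=segment.fs_hz,
        positions=segment.positions,
        valid=np.ones(SEGMENT_LENGTH, dtype=bool),
        facing=np.full(SEGMENT_LENGTH, kinect_io.FACING_FRONT, dtype=np.int8),
        joint_names=segment.joint_names,
        start_time_s=segment.start_frame / segment.fs_hz,
    )
    kinect_io.write_recording(rec, path)


def read_segment(path: Union[str, Path]) -> Segment:
    rec = kinect_io.read_recording(path, joint_names=RETAINED_JOINTS)
    return Segment(
        subject_id=rec.subject_id,
        start_frame=int(round(rec.start_time_s * rec.fs_hz)),
        positions=rec.positions,
        fs_hz=rec.fs_hz,
    )


def read_segments_dir(path: Union[str, Path]) -> dict[str, Segment]:
    segments = {}
    for f in sorted(Path(path).glob("*.csv")):
        seg = read_segment(f)
        segments[seg.subject_id] = seg
    return segments


def simulate_stage(config: RunConfig, out_dir: Path) -> list[Path]:
    model = synthetic_cohort.effect_model(config.effect_size)
    rec_dir = out_dir / "recordings"
    rec_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(_seed_for(config.seed, 1))
    written = []
    subjects = []
    for record, recording in synthetic_cohort.iter_cohort(
        config.n_subjects, model, rng,
        duration_s=config.duration_s, fs_hz=config.fs_hz,
    ):
        path = rec_dir / f"{record.subject_id}.csv"
        kinect_io.write_recording(recording, path)
        written.append(path)
        subjects.append(record)
    subjects_path = out_dir / "subjects.csv"
    kinect_io.write_subjects(subjects, subjects_path)
    written.append(subjects_path)
    logger.info("simulate: wrote %d recordings", len(subjects))
    return written


def validate_stage(out_dir: Path) -> None:
    """Re-read every artifact of the simulate stage, raising on defects."""
    subjects = kinect_io.read_subjects(out_dir / "subjects.csv")
    paths = sorted((out_dir / "recordings").glob("*.csv"))
    if len(paths) != len(subjects):
        raise kinect_io.FormatError(
            f"{len(subjects)} subjects but {len(paths)} recordings"
        )
    for path in paths:
        kinect_io.read_recording(path)
    logger.info("validate: %d recordings OK", len(paths))


def preprocess_stage(config: RunConfig, out_dir: Path) -> list[Path]:
    seg_dir = out_dir / "segments"
    seg_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(_seed_for(config.seed, 2))
    written = []
    excluded: list[str] = []
    for path in sorted((out_dir / "recordings").glob("*.csv")):
        recording = kinect_io.read_recording(path)
        seg = preprocess.preprocess_recording(
            recording, rng, use_facing_metadata=config.use_facing_metadata
        )
        if seg is None:
            excluded.append(recording.subject_id)
            continue
        seg_path = seg_dir / f"{seg.subject_id}.csv"
        _write_segment(seg, seg_path)
        written.append(seg_path)
    excl_path = out_dir / "excluded_subjects.txt"
    excl_path.write_text("".join(f"{sid}\n" for sid in excluded))
    written.append(excl_path)
    logger.info("preprocess: %d segments, %d excluded", len(written) - 1, len(excluded))
    return written


def _flat_columns(index: pd.MultiIndex) -> list[str]:
    return [f"{j}_{a}_{k}" for j, a, k in index]


def features_stage(config: RunConfig, out_dir: Path) -> list[Path]:
    """Paper-order full-sample selection per target, written as CSV."""
    feat_dir = out_dir / "features"
    feat_dir.mkdir(parents=True, exist_ok=True)
    segments = read_segments_dir(out_dir / "segments")
    subjects = subjects_to_frame(kinect_io.read_subjects(out_dir / "subjects.csv"))
    subjects = subjects.set_index("subject_id").loc[list(segments)]
    raw = features_mod.zscore(features_mod.build_feature_matrix(segments))
    written = []
    for target in ("gad7", "phq9"):
        scores = pd.to_numeric(subjects[target], errors="coerce")
        mask = scores.notna().to_numpy()
        fm = FeatureMatrix(raw.data.loc[mask], normalized=True)
        selected, report = features_mod.select_features(fm, scores[mask].to_numpy(float))
        table = selected.data.copy()
        table.columns = _flat_columns(selected.data.columns)
        table.insert(0, target, scores[mask].astype(int).to_numpy())
        p_feat = feat_dir / f"features_{target}.csv"
        p_rep = feat_dir / f"selection_{target}.csv"
        table.to_csv(p_feat, lineterminator="\n")
        report.to_csv(p_rep, index=False, lineterminator="\n")
        written.extend([p_feat, p_rep])
    return written


def evaluate_stage(config: RunConfig, out_dir: Path) -> list[Path]:
    report_dir = out_dir / "report"
    report_dir.mkdir(parents=True, exist_ok=True)
    segments = read_segments_dir(out_dir / "segments")
    subjects = subjects_to_frame(kinect_io.read_subjects(out_dir / "subjects.csv"))
    subjects = subjects[subjects["subject_id"].isin(segments)].reset_index(drop=True)
    raw = features_mod.zscore(features_mod.build_feature_matrix(segments))
    cv = modeling.CVConfig(
        n_folds=config.n_folds,
        rng_seed=int(np.random.default_rng(_seed_for(config.seed, 3)).integers(2**31)),
        nested_selection=config.nested_selection,
    )
    tables = modeling.run_study(
        raw, subjects, cv,
        regression_models=config.regression_models,
        classification_models=config.classification_models,
        strata=config.strata,
    )
    written = []
    for name, table in tables.items():
        path = report_dir / f"{name}.csv"
        table.to_csv(path, index=False, lineterminator="\n", float_format="%.6f")
        written.append(path)
    summary = report_dir / "summary.txt"
    summary.write_text(render_summary(tables))
    written.append(summary)
    return written


def render_summary(tables: dict[str, pd.DataFrame]) -> str:
    lines = []
    reg = tables["regression"]
    if len(reg):
        lines.append("Regression accuracy (Pearson r, pooled out-of-fold predictions)")
        pivot = reg.pivot_table(index=["target", "stratum"], columns="model",
                                values="r", sort=False)
        lines.append(pivot.round(3).to_string())
        lines.append("")
    cls = tables["classification"]
    if len(cls):
        lines.append("Symptom classification (precision / recall / F, symptomatic class)")
        for _, row in cls.iterrows():
            if isinstance(row.get("note"), str) and row["note"]:
                stat = row["note"]
            else:
                stat = f"P={row['precision']:.2f} R={row['recall']:.2f} F={row['f']:.2f}"
            lines.append(f"  {row['item']:<12} {row['stratum']:<7} {row['model']:<15} {stat}")
        lines.append("")
    return "\n".join(lines) + "\n"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig, out_dir: Optional[Union[str, Path]] = None) -> Path:
    """Run every stage and write a manifest; returns the output directory."""
    out = Path(out_dir) if out_dir is not None else Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = (
        ("simulate", lambda: simulate_stage(config, out)),
        ("validate", lambda: validate_stage(out)),
        ("preprocess", lambda: preprocess_stage(config, out)),
        ("features", lambda: features_stage(config, out)),
        ("evaluate", lambda: evaluate_stage(config, out)),
    )
    for name, stage in stages:
        logger.info("stage %s", name)
        try:
            stage()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    files = sorted(
        p for p in out.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "config": config.to_dict(),
        "files": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
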