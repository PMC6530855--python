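"""Synthetic cohorts of mood-modulated walking skeleton recordings.

The generator emulates the study design that motivates this package: each
subject walks back and forth along a straight footpath for two minutes in
front of a depth camera sampling 25 skeleton joints at 30 Hz, and also
answers the GAD-7 anxiety and PHQ-9 depression questionnaires.  A latent
severity score drives both the questionnaire answers and a set of gait
parameters — walking speed, cadence, arm swing, stride amplitude, mean head
height and lateral upper-body sway — through linear slopes with Gaussian
between-subject jitter, mirroring the movement correlates of low mood
reported in the gait literature (slower walk, reduced arm swing, reduced
vertical head movement, larger lateral sway).

The kinematic model is deliberately simple: a rigid 25-joint skeleton
template whose arms and legs swing sinusoidally (arms antiphase to the
ipsilateral leg) as rigid rotations about the shoulder/hip, so bone lengths
are exactly constant in the noise-free limit.  The torso translates along
the walking axis and reverses at the footpath ends; turning stretches are
flagged invalid and facing alternates front/back, giving the preprocessing
stage realistic segmentation structure to chew on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Optional, Union

import numpy as np

from .kinect_io import (
    FACING_BACK,
    FACING_FRONT,
    FACING_UNKNOWN,
    JOINT_NAMES,
    GaitRecording,
)
from .subjects import GAD7_MAX, N_PHQ9_ITEMS, SubjectRecord

__all__ = [
    "GaitParameters",
    "EffectModel",
    "SubjectRecord",
    "effect_model",
    "generate_subject",
    "generate_recording",
    "generate_cohort",
]

SeedLike = Union[int, np.random.Generator]


def _rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# skeleton template: per-joint (x, y, z) offsets from SpineBase, meters,
# for a person facing the camera (x lateral, y up, z toward the camera).
# Head y is overridden by GaitParameters.head_height_m.
_TEMPLATE_OFFSETS: dict[str, tuple[float, float, float]] = {
    "SpineBase": (0.0, 0.0, 0.0),
    "SpineMid": (0.0, 0.26, 0.0),
    "Neck": (0.0, 0.50, 0.0),
    "Head": (0.0, 0.66, 0.0),
    "ShoulderLeft": (-0.18, 0.44, 0.0),
    "ElbowLeft": (-0.20, 0.16, 0.0),
    "WristLeft": (-0.21, -0.09, 0.0),
    "HandLeft": (-0.215, -0.17, 0.0),
    "ShoulderRight": (0.18, 0.44, 0.0),
    "ElbowRight": (0.20, 0.16, 0.0),
    "WristRight": (0.21, -0.09, 0.0),
    "HandRight": (0.215, -0.17, 0.0),
    "HipLeft": (-0.09, -0.05, 0.0),
    "KneeLeft": (-0.10, -0.48, 0.0),
    "AnkleLeft": (-0.10, -0.87, 0.0),
    "FootLeft": (-0.10, -0.94, 0.08),
    "HipRight": (0.09, -0.05, 0.0),
    "KneeRight": (0.10, -0.48, 0.0),
    "AnkleRight": (0.10, -0.87, 0.0),
    "FootRight": (0.10, -0.94, 0.08),
    "SpineShoulder": (0.0, 0.46, 0.0),
    "HandTipLeft": (-0.215, -0.25, 0.0),
    "ThumbLeft": (-0.19, -0.19, 0.03),
    "HandTipRight": (0.215, -0.25, 0.0),
    "ThumbRight": (0.19, -0.19, 0.03),
}

_ARM_JOINTS = {
    "left": ("ElbowLeft", "WristLeft", "HandLeft", "HandTipLeft", "ThumbLeft"),
    "right": ("ElbowRight", "WristRight", "HandRight", "HandTipRight", "ThumbRight"),
}
_LEG_JOINTS = {
    "left": ("KneeLeft", "AnkleLeft", "FootLeft"),
    "right": ("KneeRight", "AnkleRight", "FootRight"),
}
_SHOULDER = {"left": "ShoulderLeft", "right": "ShoulderRight"}
_HIP = {"left": "HipLeft", "right": "HipRight"}

# joints that ride on the upper body: they bob vertically and sway laterally
# relative to the pelvis root
_UPPER_BODY = (
    "SpineMid", "Neck", "Head", "SpineShoulder",
    "ShoulderLeft", "ElbowLeft", "WristLeft", "HandLeft", "HandTipLeft", "ThumbLeft",
    "ShoulderRight", "ElbowRight", "WristRight", "HandRight", "HandTipRight",
    "ThumbRight",
)

_JIDX = {name: i for i, name in enumerate(JOINT_NAMES)}

SPINE_BASE_HEIGHT_M = 0.95  #: pelvis root height above the floor
FOOTPATH_LENGTH_M = 5.0     #: walkable span between the turn points
TURN_DURATION_S = 0.5       #: invalid "turning" stretch at each path end
_Z_NEAR_M = 1.2             #: closest approach to the camera

_ARM_LENGTH_M = math.dist(_TEMPLATE_OFFSETS["ShoulderLeft"], _TEMPLATE_OFFSETS["WristLeft"])
_LEG_LENGTH_M = math.dist(_TEMPLATE_OFFSETS["HipLeft"], _TEMPLATE_OFFSETS["AnkleLeft"])
_BOB_FRACTION = 0.08  #: vertical torso bob amplitude as a fraction of stride amplitude


@dataclass(frozen=True)
class GaitParameters:
    """Kinematic parameters of one subject's simulated walk."""

    cadence_hz: float = 1.85        #: limb oscillation rate, steps per second
    stride_amp_m: float = 0.25      #: ankle swing amplitude
    arm_swing_m: float = 0.12       #: wrist swing amplitude
    head_height_m: float = 0.66     #: mean head offset above SpineBase
    lateral_sway_m: float = 0.025   #: upper-body lateral oscillation amplitude
    walk_speed_mps: float = 1.10    #: forward translation speed
    noise_sd_m: float = 0.005       #: additive per-coordinate Gaussian noise SD

    def __post_init__(self) -> None:
        if not 0.5 < self.cadence_hz < 3.0:
            raise ValueError(f"cadence_hz must lie in (0.5, 3.0): {self.cadence_hz}")
        for name in ("stride_amp_m", "arm_swing_m", "lateral_sway_m", "noise_sd_m"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.walk_speed_mps <= 0:
            raise ValueError("walk_speed_mps must be positive")
        if self.head_height_m <= 0:
            raise ValueError("head_height_m must be positive")


_PARAM_FIELDS = tuple(f.name for f in fields(GaitParameters))

# clip bounds keeping jittered parameters inside GaitParameters invariants
_PARAM_BOUNDS = {
    "cadence_hz": (0.55, 2.95),
    "stride_amp_m": (0.0, 0.6),
    "arm_swing_m": (0.0, 0.5),
    "head_height_m": (0.35, 0.9),
    "lateral_sway_m": (0.0, 0.15),
    "walk_speed_mps": (0.25, 2.5),
    "noise_sd_m": (0.0, 0.05),
}

# severity -> gait slopes at full ("strong") effect, per PHQ-9 point.  Tuned
# so that, with the jitter below and the default severity distribution, the
# severity/cadence and severity/arm-swing correlations land near -0.6.
_STRONG_SLOPES = {
    "cadence_hz": -0.0225,
    "stride_amp_m": -0.004,
    "arm_swing_m": -0.003,
    "head_height_m": -0.004,
    "lateral_sway_m": 0.0015,
    "walk_speed_mps": -0.02,
    "noise_sd_m": 0.0,
}

_DEFAULT_JITTER_SD = {
    "cadence_hz": 0.12,
    "stride_amp_m": 0.022,
    "arm_swing_m": 0.016,
    "head_height_m": 0.021,
    "lateral_sway_m": 0.008,
    "walk_speed_mps": 0.11,
    "noise_sd_m": 0.0,
}

# relative propensity of each PHQ-9 item to be endorsed, most to least:
# anhedonia and low energy are common, suicidality is rare.
_DEFAULT_ITEM_WEIGHTS = (0.88, 0.67, 0.66, 0.82, 0.61, 0.41, 0.70, 0.20, 0.024)


@dataclass(frozen=True)
class EffectModel:
    """How a latent severity score shapes questionnaires and gait.

    Severity is drawn from a right-skewed gamma distribution (most subjects
    in the healthy range, a thin tail of higher scores).  PHQ-9 item scores
    are capped Poisson draws whose rates split the latent severity across
    items by ``item_weights``; the PHQ-9 total is their sum by construction.
    Gait parameters are ``baseline + slope * phq9_total + jitter``, clipped
    to physical bounds.
    """

    baseline: GaitParameters = field(default_factory=GaitParameters)
    slopes: dict[str, float] = field(default_factory=dict)
    jitter_sd: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_JITTER_SD))
    severity_mean: float = 5.0
    severity_shape: float = 1.5
    item_weights: tuple[float, ...] = _DEFAULT_ITEM_WEIGHTS
    gad7_noise_sd: float = 2.0
    p_male: float = 100 / 179
    age_mean: float = 24.2
    age_sd: float = 1.5

    def __post_init__(self) -> None:
        for table in (self.slopes, self.jitter_sd):
            unknown = set(table) - set(_PARAM_FIELDS)
            if unknown:
                raise ValueError(f"unknown gait parameter(s): {sorted(unknown)}")
        if any(sd < 0 for sd in self.jitter_sd.values()):
            raise ValueError("jitter SDs must be non-negative")
        if self.severity_mean <= 0 or self.severity_shape <= 0:
            raise ValueError("severity distribution parameters must be positive")
        if len(self.item_weights) != N_PHQ9_ITEMS or any(w < 0 for w in self.item_weights):
            raise ValueError("item_weights must be nine non-negative values")
        if not 0 <= self.p_male <= 1:
            raise ValueError("p_male must be a probability")

    def parameters_for(
        self, severity: float, rng: Optional[np.random.Generator] = None
    ) -> GaitParameters:
        """Gait parameters at a given severity: baseline + slopes x severity
        (+ jitter when an rng is supplied), clipped to physical bounds."""
        values = {}
        for name in _PARAM_FIELDS:
            v = getattr(self.baseline, name) + self.slopes.get(name, 0.0) * severity
            if rng is not None:
                sd = self.jitter_sd.get(name, 0.0)
                if sd > 0:
                    v += rng.normal(0.0, sd)
            lo, hi = _PARAM_BOUNDS[name]
            values[name] = float(np.clip(v, lo, hi))
        return GaitParameters(**values)


_EFFECT_SCALES = {"none": 0.0, "zero": 0.0, "weak": 0.5, "strong": 1.0}


def effect_model(effect_size: Union[str, float] = "strong", **overrides) -> EffectModel:
    """Build the default effect model at a named or numeric effect scale.

    ``"none"`` (0.0) decouples gait from severity, ``"weak"`` (0.5) and
    ``"strong"`` (1.0) scale the reference slopes; any float works too.
    """
    if isinstance(effect_size, str):
        try:
            scale = _EFFECT_SCALES[effect_size.lower()]
        except KeyError:
            raise ValueError(
                f"effect_size must be one of {sorted(set(_EFFECT_SCALES))} or a number"
            ) from None
    else:
        scale = float(effect_size)
    slopes = {k: v * scale for k, v in _STRONG_SLOPES.items()}
    return EffectModel(slopes=slopes, **overrides)


def generate_subject(
    model: EffectModel, rng_seed: SeedLike
) -> tuple[SubjectRecord, GaitParameters]:
    """Draw one subject: questionnaire scores plus their gait parameters.

    Deterministic for a fixed seed.  The PHQ-9 total always equals the item
    sum, and the realized total (not the latent severity) is what drives the
    gait parameters, so parameter recovery targets an observable quantity.
    """
    rng = _rng(rng_seed)
    latent = rng.gamma(model.severity_shape, model.severity_mean / model.severity_shape)
    weights = np.asarray(model.item_weights, dtype=float)
    weights = weights / weights.sum()
    items = np.minimum(rng.poisson(latent * weights), 3).astype(int)
    phq9_total = int(items.sum())
    gad7 = int(np.clip(
        round(latent * GAD7_MAX / 27 + rng.normal(0.0, model.gad7_noise_sd)),
        0, GAD7_MAX,
    ))
    gender = "male" if rng.random() < model.p_male else "female"
    age = float(np.clip(round(rng.normal(model.age_mean, model.age_sd), 1), 18.0, 80.0))
    record = SubjectRecord(
        subject_id="",
        gender=gender,
        age=age,
        gad7_total=gad7,
        phq9_total=phq9_total,
        phq9_items=tuple(int(v) for v in items),
    )
    params = model.parameters_for(phq9_total, rng)
    return record, params


def generate_recording(
    params: GaitParameters,
    duration_s: float = 120.0,
    fs_hz: float = 30.0,
    rng_seed: SeedLike = 0,
    subject_id: str = "synthetic",
) -> GaitRecording:
    """Simulate one back-and-forth walk as a 25-joint skeleton recording.

    The torso translates along Z between the footpath ends at
    ``walk_speed_mps``, reversing direction at each end; the half-second
    turning stretch is flagged invalid with unknown facing.  Limbs swing
    sinusoidally at ``cadence_hz`` as rigid rotations (arms antiphase to
    the ipsilateral leg); the upper body bobs vertically at twice the
    cadence and sways laterally at half of it.  Gaussian noise of SD
    ``noise_sd_m`` is added to every coordinate.
    """
    if duration_s <= 0:
        raise ValueError(f"duration_s must be positive, got {duration_s}")
    if fs_hz <= 0:
        raise ValueError(f"fs_hz must be positive, got {fs_hz}")
    rng = _rng(rng_seed)
    n = int(round(duration_s * fs_hz))
    t = np.arange(n) / fs_hz

    # walking timeline: front pass, turn, back pass, turn, repeat
    walk_t = FOOTPATH_LENGTH_M / params.walk_speed_mps
    cycle = 2.0 * (walk_t + TURN_DURATION_S)
    tau = t % cycle
    z_far = _Z_NEAR_M + FOOTPATH_LENGTH_M
    front = tau < walk_t
    turn1 = (tau >= walk_t) & (tau < walk_t + TURN_DURATION_S)
    back = (tau >= walk_t + TURN_DURATION_S) & (tau < 2 * walk_t + TURN_DURATION_S)
    turn2 = tau >= 2 * walk_t + TURN_DURATION_S

    z_body = np.empty(n)
    z_body[front] = z_far - params.walk_speed_mps * tau[front]
    z_body[turn1] = _Z_NEAR_M
    z_body[back] = _Z_NEAR_M + params.walk_speed_mps * (tau[back] - walk_t - TURN_DURATION_S)
    z_body[turn2] = z_far

    facing = np.full(n, FACING_UNKNOWN, dtype=np.int8)
    facing[front] = FACING_FRONT
    facing[back] = FACING_BACK
    valid = ~(turn1 | turn2)
    # body orientation: +1 facing the camera, -1 walking away
    orient = np.where(back | turn2, -1.0, 1.0)

    phase = 2.0 * math.pi * params.cadence_hz * t + rng.uniform(0.0, 2.0 * math.pi)
    swing = np.sin(phase)

    template = np.array([_TEMPLATE_OFFSETS[j] for j in JOINT_NAMES], dtype=float)
    template[_JIDX["Head"], 1] = params.head_height_m
    offsets = np.broadcast_to(template, (n, len(JOINT_NAMES), 3)).copy()

    def _rotate(joints: tuple[str, ...], pivot: str, theta: np.ndarray) -> None:
        cos_t, sin_t = np.cos(theta), np.sin(theta)
        piv = template[_JIDX[pivot]]
        for name in joints:
            rel = template[_JIDX[name]] - piv
            offsets[:, _JIDX[name], 1] = piv[1] + rel[1] * cos_t - rel[2] * sin_t
            offsets[:, _JIDX[name], 2] = piv[2] + rel[1] * sin_t + rel[2] * cos_t

    arm_theta = (params.arm_swing_m / _ARM_LENGTH_M) * swing
    leg_theta = (params.stride_amp_m / _LEG_LENGTH_M) * swing
    _rotate(_ARM_JOINTS["left"], _SHOULDER["left"], arm_theta)
    _rotate(_ARM_JOINTS["right"], _SHOULDER["right"], -arm_theta)
    _rotate(_LEG_JOINTS["left"], _HIP["left"], -leg_theta)
    _rotate(_LEG_JOINTS["right"], _HIP["right"], leg_theta)

    upper = [_JIDX[j] for j in _UPPER_BODY]
    bob = _BOB_FRACTION * params.stride_amp_m * np.cos(2.0 * phase)
    sway = params.lateral_sway_m * np.sin(0.5 * phase)
    offsets[:, upper, 1] += bob[:, None]
    offsets[:, upper, 0] += sway[:, None]

    # turn the skeleton around when walking away from the camera
    offsets[:, :, 0] *= orient[:, None]
    offsets[:, :, 2] *= orient[:, None]

    positions = offsets
    positions[:, :, 1] += SPINE_BASE_HEIGHT_M
    positions[:, :, 2] += z_body[:, None]
    if params.noise_sd_m > 0:
        positions = positions + rng.normal(0.0, params.noise_sd_m, positions.shape)

    return GaitRecording(
        subject_id=subject_id,
        fs_hz=fs_hz,
        positions=positions,
        valid=valid,
        facing=facing,
    )


def generate_cohort(
    n: int,
    model: EffectModel,
    rng_seed: SeedLike = 0,
    duration_s: float = 120.0,
    fs_hz: float = 30.0,
) -> tuple[list[SubjectRecord], list[GaitRecording]]:
    """Generate ``n`` subject/recording pairs, reproducibly for a seed."""
    subjects: list[SubjectRecord] = []
    recordings: list[GaitRecording] = []
    for record, rec in iter_cohort(n, model, rng_seed, duration_s, fs_hz):
        subjects.append(record)
        recordings.append(rec)
    return subjects, recordings


def iter_cohort(
    n: int,
    model: EffectModel,
    rng_seed: SeedLike = 0,
    duration_s: float = 120.0,
    fs_hz: float = 30.0,
):
    """Yield (SubjectRecord, GaitRecording) pairs one at a time.

    Identical draws to :func:`generate_cohort`; use this when recordings
    should not all be held in memory at once.
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    rng = _rng(rng_seed)
    seeds = rng.integers(0, 2**31, size=(n, 2))
    for i in range(n):
        record, params = generate_subject(model, int(seeds[i, 0]))
        subject_id = f"S{i + 1:04d}"
        record = replace(record, subject_id=subject_id)
        rec = generate_recording(
            params, duration_s=duration_s, fs_hz=fs_hz,
            rng_seed=int(seeds[i, 1]), subject_id=subject_id,
        )
        yield record, rec
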