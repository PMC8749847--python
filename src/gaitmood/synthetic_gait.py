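"""Class-conditioned synthetic gait generator.

Purely kinematic: a standing 16-joint pose advances along +x at a per-class
speed while limbs oscillate sinusoidally at the class's stride frequency
(left/right antiphase), the torso pitches by a class-dependent lean, and
Gaussian noise is added on every coordinate.  The four default emotion
profiles differ in cadence, amplitude, posture and speed — the exact cue
families the geometric features encode — so the classes are separable
without being copies of any real dataset.

Axes: x forward, y lateral (left positive), z up.  Units are nominal meters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .skeleton_data import (
    DEFAULT_CLASS_NAMES,
    GaitDataset,
    GaitSequence,
    SkeletonTopology,
)

# base standing pose for the default 16-joint topology, (x, y, z) per joint
_BASE_POSE = np.array([
    (0.00,  0.00, 1.00),   # root
    (0.00,  0.00, 1.25),   # spine (mid-spine reference)
    (0.00,  0.00, 1.50),   # neck
    (0.00,  0.00, 1.65),   # head
    (0.00,  0.20, 1.45),   # left_shoulder
    (0.00,  0.25, 1.20),   # left_elbow
    (0.00,  0.27, 0.95),   # left_hand
    (0.00, -0.20, 1.45),   # right_shoulder
    (0.00, -0.25, 1.20),   # right_elbow
    (0.00, -0.27, 0.95),   # right_hand
    (0.00,  0.10, 0.95),   # left_hip
    (0.00,  0.10, 0.50),   # left_knee
    (0.00,  0.10, 0.05),   # left_foot
    (0.00, -0.10, 0.95),   # right_hip
    (0.00, -0.10, 0.50),   # right_knee
    (0.00, -0.10, 0.05),   # right_foot
])

_UPPER_BODY = (1, 2, 3, 4, 5, 6, 7, 8, 9)        # pitched by torso_lean
_LEFT_ARM, _RIGHT_ARM = ((5, 6), (8, 9))          # (elbow, hand)
_LEFT_LEG, _RIGHT_LEG = ((11, 12), (14, 15))      # (knee, foot)


@dataclass(frozen=True)
class EmotionProfile:
    """Kinematic parameters for one emotion class (invented constants, tuned
    for separability — not taken from any measured dataset)."""

    emotion: str
    stride_frequency: float  # Hz
    arm_swing_amplitude: float
    step_amplitude: float
    torso_lean: float  # radians, forward pitch
    speed: float  # forward displacement per frame
    noise_sd: float

    def __post_init__(self) -> None:
        if self.stride_frequency <= 0:
            raise ConfigError("stride_frequency must be positive")
        for name in ("arm_swing_amplitude", "step_amplitude", "speed", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")

    def to_dict(self) -> dict:
        return {
            "emotion": self.emotion,
            "stride_frequency": self.stride_frequency,
            "arm_swing_amplitude": self.arm_swing_amplitude,
            "step_amplitude": self.step_amplitude,
            "torso_lean": self.torso_lean,
            "speed": self.speed,
            "noise_sd": self.noise_sd,
        }


def default_profiles() -> dict[str, EmotionProfile]:
    return {
        "angry": EmotionProfile("angry", stride_frequency=2.6,
                                arm_swing_amplitude=0.55, step_amplitude=0.55,
                                torso_lean=0.50, speed=0.040, noise_sd=0.01),
        "happy": EmotionProfile("happy", stride_frequency=1.8,
                                arm_swing_amplitude=0.35, step_amplitude=0.35,
                                torso_lean=-0.30, speed=0.028, noise_sd=0.01),
        "sad": EmotionProfile("sad", stride_frequency=0.8,
                              arm_swing_amplitude=0.03, step_amplitude=0.08,
                              torso_lean=0.90, speed=0.006, noise_sd=0.01),
        "neutral": EmotionProfile("neutral", stride_frequency=1.3,
                                  arm_swing_amplitude=0.15, step_amplitude=0.22,
                                  torso_lean=0.10, speed=0.016, noise_sd=0.01),
    }


DEFAULT_CLASS_COUNTS = (1048, 454, 254, 79)  # angry/happy/sad/neutral imbalance


def scaled_counts(counts, scale: float) -> tuple[int, ...]:
    """Scale integer class counts by largest-remainder rounding toward a
    total of floor(sum(counts) * scale)."""
    exact = [c * scale for c in counts]
    total = math.floor(sum(exact))
    base = [math.floor(e) for e in exact]
    leftover = total - sum(base)
    order = sorted(range(len(counts)), key=lambda i: -(exact[i] - base[i]))
    for i in order[:leftover]:
        base[i] += 1
    return tuple(base)


@dataclass(frozen=True)
class GeneratorConfig:
    topology: SkeletonTopology = field(default_factory=SkeletonTopology)
    n_frames: int = 240
    class_names: tuple[str, ...] = DEFAULT_CLASS_NAMES
    class_counts: tuple[int, ...] = DEFAULT_CLASS_COUNTS
    scale: float = 1.0
    profiles: dict[str, EmotionProfile] = field(default_factory=default_profiles)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ConfigError("n_frames must be >= 2")
        if len(self.class_counts) != len(self.class_names):
            raise ConfigError("class_counts must align with class_names")
        if any(c < 0 for c in self.class_counts):
            raise ConfigError("class_counts must be non-negative")
        missing = [c for c in self.class_names if c not in self.profiles]
        if missing:
            raise ConfigError(f"profiles missing for classes {missing}")

    @property
    def fps(self) -> float:
        return self.topology.fps

    def effective_counts(self) -> tuple[int, ...]:
        if self.scale == 1.0:
            return tuple(self.class_counts)
        return scaled_counts(self.class_counts, self.scale)


def generate_sequence(
    profile: EmotionProfile, gc: GeneratorConfig, seed, sequence_id: str = ""
) -> GaitSequence:
    """One synthetic gait sequence, deterministic for a given seed.

    ``seed`` may be an int or a list of ints (the dataset counter scheme).
    Per-sequence individuality: random global phase, small multiplicative
    jitter on frequency/amplitudes and additive jitter on lean.
    """
    if gc.topology.n_joints != 16 or gc.topology.n_coords != 3:
        raise ConfigError(
            "the kinematic generator is defined for the default 16-joint, "
            "3-coordinate skeleton"
        )
    rng = np.random.default_rng(seed)
    t = np.arange(gc.n_frames) / gc.fps
    freq = profile.stride_frequency * (1.0 + 0.03 * rng.standard_normal())
    arm = profile.arm_swing_amplitude * (1.0 + 0.05 * rng.standard_normal())
    step = profile.step_amplitude * (1.0 + 0.05 * rng.standard_normal())
    lean = profile.torso_lean + 0.02 * rng.standard_normal()
    phase0 = rng.uniform(0.0, 2.0 * np.pi)
    phase = 2.0 * np.pi * freq * t + phase0
    swing = np.sin(phase)
    lift = np.abs(np.sin(phase))

    coords = np.broadcast_to(_BASE_POSE, (gc.n_frames, 16, 3)).copy()

    # torso pitch about the root's height, in the x-z plane
    z_root = _BASE_POSE[0, 2]
    dz = _BASE_POSE[list(_UPPER_BODY), 2] - z_root
    coords[:, _UPPER_BODY, 0] += np.sin(lean) * dz
    coords[:, _UPPER_BODY, 2] = z_root + np.cos(lean) * dz

    # arm swing: hands full amplitude, elbows half; left/right antiphase
    for (elbow, hand), sign in ((_LEFT_ARM, 1.0), (_RIGHT_ARM, -1.0)):
        coords[:, hand, 0] += sign * arm * swing
        coords[:, elbow, 0] += sign * 0.5 * arm * swing
    # steps: feet full amplitude, knees half; legs antiphase with same-side arm
    for (knee, foot), sign in ((_LEFT_LEG, -1.0), (_RIGHT_LEG, 1.0)):
        coords[:, foot, 0] += sign * step * swing
        coords[:, knee, 0] += sign * 0.5 * step * swing
        coords[:, foot, 2] += 0.3 * step * lift

    # forward progression of the whole body
    coords[:, :, 0] += (profile.speed * np.arange(gc.n_frames))[:, None]

    if profile.noise_sd > 0:
        coords += rng.normal(0.0, profile.noise_sd, size=coords.shape)

    return GaitSequence(
        coords=coords, label=profile.emotion, sequence_id=sequence_id
    )


def generate_dataset(gc: GeneratorConfig) -> GaitDataset:
    """Full dataset with ``gc.effective_counts()`` sequences per class.

    Per-sequence seeds follow the documented counter scheme
    ``default_rng([gc.seed, class_index, counter])``.
    """
    counts = gc.effective_counts()
    if sum(counts) == 0:
        raise ConfigError("all class counts are zero; nothing to generate")
    sequences = []
    for ci, (cname, n) in enumerate(zip(gc.class_names, counts)):
        profile = gc.profiles[cname]
        for k in range(n):
            sequences.append(generate_sequence(
                profile, gc, seed=[gc.seed, ci, k],
                sequence_id=f"{cname}_{k:05d}",
            ))
    return GaitDataset(
        topology=gc.topology, sequences=sequences, class_names=gc.class_names
    )
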