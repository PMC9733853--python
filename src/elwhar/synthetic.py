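"""Synthetic cohorts of annotated wrist-accelerometer recordings.

Each of the ten electrical-line-worker tasks is emulated by a generative
profile: a static gravity orientation (the wrist posture), a sum of sinusoids
(cyclic movement such as gait or screwing), per-axis Gaussian noise
(tremor/quiver), and Poisson-timed transient impulses (jerks when a load is
caught or set down).  Subjects differ by a multiplicative amplitude scale, a
relative frequency jitter, and a small random rotation of the gravity
direction, so that models trained on some subjects face genuinely shifted
data from the others.

All randomness descends from a single master seed via ``np.random.SeedSequence``
spawning, so a cohort is a pure function of its configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal.windows import hann
from scipy.spatial.transform import Rotation

from .io import AccelRecording, AnnotationTrack
from .tasks import SESSION_ORDER, TASKS


class ConfigError(ValueError):
    """Invalid generator configuration; message names the offending field."""


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


@dataclass
class TaskProfile:
    """Generative description of one task.

    ``gravity_dir`` is the unit gravity vector in sensor coordinates (g);
    ``periodic_components`` is a list of ``(freq_hz, (ax, ay, az), phase_rad)``
    sinusoids; ``noise_sd`` is the per-axis Gaussian noise sd (g);
    ``impulse_rate`` is the expected number of transient events per second and
    ``impulse_amp`` their per-axis amplitude (g); ``duration_s`` is the task
    length in the session.
    """

    label: str
    gravity_dir: np.ndarray
    periodic_components: list[tuple[float, tuple[float, float, float], float]]
    noise_sd: tuple[float, float, float]
    impulse_rate: float
    impulse_amp: tuple[float, float, float]
    duration_s: float

    def __post_init__(self) -> None:
        if self.label not in TASKS:
            raise ConfigError(f"label: unknown task {self.label!r}")
        self.gravity_dir = np.asarray(self.gravity_dir, dtype=float)
        if abs(np.linalg.norm(self.gravity_dir) - 1.0) > 1e-9:
            raise ConfigError(f"gravity_dir: not a unit vector for {self.label!r}")
        for f, amp, _ in self.periodic_components:
            if not 0 < f < 16:
                raise ConfigError(
                    f"periodic_components: frequency {f} Hz outside (0, 16) "
                    f"for {self.label!r}"
                )
            if min(amp) < 0:
                raise ConfigError(f"periodic_components: negative amplitude for {self.label!r}")
        if min(self.noise_sd) < 0:
            raise ConfigError(f"noise_sd: negative value for {self.label!r}")
        if self.impulse_rate < 0:
            raise ConfigError(f"impulse_rate: negative value for {self.label!r}")
        if min(self.impulse_amp) < 0:
            raise ConfigError(f"impulse_amp: negative value for {self.label!r}")
        if self.duration_s <= 0:
            raise ConfigError(f"duration_s: must be positive for {self.label!r}")


@dataclass
class SubjectProfile:
    """Per-subject heterogeneity: amplitude scale, frequency jitter, and a
    small rotation (rotation vector, radians) applied to every task's gravity
    direction."""

    subject_id: str
    amp_scale: float = 1.0
    freq_jitter: float = 0.0
    orientation_rot: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.orientation_rot = np.asarray(self.orientation_rot, dtype=float)
        if self.amp_scale <= 0:
            raise ConfigError(f"amp_scale: must be positive, got {self.amp_scale}")
        if abs(self.freq_jitter) >= 0.5:
            raise ConfigError(f"freq_jitter: |{self.freq_jitter}| >= 0.5")
        if np.linalg.norm(self.orientation_rot) >= math.radians(45):
            raise ConfigError("orientation_rot: rotation angle >= 45 degrees")


# Timed tasks run 3 minutes; repetition tasks are mapped to continuous
# segments of fixed per-rep duration (9 s/rep for hoist, lift, push; 6 s/rep
# for ladder) so every task yields at least 9 windows at 10 s.
TIMED_DURATION_S = 180.0
PER_REP_S = {"hoisting": 9.0, "lifting": 9.0, "pushing": 9.0, "ladder": 6.0}
REPS = {"hoisting": 10, "lifting": 20, "pushing": 10, "ladder": 20}


def default_task_profiles() -> list[TaskProfile]:
    """The ten default task profiles.

    Postural tasks (sitting, standing, typing, electrical panel, overhead)
    get well-separated gravity orientations; gait-driven tasks (walking,
    pushing, ladder) get a dominant periodic component in the 1-2.5 Hz band;
    hoisting gets the largest noise dispersion, concentrated on the X axis,
    plus frequent impulses; the electrical-panel task concentrates both its
    static and dynamic content on the Z axis.
    """

    def dur(label: str) -> float:
        if label in PER_REP_S:
            return PER_REP_S[label] * REPS[label]
        return TIMED_DURATION_S

    profiles = [
        TaskProfile(
            label="sitting",
            gravity_dir=_unit([0.05, 0.95, 0.30]),
            periodic_components=[],
            noise_sd=(0.015, 0.015, 0.015),
            impulse_rate=0.0,
            impulse_amp=(0.0, 0.0, 0.0),
            duration_s=dur("sitting"),
        ),
        TaskProfile(
            label="standing",
            gravity_dir=_unit([0.85, 0.45, 0.15]),
            periodic_components=[],
            noise_sd=(0.02, 0.02, 0.02),
            impulse_rate=0.0,
            impulse_amp=(0.0, 0.0, 0.0),
            duration_s=dur("standing"),
        ),
        TaskProfile(
            label="typing",
            gravity_dir=_unit([0.45, 0.60, -0.60]),
            periodic_components=[(3.0, (0.04, 0.03, 0.02), 0.0)],
            noise_sd=(0.02, 0.015, 0.015),
            impulse_rate=0.0,
            impulse_amp=(0.0, 0.0, 0.0),
            duration_s=dur("typing"),
        ),
        TaskProfile(
            label="electrical_panel",
            gravity_dir=_unit([0.20, 0.25, 0.95]),
            periodic_components=[
                (1.0, (0.04, 0.05, 0.30), 0.0),
                (2.5, (0.02, 0.02, 0.12), 1.0),
            ],
            noise_sd=(0.02, 0.02, 0.06),
            impulse_rate=0.1,
            impulse_amp=(0.02, 0.02, 0.10),
            duration_s=dur("electrical_panel"),
        ),
        TaskProfile(
            label="overhead",
            gravity_dir=_unit([0.05, -0.90, 0.44]),
            periodic_components=[(1.4, (0.05, 0.05, 0.12), 0.5)],
            noise_sd=(0.03, 0.03, 0.03),
            impulse_rate=0.0,
            impulse_amp=(0.0, 0.0, 0.0),
            duration_s=dur("overhead"),
        ),
        TaskProfile(
            label="walking",
            gravity_dir=_unit([0.60, 0.75, 0.28]),
            periodic_components=[
                (2.0, (0.25, 0.35, 0.15), 0.0),
                (4.0, (0.08, 0.10, 0.05), 0.7),
            ],
            noise_sd=(0.03, 0.03, 0.03),
            impulse_rate=0.0,
            impulse_amp=(0.0, 0.0, 0.0),
            duration_s=dur("walking"),
        ),
        TaskProfile(
            label="pushing",
            gravity_dir=_unit([0.70, 0.15, 0.70]),
            periodic_components=[(1.1, (0.15, 0.10, 0.28), 0.3)],
            noise_sd=(0.04, 0.04, 0.04),
            impulse_rate=0.0,
            impulse_amp=(0.0, 0.0, 0.0),
            duration_s=dur("pushing"),
        ),
        TaskProfile(
            label="ladder",
            gravity_dir=_unit([-0.50, 0.80, 0.33]),
            periodic_components=[
                (1.7, (0.30, 0.25, 0.30), 0.0),
                (3.4, (0.10, 0.08, 0.10), 1.2),
            ],
            noise_sd=(0.05, 0.05, 0.05),
            impulse_rate=0.2,
            impulse_amp=(0.15, 0.15, 0.15),
            duration_s=dur("ladder"),
        ),
        TaskProfile(
            label="lifting",
            gravity_dir=_unit([0.30, 0.90, 0.30]),
            periodic_components=[(0.45, (0.35, 0.40, 0.20), 0.0)],
            noise_sd=(0.04, 0.04, 0.04),
            impulse_rate=0.4,
            impulse_amp=(0.30, 0.30, 0.20),
            duration_s=dur("lifting"),
        ),
        TaskProfile(
            label="hoisting",
            gravity_dir=_unit([0.55, 0.70, 0.45]),
            periodic_components=[(0.55, (0.20, 0.15, 0.10), 0.0)],
            noise_sd=(0.50, 0.15, 0.15),
            impulse_rate=1.0,
            impulse_amp=(0.50, 0.20, 0.20),
            duration_s=dur("hoisting"),
        ),
    ]
    order = {label: i for i, label in enumerate(TASKS)}
    return sorted(profiles, key=lambda p: order[p.label])


@dataclass
class CohortConfig:
    """Cohort-level generator settings (defaults mirror the lab protocol:
    37 subjects at 32 Hz, tasks in session order)."""

    n_subjects: int = 37
    task_profiles: list[TaskProfile] = field(default_factory=default_task_profiles)
    sampling_rate: float = 32.0
    master_seed: int = 0
    task_order: tuple[str, ...] = SESSION_ORDER
    # Heterogeneity distributions: amp_scale ~ LogNormal(0, amp_scale_sd),
    # freq_jitter ~ U(-j, j), rotation angle ~ U(0, max_rotation_deg).
    amp_scale_sd: float = 0.15
    freq_jitter_max: float = 0.15
    max_rotation_deg: float = 20.0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigError(
                f"n_subjects: need at least 2 for subject-wise evaluation, "
                f"got {self.n_subjects}"
            )
        labels = [p.label for p in self.task_profiles]
        if sorted(labels) != sorted(TASKS):
            raise ConfigError(
                f"task_profiles: need exactly the 10 task labels, got {sorted(labels)}"
            )
        if sorted(self.task_order) != sorted(TASKS):
            raise ConfigError("task_order: must be a permutation of the 10 labels")
        max_f = max(
            (f for p in self.task_profiles for f, _, _ in p.periodic_components),
            default=0.0,
        )
        if self.sampling_rate <= 2 * max_f:
            raise ConfigError(
                f"sampling_rate: {self.sampling_rate} Hz does not exceed twice "
                f"the maximum periodic frequency {max_f} Hz"
            )

    def profile(self, label: str) -> TaskProfile:
        for p in self.task_profiles:
            if p.label == label:
                return p
        raise KeyError(label)

    def homogeneous(self) -> "CohortConfig":
        """Copy with inter-subject heterogeneity disabled."""
        return replace(self, amp_scale_sd=0.0, freq_jitter_max=0.0, max_rotation_deg=0.0)


_IMPULSE_KERNEL = hann(5, sym=True)  # 5-sample smoothing of one-sample spikes


def _simulate_segment(
    profile: TaskProfile, subject: SubjectProfile, fs: float, rng: np.random.Generator
) -> np.ndarray:
    n = int(round(profile.duration_s * fs))
    t = np.arange(n) / fs
    rot = Rotation.from_rotvec(subject.orientation_rot)
    sig = np.tile(rot.apply(profile.gravity_dir), (n, 1))
    for f, amp, phase in profile.periodic_components:
        f_eff = f * (1.0 + subject.freq_jitter)
        phase_eff = phase + rng.uniform(0, 2 * math.pi)
        carrier = np.sin(2 * math.pi * f_eff * t + phase_eff)
        sig += subject.amp_scale * carrier[:, None] * np.asarray(amp)
    sig += rng.normal(
        0.0, subject.amp_scale * np.asarray(profile.noise_sd), size=(n, 3)
    )
    if profile.impulse_rate > 0 and max(profile.impulse_amp) > 0:
        n_events = rng.poisson(profile.impulse_rate * profile.duration_s)
        if n_events:
            spikes = np.zeros((n, 3))
            idx = rng.integers(0, n, size=n_events)
            signs = rng.choice([-1.0, 1.0], size=n_events)
            for i, s in zip(idx, signs):
                spikes[i] += s * subject.amp_scale * np.asarray(profile.impulse_amp)
            for ax in range(3):
                spikes[:, ax] = np.convolve(spikes[:, ax], _IMPULSE_KERNEL, mode="same")
            sig += spikes
    return sig


def simulate_recording(
    subject: SubjectProfile, config: CohortConfig
) -> tuple[AccelRecording, AnnotationTrack]:
    """Generate one subject's full session: all ten tasks back to back in
    ``config.task_order``, with annotations exactly tiling the samples."""
    rng = np.random.default_rng(subject.rng_seed)
    fs = config.sampling_rate
    segments, entries = [], []
    t0 = 0.0
    for label in config.task_order:
        profile = config.profile(label)
        seg = _simulate_segment(profile, subject, fs, rng)
        segments.append(seg)
        t1 = t0 + seg.shape[0] / fs
        entries.append((label, t0, t1))
        t0 = t1
    rec = AccelRecording(
        subject_id=subject.subject_id,
        sampling_rate=fs,
        samples=np.vstack(segments),
    )
    return rec, AnnotationTrack(entries=entries)


def draw_subjects(config: CohortConfig) -> list[SubjectProfile]:
    """Draw per-subject heterogeneity parameters from the cohort seed."""
    ss = np.random.SeedSequence(config.master_seed)
    children = ss.spawn(config.n_subjects)
    subjects = []
    for i, child in enumerate(children):
        seed = int(child.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(seed)
        amp = float(rng.lognormal(0.0, config.amp_scale_sd)) if config.amp_scale_sd else 1.0
        jit = (
            float(rng.uniform(-config.freq_jitter_max, config.freq_jitter_max))
            if config.freq_jitter_max
            else 0.0
        )
        if config.max_rotation_deg:
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            angle = math.radians(float(rng.uniform(0.0, config.max_rotation_deg)))
            rotvec = axis * angle
        else:
            rotvec = np.zeros(3)
        subjects.append(
            SubjectProfile(
                subject_id=f"S{i + 1:02d}",
                amp_scale=amp,
                freq_jitter=jit,
                orientation_rot=rotvec,
                rng_seed=seed,
            )
        )
    return subjects


def simulate_cohort(
    config: CohortConfig,
) -> list[tuple[AccelRecording, AnnotationTrack]]:
    """Generate the whole cohort; deterministic given ``config.master_seed``."""
    return [simulate_recording(s, config) for s in draw_subjects(config)]
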