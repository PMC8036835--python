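"""Synthetic chest motion, reference-sensor waveforms, and pediatric cohorts.

Chest displacement is modelled as two superposed tones — breathing
(default 4 mm peak) and heartbeat (default 0.3 mm peak) riding on a
baseline stand-off distance — plus optional raised-cosine body-movement
bumps and Gaussian sensor-path noise.  These magnitudes are the standard
radar-vitals literature values for a seated subject.  The clinical
reference is emulated as a 125 Hz waveform pair (an ECG-like pulse train
and a respiration sinusoid) with per-second rate readouts.

Cohorts emulate a pediatric study population (ages 0-13): vital rates
fall with age (HR ~ 150 - 6*age bpm, BR ~ 40 - 1.8*age bpm, each with
8% lognormal inter-individual spread), and height/weight follow simple
growth curves so BMI lands near the mid-teens typical of children.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import warnings

import numpy as np

from .errors import ConfigurationError
from .radar_model import RadarConfig, RadarCube, TargetEcho, max_range, synthesize_if_cube

REFERENCE_RATE_HZ = 125.0  #: clinical reference waveform sampling rate

__all__ = [
    "REFERENCE_RATE_HZ",
    "VitalProfile",
    "ChestMotionTrace",
    "ReferenceRecord",
    "ParticipantMeta",
    "generate_chest_motion",
    "generate_reference",
    "generate_cohort",
    "draw_profile_for_age",
    "generate_study",
]

# extraction default bands (Hz) used only to warn when a profile's rates
# would fall outside what the downstream filters can see
_BR_BAND = (0.1, 0.7)
_HR_BAND = (0.9, 3.0)


@dataclass
class VitalProfile:
    """Ground-truth physiological parameters for one recording."""

    breathing_rate: float  # breaths/min
    heart_rate: float      # beats/min
    breathing_amplitude: float = 4.0e-3  # m, peak
    heart_amplitude: float = 0.3e-3     # m, peak
    baseline_distance: float = 0.8      # m
    breathing_phase: float = 0.0
    heart_phase: float = 0.0
    movement_events: list = field(default_factory=list)  # (start_s, duration_s, amp_m)
    in_band: bool = True  # False when rates fall outside the extraction bands

    def __post_init__(self) -> None:
        if not (6.0 <= self.breathing_rate <= 60.0):
            raise ConfigurationError("breathing_rate outside pediatric range [6, 60] bpm")
        if not (50.0 <= self.heart_rate <= 200.0):
            raise ConfigurationError("heart_rate outside pediatric range [50, 200] bpm")
        if self.heart_amplitude >= self.breathing_amplitude and self.breathing_amplitude > 0:
            raise ConfigurationError("heart amplitude must be below breathing amplitude")
        if self.baseline_distance <= 0:
            raise ConfigurationError("baseline_distance must be positive")
        fb, fh = self.breathing_rate / 60.0, self.heart_rate / 60.0
        if not (_BR_BAND[0] <= fb <= _BR_BAND[1] and _HR_BAND[0] <= fh <= _HR_BAND[1]):
            self.in_band = False
            warnings.warn(
                "profile rates fall outside the default extraction bands",
                stacklevel=2,
            )


@dataclass
class ChestMotionTrace:
    """Displacement-vs-time signal (meters) with its provenance profile."""

    displacement: np.ndarray
    sampling_rate: float
    profile: VitalProfile


@dataclass
class ReferenceRecord:
    """Emulated clinical-sensor output: 125 Hz waveforms + per-second rates."""

    ecg_waveform: np.ndarray
    respiration_waveform: np.ndarray
    hr_series: np.ndarray  # bpm, one value per second
    br_series: np.ndarray  # bpm, one value per second
    start_time: float = 0.0


@dataclass
class ParticipantMeta:
    """One cohort member's demographic row."""

    id: int
    sex: str  # "male" | "female"
    age: float  # years
    height: float  # m
    weight: float  # kg
    bmi: float  # kg/m^2


def _movement_bump(t: np.ndarray, start: float, dur: float, amp: float) -> np.ndarray:
    """Raised-cosine displacement pulse: amp/2 * (1 - cos) over [start, start+dur]."""
    out = np.zeros_like(t)
    m = (t >= start) & (t < start + dur)
    out[m] = 0.5 * amp * (1.0 - np.cos(2.0 * np.pi * (t[m] - start) / dur))
    return out


def generate_chest_motion(
    profile: VitalProfile,
    duration: float,
    sampling_rate: float,
    noise_std: float = 0.0,
    seed: int = 0,
) -> ChestMotionTrace:
    """Two-tone chest displacement plus movement bumps and Gaussian noise.

    ``d(t) = d0 + Ab*sin(2*pi*fb*t + phi_b) + Ah*sin(2*pi*fh*t + phi_h)
    + movement pulses + noise``, deterministic under ``seed``.
    """
    if duration <= 0:
        raise ConfigurationError("duration must be positive")
    fh = profile.heart_rate / 60.0
    if sampling_rate < 2.0 * fh:
        raise ConfigurationError(
            f"sampling rate {sampling_rate} Hz below Nyquist for HR tone {fh} Hz"
        )
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    fb = profile.breathing_rate / 60.0
    d = (
        profile.baseline_distance
        + profile.breathing_amplitude * np.sin(2 * np.pi * fb * t + profile.breathing_phase)
        + profile.heart_amplitude * np.sin(2 * np.pi * fh * t + profile.heart_phase)
    )
    for start, dur, amp in profile.movement_events:
        d = d + _movement_bump(t, start, dur, amp)
    if noise_std > 0:
        d = d + np.random.default_rng(seed).normal(0.0, noise_std, n)
    return ChestMotionTrace(displacement=d, sampling_rate=sampling_rate, profile=profile)


def _ecg_template(rate: float, width: float = 0.02) -> np.ndarray:
    """Gaussian-derivative beat template (~R-wave deflection), unit peak."""
    half = int(round(4 * width * rate))
    tt = (np.arange(-half, half + 1)) / rate
    g = -tt / width ** 2 * np.exp(-tt ** 2 / (2 * width ** 2))
    return g / np.abs(g).max()


def generate_reference(
    profile: VitalProfile,
    duration: float,
    seed: int = 0,
    rate_jitter_bpm: float = 0.0,
) -> ReferenceRecord:
    """Emulated clinical waveforms and per-second rate readouts.

    The ECG channel is a pulse train with one template per beat at the
    profile heart rate; the respiration channel is a sinusoid sharing the
    chest model's breathing phase so radar and reference stay synchronous.
    """
    if duration <= 0:
        raise ConfigurationError("duration must be positive")
    fs = REFERENCE_RATE_HZ
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    fb = profile.breathing_rate / 60.0
    fh = profile.heart_rate / 60.0

    ecg = np.zeros(n)
    template = _ecg_template(fs)
    half = (len(template) - 1) // 2
    # first beat 0.1 s in so its template is not clipped by the record edge
    beat_times = np.arange(0.1, duration, 1.0 / fh)
    for bt in beat_times:
        c = int(round(bt * fs))
        lo, hi = max(0, c - half), min(n, c + half + 1)
        ecg[lo:hi] += template[half - (c - lo): half + (hi - c)]

    resp = np.sin(2 * np.pi * fb * t + profile.breathing_phase)

    n_sec = int(round(duration))
    hr_series = np.full(n_sec, profile.heart_rate)
    br_series = np.full(n_sec, profile.breathing_rate)
    if rate_jitter_bpm > 0:
        rng = np.random.default_rng(seed)
        hr_series = hr_series + rng.normal(0.0, rate_jitter_bpm, n_sec)
        br_series = br_series + rng.normal(0.0, rate_jitter_bpm, n_sec)
    return ReferenceRecord(
        ecg_waveform=ecg,
        respiration_waveform=resp,
        hr_series=hr_series,
        br_series=br_series,
    )


def _height_m(age: float) -> float:
    """Smooth pediatric growth curve: 50 cm at birth, ~85 cm at 2 y, +6 cm/y after."""
    if age < 2.0:
        return (50.0 + 17.5 * age) / 100.0
    return (85.0 + 6.0 * (age - 2.0)) / 100.0


def generate_cohort(
    n: int,
    seed: int = 0,
    sex_counts: tuple[int, int] | None = None,
) -> list[ParticipantMeta]:
    """Draw a cohort of ``n`` children with ages uniform on [0, 13).

    ``sex_counts = (n_male, n_female)`` fixes the tally exactly (order is
    shuffled); heights follow the growth curve with 4% noise and weights
    come from a BMI draw centred on 16.7 kg/m^2, so BMI is weight/height^2
    by construction.
    """
    if n < 1:
        raise ConfigurationError("cohort size must be >= 1")
    rng = np.random.default_rng(seed)
    if sex_counts is not None:
        if sum(sex_counts) != n:
            raise ConfigurationError(f"sex_counts {sex_counts} do not sum to n={n}")
        sexes = ["male"] * sex_counts[0] + ["female"] * sex_counts[1]
        rng.shuffle(sexes)
    else:
        sexes = [("male", "female")[i] for i in rng.integers(0, 2, n)]
    out = []
    for i in range(n):
        age = float(rng.uniform(0.0, 13.0))
        height = _height_m(age) * float(rng.lognormal(0.0, 0.04))
        bmi = float(np.clip(rng.normal(16.7, 1.8), 12.0, 24.0))
        weight = bmi * height ** 2
        out.append(ParticipantMeta(
            id=i + 1, sex=sexes[i], age=age,
            height=round(height, 3), weight=round(weight, 2),
            bmi=round(weight / round(height, 3) ** 2, 2),
        ))
    return out


def draw_profile_for_age(
    age: float,
    rng: np.random.Generator,
    baseline_distance: float = 0.8,
    movement_rate_per_min: float = 0.0,
    movement_amplitude: float = 0.02,
    movement_duration: float = 1.0,
    duration: float | None = None,
) -> VitalProfile:
    """Age-conditioned vital profile: younger children breathe and beat faster.

    HR = 150 - 6*age, BR = 40 - 1.8*age (bpm), each with 8% lognormal
    inter-individual spread, clipped inside the extraction bands.  Movement
    events are Poisson in time with raised-cosine bumps.
    """
    hr = float(np.clip((150.0 - 6.0 * age) * rng.lognormal(0.0, 0.08), 60.0, 175.0))
    br = float(np.clip((40.0 - 1.8 * age) * rng.lognormal(0.0, 0.08), 8.0, 40.0))
    events = []
    if movement_rate_per_min > 0 and duration is not None:
        n_ev = rng.poisson(movement_rate_per_min * duration / 60.0)
        for start in np.sort(rng.uniform(0.0, max(duration - movement_duration, 0.0), n_ev)):
            events.append((float(start), movement_duration, movement_amplitude))
    return VitalProfile(
        breathing_rate=br,
        heart_rate=hr,
        baseline_distance=baseline_distance,
        breathing_phase=float(rng.uniform(0, 2 * np.pi)),
        heart_phase=float(rng.uniform(0, 2 * np.pi)),
        movement_events=events,
    )


def generate_study(
    n_participants: int,
    config: RadarConfig,
    duration: float,
    seed: int = 0,
    root: str | Path | None = None,
    noise_std: float = 0.05,
    movement_rate_per_min: float = 2.0,
    sex_counts: tuple[int, int] | None = None,
    clutter: bool = True,
    cube_dtype: type = np.complex64,
):
    """Simulate a full cohort study and (optionally) persist it as a bundle.

    For each participant an age-conditioned profile is drawn, the chest
    motion is synthesized on the radar's slow-time grid, the IF cube is
    generated (with a static clutter echo nearer than the subject and
    complex noise of standard deviation ``noise_std``), and the reference
    record shares the same ground-truth profile and time origin.  With
    ``root`` set, everything is written through :mod:`radarvitals.dataset_io`
    and the on-disk bundle is returned; otherwise an in-memory
    :class:`~radarvitals.dataset_io.StudyData` is returned.
    """
    from .dataset_io import StudyData, write_bundle  # cycle-free at call time

    if max_range(config) <= 1.0:
        raise ConfigurationError("config max range too small for a seated subject")
    rng = np.random.default_rng(seed)
    cohort = generate_cohort(n_participants, seed=int(rng.integers(2 ** 31)),
                             sex_counts=sex_counts)
    fs_slow = float(config.frames_per_second)
    profiles, cubes, references = {}, {}, {}
    for meta in cohort:
        d0 = float(rng.uniform(0.6, 1.2))
        profile = draw_profile_for_age(
            meta.age, rng, baseline_distance=d0,
            movement_rate_per_min=movement_rate_per_min, duration=duration,
        )
        motion = generate_chest_motion(profile, duration, fs_slow)
        echoes = [TargetEcho(motion.displacement, attenuation=1.0)]
        if clutter:
            n_frames = len(motion.displacement)
            echoes.append(TargetEcho.static(
                float(rng.uniform(0.2, 0.45)), n_frames,
                attenuation=1.0, phase_offset=float(rng.uniform(0, 2 * np.pi)),
            ))
        cube = synthesize_if_cube(
            echoes, config, duration, noise_std=noise_std,
            seed=int(rng.integers(2 ** 31)), dtype=cube_dtype,
        )
        reference = generate_reference(profile, duration,
                                       seed=int(rng.integers(2 ** 31)))
        profiles[meta.id] = profile
        cubes[meta.id] = cube
        references[meta.id] = reference
    study = StudyData(config=config, duration=duration, seed=seed,
                      cohort=cohort, profiles=profiles, cubes=cubes,
                      references=references)
    if root is not None:
        return write_bundle(study, root)
    return study
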