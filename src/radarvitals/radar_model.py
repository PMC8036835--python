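"""FMCW chirp / intermediate-frequency signal model.

A frequency-modulated continuous-wave (FMCW) radar transmits chirps whose
instantaneous frequency rises linearly from ``fc`` over a bandwidth ``B``
during ``Tc`` seconds.  Mixing the received echo with the transmitted chirp
yields the complex intermediate-frequency (IF) signal

    x_IF(t) = alpha * A_T * exp(j*(2*pi*(B/Tc)*td*t + 2*pi*fc*td)),

where ``td = 2*d/c`` is the round-trip delay to a target at distance ``d``.
The first phase term is the beat frequency (distance -> frequency), the
second carries the sub-wavelength displacement used for vital signs.  The
residual video phase term (pi*(B/Tc)*td**2 plus oscillator phase noise) is
negligible at the short ranges modelled here and is dropped.

This module provides the acquisition configuration, the analytic quantities
derived from it (range resolution, maximum range, beat frequency) and a
deterministic synthesizer producing the frame x fast-time x receiver data
cube that the extraction chain consumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, DomainError, ShapeError

#: Propagation speed used throughout (m/s).
SPEED_OF_LIGHT = 3.0e8

__all__ = [
    "SPEED_OF_LIGHT",
    "RadarConfig",
    "TargetEcho",
    "RadarCube",
    "table2_config",
    "range_resolution",
    "max_range",
    "beat_frequency",
    "wavelength",
    "synthesize_if_cube",
]


@dataclass(frozen=True)
class RadarConfig:
    """FMCW acquisition parameters.

    Parameters
    ----------
    start_frequency : float
        Chirp start frequency ``fc`` in Hz.
    bandwidth : float
        Swept bandwidth ``B`` in Hz.
    chirp_duration : float
        Chirp ramp duration ``Tc`` in seconds.
    adc_rate : float
        Complex (I/Q) baseband sampling rate ``Fs`` in samples/s.
    samples_per_chirp : int
        ADC samples kept per chirp; the ADC window is the first
        ``samples_per_chirp / adc_rate`` seconds of each ramp.
    chirps_per_frame : int
        Chirps concatenated along fast time within one frame.
    frames_per_second : int
        Frame (slow-time) rate in Hz.
    n_tx, n_rx : int
        Transmit / receive channel counts.
    tx_power : float
        Transmitted amplitude scale ``A_T`` (dimensionless).
    """

    start_frequency: float
    bandwidth: float
    chirp_duration: float
    adc_rate: float
    samples_per_chirp: int = 256
    chirps_per_frame: int = 1
    frames_per_second: int = 20
    n_tx: int = 1
    n_rx: int = 1
    tx_power: float = 1.0

    def __post_init__(self) -> None:
        for name in ("start_frequency", "bandwidth", "chirp_duration", "adc_rate"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("samples_per_chirp", "chirps_per_frame", "frames_per_second",
                     "n_tx", "n_rx"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ConfigurationError(f"{name} must be a positive integer")
        if self.tx_power <= 0:
            raise ConfigurationError("tx_power must be positive")
        if self.samples_per_chirp > int(np.floor(self.adc_rate * self.chirp_duration)):
            raise ConfigurationError(
                "samples_per_chirp exceeds the number of ADC samples that fit in "
                f"one chirp (floor(Fs*Tc) = {int(self.adc_rate * self.chirp_duration)})"
            )

    @property
    def samples_per_frame(self) -> int:
        """Fast-time samples in one frame (chirps concatenated)."""
        return self.samples_per_chirp * self.chirps_per_frame

    def to_json(self, path: str | Path | None = None) -> str:
        """Serialize to a JSON object keyed by the field names."""
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RadarConfig":
        """Load from a JSON string or file path produced by :meth:`to_json`."""
        p = Path(source) if not str(source).lstrip().startswith("{") else None
        text = p.read_text() if p is not None else str(source)
        return cls(**json.loads(text))


def table2_config() -> RadarConfig:
    """The vital-sign acquisition preset: 60.25 GHz start, 3.75 GHz sweep,
    3 Msps ADC, 91.72 us chirps, 2 chirps/frame at 20 fps, 1 Tx / 4 Rx."""
    return RadarConfig(
        start_frequency=60.25e9,
        bandwidth=3.75e9,
        chirp_duration=91.72e-6,
        adc_rate=3.0e6,
        samples_per_chirp=256,
        chirps_per_frame=2,
        frames_per_second=20,
        n_tx=1,
        n_rx=4,
        tx_power=1.0,
    )


@dataclass
class TargetEcho:
    """One point reflector with a (possibly moving) range trace.

    ``distance_trace`` is sampled on the slow-time grid, one value per frame
    (stop-and-hop: the target is frozen within a frame).  ``attenuation`` is
    the two-way amplitude loss alpha in (0, 1]; ``phase_offset`` an extra
    constant phase in radians.
    """

    distance_trace: np.ndarray
    attenuation: float = 1.0
    phase_offset: float = 0.0

    def __post_init__(self) -> None:
        self.distance_trace = np.asarray(self.distance_trace, dtype=float)
        if self.attenuation <= 0 or self.attenuation > 1:
            raise DomainError("attenuation must lie in (0, 1]")

    @classmethod
    def static(cls, distance: float, n_frames: int, attenuation: float = 1.0,
               phase_offset: float = 0.0) -> "TargetEcho":
        """A motionless reflector at a fixed distance."""
        return cls(np.full(n_frames, float(distance)), attenuation, phase_offset)


@dataclass
class RadarCube:
    """Complex IF samples: [n_frames x samples_per_frame x n_rx]."""

    data: np.ndarray
    config: RadarConfig
    start_time: float = 0.0

    def __post_init__(self) -> None:
        d = np.asarray(self.data)
        if d.ndim != 3:
            raise ShapeError("cube data must have 3 axes (frame, fast time, rx)")
        if d.shape[1] != self.config.samples_per_frame or d.shape[2] != self.config.n_rx:
            raise ShapeError(
                f"cube shape {d.shape} inconsistent with config "
                f"(expected [*, {self.config.samples_per_frame}, {self.config.n_rx}])"
            )
        self.data = d

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        """Seconds of slow time covered."""
        return self.n_frames / self.config.frames_per_second


def range_resolution(config: RadarConfig) -> float:
    """Range-bin width ``c / (2B)`` in meters."""
    if config.bandwidth <= 0:
        raise ConfigurationError("bandwidth must be positive")
    return SPEED_OF_LIGHT / (2.0 * config.bandwidth)


def max_range(config: RadarConfig) -> float:
    """Maximum unambiguous range ``Fs * c * Tc / (2B)`` for complex sampling."""
    return config.adc_rate * SPEED_OF_LIGHT * config.chirp_duration / (2.0 * config.bandwidth)


def wavelength(config: RadarConfig) -> float:
    """Carrier wavelength ``c / fc`` in meters (~5 mm at 60 GHz)."""
    return SPEED_OF_LIGHT / config.start_frequency


def beat_frequency(distance: float, config: RadarConfig) -> float:
    """Beat (IF) frequency ``2*B*d / (Tc*c)`` of a target at ``distance`` meters."""
    if distance < 0 or distance > max_range(config):
        raise DomainError(
            f"distance {distance} m outside [0, {max_range(config):.3f}] m"
        )
    return 2.0 * config.bandwidth * distance / (config.chirp_duration * SPEED_OF_LIGHT)


def synthesize_if_cube(
    echoes: Sequence[TargetEcho],
    config: RadarConfig,
    duration: float,
    noise_std: float = 0.0,
    seed: int = 0,
    start_time: float = 0.0,
    dtype: type = np.complex128,
) -> RadarCube:
    """Synthesize the IF data cube for a set of point echoes.

    For frame ``k`` and fast-time instant ``t`` inside a chirp the sample is

        sum_targets alpha * A_T * exp(j*(2*pi*(B/Tc)*td_k*t + 2*pi*fc*td_k))

    with ``td_k = 2*d_k/c`` frozen within the frame.  All receivers carry the
    same deterministic signal; noise is circularly symmetric complex Gaussian
    with total standard deviation ``noise_std``, drawn independently per
    sample and per receiver.  Identical seeds give identical cubes.
    """
    if noise_std < 0:
        raise ConfigurationError("noise_std must be non-negative")
    n_frames = int(round(duration * config.frames_per_second))
    if n_frames < 1:
        raise ConfigurationError("duration shorter than one frame")
    dmax = max_range(config)
    for echo in echoes:
        if len(echo.distance_trace) != n_frames:
            raise ShapeError(
                f"distance trace length {len(echo.distance_trace)} != {n_frames} frames"
            )
        if np.any(echo.distance_trace <= 0) or np.any(echo.distance_trace > dmax):
            raise DomainError("echo distance outside (0, max_range]")

    # fast-time grid of one frame: the ADC window restarts at each chirp ramp
    t_chirp = np.arange(config.samples_per_chirp) / config.adc_rate
    t_frame = np.tile(t_chirp, config.chirps_per_frame)  # (samples_per_frame,)

    slope = config.bandwidth / config.chirp_duration
    signal = np.zeros((n_frames, config.samples_per_frame), dtype=np.complex128)
    for echo in echoes:
        td = 2.0 * echo.distance_trace / SPEED_OF_LIGHT  # (n_frames,)
        phase = (
            2.0 * np.pi * slope * td[:, None] * t_frame[None, :]
            + 2.0 * np.pi * config.start_frequency * td[:, None]
            + echo.phase_offset
        )
        signal += echo.attenuation * config.tx_power * np.exp(1j * phase)

    data = np.repeat(signal[:, :, None], config.n_rx, axis=2)
    if noise_std > 0:
        rng = np.random.default_rng(seed)
        shape = data.shape
        scale = noise_std / np.sqrt(2.0)
        data = data + scale * (
            rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        )
    return RadarCube(data.astype(dtype, copy=False), config, start_time=start_time)
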