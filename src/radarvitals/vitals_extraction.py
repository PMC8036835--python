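"""Heart- and breathing-rate extraction from an IF data cube.

The chain mirrors contactless vital-sign practice at 60 GHz:

1. range-FFT each frame's fast-time samples -> slow-time x range matrix;
2. pick the range bin with the largest slow-time magnitude variance
   (a breathing chest modulates its bin far more than static clutter);
3. unwrap the phase of that bin's slow-time series and convert to chest
   displacement via ``delta_d = lambda * delta_phi / (4*pi)``;
4. split the displacement into breathing (0.1-0.7 Hz) and heartbeat
   (0.9-3 Hz) components with zero-phase Butterworth bandpass filters;
5. per sliding window, read each rate off the in-band spectral peak
   (zero-padded FFT with quadratic peak interpolation);
6. flag windows whose out-of-band displacement energy (body-movement
   index) exceeds a threshold: gross motion swamps the millimetre-scale
   vital modulation, so rates there are reported invalid.

The range transform is zero-padded to the nominal chirp length
``round(Fs*Tc)`` so bins are spaced one range resolution ``c/(2B)`` apart
regardless of how many ADC samples the acquisition keeps per chirp.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError, NoMotionDetected, ShapeError
from .radar_model import RadarConfig, RadarCube, range_resolution, wavelength

__all__ = [
    "RangeProfileMatrix",
    "ExtractionConfig",
    "VitalsEstimate",
    "range_fft",
    "detect_subject_bin",
    "extract_displacement",
    "bandpass",
    "estimate_rate",
    "movement_index",
    "extract_vitals",
]


@dataclass
class RangeProfileMatrix:
    """Complex range profiles, one row per frame.

    ``profiles[k, b]`` is the range-FFT of frame ``k`` at bin ``b``; bin ``b``
    maps to distance ``b * bin_width``.
    """

    profiles: np.ndarray
    bin_width: float
    config: RadarConfig

    @property
    def n_frames(self) -> int:
        return self.profiles.shape[0]

    @property
    def n_bins(self) -> int:
        return self.profiles.shape[1]


@dataclass(frozen=True)
class ExtractionConfig:
    """Processing parameters for the extraction chain.

    Band edges are pediatric defaults: breathing up to ~40 breaths/min and
    heart rate up to ~180 bpm; the bands must be disjoint so the dual-filter
    split is well defined.  ``movement_threshold`` applies to the body-
    movement index (out-of-band chest velocity as a fraction of the phase
    tracking limit, see :func:`movement_index`); windows above it are
    flagged invalid.
    """

    br_band: tuple[float, float] = (0.1, 0.7)
    hr_band: tuple[float, float] = (0.9, 3.0)
    window_length: float = 15.0
    window_stride: float = 1.0
    fft_window: str = "hann"
    movement_threshold: float = 0.2
    zero_pad_factor: int = 8
    filter_order: int = 4
    rx_index: int = 0
    chirp_index: int = 0
    average_rx: bool = False

    def __post_init__(self) -> None:
        bl, bh = self.br_band
        hl, hh = self.hr_band
        if not (0 < bl < bh <= hl < hh):
            raise ConfigurationError(
                "bands must satisfy 0 < br_low < br_high <= hr_low < hr_high"
            )
        if self.window_length <= 0 or self.window_stride <= 0:
            raise ConfigurationError("window length and stride must be positive")

    def to_json(self, path: str | Path | None = None) -> str:
        d = asdict(self)
        d["br_band"] = list(d["br_band"])
        d["hr_band"] = list(d["hr_band"])
        text = json.dumps(d, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ExtractionConfig":
        p = Path(source) if not str(source).lstrip().startswith("{") else None
        text = p.read_text() if p is not None else str(source)
        d = json.loads(text)
        d["br_band"] = tuple(d["br_band"])
        d["hr_band"] = tuple(d["hr_band"])
        return cls(**d)


@dataclass
class VitalsEstimate:
    """Windowed rate estimates plus the body-movement index.

    ``valid[i]`` is False where the movement index exceeded the threshold;
    ``hr``/``br`` are NaN there.  ``displacement`` is the full slow-time
    chest-displacement trace (meters) the rates were read from.
    """

    times: np.ndarray
    hr: np.ndarray
    br: np.ndarray
    movement_index: np.ndarray
    valid: np.ndarray
    selected_bin: int
    displacement: np.ndarray
    slow_time_rate: float


def range_fft(
    cube: RadarCube,
    rx_index: int = 0,
    chirp_index: int = 0,
    taper: str | None = None,
    average_rx: bool = False,
) -> RangeProfileMatrix:
    """Per-frame fast-time FFT of one chirp/receiver after DC removal.

    The transform length is ``round(Fs*Tc)`` (zero-padding the kept ADC
    window up to the nominal chirp length) so that bin spacing equals the
    range resolution.  ``average_rx`` coherently averages all receivers
    before the transform instead of selecting one.
    """
    cfg = cube.config
    if not (0 <= rx_index < cfg.n_rx):
        raise ShapeError(f"rx_index {rx_index} out of range [0, {cfg.n_rx})")
    if not (0 <= chirp_index < cfg.chirps_per_frame):
        raise ShapeError(f"chirp_index {chirp_index} out of range")
    lo = chirp_index * cfg.samples_per_chirp
    sl = cube.data[:, lo:lo + cfg.samples_per_chirp, :]
    x = sl.mean(axis=2) if average_rx else sl[:, :, rx_index]
    x = np.asarray(x, dtype=np.complex128)
    x = x - x.mean(axis=1, keepdims=True)  # per-frame DC removal
    if taper is not None:
        x = x * sps.get_window(taper, cfg.samples_per_chirp)[None, :]
    n_fft = max(cfg.samples_per_chirp, int(round(cfg.adc_rate * cfg.chirp_duration)))
    profiles = np.fft.fft(x, n=n_fft, axis=1)
    bin_width = cfg.adc_rate * cfg.chirp_duration / n_fft * range_resolution(cfg)
    return RangeProfileMatrix(profiles=profiles, bin_width=bin_width, config=cfg)


def detect_subject_bin(
    rpm: RangeProfileMatrix,
    search_range: tuple[float, float] | None = None,
) -> int:
    """Bin index with the largest slow-time variance of the profile magnitude.

    A static reflector, however strong, contributes a constant complex value
    whose slow-time variance is zero; the chest's vibration rotates its bin's
    phasor through large angles (4*pi*Ab/lambda >> 1 at 60 GHz), so the
    variance of the complex slow-time series is maximal at the subject's bin.
    Variance is taken on the complex values, not the magnitude: magnitude
    variance peaks on the response-kernel flank one bin off the target, where
    the phase is unusable.  Ties break toward the nearer bin.  Raises
    :class:`NoMotionDetected` when no bin varies.
    """
    mags = np.abs(rpm.profiles)
    centered = rpm.profiles - rpm.profiles.mean(axis=0, keepdims=True)
    var = np.mean(np.abs(centered) ** 2, axis=0)
    lo_bin, hi_bin = 0, rpm.n_bins - 1
    if search_range is not None:
        lo_m, hi_m = search_range
        if lo_m < 0 or hi_m < lo_m:
            raise ConfigurationError("invalid search range")
        lo_bin = int(np.ceil(lo_m / rpm.bin_width))
        hi_bin = min(int(np.floor(hi_m / rpm.bin_width)), rpm.n_bins - 1)
        if lo_bin > hi_bin:
            raise ConfigurationError("search range contains no bins")
    window = var[lo_bin:hi_bin + 1]
    scale = float(np.mean(mags ** 2))
    if window.max() <= max(scale, 1.0) * 1e-24:
        raise NoMotionDetected("no range bin shows slow-time variance")
    return lo_bin + int(np.argmax(window))  # argmax takes first (nearer) on ties


def extract_displacement(
    rpm: RangeProfileMatrix,
    bin_index: int,
    config: RadarConfig | None = None,
) -> np.ndarray:
    """Chest displacement (meters, mean-removed) from one bin's phase history.

    The slow-time phase of the selected bin advances by ``4*pi*delta_d/lambda``
    per unit displacement; unwrapping tolerates excursions beyond lambda/4.
    """
    cfg = config if config is not None else rpm.config
    if not (0 <= bin_index < rpm.n_bins):
        raise ShapeError(f"bin {bin_index} out of range [0, {rpm.n_bins})")
    series = rpm.profiles[:, bin_index]
    phase = np.unwrap(np.angle(series))
    disp = wavelength(cfg) * phase / (4.0 * np.pi)
    return disp - disp.mean()


def bandpass(
    x: np.ndarray,
    band: tuple[float, float],
    rate: float,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth bandpass; output length equals input length."""
    lo, hi = band
    nyq = rate / 2.0
    if not (0 < lo < hi < nyq):
        raise ConfigurationError(f"band {band} outside (0, {nyq}) Hz")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=rate, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def _window_slices(n: int, rate: float, length: float, stride: float):
    """(start, stop, center_time) triples for the sliding analysis windows."""
    win = int(round(length * rate))
    hop = int(round(stride * rate))
    if win > n:
        raise ConfigurationError(
            f"window of {length} s ({win} samples) longer than signal ({n} samples)"
        )
    out = []
    start = 0
    while start + win <= n:
        out.append((start, start + win, (start + win / 2.0) / rate))
        start += hop
    return out


def _spectral_peak_bpm(x: np.ndarray, rate: float, band: tuple[float, float],
                       taper: str, pad: int) -> float:
    """Frequency (in bpm) of the in-band magnitude-spectrum maximum.

    Quadratic interpolation of log-magnitude around the peak gives sub-bin
    resolution well below the window's nominal 60/T bpm grid.
    """
    n = len(x)
    w = sps.get_window(taper, n)
    n_fft = int(2 ** np.ceil(np.log2(n * max(pad, 1))))
    spec = np.abs(np.fft.rfft((x - x.mean()) * w, n=n_fft))
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / rate)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    idx = np.flatnonzero(in_band)
    k = idx[int(np.argmax(spec[idx]))]
    f = freqs[k]
    if 0 < k < len(spec) - 1 and spec[k] > 0:
        with np.errstate(divide="ignore"):
            a, b, c = np.log(np.maximum(spec[k - 1:k + 2], 1e-300))
        denom = a - 2 * b + c
        if denom < 0:
            delta = 0.5 * (a - c) / denom
            f = f + np.clip(delta, -1, 1) * rate / n_fft
    return 60.0 * float(f)


def estimate_rate(
    x: np.ndarray,
    rate: float,
    band: tuple[float, float],
    econfig: ExtractionConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Windowed spectral-peak rate estimate.

    Returns ``(times, bpm)``: window-center times and one bpm value per
    window, each the in-band peak of the zero-padded, tapered spectrum.
    """
    ec = econfig if econfig is not None else ExtractionConfig()
    x = np.asarray(x, dtype=float)
    slices = _window_slices(len(x), rate, ec.window_length, ec.window_stride)
    times = np.array([t for _, _, t in slices])
    bpm = np.array([
        _spectral_peak_bpm(x[a:b], rate, band, ec.fft_window, ec.zero_pad_factor)
        for a, b, _ in slices
    ])
    return times, bpm


def _out_of_band_residual(x: np.ndarray, rate: float,
                          ec: ExtractionConfig) -> np.ndarray:
    """Displacement with the breathing and heartbeat bands spectrally removed.

    Masking the full-record FFT (both band images) avoids the boundary
    transients a time-domain zero-phase filter leaves at the record edges.
    """
    n = len(x)
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    for lo, hi in (ec.br_band, ec.hr_band):
        spec[(freqs >= lo) & (freqs <= hi)] = 0.0
    return np.fft.irfft(spec, n=n)


def movement_index(
    displacement: np.ndarray,
    rate: float,
    econfig: ExtractionConfig | None = None,
    carrier_wavelength: float = 5.0e-3,
    burst_window: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Windowed body-movement index.

    Gross body motion is transient and broadband, so the index looks at the
    chest *velocity* (per-sample displacement increments) outside the
    breathing/heartbeat bands and takes, within each analysis window, the
    maximum short-time (``burst_window`` seconds) RMS of that residual.
    Working on increments rather than the displacement itself matters for
    radar-derived traces: motion faster than a quarter wavelength per frame
    aliases the phase and leaves permanent half-wavelength steps in the
    unwrapped displacement, which would smear displacement-domain energy
    over the whole record, while the increment domain keeps the burst local.

    The RMS is normalized by the fastest unambiguously trackable chest
    velocity, ``lambda/4 * rate``: an index near 1 means motion at the phase
    tracking limit, where rate estimates are meaningless, while pure in-band
    vitals give ~0.  The short-time maximum keeps a brief movement burst
    from being diluted by the much longer rate-estimation window.  Returns
    ``(times, index)`` on the same window grid as the rates.
    """
    ec = econfig if econfig is not None else ExtractionConfig()
    x = np.asarray(displacement, dtype=float)
    velocity = np.diff(x, prepend=x[:1]) * rate
    resid = _out_of_band_residual(velocity, rate, ec)
    m = max(int(round(burst_window * rate)), 1)
    # centered moving RMS over the burst window
    power = np.convolve(resid ** 2, np.ones(m) / m, mode="same")
    short_rms = np.sqrt(np.maximum(power, 0.0))
    v_max = carrier_wavelength / 4.0 * rate
    slices = _window_slices(len(x), rate, ec.window_length, ec.window_stride)
    times = np.array([t for _, _, t in slices])
    idx = np.array([short_rms[a:b].max() / v_max for a, b, _ in slices])
    return times, idx


def extract_vitals(cube: RadarCube, econfig: ExtractionConfig | None = None) -> VitalsEstimate:
    """Run the full extraction chain on a cube.

    Windows whose movement index exceeds ``movement_threshold`` carry NaN
    rates and ``valid=False``: vital signs are only trusted while the body
    is at rest.
    """
    ec = econfig if econfig is not None else ExtractionConfig()
    cfg = cube.config
    fs_slow = float(cfg.frames_per_second)
    if fs_slow / 2.0 <= ec.hr_band[1]:
        raise ConfigurationError(
            "slow-time rate too low for the heart-rate band (Nyquist violated)"
        )
    rpm = range_fft(cube, rx_index=ec.rx_index, chirp_index=ec.chirp_index,
                    average_rx=ec.average_rx)
    sel = detect_subject_bin(rpm)
    disp = extract_displacement(rpm, sel, cfg)
    br_sig = bandpass(disp, ec.br_band, fs_slow, ec.filter_order)
    hr_sig = bandpass(disp, ec.hr_band, fs_slow, ec.filter_order)
    times, br = estimate_rate(br_sig, fs_slow, ec.br_band, ec)
    _, hr = estimate_rate(hr_sig, fs_slow, ec.hr_band, ec)
    _, mov = movement_index(disp, fs_slow, ec, carrier_wavelength=wavelength(cfg))
    valid = mov <= ec.movement_threshold
    hr = np.where(valid, hr, np.nan)
    br = np.where(valid, br, np.nan)
    return VitalsEstimate(
        times=times + cube.start_time,
        hr=hr,
        br=br,
        movement_index=mov,
        valid=valid,
        selected_bin=sel,
        displacement=disp,
        slow_time_rate=fs_slow,
    )
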